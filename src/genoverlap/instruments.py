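"""Published GWAS instruments for the bidirectional smoking-caffeine MR.

The caffeine-use risk score sums the coffee-consumption-increasing allele
dosages of eight genome-wide-significant SNPs from the Cornelis et al. (2015)
coffee GWAS meta-analysis, each weighted by its published effect size (beta
per risk allele, cups-of-coffee scale).  Smoking heaviness is instrumented by
rs1051730 (CHRNA3), the TAG consortium's cigarettes-per-day hit.

Risk-allele frequencies are the values observed in the Dutch twin cohort and
are used as generator defaults for synthetic cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SNPWeight", "RiskScoreWeights", "coffee_score_weights", "smoking_snp", "METABOLISM_ONLY_IDS"]


@dataclass(frozen=True)
class SNPWeight:
    snp_id: str
    gene: str
    risk_allele: str
    nonrisk_allele: str
    weight: float
    raf: float  # risk-allele frequency


_COFFEE = (
    SNPWeight("rs1260326", "GCKR", "C", "T", 0.04, 0.63),
    SNPWeight("rs1481012", "ABCG2", "A", "G", 0.06, 0.89),
    SNPWeight("rs6968554", "AHR", "G", "A", 0.13, 0.64),
    SNPWeight("rs7800944", "MLXIPL", "C", "T", 0.05, 0.27),
    SNPWeight("rs17685", "POR", "A", "G", 0.07, 0.26),
    SNPWeight("rs6265", "BDNF", "C", "T", 0.05, 0.80),
    SNPWeight("rs2472297", "CYP1A1", "T", "C", 0.15, 0.27),
    SNPWeight("rs9902453", "EFCAB5", "G", "A", 0.04, 0.49),
)

_SMOKING = SNPWeight("rs1051730", "CHRNA3", "A", "G", 1.03, 0.32)

#: the two caffeine-metabolism loci (AHR, CYP1A1) used for the
#: pleiotropy-sensitivity score
METABOLISM_ONLY_IDS = ("rs6968554", "rs2472297")


class RiskScoreWeights:
    """An ordered set of SNP weights defining a weighted allele score."""

    def __init__(self, entries):
        entries = tuple(entries)
        ids = [e.snp_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids in risk score weights")
        if any(e.weight <= 0 for e in entries):
            raise ValueError("risk-score weights must be positive")
        self.entries = entries

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def snp_ids(self):
        return tuple(e.snp_id for e in self.entries)

    @property
    def weights(self):
        return {e.snp_id: e.weight for e in self.entries}

    def subset(self, snp_ids) -> "RiskScoreWeights":
        keep = set(snp_ids)
        missing = keep - set(self.snp_ids)
        if missing:
            raise KeyError(f"unknown SNP ids: {sorted(missing)}")
        return RiskScoreWeights(e for e in self.entries if e.snp_id in keep)


def coffee_score_weights(metabolism_only: bool = False) -> RiskScoreWeights:
    """The eight-SNP caffeine-use score (or its two-SNP metabolism-only
    sensitivity variant)."""
    w = RiskScoreWeights(_COFFEE)
    return w.subset(METABOLISM_ONLY_IDS) if metabolism_only else w


def smoking_snp() -> SNPWeight:
    """The smoking-heaviness instrument rs1051730 (beta 1.03 cigarettes/day
    per A allele)."""
    return _SMOKING
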