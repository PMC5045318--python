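"""Synthetic data with the exact statistical structure the three analysis
stages assume: twin pairs under a bivariate ACE liability model, GWAS
summary-statistics pairs under the LD-score moment model, and individual-
level MR cohorts with configurable causal and confounding effects.

Every generator is bit-reproducible given its seed.  Defaults reflect the
motivating smoking-caffeine study: twin group sizes and age mix of a large
Dutch twin cohort, GWAS sample sizes of the TAG smoking and Cornelis coffee
meta-analyses, and instrument set-points matching the published first-stage
effects (86.7 mg caffeine/day per unit score, 0.6 cigarettes/day per risk
allele).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instruments import RiskScoreWeights, coffee_score_weights, smoking_snp
from .ldsc import SumstatsTable
from .mr import MRCohort
from .twin_model import (
    GROUP_INFO,
    N_AGE_BANDS,
    ZYGOSITY_GROUPS,
    ACEBivariateParams,
    ThresholdSpec,
    TwinPairRecord,
)

__all__ = [
    "TwinDesign",
    "SumstatsSimSpec",
    "MRSimSpec",
    "simulate_twin_sample",
    "simulate_sumstats_pair",
    "simulate_mr_cohort",
    "default_twin_truth",
]

logger = logging.getLogger(__name__)

#: age-band mix of the motivating twin sample (<20 ... >=55)
DEFAULT_AGE_PROBS = (0.116, 0.301, 0.223, 0.182, 0.070, 0.108)

#: complete-pair counts by zygosity group, scaled from the cohort's twin
#: counts to ~1700 MZ + ~2700 DZ pairs (the smoking-coffee analysis scale)
DEFAULT_PAIRS_COFFEE = {"MZM": 490, "MZF": 1210, "DZM": 450, "DZF": 975, "DOS": 1275}
#: smaller sample of the smoking-total-caffeine analysis (~1300 MZ + ~2100 DZ)
DEFAULT_PAIRS_CAFFEINE = {"MZM": 360, "MZF": 940, "DZM": 340, "DZF": 750, "DOS": 1010}


@dataclass
class TwinDesign:
    """Sampling design of a twin study: complete-pair counts per zygosity
    group, a fraction of pairs with one twin unobserved, and the age-band
    mix."""

    n_pairs_by_group: dict = field(default_factory=lambda: dict(DEFAULT_PAIRS_COFFEE))
    incomplete_fraction: float = 0.0
    age_category_probs: tuple = DEFAULT_AGE_PROBS
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.n_pairs_by_group) - set(ZYGOSITY_GROUPS)
        if unknown:
            raise ValueError(f"unknown zygosity group(s): {sorted(unknown)}")
        if any(v < 0 for v in self.n_pairs_by_group.values()):
            raise ValueError("pair counts must be non-negative")
        p = np.asarray(self.age_category_probs, dtype=float)
        if p.shape != (N_AGE_BANDS,) or abs(p.sum() - 1.0) > 1e-12 or p.min() < 0:
            raise ValueError("age_category_probs must be a length-6 probability vector")
        if not 0.0 <= self.incomplete_fraction < 1.0:
            raise ValueError("incomplete_fraction must be in [0, 1)")


def default_twin_truth(variant: str = "coffee"):
    """Generating truth for twin simulations: the best-fitting AE estimates
    and thresholds hitting realistic prevalences (~25% current smoking;
    ~17% high coffee use or ~15% high total caffeine), with mild sex and
    age moderation of the thresholds.

    Returns ``(params, thresholds, design)``.
    """
    if variant == "coffee":
        params = ACEBivariateParams.from_shares(A1=0.76, A2=0.53, rA=0.47, rE=0.30)
        prev = np.array([[0.28, 0.23], [0.19, 0.15]])  # [trait, sex(M,F)]
        design = TwinDesign(dict(DEFAULT_PAIRS_COFFEE))
    elif variant == "caffeine":
        params = ACEBivariateParams.from_shares(A1=0.74, A2=0.49, rA=0.44, rE=0.0)
        prev = np.array([[0.28, 0.23], [0.16, 0.14]])
        design = TwinDesign(dict(DEFAULT_PAIRS_CAFFEINE))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    beta_age = np.array([[0.04, 0.04], [-0.06, -0.06]])  # smoking down, caffeine up with age
    thresholds = ThresholdSpec.from_prevalence(prev, beta_age=beta_age, at_band=2.0)
    return params, thresholds, design


def simulate_twin_sample(
    params: ACEBivariateParams,
    thresholds: ThresholdSpec,
    design: TwinDesign,
    rng: np.random.Generator | None = None,
):
    """Draw twin pairs under the liability model.

    Additive-genetic factor scores correlate 1 across MZ and 0.5 across DZ
    co-twins, common-environment scores correlate 1 in both, and unique-
    environment scores are twin-specific; liabilities combine the factors
    through the Cholesky loadings and are binarized at the sex- and
    age-specific cutpoints.
    """
    params.validate(atol=1e-6, require_e=False)
    rng = np.random.default_rng(design.seed) if rng is None else rng
    records = []
    fam = 0
    for group in ZYGOSITY_GROUPS:
        n = int(design.n_pairs_by_group.get(group, 0))
        if n == 0:
            continue
        zclass, s1, s2 = GROUP_INFO[group]
        w = 1.0 if zclass == "MZ" else 0.5
        # factor scores: columns (A1, A2, C1, C2, E1, E2) per twin
        shared_a = rng.standard_normal((n, 2))
        a_t1 = np.sqrt(w) * shared_a + np.sqrt(1 - w) * rng.standard_normal((n, 2))
        a_t2 = np.sqrt(w) * shared_a + np.sqrt(1 - w) * rng.standard_normal((n, 2))
        c = rng.standard_normal((n, 2))
        e_t1 = rng.standard_normal((n, 2))
        e_t2 = rng.standard_normal((n, 2))

        def liabilities(a, e):
            l1 = params.a11 * a[:, 0] + params.c11 * c[:, 0] + params.e11 * e[:, 0]
            l2 = (params.a21 * a[:, 0] + params.a22 * a[:, 1]
                  + params.c21 * c[:, 0] + params.c22 * c[:, 1]
                  + params.e21 * e[:, 0] + params.e22 * e[:, 1])
            return np.column_stack([l1, l2])

        lia1 = liabilities(a_t1, e_t1)
        lia2 = liabilities(a_t2, e_t2)
        bands = rng.choice(N_AGE_BANDS, size=n, p=np.asarray(design.age_category_probs))
        # DOS: randomize which twin is the male
        if group == "DOS":
            male_first = rng.random(n) < 0.5
        else:
            male_first = np.ones(n, dtype=bool)
        incomplete = rng.random(n) < design.incomplete_fraction
        drop_t2 = rng.random(n) < 0.5  # which twin goes missing
        for i in range(n):
            sx1, sx2 = ("M", "F")[s1], ("M", "F")[s2]
            l1, l2 = lia1[i], lia2[i]
            if group == "DOS" and not male_first[i]:
                sx1, sx2 = sx2, sx1
            si1 = 0 if sx1 == "M" else 1
            si2 = 0 if sx2 == "M" else 1
            b = int(bands[i])
            y1 = [int(l1[t] > thresholds.threshold(t, si1, b)) for t in range(2)]
            y2 = [int(l2[t] > thresholds.threshold(t, si2, b)) for t in range(2)]
            if incomplete[i]:
                if drop_t2[i]:
                    y2 = [None, None]
                else:
                    y1 = [None, None]
            records.append(
                TwinPairRecord(
                    family_id=f"fam{fam:06d}", zygosity_group=group, age_band=b,
                    sex_t1=sx1, sex_t2=sx2,
                    pheno1_t1=y1[0], pheno2_t1=y1[1],
                    pheno1_t2=y2[0], pheno2_t2=y2[1],
                )
            )
            fam += 1
    return records


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------


@dataclass
class SumstatsSimSpec:
    """Ground truth of a pair of GWAS summary-statistics tables under the
    LD-score moment model.

    Defaults use the sample sizes of the TAG smoking (N=46 481) and Cornelis
    coffee (N=91 462) meta-analyses with 50 000 SNPs.
    """

    n_snps: int = 50_000
    h2_trait1: float = 0.3
    h2_trait2: float = 0.3
    rg_true: float = 0.44
    n1: int = 46_481
    n2: int = 91_462
    n_overlap: int = 0
    rho_pheno: float = 0.0
    ld_law: tuple = ("gamma", 2.0, 30.0, 1.0)  # shape, scale, shift
    seed: int = 0

    def __post_init__(self):
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        for h in (self.h2_trait1, self.h2_trait2):
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"heritability out of [0,1]: {h}")
        if abs(self.rg_true) > 1:
            raise ValueError("|rg_true| must be <= 1")
        if self.n_overlap > min(self.n1, self.n2):
            raise ValueError("overlap exceeds the smaller sample")


def _draw_ld_scores(law, m, rng):
    kind = law[0]
    if kind == "gamma":
        _, shape, scale, shift = law
        return rng.gamma(shape, scale, size=m) + shift
    if kind == "uniform":
        _, lo, hi = law
        return rng.uniform(lo, hi, size=m)
    raise ValueError(f"unknown LD-score law {law!r}")


_NUCS = np.array(list("ACGT"))


def simulate_sumstats_pair(spec: SumstatsSimSpec):
    """Draw per-SNP Z-score pairs with first two moments following the
    LD-score regression model; both tables share SNP ids, alleles and LD
    scores."""
    rng = np.random.default_rng(spec.seed)
    m = spec.n_snps
    l = _draw_ld_scores(spec.ld_law, m, rng)
    v1 = 1.0 + spec.n1 * spec.h2_trait1 * l / m
    v2 = 1.0 + spec.n2 * spec.h2_trait2 * l / m
    cov = (
        np.sqrt(spec.n1 * spec.n2)
        * spec.rg_true
        * np.sqrt(spec.h2_trait1 * spec.h2_trait2)
        * l / m
        + spec.rho_pheno * spec.n_overlap / np.sqrt(spec.n1 * spec.n2)
    )
    det = v1 * v2 - cov**2
    if np.any(det < 0):
        j = int(np.argmin(det))
        raise ValueError(
            "implied per-SNP covariance not positive semi-definite at SNP "
            f"{j} (v1={v1[j]:.4g}, v2={v2[j]:.4g}, cov={cov[j]:.4g}); "
            "check h2, rg and overlap parameters"
        )
    # per-SNP 2x2 Cholesky in closed form
    z1 = np.sqrt(v1) * rng.standard_normal(m)
    z2 = (cov / v1) * z1 + np.sqrt(v2 - cov**2 / v1) * rng.standard_normal(m)

    ids = np.array([f"rs{100000 + j}" for j in range(m)], dtype=object)
    a_idx = rng.integers(0, 4, size=m)
    b_off = rng.integers(1, 4, size=m)
    a1 = _NUCS[a_idx]
    a2 = _NUCS[(a_idx + b_off) % 4]
    t1 = SumstatsTable(ids, a1, a2, z1, np.full(m, spec.n1, dtype=float), l)
    t2 = SumstatsTable(ids, a1, a2, z2, np.full(m, spec.n2, dtype=float), l)
    return t1, t2


# ---------------------------------------------------------------------------
# MR cohorts
# ---------------------------------------------------------------------------


@dataclass
class MRSimSpec:
    """Structural ground truth of a synthetic MR cohort.

    The caffeine score shifts caffeine intake by ``beta_score_on_caffeine``
    mg/day per unit score and the smoking SNP shifts cigarettes/day among
    current smokers; cross-trait causal effects and a shared latent
    confounder are configurable and zero by default.
    """

    n_individuals: int = 12_000
    weights: RiskScoreWeights = field(default_factory=coffee_score_weights)
    raf_per_snp: dict | None = None
    beta_score_on_caffeine: float = 86.7
    beta_snp_on_cigs: float = 0.6
    causal_smoking_to_caffeine: float = 0.0  # mg per cigarette/day
    causal_caffeine_to_smoking: float = 0.0  # cigarettes per mg/day
    shared_confounder_sd: float = 0.0
    status_probs: tuple = (0.5, 0.25, 0.25)  # never, former, current
    # location kept well clear of zero so the truncation below is rare
    # (<~1% of draws) and the instrument-exposure relation stays linear
    caffeine_mean: float = 350.0
    caffeine_sd: float = 150.0
    coffee_fraction: float = 0.7
    cigs_mean: float = 15.0
    cigs_sd: float = 8.0
    cluster_fraction: float = 0.3  # fraction of individuals in 2-person families
    family_sd: float = 0.0  # within-family shared noise (mg/day scale)
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be non-negative")
        raf = self.raf_per_snp or {}
        for v in raf.values():
            if not 0.0 < v < 1.0:
                raise ValueError("risk-allele frequencies must be in (0, 1)")
        for name in ("beta_score_on_caffeine", "beta_snp_on_cigs",
                     "causal_smoking_to_caffeine", "causal_caffeine_to_smoking",
                     "shared_confounder_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if abs(sum(self.status_probs) - 1.0) > 1e-9:
            raise ValueError("status_probs must sum to 1")


def simulate_mr_cohort(spec: MRSimSpec) -> MRCohort:
    """Generate an individual-level cohort under the structural equations of
    the spec.  Negative phenotype draws are truncated at zero (count
    logged), keeping the instrument-exposure relation linear elsewhere."""
    if spec.n_individuals == 0:
        raise ValueError("empty cohort: n_individuals is 0")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals
    smoking = smoking_snp()
    raf = dict(spec.raf_per_snp or {})
    cols = {}
    for entry in list(spec.weights) + [smoking]:
        p = raf.get(entry.snp_id, entry.raf)
        cols[f"dosage_{entry.snp_id}"] = rng.binomial(2, p, size=n).astype(float)
    df = pd.DataFrame(cols)

    score = np.zeros(n)
    for entry in spec.weights:
        score += entry.weight * df[f"dosage_{entry.snp_id}"].to_numpy()
    snp_dos = df[f"dosage_{smoking.snp_id}"].to_numpy()

    confounder = rng.standard_normal(n) * spec.shared_confounder_sd
    status = rng.choice(np.array(["never", "former", "current"]), size=n,
                        p=np.asarray(spec.status_probs))
    current = status == "current"

    # families: a configurable fraction of individuals share a 2-person
    # cluster; clustered pairs are siblings, so their dosages correlate ~0.5
    # (each of the second sibling's SNPs is copied from the first with
    # probability 1/2)
    n_clustered = int(spec.cluster_fraction * n) // 2 * 2
    fam = np.arange(n)
    fam[:n_clustered] = np.repeat(np.arange(n_clustered // 2), 2)
    fam[n_clustered:] = np.arange(n_clustered // 2, n_clustered // 2 + n - n_clustered)
    if n_clustered:
        first = np.arange(0, n_clustered, 2)
        second = first + 1
        for col in cols:
            share = rng.random(len(first)) < 0.5
            d = df[col].to_numpy()
            d[second[share]] = d[first[share]]
            df[col] = d
        score = np.zeros(n)
        for entry in spec.weights:
            score += entry.weight * df[f"dosage_{entry.snp_id}"].to_numpy()
        snp_dos = df[f"dosage_{smoking.snp_id}"].to_numpy()
    fam_noise = np.zeros(n)
    if spec.family_sd > 0:
        per_fam = {f: rng.normal(scale=spec.family_sd) for f in np.unique(fam)}
        fam_noise = np.array([per_fam[f] for f in fam])

    # structural equations: instrument -> own exposure; smoking->caffeine acts
    # through realized cigarettes/day; caffeine->smoking is added afterwards
    cigs0 = np.zeros(n)
    cigs0[current] = (spec.cigs_mean
                      + spec.beta_snp_on_cigs * (snp_dos[current] - 2 * smoking.raf)
                      + confounder[current] * spec.cigs_sd * 0.5
                      + rng.normal(scale=spec.cigs_sd, size=current.sum()))
    caffeine = (spec.caffeine_mean
                + spec.beta_score_on_caffeine * (score - score.mean())
                + spec.causal_smoking_to_caffeine * cigs0
                + confounder * spec.caffeine_sd * 0.5
                + fam_noise
                + rng.normal(scale=spec.caffeine_sd, size=n))
    cigs = cigs0 + spec.causal_caffeine_to_smoking * caffeine

    truncated = int((caffeine < 0).sum() + (cigs[current] < 0).sum())
    if truncated:
        logger.info("truncated %d negative phenotype draws at 0", truncated)
    caffeine = np.clip(caffeine, 0.0, None)
    cigs = np.clip(cigs, 0.0, None)

    coffee_mg = np.clip(spec.coffee_fraction * caffeine
                        + rng.normal(scale=20.0, size=n), 0.0, None)

    df["caffeine_total_mg"] = caffeine
    df["caffeine_coffee_mg"] = coffee_mg
    df["cigarettes_per_day"] = np.where(current, cigs, np.nan)
    df["smoking_status"] = status
    df["age"] = rng.uniform(18, 70, size=n).round(1)
    df["sex"] = rng.integers(0, 2, size=n)
    df["cohort_label"] = rng.integers(0, 2, size=n)
    df["family_id"] = [f"f{f}" for f in fam]
    df["education"] = rng.integers(0, 5, size=n)
    df["social_class"] = rng.integers(0, 5, size=n)
    return MRCohort(table=df, snp_ids=tuple(
        [e.snp_id for e in spec.weights] + [smoking.snp_id]))
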