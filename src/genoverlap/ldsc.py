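"""LD-score regression on GWAS summary statistics.

Under a polygenic model, the expected chi-square of SNP j grows linearly in
its LD score l_j (the amount of nearby variation it tags):

    E[z_j^2]        = 1 + N h^2 l_j / M
    E[z_1j z_2j]    = sqrt(N1 N2) rho_g l_j / M  +  rho Ns / sqrt(N1 N2)

so the heritability h^2 and the genetic covariance rho_g are slopes of
(weighted) regressions of z^2 / z1*z2 on l_j, while confounding and sample
overlap land in the intercept rather than the slope.  The genetic
correlation is rg = rho_g / sqrt(h^2_1 h^2_2).  Uncertainty comes from a
delete-one block jackknife over SNP blocks.

Weighting follows the common two-step scheme: an unweighted pilot fit
supplies variance terms, then a single weighted refit; this keeps the
estimator deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SumstatsTable",
    "LdscFit",
    "align_sumstats",
    "univariate_h2",
    "cross_trait_rg",
    "recode_cessation_to_persistence",
    "jackknife_se",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SumstatsTable:
    """Per-SNP association summary statistics for one trait."""

    snp_id: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray
    z: np.ndarray
    n: np.ndarray
    ld_score: np.ndarray

    def __post_init__(self):
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.allele1 = np.char.upper(np.asarray(self.allele1, dtype=str))
        self.allele2 = np.char.upper(np.asarray(self.allele2, dtype=str))
        self.z = np.asarray(self.z, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        self.ld_score = np.asarray(self.ld_score, dtype=float)
        m = len(self.snp_id)
        for name in ("allele1", "allele2", "z", "n", "ld_score"):
            if len(getattr(self, name)) != m:
                raise ValueError(f"column {name} length mismatch")
        if len(set(self.snp_id)) != m:
            dup = pd.Series(self.snp_id).value_counts()
            raise ValueError(f"duplicate SNP id(s): {list(dup[dup > 1].index[:5])}")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite Z score(s)")
        if np.any(self.ld_score <= 0):
            raise ValueError("LD scores must be positive")
        if np.any(self.n <= 0):
            raise ValueError("sample sizes must be positive")

    def __len__(self):
        return len(self.snp_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"SNP": self.snp_id, "A1": self.allele1, "A2": self.allele2,
             "Z": self.z, "N": self.n, "L2": self.ld_score}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SumstatsTable":
        required = ["SNP", "A1", "A2", "Z", "N", "L2"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"sumstats table missing column(s): {missing}")
        return cls(df["SNP"].to_numpy(), df["A1"].to_numpy(), df["A2"].to_numpy(),
                   df["Z"].to_numpy(), df["N"].to_numpy(), df["L2"].to_numpy())


@dataclass
class LdscFit:
    slope: float
    intercept: float
    h2: float | None = None
    rho_g: float | None = None
    rg: float | None = None
    se: float | None = None
    se_rg: float | None = None
    n_blocks: int | None = None
    out_of_range: bool = False
    undefined: bool = False
    details: dict = field(default_factory=dict, repr=False)


def recode_cessation_to_persistence(rg_cessation: float) -> float:
    """Flip a genetic correlation estimated against smoking cessation
    (0 = current, 1 = former) onto the persistence coding (0 = former,
    1 = current): the trait is reversed, so the correlation changes sign."""
    if abs(rg_cessation) > 1 + 1e-9:
        raise ValueError(f"correlation out of range: {rg_cessation}")
    return -rg_cessation


def _wls(x, y, w):
    """Weighted least squares of y on (1, x); returns (slope, intercept)."""
    sw = w.sum()
    mx = (w * x).sum() / sw
    my = (w * y).sum() / sw
    sxx = (w * (x - mx) ** 2).sum()
    sxy = (w * (x - mx) * (y - my)).sum()
    slope = sxy / sxx
    return slope, my - slope * mx


def _block_bounds(m, n_blocks):
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    if n_blocks > m:
        raise ValueError(f"block count {n_blocks} exceeds {m} SNPs")
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    return list(zip(edges[:-1], edges[1:]))


def _jackknife(values_fn, m, n_blocks):
    """Delete-one-block jackknife SE of a scalar statistic.

    ``values_fn(lo, hi)`` returns the statistic with SNPs [lo, hi) removed.
    """
    blocks = _block_bounds(m, n_blocks)
    est = np.array([values_fn(lo, hi) for lo, hi in blocks])
    g = len(blocks)
    return float(np.sqrt((g - 1) / g * np.sum((est - est.mean()) ** 2)))


def jackknife_se(per_snp_products, ld_scores, n_blocks: int = 200) -> float:
    """Block-jackknife standard error of the OLS slope of per-SNP products
    (z^2 or z1*z2) on LD scores, blocks taken in SNP order."""
    y = np.asarray(per_snp_products, dtype=float)
    x = np.asarray(ld_scores, dtype=float)
    m = len(y)
    w = np.ones(m)

    def slope_without(lo, hi):
        keep = np.ones(m, dtype=bool)
        keep[lo:hi] = False
        return _wls(x[keep], y[keep], w[keep])[0]

    return _jackknife(slope_without, m, n_blocks)


def univariate_h2(ss: SumstatsTable, n_blocks: int = 200, free_intercept: bool = True) -> LdscFit:
    """SNP heritability from the regression of z^2 on the LD score."""
    m = len(ss)
    if m < 2 or len(np.unique(ss.ld_score)) < 2:
        raise ValueError("degenerate design: need >= 2 distinct LD scores")
    nbar = float(ss.n.mean())
    x = ss.ld_score
    y = ss.z**2
    if not free_intercept:
        y = y - 1.0
    w0 = np.ones(m)
    slope0, _ = _wls(x, y, w0)
    h2_0 = float(np.clip(slope0 * m / nbar, 0.0, 1.0))
    w = 1.0 / (x * (1.0 + nbar * h2_0 * x / m) ** 2)
    slope, intercept = _wls(x, y, w)
    h2 = float(slope * m / nbar)

    def h2_without(lo, hi):
        keep = np.ones(m, dtype=bool)
        keep[lo:hi] = False
        return _wls(x[keep], y[keep], w[keep])[0] * m / nbar

    se = _jackknife(h2_without, m, min(n_blocks, m)) if n_blocks else None
    return LdscFit(
        slope=float(slope),
        intercept=float(intercept) if free_intercept else 1.0,
        h2=h2, se=se, n_blocks=n_blocks,
        details={"nbar": nbar, "weights": w, "m": m},
    )


def align_sumstats(ss1: SumstatsTable, ss2: SumstatsTable):
    """Merge two tables on SNP id with consistent allele orientation.

    When a SNP's alleles are swapped between the tables, the second Z score
    is sign-flipped; SNPs with incompatible allele pairs are dropped.
    Returns aligned (ss1, ss2) with identical SNP order and LD scores taken
    from the first table.
    """
    d1 = ss1.to_frame()
    d2 = ss2.to_frame()
    merged = d1.merge(d2, on="SNP", suffixes=("_1", "_2"))
    same = (merged["A1_1"] == merged["A1_2"]) & (merged["A2_1"] == merged["A2_2"])
    swapped = (merged["A1_1"] == merged["A2_2"]) & (merged["A2_1"] == merged["A1_2"])
    keep = same | swapped
    merged = merged[keep]
    z2 = np.where(swapped[keep], -merged["Z_2"], merged["Z_2"])
    a = SumstatsTable(merged["SNP"].to_numpy(), merged["A1_1"].to_numpy(),
                      merged["A2_1"].to_numpy(), merged["Z_1"].to_numpy(),
                      merged["N_1"].to_numpy(), merged["L2_1"].to_numpy())
    b = SumstatsTable(merged["SNP"].to_numpy(), merged["A1_1"].to_numpy(),
                      merged["A2_1"].to_numpy(), z2,
                      merged["N_2"].to_numpy(), merged["L2_1"].to_numpy())
    return a, b


def cross_trait_rg(
    ss1: SumstatsTable, ss2: SumstatsTable, n_blocks: int = 200
) -> LdscFit:
    """Cross-trait genetic correlation from the regression of z1*z2 on the
    LD score.  Sample overlap inflates the (free) intercept, not the slope.

    ``rg`` is reported raw: values outside [-1, 1] are flagged
    ``out_of_range`` rather than clipped, and a non-positive heritability
    renders it ``undefined``.
    """
    ss1, ss2 = align_sumstats(ss1, ss2)
    m = len(ss1)
    if m < 200:
        raise ValueError(f"only {m} aligned SNPs; need >= 200")
    fit1 = univariate_h2(ss1, n_blocks=0)
    fit2 = univariate_h2(ss2, n_blocks=0)
    x = ss1.ld_score
    y = ss1.z * ss2.z
    n1bar, n2bar = float(ss1.n.mean()), float(ss2.n.mean())
    root_n = np.sqrt(n1bar * n2bar)
    slope0, int0 = _wls(x, y, np.ones(m))
    v1 = 1.0 + n1bar * max(fit1.h2, 0.0) * x / m
    v2 = 1.0 + n2bar * max(fit2.h2, 0.0) * x / m
    c = slope0 * x + int0  # pilot estimate of the mean product
    w = 1.0 / (x * (v1 * v2 + c**2))
    slope, intercept = _wls(x, y, w)
    rho_g = float(slope * m / root_n)

    h2_1, h2_2 = fit1.h2, fit2.h2
    undefined = h2_1 is None or h2_2 is None or h2_1 <= 0 or h2_2 <= 0
    rg = None if undefined else float(rho_g / np.sqrt(h2_1 * h2_2))

    w1, w2 = fit1.details["weights"], fit2.details["weights"]
    y1, y2 = ss1.z**2, ss2.z**2

    def rg_without(lo, hi):
        keep = np.ones(m, dtype=bool)
        keep[lo:hi] = False
        s, _ = _wls(x[keep], y[keep], w[keep])
        s1, _ = _wls(x[keep], y1[keep], w1[keep])
        s2, _ = _wls(x[keep], y2[keep], w2[keep])
        h1 = s1 * m / n1bar
        h2 = s2 * m / n2bar
        if h1 <= 0 or h2 <= 0:
            return np.nan
        return (s * m / root_n) / np.sqrt(h1 * h2)

    se_slope = _jackknife(lambda lo, hi: _wls(
        x[np.r_[0:lo, hi:m]], y[np.r_[0:lo, hi:m]], w[np.r_[0:lo, hi:m]])[0], m, n_blocks)
    se_rg = None
    if not undefined:
        blocks = _block_bounds(m, n_blocks)
        vals = np.array([rg_without(lo, hi) for lo, hi in blocks])
        vals = vals[np.isfinite(vals)]
        g = len(vals)
        if g >= 2:
            se_rg = float(np.sqrt((g - 1) / g * np.sum((vals - vals.mean()) ** 2)))
    return LdscFit(
        slope=float(slope), intercept=float(intercept),
        h2=None, rho_g=rho_g, rg=rg,
        se=se_slope, se_rg=se_rg, n_blocks=n_blocks,
        out_of_range=bool(rg is not None and abs(rg) > 1),
        undefined=bool(undefined),
        details={"h2_1": h2_1, "h2_2": h2_2, "m": m,
                 "intercept1": fit1.intercept, "intercept2": fit2.intercept},
    )
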