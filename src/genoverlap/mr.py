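"""Bidirectional Mendelian randomization between smoking and caffeine use.

The exposure-increasing instruments are a weighted allele score for caffeine
use (eight coffee SNPs) and the rs1051730 dosage for smoking heaviness.
Causality is probed in both directions: the smoking SNP against caffeine
consumption within smoking-status strata (never smokers serve as the
negative control, since the SNP can only act through smoking heaviness), and
the caffeine score against smoking outcomes.  All regressions adjust for
age, sex and cohort and use one-way cluster-robust (sandwich) standard
errors by family, so related individuals do not understate uncertainty.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .instruments import RiskScoreWeights, smoking_snp

__all__ = [
    "MRCohort",
    "MRResult",
    "PowerSpec",
    "derive_smoking_phenotypes",
    "dichotomize_high_use",
    "weighted_risk_score",
    "instrument_check",
    "causal_test_smoking_to_caffeine",
    "causal_test_caffeine_to_smoking",
    "confounder_check",
    "mr_power",
    "detectable_effect",
]

logger = logging.getLogger(__name__)

SMOKING_STATUSES = ("never", "former", "current")
_COVARIATES = ("age", "sex", "cohort_label")


@dataclass
class MRCohort:
    """Individual-level cohort table.

    ``table`` holds one row per individual with columns
    ``dosage_<rsid>`` (in [0, 2]) for every instrument SNP,
    ``caffeine_total_mg``, ``caffeine_coffee_mg``, ``cigarettes_per_day``
    (current smokers; NaN otherwise), ``smoking_status``, ``age``, ``sex``,
    ``cohort_label``, ``family_id`` and the confound-check variables
    ``education`` and ``social_class``.
    """

    table: pd.DataFrame
    snp_ids: tuple

    def __post_init__(self):
        self.snp_ids = tuple(self.snp_ids)
        if len(self.table) == 0:
            raise ValueError("empty cohort")
        required = {
            "caffeine_total_mg",
            "caffeine_coffee_mg",
            "cigarettes_per_day",
            "smoking_status",
            "age",
            "sex",
            "cohort_label",
            "family_id",
        }
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        for rsid in self.snp_ids:
            col = f"dosage_{rsid}"
            if col not in self.table.columns:
                raise ValueError(f"cohort table missing dosage column {col}")
            d = self.table[col].to_numpy(dtype=float)
            bad = d[np.isfinite(d)]
            if bad.size and (bad.min() < 0 or bad.max() > 2):
                raise ValueError(f"dosage out of [0,2] for {rsid}")
        bad_status = set(self.table["smoking_status"]) - set(SMOKING_STATUSES)
        if bad_status:
            raise ValueError(f"unknown smoking status label(s): {sorted(bad_status)}")
        for col in ("caffeine_total_mg", "caffeine_coffee_mg"):
            v = self.table[col].to_numpy(dtype=float)
            if np.nanmin(v) < 0:
                raise ValueError(f"{col} must be non-negative")

    def dosages(self, rsid: str) -> np.ndarray:
        return self.table[f"dosage_{rsid}"].to_numpy(dtype=float)


@dataclass
class MRResult:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    model_family: str
    term: str = ""
    note: str | None = None


@dataclass
class PowerSpec:
    """Inputs of the two-stage-least-squares power approximation for a
    continuous outcome: sample size, test size, instrument strength
    (variance in exposure explained) and the causal effect with the unit
    scales of exposure and outcome."""

    n: int
    alpha: float
    r2_xz: float
    beta_xy: float
    sd_x: float = 1.0
    sd_y: float = 1.0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.r2_xz <= 1:
            raise ValueError("r2_xz must be in [0, 1]")
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not all(map(math.isfinite, (self.beta_xy, self.sd_x, self.sd_y))):
            raise ValueError("effects and scales must be finite")


# ---------------------------------------------------------------------------
# phenotype derivation
# ---------------------------------------------------------------------------


def derive_smoking_phenotypes(status: str):
    """(initiation, current smoking, persistence) from a status label.

    Initiation: never = 0, ever (former or current) = 1.  Current smoking:
    current = 1, else 0.  Persistence: former = 0, current = 1, undefined
    (None) for never smokers, who are excluded from persistence analyses.
    """
    if status == "never":
        return 0, 0, None
    if status == "former":
        return 1, 0, 0
    if status == "current":
        return 1, 1, 1
    raise ValueError(f"unknown smoking status {status!r}")


def dichotomize_high_use(values, sex, return_thresholds: bool = False):
    """Split a consumption measure into high (1) vs low (0) users at one
    standard deviation above the sex-specific mean; a value exactly at the
    cutoff is low."""
    values = np.asarray(values, dtype=float)
    sex = np.asarray(sex)
    out = np.zeros(len(values), dtype=int)
    thresholds = {}
    for s in np.unique(sex):
        m = sex == s
        if m.sum() < 2:
            raise ValueError(f"sex group {s!r} has fewer than 2 individuals")
        sd = values[m].std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero variance in sex group {s!r}")
        cut = values[m].mean() + sd
        thresholds[s] = float(cut)
        out[m] = (values[m] > cut).astype(int)
    return (out, thresholds) if return_thresholds else out


def weighted_risk_score(dosages, weights: RiskScoreWeights) -> np.ndarray:
    """Weighted sum of risk-allele dosages, ``sum_k beta_k * dosage_k``.

    ``dosages`` maps SNP id -> array (or is a DataFrame of ``dosage_<rsid>``
    columns).  Missing dosages are mean-imputed per SNP with a logged count;
    dosage entries without a weight are ignored with a warning.
    """
    if isinstance(dosages, pd.DataFrame):
        dosages = {
            c.removeprefix("dosage_"): dosages[c].to_numpy(dtype=float)
            for c in dosages.columns
            if c.startswith("dosage_")
        }
    extra = set(dosages) - set(weights.snp_ids)
    if extra:
        logger.warning("ignoring dosage columns without weights: %s", sorted(extra))
    missing = set(weights.snp_ids) - set(dosages)
    if missing:
        raise KeyError(f"no dosages for weighted SNP(s): {sorted(missing)}")
    score = None
    for entry in weights:
        d = np.asarray(dosages[entry.snp_id], dtype=float).copy()
        nan = ~np.isfinite(d)
        if nan.any():
            logger.info("mean-imputing %d missing dosages for %s", nan.sum(), entry.snp_id)
            d[nan] = d[~nan].mean()
        score = entry.weight * d if score is None else score + entry.weight * d
    return score


# ---------------------------------------------------------------------------
# regression machinery
# ---------------------------------------------------------------------------


def _regress(df, y, x, family="linear", min_n=30, term=None):
    cols = [y, x, *(c for c in _COVARIATES if c in df.columns)]
    d = df[cols + ["family_id"]].dropna(subset=[y, x])
    # drop degenerate covariates (e.g. single-sex cohorts)
    keep = [c for c in cols[1:] if d[c].nunique() > 1]
    if x not in keep:
        raise ValueError(f"degenerate instrument: {x} has no variance")
    n = len(d)
    if n < min_n:
        raise ValueError(f"stratum has n={n} < {min_n}")
    X = sm.add_constant(d[keep].to_numpy(dtype=float))
    yv = d[y].to_numpy(dtype=float)
    groups = d["family_id"].to_numpy()
    ix = 1 + keep.index(x)
    if family == "linear":
        model = sm.OLS(yv, X)
    elif family == "logistic":
        if len(np.unique(yv)) < 2:
            raise ValueError(f"outcome {y} has a single class")
        model = sm.Logit(yv, X)
    else:
        raise ValueError(family)
    if len(np.unique(groups)) > 1:
        fit = model.fit(cov_type="cluster", cov_kwds={"groups": groups}, disp=0) \
            if family == "logistic" else model.fit(cov_type="cluster", cov_kwds={"groups": groups})
    else:
        fit = model.fit(disp=0) if family == "logistic" else model.fit()
    beta = float(fit.params[ix])
    se = float(fit.bse[ix])
    z = norm.ppf(0.975)
    return MRResult(
        beta=beta,
        se=se,
        ci_low=beta - z * se,
        ci_high=beta + z * se,
        p=float(fit.pvalues[ix]),
        n=n,
        model_family=family,
        term=term or f"{y} ~ {x}",
    )


def _with_score(cohort: MRCohort, weights: RiskScoreWeights) -> pd.DataFrame:
    df = cohort.table.copy()
    score_cols = df[[f"dosage_{s}" for s in weights.snp_ids]]
    df["caffeine_score"] = weighted_risk_score(score_cols, weights)
    return df


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------


def instrument_check(cohort: MRCohort, weights: RiskScoreWeights | None = None):
    """First-stage associations establishing instrumental value: caffeine
    score -> total caffeine mg/day in everyone, and smoking SNP dosage ->
    cigarettes/day in current smokers.  Returns a dict of MRResult."""
    from .instruments import coffee_score_weights

    weights = weights or coffee_score_weights()
    df = _with_score(cohort, weights)
    out = {
        "score_on_caffeine": _regress(
            df, "caffeine_total_mg", "caffeine_score", term="caffeine_total_mg ~ score"
        )
    }
    smokers = df[df["smoking_status"] == "current"]
    snp = f"dosage_{smoking_snp().snp_id}"
    if len(smokers) == 0:
        out["snp_on_cigarettes"] = None
        logger.warning("no current smokers: cigarettes/day first stage undefined")
    else:
        out["snp_on_cigarettes"] = _regress(
            smokers, "cigarettes_per_day", snp, term="cigarettes_per_day ~ rs1051730"
        )
    return out


def causal_test_smoking_to_caffeine(cohort: MRCohort, min_stratum_n: int = 30):
    """Smoking SNP against caffeine use within smoking-status strata.

    A causal effect of smoking heaviness on caffeine would show as a positive
    SNP effect among current smokers only; never smokers are the negative
    control.  Returns {(stratum, measure): MRResult or None (skipped)}.
    """
    snp = f"dosage_{smoking_snp().snp_id}"
    out = {}
    for stratum in SMOKING_STATUSES:
        sub = cohort.table[cohort.table["smoking_status"] == stratum]
        for measure in ("caffeine_total_mg", "caffeine_coffee_mg"):
            key = (stratum, measure)
            try:
                out[key] = _regress(sub, measure, snp, min_n=min_stratum_n,
                                    term=f"{measure} ~ rs1051730 | {stratum}")
            except ValueError as exc:
                logger.warning("skipping stratum %s: %s", key, exc)
                out[key] = None
    return out


def causal_test_caffeine_to_smoking(
    cohort: MRCohort, weights: RiskScoreWeights | None = None
):
    """Caffeine score against smoking outcomes: cigarettes/day (linear,
    current smokers) and initiation / current smoking / persistence
    (logistic).  Persistence drops never smokers by definition."""
    from .instruments import coffee_score_weights

    weights = weights or coffee_score_weights()
    df = _with_score(cohort, weights)
    if df["caffeine_score"].nunique() < 2:
        raise ValueError("degenerate instrument: caffeine score is constant")
    derived = df["smoking_status"].map(
        {s: derive_smoking_phenotypes(s) for s in SMOKING_STATUSES}
    )
    df["initiation"] = [d[0] for d in derived]
    df["current_smoking"] = [d[1] for d in derived]
    df["persistence"] = [np.nan if d[2] is None else d[2] for d in derived]

    out = {}
    try:
        out["cigarettes_per_day"] = _regress(
            df[df["smoking_status"] == "current"], "cigarettes_per_day",
            "caffeine_score", term="cigarettes_per_day ~ score",
        )
    except ValueError as exc:
        logger.warning("cigarettes/day model undefined: %s", exc)
        out["cigarettes_per_day"] = None
    for outcome in ("initiation", "current_smoking", "persistence"):
        try:
            out[outcome] = _regress(df, outcome, "caffeine_score",
                                    family="logistic", term=f"{outcome} ~ score")
        except ValueError as exc:
            logger.warning("%s model undefined: %s", outcome, exc)
            out[outcome] = None
    return out


def confounder_check(
    cohort: MRCohort,
    confounders=("education", "social_class"),
    weights: RiskScoreWeights | None = None,
    alpha: float = 0.05,
):
    """Association of each instrument with each putative confounder.

    A valid instrument should be independent of confounding factors; any
    association with p < alpha is flagged.  Returns
    {(instrument, confounder): (MRResult, flagged)}.
    """
    from .instruments import coffee_score_weights

    weights = weights or coffee_score_weights()
    missing = [c for c in confounders if c not in cohort.table.columns]
    if missing:
        raise ValueError(f"missing confounder column(s): {missing}")
    df = _with_score(cohort, weights)
    snp = f"dosage_{smoking_snp().snp_id}"
    out = {}
    for instrument, col in (("caffeine_score", "caffeine_score"), ("smoking_snp", snp)):
        for conf in confounders:
            res = _regress(df, conf, col, term=f"{conf} ~ {instrument}")
            out[(instrument, conf)] = (res, res.p < alpha)
    return out


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------


def mr_power(spec: PowerSpec) -> float:
    """Asymptotic power of the instrumental-variable Wald test for a
    continuous outcome.

    The non-centrality parameter is ``n * r2_xz * (beta_xy * sd_x / sd_y)^2``
    and power is the two-sided normal rejection probability at size alpha.
    """
    if spec.r2_xz == 0:
        if spec.beta_xy != 0:
            logger.warning("r2_xz = 0: instrument carries no information, power = alpha")
        return spec.alpha
    ncp = spec.n * spec.r2_xz * (spec.beta_xy * spec.sd_x / spec.sd_y) ** 2
    z = norm.ppf(1 - spec.alpha / 2)
    root = math.sqrt(ncp)
    return float(norm.cdf(-z + root) + norm.cdf(-z - root))


def detectable_effect(
    n: int, alpha: float, r2_xz: float, target_power: float = 0.8,
    sd_x: float = 1.0, sd_y: float = 1.0,
) -> float:
    """Smallest causal effect detectable at the target power (inverse of
    :func:`mr_power` in ``beta_xy``)."""
    if r2_xz <= 0:
        raise ValueError("r2_xz must be positive to invert the power function")
    z_a = norm.ppf(1 - alpha / 2)
    z_b = norm.ppf(target_power)
    # ignore the far-tail term, standard for power >= 0.5
    root = z_a + z_b
    return float(root / math.sqrt(n * r2_xz) * sd_y / sd_x)
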