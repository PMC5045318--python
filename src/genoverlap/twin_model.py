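"""Bivariate liability-threshold twin modelling for two binary traits.

Each trait (trait 1 = current smoking, trait 2 = high caffeine/coffee use in
the motivating application) is the indicator of a latent standard-normal
liability exceeding a cutpoint.  Liability variance decomposes into additive
genetic (A), common-environment (C) and unique-environment (E) components via
a bivariate Cholesky parameterization; monozygotic (MZ) co-twins correlate 1
on A and C, dizygotic (DZ) co-twins 0.5 on A and 1 on C, and E is
twin-specific.  Thresholds are sex-specific with a linear age-band moderator
on the liability scale.

Model fitting maximizes the exact multinomial orthant likelihood of the
observed 2x2x2x2 response patterns (pairs) and 2x2 patterns (single twins),
pooled by zygosity group x age band x pattern so each distinct orthant
probability is evaluated once per deviance.  Internally, free structural
parameters are the standardized variance shares and component correlations
(A1, C1, A2, C2, rA, rC, rE); Cholesky loadings are derived from them, which
keeps every implied covariance positive semi-definite by construction and
makes profile confidence intervals on the reported quantities direct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtri
from scipy.stats import chi2 as chi2_dist

from .mvn import exchangeable_pair_pattern_probs, quadrant_probs

__all__ = [
    "ZYGOSITY_GROUPS",
    "AGE_BAND_LABELS",
    "N_AGE_BANDS",
    "TwinPairRecord",
    "TwinData",
    "ACEBivariateParams",
    "ThresholdSpec",
    "ModelFitResult",
    "LRTResult",
    "CorrelationSummary",
    "implied_pair_correlation",
    "sample_minus2LL",
    "fit_model",
    "fit_saturated",
    "likelihood_ratio_test",
    "model_selection_sequence",
    "correlations_from_params",
    "confidence_intervals",
]

ZYGOSITY_GROUPS = ("MZM", "DZM", "MZF", "DZF", "DOS")
AGE_BAND_LABELS = ("<20", "20-24", "25-34", "35-44", "45-54", ">=55")
N_AGE_BANDS = 6
SEXES = ("M", "F")

#: zygosity group -> (class, sex twin 1, sex twin 2); DOS records are
#: canonicalized male-first when data are tabulated
GROUP_INFO = {
    "MZM": ("MZ", 0, 0),
    "DZM": ("DZ", 0, 0),
    "MZF": ("MZ", 1, 1),
    "DZF": ("DZ", 1, 1),
    "DOS": ("DZ", 0, 1),
}

_MIN_CELL_PROB = 1e-300


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class TwinPairRecord:
    """One twin pair: zygosity group, age band, sexes, and two binary
    phenotypes per twin (``None`` = missing; a pair with one twin entirely
    missing is an incomplete pair)."""

    family_id: str
    zygosity_group: str
    age_band: int
    sex_t1: str
    sex_t2: str
    pheno1_t1: int | None
    pheno2_t1: int | None
    pheno1_t2: int | None
    pheno2_t2: int | None

    def __post_init__(self):
        if self.zygosity_group not in ZYGOSITY_GROUPS:
            raise ValueError(f"unknown zygosity group {self.zygosity_group!r}")
        if not 0 <= self.age_band < N_AGE_BANDS:
            raise ValueError(f"age band out of range: {self.age_band}")
        if self.sex_t1 not in SEXES or self.sex_t2 not in SEXES:
            raise ValueError(f"sex labels must be M/F, got {self.sex_t1}/{self.sex_t2}")
        same_sex = self.zygosity_group != "DOS"
        if same_sex and self.sex_t1 != self.sex_t2:
            raise ValueError(f"{self.zygosity_group} pair with discordant sexes")
        if not same_sex and self.sex_t1 == self.sex_t2:
            raise ValueError("DOS pair with identical sexes")
        for v in (self.pheno1_t1, self.pheno2_t1, self.pheno1_t2, self.pheno2_t2):
            if v is not None and v not in (0, 1):
                raise ValueError(f"non-binary phenotype value {v!r}")


class TwinData:
    """Pooled pattern counts for the orthant likelihood.

    ``complete[g, b, i, j]`` counts pairs in zygosity group ``g`` and age band
    ``b`` whose twin-1 pattern is ``i`` and twin-2 pattern ``j`` (patterns
    order the two traits as (00, 01, 10, 11)).  DOS pairs are stored
    male-first.  ``singles[s, b, i]`` counts twins from incomplete pairs by
    own sex ``s``.
    """

    def __init__(self, complete: np.ndarray, singles: np.ndarray):
        self.complete = np.asarray(complete, dtype=float)
        self.singles = np.asarray(singles, dtype=float)
        if self.complete.shape != (5, N_AGE_BANDS, 4, 4):
            raise ValueError("complete counts must have shape (5, 6, 4, 4)")
        if self.singles.shape != (2, N_AGE_BANDS, 4):
            raise ValueError("singles counts must have shape (2, 6, 4)")

    @property
    def n_pairs(self) -> int:
        return int(self.complete.sum())

    @property
    def n_singles(self) -> int:
        return int(self.singles.sum())

    @property
    def n_twins(self) -> int:
        """Individual twins contributing data (pairs count twice)."""
        return 2 * self.n_pairs + self.n_singles

    @property
    def n_observations(self) -> int:
        """Observed binary statistics: two traits per twin with data."""
        return 2 * self.n_twins

    @classmethod
    def from_records(cls, records) -> "TwinData":
        complete = np.zeros((5, N_AGE_BANDS, 4, 4))
        singles = np.zeros((2, N_AGE_BANDS, 4))
        gidx = {g: i for i, g in enumerate(ZYGOSITY_GROUPS)}
        for rec in records:
            t1 = (rec.pheno1_t1, rec.pheno2_t1, rec.sex_t1)
            t2 = (rec.pheno1_t2, rec.pheno2_t2, rec.sex_t2)
            has1 = t1[0] is not None and t1[1] is not None
            has2 = t2[0] is not None and t2[1] is not None
            if has1 and has2:
                if rec.zygosity_group == "DOS" and rec.sex_t1 == "F":
                    t1, t2 = t2, t1  # canonical male-first
                p1 = 2 * t1[0] + t1[1]
                p2 = 2 * t2[0] + t2[1]
                complete[gidx[rec.zygosity_group], rec.age_band, p1, p2] += 1
            elif has1 or has2:
                obs = t1 if has1 else t2
                s = 0 if obs[2] == "M" else 1
                singles[s, rec.age_band, 2 * obs[0] + obs[1]] += 1
        return cls(complete, singles)

    def resampled(self, rng: np.random.Generator) -> "TwinData":
        """Multinomial bootstrap resample of pairs and singles (within the
        group x band margins left random, totals fixed)."""
        cflat = self.complete.ravel()
        sflat = self.singles.ravel()
        c = rng.multinomial(int(cflat.sum()), cflat / cflat.sum()) if cflat.sum() else cflat
        s = rng.multinomial(int(sflat.sum()), sflat / sflat.sum()) if sflat.sum() else sflat
        return TwinData(
            np.asarray(c, dtype=float).reshape(self.complete.shape),
            np.asarray(s, dtype=float).reshape(self.singles.shape),
        )


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class ACEBivariateParams:
    """Cholesky path loadings of the bivariate ACE liability model.

    ``x11`` loads component factor X1 on trait 1, ``x21`` factor X1 on trait 2
    (the overlap path) and ``x22`` factor X2 on trait 2.  Standardized params
    satisfy ``a11²+c11²+e11² = 1`` and ``a21²+a22²+c21²+c22²+e21²+e22² = 1``.
    """

    a11: float
    a21: float
    a22: float
    c11: float
    c21: float
    c22: float
    e11: float
    e21: float
    e22: float

    @classmethod
    def from_shares(
        cls,
        A1: float,
        A2: float,
        rA: float,
        rE: float,
        C1: float = 0.0,
        C2: float = 0.0,
        rC: float = 0.0,
    ) -> "ACEBivariateParams":
        """Build standardized loadings from variance shares and component
        correlations.  ``E`` shares are the unit-variance remainders."""
        E1 = 1.0 - A1 - C1
        E2 = 1.0 - A2 - C2
        if min(A1, A2, C1, C2) < -1e-12 or min(E1, E2) < -1e-12:
            raise ValueError(
                f"inadmissible shares: A=({A1},{A2}) C=({C1},{C2}) E=({E1},{E2})"
            )
        for name, r in (("rA", rA), ("rC", rC), ("rE", rE)):
            if abs(r) > 1 + 1e-12:
                raise ValueError(f"{name} out of [-1, 1]: {r}")

        def block(v1, v2, r):
            x11 = math.sqrt(max(v1, 0.0))
            x21 = r * math.sqrt(max(v2, 0.0)) if v1 > 0 else 0.0
            x22 = math.sqrt(max(v2 - x21 * x21, 0.0))
            return x11, x21, x22

        a11, a21, a22 = block(A1, A2, rA)
        c11, c21, c22 = block(C1, C2, rC)
        e11, e21, e22 = block(E1, E2, rE)
        return cls(a11, a21, a22, c11, c21, c22, e11, e21, e22)

    def component_cov(self, comp: str) -> np.ndarray:
        x11, x21, x22 = {
            "A": (self.a11, self.a21, self.a22),
            "C": (self.c11, self.c21, self.c22),
            "E": (self.e11, self.e21, self.e22),
        }[comp]
        return np.array(
            [[x11 * x11, x11 * x21], [x11 * x21, x21 * x21 + x22 * x22]]
        )

    @property
    def sigma_a(self) -> np.ndarray:
        return self.component_cov("A")

    @property
    def sigma_c(self) -> np.ndarray:
        return self.component_cov("C")

    @property
    def sigma_e(self) -> np.ndarray:
        return self.component_cov("E")

    def validate(self, atol: float = 1e-8, require_e: bool = True) -> None:
        total = self.sigma_a + self.sigma_c + self.sigma_e
        if np.max(np.abs(np.diag(total) - 1.0)) > atol:
            raise ValueError(
                f"liability variances not standardized: diag={np.diag(total)}"
            )
        if require_e and (self.sigma_e[0, 0] <= 0 or self.sigma_e[1, 1] <= 0):
            raise ValueError("unique-environment variance must be strictly positive")

    def standardized(self) -> "ACEBivariateParams":
        """Rescale loadings so each trait's liability variance is one."""
        total = self.sigma_a + self.sigma_c + self.sigma_e
        s1, s2 = math.sqrt(total[0, 0]), math.sqrt(total[1, 1])
        return ACEBivariateParams(
            self.a11 / s1, self.a21 / s2, self.a22 / s2,
            self.c11 / s1, self.c21 / s2, self.c22 / s2,
            self.e11 / s1, self.e21 / s2, self.e22 / s2,
        )


@dataclass
class ThresholdSpec:
    """Liability cutpoints: ``tau[trait, sex]`` baseline plus
    ``beta_age[trait, sex]`` times the ordinal age-band score (0-5)."""

    tau: np.ndarray
    beta_age: np.ndarray

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)
        self.beta_age = np.asarray(self.beta_age, dtype=float)
        if self.tau.shape != (2, 2) or self.beta_age.shape != (2, 2):
            raise ValueError("tau and beta_age must have shape (2, 2) = (trait, sex)")
        if not (np.all(np.isfinite(self.tau)) and np.all(np.isfinite(self.beta_age))):
            raise ValueError("thresholds must be finite")

    def threshold(self, trait: int, sex: int, band) -> np.ndarray:
        return self.tau[trait, sex] + self.beta_age[trait, sex] * np.asarray(band)

    def per_band(self, sex: int) -> np.ndarray:
        """Thresholds for both traits across all age bands: shape (6, 2)."""
        bands = np.arange(N_AGE_BANDS)
        return np.stack(
            [self.threshold(0, sex, bands), self.threshold(1, sex, bands)], axis=-1
        )

    @classmethod
    def from_prevalence(cls, prev, beta_age=None, at_band: float = 2.0):
        """Cutpoints hitting target prevalences ``prev[trait, sex]`` at the
        reference age-band score ``at_band``."""
        prev = np.asarray(prev, dtype=float)
        beta = np.zeros((2, 2)) if beta_age is None else np.asarray(beta_age, float)
        tau = ndtri(1.0 - prev) - beta * at_band
        return cls(tau, beta)


@dataclass
class ModelFitResult:
    minus2LL: float
    n_free: int
    df: int
    params: ACEBivariateParams | None
    thresholds: ThresholdSpec
    estimates: dict
    converged: bool
    n_function_evals: int
    label: str = ""
    context: dict = field(default_factory=dict, repr=False)


@dataclass
class LRTResult:
    chi2: float
    delta_df: int
    p: float
    retained: bool


@dataclass
class CorrelationSummary:
    rA: float | None
    rC: float | None
    rE: float | None
    A1: float
    C1: float
    E1: float
    A2: float
    C2: float
    E2: float
    overlap_A: float
    overlap_C: float
    overlap_E: float


# ---------------------------------------------------------------------------
# implied structure and deviance
# ---------------------------------------------------------------------------


def implied_pair_correlation(params: ACEBivariateParams, zygosity_class: str) -> np.ndarray:
    """4x4 correlation matrix of (trait1, trait2) x (twin1, twin2) liabilities.

    Cross-twin blocks carry A (weighted 1 for MZ, 0.5 for DZ) and C; the
    within-twin block is the full phenotypic liability correlation.
    """
    params.validate(atol=1e-6, require_e=False)
    if zygosity_class not in ("MZ", "DZ"):
        raise ValueError(f"zygosity class must be MZ or DZ, got {zygosity_class!r}")
    w = 1.0 if zygosity_class == "MZ" else 0.5
    within = params.sigma_a + params.sigma_c + params.sigma_e
    cross = w * params.sigma_a + params.sigma_c
    R = np.block([[within, cross], [cross, within]])
    np.fill_diagonal(R, 1.0)
    eig = np.linalg.eigvalsh(R)
    if eig[0] < -1e-8:
        raise ValueError(
            f"implied {zygosity_class} correlation matrix not PSD "
            f"(min eigenvalue {eig[0]:.3g}) for params {params}"
        )
    return R


def _ace_blocks(params: ACEBivariateParams, zclass: str):
    SA, SC, SE = params.sigma_a, params.sigma_c, params.sigma_e
    if zclass == "MZ":
        return SA + SC, SE
    return 0.5 * SA + SC, 0.5 * SA + SE


def _pattern_probs_for_groups(shared_within_by_group, thresholds: ThresholdSpec, n_nodes):
    """probs[g] has shape (6, 4, 4) for each group with a structure entry."""
    out = {}
    for g, (shared, within) in shared_within_by_group.items():
        _, s1, s2 = GROUP_INFO[g]
        thr1 = thresholds.per_band(s1)
        thr2 = thr1 if s1 == s2 else thresholds.per_band(s2)
        out[g] = exchangeable_pair_pattern_probs(shared, within, thr1, thr2, n_nodes)
    return out


def _singles_probs(within_corr: float, thresholds: ThresholdSpec) -> np.ndarray:
    """Marginal bivariate pattern probabilities of one twin: (2 sex, 6, 4)."""
    rho = float(np.clip(within_corr, -0.9999, 0.9999))
    out = np.empty((2, N_AGE_BANDS, 4))
    for s in range(2):
        thr = thresholds.per_band(s)
        out[s] = quadrant_probs(thr[:, 0], thr[:, 1], rho)
    return out


def _deviance_from_probs(data: TwinData, probs_by_group, singles_probs) -> float:
    ll = 0.0
    for gi, g in enumerate(ZYGOSITY_GROUPS):
        counts = data.complete[gi]
        if counts.sum() == 0:
            continue
        p = probs_by_group[g]
        mask = counts > 0
        pm = p[mask]
        if np.any(pm < _MIN_CELL_PROB):
            raise FloatingPointError(
                "orthant probability underflow; consider tighter parameter bounds"
            )
        ll += float(np.sum(counts[mask] * np.log(pm)))
    if data.singles.sum() > 0:
        mask = data.singles > 0
        pm = singles_probs[mask]
        if np.any(pm < _MIN_CELL_PROB):
            raise FloatingPointError(
                "orthant probability underflow; consider tighter parameter bounds"
            )
        ll += float(np.sum(data.singles[mask] * np.log(pm)))
    return -2.0 * ll


def sample_minus2LL(
    data: TwinData,
    params: ACEBivariateParams,
    thresholds: ThresholdSpec,
    n_nodes: int = 24,
) -> float:
    """Deviance (-2 log L) of pooled twin pattern counts under an ACE model.

    Complete pairs contribute the 4-D orthant probability of their response
    pattern; incomplete pairs the 2-D marginal of the observed twin.
    """
    structures = {}
    for g, (zc, _, _) in GROUP_INFO.items():
        structures[g] = _ace_blocks(params, zc)
    probs = _pattern_probs_for_groups(structures, thresholds, n_nodes)
    within = params.sigma_a + params.sigma_c + params.sigma_e
    sp = _singles_probs(within[0, 1], thresholds)
    return _deviance_from_probs(data, probs, sp)


def _saturated_deviance(data, corr_by_group, thresholds, n_nodes=24):
    """corr_by_group[g] = (r_t1, r_t2, r_wc, r_x).  Returns deviance or None
    when a group's implied exchangeable decomposition is not PSD."""
    structures = {}
    for g, (r1, r2, rwc, rx) in corr_by_group.items():
        shared = np.array([[r1, rx], [rx, r2]])
        within = np.array([[1 - r1, rwc - rx], [rwc - rx, 1 - r2]])
        for m in (shared, within):
            if m[0, 0] < 0 or m[1, 1] < 0 or np.linalg.det(m) < -1e-12:
                return None
        structures[g] = (shared, within)
    probs = _pattern_probs_for_groups(structures, thresholds, n_nodes)
    # within-person cross-trait correlation may differ by group; singles are
    # not group-labelled, so use the count-weighted mean r_wc
    wts = data.complete.sum(axis=(1, 2, 3))
    rwc_all = np.array([corr_by_group[g][2] for g in ZYGOSITY_GROUPS])
    rwc_bar = float(np.average(rwc_all, weights=wts)) if wts.sum() else float(rwc_all.mean())
    sp = _singles_probs(rwc_bar, thresholds)
    try:
        return _deviance_from_probs(data, probs, sp)
    except FloatingPointError:
        return None


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_STRUCT_NAMES = ("A1", "C1", "A2", "C2", "rA", "rC", "rE")
_SHARE_BOUND = (0.0, 0.97)
_CORR_BOUND = (-0.97, 0.97)


def _threshold_param_spec(threshold_constraints):
    """Names and index maps of free threshold parameters.

    ``threshold_constraints`` may contain ``drop_age`` (beta = 0) and
    ``equate_sex_trait1`` / ``equate_sex_trait2``.
    """
    tc = set(threshold_constraints or ())
    names, tau_map, beta_map = [], {}, {}
    for t in range(2):
        tied = f"equate_sex_trait{t + 1}" in tc
        for s in range(2):
            if tied and s == 1:
                tau_map[(t, 1)] = tau_map[(t, 0)]
                if "drop_age" not in tc:
                    beta_map[(t, 1)] = beta_map[(t, 0)]
                continue
            tau_map[(t, s)] = len(names)
            names.append(f"tau{t + 1}{SEXES[s]}")
            if "drop_age" not in tc:
                beta_map[(t, s)] = len(names)
                names.append(f"beta{t + 1}{SEXES[s]}")
    return names, tau_map, beta_map


def _threshold_x0_bounds(thr_names, tau_map, beta_map, tau0, beta0):
    """Initial values and box bounds for the free threshold block."""
    x0 = np.zeros(len(thr_names))
    bounds = [None] * len(thr_names)
    for (t, s), i in tau_map.items():
        if bounds[i] is None:
            x0[i] = tau0[t, s]
            bounds[i] = (-3.5, 3.5)
    for (t, s), i in beta_map.items():
        if bounds[i] is None:
            x0[i] = beta0[t, s]
            bounds[i] = (-1.5, 1.5)
    return list(x0), bounds


def _unpack_thresholds(x, tau_map, beta_map):
    tau = np.zeros((2, 2))
    beta = np.zeros((2, 2))
    for (t, s), i in tau_map.items():
        tau[t, s] = x[i]
    for (t, s), i in beta_map.items():
        beta[t, s] = x[i]
    return ThresholdSpec(tau, beta)


def _initial_thresholds(data: TwinData):
    """Probit of per-(trait, sex, band) prevalences, regressed on band score."""
    tau = np.zeros((2, 2))
    beta = np.zeros((2, 2))
    n = np.zeros((2, N_AGE_BANDS))
    k = np.zeros((2, 2, N_AGE_BANDS))  # trait, sex, band
    for gi, g in enumerate(ZYGOSITY_GROUPS):
        _, s1, s2 = GROUP_INFO[g]
        by_band = data.complete[gi]
        for b in range(N_AGE_BANDS):
            cnt = by_band[b]
            tot = cnt.sum()
            if tot == 0:
                continue
            n[s1, b] += tot
            n[s2, b] += tot
            # twin 1 margins
            k[0, s1, b] += cnt[2:, :].sum()
            k[1, s1, b] += cnt[1::2, :].sum()
            k[0, s2, b] += cnt[:, 2:].sum()
            k[1, s2, b] += cnt[:, 1::2].sum()
    for s in range(2):
        for b in range(N_AGE_BANDS):
            tot = data.singles[s, b].sum()
            if tot:
                n[s, b] += tot
                k[0, s, b] += data.singles[s, b, 2:].sum()
                k[1, s, b] += data.singles[s, b, 1::2].sum()
    bands = np.arange(N_AGE_BANDS)
    for t in range(2):
        for s in range(2):
            m = n[s] > 0
            if not m.any():
                continue
            prev = np.clip(k[t, s, m] / n[s, m], 0.02, 0.98)
            z = ndtri(1.0 - prev)
            if m.sum() >= 2:
                w = n[s, m]
                coef = np.polyfit(bands[m], z, 1, w=np.sqrt(w))
                beta[t, s], tau[t, s] = coef[0], coef[1]
            else:
                tau[t, s] = z.mean()
    return tau, beta


def _fit_by_optimizer(objective, x0, bounds, n_starts, rng, maxiter=300):
    """L-BFGS-B with jittered restarts on failure and a polish loop.

    Restarting from the incumbent solution resets the Hessian approximation,
    which reliably walks out of the shallow curved valleys this likelihood
    shows near share boundaries.
    """
    opts = {"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7}
    best = None
    nfev_total = 0
    for start in range(max(1, n_starts)):
        if start == 0:
            xs = np.asarray(x0, dtype=float)
        else:
            jitter = rng.normal(scale=0.08, size=len(x0))
            xs = np.clip(np.asarray(x0) + jitter, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(objective, xs, method="L-BFGS-B", bounds=bounds, options=opts)
        nfev_total += res.nfev
        for _ in range(4):  # polish: restart from the incumbent until flat
            res2 = optimize.minimize(
                objective, res.x, method="L-BFGS-B", bounds=bounds, options=opts
            )
            nfev_total += res2.nfev
            improved = res2.fun < res.fun - 1e-7
            res = res2 if res2.fun <= res.fun else res
            if not improved:
                break
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if best.success:
            break  # converged start found; further jittered starts only on failure
    return best, nfev_total


def fit_model(
    data: TwinData,
    model: str = "ACE",
    fixed: dict | None = None,
    threshold_constraints=(),
    n_nodes: int = 24,
    n_starts: int = 5,
    seed: int = 0,
    start_values: dict | None = None,
    label: str | None = None,
) -> ModelFitResult:
    """Maximum-likelihood fit of a structured bivariate liability model.

    Parameters
    ----------
    model : {"ACE", "AE", "CE", "E"}
        Which components carry free variance shares (dropped components are
        fixed at zero).
    fixed : dict
        Additional equality constraints on the structural free parameters,
        e.g. ``{"rE": 0.0}`` drops the unique-environment overlap path and
        ``{"A2": 0.0}`` drops A for trait 2.
    threshold_constraints : iterable
        Subset of {"drop_age", "equate_sex_trait1", "equate_sex_trait2"}.
    n_starts : int
        Jittered restarts tried until one converges (the first start uses a
        moment-based initial guess).
    """
    fixed = dict(fixed or {})
    model = model.upper()
    if model not in ("ACE", "AE", "CE", "E"):
        raise ValueError(f"unknown model family {model!r}")
    if "A" not in model:
        fixed.setdefault("A1", 0.0)
        fixed.setdefault("A2", 0.0)
    if "C" not in model:
        fixed.setdefault("C1", 0.0)
        fixed.setdefault("C2", 0.0)
    unknown = set(fixed) - set(_STRUCT_NAMES)
    if unknown:
        raise ValueError(f"unknown fixed parameter(s): {sorted(unknown)}")

    # identification: a component correlation is only a parameter when both
    # traits carry that component
    def _share_positive(name, default):
        v = fixed.get(name)
        return default if v is None else v > 0

    if not (_share_positive("A1", True) and _share_positive("A2", True)):
        fixed.setdefault("rA", 0.0)
    if not (_share_positive("C1", True) and _share_positive("C2", True)):
        fixed.setdefault("rC", 0.0)

    struct_free = [n for n in _STRUCT_NAMES if n not in fixed]
    thr_names, tau_map, beta_map = _threshold_param_spec(threshold_constraints)

    tau0, beta0 = _initial_thresholds(data)
    defaults = {"A1": 0.5, "C1": 0.05, "A2": 0.4, "C2": 0.05, "rA": 0.3, "rC": 0.2, "rE": 0.15}
    if start_values:
        defaults.update(start_values)
    x0 = []
    bounds = []
    for name in struct_free:
        x0.append(defaults[name])
        bounds.append(_CORR_BOUND if name.startswith("r") else _SHARE_BOUND)
    thr_x0, thr_bounds = _threshold_x0_bounds(thr_names, tau_map, beta_map, tau0, beta0)
    x0.extend(thr_x0)
    bounds.extend(thr_bounds)
    n_free = len(struct_free) + len(thr_names)
    rng = np.random.default_rng(seed)

    def objective(x):
        vals = dict(fixed)
        vals.update(zip(struct_free, x[: len(struct_free)]))
        # admissibility: E share strictly positive.  Rather than a hard
        # infeasibility cliff (which breaks the line search), shares are
        # rescaled into the admissible region and a smooth penalty added.
        pen = 0.0
        for t in ("1", "2"):
            a, c = vals[f"A{t}"], vals[f"C{t}"]
            e = 1.0 - a - c
            if e < 0.02:
                pen += (0.02 - e) ** 2 * 1e6
                scale = (1.0 - 0.02) / (a + c)
                vals[f"A{t}"], vals[f"C{t}"] = a * scale, c * scale
        try:
            params = ACEBivariateParams.from_shares(
                vals["A1"], vals["A2"], vals["rA"], vals["rE"], vals["C1"], vals["C2"], vals["rC"]
            )
            thr = _unpack_thresholds(x[len(struct_free):], tau_map, beta_map)
            return sample_minus2LL(data, params, thr, n_nodes) + pen
        except (ValueError, FloatingPointError):
            return 1e12

    res, nfev = _fit_by_optimizer(objective, x0, bounds, n_starts, rng)
    xb = res.x
    vals = dict(fixed)
    vals.update(zip(struct_free, xb[: len(struct_free)]))
    params = ACEBivariateParams.from_shares(
        vals["A1"], vals["A2"], vals["rA"], vals["rE"], vals["C1"], vals["C2"], vals["rC"]
    )
    thr = _unpack_thresholds(xb[len(struct_free):], tau_map, beta_map)
    return ModelFitResult(
        minus2LL=float(res.fun),
        n_free=n_free,
        df=data.n_observations - n_free,
        params=params,
        thresholds=thr,
        estimates={**vals, "thresholds": thr},
        converged=bool(res.success),
        n_function_evals=nfev,
        label=label or f"{model} model",
        context={
            "data": data,
            "model": model,
            "fixed": dict(fixed),
            "threshold_constraints": tuple(threshold_constraints),
            "n_nodes": n_nodes,
            "struct_free": struct_free,
            "minimum": xb,
        },
    )


def fit_saturated(
    data: TwinData,
    equate_across_sex: bool = True,
    threshold_constraints=(),
    n_nodes: int = 24,
    n_starts: int = 3,
    seed: int = 0,
    label: str | None = None,
):
    """Saturated correlation model: per-group tetrachoric correlation
    structure (cross-twin trait 1/trait 2, within-twin cross-trait,
    cross-twin cross-trait) plus sex- and age-moderated thresholds.

    With ``equate_across_sex`` the correlations are tied MZM = MZF and
    DZM = DZF = DOS (the constraint the motivating analysis retained);
    otherwise each of the five groups has its own four correlations.
    Birth-order symmetry is built into the likelihood engine.

    Returns ``(table, fit)`` where ``table`` is a tidy DataFrame of the
    estimated correlations per (tied) group.
    """
    if data.n_pairs == 0:
        raise ValueError("saturated fit needs complete pairs")
    tie = {g: GROUP_INFO[g][0] for g in ZYGOSITY_GROUPS} if equate_across_sex else {
        g: g for g in ZYGOSITY_GROUPS
    }
    units = sorted(set(tie.values()))
    thr_names, tau_map, beta_map = _threshold_param_spec(threshold_constraints)
    tau0, beta0 = _initial_thresholds(data)

    # internal parameterization keeps the exchangeable decomposition PSD by
    # construction: per unit (r1, r2, cx, cw) with the cross-twin cross-trait
    # and within-twin cross-trait correlations expressed as fractions of
    # their admissible ranges, rx = cx*sqrt(r1*r2) and
    # rwc = rx + cw*sqrt((1-r1)(1-r2)).  No feasibility cliffs remain, which
    # the quasi-Newton line search needs.
    x0 = []
    bounds = []
    for _ in units:
        x0.extend([0.5, 0.4, 0.4, 0.2])
        bounds.extend([(0.0, 0.98), (0.0, 0.98), (-0.99, 0.99), (-0.99, 0.99)])
    ncorr = len(x0)
    thr_x0, thr_bounds = _threshold_x0_bounds(thr_names, tau_map, beta_map, tau0, beta0)
    x0.extend(thr_x0)
    bounds.extend(thr_bounds)
    n_free = ncorr + len(thr_names)

    def _derive(raw):
        r1, r2, cx, cw = raw
        rx = cx * math.sqrt(r1 * r2)
        rwc = rx + cw * math.sqrt((1 - r1) * (1 - r2))
        return r1, r2, rwc, rx

    def unpack(x):
        corr_units = {u: _derive(x[4 * i: 4 * i + 4]) for i, u in enumerate(units)}
        corr = {g: corr_units[tie[g]] for g in ZYGOSITY_GROUPS}
        thr = _unpack_thresholds(x[ncorr:], tau_map, beta_map)
        return corr, thr

    def objective(x):
        corr, thr = unpack(x)
        dev = _saturated_deviance(data, corr, thr, n_nodes)
        return 1e12 if dev is None else dev

    rng = np.random.default_rng(seed)
    res, nfev = _fit_by_optimizer(objective, x0, bounds, n_starts, rng)
    corr, thr = unpack(res.x)

    rows = []
    for u in units:
        r1, r2, rwc, rx = corr[next(g for g in ZYGOSITY_GROUPS if tie[g] == u)]
        at_bound = max(abs(r1), abs(r2), abs(rwc), abs(rx)) > 0.975
        rows.append(
            {
                "group": u,
                "cross_twin_trait1": r1,
                "cross_twin_trait2": r2,
                "within_twin_cross_trait": rwc,
                "cross_twin_cross_trait": rx,
                "bound_hit": at_bound,
            }
        )
    table = pd.DataFrame(rows)
    fit = ModelFitResult(
        minus2LL=float(res.fun),
        n_free=n_free,
        df=data.n_observations - n_free,
        params=None,
        thresholds=thr,
        estimates={"correlations": corr, "table": table},
        converged=bool(res.success),
        n_function_evals=nfev,
        label=label or ("saturated (sex-equated)" if equate_across_sex else "saturated"),
        context={
            "data": data,
            "model": "saturated",
            "equate_across_sex": equate_across_sex,
            "threshold_constraints": tuple(threshold_constraints),
            "n_nodes": n_nodes,
        },
    )
    return table, fit


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def likelihood_ratio_test(
    fit_sub: ModelFitResult, fit_full: ModelFitResult, alpha: float = 0.05
) -> LRTResult:
    """Chi-square test of a nested restriction.

    The restricted model's deviance can never genuinely fall below the full
    model's; a negative difference beyond rounding noise signals non-nesting
    or a failed optimization.
    """
    chi2 = fit_sub.minus2LL - fit_full.minus2LL
    if chi2 < -1e-6:
        raise ValueError(
            f"negative LRT statistic ({chi2:.3g}): models not nested or not converged"
        )
    chi2 = max(chi2, 0.0)
    delta_df = fit_full.n_free - fit_sub.n_free
    if delta_df <= 0:
        raise ValueError("submodel must have fewer free parameters than the full model")
    p = float(chi2_dist.sf(chi2, delta_df))
    return LRTResult(chi2=chi2, delta_df=delta_df, p=p, retained=p >= alpha)


def model_selection_sequence(
    data: TwinData,
    steps=None,
    alpha: float = 0.05,
    n_nodes: int = 24,
    seed: int = 0,
):
    """Stepwise constraint cascade with likelihood-ratio retention.

    Each step is tested against the current best model and kept iff it does
    not significantly worsen fit (p >= alpha); rejected steps are skipped and
    the cascade continues.  ``steps`` is a list of dicts with keys ``label``
    and either ``model``/``fixed``/``threshold_constraints`` (absolute model
    specification) or ``add_fixed`` (incremental constraints on the current
    structured model).  A step with ``mandatory: True`` (e.g. the ACE
    baseline that submodels are built on) is adopted regardless of its own
    test, which is still reported.  With no steps the saturated fit is
    returned as-is.

    Returns ``(report, best_fit)`` where ``report`` is a DataFrame with one
    row per attempted model.
    """
    _, sat = fit_saturated(data, n_nodes=n_nodes, seed=seed)
    rows = [
        {
            "model": sat.label,
            "n_free": sat.n_free,
            "minus2LL": sat.minus2LL,
            "df": sat.df,
            "chi2": np.nan,
            "delta_df": 0,
            "p": np.nan,
            "retained": True,
        }
    ]
    best = sat
    if not steps:
        return pd.DataFrame(rows), best

    current_model = None  # None while still in the saturated family
    current_fixed: dict = {}
    current_tc: tuple = ()
    for step in steps:
        label = step.get("label", "constraint")
        model = step.get("model", current_model)
        fixed = dict(current_fixed)
        fixed.update(step.get("fixed", {}))
        fixed.update(step.get("add_fixed", {}))
        tc = tuple(step.get("threshold_constraints", current_tc))
        try:
            if model is None:
                raise ValueError(f"step {label!r} before any structured model step")
            fit = fit_model(
                data, model=model, fixed=fixed, threshold_constraints=tc,
                n_nodes=n_nodes, seed=seed, label=label,
            )
            lrt = likelihood_ratio_test(fit, best, alpha=alpha) if fit.n_free < best.n_free else None
        except (ValueError, FloatingPointError) as exc:
            rows.append(
                {"model": label, "n_free": np.nan, "minus2LL": np.nan, "df": np.nan,
                 "chi2": np.nan, "delta_df": np.nan, "p": np.nan, "retained": False,
                 "error": str(exc)}
            )
            continue
        retained = lrt.retained if lrt is not None else True
        adopt = retained or bool(step.get("mandatory", False))
        rows.append(
            {
                "model": label,
                "n_free": fit.n_free,
                "minus2LL": fit.minus2LL,
                "df": fit.df,
                "chi2": lrt.chi2 if lrt else np.nan,
                "delta_df": lrt.delta_df if lrt else np.nan,
                "p": lrt.p if lrt else np.nan,
                "retained": retained,
            }
        )
        if adopt:
            best = fit
            current_model = model
            current_fixed = fixed
            current_tc = tc
    return pd.DataFrame(rows), best


def correlations_from_params(params: ACEBivariateParams) -> CorrelationSummary:
    """Component correlations, standardized variance shares and the
    decomposition of the phenotypic liability covariance into A/C/E shares
    (the shares sum to one).

    A component with zero variance on either trait has an undefined
    correlation (reported as ``None``) and contributes nothing to the
    overlap decomposition.
    """
    params = params.standardized()
    covs = {c: params.component_cov(c) for c in "ACE"}
    shares = {}
    rs = {}
    contribs = {}
    for c, S in covs.items():
        v1, v2 = S[0, 0], S[1, 1]
        shares[c] = (v1, v2)
        if v1 <= 1e-12 or v2 <= 1e-12:
            rs[c] = None
            contribs[c] = 0.0
        else:
            rs[c] = float(S[0, 1] / math.sqrt(v1 * v2))
            contribs[c] = float(rs[c] * math.sqrt(v1 * v2))
    total = sum(contribs.values())
    if abs(total) < 1e-12:
        overlaps = {c: 0.0 for c in "ACE"}
    else:
        overlaps = {c: contribs[c] / total for c in "ACE"}
    return CorrelationSummary(
        rA=rs["A"], rC=rs["C"], rE=rs["E"],
        A1=shares["A"][0], C1=shares["C"][0], E1=shares["E"][0],
        A2=shares["A"][1], C2=shares["C"][1], E2=shares["E"][1],
        overlap_A=overlaps["A"], overlap_C=overlaps["C"], overlap_E=overlaps["E"],
    )


def _profiled_deviance(fit: ModelFitResult, name: str, value: float) -> float:
    ctx = fit.context
    refit = fit_model(
        ctx["data"],
        model=ctx["model"],
        fixed={**ctx["fixed"], name: value},
        threshold_constraints=ctx["threshold_constraints"],
        n_nodes=ctx["n_nodes"],
        n_starts=1,
        start_values={k: v for k, v in fit.estimates.items() if k in _STRUCT_NAMES},
    )
    return refit.minus2LL


def confidence_intervals(
    fit: ModelFitResult,
    level: float = 0.95,
    method: str = "profile",
    quantities=("rA", "rE", "A1", "A2"),
    n_boot: int = 200,
    seed: int = 0,
) -> dict:
    """Confidence intervals for structural quantities of a fitted model.

    ``profile`` inverts the likelihood-ratio test: the bound is where the
    profiled deviance rises by the chi-square(1) critical value.  When no
    crossing exists inside the parameter box the interval is one-sided and a
    warning string is attached.  ``bootstrap`` refits ``n_boot`` multinomial
    resamples of the pattern counts and takes percentile bounds.
    """
    if not fit.converged:
        raise ValueError("confidence intervals require a converged fit")
    if fit.params is None:
        raise ValueError("confidence intervals are defined for structured fits")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must be in [0, 1)")
    est = {q: float(fit.estimates[q]) for q in quantities}
    if level == 0.0:
        return {q: (v, v, None) for q, v in est.items()}

    out = {}
    if method == "profile":
        crit = float(chi2_dist.ppf(level, 1))
        target = fit.minus2LL + crit
        for q in quantities:
            if q in fit.context["fixed"]:
                out[q] = (est[q], est[q], "parameter fixed in this model")
                continue
            lo_box, hi_box = _CORR_BOUND if q.startswith("r") else _SHARE_BOUND

            def g(v):
                return _profiled_deviance(fit, q, v) - target

            bounds = []
            warn = None
            for box, side in ((lo_box, "lower"), (hi_box, "upper")):
                try:
                    if g(box) < 0:
                        bounds.append(box)
                        warn = f"{side} bound at parameter box edge"
                    else:
                        bounds.append(
                            float(optimize.brentq(g, min(est[q], box), max(est[q], box), xtol=1e-4))
                        )
                except ValueError:
                    bounds.append(box)
                    warn = f"{side} profile bound not bracketed"
            out[q] = (min(bounds), max(bounds), warn)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        ctx = fit.context
        draws = {q: [] for q in quantities}
        for _ in range(n_boot):
            bdata = ctx["data"].resampled(rng)
            bfit = fit_model(
                bdata, model=ctx["model"], fixed=ctx["fixed"],
                threshold_constraints=ctx["threshold_constraints"],
                n_nodes=ctx["n_nodes"], n_starts=1, start_values=est,
            )
            for q in quantities:
                draws[q].append(float(bfit.estimates[q]))
        a = (1.0 - level) / 2.0
        for q in quantities:
            lo, hi = np.quantile(draws[q], [a, 1.0 - a])
            out[q] = (float(min(lo, est[q])), float(max(hi, est[q])), None)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return out
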