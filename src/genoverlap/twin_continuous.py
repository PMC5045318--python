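"""Sensitivity variant: binary smoking x continuous caffeine twin model.

Instead of dichotomizing caffeine intake, trait 2 is observed on its raw
scale (mg/day), modelled as a linear transform of its standard-normal
liability: ``caffeine = mu_sex + beta_age_sex * band + scale * liability``.
Trait 1 (current smoking) remains a thresholded liability.  The pair
likelihood factorizes in closed form: the two continuous observations are
bivariate normal under the usual MZ/DZ structure, and conditionally on them
the two binary liabilities are bivariate normal with shifted means, so each
pair contributes a normal density times a bivariate rectangle probability.

This variant exists for robustness checks only; real caffeine intake is
right-skewed, which this Gaussian measurement model does not capture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import ndtri

from .mvn import quadrant_probs
from .twin_model import (
    GROUP_INFO,
    N_AGE_BANDS,
    ZYGOSITY_GROUPS,
    ACEBivariateParams,
    ModelFitResult,
    ThresholdSpec,
)

__all__ = [
    "ContinuousTwinTable",
    "simulate_twin_sample_continuous",
    "sample_minus2LL_continuous",
    "fit_model_continuous",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class ContinuousTwinTable:
    """Column arrays of complete twin pairs with a binary trait 1 and a
    continuous trait 2 (incomplete pairs enter as singles)."""

    group: np.ndarray  # zygosity group label per pair
    band: np.ndarray
    smoke_t1: np.ndarray
    caff_t1: np.ndarray
    smoke_t2: np.ndarray
    caff_t2: np.ndarray

    def __post_init__(self):
        n = len(self.group)
        for name in ("band", "smoke_t1", "caff_t1", "smoke_t2", "caff_t2"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} length mismatch")

    def __len__(self):
        return len(self.group)


def simulate_twin_sample_continuous(
    params: ACEBivariateParams,
    smoking_thresholds: ThresholdSpec,
    design,
    caffeine_mean: float = 250.0,
    caffeine_age_slope: float = 25.0,
    caffeine_scale: float = 150.0,
    rng: np.random.Generator | None = None,
) -> ContinuousTwinTable:
    """Draw complete pairs with smoking binarized and caffeine observed as
    ``mean + slope*band + scale*liability`` (same liability structure as the
    binary generator)."""
    params.validate(atol=1e-6, require_e=False)
    rng = np.random.default_rng(design.seed) if rng is None else rng
    groups, bands, s1, c1, s2, c2 = [], [], [], [], [], []
    for group in ZYGOSITY_GROUPS:
        n = int(design.n_pairs_by_group.get(group, 0))
        if n == 0:
            continue
        zclass, sx1, sx2 = GROUP_INFO[group]
        w = 1.0 if zclass == "MZ" else 0.5
        shared_a = rng.standard_normal((n, 2))
        a_t1 = np.sqrt(w) * shared_a + np.sqrt(1 - w) * rng.standard_normal((n, 2))
        a_t2 = np.sqrt(w) * shared_a + np.sqrt(1 - w) * rng.standard_normal((n, 2))
        c = rng.standard_normal((n, 2))

        def lia(a, e):
            l1 = params.a11 * a[:, 0] + params.c11 * c[:, 0] + params.e11 * e[:, 0]
            l2 = (params.a21 * a[:, 0] + params.a22 * a[:, 1]
                  + params.c21 * c[:, 0] + params.c22 * c[:, 1]
                  + params.e21 * e[:, 0] + params.e22 * e[:, 1])
            return l1, l2

        l1_t1, l2_t1 = lia(a_t1, rng.standard_normal((n, 2)))
        l1_t2, l2_t2 = lia(a_t2, rng.standard_normal((n, 2)))
        b = rng.choice(N_AGE_BANDS, size=n, p=np.asarray(design.age_category_probs))
        thr1 = smoking_thresholds.threshold(0, sx1, b)
        thr2 = smoking_thresholds.threshold(0, sx2, b)
        base = caffeine_mean + caffeine_age_slope * b
        groups.append(np.repeat(group, n))
        bands.append(b)
        s1.append((l1_t1 > thr1).astype(int))
        s2.append((l1_t2 > thr2).astype(int))
        c1.append(base + caffeine_scale * l2_t1)
        c2.append(base + caffeine_scale * l2_t2)
    return ContinuousTwinTable(
        np.concatenate(groups), np.concatenate(bands),
        np.concatenate(s1), np.concatenate(c1),
        np.concatenate(s2), np.concatenate(c2),
    )


def _pair_loglik(table, params, thresholds, mu, slope, scale):
    """Sum of log pair likelihoods; returns -inf on numerical failure."""
    SA, SC, SE = params.sigma_a, params.sigma_c, params.sigma_e
    total = 0.0
    for group in ZYGOSITY_GROUPS:
        m = table.group == group
        if not m.any():
            continue
        zclass, sx1, sx2 = GROUP_INFO[group]
        w = 1.0 if zclass == "MZ" else 0.5
        cross = w * SA + SC
        within = SA + SC + SE
        b = table.band[m]
        z1 = (table.caff_t1[m] - mu - slope * b) / scale
        z2 = (table.caff_t2[m] - mu - slope * b) / scale

        # continuous block: bivariate normal (z1, z2), var 1, corr r22
        r22 = float(np.clip(cross[1, 1], -0.999, 0.999))
        det = 1.0 - r22 * r22
        quad = (z1 * z1 - 2 * r22 * z1 * z2 + z2 * z2) / det
        total += float(np.sum(-0.5 * (quad + np.log(det)) - _LOG2PI - 2 * np.log(scale)))

        # binary block given continuous: (l1_t1, l1_t2) | (z1, z2)
        S22 = np.array([[1.0, r22], [r22, 1.0]])
        S12 = np.array([[within[0, 1], cross[0, 1]], [cross[0, 1], within[0, 1]]])
        coef = S12 @ np.linalg.inv(S22)
        cond = np.array([[1.0, cross[0, 0]], [cross[0, 0], 1.0]]) - coef @ S12.T
        sd = np.sqrt(max(cond[0, 0], 1e-8))
        rho_c = float(np.clip(cond[0, 1] / (sd * sd), -0.999, 0.999))
        mean1 = coef[0, 0] * z1 + coef[0, 1] * z2
        mean2 = coef[1, 0] * z1 + coef[1, 1] * z2
        t1 = (thresholds.threshold(0, sx1, b) - mean1) / sd
        t2 = (thresholds.threshold(0, sx2, b) - mean2) / sd
        probs = quadrant_probs(t1, t2, rho_c)
        idx = 2 * table.smoke_t1[m] + table.smoke_t2[m]
        # quadrant order (00, 01, 10, 11) maps (smoke_t1, smoke_t2)
        remap = np.array([0, 1, 2, 3])
        p = probs[np.arange(m.sum()), remap[idx]]
        if np.any(p < 1e-300):
            return -np.inf
        total += float(np.sum(np.log(p)))
    return total


def sample_minus2LL_continuous(
    table: ContinuousTwinTable,
    params: ACEBivariateParams,
    smoking_thresholds: ThresholdSpec,
    caffeine_mean: float,
    caffeine_age_slope: float,
    caffeine_scale: float,
) -> float:
    ll = _pair_loglik(table, params, smoking_thresholds, caffeine_mean,
                      caffeine_age_slope, caffeine_scale)
    if not np.isfinite(ll):
        raise FloatingPointError("likelihood underflow in continuous model")
    return -2.0 * ll


def fit_model_continuous(
    table: ContinuousTwinTable,
    model: str = "AE",
    fixed: dict | None = None,
    seed: int = 0,
) -> ModelFitResult:
    """ML fit of the binary x continuous AE/ACE model.

    Structural free parameters as in :func:`genoverlap.twin_model.fit_model`;
    nuisance parameters are the smoking threshold (tau + age beta, shared
    across sex here) and the caffeine location/age-slope/scale.
    """
    fixed = dict(fixed or {})
    if model.upper() == "AE":
        fixed.setdefault("C1", 0.0)
        fixed.setdefault("C2", 0.0)
        fixed.setdefault("rC", 0.0)
    struct_free = [n for n in ("A1", "C1", "A2", "C2", "rA", "rC", "rE") if n not in fixed]

    czs = table.caff_t1
    mu0, sc0 = float(czs.mean()), float(czs.std())
    prev = float(np.mean(np.concatenate([table.smoke_t1, table.smoke_t2])))
    x0 = [0.5 if not n.startswith("r") else 0.2 for n in struct_free]
    x0 += [ndtri(1 - prev), 0.0, mu0, 0.0, sc0]
    bounds = [(-0.97, 0.97) if n.startswith("r") else (0.0, 0.97) for n in struct_free]
    bounds += [(-3, 3), (-1, 1), (mu0 - 5 * sc0, mu0 + 5 * sc0), (-sc0, sc0),
               (sc0 / 10, sc0 * 10)]

    def objective(x):
        vals = dict(fixed)
        vals.update(zip(struct_free, x[: len(struct_free)]))
        pen = 0.0
        for t in ("1", "2"):
            a, c = vals[f"A{t}"], vals[f"C{t}"]
            if 1 - a - c < 0.02:
                pen += 1e6 * (0.02 - (1 - a - c)) ** 2
                s = 0.98 / (a + c)
                vals[f"A{t}"], vals[f"C{t}"] = a * s, c * s
        tau, beta, mu, slope, scale = x[len(struct_free):]
        try:
            params = ACEBivariateParams.from_shares(
                vals["A1"], vals["A2"], vals["rA"], vals["rE"],
                vals["C1"], vals["C2"], vals["rC"],
            )
            thr = ThresholdSpec(np.full((2, 2), tau), np.full((2, 2), beta))
            return sample_minus2LL_continuous(table, params, thr, mu, slope, scale) + pen
        except (ValueError, FloatingPointError):
            return 1e12

    res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 400, "ftol": 1e-11})
    for _ in range(3):
        res2 = optimize.minimize(objective, res.x, method="L-BFGS-B", bounds=bounds,
                                 options={"maxiter": 400, "ftol": 1e-11})
        if res2.fun >= res.fun - 1e-7:
            res = res2 if res2.fun < res.fun else res
            break
        res = res2
    vals = dict(fixed)
    vals.update(zip(struct_free, res.x[: len(struct_free)]))
    tau, beta, mu, slope, scale = res.x[len(struct_free):]
    params = ACEBivariateParams.from_shares(
        vals["A1"], vals["A2"], vals["rA"], vals["rE"],
        vals["C1"], vals["C2"], vals["rC"],
    )
    n_free = len(struct_free) + 5
    return ModelFitResult(
        minus2LL=float(res.fun),
        n_free=n_free,
        df=3 * len(table) - n_free,
        params=params,
        thresholds=ThresholdSpec(np.full((2, 2), tau), np.full((2, 2), beta)),
        estimates={**vals, "caffeine_mean": mu, "caffeine_age_slope": slope,
                   "caffeine_scale": scale},
        converged=bool(res.success),
        n_function_evals=int(res.nfev),
        label=f"{model} (continuous trait 2)",
    )
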