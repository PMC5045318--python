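"""Multivariate-normal rectangle probabilities for liability-threshold models.

Two engines live here:

* :func:`bvn_upper` — a vectorized bivariate-normal upper-orthant probability
  P(X > h, Y > k) following Genz's hybrid of Drezner–Wesolowsky quadrature
  (moderate correlation) and the tail-series expansion (|rho| >= 0.925).
  scipy only exposes the bivariate CDF through the generic Fortran MVN
  routine, one point at a time; liability likelihoods need tens of
  thousands of evaluations per deviance, so a NumPy-vectorized form is
  implemented here and cross-checked against scipy in the test suite.

* :func:`exchangeable_pair_pattern_probs` — joint probabilities of the 16
  binary response patterns of a twin pair whose liabilities decompose into a
  shared bivariate factor plus independent within-twin residuals.  The pair
  integral factorizes conditionally on the shared factor, which reduces the
  4-D orthant problem to a 2-D Gauss–Hermite quadrature over products of
  bivariate rectangle probabilities.  The 16 probabilities of a cell come out
  of a single quadrature pass and sum to one by construction.

A generic (any dimension, any correlation matrix) rectangle probability
:func:`orthant_probability` wraps scipy's Genz–Bretz integrator with a fixed
internal seed so deviances are reproducible run to run.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from numpy.polynomial.legendre import leggauss
from scipy.special import ndtr
from scipy.stats import multivariate_normal

__all__ = [
    "bvn_upper",
    "quadrant_probs",
    "orthant_probability",
    "exchangeable_pair_pattern_probs",
]

# liability cutpoints beyond +-8.5 SD carry probabilities < 1e-17; clipping
# keeps the tail series finite without visible error
_CLIP = 8.5

_LEGENDRE = {n: leggauss(n) for n in (6, 12, 20)}


def _phid(x):
    return ndtr(x)


def bvn_upper(h, k, rho):
    """P(X > h, Y > k) for standard bivariate normal with correlation rho.

    ``h`` and ``k`` broadcast; ``rho`` is a scalar in [-1, 1].
    Accuracy is ~1e-15 (moderate rho) to ~1e-14 (|rho| near 1).
    """
    h = np.clip(np.asarray(h, dtype=float), -_CLIP, _CLIP)
    k = np.clip(np.asarray(k, dtype=float), -_CLIP, _CLIP)
    h, k = np.broadcast_arrays(h, k)
    rho = float(rho)
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"correlation out of range: {rho}")

    if rho == 1.0:
        return _phid(-np.maximum(h, k))
    if rho == -1.0:
        return np.maximum(0.0, _phid(-k) - _phid(h))

    if abs(rho) < 0.925:
        if abs(rho) < 0.3:
            x, w = _LEGENDRE[6]
        elif abs(rho) < 0.75:
            x, w = _LEGENDRE[12]
        else:
            x, w = _LEGENDRE[20]
        asr = np.arcsin(rho)
        sn = np.sin(asr * (1.0 + x) / 2.0)  # nodes on (0, asin rho)
        hk = (h * k)[..., None]
        hs = ((h * h + k * k) / 2.0)[..., None]
        integrand = np.exp((sn * hk - hs) / (1.0 - sn * sn))
        bvn = integrand @ w * (asr / (4.0 * np.pi))
        return bvn + _phid(-h) * _phid(-k)

    # |rho| >= 0.925: Drezner-Wesolowsky tail expansion (Genz's BVND)
    x, w = _LEGENDRE[20]
    kk = -k if rho < 0 else k.copy()
    hk = h * kk
    bvn = np.zeros_like(h)
    if abs(rho) < 1.0:
        ass = (1.0 - rho) * (1.0 + rho)
        a = np.sqrt(ass)
        bs = (h - kk) ** 2
        c = (4.0 - hk) / 8.0
        d = (12.0 - hk) / 16.0
        asr = -(bs / ass + hk) / 2.0
        m = asr > -100.0
        bvn[m] = (
            a
            * np.exp(asr[m])
            * (
                1.0
                - c[m] * (bs[m] - ass) * (1.0 - d[m] * bs[m] / 5.0) / 3.0
                + c[m] * d[m] * ass * ass / 5.0
            )
        )
        m = -hk < 100.0
        b = np.sqrt(bs)
        bvn[m] -= (
            np.exp(-hk[m] / 2.0)
            * np.sqrt(2.0 * np.pi)
            * _phid(-b[m] / a)
            * b[m]
            * (1.0 - c[m] * bs[m] * (1.0 - d[m] * bs[m] / 5.0) / 3.0)
        )
        a2 = a / 2.0
        for xi, wi in zip(x, w):
            xs = (a2 * (xi + 1.0)) ** 2
            rs = np.sqrt(1.0 - xs)
            asr = -(bs / xs + hk) / 2.0
            m = asr > -100.0
            sp = 1.0 + c[m] * xs * (1.0 + d[m] * xs)
            ep = np.exp(-hk[m] * (1.0 - rs) / (2.0 * (1.0 + rs))) / rs
            bvn[m] += a2 * wi * np.exp(asr[m]) * (ep - sp)
        bvn = -bvn / (2.0 * np.pi)
    if rho > 0:
        bvn = bvn + _phid(-np.maximum(h, kk))
    else:
        bvn = -bvn
        m = kk > h
        bvn[m] += _phid(kk[m]) - _phid(h[m])
    return np.clip(bvn, 0.0, 1.0)


def quadrant_probs(t1, t2, rho):
    """Probabilities of the four joint binary outcomes of two thresholded
    standard-normal variables with correlation ``rho``.

    Returns an array ``(..., 4)`` ordered (00, 01, 10, 11) where outcome 1
    means the liability exceeds its cutpoint.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    p11 = bvn_upper(t1, t2, rho)
    p1 = _phid(-np.clip(t1, -_CLIP, _CLIP))
    p2 = _phid(-np.clip(t2, -_CLIP, _CLIP))
    p10 = np.clip(p1 - p11, 0.0, 1.0)
    p01 = np.clip(p2 - p11, 0.0, 1.0)
    p00 = np.clip(1.0 - p1 - p2 + p11, 0.0, 1.0)
    return np.stack([p00, p01, p10, p11], axis=-1)


def orthant_probability(R, lower, upper, abseps=1e-7):
    """Rectangle probability of a zero-mean MVN with correlation matrix R.

    Bounds may be ``+-inf``.  Uses scipy's Genz–Bretz quadrature with a fixed
    internal seed so repeated calls return identical values.
    """
    R = np.asarray(R, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    d = R.shape[0]
    if R.shape != (d, d) or lower.shape != (d,) or upper.shape != (d,):
        raise ValueError(
            f"dimension mismatch: R {R.shape}, lower {lower.shape}, upper {upper.shape}"
        )
    if np.any(lower > upper):
        raise ValueError("lower bound exceeds upper bound")
    eig = np.linalg.eigvalsh(R)
    if eig[0] < -1e-8:
        raise ValueError(f"correlation matrix not PSD (min eigenvalue {eig[0]:.3g})")
    p = multivariate_normal.cdf(
        upper,
        mean=np.zeros(d),
        cov=R,
        allow_singular=True,
        lower_limit=lower,
        abseps=abseps,
        releps=0.0,
        rng=np.random.default_rng(0),
    )
    # Genz-Bretz returns tiny negatives for near-empty rectangles
    return float(np.clip(p, 0.0, 1.0))


def _gh_nodes(n_nodes):
    x, w = hermgauss(n_nodes)
    z = np.sqrt(2.0) * x
    w = w / np.sqrt(np.pi)
    zz1, zz2 = np.meshgrid(z, z, indexing="ij")
    grid = np.column_stack([zz1.ravel(), zz2.ravel()])
    wts = np.outer(w, w).ravel()
    return grid, wts


_GH_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def exchangeable_pair_pattern_probs(
    cov_shared, cov_within, thr_twin1, thr_twin2, n_nodes=24
):
    """Joint pattern probabilities for a pair of bivariate binary liabilities.

    The pair's 4-D liability vector is assumed exchangeable:
    ``y_twin = u + e_twin`` with a shared factor ``u ~ N(0, cov_shared)`` and
    independent residuals ``e ~ N(0, cov_within)``; ``cov_shared +
    cov_within`` must have unit diagonal.  Any ACE twin structure and any
    birth-order-symmetric saturated correlation model can be written this way.

    Parameters
    ----------
    thr_twin1, thr_twin2 : array (..., 2)
        Liability cutpoints per trait for each twin (batched, e.g. over age
        bands).
    n_nodes : int
        Gauss–Hermite nodes per shared-factor dimension.

    Returns
    -------
    array (..., 4, 4)
        ``probs[..., i, j]`` is the probability twin 1 shows pattern ``i``
        and twin 2 pattern ``j``, patterns ordered (00, 01, 10, 11).
    """
    cov_shared = np.asarray(cov_shared, dtype=float)
    cov_within = np.asarray(cov_within, dtype=float)
    total = cov_shared + cov_within
    if np.max(np.abs(np.diag(total) - 1.0)) > 1e-6:
        raise ValueError("shared + within covariance must have unit diagonal")
    # PSD checks with an informative message: non-PSD structures arise from
    # invalid path loadings or inadmissible saturated correlations
    for name, m in (("shared", cov_shared), ("within", cov_within)):
        if m[0, 0] < -1e-10 or m[1, 1] < -1e-10 or np.linalg.det(m) < -1e-10:
            raise ValueError(
                f"{name} covariance block is not positive semi-definite: {m.tolist()}"
            )

    if n_nodes not in _GH_CACHE:
        _GH_CACHE[n_nodes] = _gh_nodes(n_nodes)
    grid, wts = _GH_CACHE[n_nodes]

    # closed-form 2x2 lower Cholesky of the shared block (smooth in the
    # entries, unlike an eigendecomposition, which matters for finite-
    # difference gradients during fitting); tolerates semi-definiteness
    s11 = max(cov_shared[0, 0], 0.0)
    s22 = max(cov_shared[1, 1], 0.0)
    s12 = cov_shared[0, 1]
    if s11 > 1e-14:
        l11 = np.sqrt(s11)
        l21 = s12 / l11
        l22 = np.sqrt(max(s22 - l21 * l21, 0.0))
    else:
        l11, l21, l22 = 0.0, 0.0, np.sqrt(s22)
    L = np.array([[l11, 0.0], [l21, l22]])
    u = grid @ L.T  # (n_nodes^2, 2)

    s = np.sqrt(np.clip(np.diag(cov_within), 1e-12, None))
    rho_w = float(np.clip(cov_within[0, 1] / (s[0] * s[1]), -0.9999, 0.9999))

    thr_twin1 = np.asarray(thr_twin1, dtype=float)
    thr_twin2 = np.asarray(thr_twin2, dtype=float)
    same = thr_twin1 is thr_twin2 or np.array_equal(thr_twin1, thr_twin2)

    def conditional(thr):
        a = (thr[..., None, :] - u) / s  # (..., nodes, 2)
        return quadrant_probs(a[..., 0], a[..., 1], rho_w)  # (..., nodes, 4)

    p1 = conditional(thr_twin1)
    p2 = p1 if same else conditional(thr_twin2)
    return np.einsum("n,...ni,...nj->...ij", wts, p1, p2)
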