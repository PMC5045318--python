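"""Mendelian randomization: phenotype derivation, allele scores, causal
tests, cluster-robust inference and the power calculator."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from genoverlap.instruments import coffee_score_weights
from genoverlap.mr import (
    PowerSpec,
    causal_test_caffeine_to_smoking,
    causal_test_smoking_to_caffeine,
    confounder_check,
    derive_smoking_phenotypes,
    detectable_effect,
    dichotomize_high_use,
    instrument_check,
    mr_power,
    weighted_risk_score,
)
from genoverlap.synthetic import MRSimSpec, simulate_mr_cohort


@pytest.fixture(scope="module")
def null_cohort():
    return simulate_mr_cohort(MRSimSpec(n_individuals=12_000, seed=42))


# ---------------------------------------------------------------------------
# phenotype derivation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "status,expected",
    [("never", (0, 0, None)), ("former", (1, 0, 0)), ("current", (1, 1, 1))],
)
def test_smoking_phenotype_definitions(status, expected):
    assert derive_smoking_phenotypes(status) == expected


def test_unknown_status_rejected():
    with pytest.raises(ValueError, match="unknown smoking status"):
        derive_smoking_phenotypes("sometimes")


def test_dichotomize_normal_upper_tail():
    rng = np.random.default_rng(0)
    v = rng.normal(size=100_000)
    high = dichotomize_high_use(v, np.zeros(len(v)))
    assert high.mean() == pytest.approx(norm.sf(1.0), abs=0.01)


def test_dichotomize_boundary_value_is_low():
    # mean 0, sd 1 by construction; 1.0 sits exactly at the cutoff
    v = np.array([-1.0, 1.0] * 50)
    out = dichotomize_high_use(v, np.zeros(100))
    assert out.sum() == 0


def test_dichotomize_sex_specific_thresholds():
    rng = np.random.default_rng(1)
    v = np.concatenate([rng.normal(10, 2, 5000), rng.normal(20, 5, 5000)])
    sex = np.repeat([0, 1], 5000)
    out, thresholds = dichotomize_high_use(v, sex, return_thresholds=True)
    assert thresholds[0] == pytest.approx(12, abs=0.2)
    assert thresholds[1] == pytest.approx(25, abs=0.5)


def test_dichotomize_zero_variance_rejected():
    with pytest.raises(ValueError, match="zero variance"):
        dichotomize_high_use(np.full(10, 3.0), np.zeros(10))


# ---------------------------------------------------------------------------
# allele score
# ---------------------------------------------------------------------------


def test_score_zero_dosages():
    w = coffee_score_weights()
    d = {s: np.zeros(5) for s in w.snp_ids}
    assert np.allclose(weighted_risk_score(d, w), 0.0)


def test_score_single_risk_allele():
    w = coffee_score_weights()
    d = {s: np.zeros(1) for s in w.snp_ids}
    d["rs2472297"] = np.ones(1)
    assert weighted_risk_score(d, w)[0] == pytest.approx(0.15)


def test_score_all_homozygous():
    w = coffee_score_weights()
    d = {s: np.full(3, 2.0) for s in w.snp_ids}
    assert np.allclose(weighted_risk_score(d, w), 1.18)


def test_score_missing_weight_errors_extra_ignored():
    w = coffee_score_weights()
    d = {s: np.zeros(2) for s in w.snp_ids}
    d["rs999"] = np.ones(2)  # extra: ignored with a warning
    assert np.allclose(weighted_risk_score(d, w), 0.0)
    del d["rs1260326"]
    with pytest.raises(KeyError, match="rs1260326"):
        weighted_risk_score(d, w)


def test_score_mean_imputes_missing_dosages():
    w = coffee_score_weights().subset(["rs2472297"])
    d = {"rs2472297": np.array([0.0, 2.0, np.nan])}
    out = weighted_risk_score(d, w)
    assert out[2] == pytest.approx(0.15 * 1.0)


def test_score_affine_under_allele_recoding():
    """dosage -> 2 - dosage complements the score: s + s_flipped = 2*sum(b),
    so association results are unchanged up to sign bookkeeping."""
    w = coffee_score_weights()
    rng = np.random.default_rng(2)
    d = {s: rng.integers(0, 3, 50).astype(float) for s in w.snp_ids}
    flipped = {s: 2.0 - v for s, v in d.items()}
    total = weighted_risk_score(d, w) + weighted_risk_score(flipped, w)
    assert np.allclose(total, 2 * 0.59)


# ---------------------------------------------------------------------------
# instrument and causal tests
# ---------------------------------------------------------------------------


def test_instrument_check_recovers_set_points(null_cohort):
    res = instrument_check(null_cohort)
    assert res["score_on_caffeine"].ci_low < 86.7 < res["score_on_caffeine"].ci_high
    cig = res["snp_on_cigarettes"]
    assert cig.ci_low < 0.6 < cig.ci_high


def test_instrument_check_without_smokers():
    cohort = simulate_mr_cohort(
        MRSimSpec(n_individuals=2000, status_probs=(0.7, 0.3, 0.0), seed=1)
    )
    res = instrument_check(cohort)
    assert res["snp_on_cigarettes"] is None


def test_smoking_to_caffeine_positive_in_smokers_null_in_never():
    spec = MRSimSpec(n_individuals=40_000, causal_smoking_to_caffeine=25.0, seed=3)
    cohort = simulate_mr_cohort(spec)
    res = causal_test_smoking_to_caffeine(cohort)
    cur = res[("current", "caffeine_total_mg")]
    nev = res[("never", "caffeine_total_mg")]
    assert cur.beta > 0 and cur.p < 0.05
    assert nev.ci_low < 0 < nev.ci_high


def test_smoking_to_caffeine_skips_empty_stratum():
    cohort = simulate_mr_cohort(
        MRSimSpec(n_individuals=3000, status_probs=(0.7, 0.3, 0.0), seed=4)
    )
    res = causal_test_smoking_to_caffeine(cohort)
    assert res[("current", "caffeine_total_mg")] is None
    assert res[("never", "caffeine_total_mg")] is not None


def test_caffeine_to_smoking_reports_all_outcomes(null_cohort):
    res = causal_test_caffeine_to_smoking(null_cohort)
    assert set(res) == {"cigarettes_per_day", "initiation", "current_smoking", "persistence"}
    for name, r in res.items():
        assert r is not None
        family = "linear" if name == "cigarettes_per_day" else "logistic"
        assert r.model_family == family
    # null generator: cigarettes/day CI covers zero
    assert res["cigarettes_per_day"].ci_low < 0 < res["cigarettes_per_day"].ci_high


def test_degenerate_instrument_rejected(null_cohort):
    df = null_cohort.table.copy()
    for s in coffee_score_weights().snp_ids:
        df[f"dosage_{s}"] = 1.0
    from genoverlap.mr import MRCohort

    monomorphic = MRCohort(table=df, snp_ids=null_cohort.snp_ids)
    with pytest.raises(ValueError, match="degenerate instrument"):
        causal_test_caffeine_to_smoking(monomorphic)


def test_confounder_copied_from_score_is_flagged(null_cohort):
    df = null_cohort.table.copy()
    df["education"] = weighted_risk_score(df, coffee_score_weights())
    from genoverlap.mr import MRCohort

    rigged = MRCohort(table=df, snp_ids=null_cohort.snp_ids)
    res = confounder_check(rigged)
    r, flagged = res[("caffeine_score", "education")]
    assert flagged and r.p < 1e-10
    # independent confounder not flagged at this seed
    _, flagged2 = res[("caffeine_score", "social_class")]
    assert not flagged2


def test_confounder_missing_column_errors(null_cohort):
    with pytest.raises(ValueError, match="missing confounder"):
        confounder_check(null_cohort, confounders=("income",))


def test_cluster_robust_se_exceeds_classical_under_family_noise():
    import statsmodels.api as sm

    spec = MRSimSpec(n_individuals=6000, cluster_fraction=0.9, family_sd=150.0, seed=5)
    cohort = simulate_mr_cohort(spec)
    df = cohort.table
    df = df.assign(score=weighted_risk_score(df, coffee_score_weights()))
    X = sm.add_constant(df[["score", "age"]].to_numpy())
    y = df["caffeine_total_mg"].to_numpy()
    classical = sm.OLS(y, X).fit()
    clustered = sm.OLS(y, X).fit(cov_type="cluster",
                                 cov_kwds={"groups": df["family_id"].to_numpy()})
    assert clustered.bse[1] > classical.bse[1]


def test_type_one_error_calibrated_under_null():
    """Null generator: the current-smoker smoking-SNP test rejects at ~alpha
    across 200 replicates (binomial 99% band)."""
    rejections = 0
    n_reps = 200
    for seed in range(n_reps):
        cohort = simulate_mr_cohort(MRSimSpec(n_individuals=1500, seed=seed))
        res = causal_test_smoking_to_caffeine(cohort, min_stratum_n=30)
        r = res[("current", "caffeine_total_mg")]
        if r is not None and r.p < 0.05:
            rejections += 1
    assert 3 <= rejections <= 20  # 99.9% binomial band around 10/200


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------


def test_power_zero_effect_equals_alpha():
    assert mr_power(PowerSpec(n=1000, alpha=0.05, r2_xz=0.02, beta_xy=0.0)) == \
        pytest.approx(0.05, abs=1e-12)


def test_power_at_canonical_anchor():
    """sqrt(NCP) = z_0.975 + z_0.80 gives 80% power by construction."""
    root = norm.ppf(0.975) + norm.ppf(0.80)
    n, r2 = 10_000, 0.01
    beta = root / np.sqrt(n * r2)
    assert mr_power(PowerSpec(n=n, alpha=0.05, r2_xz=r2, beta_xy=beta)) == \
        pytest.approx(0.80, abs=1e-3)


def test_detectable_effect_inverts_power():
    beta = detectable_effect(n=12_319, alpha=0.05, r2_xz=0.01, target_power=0.8)
    assert mr_power(PowerSpec(n=12_319, alpha=0.05, r2_xz=0.01, beta_xy=beta)) == \
        pytest.approx(0.8, abs=1e-3)


def test_no_instrument_power_falls_back_to_alpha():
    assert mr_power(PowerSpec(n=1000, alpha=0.05, r2_xz=0.0, beta_xy=0.5)) == 0.05


@given(
    n=st.integers(100, 50_000),
    r2=st.floats(0.001, 0.2),
    beta=st.floats(0.0, 1.0),
)
def test_power_monotone_in_all_arguments(n, r2, beta):
    base = mr_power(PowerSpec(n=n, alpha=0.05, r2_xz=r2, beta_xy=beta))
    assert mr_power(PowerSpec(n=n + 500, alpha=0.05, r2_xz=r2, beta_xy=beta)) >= base - 1e-12
    assert mr_power(PowerSpec(n=n, alpha=0.05, r2_xz=min(r2 * 1.5, 1.0), beta_xy=beta)) >= base - 1e-12
    assert mr_power(PowerSpec(n=n, alpha=0.05, r2_xz=r2, beta_xy=beta * 1.5)) >= base - 1e-12


def _simulated_iv_power(n, r2, beta, n_reps=2000, seed=0):
    """Brute-force oracle: rejection rate of the instrument-outcome test
    across replicate cohorts (vectorized OLS per replicate)."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_reps, n))
    x = np.sqrt(r2) * z + np.sqrt(1 - r2) * rng.standard_normal((n_reps, n))
    y = beta * x + rng.standard_normal((n_reps, n))
    zc = z - z.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    slope = (zc * yc).sum(axis=1) / (zc * zc).sum(axis=1)
    resid = yc - slope[:, None] * zc
    se = np.sqrt((resid**2).sum(axis=1) / (n - 2) / (zc * zc).sum(axis=1))
    t = np.abs(slope / se)
    return float((t > norm.ppf(0.975)).mean())


@pytest.mark.parametrize("n", [500, 2000, 8000])
@pytest.mark.parametrize("beta", [0.05, 0.15, 0.3])
def test_power_formula_matches_simulation_oracle(n, beta):
    r2 = 0.02
    formula = mr_power(PowerSpec(n=n, alpha=0.05, r2_xz=r2, beta_xy=beta))
    sim = _simulated_iv_power(n, r2, beta, seed=n + int(beta * 100))
    assert formula == pytest.approx(sim, abs=0.03)
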