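"""Liability-threshold model: implied structure, deviance, fitting,
likelihood-ratio machinery and the overlap decomposition."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from genoverlap.synthetic import TwinDesign, simulate_twin_sample
from genoverlap.twin_model import (
    ACEBivariateParams,
    ModelFitResult,
    ThresholdSpec,
    TwinData,
    confidence_intervals,
    correlations_from_params,
    fit_model,
    fit_saturated,
    implied_pair_correlation,
    likelihood_ratio_test,
    model_selection_sequence,
    sample_minus2LL,
)


def _dummy_fit(minus2LL, n_free):
    return ModelFitResult(
        minus2LL=minus2LL, n_free=n_free, df=0, params=None,
        thresholds=ThresholdSpec(np.zeros((2, 2)), np.zeros((2, 2))),
        estimates={}, converged=True, n_function_evals=0,
    )


# ---------------------------------------------------------------------------
# implied correlation structure
# ---------------------------------------------------------------------------


def test_implied_correlation_pure_e_is_block_diagonal():
    params = ACEBivariateParams.from_shares(0.0, 0.0, rA=0.0, rE=0.25)
    R = implied_pair_correlation(params, "MZ")
    assert np.allclose(R[:2, 2:], 0.0)
    assert R[0, 1] == pytest.approx(0.25)
    assert np.allclose(np.diag(R), 1.0)


def test_implied_correlation_ae_cells():
    # a^2 = 0.76 for trait 1: MZ cross-twin cell 0.76, DZ cell 0.38
    params = ACEBivariateParams.from_shares(0.76, 0.53, rA=0.47, rE=0.30)
    assert implied_pair_correlation(params, "MZ")[0, 2] == pytest.approx(0.76)
    assert implied_pair_correlation(params, "DZ")[0, 2] == pytest.approx(0.38)
    # cross-twin cross-trait MZ cell = rA*sqrt(A1*A2) = 0.2983, the model's
    # counterpart of the saturated estimate 0.26
    assert implied_pair_correlation(params, "MZ")[0, 3] == pytest.approx(
        0.47 * math.sqrt(0.76 * 0.53), abs=1e-12
    )


@given(
    A1=st.floats(0.0, 0.9), A2=st.floats(0.0, 0.9),
    rA=st.floats(0.0, 1.0), rE=st.floats(0.0, 1.0),
)
def test_mz_implied_correlations_dominate_dz(A1, A2, rA, rE):
    """With all non-negative loadings every MZ cell >= its DZ counterpart."""
    params = ACEBivariateParams.from_shares(A1, A2, rA=rA, rE=rE)
    mz = implied_pair_correlation(params, "MZ")
    dz = implied_pair_correlation(params, "DZ")
    assert np.all(mz[:2, 2:] >= dz[:2, 2:] - 1e-12)


# ---------------------------------------------------------------------------
# deviance
# ---------------------------------------------------------------------------


def test_single_pair_identity_structure_deviance():
    """Independent liabilities, cutpoints at 0: every 16-pattern has mass
    1/16, so one pair contributes -2 log(0.0625)."""
    params = ACEBivariateParams.from_shares(0.0, 0.0, rA=0.0, rE=0.0)
    thr = ThresholdSpec(np.zeros((2, 2)), np.zeros((2, 2)))
    complete = np.zeros((5, 6, 4, 4))
    complete[0, 0, 1, 2] = 1  # MZM pair, arbitrary pattern
    data = TwinData(complete, np.zeros((2, 6, 4)))
    dev = sample_minus2LL(data, params, thr)
    assert dev == pytest.approx(-2 * math.log(0.0625), abs=1e-6)


def test_deviance_invariant_under_twin_relabeling(coffee_truth):
    params, thresholds, _ = coffee_truth
    design = TwinDesign({"MZM": 300, "DZF": 300})
    recs = simulate_twin_sample(params, thresholds, design, rng=np.random.default_rng(5))
    data = TwinData.from_records(recs)
    swapped = TwinData(np.swapaxes(data.complete, 2, 3).copy(), data.singles.copy())
    d1 = sample_minus2LL(data, params, thresholds)
    d2 = sample_minus2LL(swapped, params, thresholds)
    assert d1 == pytest.approx(d2, abs=1e-8)


def test_incomplete_pairs_contribute_marginals(coffee_truth):
    """Adding incomplete pairs increases the deviance by the singles'
    bivariate marginal terms only."""
    params, thresholds, _ = coffee_truth
    design = TwinDesign({"MZF": 400}, incomplete_fraction=0.3)
    recs = simulate_twin_sample(params, thresholds, design, rng=np.random.default_rng(6))
    data = TwinData.from_records(recs)
    assert data.n_singles > 0
    full = sample_minus2LL(data, params, thresholds)
    no_singles = sample_minus2LL(
        TwinData(data.complete, np.zeros((2, 6, 4))), params, thresholds
    )
    assert full > no_singles


# ---------------------------------------------------------------------------
# likelihood ratio tests
# ---------------------------------------------------------------------------


def test_lrt_identical_fits_retained():
    res = likelihood_ratio_test(_dummy_fit(100.0, 10), _dummy_fit(100.0, 12))
    assert res.chi2 == 0.0
    assert res.p == pytest.approx(1.0)
    assert res.retained


def test_lrt_reproduces_printed_deviance_differences():
    """Dropping the age moderator: deviances 17850.72 vs 17021.62 give
    chi2 = 829.10 on 4 df (p << 0.001); a 2.36 deviance rise on 1 df gives
    p = 0.124 and is retained."""
    res = likelihood_ratio_test(_dummy_fit(17850.72, 42), _dummy_fit(17021.62, 46))
    assert res.chi2 == pytest.approx(829.11, abs=0.02)
    assert res.delta_df == 4
    assert res.p < 0.001 and not res.retained

    res = likelihood_ratio_test(_dummy_fit(17048.90, 24), _dummy_fit(17046.54, 25))
    assert res.chi2 == pytest.approx(2.36, abs=1e-9)
    assert res.p == pytest.approx(0.124, abs=5e-4)
    assert res.retained


def test_lrt_rejects_negative_statistic():
    with pytest.raises(ValueError, match="not nested"):
        likelihood_ratio_test(_dummy_fit(99.0, 10), _dummy_fit(100.0, 12))


# ---------------------------------------------------------------------------
# overlap decomposition
# ---------------------------------------------------------------------------


def test_overlap_decomposition_best_fitting_values():
    """Best-fitting AE estimates decompose the smoking-coffee covariance
    75% genetic / 25% environmental; with rE = 0 the overlap is all A."""
    s = correlations_from_params(
        ACEBivariateParams.from_shares(0.76, 0.53, rA=0.47, rE=0.30)
    )
    assert round(s.overlap_A, 2) == 0.75
    assert round(s.overlap_E, 2) == 0.25
    assert s.overlap_A + s.overlap_C + s.overlap_E == pytest.approx(1.0, abs=1e-8)

    s = correlations_from_params(
        ACEBivariateParams.from_shares(0.74, 0.49, rA=0.44, rE=0.0)
    )
    assert round(s.overlap_A, 2) == 1.00


def test_overlap_zero_shared_path():
    params = ACEBivariateParams.from_shares(0.5, 0.4, rA=0.0, rE=0.3)
    s = correlations_from_params(params)
    assert s.rA == pytest.approx(0.0)
    assert s.overlap_A == pytest.approx(0.0)


def test_component_absent_reports_undefined_correlation():
    s = correlations_from_params(ACEBivariateParams.from_shares(0.0, 0.5, rA=0.0, rE=0.2))
    assert s.rA is None
    assert s.overlap_A == 0.0


@given(
    A1=st.floats(0.05, 0.9), A2=st.floats(0.05, 0.9),
    rA=st.floats(-0.95, 0.95), rE=st.floats(-0.95, 0.95),
)
def test_shares_correlations_round_trip(A1, A2, rA, rE):
    s = correlations_from_params(ACEBivariateParams.from_shares(A1, A2, rA=rA, rE=rE))
    assert s.A1 == pytest.approx(A1, abs=1e-10)
    assert s.A2 == pytest.approx(A2, abs=1e-10)
    assert s.rA == pytest.approx(rA, abs=1e-10)
    assert s.rE == pytest.approx(rE, abs=1e-10)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_fit_recovers_null_under_pure_e():
    params = ACEBivariateParams.from_shares(0.0, 0.0, rA=0.0, rE=0.2)
    thr = ThresholdSpec.from_prevalence(np.full((2, 2), 0.3))
    design = TwinDesign({"MZM": 1250, "MZF": 1250, "DZM": 1250, "DZF": 1250})
    recs = simulate_twin_sample(params, thr, design, rng=np.random.default_rng(21))
    fit = fit_model(TwinData.from_records(recs), model="ACE", seed=21,
                    threshold_constraints=("drop_age",))
    assert fit.converged
    # at the zero boundary the MLE of each share is half-normal; 0.1 is
    # ~2.5 sampling SEs at this design
    for name in ("A1", "C1", "A2", "C2"):
        assert fit.estimates[name] < 0.10


def test_submodel_never_beats_supermodel(coffee_sample, coffee_ae_fit):
    _, data = coffee_sample
    sub = fit_model(data, model="AE", fixed={"rE": 0.0}, seed=3)
    assert sub.minus2LL >= coffee_ae_fit.minus2LL - 1e-6
    lrt = likelihood_ratio_test(sub, coffee_ae_fit)
    assert lrt.delta_df == 1


def test_fit_counts_free_parameters(coffee_ae_fit, coffee_sample):
    # AE bivariate: A1, A2, rA, rE + 8 threshold parameters
    _, data = coffee_sample
    assert coffee_ae_fit.n_free == 12
    assert coffee_ae_fit.df == data.n_observations - 12


def test_saturated_recovers_generating_correlations(coffee_sample):
    """MZ cross-twin smoking correlation simulated at 0.76 is recovered
    within +-0.05 by the saturated orthant fit at realistic sample size."""
    _, data = coffee_sample
    table, fit = fit_saturated(data, seed=3)
    assert fit.converged
    mz = table[table.group == "MZ"].iloc[0]
    dz = table[table.group == "DZ"].iloc[0]
    assert mz.cross_twin_trait1 == pytest.approx(0.76, abs=0.05)
    assert dz.cross_twin_trait1 == pytest.approx(0.38, abs=0.07)
    assert mz.cross_twin_cross_trait > dz.cross_twin_cross_trait - 0.05


def test_saturated_deviance_bounds_structured(coffee_sample, coffee_ae_fit):
    _, data = coffee_sample
    _, sat = fit_saturated(data, seed=3)
    assert sat.minus2LL <= coffee_ae_fit.minus2LL + 1e-6


def test_perfectly_concordant_pairs_hit_bound():
    complete = np.zeros((5, 6, 4, 4))
    complete[0, 2, 3, 3] = 40  # MZM all (1,1)/(1,1)
    complete[0, 2, 0, 0] = 60
    complete[1, 2, 3, 3] = 25  # DZM
    complete[1, 2, 0, 0] = 75
    data = TwinData(complete, np.zeros((2, 6, 4)))
    table, fit = fit_saturated(data, threshold_constraints=("drop_age",), seed=0)
    assert bool(table[table.group == "MZ"].bound_hit.iloc[0])


def test_cascade_empty_returns_saturated(coffee_sample):
    _, data = coffee_sample
    report, best = model_selection_sequence(data, steps=[])
    assert len(report) == 1
    assert best.label.startswith("saturated")


def test_cascade_on_ae_truth_drops_c_keeps_a_overlap(coffee_sample):
    """Data generated without C: C-dropping steps retained; dropping the A
    or E overlap path is rejected at this sample size."""
    _, data = coffee_sample
    steps = [
        {"label": "ACE model", "model": "ACE", "mandatory": True},
        {"label": "C for trait 2 dropped", "add_fixed": {"C2": 0.0}},
        {"label": "C for trait 1 dropped", "add_fixed": {"C1": 0.0}},
        {"label": "A for overlap dropped", "add_fixed": {"rA": 0.0}},
        {"label": "E for overlap dropped", "add_fixed": {"rE": 0.0}},
    ]
    report, best = model_selection_sequence(data, steps=steps, seed=3)
    by_label = report.set_index("model")
    assert bool(by_label.loc["C for trait 2 dropped", "retained"])
    assert bool(by_label.loc["C for trait 1 dropped", "retained"])
    assert not bool(by_label.loc["A for overlap dropped", "retained"])
    assert by_label.loc["A for overlap dropped", "p"] < 0.001
    assert not bool(by_label.loc["E for overlap dropped", "retained"])
    assert best.estimates["C1"] == 0.0 and best.estimates["C2"] == 0.0
    assert best.estimates["rA"] != 0.0


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------


def test_profile_interval_brackets_estimate(coffee_ae_fit):
    ci = confidence_intervals(coffee_ae_fit, level=0.95, method="profile",
                              quantities=("rA",))
    lo, hi, warn = ci["rA"]
    est = coffee_ae_fit.estimates["rA"]
    assert lo < est < hi
    assert hi - lo < 0.5  # informative at ~4400 pairs
    assert warn is None


def test_degenerate_level_returns_point(coffee_ae_fit):
    ci = confidence_intervals(coffee_ae_fit, level=0.0, quantities=("rA", "A1"))
    assert ci["rA"][0] == ci["rA"][1] == coffee_ae_fit.estimates["rA"]


def test_bootstrap_and_profile_intervals_overlap(coffee_ae_fit):
    prof = confidence_intervals(coffee_ae_fit, method="profile", quantities=("rA",))
    boot = confidence_intervals(coffee_ae_fit, method="bootstrap",
                                quantities=("rA",), n_boot=30, seed=5)
    assert max(prof["rA"][0], boot["rA"][0]) < min(prof["rA"][1], boot["rA"][1])
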