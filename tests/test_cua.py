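import dataclasses

import numpy as np
import pytest

from deprecon.cohort import generate_cohort
from deprecon.costs import add_costs, default_tariffs, round_half_up
from deprecon.cua import (
    ArmMoments,
    arm_moments_from_cohort,
    beta_from_moments,
    classify_quadrant,
    compute_icer,
    gamma_from_moments,
    icer_histogram,
    run_psa,
    subgroup_psa,
)
from deprecon.errors import CohortError, DomainError
from deprecon.qaly import add_utility_columns

from conftest import make_cohort

# arm moments as published: mean (SE) of total cost and half-year QALY gain
CONT = ArmMoments(cost_mean=826.60, cost_se=45.79, qaly_mean=0.0275, qaly_se=0.0087, n=223)
DISC = ArmMoments(cost_mean=753.20, cost_se=58.43, qaly_mean=0.0611, qaly_se=0.0092, n=107)


# ---- deterministic ICER -----------------------------------------------------

def test_icer_published_arms_dominant():
    res = compute_icer(CONT, DISC)
    assert res.delta_cost == pytest.approx(-73.40)
    assert res.delta_qaly == pytest.approx(0.0336)
    assert res.dominance == "dominant"
    assert res.icer == pytest.approx(-73.40 / 0.0336)
    assert round_half_up(res.icer) == -2185


def test_icer_identical_arms_undefined():
    res = compute_icer(CONT, CONT)
    assert res.delta_cost == 0.0
    assert res.delta_qaly == 0.0
    assert res.icer is None and not res.icer_defined
    assert res.dominance == "equivalent"


def test_icer_zero_qaly_delta_cost_sign():
    cheaper = dataclasses.replace(CONT, cost_mean=CONT.cost_mean - 10)
    res = compute_icer(CONT, dataclasses.replace(cheaper, qaly_mean=CONT.qaly_mean))
    assert not res.icer_defined
    assert res.dominance == "dominant"


def test_icer_antisymmetric_under_arm_swap():
    a = compute_icer(CONT, DISC)
    b = compute_icer(DISC, CONT)
    assert b.delta_cost == pytest.approx(-a.delta_cost)
    assert b.delta_qaly == pytest.approx(-a.delta_qaly)
    assert (a.dominance, b.dominance) == ("dominant", "dominated")


@pytest.mark.parametrize(
    "dc, dq, expected",
    [(5.0, 0.01, "tradeoff_ne"), (-5.0, -0.01, "tradeoff_sw")],
)
def test_icer_tradeoff_quadrants(dc, dq, expected):
    disc = dataclasses.replace(
        CONT, cost_mean=CONT.cost_mean + dc, qaly_mean=CONT.qaly_mean + dq
    )
    assert compute_icer(CONT, disc).dominance == expected


# ---- moment matching --------------------------------------------------------

def test_gamma_unit_moments_is_exponential():
    assert gamma_from_moments(1.0, 1.0) == (1.0, 1.0)


def test_gamma_published_cost_moments():
    shape, scale = gamma_from_moments(826.60, 45.79)
    assert shape == pytest.approx((826.60 / 45.79) ** 2)
    assert shape == pytest.approx(325.87, abs=0.01)
    assert scale == pytest.approx(45.79**2 / 826.60, abs=1e-9)
    # analytic round trip at machine precision
    assert shape * scale == pytest.approx(826.60, rel=1e-14)
    assert np.sqrt(shape) * scale == pytest.approx(45.79, rel=1e-14)


def test_gamma_domain_errors():
    for mu, sigma in [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0)]:
        with pytest.raises(DomainError):
            gamma_from_moments(mu, sigma)


def test_beta_symmetric_half():
    a, b = beta_from_moments(0.5, np.sqrt(0.125))
    assert a == pytest.approx(0.5)
    assert b == pytest.approx(0.5)


def test_beta_published_qaly_moments():
    a, b = beta_from_moments(0.0611, 0.0092)
    assert a == pytest.approx(41.35, abs=0.05)
    assert b == pytest.approx(635.4, abs=0.5)
    # implied mean and SD recover the inputs at machine precision
    assert a / (a + b) == pytest.approx(0.0611, rel=1e-13)
    sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
    assert sd == pytest.approx(0.0092, rel=1e-13)


def test_beta_infeasible_variance_states_bound():
    with pytest.raises(DomainError, match="mu\\(1-mu\\)"):
        beta_from_moments(0.5, 0.6)
    with pytest.raises(DomainError):
        beta_from_moments(-0.1, 0.01)
    with pytest.raises(DomainError):
        beta_from_moments(0.5, 0.0)


def test_monte_carlo_recovers_moments():
    rng = np.random.default_rng(0)
    shape, scale = gamma_from_moments(753.20, 58.43)
    draws = rng.gamma(shape, scale, size=1_000_000)
    assert draws.mean() == pytest.approx(753.20, rel=0.005)
    a, b = beta_from_moments(0.0275, 0.0087)
    bdraws = rng.beta(a, b, size=1_000_000)
    assert bdraws.std() == pytest.approx(0.0087, rel=0.01)


# ---- PSA --------------------------------------------------------------------

def test_psa_published_moments_majority_southeast():
    res = run_psa(CONT, DISC, n_iter=1000, seed=1)
    assert res.quadrant_proportions["se"] > 0.5
    assert len(res.draws) == 1000


def test_psa_deterministic_given_seed():
    a = run_psa(CONT, DISC, n_iter=500, seed=3)
    b = run_psa(CONT, DISC, n_iter=500, seed=3)
    assert a.draws.equals(b.draws)
    c = run_psa(CONT, DISC, n_iter=500, seed=4)
    assert not a.draws.equals(c.draws)


def test_psa_quadrants_sum_to_one():
    res = run_psa(CONT, DISC, n_iter=777, seed=0)
    assert sum(res.quadrant_proportions.values()) == pytest.approx(1.0, abs=1e-12)


def test_psa_equal_arms_near_uniform_quadrants():
    res = run_psa(CONT, CONT, n_iter=8000, seed=2)
    for q, p in res.quadrant_proportions.items():
        assert p == pytest.approx(0.25, abs=0.03), q


def test_psa_mean_consistency():
    n = 20_000
    res = run_psa(CONT, DISC, n_iter=n, seed=5)
    se_cost = np.sqrt(CONT.cost_se**2 + DISC.cost_se**2) / np.sqrt(n)
    se_qaly = np.sqrt(CONT.qaly_se**2 + DISC.qaly_se**2) / np.sqrt(n)
    assert abs(res.draws["delta_cost"].mean() - (-73.40)) < 3 * se_cost
    assert abs(res.draws["delta_qaly"].mean() - 0.0336) < 3 * se_qaly


def test_psa_infeasible_moments_fail_before_sampling():
    bad = dataclasses.replace(DISC, qaly_se=0.9)
    with pytest.raises(DomainError, match="discontinuation"):
        run_psa(CONT, bad, n_iter=10, seed=0)


def test_classify_quadrant_boundary_convention():
    q = classify_quadrant(np.array([0.0, 0.0, -1.0, 1.0]), np.array([0.0, 5.0, 0.0, 5.0]))
    assert list(q) == ["se", "ne", "sw", "ne"]


def test_icer_histogram_counts_all_draws():
    res = run_psa(CONT, DISC, n_iter=400, seed=6)
    hist = icer_histogram(res, bins=20)
    assert hist["count"].sum() == res.icer_summary["n_finite"]
    assert (hist["bin_left"] < hist["bin_right"]).all()


# ---- cohort-level estimation and subgroups ----------------------------------

def _analysed_cohort(config, **patch):
    cfg = dataclasses.replace(config, **patch) if patch else config
    cohort = generate_cohort(cfg)
    return add_utility_columns(add_costs(cohort, default_tariffs()))


def test_arm_moments_from_cohort(small_config):
    analysed = _analysed_cohort(small_config)
    arm = arm_moments_from_cohort(analysed, "continuation")
    sub = analysed[analysed["group"] == "continuation"]
    assert arm.cost_mean == pytest.approx(sub["total_cost"].mean())
    assert arm.qaly_se == pytest.approx(
        sub["qaly_gain"].std(ddof=1) / np.sqrt(len(sub))
    )
    with pytest.raises(CohortError):
        arm_moments_from_cohort(analysed.iloc[:0], "continuation")


def test_subgroup_psa_sex_majority_southeast(paper_config):
    analysed = _analysed_cohort(paper_config, n_total=4000, seed=21)
    results = subgroup_psa(analysed, "sex", n_iter=500, seed=9)
    assert set(results) == {"men", "women"}
    for level, res in results.items():
        assert res.quadrant_proportions["se"] > 0.5, level


def test_subgroup_psa_skips_degenerate_stratum():
    rows = (
        [{"group": "continuation", "sex": "men", "primary_care": k,
          "wonca_baseline": 20, "wonca_6m": 14 + (k % 3)} for k in range(6)]
        + [{"group": "discontinuation", "sex": "men", "primary_care": k + 1,
            "wonca_baseline": 22, "wonca_6m": 12 + (k % 4)} for k in range(6)]
        + [{"group": "continuation", "sex": "women", "primary_care": 2}]
    )
    analysed = add_utility_columns(add_costs(make_cohort(rows), default_tariffs()))
    results = subgroup_psa(analysed, "sex", n_iter=50, seed=0)
    assert isinstance(results["women"], dict) and "skipped" in results["women"]
    assert not isinstance(results["men"], dict)


def test_subgroup_psa_missing_band_reported(paper_config):
    analysed = _analysed_cohort(paper_config, n_total=2000, seed=22)
    analysed = analysed[analysed["cci_band"] != ">=5"]
    results = subgroup_psa(analysed, "cci_band", n_iter=100, seed=1)
    assert set(results) == {"0-2", "3-4"}
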