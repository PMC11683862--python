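"""OLS fitting, bootstrap SEs, backward elimination, coefficient z-tests."""

import numpy as np
import pytest

from lfer2p import (
    bootstrap_coefficient_se,
    compare_coefficients_z,
    drop_insignificant_terms,
    fit_ols,
    fit_ols_arrays,
)
from tests.conftest import make_table


def normal_equations(y, X, intercept=True):
    """Independent brute-force oracle: solve X'X b = X'y directly."""
    if intercept:
        X = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(X.T @ X, X.T @ y)


FOUR_POINT = (np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float),
              np.array([0.0, 1.0, 1.0, 3.0]))


def test_noise_free_recovery():
    x1 = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    x2 = np.array([1.0, -1.0, 0.5, 2.0, -0.3])
    y = 2.0 * x1 + 0.0 * x2 + 1.0
    fit = fit_ols_arrays(y, np.column_stack([x1, x2]), ("x1", "x2"))
    assert fit.coefficients["x1"] == pytest.approx(2.0, abs=1e-10)
    assert fit.coefficients["x2"] == pytest.approx(0.0, abs=1e-10)
    assert fit.coefficients["intercept"] == pytest.approx(1.0, abs=1e-10)
    assert fit.r2 == pytest.approx(1.0, abs=1e-12)
    assert fit.rmse == pytest.approx(0.0, abs=1e-10)


def test_four_point_hand_oracle():
    X, y = FOUR_POINT
    fit = fit_ols_arrays(y, X, ("x1", "x2"))
    assert fit.coefficients["intercept"] == pytest.approx(-0.25, abs=1e-9)
    assert fit.coefficients["x1"] == pytest.approx(1.5, abs=1e-9)
    assert fit.coefficients["x2"] == pytest.approx(1.5, abs=1e-9)
    assert fit.r2 == pytest.approx(0.947368, abs=1e-6)
    assert fit.rmse == pytest.approx(0.25, abs=1e-9)  # sqrt(SSE/n)


def test_rmse_denominator_flag():
    X, y = FOUR_POINT
    fit = fit_ols_arrays(y, X, ("x1", "x2"), rmse_denominator="residual_df")
    assert fit.rmse == pytest.approx(np.sqrt(0.25 / 1), abs=1e-9)


def test_fit_matches_normal_equations_on_random_instances(rng):
    for _ in range(20):
        n = int(rng.integers(5, 11))
        p = int(rng.integers(1, 3))
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        fit = fit_ols_arrays(y, X, tuple(f"x{j}" for j in range(p)))
        beta = normal_equations(y, X)
        got = [fit.coefficients["intercept"]] + [
            fit.coefficients[f"x{j}"] for j in range(p)]
        assert np.allclose(got, beta, atol=1e-9)


def test_fit_statistics_identities(noisy_table):
    fit = fit_ols(noisy_table, "structural_protein")
    n, p = fit.n, fit.p
    # F and Adj R2 recomputed from R2
    f_again = (fit.r2 / p) / ((1 - fit.r2) / (n - p - 1))
    adj_again = 1 - (1 - fit.r2) * (n - 1) / (n - p - 1)
    assert f_again == pytest.approx(fit.f_stat, abs=1e-9)
    assert adj_again == pytest.approx(fit.adj_r2, abs=1e-9)
    assert fit.adj_r2 <= fit.r2
    assert 0.0 <= fit.r2 <= 1.0
    # hat values sum to the parameter count; residuals sum to 0
    assert fit.leverage.sum() == pytest.approx(p + 1, abs=1e-9)
    assert fit.residuals.sum() == pytest.approx(0.0, abs=1e-9)


def test_fit_errors_on_rank_deficiency_and_small_n():
    X = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
    with pytest.raises(ValueError, match="rank"):
        fit_ols_arrays(np.arange(6.0), X, ("x1", "x2"))
    with pytest.raises(ValueError, match="at least"):
        fit_ols_arrays(np.arange(3.0), X[:3], ("x1", "x2"))


def test_bootstrap_se_deterministic_and_zero_for_exact_data():
    exact = make_table(n=30, sigma=0.0, seed=5)
    se1 = bootstrap_coefficient_se(exact, "structural_protein",
                                   replicates=50, seed=77)
    se2 = bootstrap_coefficient_se(exact, "structural_protein",
                                   replicates=50, seed=77)
    assert se1 == se2
    assert all(v < 1e-8 for v in se1.values())


def test_bootstrap_se_agrees_with_analytic_at_large_n():
    table = make_table(n=200, sigma=0.3, seed=21)
    bse = bootstrap_coefficient_se(table, "structural_protein",
                                   replicates=400, seed=3)
    fit = fit_ols(table, "structural_protein")
    for term, se in bse.items():
        assert se == pytest.approx(fit.analytic_se[term], rel=0.15)


def test_bootstrap_se_rejects_too_few_replicates(noisy_table):
    with pytest.raises(ValueError):
        bootstrap_coefficient_se(noisy_table, "structural_protein", replicates=1)


def test_drop_terms_removes_pure_noise_predictor(rng):
    table = make_table(n=150, sigma=0.3, seed=8)
    frame = table.to_frame()
    frame["junk"] = rng.normal(size=len(frame))
    y = frame["logK_structural_protein"].to_numpy()
    X = frame[["logKow", "logKaw", "junk"]].to_numpy()
    fit = fit_ols_arrays(y, X, ("logKow", "logKaw", "junk"))
    reduced = drop_insignificant_terms(fit)
    assert reduced.dropped_terms == ("junk",)
    assert reduced.coefficients["junk"] == 0.0
    assert reduced.coefficients["logKow"] == pytest.approx(0.851, abs=0.1)
    assert reduced.coefficients["logKaw"] == pytest.approx(-0.092, abs=0.05)


def test_drop_terms_noop_on_strong_model(noisy_table):
    fit = fit_ols(noisy_table, "structural_protein")
    assert drop_insignificant_terms(fit).dropped_terms == ()


def test_drop_terms_is_idempotent(rng):
    table = make_table(n=80, sigma=0.4, seed=9)
    frame = table.to_frame()
    frame["junk"] = rng.normal(size=len(frame))
    fit = fit_ols_arrays(
        frame["logK_structural_protein"].to_numpy(),
        frame[["logKow", "logKaw", "junk"]].to_numpy(),
        ("logKow", "logKaw", "junk"),
    )
    once = drop_insignificant_terms(fit)
    twice = drop_insignificant_terms(once)
    assert once.dropped_terms == twice.dropped_terms
    assert once.coefficients == twice.coefficients


def test_drop_terms_removes_statistically_zero_intercept():
    # truth has zero intercept, mirroring the serum-albumin case
    table = make_table(n=120, sigma=0.3, seed=10, truth=(0.788, -0.053, 0.0))
    fit = fit_ols(table, "structural_protein")
    reduced = drop_insignificant_terms(fit)
    assert "intercept" in reduced.dropped_terms
    assert reduced.coefficients["intercept"] == 0.0
    assert reduced.coefficients["logKow"] == pytest.approx(0.788, abs=0.05)


@pytest.mark.parametrize("b1,b2,z_expected,flag", [
    (0.9, 0.8, 1.414, False),
    (1.0, 0.7, 4.243, True),
])
def test_z_comparison_hand_values(b1, b2, z_expected, flag):
    cmp = compare_coefficients_z({"b": (b1, 0.05)}, {"b": (b2, 0.05)})
    assert cmp.z["b"] == pytest.approx(z_expected, abs=1e-3)
    assert cmp.significant["b"] is flag


def test_z_comparison_identical_fits_and_antisymmetry(noisy_table):
    fit = fit_ols(noisy_table, "structural_protein")
    same = compare_coefficients_z(fit, fit)
    assert all(z == 0.0 for z in same.z.values())
    assert not any(same.significant.values())
    other = fit_ols(make_table(seed=999), "structural_protein")
    ab = compare_coefficients_z(fit, other)
    ba = compare_coefficients_z(other, fit)
    for term in ab.terms:
        assert ab.z[term] == pytest.approx(-ba.z[term], abs=1e-12)


def test_z_comparison_requires_shared_terms():
    with pytest.raises(ValueError):
        compare_coefficients_z({"a": (1.0, 0.1)}, {"b": (1.0, 0.1)})
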