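"""FIML twin-model engine: implied moments, likelihood, fitting, selection."""

import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from epitwin.biometric import (
    ComparisonResult,
    ModelSpec,
    ZygosityGroupData,
    _Group,
    assumption_checks,
    fit_model,
    implied_cov_bivariate,
    implied_cov_univariate,
    linear_path_from_endpoints,
    lrt,
    make_bivariate_groups,
    make_univariate_groups,
    model_ladder_univariate,
    moderation_ladder,
    negloglik,
    param_names,
    profile_ci,
    standardize,
    standardize_percent,
    variance_components_at_age,
)
from epitwin.biometric import test_equality_over_time as equality_over_time
from epitwin.cohort import TrueParams, generate_cohort

LOG2PI = math.log(2 * math.pi)


def random_params(spec, rng):
    params = {}
    for n in param_names(spec):
        if n.startswith("r"):
            params[n] = rng.uniform(-0.9, 0.9)
        elif n.startswith("mu") or n in ("b1", "b2"):
            params[n] = rng.normal(scale=0.5)
        else:
            params[n] = rng.uniform(0.3, 1.5)
    return params


# ------------------------------------------------------------------ implied

def test_implied_univariate_identity_for_pure_e():
    spec = ModelSpec()
    params = {"a0": 0.0, "c0": 0.0, "e0": 1.0, "mu0": 0.0}
    for zyg in ("MZ", "DZ"):
        assert np.allclose(implied_cov_univariate(spec, params, zyg), np.eye(2))


def test_implied_univariate_dz_additive_coefficient():
    spec = ModelSpec()
    params = {"a0": 1.0, "c0": 0.0, "e0": 0.0, "mu0": 0.0}
    assert implied_cov_univariate(spec, params, "DZ")[0, 1] == pytest.approx(0.5)


def test_implied_univariate_ade_dz():
    spec = ModelSpec(mode="ADE")
    params = {"a0": 1.0, "c0": 1.0, "e0": 1.0, "mu0": 0.0}
    cov = implied_cov_univariate(spec, params, "DZ")
    assert cov[0, 0] == pytest.approx(3.0)
    assert cov[0, 1] == pytest.approx(0.75)  # 0.5*a2 + 0.25*d2


def test_implied_univariate_unknown_zygosity_rejected():
    with pytest.raises(ValueError):
        implied_cov_univariate(ModelSpec(), {"a0": 1, "c0": 0, "e0": 1, "mu0": 0}, "XX")


def test_implied_bivariate_block_diagonal_without_cross_time_correlation():
    spec = ModelSpec(design="bivariate")
    params = dict(sa1=0.7, sa2=0.8, ra=0.0, sc1=0.5, sc2=0.4, rc=0.0,
                  se1=0.6, se2=0.9, re=0.0, mu1=0.0, mu2=0.0)
    cov = implied_cov_bivariate(spec, params, "MZ")
    # occasion-1 slots are rows/cols 0 and 2, occasion-2 slots 1 and 3
    assert cov[0, 1] == cov[0, 3] == cov[2, 1] == 0.0
    assert cov[0, 2] == pytest.approx(0.7**2 + 0.5**2)


def test_implied_bivariate_dz_cross_twin_cross_time_plugin():
    spec = ModelSpec(design="bivariate")
    params = dict(sa1=np.sqrt(2), sa2=np.sqrt(2), ra=0.9, sc1=0.0, sc2=0.0,
                  rc=0.0, se1=0.5, se2=0.5, re=0.0, mu1=0.0, mu2=0.0)
    cov = implied_cov_bivariate(spec, params, "DZ")
    assert cov[0, 3] == pytest.approx(0.5 * 0.9 * 2.0)  # kA * rA * sA1 * sA2


def test_implied_bivariate_perfect_stability_is_rank_deficient():
    spec = ModelSpec(design="bivariate")
    params = dict(sa1=0.8, sa2=0.8, ra=1.0, sc1=0.5, sc2=0.5, rc=1.0,
                  se1=0.0, se2=0.0, re=0.0, mu1=0.0, mu2=0.0)
    cov = implied_cov_bivariate(spec, params, "MZ")
    assert np.linalg.matrix_rank(cov, tol=1e-10) < 4
    assert np.allclose(cov, cov[0, 0])  # every entry equals the A+C variance


from hypothesis import given, settings, strategies as st

_sd = st.floats(0.0, 2.0, allow_nan=False)
_r = st.floats(-1.0, 1.0, allow_nan=False)


@settings(derandomize=True, max_examples=100)
@given(sa1=_sd, sa2=_sd, sc1=_sd, sc2=_sd, se1=_sd, se2=_sd,
       ra=_r, rc=_r, re=_r)
def test_implied_bivariate_symmetric_and_psd(sa1, sa2, sc1, sc2, se1, se2,
                                             ra, rc, re):
    spec = ModelSpec(design="bivariate")
    params = dict(sa1=sa1, sa2=sa2, ra=ra, sc1=sc1, sc2=sc2, rc=rc,
                  se1=se1, se2=se2, re=re, mu1=0.0, mu2=0.0)
    for zyg in ("MZ", "DZ"):
        cov = implied_cov_bivariate(spec, params, zyg)
        assert np.allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() > -1e-9


def test_mz_off_diagonal_at_least_dz():
    rng = np.random.default_rng(7)
    for mode in ("ACE", "ADE"):
        spec = ModelSpec(mode=mode)
        for _ in range(20):
            params = random_params(spec, rng)
            mz = implied_cov_univariate(spec, params, "MZ")[0, 1]
            dz = implied_cov_univariate(spec, params, "DZ")[0, 1]
            assert mz >= dz - 1e-12


def test_rejects_cross_time_correlation_above_one():
    spec = ModelSpec(design="bivariate")
    params = dict(sa1=1, sa2=1, ra=1.2, sc1=0, sc2=0, rc=0, se1=1, se2=1,
                  re=0, mu1=0, mu2=0)
    with pytest.raises(ValueError):
        implied_cov_bivariate(spec, params, "MZ")


# --------------------------------------------------------------- likelihood

def test_single_standard_normal_pair_likelihood():
    data = ZygosityGroupData(
        mz=_Group(y=np.zeros((1, 2))), dz=_Group(y=np.empty((0, 2)))
    )
    spec = ModelSpec(drop=frozenset("ac"))
    m2ll = negloglik(data, spec, {"e0": 1.0, "mu0": 0.0})
    assert m2ll == pytest.approx(2 * LOG2PI, abs=1e-12)


def test_negloglik_matches_generic_mvn_oracle():
    rng = np.random.default_rng(0)
    for _ in range(25):
        design = rng.choice(["univariate", "bivariate"])
        p = 2 if design == "univariate" else 4
        spec = ModelSpec(mode=rng.choice(["ACE", "ADE"]), design=design)
        params = random_params(spec, rng)
        y_mz = rng.normal(size=(6, p))
        y_dz = rng.normal(size=(4, p))
        data = ZygosityGroupData(mz=_Group(y=y_mz), dz=_Group(y=y_dz), design=design)
        expected = 0.0
        for zyg, y in (("MZ", y_mz), ("DZ", y_dz)):
            if design == "univariate":
                cov = implied_cov_univariate(spec, params, zyg)
                mu = [params["mu0"]] * 2
            else:
                cov = implied_cov_bivariate(spec, params, zyg)
                mu = [params["mu1"], params["mu2"]] * 2
            expected += -2.0 * multivariate_normal(mu, cov).logpdf(y).sum()
        assert negloglik(data, spec, params) == pytest.approx(expected, abs=1e-8)


def test_moderated_negloglik_matches_per_pair_oracle():
    rng = np.random.default_rng(1)
    spec = ModelSpec(moderated=frozenset("ae"), means="age")
    params = random_params(spec, rng)
    params["a1"], params["e1"] = 0.02, 0.03
    y = rng.normal(size=(8, 2))
    ages = rng.uniform(9, 30, 8)
    data = ZygosityGroupData(
        mz=_Group(y=y, ages=ages), dz=_Group(y=np.empty((0, 2)), ages=np.empty(0))
    )
    expected = 0.0
    for i in range(8):
        cov = implied_cov_univariate(spec, params, "MZ", age=ages[i])
        mu = params["mu0"] + params["b1"] * ages[i] + params["b2"] * ages[i] ** 2
        expected += -2.0 * multivariate_normal([mu, mu], cov).logpdf(y[i])
    assert negloglik(data, spec, params) == pytest.approx(expected, abs=1e-8)


def test_duplicating_pairs_doubles_minus2ll():
    rng = np.random.default_rng(2)
    y = rng.normal(size=(10, 2))
    spec = ModelSpec()
    params = {"a0": 0.5, "c0": 0.4, "e0": 0.8, "mu0": 0.1}
    d1 = ZygosityGroupData(mz=_Group(y=y), dz=_Group(y=y))
    d2 = ZygosityGroupData(mz=_Group(y=np.vstack([y, y])), dz=_Group(y=np.vstack([y, y])))
    assert negloglik(d2, spec, params) == pytest.approx(
        2 * negloglik(d1, spec, params), rel=1e-12
    )


def test_nonpositive_definite_returns_penalty_not_crash():
    data = ZygosityGroupData(mz=_Group(y=np.zeros((3, 2))), dz=_Group(y=np.zeros((3, 2))))
    val = negloglik(data, ModelSpec(), {"a0": 1.0, "c0": 0.0, "e0": 0.0, "mu0": 0.0})
    # MZ implied covariance is singular (a-only): off-diagonal == diagonal
    assert val >= 1e10


# ------------------------------------------------------------------ fitting

def test_e_only_fit_equals_pooled_ml_variance(ace_table):
    data = make_univariate_groups(ace_table)
    fit = fit_model(data, ModelSpec(drop=frozenset("ac")))
    y = np.concatenate([data.mz.y.ravel(), data.dz.y.ravel()])
    ml_var = float(((y - y.mean()) ** 2).mean())
    assert fit.components["E"] == pytest.approx(ml_var, abs=1e-6)
    assert fit.n_params == 2
    assert fit.aic == pytest.approx(fit.minus2ll + 4.0)


def test_distinct_starts_agree_to_1e6(ace_table):
    data = make_univariate_groups(ace_table)
    vals = [fit_model(data, ModelSpec(), seed=s).minus2ll for s in range(5)]
    assert max(vals) - min(vals) < 1e-6


def test_ace_recovery_and_share_normalization(one_age_design):
    # single-draw share estimates have SD ~0.06 at this n, so recovery (bias)
    # is checked on the mean over seeded replicates
    params = TrueParams(a0=np.sqrt(0.3), c0=np.sqrt(0.2), e0=np.sqrt(0.5))
    shares = []
    for seed in range(4):
        tab = generate_cohort(one_age_design(1000, 1000), params, seed=300 + seed)
        tab = tab[tab.occasion == 1].rename(columns={"value": "acceleration"})
        data = make_univariate_groups(tab)
        fit = fit_model(data, ModelSpec(), seed=0, n_starts=2)
        assert sum(fit.shares.values()) == pytest.approx(1.0, abs=1e-6)
        shares.append([fit.shares["A"], fit.shares["C"], fit.shares["E"]])
    mean = np.mean(shares, axis=0)
    assert mean == pytest.approx([0.30, 0.20, 0.50], abs=0.08)


def test_nesting_monotonicity(ace_table):
    data = make_univariate_groups(ace_table)
    full = fit_model(data, ModelSpec(), seed=0)
    for drop in ("a", "c", "ac"):
        red = fit_model(data, ModelSpec(drop=frozenset(drop)), seed=0)
        assert red.minus2ll >= full.minus2ll - 1e-8
        cmp = lrt(full, red)
        assert 0.0 <= cmp.p_value <= 1.0
        assert cmp.delta_df == len(drop)


def test_tiny_variance_phenotype_rescaled_consistently(ace_table):
    # pace-of-aging scale: components of order 1e-3
    shrunk = ace_table.copy()
    shrunk["acceleration"] = shrunk["acceleration"] * 0.03
    data = make_univariate_groups(shrunk)
    ref = fit_model(make_univariate_groups(ace_table), ModelSpec(), seed=0)
    fit = fit_model(data, ModelSpec(), seed=0)
    assert fit.components["A"] == pytest.approx(ref.components["A"] * 0.03**2, rel=1e-3)
    assert sum(fit.shares.values()) == pytest.approx(1.0, abs=1e-6)


def test_ladder_excludes_ce_when_dominance_signalled(one_age_design):
    params = TrueParams(a0=np.sqrt(0.5), c0=np.sqrt(0.3), e0=np.sqrt(0.2),
                        mode="ADE")
    tab = generate_cohort(one_age_design(800, 800), params, seed=31)
    tab = tab.rename(columns={"value": "acceleration"})
    data = make_univariate_groups(tab)
    comparisons, selected, fits = model_ladder_univariate(data, seed=0)
    labels = {f.label for f in fits}
    assert "CE" not in labels
    assert labels <= {"ADE", "AE", "E"}


def test_ladder_selects_e_model_for_pure_noise(one_age_design):
    tab = generate_cohort(one_age_design(400, 400), TrueParams(e0=1.0), seed=32)
    tab = tab.rename(columns={"value": "acceleration"})
    data = make_univariate_groups(tab)
    _, selected, _ = model_ladder_univariate(data, seed=0)
    assert selected.label in ("E", "AE")
    if selected.label == "AE":
        assert selected.shares["A"] < 0.1


# --------------------------------------------------------------- moderation

def test_zero_slopes_reduce_to_unmoderated_age_means_model(ace_table):
    data = make_univariate_groups(ace_table)
    spec_mod = ModelSpec(moderated=frozenset("ace"), means="age")
    spec_plain = ModelSpec(means="age")
    params = {"a0": 0.5, "c0": 0.4, "e0": 0.7, "a1": 0.0, "c1": 0.0, "e1": 0.0,
              "mu0": 0.05, "b1": 0.01, "b2": 0.0}
    plain = {k: v for k, v in params.items() if not k.endswith("1") or k == "b1"}
    assert negloglik(data, spec_mod, params) == pytest.approx(
        negloglik(data, spec_plain, plain), abs=1e-6
    )


def test_full_moderation_model_has_nine_parameters():
    spec = ModelSpec(moderated=frozenset("ace"), means="age")
    assert len(param_names(spec)) == 9


def test_moderated_spec_requires_age_means_model():
    with pytest.raises(ValueError):
        ModelSpec(moderated=frozenset("e"))


def test_moderation_rejects_constant_ages(one_age_design):
    tab = generate_cohort(one_age_design(100, 100, sd=0.0, gap=2.5), TrueParams(), seed=33)
    tab = tab.rename(columns={"value": "acceleration"})
    data = make_univariate_groups(tab, first_occasion_only=True)
    with pytest.raises(ValueError):
        fit_model(data, ModelSpec(moderated=frozenset("e"), means="age"))


def test_e_slope_recovery(one_age_design):
    from epitwin.cohort import CohortDesign

    e0, e1 = linear_path_from_endpoints(9.5, 0.29, 30, 1.23)
    params = TrueParams(a0=0.4, c0=0.65, e0=e0, e1=e1)
    design = CohortDesign(
        cohorts=tuple(
            (f"c{i}", m, 0.3, 400, 400) for i, m in enumerate([9.5, 15.5, 21.5, 27.5])
        )
    )
    tab = generate_cohort(design, params, seed=34).rename(columns={"value": "acceleration"})
    data = make_univariate_groups(tab)
    fit = fit_model(data, ModelSpec(moderated=frozenset("e"), means="age"), seed=0)
    assert abs(fit.params["e1"]) == pytest.approx(e1, abs=0.01)


def test_moderation_ladder_keeps_true_slope(one_age_design):
    from epitwin.cohort import CohortDesign

    e0, e1 = linear_path_from_endpoints(9.5, 0.29, 30, 1.23)
    params = TrueParams(a0=0.4, c0=0.65, e0=e0, e1=e1)
    design = CohortDesign(
        cohorts=tuple(
            (f"c{i}", m, 0.3, 200, 200) for i, m in enumerate([9.5, 15.5, 21.5, 27.5])
        )
    )
    tab = generate_cohort(design, params, seed=50).rename(columns={"value": "acceleration"})
    data = make_univariate_groups(tab)
    history, fit = moderation_ladder(data, mode="ACE", seed=0, n_starts=3)
    assert "e" in fit.spec.moderated
    # every committed prune was admissible: not significantly worse, lower AIC
    committed = [c for c in history if c.delta_aic < 0]
    assert all(c.p_value >= 0.05 for c in committed)


# --------------------------------------- components, shares, calibration

def test_component_grid_reproduces_published_intermediate_values():
    a0, a1 = linear_path_from_endpoints(9.5, 1.59, 30, 9.37)
    e0, e1 = linear_path_from_endpoints(9.5, 4.18, 30, 11.73)
    spec = ModelSpec(moderated=frozenset("ae"), means="age")
    params = {"a0": a0, "a1": a1, "c0": np.sqrt(3.04), "e0": e0, "e1": e1,
              "mu0": 0, "b1": 0, "b2": 0}
    grid = variance_components_at_age((spec, params), [21.5]).iloc[0]
    assert grid["A"] == pytest.approx(5.36, abs=0.01)
    assert grid["E"] == pytest.approx(8.14, abs=0.01)

    a0, a1 = linear_path_from_endpoints(9.5, 1.17, 30, 2.81)
    spec = ModelSpec(moderated=frozenset("a"), means="age", drop=frozenset("c"))
    params = {"a0": a0, "a1": a1, "e0": np.sqrt(3.78), "mu0": 0, "b1": 0, "b2": 0}
    grid = variance_components_at_age((spec, params), [18]).iloc[0]
    assert grid["A"] == pytest.approx(1.76, abs=0.01)
    assert grid["A_pct"] == 32


def test_component_grid_constant_without_moderation():
    spec = ModelSpec()
    params = {"a0": 0.6, "c0": 0.5, "e0": 0.8, "mu0": 0.0}
    grid = variance_components_at_age((spec, params), [10, 20, 30])
    assert grid["A"].nunique() == 1
    assert grid["V"].nunique() == 1


def test_standardize_shares_and_percent_rounding():
    shares = standardize({"A": 2.20, "C": 3.04, "E": 4.90})
    assert sum(shares.values()) == pytest.approx(1.0)
    assert standardize_percent(2.20, 10.14) == 22
    thirds = [standardize_percent(1.0, 3.0)] * 3
    assert thirds == [33, 33, 33]
    with pytest.raises(ValueError):
        standardize({"A": 0.0, "E": 0.0})


# ----------------------------------------------------------- profile CIs

def test_profile_ci_boundary_parameter_has_zero_lower_bound(one_age_design):
    # true c2 = 0: the shared-environment path estimate sits at/near the
    # boundary and the profile interval's lower limit is exactly 0
    params = TrueParams(a0=np.sqrt(0.4), c0=0.0, e0=np.sqrt(0.6))
    tab = generate_cohort(one_age_design(400, 400), params, seed=35)
    tab = tab.rename(columns={"value": "acceleration"})
    data = make_univariate_groups(tab)
    fit = fit_model(data, ModelSpec(), seed=0)
    ci = profile_ci(data, fit, "c0")
    assert ci["lower"] == 0.0
    assert ci["component_lower"] == 0.0
    assert ci["upper"] > 0.0


def test_profile_ci_width_shrinks_with_sample_size(one_age_design):
    params = TrueParams(e0=1.0)
    widths = {}
    for n in (250, 1000):
        tab = generate_cohort(one_age_design(n, n), params, seed=36)
        tab = tab.rename(columns={"value": "acceleration"})
        data = make_univariate_groups(tab)
        fit = fit_model(data, ModelSpec(drop=frozenset("ac")), seed=0)
        ci = profile_ci(data, fit, "e0")
        widths[n] = ci["upper"] - ci["lower"]
    # quadrupling n roughly halves the width
    assert widths[1000] == pytest.approx(widths[250] / 2.0, rel=0.25)


# --------------------------------------------- assumptions & equality tests

def test_assumption_checks_pass_on_symmetric_data(ace_table):
    data = make_univariate_groups(ace_table)
    results = assumption_checks(data)
    assert {r.reduced for r in results} == {
        "equal_means", "equal_variances", "equal_means_and_variances"
    }
    for r in results:
        assert r.delta_minus2ll >= -1e-6  # constrained never beats saturated
        assert r.p_value > 0.05


def test_assumption_checks_detect_twin_order_mean_shift(ace_table):
    shifted = ace_table.copy()
    sd = shifted["acceleration"].std()
    shifted.loc[shifted.twin_index == 2, "acceleration"] += 0.5 * sd
    data = make_univariate_groups(shifted)
    results = {r.reduced: r for r in assumption_checks(data)}
    assert results["equal_means"].p_value < 0.05


def test_equality_over_time_constraint(one_age_design):
    params = TrueParams(a0=np.sqrt(0.3), c0=np.sqrt(0.2), e0=np.sqrt(0.5),
                        r_a=0.8, r_c=0.9, r_e=0.1)
    tab = generate_cohort(one_age_design(600, 600), params, seed=37)
    tab = tab.rename(columns={"value": "acceleration"})
    data = make_bivariate_groups(tab)
    fit = fit_model(data, ModelSpec(design="bivariate"), seed=0)
    cmp = equality_over_time(data, fit, ["a", "c", "e"])
    assert cmp.delta_minus2ll >= -1e-6
    assert cmp.delta_df == 3
    with pytest.raises(ValueError):
        equality_over_time(data, fit, [])


def test_bivariate_cross_time_correlation_recovery(one_age_design):
    params = TrueParams(a0=np.sqrt(0.4), c0=np.sqrt(0.2), e0=np.sqrt(0.4),
                        r_a=0.8, r_c=0.9, r_e=0.1)
    tab = generate_cohort(one_age_design(1500, 1500), params, seed=38)
    tab = tab.rename(columns={"value": "acceleration"})
    data = make_bivariate_groups(tab)
    fit = fit_model(data, ModelSpec(design="bivariate"), seed=0)
    assert fit.correlations["rA"] == pytest.approx(0.8, abs=0.08)
    assert fit.correlations["rE"] == pytest.approx(0.1, abs=0.08)
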