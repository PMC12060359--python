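"""Power analysis for the classical twin design via non-central chi-square.

The non-centrality parameter (ncp) of the likelihood-ratio test is obtained by
fitting the reduced model to the *population* moments implied by the true
model, weighted by the group sizes: the minimized ML discrepancy equals the
expected -2 log-likelihood-ratio, and power is the upper-tail mass of the
non-central chi-square beyond the test's critical value.

Dropping a single variance component tests a parameter on the boundary of its
space, so the reference distribution of the LRT under the null is the 50:50
mixture of chi-square(0) and chi-square(1); the mixture critical value
(= the central chi-square(1) quantile at 1 - 2*alpha) is the default, with the
plain central chi-square(1) rule available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .biometric import (
    ModelSpec,
    ZygosityGroupData,
    fit_model,
    implied_cov_univariate,
    implied_cov_bivariate,
    negloglik,
    param_names,
)

__all__ = [
    "PowerScenario",
    "PowerResult",
    "analytic_power",
    "simulate_power",
    "two_group_moderation_power",
]

_SLOT = {"A": "a", "C": "c", "D": "c", "E": "e"}


@dataclass(frozen=True)
class PowerScenario:
    """True variance-component shares and design for a power calculation.

    ``shares`` maps 'A', 'C' (or 'D'), 'E' to shares of the total variance
    (non-negative, summing to 1).  ``test`` names the component dropped in the
    reduced model.  For the bivariate design, ``cross_time`` maps component
    letters to cross-occasion factor correlations.
    """

    shares: dict
    n_mz: int
    n_dz: int
    test: str = "C"
    alpha: float = 0.05
    design: str = "univariate"
    cross_time: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = list(self.shares.values())
        if any(v < 0 for v in vals):
            raise ValueError("shares must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-8:
            raise ValueError(f"shares must sum to 1, got {sum(vals)}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if "C" in self.shares and "D" in self.shares:
            raise ValueError("C and D are not jointly identified")
        if self.test not in self.shares:
            raise ValueError(f"test component {self.test!r} not in shares")

    @property
    def mode(self) -> str:
        return "ADE" if "D" in self.shares else "ACE"


@dataclass
class PowerResult:
    ncp: float
    df: int
    power: float
    alpha: float
    critical_value: float
    n_mz: int
    n_dz: int
    mc_power: float = None
    mc_se: float = None
    mc_reps: int = None
    mc_failed: int = 0


def _critical_value(alpha: float, df: int, boundary_mixture: bool) -> float:
    if boundary_mixture and df == 1:
        # 0.5*chi2_0 + 0.5*chi2_1 mixture: P(LRT > c) = 0.5 * sf_chi2_1(c)
        return float(stats.chi2.ppf(1.0 - 2.0 * alpha, 1))
    return float(stats.chi2.ppf(1.0 - alpha, df))


def _scenario_params(scenario: PowerScenario) -> dict:
    p = {"a0": 0.0, "c0": 0.0, "e0": 0.0, "mu0": 0.0}
    for comp, share in scenario.shares.items():
        p[_SLOT[comp] + "0"] = math.sqrt(share)
    return p


def _scenario_spec(scenario: PowerScenario, drop=frozenset()) -> ModelSpec:
    return ModelSpec(mode=scenario.mode, design=scenario.design, drop=drop)


def _population_data(scenario: PowerScenario) -> ZygosityGroupData:
    spec = _scenario_spec(scenario)
    if scenario.design == "univariate":
        params = _scenario_params(scenario)
        cov_mz = implied_cov_univariate(spec, params, "MZ")
        cov_dz = implied_cov_univariate(spec, params, "DZ")
    elif scenario.design == "bivariate":
        params = {"mu1": 0.0, "mu2": 0.0}
        for comp, share in scenario.shares.items():
            c = _SLOT[comp]
            params[f"s{c}1"] = params[f"s{c}2"] = math.sqrt(share)
            params[f"r{c}"] = scenario.cross_time.get(comp, 0.0)
        for c in ("a", "c", "e"):
            params.setdefault(f"s{c}1", 0.0)
            params.setdefault(f"s{c}2", 0.0)
            params.setdefault(f"r{c}", 0.0)
        cov_mz = implied_cov_bivariate(spec, params, "MZ")
        cov_dz = implied_cov_bivariate(spec, params, "DZ")
    else:
        raise ValueError(f"unknown design {scenario.design!r}")
    return ZygosityGroupData.from_moments(
        scenario.n_mz, cov_mz, scenario.n_dz, cov_dz, design=scenario.design
    )


def _true_m2ll(data: ZygosityGroupData, scenario: PowerScenario) -> float:
    """-2LL of the true (full) model at the population moments (the floor)."""
    spec = _scenario_spec(scenario)
    if scenario.design == "univariate":
        params = _scenario_params(scenario)
    else:
        fit = fit_model(data, spec, seed=0, n_starts=3)
        return fit.minus2ll
    return negloglik(data, spec, params)


def analytic_power(
    scenario: PowerScenario, boundary_mixture: bool = True
) -> PowerResult:
    """Analytic LRT power for dropping one component from the true model.

    The reduced model (true model minus the tested component) is fitted to the
    implied population covariances weighted by the group pair counts; the
    minimized discrepancy is the non-centrality parameter, which is exactly
    linear in the total pair count at a fixed MZ:DZ ratio.  When the dropped
    component's true share is zero the ncp is zero and power equals alpha.
    """
    data = _population_data(scenario)
    drop = frozenset(_SLOT[scenario.test])
    reduced_spec = _scenario_spec(scenario, drop=drop)
    df = len(param_names(_scenario_spec(scenario))) - len(param_names(reduced_spec))
    floor = _true_m2ll(data, scenario)
    if scenario.shares[scenario.test] == 0.0:
        ncp = 0.0
    else:
        fit = fit_model(data, reduced_spec, seed=0, n_starts=3)
        ncp = max(fit.minus2ll - floor, 0.0)
    crit = _critical_value(scenario.alpha, df, boundary_mixture)
    # at ncp 0 the LRT keeps its null (mixture) distribution, so power = size;
    # for ncp > 0 the standard practice takes the noncentral chi-square tail
    # (the boundary atom at 0 carries negligible mass under the alternative)
    power = scenario.alpha if ncp < 1e-8 else float(stats.ncx2.sf(crit, df, ncp))
    return PowerResult(
        ncp=float(ncp),
        df=df,
        power=power,
        alpha=scenario.alpha,
        critical_value=crit,
        n_mz=scenario.n_mz,
        n_dz=scenario.n_dz,
    )


def simulate_power(
    scenario: PowerScenario,
    reps: int,
    seed: int,
    boundary_mixture: bool = True,
    n_starts: int = 2,
) -> PowerResult:
    """Monte-Carlo LRT power: fraction of simulated datasets rejecting.

    Each replicate draws MZ/DZ pair vectors from the true implied covariances,
    fits the full and reduced models, and rejects when the -2LL difference
    exceeds the same critical value the analytic method uses.  Non-convergent
    replicates are excluded and counted.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    res = analytic_power(scenario, boundary_mixture=boundary_mixture)
    spec_full = _scenario_spec(scenario)
    spec_red = _scenario_spec(scenario, drop=frozenset(_SLOT[scenario.test]))
    pop = _population_data(scenario)
    chol_mz = np.linalg.cholesky(pop.mz.cov)
    chol_dz = np.linalg.cholesky(pop.dz.cov)
    p = pop.mz.cov.shape[0]
    from .biometric import _Group

    rejections = 0
    failed = 0
    for i in range(reps):
        y_mz = rng.standard_normal((scenario.n_mz, p)) @ chol_mz.T
        y_dz = rng.standard_normal((scenario.n_dz, p)) @ chol_dz.T
        data = ZygosityGroupData(
            mz=_Group(y=y_mz), dz=_Group(y=y_dz), design=scenario.design
        )
        try:
            full = fit_model(data, spec_full, seed=int(rng.integers(2**31)),
                             n_starts=n_starts)
            red = fit_model(data, spec_red, seed=int(rng.integers(2**31)),
                            n_starts=n_starts)
        except RuntimeError:
            failed += 1
            continue
        stat = red.minus2ll - full.minus2ll
        if stat > res.critical_value:
            rejections += 1
    n_ok = reps - failed
    mc = rejections / n_ok if n_ok else float("nan")
    res.mc_power = mc
    res.mc_se = math.sqrt(mc * (1 - mc) / n_ok) if n_ok else float("nan")
    res.mc_reps = n_ok
    res.mc_failed = failed
    return res


def two_group_moderation_power(
    scenario_1: PowerScenario,
    scenario_2: PowerScenario,
    component: str = None,
    boundary_mixture: bool = True,
) -> PowerResult:
    """Power to detect a component difference between two groups (binary
    moderator): the reduced model constrains the named component's path equal
    across the two groups, everything else free per group.

    The ncp is the summed ML discrepancy of the constrained model fitted to
    both groups' population moments.  Identical scenarios give ncp 0 and
    power alpha.
    """
    if scenario_1.design != scenario_2.design or scenario_1.design != "univariate":
        raise ValueError("two-group power implemented for univariate designs")
    component = component or scenario_1.test
    slot = _SLOT[component]
    data1 = _population_data(scenario_1)
    data2 = _population_data(scenario_2)
    spec = _scenario_spec(scenario_1)
    names = param_names(spec)

    floor = _true_m2ll(data1, scenario_1) + _true_m2ll(data2, scenario_2)

    # shared path for the tested component, all other params free per group
    free1 = [n for n in names]
    free2 = [n for n in names if n != slot + "0"]

    from scipy import optimize

    def objective(vec):
        p1 = dict(zip(free1, vec[: len(free1)]))
        p2 = dict(zip(free2, vec[len(free1):]))
        p2[slot + "0"] = p1[slot + "0"]
        return negloglik(data1, spec, p1) + negloglik(data2, spec, p2)

    s1 = _scenario_params(scenario_1)
    s2 = _scenario_params(scenario_2)
    x0 = np.array([s1[n] for n in free1] + [s2[n] for n in free2])
    best = None
    for jitter in (0.0, 0.1, -0.1):
        res = optimize.minimize(
            objective, x0 + jitter, method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-13},
        )
        if best is None or res.fun < best.fun:
            best = res
    ncp = max(float(best.fun) - floor, 0.0)
    df = 1
    alpha = scenario_1.alpha
    crit = _critical_value(alpha, df, boundary_mixture)
    power = alpha if ncp < 1e-8 else float(stats.ncx2.sf(crit, df, ncp))
    return PowerResult(
        ncp=ncp,
        df=df,
        power=power,
        alpha=alpha,
        critical_value=crit,
        n_mz=scenario_1.n_mz + scenario_2.n_mz,
        n_dz=scenario_1.n_dz + scenario_2.n_dz,
    )
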