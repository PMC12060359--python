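"""Maximum-likelihood biometrical twin models (ACE/ADE), full information.

The likelihood unit is the twin pair: each pair contributes a multivariate-
normal density with an implied mean and covariance determined by its zygosity
(and, under age moderation, its age, treated as a definition variable).

Three model families are supported:

* **Univariate** — pair vector (twin1, twin2); implied covariance
  diag = a^2 + c^2 + e^2, off-diag = kA*a^2 + kC*c^2 with kA = 1 (MZ) / 0.5
  (DZ) and, in ADE mode, the c slot holding dominance d with kD = 1 / 0.25.
  Paths are unconstrained (sign-indeterminate); variance components are
  reported as squared paths.
* **Age-moderated univariate** — each path is linear in the pair's age,
  x(age) = x0 + x1*age, with a linear+quadratic age mean structure; the full
  ACE model has 9 free parameters (3 baselines, 3 slopes, 3 mean terms).
* **Bivariate correlated-factors** — pair vector (twin1-t1, twin1-t2,
  twin2-t1, twin2-t2) across two measurement occasions; factor loadings fixed
  to 1 and factor standard deviations free per occasion, with cross-occasion
  factor correlations rA, rC (rD), rE.

Model selection follows the classical ladder: chi-square difference tests of
nested reductions combined with AIC arbitration.  Confidence intervals are
profile-likelihood based.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "ZygosityGroupData",
    "FitResult",
    "ComparisonResult",
    "make_univariate_groups",
    "make_bivariate_groups",
    "implied_cov_univariate",
    "implied_cov_bivariate",
    "negloglik",
    "fit_model",
    "lrt",
    "model_ladder_univariate",
    "fit_moderation",
    "moderation_ladder",
    "test_equality_over_time",
    "variance_components_at_age",
    "standardize",
    "profile_ci",
    "assumption_checks",
    "linear_path_from_endpoints",
]

LOG2PI = math.log(2.0 * math.pi)
_PENALTY = 1e12

_COMPONENTS = ("a", "c", "e")


# --------------------------------------------------------------------------
# specification & data containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Which biometrical model to fit.

    ``drop`` removes components entirely (the 'c' slot is C in ACE mode and D
    in ADE mode); ``moderated`` adds a linear age slope to the named paths and
    requires the linear+quadratic age means model.  ``equal_over_time``
    (bivariate only) constrains a component's factor variance to be equal at
    both occasions.
    """

    mode: str = "ACE"
    design: str = "univariate"
    drop: frozenset = frozenset()
    moderated: frozenset = frozenset()
    means: str = "constant"          # 'constant' or 'age' (linear+quadratic)
    equal_over_time: frozenset = frozenset()

    def __post_init__(self):
        if self.mode not in ("ACE", "ADE"):
            raise ValueError(f"mode must be ACE or ADE, got {self.mode!r}")
        if self.design not in ("univariate", "bivariate"):
            raise ValueError(f"unknown design {self.design!r}")
        for s in (self.drop, self.moderated, self.equal_over_time):
            bad = set(s) - set(_COMPONENTS)
            if bad:
                raise ValueError(f"unknown components {bad}")
        if self.moderated and self.means != "age":
            raise ValueError("moderated paths require the 'age' means model")
        if self.moderated and self.design == "bivariate":
            raise ValueError("moderation is univariate-only")

    @property
    def free(self) -> tuple:
        return tuple(c for c in _COMPONENTS if c not in self.drop)

    def genetic_coef(self, zygosity: str):
        """(kA, kC) covariance weights for a zygosity group."""
        if zygosity == "MZ":
            return 1.0, 1.0
        if zygosity == "DZ":
            return 0.5, (1.0 if self.mode == "ACE" else 0.25)
        raise ValueError(f"unknown zygosity {zygosity!r}")

    @property
    def label(self) -> str:
        base = {"ACE": "ACE", "ADE": "ADE"}[self.mode]
        keep = "".join(
            ("D" if (c == "c" and self.mode == "ADE") else c.upper())
            for c in self.free
        )
        return keep if keep else "null"


def param_names(spec: ModelSpec) -> list:
    """Ordered free-parameter names for a spec."""
    names = []
    if spec.design == "univariate":
        for c in spec.free:
            names.append(c + "0")
        for c in spec.free:
            if c in spec.moderated:
                names.append(c + "1")
        names += ["mu0"] + (["b1", "b2"] if spec.means == "age" else [])
    else:
        for c in spec.free:
            if c in spec.equal_over_time:
                names.append(f"s{c}")
            else:
                names += [f"s{c}1", f"s{c}2"]
            names.append(f"r{c}")
        names += ["mu1", "mu2"]
    return names


@dataclass
class _Group:
    """One zygosity group: raw pair vectors and/or sufficient statistics."""

    y: np.ndarray = None          # (n, p) pair observation vectors
    ages: np.ndarray = None       # (n,) per-pair moderator age
    n: int = 0
    mean: np.ndarray = None       # (p,)
    cov: np.ndarray = None        # (p, p), n-denominator

    def __post_init__(self):
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            self.n = self.y.shape[0]
            if self.n:
                self.mean = self.y.mean(axis=0)
                d = self.y - self.mean
                self.cov = d.T @ d / self.n


@dataclass
class ZygosityGroupData:
    """Stacked complete pair vectors per zygosity, plus per-pair ages."""

    mz: _Group
    dz: _Group
    design: str = "univariate"

    @property
    def n_mz(self) -> int:
        return self.mz.n

    @property
    def n_dz(self) -> int:
        return self.dz.n

    def groups(self):
        return (("MZ", self.mz), ("DZ", self.dz))

    @classmethod
    def from_moments(cls, n_mz, cov_mz, n_dz, cov_dz, mean=None, design="univariate"):
        """Build data from population moments (for non-centrality power)."""
        p = np.asarray(cov_mz).shape[0]
        m = np.zeros(p) if mean is None else np.asarray(mean, float)
        mz = _Group(n=n_mz, mean=m.copy(), cov=np.asarray(cov_mz, float))
        dz = _Group(n=n_dz, mean=m.copy(), cov=np.asarray(cov_dz, float))
        return cls(mz=mz, dz=dz, design=design)

    def pooled_variance(self) -> float:
        tot = self.n_mz + self.n_dz
        return float(
            (self.n_mz * np.trace(self.mz.cov) + self.n_dz * np.trace(self.dz.cov))
            / (tot * self.mz.cov.shape[0])
        )

    def pooled_mean(self) -> float:
        tot = self.n_mz + self.n_dz
        return float(
            (self.n_mz * self.mz.mean.mean() + self.n_dz * self.dz.mean.mean()) / tot
        )


def make_univariate_groups(
    acc: pd.DataFrame,
    value_col: str = "acceleration",
    first_occasion_only: bool = False,
) -> ZygosityGroupData:
    """Univariate pair vectors (twin1, twin2), occasions pooled as units.

    Pooling the two measurement occasions treats each (pair, occasion) as an
    independent likelihood unit (deliberately ignoring within-person
    clustering); ``first_occasion_only`` keeps occasion 1 only, the
    sensitivity variant.
    """
    sub = acc[acc["occasion"] == 1] if first_occasion_only else acc
    wide = sub.pivot_table(
        index=["pair_id", "zygosity", "occasion"],
        columns="twin_index",
        values=value_col,
    )
    age = sub.groupby(["pair_id", "zygosity", "occasion"])["age"].mean()
    wide = wide.join(age).dropna(subset=[1, 2]).reset_index()
    out = {}
    for zyg in ("MZ", "DZ"):
        grp = wide[wide["zygosity"] == zyg]
        out[zyg] = _Group(
            y=grp[[1, 2]].to_numpy(float), ages=grp["age"].to_numpy(float)
        )
    return ZygosityGroupData(mz=out["MZ"], dz=out["DZ"], design="univariate")


def make_bivariate_groups(
    acc: pd.DataFrame, value_col: str = "acceleration"
) -> ZygosityGroupData:
    """Bivariate pair vectors (twin1-t1, twin1-t2, twin2-t1, twin2-t2)."""
    wide = acc.pivot_table(
        index=["pair_id", "zygosity"],
        columns=["twin_index", "occasion"],
        values=value_col,
    )
    cols = [(1, 1), (1, 2), (2, 1), (2, 2)]
    missing = [c for c in cols if c not in wide.columns]
    if missing:
        raise ValueError(f"bivariate data needs twin x occasion cells {missing}")
    wide = wide[cols].dropna().reset_index()
    out = {}
    for zyg in ("MZ", "DZ"):
        grp = wide[wide["zygosity"] == zyg]
        out[zyg] = _Group(y=grp[cols].to_numpy(float))
    return ZygosityGroupData(mz=out["MZ"], dz=out["DZ"], design="bivariate")


# --------------------------------------------------------------------------
# implied moments
# --------------------------------------------------------------------------

def _univariate_vw(spec: ModelSpec, params: dict, zygosity: str, age=None):
    """Diagonal v and off-diagonal w of the implied 2x2 pair covariance."""
    k_a, k_c = spec.genetic_coef(zygosity)
    age = 0.0 if age is None else np.asarray(age, float)
    paths = {}
    for c in _COMPONENTS:
        if c in spec.drop:
            paths[c] = 0.0 * age if np.ndim(age) else 0.0
        else:
            x = params[c + "0"]
            if c in spec.moderated:
                x = x + params[c + "1"] * age
            paths[c] = x
    a2, c2, e2 = paths["a"] ** 2, paths["c"] ** 2, paths["e"] ** 2
    v = a2 + c2 + e2
    w = k_a * a2 + k_c * c2
    return v, w


def implied_cov_univariate(
    spec: ModelSpec, params: dict, zygosity: str, age=None
) -> np.ndarray:
    """Implied 2x2 within-pair covariance matrix at the given (scalar) age."""
    v, w = _univariate_vw(spec, params, zygosity, age)
    return np.array([[v, w], [w, v]], dtype=float)


def implied_cov_bivariate(
    spec: ModelSpec, params: dict, zygosity: str
) -> np.ndarray:
    """Implied 4x4 covariance of (twin1-t1, twin1-t2, twin2-t1, twin2-t2).

    Within-twin cross-time covariance sums r_x * sigma_x1 * sigma_x2 over all
    components; cross-twin terms weight the genetic parts by the zygosity
    coefficients and drop E (unique environment is twin-specific).
    """
    k_a, k_c = spec.genetic_coef(zygosity)
    k = {"a": k_a, "c": k_c, "e": 0.0}
    s1, s2, r = {}, {}, {}
    for c in _COMPONENTS:
        if c in spec.drop:
            s1[c] = s2[c] = r[c] = 0.0
        elif c in spec.equal_over_time:
            s1[c] = s2[c] = params[f"s{c}"]
            r[c] = params[f"r{c}"]
        else:
            s1[c], s2[c], r[c] = params[f"s{c}1"], params[f"s{c}2"], params[f"r{c}"]
        if abs(r[c]) > 1:
            raise ValueError(f"|r_{c}| > 1")
    var1 = sum(s1[c] ** 2 for c in _COMPONENTS)
    var2 = sum(s2[c] ** 2 for c in _COMPONENTS)
    within_ct = sum(r[c] * s1[c] * s2[c] for c in _COMPONENTS)
    cross_t1 = sum(k[c] * s1[c] ** 2 for c in _COMPONENTS)
    cross_t2 = sum(k[c] * s2[c] ** 2 for c in _COMPONENTS)
    cross_ct = sum(k[c] * r[c] * s1[c] * s2[c] for c in _COMPONENTS)
    sig = np.array(
        [
            [var1, within_ct, cross_t1, cross_ct],
            [within_ct, var2, cross_ct, cross_t2],
            [cross_t1, cross_ct, var1, within_ct],
            [cross_ct, cross_t2, within_ct, var2],
        ],
        dtype=float,
    )
    return sig


def _mean_univariate(spec: ModelSpec, params: dict, age=None):
    m = params["mu0"]
    if spec.means == "age":
        age = 0.0 if age is None else np.asarray(age, float)
        m = m + params["b1"] * age + params["b2"] * age**2
    return m


# --------------------------------------------------------------------------
# -2 log likelihood
# --------------------------------------------------------------------------

def _m2ll_suffstats(group: _Group, sigma: np.ndarray, mu: np.ndarray) -> float:
    """-2 log MVN likelihood of a group from sufficient statistics."""
    if group.n == 0:
        return 0.0
    p = sigma.shape[0]
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return _PENALTY
    try:
        sinv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        return _PENALTY
    d = group.mean - mu
    return group.n * (
        p * LOG2PI + logdet + float(np.trace(sinv @ group.cov)) + float(d @ sinv @ d)
    )


def _m2ll_group(group: _Group, spec: ModelSpec, params: dict, zygosity: str) -> float:
    """-2LL of one zygosity group under the spec at the given parameters."""
    needs_defvar = spec.moderated or spec.means == "age"
    if spec.design == "bivariate":
        sigma = implied_cov_bivariate(spec, params, zygosity)
        mu = np.array([params["mu1"], params["mu2"]] * 2)
        return _m2ll_suffstats(group, sigma, mu)
    if not needs_defvar:
        sigma = implied_cov_univariate(spec, params, zygosity)
        mu = np.full(2, params["mu0"])
        return _m2ll_suffstats(group, sigma, mu)
    # definition-variable path: covariance and mean evaluated at each pair's age
    if group.y is None or group.ages is None:
        raise ValueError("raw pair vectors with ages required for this spec")
    v, w = _univariate_vw(spec, params, zygosity, group.ages)
    v = np.broadcast_to(np.asarray(v, float), group.ages.shape).copy()
    w = np.broadcast_to(np.asarray(w, float), group.ages.shape).copy()
    det = v * v - w * w
    if np.any(v <= 0) or np.any(det <= 0):
        return _PENALTY
    m = _mean_univariate(spec, params, group.ages)
    d1 = group.y[:, 0] - m
    d2 = group.y[:, 1] - m
    quad = (v * (d1 * d1 + d2 * d2) - 2.0 * w * d1 * d2) / det
    return float(np.sum(2.0 * LOG2PI + np.log(det) + quad))


def negloglik(data: ZygosityGroupData, spec: ModelSpec, params: dict) -> float:
    """-2 log likelihood over both zygosity groups.

    Means and variances are constrained equal across twin order and zygosity;
    under moderation the implied covariance is evaluated per pair at the
    pair's own age.  A non-positive-definite implied covariance returns a
    large finite penalty so the optimizer backs away.
    """
    return sum(_m2ll_group(g, spec, params, zyg) for zyg, g in data.groups())


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates and fit statistics for one biometrical model."""

    spec: ModelSpec
    params: dict
    minus2ll: float
    n_params: int
    aic: float
    converged: bool
    n_mz: int
    n_dz: int
    components: dict = field(default_factory=dict)   # unstandardized (squared paths)
    shares: dict = field(default_factory=dict)       # components / total variance
    correlations: dict = field(default_factory=dict) # bivariate rA/rC/rE
    cis: dict = field(default_factory=dict)          # 90% profile CIs per component
    label: str = ""


@dataclass
class ComparisonResult:
    """Nested-model chi-square difference test plus AIC difference."""

    full: str
    reduced: str
    delta_minus2ll: float
    delta_df: int
    p_value: float
    delta_aic: float
    selected: str = ""


def _component_key(spec: ModelSpec, c: str) -> str:
    return "D" if (c == "c" and spec.mode == "ADE") else c.upper()


def _summarize(spec, params, data, minus2ll, converged) -> FitResult:
    names = param_names(spec)
    n_params = len(names)
    aic = minus2ll + 2.0 * n_params
    comps, corrs = {}, {}
    if spec.design == "univariate":
        # moderated components are age-dependent; summarize at the pooled mean age
        ages = [g.ages for _, g in data.groups() if g.ages is not None and g.n]
        ref_age = float(np.mean(np.concatenate(ages))) if ages else None
        for c in _COMPONENTS:
            if c in spec.drop:
                comps[_component_key(spec, c)] = 0.0
            else:
                x = params[c + "0"]
                if c in spec.moderated:
                    x = x + params[c + "1"] * (ref_age or 0.0)
                comps[_component_key(spec, c)] = float(x**2)
    else:
        for c in _COMPONENTS:
            key = _component_key(spec, c)
            if c in spec.drop:
                comps[key + "_t1"] = comps[key + "_t2"] = 0.0
                continue
            if c in spec.equal_over_time:
                s1 = s2 = params[f"s{c}"]
            else:
                s1, s2 = params[f"s{c}1"], params[f"s{c}2"]
            comps[key + "_t1"], comps[key + "_t2"] = float(s1**2), float(s2**2)
            corrs["r" + key] = float(params[f"r{c}"])
    shares = {}
    if spec.design == "univariate":
        v = sum(comps.values())
        if v > 0:
            shares = {k: val / v for k, val in comps.items()}
    else:
        for t in ("_t1", "_t2"):
            v = sum(val for k, val in comps.items() if k.endswith(t))
            if v > 0:
                shares.update(
                    {k: val / v for k, val in comps.items() if k.endswith(t)}
                )
    return FitResult(
        spec=spec,
        params=dict(params),
        minus2ll=float(minus2ll),
        n_params=n_params,
        aic=float(aic),
        converged=converged,
        n_mz=data.n_mz,
        n_dz=data.n_dz,
        components=comps,
        shares=shares,
        correlations=corrs,
        label=spec.label,
    )


def _moment_start(data: ZygosityGroupData, spec: ModelSpec) -> dict:
    """Falconer-moment starting values."""
    v_tot = max(data.pooled_variance(), 1e-12)
    mu = data.pooled_mean()

    def corr(g):
        c = g.cov
        d = np.sqrt(np.diag(c))
        if np.any(d <= 0):
            return 0.0
        return float(c[0, 1] / (d[0] * d[1]))

    r_mz, r_dz = corr(data.mz), corr(data.dz)
    if spec.design == "bivariate":
        r_mz = float(np.clip((data.mz.cov[0, 2] + data.mz.cov[1, 3]) / (2 * v_tot), -0.95, 0.95))
        r_dz = float(np.clip((data.dz.cov[0, 2] + data.dz.cov[1, 3]) / (2 * v_tot), -0.95, 0.95))
    h2 = min(max(2.0 * (r_mz - r_dz), 0.05), 0.9)
    c2 = min(max(2.0 * r_dz - r_mz, 0.05), 0.9)
    e2 = min(max(1.0 - r_mz, 0.05), 0.9)
    tot = h2 + c2 + e2
    share = {"a": h2 / tot, "c": c2 / tot, "e": e2 / tot}
    start = {}
    if spec.design == "univariate":
        for c in spec.free:
            start[c + "0"] = math.sqrt(share[c] * v_tot)
            if c in spec.moderated:
                start[c + "1"] = 0.0
        start["mu0"] = mu
        if spec.means == "age":
            start["b1"] = 0.0
            start["b2"] = 0.0
            if spec.moderated:
                # center the baseline path at the low end of the age range
                start["mu0"] = mu
    else:
        for c in spec.free:
            s = math.sqrt(share[c] * v_tot)
            if c in spec.equal_over_time:
                start[f"s{c}"] = s
            else:
                start[f"s{c}1"] = start[f"s{c}2"] = s
            start[f"r{c}"] = 0.5
        m1 = (data.n_mz * data.mz.mean + data.n_dz * data.dz.mean) / max(
            data.n_mz + data.n_dz, 1
        )
        start["mu1"] = float((m1[0] + m1[2]) / 2)
        start["mu2"] = float((m1[1] + m1[3]) / 2)
    return start


def _bounds(names):
    return [(-0.999, 0.999) if n.startswith("r") else (None, None) for n in names]


def fit_model(
    data: ZygosityGroupData,
    spec: ModelSpec,
    seed: int = 0,
    n_starts: int = 5,
    gtol: float = 1e-8,
    start: dict = None,
) -> FitResult:
    """Minimize the FIML -2LL with multiple jittered quasi-Newton starts.

    The best of ``n_starts`` L-BFGS-B runs is returned; the convergence flag
    requires optimizer success and agreement (within 1e-4 in -2LL) of at
    least one other successful start when several are run.  Phenotypes with
    pooled variance below 1e-3 (e.g. pace-of-aging scores with components of
    order 1e-3) are internally rescaled to unit order and results
    back-transformed, which keeps the quasi-Newton steps well conditioned.
    """
    if data.n_mz + data.n_dz < 1:
        raise ValueError("no complete pairs")
    if min(data.n_mz, data.n_dz) < 50:
        log.warning(
            "fewer than 50 pairs in a zygosity group (MZ=%d, DZ=%d): "
            "estimates may be unstable", data.n_mz, data.n_dz
        )
    if spec.moderated:
        for zyg, g in data.groups():
            if g.n and (g.ages is None or np.ptp(g.ages) < 1e-9):
                raise ValueError(
                    f"moderated spec requires varying ages ({zyg} group is constant)"
                )

    data, scale = _maybe_rescale(data)
    names = param_names(spec)
    base = start or _moment_start(data, spec)
    base_vec = np.array([base.get(n, 0.0) for n in names], dtype=float)
    rng = np.random.default_rng(seed)
    bounds = _bounds(names)

    def objective(vec):
        return negloglik(data, spec, dict(zip(names, vec)))

    results = []
    for i in range(max(n_starts, 1)):
        if i == 0:
            x0 = base_vec
        else:
            jitter = rng.normal(0.0, 0.3, size=base_vec.shape) * (
                np.abs(base_vec) + 0.1
            )
            x0 = base_vec + jitter
        x0 = np.array(
            [np.clip(x, lo, hi) if lo is not None else x
             for x, (lo, hi) in zip(x0, bounds)]
        )
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": gtol},
        )
        if np.isfinite(res.fun):
            results.append(res)
    if not results:
        raise RuntimeError(f"all optimizer starts failed for model {spec.label}")
    results.sort(key=lambda r: r.fun)
    best = results[0]
    agree = [r for r in results if abs(r.fun - best.fun) < 1e-4]
    converged = bool(best.success) and (len(results) == 1 or len(agree) >= 2)
    params = dict(zip(names, best.x))
    m2ll = float(best.fun)
    params, m2ll = _unscale(spec, params, m2ll, scale, data)
    fit = _summarize(spec, params, _unscale_data(data, scale), m2ll, converged)
    return fit


def _maybe_rescale(data: ZygosityGroupData, threshold: float = 1e-3):
    """Rescale tiny-variance phenotypes to unit order for optimization."""
    v = data.pooled_variance()
    if v >= threshold or v <= 0:
        return data, 1.0
    f = 1.0 / math.sqrt(v)

    def scale_group(g: _Group) -> _Group:
        out = _Group(n=g.n)
        out.ages = g.ages
        if g.y is not None:
            return _Group(y=g.y * f, ages=g.ages)
        out.mean = g.mean * f
        out.cov = g.cov * f * f
        return out

    return ZygosityGroupData(
        mz=scale_group(data.mz), dz=scale_group(data.dz), design=data.design
    ), f


def _unscale_data(data, scale):
    if scale == 1.0:
        return data
    return _maybe_rescale_inverse(data, scale)


def _maybe_rescale_inverse(data, f):
    def unscale_group(g: _Group) -> _Group:
        out = _Group(n=g.n)
        out.ages = g.ages
        if g.y is not None:
            return _Group(y=g.y / f, ages=g.ages)
        out.mean = g.mean / f
        out.cov = g.cov / (f * f)
        return out

    return ZygosityGroupData(
        mz=unscale_group(data.mz), dz=unscale_group(data.dz), design=data.design
    )


def _unscale(spec, params, m2ll, f, data):
    """Back-transform parameters and -2LL from the rescaled to original scale."""
    if f == 1.0:
        return params, m2ll
    out = dict(params)
    for k in params:
        if k.startswith("r"):
            continue
        out[k] = params[k] / f
    p = 4 if spec.design == "bivariate" else 2
    n_obs = (data.n_mz + data.n_dz) * p
    # y' = f*y shifts each log-density by +log f per observation
    m2ll_orig = m2ll + 2.0 * n_obs * math.log(f)
    return out, m2ll_orig


def lrt(full: FitResult, reduced: FitResult) -> ComparisonResult:
    """Chi-square difference test of a nested reduction against a fuller model."""
    delta = reduced.minus2ll - full.minus2ll
    df = full.n_params - reduced.n_params
    if df < 1:
        raise ValueError("reduced model must have fewer parameters")
    p = float(stats.chi2.sf(max(delta, 0.0), df))
    return ComparisonResult(
        full=full.label,
        reduced=reduced.label,
        delta_minus2ll=float(delta),
        delta_df=df,
        p_value=p,
        delta_aic=float(reduced.aic - full.aic),
    )


# --------------------------------------------------------------------------
# model ladders
# --------------------------------------------------------------------------

def _data_twin_correlations(data: ZygosityGroupData):
    def corr(g):
        c = g.cov
        if data.design == "bivariate":
            # average the per-occasion cross-twin correlations
            r1 = c[0, 2] / math.sqrt(c[0, 0] * c[2, 2])
            r2 = c[1, 3] / math.sqrt(c[1, 1] * c[3, 3])
            return (r1 + r2) / 2.0
        return c[0, 1] / math.sqrt(c[0, 0] * c[1, 1])

    return corr(data.mz), corr(data.dz)


def choose_mode(data: ZygosityGroupData) -> str:
    """ACE vs ADE from the data's Pearson twin correlations (rMZ vs 2 rDZ)."""
    from .descriptives import classify_ace_ade

    r_mz, r_dz = _data_twin_correlations(data)
    return classify_ace_ade(float(np.clip(r_mz, -1, 1)), float(np.clip(r_dz, -1, 1)))


def _ladder_candidates(mode: str):
    if mode == "ACE":
        return [frozenset(), frozenset("c"), frozenset("a"), frozenset("ac")]
    return [frozenset(), frozenset("c"), frozenset("ac")]  # ADE, AE, E


def model_ladder_univariate(
    data: ZygosityGroupData,
    mode: str = "auto",
    seed: int = 0,
    alpha: float = 0.05,
    n_starts: int = 5,
):
    """Fit the nested univariate model ladder and select the best model.

    Mode (ACE vs ADE) is chosen from the data's twin correlations unless
    given.  Each reduction is tested against the full model with a chi-square
    difference test; among the full model and all reductions that do not fit
    significantly worse, the lowest AIC wins (AIC ties below 1e-6 go to the
    model with fewer parameters).
    """
    if mode == "auto":
        mode = choose_mode(data)
    fits, comparisons = [], []
    full = None
    for i, drop in enumerate(_ladder_candidates(mode)):
        spec = ModelSpec(mode=mode, drop=drop)
        fit = fit_model(data, spec, seed=seed + i, n_starts=n_starts)
        fits.append(fit)
        if full is None:
            full = fit
        else:
            comparisons.append(lrt(full, fit))
    admissible = [full] + [
        f for f, cmp in zip(fits[1:], comparisons) if cmp.p_value >= alpha
    ]
    admissible.sort(key=lambda f: (round(f.aic / 1e-6), f.n_params))
    selected = admissible[0]
    for cmp in comparisons:
        cmp.selected = selected.label
    return comparisons, selected, fits


def fit_moderation(
    data: ZygosityGroupData,
    spec: ModelSpec = None,
    mode: str = "ACE",
    seed: int = 0,
    n_starts: int = 5,
) -> FitResult:
    """Fit an age-moderated univariate model (definition-variable FIML).

    Default spec moderates all free paths with linear+quadratic age means —
    the full 9-parameter moderation model for ACE/ADE.
    """
    if spec is None:
        spec = ModelSpec(
            mode=mode, moderated=frozenset("ace"), means="age"
        )
    return fit_model(data, spec, seed=seed, n_starts=n_starts)


def moderation_ladder(
    data: ZygosityGroupData,
    mode: str = "auto",
    seed: int = 0,
    alpha: float = 0.05,
    n_starts: int = 5,
):
    """Backward-prune moderation slopes from the full 9-parameter model.

    At each step every remaining slope is provisionally dropped; among drops
    that are not significantly worse (chi-square difference) and lower the
    AIC, the best is committed.  Stops when no admissible drop remains.
    """
    if mode == "auto":
        mode = choose_mode(data)
    spec = ModelSpec(mode=mode, moderated=frozenset("ace"), means="age")
    current = fit_model(data, spec, seed=seed, n_starts=n_starts)
    history = []
    step = 0
    while current.spec.moderated:
        trials = []
        for c in sorted(current.spec.moderated):
            step += 1
            trial_spec = replace(
                current.spec, moderated=current.spec.moderated - {c}
            )
            trial = fit_model(data, trial_spec, seed=seed + step, n_starts=n_starts)
            cmp = lrt(current, trial)
            trials.append((trial, cmp))
        admissible = [
            (t, cmp) for t, cmp in trials
            if cmp.p_value >= alpha and cmp.delta_aic < 0
        ]
        if not admissible:
            history.extend(cmp for _, cmp in trials)
            break
        admissible.sort(key=lambda tc: tc[0].aic)
        current, best_cmp = admissible[0]
        history.append(best_cmp)
    return history, current


def test_equality_over_time(
    data: ZygosityGroupData,
    fit: FitResult,
    components,
    seed: int = 0,
    n_starts: int = 5,
) -> ComparisonResult:
    """Constrain named components' factor variances equal over occasions.

    Refits the bivariate model with sigma_t1 = sigma_t2 for each component in
    ``components`` and compares by chi-square difference (df = number of new
    constraints).
    """
    components = frozenset(components)
    if not components:
        raise ValueError("empty constraint set")
    if fit.spec.design != "bivariate":
        raise ValueError("equality-over-time applies to bivariate fits")
    spec_c = replace(fit.spec, equal_over_time=fit.spec.equal_over_time | components)
    start = dict(fit.params)
    for c in components:
        if f"s{c}1" in start:
            start[f"s{c}"] = 0.5 * (start.pop(f"s{c}1") + start.pop(f"s{c}2"))
    constrained = fit_model(data, spec_c, seed=seed, n_starts=n_starts, start=start)
    return lrt(fit, constrained)


# --------------------------------------------------------------------------
# components, standardization, calibration
# --------------------------------------------------------------------------

def variance_components_at_age(fit, ages) -> pd.DataFrame:
    """Component-by-age grid A, C/D, E, V with percent shares.

    ``fit`` is a FitResult (or a (spec, params) tuple) from a univariate,
    possibly age-moderated, model.  Non-moderated components are constant
    across the grid.
    """
    if isinstance(fit, FitResult):
        spec, params = fit.spec, fit.params
    else:
        spec, params = fit
    rows = []
    for age in ages:
        comps = {}
        for c in _COMPONENTS:
            key = _component_key(spec, c)
            if c in spec.drop:
                comps[key] = 0.0
                continue
            x = params[c + "0"]
            if c in spec.moderated:
                x = x + params[c + "1"] * age
            comps[key] = float(x * x)
        v = sum(comps.values())
        row = {"age": age, **comps, "V": v}
        for key, val in comps.items():
            row[key + "_pct"] = standardize_percent(val, v)
        rows.append(row)
    return pd.DataFrame(rows)


def standardize(components: dict) -> dict:
    """Standardized shares: each component divided by the total variance V."""
    v = sum(components.values())
    if v <= 0:
        raise ValueError("total variance must be positive")
    return {k: val / v for k, val in components.items()}


def standardize_percent(component: float, v: float) -> int:
    """Integer percent share, rounding half away from zero (report parity)."""
    if v <= 0:
        raise ValueError("total variance must be positive")
    return int(math.floor(100.0 * component / v + 0.5))


def linear_path_from_endpoints(age_lo, comp_lo, age_hi, comp_hi):
    """Linear path x(age)=x0+x1*age through square roots of endpoint components.

    Used to calibrate a moderated path from two variance-component values at
    the ends of the age range (e.g. a published component grid).
    """
    if comp_lo < 0 or comp_hi < 0:
        raise ValueError("components must be non-negative")
    x_lo, x_hi = math.sqrt(comp_lo), math.sqrt(comp_hi)
    x1 = (x_hi - x_lo) / (age_hi - age_lo)
    x0 = x_lo - x1 * age_lo
    return x0, x1


# --------------------------------------------------------------------------
# profile confidence intervals
# --------------------------------------------------------------------------

def profile_ci(
    data: ZygosityGroupData,
    fit: FitResult,
    parameter: str,
    level: float = 0.90,
    n_starts: int = 1,
    max_expand: int = 40,
) -> dict:
    """Likelihood-based (profile) confidence interval for one parameter.

    The interval is the set of fixed values of ``parameter`` whose profiled
    -2LL (all other parameters re-optimized) lies within the chi-square(1)
    quantile of the minimum.  Path and factor-SD parameters are
    sign-indeterminate and are profiled on the non-negative half-line, so a
    boundary estimate of 0 yields an exact lower bound of 0; the interval is
    also returned on the squared (variance-component) scale for such
    parameters.  A bound that cannot be bracketed is flagged unbounded.
    """
    names = param_names(fit.spec)
    if parameter not in names:
        raise ValueError(f"unknown parameter {parameter!r} (free: {names})")
    q = stats.chi2.ppf(level, 1)
    free = [n for n in names if n != parameter]
    is_path = not parameter.startswith(("r", "mu", "b"))
    mle = abs(fit.params[parameter]) if is_path else fit.params[parameter]
    base = {n: fit.params[n] for n in free}
    bounds = _bounds(free)

    def profiled(value):
        def obj(vec):
            p = dict(zip(free, vec))
            p[parameter] = value
            return negloglik(data, fit.spec, p)

        x0 = np.array([base[n] for n in free])
        res = optimize.minimize(
            obj, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 1000, "ftol": 1e-12},
        )
        return float(res.fun)

    def deviance(value):
        return profiled(value) - fit.minus2ll - q

    scale = abs(mle) + 0.1 * math.sqrt(max(data.pooled_variance(), 1e-12)) + 1e-6
    out = {"parameter": parameter, "level": level, "unbounded": False}

    # upper bound
    hi = mle + 0.5 * scale
    for _ in range(max_expand):
        if deviance(hi) > 0:
            break
        hi = mle + 2.0 * (hi - mle)
    else:
        out["unbounded"] = True
    upper = (
        float(optimize.brentq(deviance, mle, hi, xtol=1e-5 * scale))
        if not out["unbounded"]
        else math.inf
    )

    # lower bound
    floor = 0.0 if is_path else -math.inf
    lo = mle - 0.5 * scale
    if is_path:
        lo = max(lo, 0.0)
    lower = None
    for _ in range(max_expand):
        if is_path and lo <= 0.0:
            if deviance(0.0) <= 0:
                lower = 0.0  # boundary: profile stays inside at 0
            break
        if deviance(lo) > 0:
            break
        lo = mle - 2.0 * (mle - lo)
    if lower is None:
        if is_path and lo <= 0.0:
            lower = float(optimize.brentq(deviance, 0.0, mle, xtol=1e-5 * scale)) \
                if deviance(0.0) > 0 else 0.0
        elif not is_path and not np.isfinite(lo):
            out["unbounded"] = True
            lower = -math.inf
        else:
            lower = float(optimize.brentq(deviance, lo, mle, xtol=1e-5 * scale))

    out["lower"], out["upper"] = float(lower), float(upper)
    if is_path:
        out["component_lower"] = float(lower) ** 2
        out["component_upper"] = float(upper) ** 2 if np.isfinite(upper) else math.inf
    return out


# --------------------------------------------------------------------------
# assumption checks (saturated vs constrained moments)
# --------------------------------------------------------------------------

def _saturated_m2ll(data: ZygosityGroupData) -> float:
    """Closed-form saturated -2LL: per-zygosity MVN at the sample moments."""
    total = 0.0
    for _, g in data.groups():
        if g.n == 0:
            continue
        p = g.cov.shape[0]
        sign, logdet = np.linalg.slogdet(g.cov)
        if sign <= 0:
            return _PENALTY
        total += g.n * (p * LOG2PI + logdet + p)
    return total


def _constrained_moments_m2ll(data: ZygosityGroupData, equal_means, equal_vars):
    """-2LL with means and/or variances constrained equal across twin order
    and zygosity; within-pair correlations stay free per zygosity."""
    # parameters: means (1 or 4), log-variances (1 or 4), atanh-corr (2)
    n_mean = 1 if equal_means else 4
    n_var = 1 if equal_vars else 4

    def unpack(vec):
        mus = vec[:n_mean]
        lvs = vec[n_mean:n_mean + n_var]
        rs = np.tanh(vec[n_mean + n_var:])
        if equal_means:
            means = {"MZ": np.full(2, mus[0]), "DZ": np.full(2, mus[0])}
        else:
            means = {"MZ": mus[:2], "DZ": mus[2:]}
        if equal_vars:
            vs = {"MZ": np.full(2, math.exp(lvs[0])), "DZ": np.full(2, math.exp(lvs[0]))}
        else:
            vs = {"MZ": np.exp(lvs[:2]), "DZ": np.exp(lvs[2:])}
        return means, vs, {"MZ": rs[0], "DZ": rs[1]}

    def obj(vec):
        means, vs, rs = unpack(vec)
        total = 0.0
        for zyg, g in data.groups():
            if g.n == 0:
                continue
            v = vs[zyg]
            w = rs[zyg] * math.sqrt(v[0] * v[1])
            sigma = np.array([[v[0], w], [w, v[1]]])
            total += _m2ll_suffstats(g, sigma, np.asarray(means[zyg], float))
        return total

    m0 = data.pooled_mean()
    v0 = max(data.pooled_variance(), 1e-12)
    x0 = np.concatenate(
        [
            np.full(n_mean, m0),
            np.full(n_var, math.log(v0)),
            np.zeros(2),
        ]
    )
    res = optimize.minimize(
        obj, x0, method="L-BFGS-B", options={"maxiter": 2000, "ftol": 1e-13}
    )
    return float(res.fun), n_mean + n_var + 2


def assumption_checks(data: ZygosityGroupData, alpha: float = 0.05):
    """Twin-modeling precondition tests: equal means/variances across co-twins
    and zygosity groups, each block tested against the saturated model.

    Returns ComparisonResults for the means block, the variances block, and
    the omnibus (both) constraint.  Univariate (pair-vector length 2) data.
    """
    if data.mz.cov.shape[0] != 2:
        raise ValueError("assumption checks implemented for univariate data")
    sat = _saturated_m2ll(data)
    n_sat = 10  # 4 means + 4 variances + 2 correlations
    out = []
    for label, eq_m, eq_v in (
        ("equal_means", True, False),
        ("equal_variances", False, True),
        ("equal_means_and_variances", True, True),
    ):
        m2ll, n_par = _constrained_moments_m2ll(data, eq_m, eq_v)
        df = n_sat - n_par
        delta = m2ll - sat
        out.append(
            ComparisonResult(
                full="saturated",
                reduced=label,
                delta_minus2ll=float(delta),
                delta_df=df,
                p_value=float(stats.chi2.sf(max(delta, 0.0), df)),
                delta_aic=float((m2ll + 2 * n_par) - (sat + 2 * n_sat)),
            )
        )
    return out
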