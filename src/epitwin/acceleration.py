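"""Epigenetic age -> acceleration scores by per-occasion covariate residualization.

An acceleration score is the residual of the clock value after regressing out
chronological age and technical/biological covariates within each measurement
occasion (cohorts pooled).  Positive residuals mean accelerated, negative
decelerated epigenetic aging.  Clock-specific covariate defaults:

=============  ====  ===  =======  =============
clock          age   sex  cell PC  smoking probe
=============  ====  ===  =======  =============
Horvath        yes   yes  yes      yes
PedBE          yes   yes  yes      yes
GrimAge        yes   yes  yes      no
DunedinPACE    no    yes  yes      yes
=============  ====  ===  =======  =============

DunedinPACE is a pace-of-aging measure (already a rate, not an accumulated
age), so it is not regressed on chronological age.  GrimAge embeds smoking
information in its training, so the smoking probe is not partialled out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)

__all__ = [
    "CovariateSpec",
    "CLOCK_DEFAULTS",
    "default_spec",
    "residualize",
    "median_absolute_error",
]


@dataclass(frozen=True)
class CovariateSpec:
    """Which covariates to partial out of a clock value, per occasion."""

    clock: str
    regress_on_chronological_age: bool = True
    include_sex: bool = True
    include_cell_pc: bool = True
    include_smoking_beta: bool = True

    @property
    def columns(self) -> list:
        cols = []
        if self.regress_on_chronological_age:
            cols.append("age")
        if self.include_sex:
            cols.append("sex")
        if self.include_cell_pc:
            cols.append("cell_pc")
        if self.include_smoking_beta:
            cols.append("smoking_beta")
        return cols

    def tag(self) -> str:
        return "+".join(self.columns) if self.columns else "intercept-only"


CLOCK_DEFAULTS = {
    "Horvath": CovariateSpec("Horvath"),
    "PedBE": CovariateSpec("PedBE"),
    "GrimAge": CovariateSpec("GrimAge", include_smoking_beta=False),
    "DunedinPACE": CovariateSpec(
        "DunedinPACE", regress_on_chronological_age=False
    ),
}


def default_spec(clock: str) -> CovariateSpec:
    """Default covariate set for a clock; unknown clocks get the full set."""
    return CLOCK_DEFAULTS.get(clock, CovariateSpec(clock))


def residualize(
    table: pd.DataFrame,
    spec: CovariateSpec,
    per_cohort: bool = False,
) -> pd.DataFrame:
    """OLS-residualize clock values on the spec's covariates within occasion.

    Cohorts are pooled within each measurement occasion by default (the
    residual mean is 0 per occasion, but per-cohort means may deviate);
    ``per_cohort=True`` residualizes within cohort x occasion instead.
    Rows with a missing value or covariate are dropped (complete-case within
    occasion), with counts logged.

    Returns an acceleration table with one row per surviving
    (pair, twin, occasion) and a ``covariate_set`` provenance column.
    """
    sub = table[table["clock"] == spec.clock] if "clock" in table else table
    if sub.empty:
        raise ValueError(f"no rows for clock {spec.clock!r}")
    for col in spec.columns:
        if col not in sub.columns:
            raise ValueError(f"missing covariate column: {col!r}")

    group_cols = ["occasion", "cohort"] if per_cohort else ["occasion"]
    out_frames = []
    for keys, grp in sub.groupby(group_cols):
        complete = grp.dropna(subset=["value"] + spec.columns)
        n_dropped = len(grp) - len(complete)
        if n_dropped:
            log.info(
                "residualize %s %s=%s: dropped %d incomplete of %d rows",
                spec.clock, group_cols, keys, n_dropped, len(grp),
            )
        p = len(spec.columns)
        if len(complete) < p + 2:
            raise ValueError(
                f"occasion group {keys}: {len(complete)} complete rows, "
                f"need at least {p + 2}"
            )
        X = sm.add_constant(complete[spec.columns].astype(float), has_constant="add")
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError(
                f"rank-deficient design in occasion group {keys} "
                f"(covariates: {spec.columns})"
            )
        fit = sm.OLS(complete["value"].astype(float), X).fit()
        res = complete[
            ["pair_id", "twin_index", "zygosity", "cohort", "occasion", "age"]
        ].copy()
        res["clock"] = spec.clock
        res["acceleration"] = fit.resid.to_numpy()
        res["covariate_set"] = spec.tag()
        out_frames.append(res)
    acc = pd.concat(out_frames, ignore_index=True)
    return acc.sort_values(
        ["pair_id", "occasion", "twin_index"], kind="mergesort"
    ).reset_index(drop=True)


def median_absolute_error(epi_age, chrono_age) -> float:
    """Median of |epigenetic age - chronological age| (clock calibration MAE)."""
    epi = np.asarray(epi_age, dtype=float)
    chrono = np.asarray(chrono_age, dtype=float)
    if epi.size == 0:
        raise ValueError("empty input")
    if epi.shape != chrono.shape:
        raise ValueError("epi_age and chrono_age must have equal length")
    return float(np.median(np.abs(epi - chrono)))
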