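"""Twin correlations, Falconer moment estimates, ACE/ADE choice, stability.

The MZ/DZ twin-correlation contrast is the information source of the classical
twin design: a larger MZ than DZ correlation signals genetic variance; an MZ
correlation exceeding twice the DZ correlation signals non-additive genetic
(dominance) variance, which motivates an ADE rather than an ACE decomposition.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "twin_correlation",
    "falconer",
    "classify_ace_ade",
    "rank_order_stability",
    "pair_wide",
]


def pair_wide(acc: pd.DataFrame, value_col: str = "acceleration") -> pd.DataFrame:
    """Pivot an acceleration table to one row per (pair, occasion) with
    twin-1/twin-2 columns; incomplete pairs are dropped."""
    wide = acc.pivot_table(
        index=["pair_id", "zygosity", "cohort", "occasion"],
        columns="twin_index",
        values=value_col,
    )
    wide = wide.dropna(subset=[1, 2]).reset_index()
    return wide.rename(columns={1: "twin1", 2: "twin2"})


def _corr(x, y, method: str):
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def twin_correlation(
    acc: pd.DataFrame,
    stratum=None,
    method: str = "spearman",
    double_entry: bool = False,
) -> pd.DataFrame:
    """Within-pair twin correlations per zygosity group.

    Parameters
    ----------
    acc
        Acceleration table (long format).
    stratum
        Extra grouping columns, e.g. ``["cohort", "occasion"]``; None pools
        everything into a single cross-cohort correlation per zygosity.
    method
        'spearman' (rank, the reporting default) or 'pearson' (moment
        diagnostics).
    double_entry
        If True, each pair enters twice with twins swapped (robustness check
        for arbitrary within-pair ordering).

    Strata with fewer than 2 complete pairs are skipped with a warning.
    """
    wide = pair_wide(acc)
    group_cols = ["zygosity"] + (list(stratum) if stratum else [])
    rows = []
    for keys, grp in wide.groupby(group_cols):
        if not isinstance(keys, tuple):
            keys = (keys,)
        if len(grp) < 2:
            log.warning("stratum %s: %d pairs, skipped", keys, len(grp))
            continue
        x, y = grp["twin1"].to_numpy(), grp["twin2"].to_numpy()
        if double_entry:
            x, y = np.concatenate([x, y]), np.concatenate([y, x])
        r, p = _corr(x, y, method)
        rows.append(dict(zip(group_cols, keys), method=method, r=r, p=p, n_pairs=len(grp)))
    return pd.DataFrame(rows)


def falconer(r_mz: float, r_dz: float):
    """Falconer moment estimates from twin correlations.

    h2 = 2(rMZ - rDZ), c2 = 2 rDZ - rMZ, e2 = 1 - rMZ.  Values are returned
    unclipped, with ``in_bounds=False`` when any falls outside [0, 1] (a
    negative c2 is the moment-level signal of non-additive genetic variance).
    """
    if abs(r_mz) > 1 or abs(r_dz) > 1:
        raise ValueError("twin correlations must lie in [-1, 1]")
    h2 = 2.0 * (r_mz - r_dz)
    c2 = 2.0 * r_dz - r_mz
    e2 = 1.0 - r_mz
    in_bounds = all(0.0 <= v <= 1.0 for v in (h2, c2, e2))
    return h2, c2, e2, in_bounds


def classify_ace_ade(r_mz: float, r_dz: float) -> str:
    """ADE if rMZ > 2*rDZ (dominance signal), else ACE; ties go to ACE."""
    if abs(r_mz) > 1 or abs(r_dz) > 1:
        raise ValueError("twin correlations must lie in [-1, 1]")
    return "ADE" if r_mz > 2.0 * r_dz else "ACE"


def rank_order_stability(
    acc: pd.DataFrame, method: str = "spearman"
) -> pd.DataFrame:
    """Cross-occasion stability correlations per zygosity.

    ``within_individual``: occasion-1 x occasion-2 correlation of the same
    twin's scores.  ``cross_twin``: twin 1 at occasion 1 x co-twin at occasion
    2 (and vice versa, pooled) — larger values for MZ than DZ pairs indicate
    genetically driven stability.
    """
    wide = acc.pivot_table(
        index=["pair_id", "zygosity", "twin_index"],
        columns="occasion",
        values="acceleration",
    )
    if not {1, 2}.issubset(wide.columns):
        raise ValueError("both occasions required for rank-order stability")
    wide = wide.dropna(subset=[1, 2]).reset_index()
    rows = []
    for zyg, grp in wide.groupby("zygosity"):
        r_w, _ = _corr(grp[1], grp[2], method)
        t1 = grp[grp.twin_index == 1].set_index("pair_id")
        t2 = grp[grp.twin_index == 2].set_index("pair_id")
        common = t1.index.intersection(t2.index)
        x = np.concatenate([t1.loc[common, 1], t2.loc[common, 1]])
        y = np.concatenate([t2.loc[common, 2], t1.loc[common, 2]])
        r_x, _ = _corr(x, y, method)
        rows.append(
            dict(
                zygosity=zyg,
                within_individual=r_w,
                cross_twin=r_x,
                n_individuals=len(grp),
                n_pairs=len(common),
            )
        )
    return pd.DataFrame(rows)
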