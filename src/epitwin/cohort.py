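"""Synthetic twin-cohort generator with known genetic/environmental structure.

Simulates acceleration-scale phenotypes for same-sex twin pairs measured at two
occasions, under the classical biometrical model: additive-genetic (A), shared-
environment (C) or non-additive-genetic dominance (D), and unique-environment (E)
latent factors, with optional linear age moderation of the path coefficients and
cross-occasion factor correlations (rA, rC/rD, rE).

Within a pair, A factor scores correlate 1 (MZ) / 0.5 (DZ), D scores 1 / 0.25,
C is shared exactly, and E is independent across twins.  Across the two
measurement occasions, same-kind factor scores follow a bivariate normal with
the requested cross-time correlation, so marginal variances are exactly 1 by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "CohortDesign",
    "TrueParams",
    "TWINLIFE_DESIGN",
    "generate_cohort",
    "inject_missingness",
    "write_table",
    "read_table",
]

#: Column order of the long-format twin table.
TABLE_COLUMNS = [
    "pair_id",
    "twin_index",
    "zygosity",
    "cohort",
    "occasion",
    "age",
    "sex",
    "clock",
    "value",
    "cell_pc",
    "smoking_beta",
]


@dataclass(frozen=True)
class CohortDesign:
    """Study design: birth cohorts, pair counts, and the occasion spacing.

    Each cohort is a tuple ``(label, mean_age_occ1, age_sd, n_mz, n_dz)`` with
    ages in decimal years.  Both twins of a pair share the same age at each
    occasion; the second occasion is ``occasion_gap`` years after the first.
    """

    cohorts: tuple = ()
    occasion_gap: float = 2.5
    same_sex: bool = True

    def __post_init__(self):
        if self.occasion_gap <= 0:
            raise ValueError("occasion_gap must be > 0")
        for label, mean_age, sd, n_mz, n_dz in self.cohorts:
            if sd < 0:
                raise ValueError(f"cohort {label!r}: age SD must be >= 0")
            if n_mz < 0 or n_dz < 0:
                raise ValueError(f"cohort {label!r}: pair counts must be >= 0")

    @property
    def n_pairs(self) -> int:
        return sum(c[3] + c[4] for c in self.cohorts)


#: Four same-sex twin birth cohorts measured twice ~2.5 years apart:
#: early adolescents, late adolescents, emerging adults, young adults.
#: MZ/DZ pair splits 82/81, 87/99, 42/34, 52/11 (263 MZ + 225 DZ = 488 pairs).
TWINLIFE_DESIGN = CohortDesign(
    cohorts=(
        ("early_adolescence", 9.5, 0.33, 82, 81),
        ("late_adolescence", 15.5, 0.31, 87, 99),
        ("emerging_adulthood", 21.5, 0.37, 42, 34),
        ("young_adulthood", 27.5, 0.70, 52, 11),
    ),
    occasion_gap=2.5,
)


@dataclass
class TrueParams:
    """Generating parameters of the biometrical model.

    Paths are in phenotype SD units; ``a1/c1/e1`` are linear moderation slopes
    per year, so the path for component x at a given age is ``x0 + x1 * age``.
    In ADE mode the ``c`` slots hold the dominance path d (DZ within-pair factor
    correlation 0.25 instead of the shared-C correlation of 1).
    ``r_a/r_c/r_e`` are cross-occasion correlations of same-kind factor scores.
    """

    a0: float = 0.0
    c0: float = 0.0
    e0: float = 1.0
    a1: float = 0.0
    c1: float = 0.0
    e1: float = 0.0
    r_a: float = 1.0
    r_c: float = 1.0
    r_e: float = 0.0
    mu0: float = 0.0
    beta_age: float = 0.0
    beta_age2: float = 0.0
    beta_sex: float = 0.0
    beta_cell_pc: float = 0.0
    beta_smoking: float = 0.0
    mode: str = "ACE"

    def __post_init__(self):
        if self.mode not in ("ACE", "ADE"):
            raise ValueError(f"mode must be 'ACE' or 'ADE', got {self.mode!r}")
        for name in ("r_a", "r_c", "r_e"):
            r = getattr(self, name)
            if abs(r) > 1:
                raise ValueError(f"|{name}| must be <= 1, got {r}")

    def path(self, which: str, age) -> np.ndarray:
        """Evaluate the path coefficient x0 + x1*age for component 'a'/'c'/'e'."""
        x0 = getattr(self, which + "0")
        x1 = getattr(self, which + "1")
        return x0 + x1 * np.asarray(age, dtype=float)


def _cross_time_pair(rng: np.random.Generator, r: float, n: int) -> np.ndarray:
    """n draws of a standard-normal 2-vector with cross-time correlation r."""
    z = rng.standard_normal((n, 2))
    out = np.empty_like(z)
    out[:, 0] = z[:, 0]
    out[:, 1] = r * z[:, 0] + np.sqrt(max(0.0, 1.0 - r * r)) * z[:, 1]
    return out


def generate_cohort(
    design: CohortDesign,
    params: TrueParams,
    seed: int,
    clock: str = "synthetic",
    emit_epigenetic_age: bool = False,
) -> pd.DataFrame:
    """Simulate a long-format twin table under the given design and parameters.

    Parameters
    ----------
    design, params
        Study layout and generating biometrical parameters.
    seed
        Fixes all randomness; same seed gives a byte-identical table.
    clock
        Label written to the ``clock`` column.
    emit_epigenetic_age
        If True, the ``value`` column holds chronological age plus the
        simulated acceleration score (a raw "epigenetic age"), so the
        residualization stage can be exercised end to end.  Default emits the
        acceleration-scale score itself.

    Returns
    -------
    DataFrame with one row per (pair, twin, occasion), columns TABLE_COLUMNS.
    """
    if design.n_pairs == 0:
        raise ValueError("design has zero total pairs")
    rng = np.random.default_rng(seed)
    frames = []
    pair_counter = 0
    for label, mean_age, sd, n_mz, n_dz in design.cohorts:
        for zyg, n_pairs in (("MZ", n_mz), ("DZ", n_dz)):
            if n_pairs == 0:
                continue
            # ages: Normal(mean, sd) truncated at +/-3 SD, shared by co-twins
            age1 = mean_age + sd * np.clip(rng.standard_normal(n_pairs), -3, 3)
            ages = np.column_stack([age1, age1 + design.occasion_gap])  # (n, 2)

            # genetic factors: twin score = shared + unique parts with the
            # classical weights, so DZ within-pair correlation is exactly 0.5
            # (additive) and 0.25 (dominance) by construction
            def genetic_factor(r_time, k_dz):
                sh = _cross_time_pair(rng, r_time, n_pairs)
                u = [_cross_time_pair(rng, r_time, n_pairs) for _ in range(2)]
                if zyg == "MZ":
                    return [sh, sh]
                w_sh, w_u = np.sqrt(k_dz), np.sqrt(1.0 - k_dz)
                return [w_sh * sh + w_u * u[0], w_sh * sh + w_u * u[1]]

            a_tw = genetic_factor(params.r_a, 0.5)
            if params.mode == "ACE":
                c_sh = _cross_time_pair(rng, params.r_c, n_pairs)
                c_tw = [c_sh, c_sh]
            else:  # dominance in the c slot
                c_tw = genetic_factor(params.r_c, 0.25)
            e_tw = [_cross_time_pair(rng, params.r_e, n_pairs) for _ in range(2)]

            sex = rng.integers(0, 2, n_pairs)  # shared within pair (same-sex)
            a_path = params.path("a", ages)
            c_path = params.path("c", ages)
            e_path = params.path("e", ages)
            mean = (
                params.mu0
                + params.beta_age * ages
                + params.beta_age2 * ages**2
                + params.beta_sex * sex[:, None]
            )
            pair_ids = np.arange(pair_counter, pair_counter + n_pairs)
            pair_counter += n_pairs
            for t_idx, twin in enumerate((1, 2)):
                cell_pc = rng.standard_normal((n_pairs, 2))
                # bounded smoking-probe beta in [0, 1]
                smoking = rng.beta(8.0, 2.0, (n_pairs, 2))
                value = (
                    mean
                    + params.beta_cell_pc * cell_pc
                    + params.beta_smoking * smoking
                    + a_path * a_tw[t_idx]
                    + c_path * c_tw[t_idx]
                    + e_path * e_tw[t_idx]
                )
                if emit_epigenetic_age:
                    value = value + ages
                for occ in (1, 2):
                    frames.append(
                        pd.DataFrame(
                            {
                                "pair_id": pair_ids,
                                "twin_index": twin,
                                "zygosity": zyg,
                                "cohort": label,
                                "occasion": occ,
                                "age": ages[:, occ - 1],
                                "sex": sex,
                                "clock": clock,
                                "value": value[:, occ - 1],
                                "cell_pc": cell_pc[:, occ - 1],
                                "smoking_beta": smoking[:, occ - 1],
                            }
                        )
                    )
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(
        ["pair_id", "occasion", "twin_index"], kind="mergesort"
    ).reset_index(drop=True)
    return table[TABLE_COLUMNS]


def inject_missingness(
    table: pd.DataFrame, fraction: float, seed: int
) -> pd.DataFrame:
    """Mask a random fraction of observations (value -> NaN), keys preserved.

    The number of masked rows is ``round(fraction * n_rows)`` (banker's
    rounding, numpy convention).  ``fraction`` must lie in [0, 1).
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    out = table.copy()
    if fraction == 0:
        return out
    rng = np.random.default_rng(seed)
    n_mask = int(np.round(fraction * len(out)))
    idx = rng.choice(len(out), size=n_mask, replace=False)
    out.iloc[idx, out.columns.get_loc("value")] = np.nan
    return out


def write_table(table: pd.DataFrame, path) -> None:
    """Write a twin table as tab-separated text with the fixed header."""
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"twin table is missing columns: {missing}")
    return table


def params_from_dict(d: dict) -> TrueParams:
    return TrueParams(**d)


def design_from_dict(d: dict) -> CohortDesign:
    cohorts = tuple(tuple(c) for c in d.get("cohorts", ()))
    return CohortDesign(
        cohorts=cohorts,
        occasion_gap=d.get("occasion_gap", 2.5),
        same_sex=d.get("same_sex", True),
    )


def design_to_dict(design: CohortDesign) -> dict:
    d = asdict(design)
    d["cohorts"] = [list(c) for c in design.cohorts]
    return d
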