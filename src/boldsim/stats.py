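"""Variance partitioning for sweep outputs.

Three analyses quantify how detectable the boldness hierarchy is:

* a one-way ANOVA of a per-run behavioural measure on the swept parameter
  (treated as a categorical factor), summarising how much of the replicate
  scatter the parameter explains;
* a mixed repeated-measures ANOVA of within-run min-max rescaled event
  times, with the swept parameter as the between-run factor and individual
  identity as the within-run factor (runs are the repeated-measures unit):
  the parameter F is tested against the runs-within-levels stratum and the
  identity F against the within-run residual, with the parameter x identity
  interaction in the model.  A large identity F means individuals are easy
  to tell apart from their timing alone;
* a per-identity ordering-difference metric in [-1, 1] between a social
  rule and the non-social baseline on seed-paired replicates (-1: fastest
  socially but slowest non-socially).

F ratios follow an explicit degenerate-table convention: a zero
numerator sum of squares gives F = 0; a positive numerator over a zero
denominator gives F = +inf (``F_CAP`` is provided as a CSV-safe sentinel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Sentinel used in CSV output in place of an infinite F ratio.
F_CAP = 1e12

RESCALABLE_MEASURES = ("travel_time", "leave_time", "arrival_time")


class UnbalancedTableError(ValueError):
    """Raised when a repeated-measures table is not fully balanced."""


@dataclass(frozen=True)
class AnovaResult:
    """F ratios and degrees of freedom from one variance decomposition."""

    measure: str
    parameter_F: float
    df_parameter: tuple[int, int]
    individual_F: float | None = None
    df_individual: tuple[int, int] | None = None
    interaction_F: float | None = None
    df_interaction: tuple[int, int] | None = None


def _f_ratio(ss_num: float, df_num: int, ss_den: float, df_den: int) -> float:
    """MS ratio with the documented zero conventions."""
    if df_num <= 0 or df_den <= 0:
        raise ValueError("non-positive degrees of freedom")
    ms_num = ss_num / df_num
    if ms_num == 0.0:
        return 0.0
    ms_den = ss_den / df_den
    if ms_den == 0.0:
        return np.inf
    return ms_num / ms_den


def rescale_within_group(raw) -> np.ndarray:
    """Min-max rescale one run's event times to [0, 1].

    All-equal input maps to all zeros (no within-run information).
    """
    x = np.asarray(raw, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def add_rescaled(table: pd.DataFrame,
                 measures: tuple = RESCALABLE_MEASURES,
                 by: tuple = ("rule", "value", "replicate")) -> pd.DataFrame:
    """Append ``rescaled_<measure>`` columns, rescaling within each run."""
    out = table.copy()
    groups = out.groupby(list(by), sort=False)
    for m in measures:
        out[f"rescaled_{m}"] = groups[m].transform(
            lambda x: rescale_within_group(x.to_numpy()))
    return out


def oneway_parameter_F(table: pd.DataFrame, response: str,
                       factor: str = "value") -> AnovaResult:
    """Classical one-way F of a per-run measure on the swept parameter.

    F = MS_between / MS_within over the factor's levels; each level needs
    at least two runs.
    """
    levels = [np.asarray(g, dtype=float)
              for _, g in table.groupby(factor, sort=True)[response]]
    if len(levels) < 2:
        raise ValueError(f"need >= 2 levels of {factor!r}, got {len(levels)}")
    if any(len(g) < 2 for g in levels):
        raise ValueError("every factor level needs >= 2 runs")
    grand = np.concatenate(levels).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in levels)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in levels)
    df_between = len(levels) - 1
    df_within = sum(len(g) for g in levels) - len(levels)
    return AnovaResult(
        measure=response,
        parameter_F=_f_ratio(ss_between, df_between, ss_within, df_within),
        df_parameter=(df_between, df_within),
    )


def _check_balance(table: pd.DataFrame, level_col: str, subject_col: str,
                   id_col: str) -> tuple[int, int, int]:
    """Return (a, r, n_id) for a balanced design or raise."""
    counts = table.groupby([level_col, subject_col], sort=False)[id_col].agg(
        ["count", "nunique"])
    if (counts["count"] != counts["nunique"]).any():
        raise UnbalancedTableError("duplicate identity within a run")
    n_id = table[id_col].nunique()
    if (counts["count"] != n_id).any():
        raise UnbalancedTableError("every run must contribute all identities")
    per_level = table.groupby(level_col, sort=False)[subject_col].nunique()
    if per_level.nunique() != 1:
        raise UnbalancedTableError("every level needs the same replicate count")
    return len(per_level), int(per_level.iloc[0]), n_id


def repeated_measures_F(table: pd.DataFrame, response: str,
                        level_col: str = "value",
                        subject_col: str = "replicate",
                        id_col: str = "identity") -> AnovaResult:
    """Mixed repeated-measures ANOVA on rescaled per-identity event times.

    The table must be balanced: ``a`` levels x ``r`` runs per level x
    ``n_id`` identities per run.  Strata:

    * between runs — SS_parameter (df a-1) over SS_runs-within-levels
      (df a(r-1));
    * within runs — SS_identity (df n_id-1) and SS_interaction
      (df (a-1)(n_id-1)) over the residual (df a(r-1)(n_id-1)).
    """
    a, r, n_id = _check_balance(table, level_col, subject_col, id_col)
    if a < 2 or r < 2 or n_id < 2:
        raise UnbalancedTableError(
            f"need >= 2 levels, runs per level and identities; "
            f"got a={a}, r={r}, n_id={n_id}")
    y = table[response].astype(float)
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()

    run_means = table.groupby([level_col, subject_col], sort=False)[response].mean()
    ss_between_runs = n_id * ((run_means - grand) ** 2).sum()
    level_means = table.groupby(level_col, sort=False)[response].mean()
    ss_parameter = n_id * r * ((level_means - grand) ** 2).sum()
    ss_runs_within = ss_between_runs - ss_parameter

    id_means = table.groupby(id_col, sort=False)[response].mean()
    ss_identity = a * r * ((id_means - grand) ** 2).sum()
    cell = table.groupby([level_col, id_col], sort=False)[response].mean()
    lev_of = cell.index.get_level_values(0)
    id_of = cell.index.get_level_values(1)
    ss_cells = r * ((cell - level_means.loc[lev_of].to_numpy()
                     - id_means.loc[id_of].to_numpy() + grand) ** 2).sum()
    ss_within_runs = ss_total - ss_between_runs
    ss_residual = ss_within_runs - ss_identity - ss_cells
    ss_residual = max(ss_residual, 0.0)  # guard tiny negative round-off

    df_param = (a - 1, a * (r - 1))
    df_id = (n_id - 1, a * (r - 1) * (n_id - 1))
    df_inter = ((a - 1) * (n_id - 1), a * (r - 1) * (n_id - 1))
    return AnovaResult(
        measure=response,
        parameter_F=_f_ratio(ss_parameter, df_param[0],
                             ss_runs_within, df_param[1]),
        df_parameter=df_param,
        individual_F=_f_ratio(ss_identity, df_id[0], ss_residual, df_id[1]),
        df_individual=df_id,
        interaction_F=_f_ratio(ss_cells, df_inter[0], ss_residual, df_inter[1]),
        df_interaction=df_inter,
    )


def social_nonsocial_difference(social: pd.DataFrame, nonsocial: pd.DataFrame,
                                response: str,
                                keys: tuple = ("value", "replicate", "identity")
                                ) -> pd.DataFrame:
    """Per-identity difference of rescaled times, social minus non-social.

    Inputs must be seed-paired replicates of the same cells; the result has
    one ``difference`` value in [-1, 1] per (cell, replicate, identity).
    """
    left = social[list(keys) + [response]]
    right = nonsocial[list(keys) + [response]]
    if len(left) != len(right):
        raise ValueError(
            f"unpaired inputs: {len(left)} social vs {len(right)} non-social rows")
    merged = left.merge(right, on=list(keys), suffixes=("_social", "_nonsocial"),
                        validate="one_to_one")
    if len(merged) != len(left):
        raise ValueError("unpaired inputs: cells do not match one-to-one")
    merged["difference"] = (merged[f"{response}_social"]
                            - merged[f"{response}_nonsocial"])
    return merged[list(keys) + ["difference"]]


def identity_difference_medians(diff: pd.DataFrame) -> pd.Series:
    """Median ordering-difference per identity (the sign-structure summary)."""
    return diff.groupby("identity", sort=True)["difference"].median()


def anova_table(results: list[AnovaResult], **labels) -> pd.DataFrame:
    """Flatten AnovaResults to a tidy frame, capping infinite F at ``F_CAP``."""
    rows = []
    for res in results:
        row = dict(labels)
        row["measure"] = res.measure
        for name in ("parameter_F", "individual_F", "interaction_F"):
            val = getattr(res, name)
            if val is not None:
                row[name] = min(val, F_CAP)
        rows.append(row)
    return pd.DataFrame(rows)
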