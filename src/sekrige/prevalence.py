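"""Descriptive summaries and deficiency-prevalence tables.

Reproduces the summary products of a national plasma Se survey from any
survey table: per-group n / median / mean / SD / min / max on the natural
ng/mL scale, prevalence (%) below each selenoprotein threshold by stratum,
and near/far stratification by proximity to vertisol soils and major
water bodies.

Counting convention: a record is deficient when its concentration is
*strictly* below the threshold ("< T"); values exactly at T are not.
Proportions are unweighted; if a ``survey_weight`` column is present,
weighted percentages are emitted alongside the unweighted ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceedance import ThresholdSet

__all__ = [
    "summarize_groups",
    "prevalence_below",
    "stratify_by_proximity",
    "render_table",
]


def summarize_groups(table: pd.DataFrame, group_keys) -> pd.DataFrame:
    """Per-stratum n, median, mean, SD (n-1 divisor), min, max of plasma Se.

    ``group_keys`` is a column name or list of column names to stratify by;
    a pooled "All" row is appended.  Single-record strata report SD as NaN.
    """
    if isinstance(group_keys, str):
        group_keys = [group_keys]
    for k in group_keys:
        if k not in table.columns:
            raise KeyError(f"unknown group key {k!r}")
    if len(table) == 0:
        raise ValueError("empty survey table")

    def _stats(s: pd.Series) -> pd.Series:
        return pd.Series(
            {
                "n": len(s),
                "median": s.median(),
                "mean": s.mean(),
                "sd": s.std(ddof=1) if len(s) > 1 else np.nan,
                "min": s.min(),
                "max": s.max(),
            }
        )

    out = (
        table.groupby(group_keys, sort=True)["plasma_se"]
        .apply(_stats)
        .unstack()
        .reset_index()
    )
    pooled = _stats(table["plasma_se"])
    pooled_row = {k: "All" for k in group_keys} | pooled.to_dict()
    out = pd.concat([out, pd.DataFrame([pooled_row])], ignore_index=True)
    out["n"] = out["n"].astype(int)
    return out


def prevalence_below(
    table: pd.DataFrame,
    thresholds: ThresholdSet | None = None,
    strata=None,
) -> pd.DataFrame:
    """Percentage of records strictly below each threshold, per stratum.

    Returns one row per stratum (plus a pooled "All" row) with columns
    ``pct_below_<name>``; empty strata yield n = 0 with missing
    percentages.  With a ``survey_weight`` column present,
    ``wpct_below_<name>`` columns carry weight-adjusted percentages.
    """
    if thresholds is None:
        thresholds = ThresholdSet()
    if strata is None:
        groups = [("All", table)]
    else:
        if isinstance(strata, str):
            strata = [strata]
        for k in strata:
            if k not in table.columns:
                raise KeyError(f"unknown stratum key {k!r}")
        groups = [
            (label if isinstance(label, str) else "/".join(map(str, np.atleast_1d(label))), g)
            for label, g in table.groupby(strata, sort=True)
        ]
        groups.append(("All", table))

    weighted = "survey_weight" in table.columns
    rows = []
    for label, g in groups:
        row: dict = {"stratum": label, "n": len(g)}
        z = g["plasma_se"].to_numpy(dtype=float)
        for name, t in thresholds.items():
            row[f"pct_below_{name}"] = (
                100.0 * np.mean(z < t) if len(g) else np.nan
            )
        if weighted:
            w = g["survey_weight"].to_numpy(dtype=float)
            for name, t in thresholds.items():
                row[f"wpct_below_{name}"] = (
                    100.0 * float(w[z < t].sum() / w.sum()) if len(g) else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)


def stratify_by_proximity(
    table: pd.DataFrame,
    vertisol_cutoff: float = 10.0,
    water_cutoff: float = 30.0,
) -> pd.DataFrame:
    """Summaries of the near vs far proximity groups.

    "Near" means within ``vertisol_cutoff`` km of a vertisol AND within
    ``water_cutoff`` km of a lake/river; everyone else is "far".  Requires
    the distance covariates from ``attach_proximity_covariates``.
    """
    for col in ("dist_vertisol", "dist_water"):
        if col not in table.columns:
            raise KeyError(
                f"missing {col!r}: run attach_proximity_covariates first"
            )
    near = (table["dist_vertisol"] <= vertisol_cutoff) & (
        table["dist_water"] <= water_cutoff
    )
    rows = []
    for label, g in (("near", table[near]), ("far", table[~near])):
        if len(g):
            s = g["plasma_se"]
            rows.append(
                {
                    "group": label,
                    "n": len(g),
                    "median": s.median(),
                    "mean": s.mean(),
                    "sd": s.std(ddof=1) if len(g) > 1 else np.nan,
                    "min": s.min(),
                    "max": s.max(),
                }
            )
        else:
            rows.append(
                {
                    "group": label,
                    "n": 0,
                    "median": np.nan,
                    "mean": np.nan,
                    "sd": np.nan,
                    "min": np.nan,
                    "max": np.nan,
                }
            )
    return pd.DataFrame(rows)


def render_table(df: pd.DataFrame, floatfmt: str = "{:.1f}") -> str:
    """Aligned plain-text rendering of a summary/prevalence table."""
    show = df.copy()
    for c in show.columns:
        if show[c].dtype.kind == "f":
            show[c] = show[c].map(
                lambda v: "-" if pd.isna(v) else floatfmt.format(v)
            )
    return show.to_string(index=False)
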