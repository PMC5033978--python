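"""Block-level descriptive summaries of a cohort trial table.

These feed figure-style overviews and export tidy long-format tables for
external repeated-measures statistics: per-block means of directional error
(signed and absolute), movement time and clamp force, first/last six-trial
bins, the entry three-trial bin, within-block success probability, and
within-block variances (the exploratory-behavior measure).

Failed trials are excluded from all means and success counts.  Interspersed
clamp trials inside null or field blocks are excluded from that block's
directional-error summaries (the channel straightens them) but provide the
block's force readout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class SummaryError(ValueError):
    pass


def block_bins(values, bin_size: int = 6, which: str = "first") -> float:
    """Mean of the first or last ``bin_size`` trials of a block."""
    values = np.asarray(values, dtype=float)
    if values.size < bin_size:
        raise SummaryError(
            f"block has {values.size} trials, need at least {bin_size}")
    if which == "first":
        chunk = values[:bin_size]
    elif which == "last":
        chunk = values[-bin_size:]
    else:
        raise SummaryError(f"which must be 'first' or 'last', got {which!r}")
    return float(chunk.mean())


def success_probability(block_records: pd.DataFrame) -> float:
    """Fraction of non-failed trials inside a block that were on time."""
    ok = block_records[~block_records["failure_flag"]]
    if len(ok) == 0:
        raise SummaryError("no non-failed trials in block")
    return float(ok["success"].mean())


def exploratory_variance(values, ddof: int = 1) -> float:
    """Unbiased within-block sample variance of a metric."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise SummaryError("need at least 2 trials for a variance")
    return float(values.var(ddof=ddof))


def _bin_or_nan(values, bin_size, which):
    values = np.asarray(values, dtype=float)
    return block_bins(values, bin_size, which) if values.size >= bin_size else np.nan


def block_summaries(records: pd.DataFrame, bin_size: int = 6,
                    entry_bin: int = 3) -> pd.DataFrame:
    """Per (group, participant, block) summary row.

    Directional-error statistics use non-channel trials of the block;
    force statistics use the channel trials (all of them in assessment
    blocks, the interspersed ones in null/field blocks).
    """
    rows = []
    ok = records[~records["failure_flag"]]
    for (group, participant, block), sub in ok.groupby(
            ["group", "participant", "block_label"], sort=False):
        sub = sub.sort_values("within_block_index")
        kinematic = sub[~sub["phase"].isin(["EC", "IEC"])]
        channel = sub[sub["phase"].isin(["EC", "IEC"])]
        de = kinematic["directional_error_deg"].to_numpy(dtype=float)
        fpv = channel["force_at_pv"].to_numpy(dtype=float)
        mt = sub["movement_time_ms"].to_numpy(dtype=float)
        rows.append({
            "group": group, "participant": participant, "block_label": block,
            "n_trials": len(sub),
            "mean_directional_error": de.mean() if de.size else np.nan,
            "mean_abs_directional_error": np.abs(de).mean() if de.size else np.nan,
            "mean_movement_time": mt.mean() if mt.size else np.nan,
            "mean_force_at_pv": fpv.mean() if fpv.size else np.nan,
            "first_bin_force": _bin_or_nan(fpv, bin_size, "first"),
            "last_bin_force": _bin_or_nan(fpv, bin_size, "last"),
            "first3_force": _bin_or_nan(fpv, entry_bin, "first"),
            "first_bin_de": _bin_or_nan(de, bin_size, "first"),
            "last_bin_de": _bin_or_nan(de, bin_size, "last"),
            "p_success": success_probability(sub),
            "var_directional_error": (exploratory_variance(de)
                                      if de.size >= 2 else np.nan),
            "var_force_at_pv": (exploratory_variance(fpv)
                                if fpv.size >= 2 else np.nan),
        })
    return pd.DataFrame(rows)


def group_block_summaries(block_table: pd.DataFrame) -> pd.DataFrame:
    """Average the per-participant block summaries within each group."""
    value_cols = [c for c in block_table.columns
                  if c not in ("group", "participant", "block_label", "n_trials")]
    return (block_table
            .groupby(["group", "block_label"], sort=False)[value_cols]
            .mean()
            .reset_index())


def tidy_long(block_table: pd.DataFrame) -> pd.DataFrame:
    """(group, participant, block_label, measure, value) long format for ANOVA software."""
    value_cols = [c for c in block_table.columns
                  if c not in ("group", "participant", "block_label")]
    return block_table.melt(
        id_vars=["group", "participant", "block_label"],
        value_vars=value_cols, var_name="measure", value_name="value",
    )
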