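"""Per-neuron calcium-event aggregation and drug-response grouping.

Works on tidy event tables produced by :mod:`fibsinet.fibsi`: a
low-amplitude noise cutoff relative to each cell's largest fluctuation,
per-cell summary metrics (to control for differing recording times),
silent/active classification, pooled normalized-amplitude histograms,
and paired pre/post drug comparisons including fold-change grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fibsi import Event

__all__ = [
    "CellSummary",
    "FoldChangeGroup",
    "apply_amplitude_cutoff",
    "summarize_cell",
    "summarize_cells",
    "classify_silent",
    "normalized_amplitude_histogram",
    "fold_change_grouping",
    "pre_post_drug_compare",
    "DEFAULT_SILENT_THRESHOLD_AU",
    "DEFAULT_CUTOFF_FRACTION",
]

# Absolute mean-amplitude threshold (AU) separating silent cells (~1-2 AU,
# noise-scale fluctuations) from active ones (tens of AU). Explicit
# configuration, reported with every run.
DEFAULT_SILENT_THRESHOLD_AU = 5.0
DEFAULT_CUTOFF_FRACTION = 0.10


@dataclass
class CellSummary:
    """Per-neuron means of event metrics plus event frequency."""

    cell_id: str
    condition: str
    n_events: int
    mean_amplitude: float | None
    mean_auc: float | None
    mean_duration: float | None
    mean_peak_offset: float | None
    frequency: float  # events/s
    is_silent: bool | None = None


@dataclass
class FoldChangeGroup:
    """Sign-of-fold-change grouping of one cell's paired recordings."""

    cell_id: str
    pre_mean: float
    post_mean: float
    fold_change: float
    group: str  # "increase" | "decrease"


def _as_frame(events) -> pd.DataFrame:
    if isinstance(events, pd.DataFrame):
        return events
    from .fibsi import events_to_frame

    return events_to_frame(list(events))


def apply_amplitude_cutoff(events, fraction: float = DEFAULT_CUTOFF_FRACTION) -> pd.DataFrame:
    """Drop events below ``fraction`` of the cell's maximal amplitude.

    Mirrors the noise-control step of omitting fluctuations smaller than
    10% of each neuron's largest fluctuation; the boundary is inclusive
    (an event exactly at the cutoff is kept). Expects one cell's events.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    df = _as_frame(events)
    if df.empty:
        return df
    if df["cell_id"].nunique() > 1:
        raise ValueError("apply_amplitude_cutoff expects events from one cell")
    return df[df["amplitude"] >= fraction * df["amplitude"].max()].reset_index(drop=True)


def summarize_cell(events, duration_s: float, condition: str = "",
                   cell_id: str | None = None,
                   exclude_boundary_kinetics: bool = True) -> CellSummary:
    """Per-neuron means of each event metric and the event frequency.

    With zero events the means are undefined (``None``) and the
    frequency is 0. Events flagged ``boundary_truncated`` are excluded
    from the duration/rise/peak-offset means by default (their temporal
    extent is censored), but still count toward amplitude, AUC and
    frequency.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    df = _as_frame(events)
    if cell_id is None:
        cell_id = str(df["cell_id"].iloc[0]) if len(df) else ""
    n = len(df)
    if n == 0:
        return CellSummary(cell_id, condition, 0, None, None, None, None, 0.0)
    kin = df
    if exclude_boundary_kinetics and "flags" in df:
        kin = df[~df["flags"].fillna("").str.contains("boundary_truncated")]
    if kin.empty:
        kin = df
    return CellSummary(
        cell_id=cell_id,
        condition=condition,
        n_events=n,
        mean_amplitude=float(df["amplitude"].mean()),
        mean_auc=float(df["auc"].mean()),
        mean_duration=float(kin["duration"].mean()),
        mean_peak_offset=float(kin["peak_offset"].mean()),
        frequency=n / duration_s,
    )


def summarize_cells(event_table: pd.DataFrame, duration_s: float, condition: str = "",
                    cutoff_fraction: float | None = DEFAULT_CUTOFF_FRACTION,
                    cell_ids=None) -> list[CellSummary]:
    """Summaries for every cell in a multi-cell event table.

    ``cell_ids`` may list cells with zero detected events so they appear
    with frequency 0. ``cutoff_fraction=None`` skips the noise cutoff
    (needed when the summary feeds silent classification).
    """
    df = _as_frame(event_table)
    ids = list(cell_ids) if cell_ids is not None else sorted(df["cell_id"].unique())
    out = []
    for cid in ids:
        sub = df[df["cell_id"] == cid]
        if cutoff_fraction is not None:
            sub = apply_amplitude_cutoff(sub, cutoff_fraction)
        out.append(summarize_cell(sub, duration_s, condition, cell_id=str(cid)))
    return out


def classify_silent(summary: CellSummary,
                    threshold_au: float = DEFAULT_SILENT_THRESHOLD_AU) -> bool:
    """Silent iff the cell's mean fluctuation amplitude is below threshold.

    The summary must be computed *without* the 10% cutoff (a silent
    cell's noise fluctuations would otherwise self-normalize). A cell
    with no events at all is silent; a mean exactly at threshold is
    active (strict ``<``).
    """
    if summary.mean_amplitude is None:
        return True
    return summary.mean_amplitude < threshold_au


def normalized_amplitude_histogram(event_table: pd.DataFrame, n_bins: int = 20) -> pd.DataFrame:
    """Pooled relative-frequency histogram of per-cell-normalized amplitudes.

    Each cell's amplitudes are divided by that cell's largest fluctuation
    (so the top bin always contains every cell's maximum), pooled, and
    binned over (0, 1]. Relative frequencies sum to 100%.
    """
    df = _as_frame(event_table)
    if df.empty:
        raise ValueError("no events to histogram")
    normed = df.groupby("cell_id")["amplitude"].transform(lambda a: a / a.max())
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # right-closed bins over (0, 1]
    counts, _ = np.histogram(normed, bins=edges)
    # np.histogram is left-closed; shift exact-zero values (impossible for
    # amplitudes > 0) is moot, but the max=1.0 values land in the last bin.
    rel = 100.0 * counts / counts.sum()
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "relative_frequency_pct": rel}
    )


def fold_change_grouping(pre: CellSummary, post: CellSummary,
                         metric: str = "mean_amplitude") -> FoldChangeGroup | None:
    """Group a cell by the sign of its pre→post fold change.

    ``fold = (post - pre)/pre``; positive → "increase", otherwise
    (including exactly zero) → "decrease". A zero or missing pre mean
    makes the fold change undefined; the cell is excluded with a warning
    and ``None`` is returned.
    """
    if pre.cell_id != post.cell_id:
        raise ValueError("fold change requires paired recordings of the same cell")
    a = getattr(pre, metric)
    b = getattr(post, metric)
    if a is None or b is None or a == 0:
        warnings.warn(
            f"cell {pre.cell_id}: undefined fold change (pre={a!r}); excluded",
            RuntimeWarning,
            stacklevel=2,
        )
        return None
    fc = (b - a) / a
    return FoldChangeGroup(pre.cell_id, float(a), float(b), float(fc),
                           "increase" if fc > 0 else "decrease")


def pre_post_drug_compare(pre_summaries, post_summaries, metric: str = "mean_amplitude",
                          method: str = "paired_t"):
    """Paired pre/post comparison of a per-cell metric.

    Pairs cells by id, drops incomplete pairs, and delegates to
    :func:`fibsinet.stats.paired_compare`. Returns the comparison result
    with the mean paired difference attached.
    """
    from .stats import paired_compare

    pre_map = {s.cell_id: getattr(s, metric) for s in pre_summaries}
    post_map = {s.cell_id: getattr(s, metric) for s in post_summaries}
    ids = [c for c in pre_map if c in post_map
           and pre_map[c] is not None and post_map[c] is not None]
    if len(ids) < 2:
        raise ValueError("need at least 2 complete pairs")
    pre_v = np.array([pre_map[c] for c in ids], dtype=float)
    post_v = np.array([post_map[c] for c in ids], dtype=float)
    res = paired_compare(pre_v, post_v, method=method)
    res.extra["mean_difference"] = float(np.mean(post_v - pre_v))
    res.extra["direction"] = (
        "increase" if np.mean(post_v - pre_v) > 0
        else "decrease" if np.mean(post_v - pre_v) < 0 else "none"
    )
    res.extra["n_pairs"] = len(ids)
    return res
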