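"""Network synchrony among co-recorded cells.

Synchrony is quantified on the *processed* residual traces (signal minus
the traced reference line), each normalized to a 0–1 scale: an adjacency
matrix of pairwise Pearson r within each culture, a per-cell mean
correlation computed on the Fisher-Z (arctanh) scale and back-
transformed, a between-condition rank test on the pooled per-cell means,
and a simple binned criterion for network-wide synchronous waves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AdjacencyMatrix",
    "normalize_processed_trace",
    "build_adjacency",
    "mean_pearson_fisher",
    "condition_synchrony_compare",
    "detect_sync_waves",
]

_CLIP = 1.0 - 1e-7


@dataclass
class AdjacencyMatrix:
    """Pairwise Pearson r among cells imaged together in one culture."""

    cell_ids: list[str]
    r: np.ndarray
    mean_r_per_cell: np.ndarray
    zero_variance_cells: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.cell_ids)
        if self.r.shape != (n, n):
            raise ValueError("r must be n x n")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("r must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0):
            raise ValueError("r must have a unit diagonal")
        if np.any(self.r < -1 - 1e-12) or np.any(self.r > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")


def normalize_processed_trace(residual: np.ndarray) -> np.ndarray:
    """Min–max rescale a processed (reference-subtracted) trace to [0, 1].

    A constant trace maps to all zeros rather than raising.
    """
    x = np.asarray(residual, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def mean_pearson_fisher(r: np.ndarray, cell_index: int) -> float:
    """Fisher-Z mean correlation of one cell with all its partners.

    ``z = arctanh(clip(r, ±(1 - 1e-7)))`` over the off-diagonal entries
    of the cell's row, back-transformed with tanh. Exact for a constant
    off-diagonal (tanh and arctanh cancel).
    """
    r = np.asarray(r, dtype=float)
    n = r.shape[0]
    if n < 2:
        raise ValueError("a single-cell culture has no partners")
    mask = np.ones(n, dtype=bool)
    mask[cell_index] = False
    z = np.arctanh(np.clip(r[cell_index, mask], -_CLIP, _CLIP))
    return float(np.tanh(z.mean()))


def build_adjacency(traces, normalize: bool = True) -> AdjacencyMatrix:
    """Pearson adjacency of co-recorded processed traces.

    ``traces`` maps cell id -> processed residual vector (equal lengths);
    a :class:`~fibsinet.fibsi.Trace` list is also accepted. Zero-variance
    traces get correlation 0 with every partner (flagged) so culture
    matrices stay complete.
    """
    if isinstance(traces, dict):
        ids = list(traces.keys())
        mat = [np.asarray(traces[c], dtype=float) for c in ids]
    else:
        ids = [tr.cell_id for tr in traces]
        mat = [np.asarray(tr.y, dtype=float) for tr in traces]
    if len(ids) < 2:
        raise ValueError("need at least 2 co-recorded cells")
    lengths = {len(v) for v in mat}
    if len(lengths) != 1:
        raise ValueError("co-recorded traces must have equal sample counts")
    if normalize:
        mat = [normalize_processed_trace(v) for v in mat]
    X = np.vstack(mat)
    sd = X.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    # corrcoef would emit nan rows for constant traces; substitute unit-
    # variance noise-free placeholders then zero their correlations.
    Xs = X.copy()
    for i in flat:
        Xs[i] = np.linspace(0, 1, X.shape[1])
    r = np.corrcoef(Xs)
    for i in flat:
        r[i, :] = 0.0
        r[:, i] = 0.0
        r[i, i] = 1.0
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    mean_r = np.array([mean_pearson_fisher(r, i) for i in range(len(ids))])
    return AdjacencyMatrix(ids, r, mean_r, [ids[i] for i in flat])


def condition_synchrony_compare(cultures_a, cultures_b) -> dict:
    """Mann–Whitney comparison of per-cell mean r between two conditions.

    Each element of ``cultures_a``/``cultures_b`` is one culture's
    adjacency input (dict or trace list); mean correlations are computed
    strictly within each culture, then pooled per condition. A condition
    with a single culture is allowed but flagged low-power.
    """
    def pool(cultures):
        vals = []
        for cul in cultures:
            adj = cul if isinstance(cul, AdjacencyMatrix) else build_adjacency(cul)
            vals.extend(adj.mean_r_per_cell.tolist())
        return np.array(vals)

    if not len(cultures_a) or not len(cultures_b):
        raise ValueError("each condition needs at least one culture")
    a, b = pool(cultures_a), pool(cultures_b)
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    flags = []
    if len(cultures_a) < 2 or len(cultures_b) < 2:
        flags.append("single_culture_low_power")
    return {
        "mean_r_a": a,
        "mean_r_b": b,
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "U": float(u),
        "p": float(p),
        "flags": flags,
    }


def detect_sync_waves(event_table: pd.DataFrame, n_cells: int,
                      duration_s: float, bin_s: float = 2.0,
                      min_fraction: float = 0.5) -> np.ndarray:
    """Network waves: bins in which enough cells have an event peak.

    A wave is a ``bin_s``-wide time bin in which at least
    ``min_fraction`` of the ``n_cells`` co-recorded cells have an event
    peak; consecutive qualifying bins merge into one wave, reported at
    the center of the merged span. The bin/fraction criterion is a
    package convention (no published definition exists) and is recorded
    in output metadata.
    """
    if event_table.empty:
        return np.empty(0)
    edges = np.arange(0.0, duration_s + bin_s, bin_s)
    n_bins = len(edges) - 1
    which = np.clip(np.digitize(event_table["t_peak"], edges) - 1, 0, n_bins - 1)
    cells_per_bin = (
        pd.DataFrame({"bin": which, "cell": event_table["cell_id"]})
        .groupby("bin")["cell"].nunique()
        .reindex(range(n_bins), fill_value=0)
        .to_numpy()
    )
    qual = cells_per_bin >= min_fraction * n_cells
    waves = []
    i = 0
    while i < n_bins:
        if qual[i]:
            j = i
            while j + 1 < n_bins and qual[j + 1]:
                j += 1
            waves.append(0.5 * (edges[i] + edges[j + 1]))
            i = j + 1
        else:
            i += 1
    return np.array(waves)
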