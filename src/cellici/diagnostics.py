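"""Robustness/signal diagnostics for choosing the cumulative information threshold.

Small marker sets make the identity vector sensitive to the exact threshold
(high *ICI variability*: Euclidean distance between a cell's normalized ICI
vectors at consecutive thresholds); very large sets admit weakly informative
markers and dilute the index (low *ICI signal*: mean over cells of the
maximal normalized ICI).  Scanning thresholds exposes the tradeoff; the
threshold should sit where variability has flattened out while signal is
still high.  The recommendation heuristic here is advisory only — the
optimum is system-specific and should be confirmed by eye.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CellProfile
from .ici import raw_ici
from .markers import select_markers
from .spec_scoring import SpecTable

DEFAULT_GRID = range(5, 101)


@dataclass
class ThresholdScan:
    """Normalized ICI vectors, per-cell variability and signal over a threshold grid.

    ``ici`` is indexed by (threshold, cell) with one column per tissue;
    ``variability`` by (threshold, cell) — defined for all grid points but
    the last; ``signal`` by threshold.
    """

    thresholds: np.ndarray
    ici: pd.DataFrame
    variability: pd.DataFrame  # rows: threshold (all but last), cols: cells
    signal: pd.Series
    skipped: list[int]

    def median_variability(self) -> pd.Series:
        return self.variability.median(axis=1)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"signal": self.signal})
        out["median_variability"] = self.median_variability()
        out.index.name = "threshold"
        return out


def _norm_ici_vector(cell: CellProfile, markers, tissues: list[str]) -> np.ndarray:
    raw = np.array(
        [raw_ici(cell, markers, t) if markers.n_markers(t) else 0.0 for t in tissues]
    )
    total = raw.sum()
    return raw / total if total > 0 else raw


def scan(
    cells,
    spec: SpecTable,
    grid=DEFAULT_GRID,
    min_spec: float = 0.15,
) -> ThresholdScan:
    """Rebuild marker sets and normalized ICI vectors at every grid threshold."""
    grid = np.asarray(sorted(grid))
    tissues = spec.tissues
    cell_ids = [c.cell_id for c in cells]
    vecs: dict[int, np.ndarray] = {}
    skipped: list[int] = []
    for thr in grid:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            markers = select_markers(spec, threshold=float(thr), min_spec=min_spec)
        if all(markers.n_markers(t) == 0 for t in tissues):
            skipped.append(int(thr))
            continue
        vecs[int(thr)] = np.vstack([_norm_ici_vector(c, markers, tissues) for c in cells])
    kept = [t for t in grid.tolist() if t in vecs]
    ici = pd.DataFrame(
        np.vstack([vecs[t] for t in kept]) if kept else np.empty((0, len(tissues))),
        index=pd.MultiIndex.from_product([kept, cell_ids], names=["threshold", "cell"])
        if kept
        else pd.MultiIndex.from_arrays([[], []], names=["threshold", "cell"]),
        columns=tissues,
    )
    var_rows = {}
    for a, b in zip(kept[:-1], kept[1:]):
        var_rows[a] = np.linalg.norm(vecs[a] - vecs[b], axis=1)
    variability = pd.DataFrame.from_dict(var_rows, orient="index", columns=cell_ids)
    signal = pd.Series(
        {t: float(vecs[t].max(axis=1).mean()) for t in kept}, name="signal", dtype=float
    )
    return ThresholdScan(
        thresholds=np.asarray(kept), ici=ici, variability=variability, signal=signal,
        skipped=skipped,
    )


def recommend(
    scan_result: ThresholdScan,
    window: int = 5,
    rel_tol: float = 0.10,
) -> int:
    """Smallest threshold whose trailing ``window`` of median variabilities
    all fall below ``rel_tol`` × the scan's maximal median variability.

    Advisory only; falls back to the grid maximum (with a warning) when no
    plateau is found.
    """
    med = scan_result.median_variability()
    if med.empty:
        raise ValueError("empty scan")
    vals = med.to_numpy()
    idx = med.index.to_numpy()
    if vals.max() == vals.min():  # the whole scan is one plateau
        return int(idx[0])
    tol = rel_tol * float(vals.max())
    for j in range(len(vals)):
        if np.all(vals[j : j + window] <= tol):
            return int(idx[j])
    warnings.warn("no variability plateau found; returning the grid maximum", stacklevel=2)
    return int(scan_result.thresholds.max())


def plot_scan(scan_result: ThresholdScan, path: str | None = None):
    """Variability and signal curves versus threshold (matplotlib optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
    for cell in scan_result.variability.columns:
        ax1.plot(scan_result.variability.index, scan_result.variability[cell], alpha=0.3, lw=0.8)
    ax1.set_ylabel("ICI variability")
    ax2.plot(scan_result.signal.index, scan_result.signal.to_numpy(), color="k")
    ax2.set_ylabel("ICI signal")
    ax2.set_xlabel("cumulative information threshold")
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
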