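"""Per-tissue marker selection under a cumulative information threshold.

Tissues differ in how many highly informative genes they possess, so a fixed
marker count would give unequal diagnostic power.  Instead, for each tissue
genes are ranked by decreasing Spec score (ties broken by decreasing mean
expression over background, then gene id) and included while the running sum
of Spec scores stays below a cumulative information threshold — more distinct
tissues end up with fewer, stronger markers.  A gene may serve several
tissues, each time with its tissue-specific Spec weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spec_scoring import SpecTable

DEFAULT_THRESHOLD = 20.0
DEFAULT_MIN_SPEC = 0.15


@dataclass
class MarkerSet:
    """Ordered (gene, Spec weight) lists per tissue."""

    per_tissue: dict[str, list[tuple[str, float]]]
    threshold: float = DEFAULT_THRESHOLD
    min_spec: float = DEFAULT_MIN_SPEC

    @property
    def tissues(self) -> list[str]:
        return list(self.per_tissue)

    def n_markers(self, tissue: str) -> int:
        return len(self.per_tissue[tissue])

    def genes(self, tissue: str) -> list[str]:
        return [g for g, _ in self.per_tissue[tissue]]

    def weights(self, tissue: str) -> np.ndarray:
        return np.array([s for _, s in self.per_tissue[tissue]], dtype=float)

    @property
    def empty_tissues(self) -> list[str]:
        """Tissues with zero admissible markers — these cannot be called."""
        return [t for t, m in self.per_tissue.items() if not m]


def _ranked(spec: SpecTable, tissue: str, min_spec: float = 0.0) -> pd.DataFrame:
    s = spec.spec[tissue]
    s = s[s >= min_spec] if min_spec > 0 else s[s > 0]
    df = pd.DataFrame(
        {"spec": s, "mob": spec.mean_over_background.reindex(s.index)}
    )
    df["gene"] = df.index
    # stable sort: decreasing spec, then decreasing mean-over-background, then gene id
    return df.sort_values(
        ["spec", "mob", "gene"], ascending=[False, False, True], kind="mergesort"
    )


def select_markers(
    spec: SpecTable,
    threshold: float = DEFAULT_THRESHOLD,
    min_spec: float = DEFAULT_MIN_SPEC,
) -> MarkerSet:
    """Walk each tissue's ranked gene list accumulating Spec scores.

    A gene is included iff its Spec is at least ``min_spec`` and the
    cumulative sum *before* adding it is strictly below ``threshold`` — so
    any tissue with at least one admissible marker always gets one.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not 0 <= min_spec <= 1:
        raise ValueError("min_spec must lie in [0, 1]")
    per_tissue: dict[str, list[tuple[str, float]]] = {}
    for t in spec.tissues:
        ranked = _ranked(spec, t, min_spec=min_spec)
        chosen: list[tuple[str, float]] = []
        cum = 0.0
        for gene, s in zip(ranked["gene"], ranked["spec"]):
            if cum >= threshold:
                break
            chosen.append((gene, float(s)))
            cum += float(s)
        if not chosen:
            warnings.warn(
                f"tissue {t!r} has no admissible markers and cannot be called",
                stacklevel=2,
            )
        per_tissue[t] = chosen
    return MarkerSet(per_tissue=per_tissue, threshold=threshold, min_spec=min_spec)


def marker_curve(spec: SpecTable, tissue: str) -> list[tuple[int, float]]:
    """Cumulative-Spec profile (rank, running sum) for threshold diagnostics."""
    ranked = _ranked(spec, tissue)
    cum = np.cumsum(ranked["spec"].to_numpy())
    return list(zip(range(1, len(cum) + 1), cum.tolist()))
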