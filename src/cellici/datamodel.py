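"""Domain containers for reference compendia, query cells, and identity reports.

The reference compendium is a labeled genes × samples expression matrix on an
arbitrary non-negative platform scale (microarray intensities or normalized
counts).  Query cells carry per-gene expression on the fragments-per-million
(FPM) scale.  An identity report holds, for one cell, the raw and normalized
Index of Cell Identity (ICI) per tissue, the permutation p-values, and the
categorical call (single / mixed / unclassified).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Input data violates a structural invariant; message names the offender."""


@dataclass
class ReferenceCompendium:
    """Labeled genes × samples expression matrix used to learn Spec scores.

    Parameters
    ----------
    expression
        DataFrame indexed by gene id with one column per sample id.  Values
        must be finite and non-negative.
    tissue_of
        Series mapping sample id → tissue label; must cover every sample.
    """

    expression: pd.DataFrame
    tissue_of: pd.Series

    def __post_init__(self) -> None:
        genes = self.expression.index
        if genes.has_duplicates:
            dup = genes[genes.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        samples = self.expression.columns
        if samples.has_duplicates:
            dup = samples[samples.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        missing = samples.difference(self.tissue_of.index)
        if len(missing):
            raise ValidationError(f"unlabeled sample: {missing[0]!r}")
        # Drop labels for samples absent from the matrix, align order.
        self.tissue_of = self.tissue_of.reindex(samples)
        vals = self.expression.to_numpy()
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite value for gene {genes[bad[0]]!r} sample {samples[bad[1]]!r}"
            )
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative value for gene {genes[bad[0]]!r} sample {samples[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.expression.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.expression.columns

    @property
    def M(self) -> int:
        """Total number of measurements across all tissues and replicates."""
        return self.expression.shape[1]

    @property
    def tissues(self) -> list[str]:
        """Distinct tissue labels, sorted for determinism."""
        return sorted(self.tissue_of.unique())

    @property
    def n_tissues(self) -> int:
        return len(self.tissues)

    def labels(self) -> np.ndarray:
        """Tissue label per sample, in matrix column order."""
        return self.tissue_of.to_numpy()


@dataclass
class CellProfile:
    """One query cell's per-gene expression on the FPM scale.

    ``values`` maps gene id → FPM.  ``counts`` optionally retains the raw
    integer counts the FPM was derived from (required for downsampling and
    read mixing).  ``total_counts`` is the raw library size when known.
    """

    cell_id: str
    values: pd.Series
    counts: pd.Series | None = None
    total_counts: float | None = None

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError(f"cell {self.cell_id!r}: non-finite expression")
        if (vals < 0).any():
            gene = self.values.index[int(np.argmax(vals < 0))]
            raise ValidationError(f"cell {self.cell_id!r}: negative value for gene {gene!r}")
        if self.counts is not None and self.total_counts is None:
            self.total_counts = float(self.counts.sum())

    @classmethod
    def from_counts(cls, cell_id: str, counts: pd.Series) -> "CellProfile":
        """Build a profile from raw counts, converting to fragments per million."""
        total = float(counts.sum())
        fpm = counts.astype(float) * (1e6 / total) if total > 0 else counts.astype(float)
        return cls(cell_id=cell_id, values=fpm, counts=counts, total_counts=total)

    def expression_of(self, genes: Sequence[str], strict: bool = False) -> np.ndarray:
        """FPM vector over ``genes``; genes absent from the table score 0.

        With ``strict`` an absent gene raises instead — use when silent
        zero-filling would mask an identifier mismatch.
        """
        if strict:
            missing = pd.Index(genes).difference(self.values.index)
            if len(missing):
                raise ValidationError(
                    f"cell {self.cell_id!r}: gene {missing[0]!r} absent from expression table"
                )
        return self.values.reindex(genes, fill_value=0.0).to_numpy(dtype=float)


#: categorical identity calls
SINGLE = "single"
MIXED = "mixed"
UNCLASSIFIED = "unclassified"


@dataclass
class IdentityReport:
    """Per-cell ICI vector with permutation significance and the identity call.

    ``call`` is ``single``, ``mixed`` or ``unclassified``; ``call_tissues``
    lists the significant tissues (one for single, several for mixed, empty
    for unclassified) and ``proportions`` their normalized-ICI proportions.
    """

    cell_id: str
    raw_ici: Mapping[str, float]
    norm_ici: Mapping[str, float]
    p_value: Mapping[str, float]
    call: str
    call_tissues: tuple[str, ...] = ()
    proportions: Mapping[str, float] = field(default_factory=dict)
    alpha: float = 0.05

    @property
    def tissues(self) -> list[str]:
        return list(self.raw_ici)

    @property
    def max_tissue(self) -> str:
        return max(self.norm_ici, key=lambda t: self.norm_ici[t])
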