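"""Per-gene background cutoffs and two-state Spec specificity scores.

A gene's expression across the reference compendium is split into a *low*
(background / noise) and a *high* (true expression) state by a per-gene
cutoff.  The cutoff region is found empirically: the gene's values are
binned into ``l`` equal-width bins over their own range; with ``M`` samples
the null expectation per bin is ``e = M / l``, and the transition bin ``m``
is the first bin whose occupancy drops below ``e`` — the end of the abundant
background mass.  Genes whose transition bin lies above an upper limit ``u``
show too small a separation between background and true expression and are
rejected.  The precise cutoff is then the value in the preceding bin that
maximizes the gene's Spec score.

The two-state Spec score of gene g for tissue t is an information measure of
how predictive the binarized expression is of the tissue label:

    q_t(b)  = fraction of tissue t's samples falling in state b ∈ {low, high}
    p(t|b)  = q_t(b) / Σ_t' q_t'(b)
    I(b)    = 1 + Σ_t p(t|b) · ln p(t|b) / ln N            (∈ [0, 1])
    Spec_{g,t} = q_t(high)·I(high) − q_t(low)·I(low)       (∈ [−1, 1])

Negative scores mark *absence* markers (tissues characterized by lack of
expression); they are clipped to 0 because the identity index only uses
presence markers.  Using per-tissue occupancy fractions rather than raw
sample counts weights tissues with unequal replicate numbers equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ReferenceCompendium

DEFAULT_BINS = 10
DEFAULT_MAX_TRANSITION_BIN = 3  # u = 3 for tissue compendia; 10 suits tumor-style data
DEFAULT_MEDIAN_CAP = 250.0


@dataclass
class BinOccupancy:
    """Equal-width bin occupancy of one gene's expression values."""

    l: int
    counts: np.ndarray  # o_1..o_l
    e: float  # null expectation M / l
    m: int  # transition bin (1-based)
    u: int
    edges: np.ndarray  # l + 1 bin edges over [min, max]


class GeneRejected(Exception):
    """Gene has no separable background under the binning rule."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


def filter_genes(
    ref: ReferenceCompendium,
    exclude: set[str] | frozenset[str] = frozenset(),
    median_cap: float = DEFAULT_MEDIAN_CAP,
) -> set[str]:
    """Drop excluded genes and constitutively highly expressed genes.

    A gene is constitutively high when its across-sample median exceeds
    ``median_cap`` (strictly: median > cap removes, median == cap retains).
    """
    if median_cap < 0:
        raise ValueError("median_cap must be non-negative")
    medians = ref.expression.median(axis=1)
    keep = medians.index[(medians <= median_cap)]
    return set(keep) - set(exclude)


def find_transition_bin(
    values: np.ndarray,
    l: int = DEFAULT_BINS,
    u: int = DEFAULT_MAX_TRANSITION_BIN,
    rule: str = "first",
) -> BinOccupancy:
    """Bin a gene's values into ``l`` equal-width bins and locate bin ``m``.

    ``rule='first'`` takes the smallest bin index with occupancy below the
    null expectation e = M/l (the end of the abundant background);
    ``rule='highest'`` takes the largest such index.  Raises
    :class:`GeneRejected` for constant genes, genes with no sub-expected
    bin, or m > u.
    """
    values = np.asarray(values, dtype=float)
    M = values.size
    if l < 2 or M < l:
        raise ValueError("need M >= l >= 2")
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise GeneRejected("constant")
    counts, edges = np.histogram(values, bins=l, range=(lo, hi))
    e = M / l
    below = np.nonzero(counts < e)[0]
    if below.size == 0:
        raise GeneRejected("constant")  # occupancy uniform at e: no transition
    if rule == "first":
        m = int(below[0]) + 1
    elif rule == "highest":
        m = int(below[-1]) + 1
    else:
        raise ValueError(f"unknown transition rule {rule!r}")
    occ = BinOccupancy(l=l, counts=counts, e=e, m=m, u=u, edges=edges)
    if m > u:
        raise GeneRejected("m_gt_u")
    return occ


def cutoff_candidates(values: np.ndarray, occ: BinOccupancy) -> np.ndarray:
    """Distinct observed values in bin m−1 plus that bin's lower edge.

    When m == 1 there is no preceding bin and the range minimum is the sole
    candidate; likewise when bin m−1 holds no observations.
    """
    values = np.asarray(values, dtype=float)
    if occ.m == 1:
        return np.array([occ.edges[0]])
    lo, hi = occ.edges[occ.m - 2], occ.edges[occ.m - 1]
    in_bin = values[(values >= lo) & (values < hi)]
    return np.unique(np.concatenate([[lo], in_bin]))


def spec_scores(
    values: np.ndarray,
    cutoff: float,
    labels: np.ndarray,
    clip: bool = True,
) -> dict[str, float]:
    """Two-state Spec score per tissue for one gene at a given cutoff.

    Samples are binarized strictly: *high* iff value > cutoff.  With ``clip``
    negative (absence-marker) scores are set to 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    tissues, inv = np.unique(labels, return_inverse=True)
    N = tissues.size
    if N < 2:
        raise ValueError("need at least 2 tissues")
    high = values > cutoff
    n_per_tissue = np.bincount(inv, minlength=N).astype(float)
    q_high = np.bincount(inv, weights=high.astype(float), minlength=N) / n_per_tissue
    q_low = 1.0 - q_high

    def bin_information(q: np.ndarray) -> float:
        s = q.sum()
        if s == 0.0:
            return 0.0
        p = q / s
        nz = p > 0
        return 1.0 + float(np.sum(p[nz] * np.log(p[nz]))) / np.log(N)

    i_high = bin_information(q_high)
    i_low = bin_information(q_low)
    spec = q_high * i_high - q_low * i_low
    if clip:
        spec = np.maximum(spec, 0.0)
    return dict(zip(tissues.tolist(), spec.tolist()))


def refine_cutoff(
    values: np.ndarray,
    occ: BinOccupancy,
    labels: np.ndarray,
) -> float:
    """Choose the cutoff in the bin preceding the transition that maximizes
    the gene's maximum per-tissue Spec score; ties favor the smallest value."""
    best_c, best_s = None, -np.inf
    for c in cutoff_candidates(values, occ):
        s = max(spec_scores(values, c, labels).values())
        if s > best_s + 1e-15:  # strict improvement; ties keep the smaller cutoff
            best_c, best_s = float(c), s
    return best_c


@dataclass
class SpecTable:
    """Per-gene per-tissue Spec scores with per-gene background cutoffs.

    ``spec`` is indexed by gene with one column per tissue; ``cutoff`` maps
    gene → background cutoff; ``mean_over_background`` maps gene → mean
    expression in the samples above the gene's cutoff (the marker-selection
    tie-break key).  ``rejections`` records (gene, reason) for every filtered
    gene.
    """

    spec: pd.DataFrame
    cutoff: pd.Series
    mean_over_background: pd.Series
    rejections: list[tuple[str, str]] = field(default_factory=list)

    @property
    def eligible(self) -> pd.Index:
        return self.spec.index

    @property
    def tissues(self) -> list[str]:
        return list(self.spec.columns)

    def to_frame(self) -> pd.DataFrame:
        df = self.spec.copy()
        df.insert(0, "cutoff", self.cutoff)
        df.insert(1, "mean_over_background", self.mean_over_background)
        df.index.name = "gene"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpecTable":
        cutoff = df["cutoff"].astype(float)
        mob = df["mean_over_background"].astype(float)
        spec = df.drop(columns=["cutoff", "mean_over_background"]).astype(float)
        return cls(spec=spec, cutoff=cutoff, mean_over_background=mob)


def build_spec_table(
    ref: ReferenceCompendium,
    exclude: set[str] | frozenset[str] = frozenset(),
    l: int = DEFAULT_BINS,
    u: int = DEFAULT_MAX_TRANSITION_BIN,
    median_cap: float = DEFAULT_MEDIAN_CAP,
    rule: str = "first",
) -> SpecTable:
    """Run the full per-gene pipeline: filters, binning, cutoff refinement,
    Spec scoring.  Genes failing any stage are recorded in ``rejections``
    (reasons: excluded, high_median, constant, m_gt_u); genes whose scores
    clip to zero everywhere stay eligible but are logged as low_spec."""
    labels = ref.labels()
    keep = filter_genes(ref, exclude=set(), median_cap=median_cap)
    rejections: list[tuple[str, str]] = []
    rows: dict[str, dict[str, float]] = {}
    cutoffs: dict[str, float] = {}
    mob: dict[str, float] = {}
    for gene in ref.gene_ids:
        if gene in exclude:
            rejections.append((gene, "excluded"))
            continue
        if gene not in keep:
            rejections.append((gene, "high_median"))
            continue
        values = ref.expression.loc[gene].to_numpy(dtype=float)
        try:
            occ = find_transition_bin(values, l=l, u=u, rule=rule)
        except GeneRejected as exc:
            rejections.append((gene, exc.reason))
            continue
        c = refine_cutoff(values, occ, labels)
        scores = spec_scores(values, c, labels)
        rows[gene] = scores
        cutoffs[gene] = c
        above = values[values > c]
        mob[gene] = float(above.mean()) if above.size else 0.0
        if max(scores.values()) == 0.0:
            rejections.append((gene, "low_spec"))
    spec = pd.DataFrame.from_dict(rows, orient="index").reindex(
        index=[g for g in ref.gene_ids if g in rows]
    )
    if spec.empty:
        spec = pd.DataFrame(columns=ref.tissues, dtype=float)
    return SpecTable(
        spec=spec,
        cutoff=pd.Series(cutoffs, dtype=float, name="cutoff").reindex(spec.index),
        mean_over_background=pd.Series(
            mob, dtype=float, name="mean_over_background"
        ).reindex(spec.index),
        rejections=rejections,
    )
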