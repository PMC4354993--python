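"""The Index of Cell Identity: score, permutation significance, and call.

For a query cell and tissue t with marker set g = 1..n_t, Spec weights
s_{g,t} and per-gene FPM expression e_g, the raw index is

    ICI_t = (Σ_g e_g · s_{g,t} / n_t) · (Σ_g [e_g > 0] / n_t)

— the Spec-weighted mean marker expression, down-weighted by the fraction of
markers detected at all, which buffers both marker dropout and sporadic
ectopic expression.  Significance comes from a per-cell permutation null:
random gene sets of the same size drawn from the eligible gene universe,
carrying the tissue's original weight multiset.  Raw indices are normalized
to sum 1 across tissues; a cell is called *single* when exactly one tissue is
significant, *mixed* (chimeric) when several are, *unclassified* when none.
"""

from __future__ import annotations

import zlib
from typing import Mapping, Sequence

import numpy as np

from .datamodel import MIXED, SINGLE, UNCLASSIFIED, CellProfile, IdentityReport
from .markers import MarkerSet

DEFAULT_N_PERM = 1000
DEFAULT_ALPHA = 0.05


def raw_ici(cell: CellProfile, markers: MarkerSet, tissue: str, strict_genes: bool = False) -> float:
    """Raw identity index of one cell for one tissue.

    Markers absent from the cell's expression table score e_g = 0 unless
    ``strict_genes`` asks for an error instead.
    """
    genes = markers.genes(tissue)
    if not genes:
        raise ValueError(f"tissue {tissue!r} has no markers")
    e = cell.expression_of(genes, strict=strict_genes)
    w = markers.weights(tissue)
    n_t = len(genes)
    return float((e @ w) / n_t * np.count_nonzero(e) / n_t)


def _cell_rng(base_seed: int, cell_id: str) -> np.random.Generator:
    # keyed on the cell identifier (not batch position) so a cell's result is
    # invariant to the composition and order of the batch
    return np.random.default_rng(
        np.random.SeedSequence([int(base_seed), zlib.crc32(cell_id.encode())])
    )


def permutation_test(
    cell: CellProfile,
    markers: MarkerSet,
    universe: Sequence[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    observed: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """One-sided permutation p-value per tissue.

    For each of ``n_perm`` permutations and each tissue, n_t genes are drawn
    uniformly without replacement from ``universe`` (the post-filter gene set
    the Spec table was built on), the tissue's original Spec weight multiset
    is attached in drawn order, and a null index is computed identically to
    the observed one.  The add-one estimator
    p = (1 + #{null ≥ observed}) / (n_perm + 1) never returns exactly 0.
    """
    universe = list(universe)
    U = len(universe)
    max_nt = max((markers.n_markers(t) for t in markers.tissues), default=0)
    if U < max_nt:
        raise ValueError(f"universe of {U} genes is smaller than largest marker set ({max_nt})")
    expr = cell.expression_of(universe)
    rng = _cell_rng(seed, cell.cell_id)
    pvals: dict[str, float] = {}
    for t in markers.tissues:
        n_t = markers.n_markers(t)
        if n_t == 0:
            pvals[t] = float("nan")
            continue
        obs = observed[t] if observed is not None else raw_ici(cell, markers, t)
        w = markers.weights(t)
        keys = rng.random((n_perm, U))
        idx = np.argpartition(keys, n_t - 1, axis=1)[:, :n_t] if n_t < U else np.tile(
            np.arange(U), (n_perm, 1)
        )
        E = expr[idx]
        null = (E @ w) / n_t * np.count_nonzero(E, axis=1) / n_t
        pvals[t] = float((1 + int(np.sum(null >= obs))) / (n_perm + 1))
    return pvals


def classify(
    cell_id: str,
    raw: Mapping[str, float],
    p: Mapping[str, float],
    alpha: float = DEFAULT_ALPHA,
) -> IdentityReport:
    """Normalize the raw index vector to sum 1 and make the categorical call.

    Significance is judged on the raw values' p-values before normalization;
    a cell with every raw index zero reports an all-zero normalized vector.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    tissues = list(raw)
    total = float(sum(raw.values()))
    if total > 0:
        norm = {t: raw[t] / total for t in tissues}
    else:
        norm = {t: 0.0 for t in tissues}
    sig = tuple(t for t in tissues if np.isfinite(p[t]) and p[t] < alpha)
    if len(sig) == 1:
        call = SINGLE
    elif len(sig) >= 2:
        call = MIXED
    else:
        call = UNCLASSIFIED
    return IdentityReport(
        cell_id=cell_id,
        raw_ici=dict(raw),
        norm_ici=norm,
        p_value=dict(p),
        call=call,
        call_tissues=sig,
        proportions={t: norm[t] for t in sig},
        alpha=alpha,
    )


def score_cell(
    cell: CellProfile,
    markers: MarkerSet,
    universe: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    strict_genes: bool = False,
) -> IdentityReport:
    """Raw indices, permutation p-values and the call for one cell."""
    raw = {
        t: raw_ici(cell, markers, t, strict_genes=strict_genes)
        for t in markers.tissues
        if markers.n_markers(t) > 0
    }
    p = permutation_test(cell, markers, universe, n_perm=n_perm, seed=seed, observed=raw)
    p = {t: p[t] for t in raw}
    return classify(cell.cell_id, raw, p, alpha=alpha)


def score_cells(
    cells: Sequence[CellProfile],
    markers: MarkerSet,
    universe: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    strict_genes: bool = False,
) -> list[IdentityReport]:
    """Score each cell independently; results do not depend on the batch."""
    return [
        score_cell(
            c, markers, universe, alpha=alpha, n_perm=n_perm, seed=seed, strict_genes=strict_genes
        )
        for c in cells
    ]
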