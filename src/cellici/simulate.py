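"""Synthetic compendia and single cells for benchmarking identity calls.

The generator plants, for each tissue, a block of marker genes expressed
high in all of that tissue's reference replicates and at a low background
floor elsewhere, on top of a pool of noise genes expressed exchangeably
across tissues.  Synthetic single cells reproduce the two noise phenomena
that dominate real single-cell profiles: *dropout* (an expressed marker
going undetected) and sporadic low-level *ectopic* expression of another
identity's markers.  Counts are gamma-Poisson (negative binomial) with
Bernoulli thinning; read-depth effects are emulated by multinomial
resampling, and chimeric profiles by mixing reads of two cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import CellProfile, ReferenceCompendium


@dataclass
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    ``marker_fold`` is the fold separation between a marker's background
    floor and its true expression; ``dropout`` the per-gene probability that
    an expressed gene is lost from a cell; ``ectopic_rate`` the per-gene
    probability that an off-tissue marker shows low-level expression at mean
    ``ectopic_mean``.  Expression units are arbitrary platform-scale
    intensities for the reference and raw read counts for cells.
    """

    n_tissues: int = 5
    replicates: int | tuple[int, ...] = 4
    n_markers_per_tissue: int = 10
    n_noise_genes: int = 2000
    marker_fold: float = 250.0
    marker_floor_mean: float = 2.0
    background_mean: float = 50.0
    dispersion: float = 0.3
    dropout: float = 0.3
    ectopic_rate: float = 0.05
    ectopic_mean: float = 2.0
    library_size: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.dropout, self.ectopic_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must exceed 1")

    @property
    def tissue_names(self) -> list[str]:
        return [f"T{i}" for i in range(self.n_tissues)]

    @property
    def replicate_counts(self) -> list[int]:
        if isinstance(self.replicates, int):
            return [self.replicates] * self.n_tissues
        return list(self.replicates)

    def marker_genes(self, tissue_index: int) -> list[str]:
        return [f"MK_T{tissue_index}_{k}" for k in range(self.n_markers_per_tissue)]

    @property
    def noise_genes(self) -> list[str]:
        return [f"NOISE_{j}" for j in range(self.n_noise_genes)]

    @property
    def all_genes(self) -> list[str]:
        genes: list[str] = []
        for i in range(self.n_tissues):
            genes.extend(self.marker_genes(i))
        genes.extend(self.noise_genes)
        return genes


def _nb(rng: np.random.Generator, mean, dispersion: float, size) -> np.ndarray:
    """Negative binomial with the given mean and dispersion (var = μ + αμ²)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion, size=size)
    return rng.poisson(lam).astype(float)


def make_reference(cfg: SynthConfig) -> tuple[ReferenceCompendium, dict[str, list[str]]]:
    """Reference compendium with planted markers, plus the ground-truth map."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    reps = cfg.replicate_counts
    samples, labels = [], []
    for i, t in enumerate(cfg.tissue_names):
        for r in range(reps[i]):
            samples.append(f"{t}_rep{r}")
            labels.append(t)
    M = len(samples)
    genes = cfg.all_genes
    mean = np.empty((len(genes), M))
    truth: dict[str, list[str]] = {}
    row = 0
    for i, t in enumerate(cfg.tissue_names):
        truth[t] = cfg.marker_genes(i)
        own = np.array([lab == t for lab in labels])
        for _ in range(cfg.n_markers_per_tissue):
            mean[row] = np.where(own, cfg.marker_floor_mean * cfg.marker_fold, cfg.marker_floor_mean)
            row += 1
    mean[row:] = cfg.background_mean
    values = _nb(rng, mean, cfg.dispersion, mean.shape)
    ref = ReferenceCompendium(
        expression=pd.DataFrame(values, index=genes, columns=samples),
        tissue_of=pd.Series(labels, index=samples),
    )
    return ref, truth


def _cell_rates(cfg: SynthConfig, tissue: str, rng: np.random.Generator) -> np.ndarray:
    """Expected expression per gene for one cell of the given tissue."""
    genes = cfg.all_genes
    rates = np.empty(len(genes))
    row = 0
    for i, t in enumerate(cfg.tissue_names):
        n = cfg.n_markers_per_tissue
        if t == tissue:
            rates[row : row + n] = cfg.marker_floor_mean * cfg.marker_fold
        else:
            ectopic = rng.random(n) < cfg.ectopic_rate
            rates[row : row + n] = np.where(ectopic, cfg.ectopic_mean, 0.0)
        row += n
    rates[row:] = cfg.background_mean
    # gamma heterogeneity then Bernoulli dropout
    rates = rates * rng.gamma(1.0 / cfg.dispersion, cfg.dispersion, size=rates.size)
    rates[rng.random(rates.size) < cfg.dropout] = 0.0
    return rates


def make_cell(
    cfg: SynthConfig, tissue: str, library_size: int | None = None, cell_index: int = 0
) -> tuple[CellProfile, str]:
    """One synthetic cell of the given tissue, with its truth label."""
    if tissue not in cfg.tissue_names:
        raise ValueError(f"unknown tissue {tissue!r}")
    lib = int(library_size or cfg.library_size)
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 1, cfg.tissue_names.index(tissue), cell_index])
    )
    rates = _cell_rates(cfg, tissue, rng)
    total = rates.sum()
    counts = rng.multinomial(lib, rates / total) if total > 0 else np.zeros_like(rates)
    profile = CellProfile.from_counts(
        f"{tissue}_cell{cell_index}", pd.Series(counts, index=cfg.all_genes, dtype=float)
    )
    return profile, tissue


def make_cohort(
    cfg: SynthConfig, cells_per_tissue: int, library_size: int | None = None
) -> tuple[list[CellProfile], dict[str, str]]:
    """A cohort of cells with equal numbers per tissue and its truth table."""
    cells, truth = [], {}
    for t in cfg.tissue_names:
        for k in range(cells_per_tissue):
            c, lab = make_cell(cfg, t, library_size=library_size, cell_index=k)
            cells.append(c)
            truth[c.cell_id] = lab
    return cells, truth


def downsample(cell: CellProfile, depth: int, seed: int = 0) -> CellProfile:
    """Resample a cell to a shallower read depth (multinomial without
    read-identity tracking; equivalent to read-level resampling under
    exchangeability).  Never creates genes absent from the source."""
    if cell.counts is None:
        raise ValueError(f"cell {cell.cell_id!r} carries no raw counts")
    total = cell.counts.sum()
    if depth > total:
        raise ValueError(f"depth {depth} exceeds total counts {int(total)}")
    rng = np.random.default_rng(seed)
    p = cell.counts.to_numpy(dtype=float) / total
    counts = rng.multinomial(int(depth), p)
    return CellProfile.from_counts(
        f"{cell.cell_id}_ds{depth}", pd.Series(counts, index=cell.counts.index, dtype=float)
    )


def mix(
    cell_a: CellProfile,
    cell_b: CellProfile,
    depth: int,
    fraction_a: float = 0.5,
    seed: int = 0,
) -> CellProfile:
    """Chimeric profile: sample reads from two cells' count distributions."""
    if not 0 <= fraction_a <= 1:
        raise ValueError("fraction_a must lie in [0, 1]")
    for c in (cell_a, cell_b):
        if c.counts is None:
            raise ValueError(f"cell {c.cell_id!r} carries no raw counts")
    rng = np.random.default_rng(seed)
    genes = cell_a.counts.index.union(cell_b.counts.index)
    ca = cell_a.counts.reindex(genes, fill_value=0.0).to_numpy(dtype=float)
    cb = cell_b.counts.reindex(genes, fill_value=0.0).to_numpy(dtype=float)
    n_a = int(round(depth * fraction_a))
    counts = np.zeros(len(genes))
    if n_a > 0:
        counts += rng.multinomial(n_a, ca / ca.sum())
    if depth - n_a > 0:
        counts += rng.multinomial(depth - n_a, cb / cb.sum())
    return CellProfile.from_counts(
        f"mix_{cell_a.cell_id}_{cell_b.cell_id}", pd.Series(counts, index=genes, dtype=float)
    )


def null_cells(
    n_cells: int, universe: list[str], seed: int = 0, scale: float = 100.0
) -> list[CellProfile]:
    """Cells whose expression is exchangeable over the gene universe —
    identical log-normal law for every gene, so marker identity carries no
    information.  Used for type-I-error calibration of the permutation test."""
    out = []
    for k in range(n_cells):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2, k]))
        vals = rng.lognormal(mean=np.log(scale), sigma=1.0, size=len(universe))
        out.append(
            CellProfile(cell_id=f"null_{k}", values=pd.Series(vals, index=list(universe)))
        )
    return out
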