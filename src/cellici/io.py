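"""Readers and writers for compendia, cell matrices, marker tables and reports.

All tabular output is TSV with a fixed column order and ``#``-prefixed header
lines carrying provenance (tool version, parameters).  Delimiters on input are
tab by default with comma autodetected.  Query cells may also arrive as a
Matrix Market triplet with companion gene/cell name files.
"""

from __future__ import annotations

import io as _io
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datamodel import CellProfile, IdentityReport, ReferenceCompendium, ValidationError

_FLOAT_FMT = "%.17g"  # full double precision: round-trips exactly


def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if "\t" in line else ","
    return "\t"


def _read_table(path: str, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sniff_sep(path), comment="#", **kw)


def _provenance(params: dict | None) -> str:
    from . import __version__

    head = f"# cellici {__version__}"
    if params:
        head += " " + " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return head + "\n"


def read_reference(matrix_path: str, labels_path: str) -> ReferenceCompendium:
    """Load a genes × samples matrix plus a two-column sample → tissue table.

    Samples are reconciled by identifier, not position: the label file may
    list samples in any order, but must cover every matrix column.
    """
    mat = _read_table(matrix_path, index_col=0)
    labels = _read_table(labels_path, index_col=0)
    if labels.shape[1] < 1:
        raise ValidationError(f"{labels_path}: expected columns sample, tissue")
    tissue_of = labels.iloc[:, 0].astype(str)
    if tissue_of.index.has_duplicates:
        dup = tissue_of.index[tissue_of.index.duplicated()][0]
        raise ValidationError(f"duplicate sample in label file: {dup!r}")
    return ReferenceCompendium(expression=mat.astype(float), tissue_of=tissue_of)


def read_cells(
    path: str,
    format: str = "tsv",
    genes_path: str | None = None,
    cells_path: str | None = None,
    counts_to_fpm: bool = False,
) -> list[CellProfile]:
    """Load query cells from a genes × cells TSV or a Matrix Market triplet.

    With ``counts_to_fpm`` the input is treated as raw counts and converted
    to fragments per million (value / library size × 1e6); otherwise values
    pass through unchanged.
    """
    if format == "tsv":
        df = _read_table(path, index_col=0).astype(float)
    elif format == "mtx":
        if genes_path is None or cells_path is None:
            raise ValidationError("mtx format requires genes_path and cells_path")
        m = scipy.io.mmread(path)
        genes = [ln.strip().split("\t")[0] for ln in open(genes_path) if ln.strip()]
        cells = [ln.strip().split("\t")[0] for ln in open(cells_path) if ln.strip()]
        if m.shape[0] != len(genes):
            raise ValidationError(
                f"matrix has {m.shape[0]} gene rows but {len(genes)} gene names"
            )
        if m.shape[1] != len(cells):
            raise ValidationError(
                f"matrix has {m.shape[1]} cell columns but {len(cells)} cell names"
            )
        dense = m.toarray() if scipy.sparse.issparse(m) else np.asarray(m)
        df = pd.DataFrame(dense, index=genes, columns=cells, dtype=float)
    else:
        raise ValidationError(f"unknown cell matrix format: {format!r}")

    out: list[CellProfile] = []
    for cell_id in df.columns:
        col = df[cell_id]
        if counts_to_fpm:
            out.append(CellProfile.from_counts(str(cell_id), col))
        else:
            out.append(CellProfile(cell_id=str(cell_id), values=col))
    return out


_REPORT_COLS = ["cell", "tissue", "raw_ici", "norm_ici", "p_value", "call", "alpha"]


def write_report(reports: Sequence[IdentityReport], path: str, params: dict | None = None) -> None:
    """Write one row per cell × tissue; the ``call`` column names the overall
    call with its significant tissues, identically on every row of a cell."""
    rows = []
    for r in reports:
        call_str = r.call
        if r.call_tissues:
            call_str += ":" + "+".join(r.call_tissues)
        for t in r.tissues:
            rows.append((r.cell_id, t, r.raw_ici[t], r.norm_ici[t], r.p_value[t], call_str, r.alpha))
    with open(path, "w") as fh:
        fh.write(_provenance(params))
        fh.write("\t".join(_REPORT_COLS) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    _FLOAT_FMT % v if isinstance(v, float) else str(v) for v in row
                )
                + "\n"
            )


def read_report(path: str) -> list[IdentityReport]:
    df = _read_table(path)
    out = []
    for cell_id, grp in df.groupby("cell", sort=False):
        call_str = str(grp["call"].iloc[0])
        call, _, tail = call_str.partition(":")
        call_tissues = tuple(tail.split("+")) if tail else ()
        norm = dict(zip(grp["tissue"], grp["norm_ici"].astype(float)))
        out.append(
            IdentityReport(
                cell_id=str(cell_id),
                raw_ici=dict(zip(grp["tissue"], grp["raw_ici"].astype(float))),
                norm_ici=norm,
                p_value=dict(zip(grp["tissue"], grp["p_value"].astype(float))),
                call=call,
                call_tissues=call_tissues,
                proportions={t: norm[t] for t in call_tissues},
                alpha=float(grp["alpha"].iloc[0]),
            )
        )
    return out


def write_spec_table(spec_table, path: str, params: dict | None = None) -> None:
    """Serialize a SpecTable as TSV: gene, cutoff, then one column per tissue."""
    df = spec_table.to_frame()
    with open(path, "w") as fh:
        fh.write(_provenance(params))
        df.to_csv(fh, sep="\t", float_format=_FLOAT_FMT)


def read_spec_table(path: str):
    from .spec_scoring import SpecTable

    df = _read_table(path, index_col=0)
    df.index.name = None
    return SpecTable.from_frame(df)


def write_markers(markers, path: str, params: dict | None = None) -> None:
    """Marker table TSV: gene, tissue, spec, rank, cumulative_spec."""
    with open(path, "w") as fh:
        fh.write(_provenance(params))
        fh.write("gene\ttissue\tspec\trank\tcumulative_spec\n")
        for t in markers.tissues:
            cum = 0.0
            for rank, (gene, s) in enumerate(markers.per_tissue[t], start=1):
                cum += s
                fh.write(f"{gene}\t{t}\t{_FLOAT_FMT % s}\t{rank}\t{_FLOAT_FMT % cum}\n")


def read_markers(path: str):
    from .markers import MarkerSet

    df = _read_table(path)
    per_tissue: dict[str, list[tuple[str, float]]] = {}
    for t, grp in df.groupby("tissue", sort=True):
        grp = grp.sort_values("rank")
        per_tissue[str(t)] = list(zip(grp["gene"].astype(str), grp["spec"].astype(float)))
    return MarkerSet(per_tissue=per_tissue)


def write_rejection_log(rejections: Iterable[tuple[str, str]], path: str) -> None:
    """Gene rejection log TSV: gene, reason."""
    with open(path, "w") as fh:
        fh.write("gene\treason\n")
        for gene, reason in rejections:
            fh.write(f"{gene}\t{reason}\n")
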