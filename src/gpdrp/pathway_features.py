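"""Gene-set handling and pathway-score feature preparation.

Cell lines are represented by pathway activity scores (GSVA-style, bounded,
one score per pathway per cell line).  Computing the scores from expression
data is out of scope here: the matrix is consumed as input or synthesised.
This module reads GMT gene-set collections, applies the minimum-size filter
(after intersecting each set with the measured gene universe), and min–max
normalises each pathway across cell lines onto [0, 1]:

    x̂_ik = (x_ik − min_k x_ik) / (max_k x_ik − min_k x_ik)

Constant pathways are mapped to all-zeros with a warning, since the formula
is undefined there and a constant feature carries no signal either way.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class PathwayScoreMatrix:
    """Real matrix of pathways × cell lines with labelled axes."""

    values: np.ndarray
    pathway_ids: list[str]
    cell_line_ids: list[str]
    normalized: bool = False
    # Row min/max recorded at normalisation time, so the same affine map can
    # be applied to columns not seen when the statistics were computed.
    norm_stats: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.pathway_ids), len(self.cell_line_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match axes "
                f"({len(self.pathway_ids)} pathways, {len(self.cell_line_ids)} cell lines)"
            )
        if np.isnan(self.values).any():
            raise ValueError("pathway score matrix contains missing values")

    def column(self, cell_line_id: str) -> np.ndarray:
        return self.values[:, self.cell_line_ids.index(cell_line_id)]

    def subset_cell_lines(self, ids: list[str]) -> "PathwayScoreMatrix":
        idx = [self.cell_line_ids.index(c) for c in ids]
        return replace(self, values=self.values[:, idx], cell_line_ids=list(ids))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read an MSigDB-dialect GMT file (name, description, genes per line)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT format error at line {lineno}: fewer than 3 fields")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"GMT format error at line {lineno}: set {name!r} has no genes")
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r} at line {lineno}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning("gene set %s: %d duplicate genes removed", name, len(genes) - len(deduped))
            sets[name] = deduped
    return GeneSetCollection(sets=sets, source=str(path))


def filter_gene_sets(
    collection: GeneSetCollection,
    universe: list[str],
    min_size: int = 5,
) -> GeneSetCollection:
    """Intersect each set with the gene universe, keep sets of >= min_size.

    The size filter counts genes *after* intersection, mirroring how GSVA's
    ``min.sz`` behaves against the expression matrix it is given.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if not universe:
        raise ValueError("gene universe is empty")
    uni = set(universe)
    kept = {
        name: inter
        for name, genes in collection.sets.items()
        if len(inter := [g for g in genes if g in uni]) >= min_size
    }
    return GeneSetCollection(sets=kept, source=collection.source)


def minmax_normalize(
    matrix: PathwayScoreMatrix,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> PathwayScoreMatrix:
    """Per-pathway min–max scaling onto [0, 1].

    With ``stats=(row_min, row_max)`` the supplied statistics are applied
    instead of the matrix's own (the leak-free path: fit on training cell
    lines, apply to held-out columns, clipping to [0, 1]).
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    if matrix.values.shape[1] < 1:
        raise ValueError("need at least one cell line")
    if stats is None:
        lo = matrix.values.min(axis=1, keepdims=True)
        hi = matrix.values.max(axis=1, keepdims=True)
    else:
        lo = np.asarray(stats[0], dtype=np.float64).reshape(-1, 1)
        hi = np.asarray(stats[1], dtype=np.float64).reshape(-1, 1)
    span = hi - lo
    constant = (span == 0).ravel()
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant pathway row(s) mapped to zeros during normalization"
        )
    safe = np.where(span == 0, 1.0, span)
    out = (matrix.values - lo) / safe
    out[constant, :] = 0.0
    out = np.clip(out, 0.0, 1.0)
    return PathwayScoreMatrix(
        values=out,
        pathway_ids=list(matrix.pathway_ids),
        cell_line_ids=list(matrix.cell_line_ids),
        normalized=True,
        norm_stats=(lo.ravel().copy(), hi.ravel().copy()),
    )


def read_score_matrix(path: str | Path) -> PathwayScoreMatrix:
    """Read a CSV/TSV score matrix: first column pathway id, header cell lines."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicated pathway id(s): {dups}")
    if df.isna().any().any():
        row, col = next(zip(*np.where(df.isna().values)))
        raise ValueError(
            f"missing entry at pathway {df.index[row]!r}, cell line {df.columns[col]!r}"
        )
    return PathwayScoreMatrix(
        values=df.values.astype(np.float64),
        pathway_ids=[str(i) for i in df.index],
        cell_line_ids=[str(c) for c in df.columns],
    )


def write_score_matrix(matrix: PathwayScoreMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.DataFrame(matrix.values, index=matrix.pathway_ids, columns=matrix.cell_line_ids)
    df.index.name = "pathway"
    df.to_csv(path, sep=sep, float_format="%.17g")
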