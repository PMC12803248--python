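"""Gene assignment joining, UMI collapse, count-matrix construction and QC.

After demultiplexing, each annotated read carries its cell label and UMI in
the read ID; an external mapping/feature-assignment stage supplies the
read -> gene relation, consumed here as a plain two-column table.  Distinct
UMIs per (cell, gene) approximate molecule counts; the directional collapse
merges UMI pairs one mismatch apart when the putative parent's read count
is at least twice the child's minus one, absorbing PCR/sequencing-error
satellites into their parent molecule.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import scipy.io
import scipy.sparse as sp

from .demux import parse_annotated_id
from .schema import SchemaError


class MatrixFormatError(ValueError):
    """Raised when an on-disk matrix trio is internally inconsistent."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One observed (cell, gene, UMI) triple with its supporting read count."""

    cell_label: str
    gene_id: str
    umi: str
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")


def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def load_assignments(path: str | Path) -> dict[str, str]:
    """Read a ``read_id<TAB>gene_id`` table (gzip allowed).

    Duplicate read IDs are an error: one read maps to one feature.
    """
    table: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SchemaError(
                    f"{path}:{lineno}: expected 2 tab-separated fields"
                )
            read_id, gene_id = parts[0].strip(), parts[1].strip()
            if read_id in table:
                raise SchemaError(
                    f"{path}:{lineno}: duplicate read_id {read_id!r}"
                )
            table[read_id] = gene_id
    return table


def iter_annotated_ids(annotated_fastq: str | Path) -> Iterable[str]:
    """Yield the ID line (without '@') of each record in an annotated FASTQ."""
    with _open_text(annotated_fastq) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            fh.readline()  # sequence
            fh.readline()  # separator
            fh.readline()  # qualities
            yield header[1:].rstrip("\n").split()[0]


def join_assignments(
    annotated_ids: Iterable[str],
    assignments: Mapping[str, str],
    delimiter: str = "|",
) -> tuple[list[MoleculeRecord], int]:
    """Join annotated reads with their gene assignments.

    Reads without an assignment are dropped and counted; the remainder are
    aggregated by exact (cell, gene, UMI) triple.  Returns the aggregated
    records and the unassigned-read count.
    """
    counts: Counter = Counter()
    unassigned = 0
    for annotated_id in annotated_ids:
        original_id, cell_label, umi = parse_annotated_id(annotated_id, delimiter)
        gene_id = assignments.get(original_id)
        if gene_id is None:
            unassigned += 1
            continue
        counts[(cell_label, gene_id, umi)] += 1
    records = [
        MoleculeRecord(cell_label=c, gene_id=g, umi=u, read_count=n)
        for (c, g, u), n in counts.items()
    ]
    return records, unassigned


# ---------------------------------------------------------------------------
# UMI collapse
# ---------------------------------------------------------------------------

def _hamming1(a: str, b: str) -> bool:
    diff = 0
    for x, y in zip(a, b):
        if x != y:
            diff += 1
            if diff > 1:
                return False
    return diff == 1


def directional_cluster_count(umi_counts: Mapping[str, int]) -> int:
    """Number of molecule clusters under the directional-adjacency rule.

    UMIs are nodes; a directed edge u -> v exists when Hamming(u, v) = 1
    and reads(u) >= 2 * reads(v) - 1.  Starting from the highest-count
    unassigned UMI, all UMIs reachable along such edges join its cluster;
    repeat until every UMI is assigned.  Ties in read count break by UMI
    sequence so the result is deterministic.
    """
    if not umi_counts:
        return 0
    umis = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    lengths = {len(u) for u in umis}
    if len(lengths) > 1:
        raise ValueError(
            f"UMIs of unequal length within one (cell, gene) group: "
            f"lengths {sorted(lengths)}"
        )
    visited: set[str] = set()
    clusters = 0
    for seed in umis:
        if seed in visited:
            continue
        clusters += 1
        queue = [seed]
        visited.add(seed)
        while queue:
            u = queue.pop()
            cu = umi_counts[u]
            for v in umis:
                if v in visited:
                    continue
                if cu >= 2 * umi_counts[v] - 1 and _hamming1(u, v):
                    visited.add(v)
                    queue.append(v)
    return clusters


def collapse_umis(
    records: Iterable[MoleculeRecord],
    method: str = "directional",
) -> dict[tuple[str, str], int]:
    """Collapse UMIs within each (cell, gene) group into molecule counts.

    ``unique`` counts distinct UMI sequences; ``directional`` additionally
    merges likely-error UMIs into their parents (see
    :func:`directional_cluster_count`).  ``unique`` is an upper bound on
    ``directional`` for every group.
    """
    if method not in ("unique", "directional"):
        raise ValueError(f"unknown collapse method {method!r}")
    groups: dict[tuple[str, str], dict[str, int]] = defaultdict(dict)
    for rec in records:
        key = (rec.cell_label, rec.gene_id)
        groups[key][rec.umi] = groups[key].get(rec.umi, 0) + rec.read_count
    out: dict[tuple[str, str], int] = {}
    for key, umi_counts in groups.items():
        if method == "unique":
            lengths = {len(u) for u in umi_counts}
            if len(lengths) > 1:
                raise ValueError(
                    f"UMIs of unequal length in group {key}: {sorted(lengths)}"
                )
            out[key] = len(umi_counts)
        else:
            out[key] = directional_cluster_count(umi_counts)
    return out


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Sparse gene x cell molecule counts with name vectors.

    ``matrix`` is genes (rows) by cells (columns); names are sorted
    lexicographically at construction so the layout is order-invariant.
    """

    gene_names: list[str]
    cell_labels: list[str]
    matrix: sp.csr_matrix

    def __post_init__(self) -> None:
        n_genes, n_cells = self.matrix.shape
        if n_genes != len(self.gene_names) or n_cells != len(self.cell_labels):
            raise MatrixFormatError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_names)} genes x {len(self.cell_labels)} cells"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def total(self) -> int:
        return int(self.matrix.sum())

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def genes_per_cell_detected(self) -> np.ndarray:
        return np.asarray((self.matrix > 0).sum(axis=0)).ravel()

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.gene_names == other.gene_names
            and self.cell_labels == other.cell_labels
            and (self.matrix != other.matrix).nnz == 0
        )


def build_matrix(collapsed: Mapping[tuple[str, str], int]) -> CountMatrix:
    """Assemble per-(cell, gene) molecule counts into a sparse matrix.

    Gene and cell name vectors are sorted lexicographically, so any input
    ordering yields the identical matrix.
    """
    genes = sorted({g for _, g in collapsed})
    cells = sorted({c for c, _ in collapsed})
    gene_idx = {g: i for i, g in enumerate(genes)}
    cell_idx = {c: i for i, c in enumerate(cells)}
    rows, cols, data = [], [], []
    for (cell, gene), n in collapsed.items():
        if n < 1:
            continue
        rows.append(gene_idx[gene])
        cols.append(cell_idx[cell])
        data.append(n)
    mat = sp.coo_matrix(
        (data, (rows, cols)), shape=(len(genes), len(cells)), dtype=np.int64
    ).tocsr()
    mat.sum_duplicates()
    return CountMatrix(gene_names=genes, cell_labels=cells, matrix=mat)


def count_matrix_from_fastq(
    annotated_fastq: str | Path,
    assignments: Mapping[str, str],
    method: str = "directional",
    delimiter: str = "|",
) -> tuple[CountMatrix, int]:
    """Annotated FASTQ + gene assignments -> count matrix.

    Convenience composition of :func:`join_assignments`,
    :func:`collapse_umis` and :func:`build_matrix`; returns the matrix and
    the number of unassigned reads.
    """
    records, unassigned = join_assignments(
        iter_annotated_ids(annotated_fastq), assignments, delimiter
    )
    collapsed = collapse_umis(records, method)
    return build_matrix(collapsed), unassigned


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Accounting for the three-step nucleus/gene QC filter."""

    min_umis: int
    max_umis: int
    min_cells_per_gene: int
    max_mito_frac: float
    input_shape: tuple[int, int] = (0, 0)
    output_shape: tuple[int, int] = (0, 0)
    cells_removed_low_umi: int = 0
    genes_removed_low_cells: int = 0
    cells_removed_high_mito: int = 0
    cells_removed_high_umi: int = 0

    def to_dict(self) -> dict:
        return {
            "thresholds": {
                "min_umis": self.min_umis,
                "max_umis": self.max_umis,
                "min_cells_per_gene": self.min_cells_per_gene,
                "max_mito_frac": self.max_mito_frac,
            },
            "input_shape": list(self.input_shape),
            "output_shape": list(self.output_shape),
            "cells_removed_low_umi": self.cells_removed_low_umi,
            "genes_removed_low_cells": self.genes_removed_low_cells,
            "cells_removed_high_mito": self.cells_removed_high_mito,
            "cells_removed_high_umi": self.cells_removed_high_umi,
        }


def qc_filter(
    matrix: CountMatrix,
    mito_gene_set: Iterable[str] = (),
    min_umis: int = 500,
    max_umis: int = 15000,
    min_cells_per_gene: int = 10,
    max_mito_frac: float = 0.05,
) -> tuple[CountMatrix, QCReport]:
    """Apply the standard single-nucleus QC filters, in a fixed order.

    1. Drop cells with total UMIs strictly below ``min_umis``.
    2. Drop genes detected in fewer than ``min_cells_per_gene`` of the
       remaining cells.
    3. Drop cells whose mitochondrial UMI fraction exceeds
       ``max_mito_frac`` or whose total UMIs exceed ``max_umis``; both are
       computed on the matrix entering this step.

    The defaults (500 / 15000 UMIs, 10 cells, 5% mito) are conventional
    for single-nucleus data, where high mitochondrial content flags
    cytoplasmic contamination or damage.  Outcomes are order-sensitive, so
    the order is fixed and recorded in the report.
    """
    if min_umis <= 0 or max_umis <= 0 or min_cells_per_gene <= 0 or max_mito_frac <= 0:
        raise SchemaError("QC thresholds must be positive")
    report = QCReport(
        min_umis=min_umis,
        max_umis=max_umis,
        min_cells_per_gene=min_cells_per_gene,
        max_mito_frac=max_mito_frac,
        input_shape=matrix.shape,
    )
    mito = set(mito_gene_set)

    # step 1: low-UMI cells
    totals = matrix.cell_totals()
    keep_cells = totals >= min_umis
    report.cells_removed_low_umi = int((~keep_cells).sum())
    m = matrix.matrix[:, keep_cells]
    cells = [c for c, k in zip(matrix.cell_labels, keep_cells) if k]

    # step 2: genes detected in too few remaining cells
    detected_in = np.asarray((m > 0).sum(axis=1)).ravel()
    keep_genes = detected_in >= min_cells_per_gene
    report.genes_removed_low_cells = int((~keep_genes).sum())
    m = m[keep_genes, :]
    genes = [g for g, k in zip(matrix.gene_names, keep_genes) if k]

    # step 3: mito fraction and high-UMI ceiling, on the post-step-2 matrix
    totals3 = np.asarray(m.sum(axis=0)).ravel()
    mito_rows = np.fromiter((g in mito for g in genes), dtype=bool, count=len(genes))
    if mito_rows.any():
        mito_totals = np.asarray(m[mito_rows, :].sum(axis=0)).ravel()
    else:
        mito_totals = np.zeros_like(totals3)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals3 > 0, mito_totals / np.maximum(totals3, 1), 0.0)
    high_mito = mito_frac > max_mito_frac
    high_umi = (totals3 > max_umis) & ~high_mito
    report.cells_removed_high_mito = int(high_mito.sum())
    report.cells_removed_high_umi = int(high_umi.sum())
    keep3 = ~(high_mito | high_umi)
    m = m[:, keep3]
    cells = [c for c, k in zip(cells, keep3) if k]

    out = CountMatrix(gene_names=genes, cell_labels=cells, matrix=m.tocsr())
    report.output_shape = out.shape
    return out, report


# ---------------------------------------------------------------------------
# MatrixMarket trio I/O
# ---------------------------------------------------------------------------

def write_mtx(matrix: CountMatrix, outdir: str | Path) -> None:
    """Write ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(outdir / "matrix.mtx"), matrix.matrix.tocoo(), field="integer"
    )
    with open(outdir / "features.tsv", "w") as fh:
        for g in matrix.gene_names:
            fh.write(g + "\n")
    with open(outdir / "barcodes.tsv", "w") as fh:
        for c in matrix.cell_labels:
            fh.write(c + "\n")


def read_mtx(outdir: str | Path) -> CountMatrix:
    """Read a trio written by :func:`write_mtx`; inverse up to matrix layout."""
    outdir = Path(outdir)
    try:
        mat = scipy.io.mmread(str(outdir / "matrix.mtx"))
    except Exception as exc:
        raise MatrixFormatError(f"cannot read {outdir / 'matrix.mtx'}: {exc}") from exc
    mat = sp.csr_matrix(mat, dtype=np.int64)
    with open(outdir / "features.tsv") as fh:
        genes = [line.rstrip("\n") for line in fh if line.strip()]
    with open(outdir / "barcodes.tsv") as fh:
        cells = [line.rstrip("\n") for line in fh if line.strip()]
    if mat.shape != (len(genes), len(cells)):
        raise MatrixFormatError(
            f"matrix dims {mat.shape} do not match {len(genes)} features "
            f"x {len(cells)} barcodes"
        )
    return CountMatrix(gene_names=genes, cell_labels=cells, matrix=mat)


def write_qc_report(report: QCReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")
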