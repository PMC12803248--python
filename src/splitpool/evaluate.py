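"""Scoring of pipeline output against simulated ground truth."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .counting import CountMatrix, iter_annotated_ids
from .demux import parse_annotated_id
from .simulate import SyntheticTruth


@dataclass
class EvaluationReport:
    """How faithfully the pipeline recovered the simulated library.

    ``read_assignment_accuracy`` is the fraction of genuine (non-junk)
    reads assigned to their true cell; a discarded read counts as not
    assigned.  ``junk_false_assignment_rate`` is the fraction of junk
    reads that nonetheless received a cell.  ``cell_recovery`` is the
    fraction of truth cells represented in the final output.
    ``matrix_entry_agreement`` compares produced and truth matrices over
    the union of their nonzero entries.
    """

    reads_genuine: int
    reads_junk: int
    reads_correctly_assigned: int
    junk_assigned: int
    cells_truth: int
    cells_recovered: int
    matrix_entries_union: int
    matrix_entries_agreeing: int
    matrix_exact: bool

    @property
    def read_assignment_accuracy(self) -> float:
        return (
            self.reads_correctly_assigned / self.reads_genuine
            if self.reads_genuine
            else 1.0
        )

    @property
    def junk_false_assignment_rate(self) -> float:
        return self.junk_assigned / self.reads_junk if self.reads_junk else 0.0

    @property
    def cell_recovery(self) -> float:
        return self.cells_recovered / self.cells_truth if self.cells_truth else 1.0

    @property
    def matrix_entry_agreement(self) -> float:
        return (
            self.matrix_entries_agreeing / self.matrix_entries_union
            if self.matrix_entries_union
            else 1.0
        )

    def to_dict(self) -> dict:
        return {
            "reads_genuine": self.reads_genuine,
            "reads_junk": self.reads_junk,
            "reads_correctly_assigned": self.reads_correctly_assigned,
            "read_assignment_accuracy": self.read_assignment_accuracy,
            "junk_assigned": self.junk_assigned,
            "junk_false_assignment_rate": self.junk_false_assignment_rate,
            "cells_truth": self.cells_truth,
            "cells_recovered": self.cells_recovered,
            "cell_recovery": self.cell_recovery,
            "matrix_entries_union": self.matrix_entries_union,
            "matrix_entries_agreeing": self.matrix_entries_agreeing,
            "matrix_entry_agreement": self.matrix_entry_agreement,
            "matrix_exact": self.matrix_exact,
        }


def _matrix_entries(m: CountMatrix) -> dict[tuple[str, str], int]:
    coo = m.matrix.tocoo()
    return {
        (m.gene_names[i], m.cell_labels[j]): int(v)
        for i, j, v in zip(coo.row, coo.col, coo.data)
    }


def evaluate(
    assigned_labels: Mapping[str, str],
    matrix: CountMatrix | None,
    truth: SyntheticTruth,
    retained_cells: Iterable[str] | None = None,
) -> EvaluationReport:
    """Score demultiplexing output and a count matrix against truth.

    ``assigned_labels`` maps original read IDs to the cell label the
    pipeline assigned (reads absent from the map were discarded).  The
    label namespaces must be comparable: if pipeline and truth labels are
    both non-empty but share no cell, the comparison is refused.
    """
    genuine = truth.genuine_reads()
    truth_cells = set(truth.cells)
    assigned_cells = set(assigned_labels.values())
    if assigned_cells and truth_cells and not (assigned_cells & truth_cells):
        raise ValueError(
            "cell-label namespace mismatch: no overlap between pipeline "
            "labels and truth labels (sublibrary tag applied on one side "
            "only?)"
        )

    correct = sum(
        1 for tr in genuine if assigned_labels.get(tr.read_id) == tr.cell_label
    )
    junk_assigned = sum(
        1 for tr in truth.reads if tr.is_junk and tr.read_id in assigned_labels
    )

    if retained_cells is not None:
        recovered = truth_cells & set(retained_cells)
    elif matrix is not None:
        recovered = truth_cells & set(matrix.cell_labels)
    else:
        recovered = truth_cells & assigned_cells

    if matrix is not None:
        prod = _matrix_entries(matrix)
        ref = _matrix_entries(truth.truth_matrix)
        union = set(prod) | set(ref)
        agreeing = sum(1 for k in union if prod.get(k) == ref.get(k))
        exact = matrix.equals(truth.truth_matrix)
        n_union, n_agree = len(union), agreeing
    else:
        n_union, n_agree, exact = 0, 0, False

    return EvaluationReport(
        reads_genuine=len(genuine),
        reads_junk=truth.junk_count,
        reads_correctly_assigned=correct,
        junk_assigned=junk_assigned,
        cells_truth=len(truth_cells),
        cells_recovered=len(recovered),
        matrix_entries_union=n_union,
        matrix_entries_agreeing=n_agree,
        matrix_exact=exact,
    )


def assigned_labels_from_fastq(
    annotated_fastq: str | Path, delimiter: str = "|"
) -> dict[str, str]:
    """Recover the read-ID -> cell-label map from an annotated FASTQ."""
    out: dict[str, str] = {}
    for annotated_id in iter_annotated_ids(annotated_fastq):
        original, label, _ = parse_annotated_id(annotated_id, delimiter)
        out[original] = label
    return out


def write_evaluation(report: EvaluationReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")
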