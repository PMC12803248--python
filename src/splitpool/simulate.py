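"""Ground-truthed synthetic split-pool libraries, and evaluation against truth.

The simulator emulates the structure demultiplexing depends on — three 8-nt
well barcodes at fixed read-2 offsets separated by static linkers, a UMI,
per-base substitution errors, and unparseable "junk" reads — while recording
per-read truth (cell, gene, UMI, injected errors) and the ground-truth
gene x cell molecule matrix.  It makes no attempt at transcriptome realism
(no splicing, ambient RNA or doublets); it exists to give the pipeline an
exact oracle.

Everything is drawn from one seeded generator, so identical parameters and
seed give byte-identical FASTQ and truth files.
"""

from __future__ import annotations

import csv
import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .counting import CountMatrix, build_matrix, read_mtx, write_mtx
from .schema import (
    BarcodeWhitelist,
    DemuxConfig,
    ReadLayout,
    RunConfig,
    hamming,
    write_whitelist,
)

BASES = "ACGT"

#: plate rows, for well naming (A1..H12)
_ROWS = "ABCDEFGH"


def _well_name(i: int) -> str:
    return f"{_ROWS[i // 12]}{i % 12 + 1}"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def random_whitelist(
    rng: np.random.Generator,
    round_id: int,
    n_wells: int,
    barcode_length: int = 8,
    min_distance: int = 3,
) -> BarcodeWhitelist:
    """Draw ``n_wells`` random barcodes with pairwise Hamming distance at
    least ``min_distance`` (greedy rejection sampling).

    ``min_distance`` 3 guarantees unambiguous single-substitution
    correction; 5 guarantees it at tolerance 2.
    """
    chosen: list[str] = []
    attempts = 0
    while len(chosen) < n_wells:
        attempts += 1
        if attempts > 200_000:
            raise RuntimeError(
                f"cannot place {n_wells} barcodes of length {barcode_length} "
                f"at min distance {min_distance}"
            )
        cand = _random_seq(rng, barcode_length)
        if all(hamming(cand, c) >= min_distance for c in chosen):
            chosen.append(cand)
    entries = [(_well_name(i), seq) for i, seq in enumerate(chosen)]
    return BarcodeWhitelist(
        round_id=round_id, entries=entries, barcode_length=barcode_length
    )


@dataclass
class SimulationParams:
    """Study conditions for one synthetic library.

    ``wells_used`` mirrors the plate design: 48 round-1 wells (in-well
    reverse transcription) and 96 wells each for the two ligation rounds.
    ``reads_per_cell`` is either a fixed integer or a negative-binomial
    draw when ``reads_per_cell_dispersion`` is set (mean ``reads_per_cell``,
    shape ``dispersion``).  ``fixed_barcode_errors`` switches from i.i.d.
    per-base substitution noise to exactly that many substitutions placed
    in one randomly chosen barcode segment of every read — the regime used
    to probe the correction tolerance directly.
    """

    n_cells: int = 100
    wells_used: tuple[int, int, int] = (48, 96, 96)
    n_genes: int = 50
    transcript_length: int = 500
    reads_per_cell: int = 100
    reads_per_cell_dispersion: float | None = None
    molecules_per_cell: int = 50
    substitution_error_rate: float = 0.0
    error_segments: str = "all"  # "all" | "barcodes"
    fixed_barcode_errors: int | None = None
    junk_read_fraction: float = 0.0
    seed: int = 0
    read1_length: int = 106
    umi_length: int = 10
    barcode_length: int = 8
    linker_length: int = 30
    whitelist_min_distance: int = 3
    layout: ReadLayout | None = None

    def __post_init__(self) -> None:
        for p in (self.substitution_error_rate, self.junk_read_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.error_segments not in ("all", "barcodes"):
            raise ValueError("error_segments must be 'all' or 'barcodes'")
        if self.transcript_length < self.read1_length:
            raise ValueError("transcript_length must cover read1_length")


@dataclass
class TruthRead:
    """Ground truth for one simulated read pair."""

    read_id: str
    is_junk: bool
    cell_label: str = ""
    gene_id: str = ""
    umi: str = ""
    errors: str = ""  # "segment:pos" entries, ';'-joined; read-2 coords


@dataclass
class SyntheticTruth:
    """Everything needed to score pipeline output against the simulation."""

    reads: list[TruthRead]
    cells: list[str]
    truth_matrix: CountMatrix
    reads_per_cell: dict[str, int]
    molecules_per_cell: dict[str, int]
    junk_count: int

    def genuine_reads(self) -> list[TruthRead]:
        return [r for r in self.reads if not r.is_junk]


@dataclass
class SimulatedLibrary:
    """In-memory result of :func:`simulate_library`."""

    params: SimulationParams
    layout: ReadLayout
    whitelists: list[BarcodeWhitelist]
    r1_records: list[tuple[str, str, str]]  # (id, seq, qual)
    r2_records: list[tuple[str, str, str]]
    truth: SyntheticTruth
    assignments: dict[str, str]  # read_id -> gene_id, genuine reads only


def _inject_iid_errors(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    segments: Sequence[tuple[str, int, int]],
) -> tuple[str, list[str]]:
    """Substitute each base of the listed (name, start, end) windows
    independently with probability ``rate``; return new seq and error tags."""
    if rate == 0.0:
        return seq, []
    chars = list(seq)
    tags: list[str] = []
    for name, start, end in segments:
        hits = np.nonzero(rng.random(end - start) < rate)[0]
        for off in hits:
            pos = start + int(off)
            old = chars[pos]
            chars[pos] = rng.choice([b for b in BASES if b != old])
            tags.append(f"{name}:{pos}")
    return "".join(chars), tags


def _inject_fixed_barcode_errors(
    rng: np.random.Generator,
    seq: str,
    layout: ReadLayout,
    k: int,
) -> tuple[str, list[str]]:
    """Place exactly ``k`` substitutions inside one randomly chosen barcode
    segment."""
    kind = ("bc1", "bc2", "bc3")[rng.integers(3)]
    seg = layout.find(kind)
    positions = rng.choice(seg.length, size=k, replace=False)
    chars = list(seq)
    tags = []
    for off in sorted(int(p) for p in positions):
        pos = seg.start + off
        old = chars[pos]
        chars[pos] = rng.choice([b for b in BASES if b != old])
        tags.append(f"{kind}:{pos}")
    return "".join(chars), tags


def simulate_library(params: SimulationParams) -> SimulatedLibrary:
    """Generate one paired-end split-pool library with full ground truth.

    Read 2 is assembled as UMI + bc3 + linker_a + bc2 + linker_b + bc1
    (94 nt with the defaults); read 1 carries a fragment of the cell's
    assigned transcript.  Cells are distinct well triples sampled without
    replacement, so barcode collisions cannot confound evaluation.  The
    truth matrix is the unique-UMI collapse of the simulated molecules.
    """
    rng = np.random.default_rng(params.seed)
    bl = params.barcode_length

    whitelists = [
        random_whitelist(
            rng, r + 1, params.wells_used[r], bl, params.whitelist_min_distance
        )
        for r in range(3)
    ]
    layout = params.layout
    if layout is None:
        layout = ReadLayout.default(
            linker_a_sequence=_random_seq(rng, params.linker_length),
            linker_b_sequence=_random_seq(rng, params.linker_length),
            umi_length=params.umi_length,
            barcode_length=bl,
        )

    n_combos = int(np.prod(params.wells_used))
    if params.n_cells > n_combos:
        raise ValueError(
            f"{params.n_cells} cells requested but only {n_combos} distinct "
            "well combinations exist"
        )
    combo_idx = rng.choice(n_combos, size=params.n_cells, replace=False)
    w2n, w3n = params.wells_used[1], params.wells_used[2]
    cell_wells = []
    for idx in combo_idx:
        i1, rem = divmod(int(idx), w2n * w3n)
        i2, i3 = divmod(rem, w3n)
        cell_wells.append(
            (
                whitelists[0].entries[i1],
                whitelists[1].entries[i2],
                whitelists[2].entries[i3],
            )
        )
    cell_labels = [f"{w1}.{w2}.{w3}" for (w1, _), (w2, _), (w3, _) in cell_wells]

    transcripts = [_random_seq(rng, params.transcript_length) for _ in range(params.n_genes)]
    gene_names = [f"gene{g:04d}" for g in range(params.n_genes)]

    # molecules per cell: (gene index, umi)
    molecules: list[list[tuple[int, str]]] = []
    for _ in range(params.n_cells):
        mols = [
            (int(rng.integers(params.n_genes)), _random_seq(rng, params.umi_length))
            for _ in range(params.molecules_per_cell)
        ]
        molecules.append(mols)

    if params.reads_per_cell_dispersion is not None:
        shape = params.reads_per_cell_dispersion
        p = shape / (shape + params.reads_per_cell)
        reads_per_cell = rng.negative_binomial(shape, p, size=params.n_cells)
        reads_per_cell = np.maximum(reads_per_cell, 1)
    else:
        reads_per_cell = np.full(params.n_cells, params.reads_per_cell)

    err_segments_all = [
        (s.kind, s.start, s.end) for s in layout.segments
    ]
    err_segments_bc = [
        (s.kind, s.start, s.end)
        for s in layout.segments
        if s.kind in ("bc1", "bc2", "bc3")
    ]
    error_windows = (
        err_segments_bc if params.error_segments == "barcodes" else err_segments_all
    )

    qual1 = "I" * params.read1_length
    qual2 = "I" * layout.min_read2_length

    r1_records: list[tuple[str, str, str]] = []
    r2_records: list[tuple[str, str, str]] = []
    truth_reads: list[TruthRead] = []
    assignments: dict[str, str] = {}
    reads_per_cell_truth: dict[str, int] = {}
    junk_count = 0
    read_no = 0

    seg_by_kind = {s.kind: s for s in layout.segments}

    for ci in range(params.n_cells):
        label = cell_labels[ci]
        (w1, s1), (w2, s2), (w3, s3) = cell_wells[ci]
        n_reads = int(reads_per_cell[ci])
        reads_per_cell_truth[label] = 0
        for _ in range(n_reads):
            read_id = f"read{read_no:07d}"
            read_no += 1
            if params.junk_read_fraction > 0 and rng.random() < params.junk_read_fraction:
                junk_count += 1
                r1_records.append(
                    (read_id, _random_seq(rng, params.read1_length), qual1)
                )
                r2_records.append(
                    (read_id, _random_seq(rng, layout.min_read2_length), qual2)
                )
                truth_reads.append(TruthRead(read_id=read_id, is_junk=True))
                continue
            reads_per_cell_truth[label] += 1
            gi, umi = molecules[ci][int(rng.integers(len(molecules[ci])))]
            # assemble read 2 segment by segment
            chars = ["A"] * layout.min_read2_length
            pieces = {
                "umi": umi, "bc3": s3, "bc2": s2, "bc1": s1,
                "linker_a": layout.linker_a_sequence,
                "linker_b": layout.linker_b_sequence,
            }
            for kind, piece in pieces.items():
                seg = seg_by_kind[kind]
                chars[seg.start : seg.end] = piece
            r2 = "".join(chars)
            if params.fixed_barcode_errors is not None:
                r2, tags = _inject_fixed_barcode_errors(
                    rng, r2, layout, params.fixed_barcode_errors
                )
            else:
                r2, tags = _inject_iid_errors(
                    rng, r2, params.substitution_error_rate, error_windows
                )
            start = int(rng.integers(params.transcript_length - params.read1_length + 1))
            r1 = transcripts[gi][start : start + params.read1_length]
            r1_records.append((read_id, r1, qual1))
            r2_records.append((read_id, r2, qual2))
            truth_reads.append(
                TruthRead(
                    read_id=read_id,
                    is_junk=False,
                    cell_label=label,
                    gene_id=gene_names[gi],
                    umi=umi,
                    errors=";".join(tags),
                )
            )
            assignments[read_id] = gene_names[gi]

    # ground-truth matrix: unique-UMI collapse of the molecule lists,
    # restricted to molecules actually observed in at least one read
    observed: dict[tuple[str, str], set[str]] = {}
    for tr in truth_reads:
        if tr.is_junk:
            continue
        observed.setdefault((tr.cell_label, tr.gene_id), set()).add(tr.umi)
    truth_matrix = build_matrix({k: len(v) for k, v in observed.items()})
    mols_per_cell: dict[str, int] = {label: 0 for label in cell_labels}
    for (c, _), umis in observed.items():
        mols_per_cell[c] += len(umis)

    truth = SyntheticTruth(
        reads=truth_reads,
        cells=cell_labels,
        truth_matrix=truth_matrix,
        reads_per_cell=reads_per_cell_truth,
        molecules_per_cell=mols_per_cell,
        junk_count=junk_count,
    )
    return SimulatedLibrary(
        params=params,
        layout=layout,
        whitelists=whitelists,
        r1_records=r1_records,
        r2_records=r2_records,
        truth=truth,
        assignments=assignments,
    )


# ---------------------------------------------------------------------------
# on-disk form
# ---------------------------------------------------------------------------

def _write_fastq(records, path: str | Path) -> None:
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_library(
    lib: SimulatedLibrary, outdir: str | Path, compress: bool = False
) -> dict[str, Path]:
    """Write FASTQ pair, whitelists, run config, gene assignments and the
    truth tables under ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    ext = ".fastq.gz" if compress else ".fastq"
    paths = {
        "r1": outdir / f"r1{ext}",
        "r2": outdir / f"r2{ext}",
        "assignments": outdir / "assignments.tsv",
        "config": outdir / "config.yaml",
        "truth_reads": truth_dir / "reads.tsv",
        "truth_matrix": truth_dir,
    }
    _write_fastq(lib.r1_records, paths["r1"])
    _write_fastq(lib.r2_records, paths["r2"])
    for wl in lib.whitelists:
        p = outdir / f"whitelist_round{wl.round_id}.tsv"
        write_whitelist(wl, p)
        paths[f"whitelist{wl.round_id}"] = p
    with open(paths["assignments"], "w") as fh:
        for rid, gene in lib.assignments.items():
            fh.write(f"{rid}\t{gene}\n")
    run_config = RunConfig(
        whitelist_paths={
            r: f"whitelist_round{r}.tsv" for r in (1, 2, 3)
        },
        layout=lib.layout,
        demux=DemuxConfig(),
    )
    run_config.to_yaml(paths["config"])
    with open(paths["truth_reads"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["read_id", "is_junk", "cell_label", "gene_id", "umi", "errors"])
        for tr in lib.truth.reads:
            w.writerow(
                [tr.read_id, int(tr.is_junk), tr.cell_label, tr.gene_id,
                 tr.umi, tr.errors]
            )
    write_mtx(lib.truth.truth_matrix, truth_dir)
    return paths


def load_truth_reads(path: str | Path) -> list[TruthRead]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                TruthRead(
                    read_id=row["read_id"],
                    is_junk=bool(int(row["is_junk"])),
                    cell_label=row["cell_label"],
                    gene_id=row["gene_id"],
                    umi=row["umi"],
                    errors=row["errors"],
                )
            )
    return out


def load_truth(truth_dir: str | Path) -> SyntheticTruth:
    """Reload the truth tables written by :func:`write_library`.

    Per-cell read/molecule totals are recomputed from the read table.
    """
    truth_dir = Path(truth_dir)
    reads = load_truth_reads(truth_dir / "reads.tsv")
    matrix = read_mtx(truth_dir)
    cells = sorted({r.cell_label for r in reads if not r.is_junk})
    rpc: dict[str, int] = {}
    for r in reads:
        if not r.is_junk:
            rpc[r.cell_label] = rpc.get(r.cell_label, 0) + 1
    mols: dict[str, set] = {}
    for r in reads:
        if not r.is_junk:
            mols.setdefault(r.cell_label, set()).add((r.gene_id, r.umi))
    return SyntheticTruth(
        reads=reads,
        cells=cells,
        truth_matrix=matrix,
        reads_per_cell=rpc,
        molecules_per_cell={c: len(s) for c, s in mols.items()},
        junk_count=sum(r.is_junk for r in reads),
    )
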