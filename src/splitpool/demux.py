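"""Barcode position learning, extraction, correction and parallel streaming.

The demultiplexer slices read 2 at the offsets given by a
:class:`~splitpool.schema.ReadLayout` (optionally learned from the data via
the static linker sequences), corrects each 8-nt barcode against its round's
whitelist within an edit tolerance ``e``, and appends the corrected cell
label plus UMI to the read-1 identifier.  Reads lacking a complete,
correctable barcode set are discarded with a reason.

Input is processed in consecutive bins of ``bin_size`` read pairs; bins are
dispatched to worker processes and their outputs concatenated in index
order, so the merged output is byte-identical for any thread count.
"""

from __future__ import annotations

import gzip
import itertools
import json
from collections import Counter
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .schema import (
    BarcodeWhitelist,
    DemuxConfig,
    ReadLayout,
    SchemaError,
    Segment,
    SEGMENT_KINDS,
)

try:
    import edlib
except ImportError:  # levenshtein metric then unavailable
    edlib = None

FAIL_REASONS = (
    "read_too_short",
    "no_match_round1",
    "no_match_round2",
    "no_match_round3",
    "ambiguous_round1",
    "ambiguous_round2",
    "ambiguous_round3",
    "umi_invalid",
)


class DemuxError(RuntimeError):
    """Raised on malformed or inconsistent FASTQ input."""


class LayoutLearningError(RuntimeError):
    """Raised when linker anchors cannot be located in the sampled reads."""


def hamming_n(observed: str, reference: str) -> int:
    """Substitution count; any character pair that is not an exact match
    counts, so 'N' mismatches every base."""
    if len(observed) != len(reference):
        raise ValueError("hamming_n requires equal lengths")
    return sum(a != b for a, b in zip(observed, reference))


# ---------------------------------------------------------------------------
# barcode correction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrectionResult:
    """Outcome of matching one observed barcode against a whitelist."""

    status: str  # "match" | "no_match" | "ambiguous"
    well_id: str | None = None
    corrected_seq: str | None = None
    distance: int | None = None


_NO_MATCH = CorrectionResult("no_match")
_AMBIGUOUS = CorrectionResult("ambiguous")


def correct_barcode(
    observed: str,
    whitelist: BarcodeWhitelist,
    e: int,
    metric: str = "hamming",
) -> CorrectionResult:
    """Match ``observed`` to the unique whitelist entry within distance ``e``.

    Exhaustive reference implementation: computes the distance to every
    entry.  An exact hit returns that entry at distance 0; otherwise the
    unique entry at minimal distance <= e wins; a tie at the minimal
    qualifying distance is ``ambiguous``; no entry within ``e`` is
    ``no_match``.  'N' counts as a mismatch against every base.

    The streaming pipeline uses :class:`BarcodeCorrector`, a precomputed
    lookup table with identical semantics.
    """
    if metric == "hamming":
        if len(observed) != whitelist.barcode_length:
            raise ValueError(
                f"observed length {len(observed)} != barcode length "
                f"{whitelist.barcode_length}"
            )
        dist = hamming_n
    elif metric == "levenshtein":
        if edlib is None:
            raise RuntimeError("edlib is required for the levenshtein metric")
        def dist(a: str, b: str) -> int:
            d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
            return d
    else:
        raise ValueError(f"unknown metric {metric!r}")

    best_d: int | None = None
    best: list[tuple[str, str]] = []
    for well, seq in whitelist.entries:
        d = dist(observed, seq)
        if best_d is None or d < best_d:
            best_d, best = d, [(well, seq)]
        elif d == best_d:
            best.append((well, seq))
    if best_d is None or best_d > e:
        return _NO_MATCH
    if len(best) > 1:
        return _AMBIGUOUS
    well, seq = best[0]
    return CorrectionResult("match", well, seq, best_d)


def _substitution_mutants(seq: str, dist: int, alphabet: str = "ACGTN") -> Iterator[str]:
    """All strings at Hamming distance exactly ``dist`` from ``seq`` over
    ``alphabet`` (N included: sequencers emit it and it must stay reachable)."""
    positions = range(len(seq))
    for pos_combo in itertools.combinations(positions, dist):
        choices = []
        for p in pos_combo:
            choices.append([c for c in alphabet if c != seq[p]])
        for repl in itertools.product(*choices):
            chars = list(seq)
            for p, c in zip(pos_combo, repl):
                chars[p] = c
            yield "".join(chars)


class BarcodeCorrector:
    """Constant-time barcode correction via a precomputed mutation table.

    For the Hamming metric with small ``e`` every sequence within distance
    ``e`` of a whitelist entry is enumerated up front and mapped to
    ``(distance, candidate entries)``; lookup is then a single dict access.
    Falls back to the exhaustive scan for the levenshtein metric or large
    ``e``.
    """

    #: table construction is worthwhile up to this tolerance (8-mers: ~50k keys)
    MAX_TABLE_E = 2

    def __init__(self, whitelist: BarcodeWhitelist, e: int, metric: str = "hamming"):
        self.whitelist = whitelist
        self.e = e
        self.metric = metric
        self._table: dict[str, CorrectionResult] | None = None
        if metric == "hamming" and e <= self.MAX_TABLE_E:
            self._table = self._build_table()

    def _build_table(self) -> dict[str, CorrectionResult]:
        # seq -> (best distance, entries at that distance)
        hits: dict[str, tuple[int, list[tuple[str, str]]]] = {}
        for well, seq in self.whitelist.entries:
            for d in range(self.e + 1):
                for mutant in _substitution_mutants(seq, d):
                    cur = hits.get(mutant)
                    if cur is None or d < cur[0]:
                        hits[mutant] = (d, [(well, seq)])
                    elif d == cur[0]:
                        cur[1].append((well, seq))
        table: dict[str, CorrectionResult] = {}
        for mutant, (d, entries) in hits.items():
            if len(entries) > 1:
                table[mutant] = _AMBIGUOUS
            else:
                well, seq = entries[0]
                table[mutant] = CorrectionResult("match", well, seq, d)
        return table

    def correct(self, observed: str) -> CorrectionResult:
        if self._table is not None:
            return self._table.get(observed, _NO_MATCH)
        return correct_barcode(observed, self.whitelist, self.e, self.metric)


# ---------------------------------------------------------------------------
# per-read extraction
# ---------------------------------------------------------------------------

@dataclass
class RoundCall:
    """Extraction/correction outcome for one barcoding round of one read."""

    observed_seq: str | None = None
    corrected_well_id: str | None = None
    corrected_seq: str | None = None
    distance_used: int | None = None


@dataclass
class BarcodeCall:
    """Full extraction result for one read 2."""

    status: str  # "pass" | "fail"
    fail_reason: str = ""
    rounds: dict[int, RoundCall] = field(default_factory=dict)
    umi: str = ""

    @property
    def cell_wells(self) -> tuple[str, str, str]:
        return (
            self.rounds[1].corrected_well_id,
            self.rounds[2].corrected_well_id,
            self.rounds[3].corrected_well_id,
        )


@dataclass(frozen=True)
class CellLabel:
    """Corrected well identity triple naming one cell/nucleus.

    Rendered dot-joined (``A1.B5.C9``); an optional sublibrary tag is
    appended (``A1.B5.C9.S1``) so labels stay unique when matrices from
    separately indexed sublibraries are merged.
    """

    bc1_well: str
    bc2_well: str
    bc3_well: str
    sublibrary_id: str | None = None

    def render(self) -> str:
        parts = [self.bc1_well, self.bc2_well, self.bc3_well]
        if self.sublibrary_id is not None:
            parts.append(self.sublibrary_id)
        return ".".join(parts)

    def __str__(self) -> str:
        return self.render()


def extract_call(
    read2_sequence: str,
    layout: ReadLayout,
    correctors: dict[int, BarcodeCorrector],
) -> BarcodeCall:
    """Slice read 2 at the layout offsets and correct the three barcodes.

    Failure reasons, in priority order: ``read_too_short`` when the read
    does not cover the layout; the first round (1, 2, 3) with no acceptable
    or a tied correction; ``umi_invalid`` when the UMI contains 'N' (UMIs
    are taken verbatim and never corrected).
    """
    call = BarcodeCall(status="fail")
    if len(read2_sequence) < layout.min_read2_length:
        call.fail_reason = "read_too_short"
        return call
    for round_id in (1, 2, 3):
        seg = layout.barcode_segment(round_id)
        observed = read2_sequence[seg.start : seg.end]
        rc = RoundCall(observed_seq=observed)
        call.rounds[round_id] = rc
        res = correctors[round_id].correct(observed)
        if res.status == "match":
            rc.corrected_well_id = res.well_id
            rc.corrected_seq = res.corrected_seq
            rc.distance_used = res.distance
        else:
            call.fail_reason = f"{res.status}_round{round_id}"
            return call
    umi_seg = layout.find("umi")
    umi = read2_sequence[umi_seg.start : umi_seg.end]
    call.umi = umi
    if "N" in umi:
        call.fail_reason = "umi_invalid"
        return call
    call.status = "pass"
    call.fail_reason = ""
    return call


# ---------------------------------------------------------------------------
# read-1 annotation
# ---------------------------------------------------------------------------

@dataclass
class AnnotatedRead:
    """Read-1 record whose ID token carries the cell label and UMI."""

    original_id: str
    annotated_id: str
    sequence: str
    qualities: str

    def to_fastq(self) -> str:
        return f"@{self.annotated_id}\n{self.sequence}\n+\n{self.qualities}\n"


def annotate_mate(
    read1_id: str,
    read1_sequence: str,
    read1_qualities: str,
    call: BarcodeCall,
    delimiter: str = "|",
    sublibrary_id: str | None = None,
) -> AnnotatedRead:
    """Append ``delimiter + cell_label + delimiter + umi`` to the read-1 ID.

    ``read1_id`` must already be the token before the first whitespace of
    the header (the comment is dropped).  Requires a passing call.
    """
    if call.status != "pass":
        raise ValueError("annotate_mate requires a passing BarcodeCall")
    original_id = read1_id.split()[0] if read1_id else read1_id
    w1, w2, w3 = call.cell_wells
    label = CellLabel(w1, w2, w3, sublibrary_id).render()
    annotated_id = f"{original_id}{delimiter}{label}{delimiter}{call.umi}"
    return AnnotatedRead(
        original_id=original_id,
        annotated_id=annotated_id,
        sequence=read1_sequence,
        qualities=read1_qualities,
    )


def parse_annotated_id(annotated_id: str, delimiter: str = "|") -> tuple[str, str, str]:
    """Invert :func:`annotate_mate`: return (original_id, cell_label, umi).

    Splits from the right so an original ID containing the delimiter cannot
    shift the two appended fields.
    """
    parts = annotated_id.rsplit(delimiter, 2)
    if len(parts) != 3:
        raise ValueError(
            f"cannot parse annotated id {annotated_id!r} with "
            f"delimiter {delimiter!r}"
        )
    return parts[0], parts[1], parts[2]


# ---------------------------------------------------------------------------
# position learning
# ---------------------------------------------------------------------------

def _linker_offsets(
    reads: Sequence[str], linker: str, allowance: int
) -> np.ndarray:
    """Best-matching start offset of ``linker`` in each read, or -1.

    For each read the leftmost offset with the fewest mismatches is taken;
    a read counts as matching when that minimum is <= ``allowance``.
    Vectorized over a padded byte matrix.
    """
    if not reads:
        return np.empty(0, dtype=np.int64)
    L = len(linker)
    width = max(len(r) for r in reads)
    # pad with NUL so short reads can never match
    mat = np.zeros((len(reads), width), dtype=np.uint8)
    for i, r in enumerate(reads):
        mat[i, : len(r)] = np.frombuffer(r.encode("ascii"), dtype=np.uint8)
    link = np.frombuffer(linker.encode("ascii"), dtype=np.uint8)
    n_offsets = width - L + 1
    if n_offsets <= 0:
        return np.full(len(reads), -1, dtype=np.int64)
    mism = np.empty((len(reads), n_offsets), dtype=np.int32)
    for off in range(n_offsets):
        mism[:, off] = (mat[:, off : off + L] != link).sum(axis=1)
    best_off = mism.argmin(axis=1)  # first occurrence = leftmost
    best_val = mism[np.arange(len(reads)), best_off]
    out = np.where(best_val <= allowance, best_off, -1)
    return out.astype(np.int64)


def _modal_offset(
    offsets: np.ndarray, n_sampled: int, linker_name: str
) -> int:
    matched = offsets[offsets >= 0]
    if n_sampled == 0 or len(matched) < 0.10 * n_sampled:
        raise LayoutLearningError(
            f"layout learning failed: {linker_name} found in "
            f"{len(matched)}/{n_sampled} sampled reads (< 10%)"
        )
    values, counts = np.unique(matched, return_counts=True)
    top = counts.argmax()
    if counts[top] < 0.5 * len(matched):
        hist = {int(v): int(c) for v, c in zip(values, counts)}
        raise LayoutLearningError(
            f"layout learning failed: modal {linker_name} offset "
            f"{int(values[top])} accounts for {int(counts[top])}/"
            f"{len(matched)} matching reads (< 50%); offset histogram: {hist}"
        )
    return int(values[top])


def learn_positions(
    read2_sample: Iterable[str],
    layout_template: ReadLayout,
    config: DemuxConfig,
) -> ReadLayout:
    """Confirm segment offsets from the data using the static linkers.

    Up to ``learning_sample_size`` reads are scanned for each linker at
    <= ``linker_mismatch_allowance`` mismatches; the modal start offset is
    adopted (it must cover at least half of the linker-matching reads, and
    each linker must be found in at least 10% of the sample).  Barcode and
    UMI offsets are then anchored to the linkers: bc3 ends where linker A
    starts, the UMI precedes bc3, bc2 follows linker A, bc1 follows
    linker B.
    """
    sample = list(itertools.islice(iter(read2_sample), config.learning_sample_size))
    n = len(sample)
    if n == 0:
        raise LayoutLearningError("layout learning failed: empty read sample")
    for name, seq in (
        ("linker_a", layout_template.linker_a_sequence),
        ("linker_b", layout_template.linker_b_sequence),
    ):
        if not seq:
            raise LayoutLearningError(f"{name} sequence is empty")

    la_off = _modal_offset(
        _linker_offsets(sample, layout_template.linker_a_sequence,
                        config.linker_mismatch_allowance),
        n, "linker_a",
    )
    lb_off = _modal_offset(
        _linker_offsets(sample, layout_template.linker_b_sequence,
                        config.linker_mismatch_allowance),
        n, "linker_b",
    )

    bl = layout_template.barcode_length
    ul = layout_template.umi_length
    la_len = len(layout_template.linker_a_sequence)
    lb_len = len(layout_template.linker_b_sequence)
    bc3_start = la_off - bl
    umi_start = bc3_start - ul
    if umi_start < 0:
        raise LayoutLearningError(
            f"learned linker_a offset {la_off} leaves no room for the UMI "
            f"({ul} nt) and round-3 barcode ({bl} nt) upstream"
        )
    bc2_start = la_off + la_len
    if lb_off < bc2_start + bl:
        raise LayoutLearningError(
            f"learned linker offsets overlap: linker_b at {lb_off}, but "
            f"round-2 barcode after linker_a spans "
            f"[{bc2_start}, {bc2_start + bl})"
        )
    bc1_start = lb_off + lb_len
    segments = [
        Segment("umi", umi_start, ul),
        Segment("bc3", bc3_start, bl),
        Segment("linker_a", la_off, la_len),
        Segment("bc2", bc2_start, bl),
        Segment("linker_b", lb_off, lb_len),
        Segment("bc1", bc1_start, bl),
    ]
    return ReadLayout(
        segments=segments,
        linker_a_sequence=layout_template.linker_a_sequence,
        linker_b_sequence=layout_template.linker_b_sequence,
        umi_length=ul,
        barcode_length=bl,
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class DemuxMetrics:
    """Run-level accounting; satisfies
    ``reads_total == reads_pass + sum(reads_fail_by_reason.values())``."""

    reads_total: int = 0
    reads_pass: int = 0
    reads_fail_by_reason: dict[str, int] = field(default_factory=dict)
    exact_match_by_round: dict[int, int] = field(
        default_factory=lambda: {1: 0, 2: 0, 3: 0}
    )
    corrected_match_by_round: dict[int, int] = field(
        default_factory=lambda: {1: 0, 2: 0, 3: 0}
    )
    barcodes_detected: int = 0
    barcodes_passing_min_reads: int = 0
    reads_in_passing_barcodes: int = 0

    def record(self, call: BarcodeCall) -> None:
        self.reads_total += 1
        for round_id, rc in call.rounds.items():
            if rc.distance_used is None:
                continue
            if rc.distance_used == 0:
                self.exact_match_by_round[round_id] += 1
            else:
                self.corrected_match_by_round[round_id] += 1
        if call.status == "pass":
            self.reads_pass += 1
        else:
            self.reads_fail_by_reason[call.fail_reason] = (
                self.reads_fail_by_reason.get(call.fail_reason, 0) + 1
            )

    def merge(self, other: "DemuxMetrics") -> None:
        self.reads_total += other.reads_total
        self.reads_pass += other.reads_pass
        for k, v in other.reads_fail_by_reason.items():
            self.reads_fail_by_reason[k] = self.reads_fail_by_reason.get(k, 0) + v
        for r in (1, 2, 3):
            self.exact_match_by_round[r] += other.exact_match_by_round[r]
            self.corrected_match_by_round[r] += other.corrected_match_by_round[r]

    def check_conservation(self) -> None:
        total_fail = sum(self.reads_fail_by_reason.values())
        if self.reads_total != self.reads_pass + total_fail:
            raise AssertionError(
                f"read conservation violated: total {self.reads_total} != "
                f"pass {self.reads_pass} + fail {total_fail}"
            )

    def to_dict(self) -> dict:
        return {
            "reads_total": self.reads_total,
            "reads_pass": self.reads_pass,
            "reads_fail_by_reason": dict(sorted(self.reads_fail_by_reason.items())),
            "exact_match_by_round": {
                str(r): self.exact_match_by_round[r] for r in (1, 2, 3)
            },
            "corrected_match_by_round": {
                str(r): self.corrected_match_by_round[r] for r in (1, 2, 3)
            },
            "barcodes_detected": self.barcodes_detected,
            "barcodes_passing_min_reads": self.barcodes_passing_min_reads,
            "reads_in_passing_barcodes": self.reads_in_passing_barcodes,
        }


# ---------------------------------------------------------------------------
# streaming pipeline
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def iter_read_pairs(
    fastq_r1: str | Path, fastq_r2: str | Path
) -> Iterator[tuple[str, str, str, str]]:
    """Yield ``(r1_id, r1_seq, r1_qual, r2_seq)`` for mate-synchronized
    FASTQ files (record k of each file is one pair).

    Raises :class:`DemuxError` at the first record-count discrepancy or on
    a malformed record.
    """
    sentinel = object()
    idx = 0
    with pysam.FastxFile(str(fastq_r1)) as f1, pysam.FastxFile(str(fastq_r2)) as f2:
        it = itertools.zip_longest(f1, f2, fillvalue=sentinel)
        while True:
            try:
                pair = next(it)
            except StopIteration:
                return
            except Exception as exc:  # truncated/malformed record
                raise DemuxError(
                    f"malformed FASTQ record at pair index {idx}: {exc}"
                ) from exc
            r1, r2 = pair
            if r1 is sentinel or r2 is sentinel:
                short = "read-1" if r1 is sentinel else "read-2"
                raise DemuxError(
                    f"mate files have unequal record counts: {short} file "
                    f"ended before pair index {idx}"
                )
            if r1.sequence is None or r2.sequence is None:
                raise DemuxError(f"malformed FASTQ record at pair index {idx}")
            yield (r1.name, r1.sequence, r1.quality or "", r2.sequence)
            idx += 1


def _chunked(iterable: Iterable, size: int) -> Iterator[list]:
    it = iter(iterable)
    while True:
        chunk = list(itertools.islice(it, size))
        if not chunk:
            return
        yield chunk


# worker-process state, set once per worker by the pool initializer
_worker_state: dict = {}


def _init_worker(whitelists, layout, config, sublibrary_id):
    correctors = {
        wl.round_id: BarcodeCorrector(wl, config.edit_tolerance, config.edit_metric)
        for wl in whitelists
    }
    _worker_state.update(
        correctors=correctors,
        layout=layout,
        config=config,
        sublibrary_id=sublibrary_id,
    )


def _process_bin(
    pairs: list[tuple[str, str, str, str]],
    correctors: dict[int, BarcodeCorrector],
    layout: ReadLayout,
    config: DemuxConfig,
    sublibrary_id: str | None,
) -> tuple[str, DemuxMetrics, Counter]:
    metrics = DemuxMetrics()
    label_counts: Counter = Counter()
    out: list[str] = []
    for r1_id, r1_seq, r1_qual, r2_seq in pairs:
        call = extract_call(r2_seq, layout, correctors)
        metrics.record(call)
        if call.status == "pass":
            ann = annotate_mate(
                r1_id, r1_seq, r1_qual, call,
                delimiter=config.annotation_delimiter,
                sublibrary_id=sublibrary_id,
            )
            _, label, _ = parse_annotated_id(
                ann.annotated_id, config.annotation_delimiter
            )
            label_counts[label] += 1
            out.append(ann.to_fastq())
    return "".join(out), metrics, label_counts


def _process_bin_worker(pairs):
    s = _worker_state
    return _process_bin(
        pairs, s["correctors"], s["layout"], s["config"], s["sublibrary_id"]
    )


@dataclass
class DemuxResult:
    """Output of one demultiplexing run."""

    metrics: DemuxMetrics
    label_counts: Counter
    layout: ReadLayout
    output_path: Path | None = None


def demultiplex(
    fastq_r1: str | Path,
    fastq_r2: str | Path,
    whitelists: Sequence[BarcodeWhitelist],
    layout: ReadLayout,
    config: DemuxConfig,
    output_path: str | Path | None = None,
    sublibrary_id: str | None = None,
    learn: bool = True,
) -> DemuxResult:
    """Demultiplex a mate-synchronized FASTQ pair.

    When ``learn`` is true the segment offsets are first confirmed from a
    sample of read 2 via the linker anchors.  Read pairs are then processed
    in consecutive bins of ``config.bin_size`` across up to
    ``config.threads`` worker processes; per-bin outputs are concatenated
    in input order, so results do not depend on the thread count.

    Returns metrics plus per-cell-label read counts; annotated read-1
    records are written to ``output_path`` (plain or .gz) when given.
    """
    config.check_against_layout(layout)
    by_round = {wl.round_id: wl for wl in whitelists}
    if set(by_round) != {1, 2, 3}:
        raise SchemaError("demultiplex needs whitelists for rounds 1, 2 and 3")

    if learn:
        sample = (
            r2 for _, _, _, r2 in iter_read_pairs(fastq_r1, fastq_r2)
        )
        layout = learn_positions(sample, layout, config)

    pairs = iter_read_pairs(fastq_r1, fastq_r2)
    bins = _chunked(pairs, config.bin_size)

    metrics = DemuxMetrics()
    label_counts: Counter = Counter()
    out_fh = _open_text(output_path, "wt") if output_path is not None else None
    try:
        if config.threads == 1:
            correctors = {
                wl.round_id: BarcodeCorrector(
                    wl, config.edit_tolerance, config.edit_metric
                )
                for wl in whitelists
            }
            results = (
                _process_bin(b, correctors, layout, config, sublibrary_id)
                for b in bins
            )
            for text, m, counts in results:
                metrics.merge(m)
                label_counts.update(counts)
                if out_fh is not None:
                    out_fh.write(text)
        else:
            with ProcessPoolExecutor(
                max_workers=config.threads,
                initializer=_init_worker,
                initargs=(list(whitelists), layout, config, sublibrary_id),
            ) as pool:
                for text, m, counts in pool.map(_process_bin_worker, bins):
                    metrics.merge(m)
                    label_counts.update(counts)
                    if out_fh is not None:
                        out_fh.write(text)
    finally:
        if out_fh is not None:
            out_fh.close()

    metrics.barcodes_detected = len(label_counts)
    metrics.check_conservation()
    return DemuxResult(
        metrics=metrics,
        label_counts=label_counts,
        layout=layout,
        output_path=Path(output_path) if output_path is not None else None,
    )


def filter_min_reads(
    label_counts: Counter | dict[str, int],
    m: int,
    annotated_fastq: str | Path | None = None,
    output_path: str | Path | None = None,
    metrics: DemuxMetrics | None = None,
    delimiter: str = "|",
) -> set[str]:
    """Retain cell labels with at least ``m`` demultiplexed reads.

    Low-read barcodes are mostly ambient molecules and barcode hopping;
    dropping them up front bounds downstream matrix size.  When
    ``annotated_fastq`` and ``output_path`` are given, the annotated stream
    is additionally rewritten with only retained-label records.
    Returns the retained label set and updates ``metrics`` in place.
    """
    if m < 1:
        raise SchemaError(f"min reads per barcode must be >= 1, got {m}")
    retained = {label for label, n in label_counts.items() if n >= m}
    if metrics is not None:
        metrics.barcodes_detected = len(label_counts)
        metrics.barcodes_passing_min_reads = len(retained)
        metrics.reads_in_passing_barcodes = sum(
            n for label, n in label_counts.items() if label in retained
        )
    if annotated_fastq is not None and output_path is not None:
        with _open_text(annotated_fastq) as fin, _open_text(output_path, "wt") as fout:
            while True:
                header = fin.readline()
                if not header:
                    break
                seq = fin.readline()
                plus = fin.readline()
                qual = fin.readline()
                _, label, _ = parse_annotated_id(
                    header[1:].rstrip("\n"), delimiter
                )
                if label in retained:
                    fout.write(header + seq + plus + qual)
    return retained


def write_metrics(metrics: DemuxMetrics, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(metrics.to_dict(), fh, indent=2)
        fh.write("\n")
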