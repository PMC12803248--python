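"""Barcode whitelists, the read-2 segment layout, and run configuration.

A split-pool library encodes cell identity as three 8-nt well barcodes
ligated in successive plate rounds.  Read 2 of the paired-end output carries,
in order: the UMI, the round-3 barcode, a static linker, the round-2 barcode,
a second static linker, and the round-1 barcode.  Everything downstream
(position learning, extraction, correction) is driven by the types defined
here.

Offsets are 0-based and end-exclusive throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

VALID_BASES = frozenset("ACGT")

#: canonical order of read-2 segments, 5' to 3'
SEGMENT_KINDS = ("umi", "bc3", "linker_a", "bc2", "linker_b", "bc1")

BARCODE_SEGMENTS = ("bc1", "bc2", "bc3")
LINKER_SEGMENTS = ("linker_a", "linker_b")

#: which read-2 segment carries which barcoding round
ROUND_TO_SEGMENT = {1: "bc1", 2: "bc2", 3: "bc3"}


class SchemaError(ValueError):
    """Raised when a whitelist, layout or config violates its contract."""


class AmbiguousCorrectionWarning(UserWarning):
    """A whitelist's minimum pairwise distance cannot guarantee unambiguous
    correction at the configured edit tolerance."""


def hamming(a: str, b: str) -> int:
    """Substitution-only distance between equal-length strings.

    'N' (or any non-ACGT symbol) mismatches every base, including itself
    unless the characters are literally equal -- callers that need the
    N-always-mismatches rule should route through
    :func:`splitpool.demux.hamming_n`.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class BarcodeWhitelist:
    """Legal barcode sequences for one barcoding round, keyed by plate well.

    Parameters
    ----------
    round_id
        Barcoding round, 1-3.  Round 1 is attached during in-well reverse
        transcription; rounds 2 and 3 by ligation.
    entries
        Ordered ``(well_id, sequence)`` pairs.
    barcode_length
        Fixed length of every sequence in the round.

    The minimum pairwise Hamming distance over all entries is computed on
    construction; correction at edit tolerance ``e`` is guaranteed
    unambiguous iff that minimum is at least ``2e + 1``.
    """

    round_id: int
    entries: list[tuple[str, str]]
    barcode_length: int = 8
    min_pairwise_distance: int | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        if self.round_id not in (1, 2, 3):
            raise SchemaError(f"round_id must be 1, 2 or 3, got {self.round_id}")
        if self.barcode_length < 1:
            raise SchemaError("barcode_length must be positive")
        self.entries = [(str(w), str(s)) for w, s in self.entries]
        seen_wells: dict[str, str] = {}
        seen_seqs: dict[str, str] = {}
        for well, seq in self.entries:
            if len(seq) != self.barcode_length:
                raise SchemaError(
                    f"round {self.round_id} well {well}: sequence {seq!r} has "
                    f"length {len(seq)}, expected {self.barcode_length}"
                )
            bad = set(seq) - VALID_BASES
            if bad:
                raise SchemaError(
                    f"round {self.round_id} well {well}: non-ACGT character(s) "
                    f"{sorted(bad)} in {seq!r}"
                )
            if well in seen_wells:
                raise SchemaError(
                    f"round {self.round_id}: duplicate well_id {well!r}"
                )
            if seq in seen_seqs:
                raise SchemaError(
                    f"round {self.round_id}: duplicate sequence {seq!r} "
                    f"(wells {seen_seqs[seq]!r} and {well!r})"
                )
            seen_wells[well] = seq
            seen_seqs[seq] = well
        self.min_pairwise_distance = self._min_pairwise()

    def _min_pairwise(self) -> int | None:
        seqs = [s for _, s in self.entries]
        if len(seqs) < 2:
            return None  # undefined: no pairs
        best = self.barcode_length
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                d = hamming(seqs[i], seqs[j])
                if d < best:
                    best = d
        return best

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def sequences(self) -> list[str]:
        return [s for _, s in self.entries]

    @property
    def wells(self) -> list[str]:
        return [w for w, _ in self.entries]

    def check_tolerance(self, edit_tolerance: int) -> bool:
        """Return True (and warn otherwise) if correction at the given
        tolerance is guaranteed unambiguous for this whitelist."""
        d = self.min_pairwise_distance
        if d is None:
            return True
        if d >= 2 * edit_tolerance + 1:
            return True
        warnings.warn(
            f"round {self.round_id}: min pairwise Hamming distance {d} < "
            f"{2 * edit_tolerance + 1}; correction at e={edit_tolerance} can "
            "be ambiguous",
            AmbiguousCorrectionWarning,
            stacklevel=2,
        )
        return False


def load_whitelist(
    path: str | Path, round_id: int, barcode_length: int = 8, edit_tolerance: int = 1
) -> BarcodeWhitelist:
    """Read a two-column ``well_id<TAB>sequence`` table.

    A header line is auto-detected: if the second field of the first line is
    not a sequence over ACGT of the expected length it is skipped.
    """
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SchemaError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(parts)}"
                )
            rows.append((parts[0].strip(), parts[1].strip()))
    if rows and not (
        set(rows[0][1]) <= VALID_BASES and len(rows[0][1]) == barcode_length
    ):
        rows = rows[1:]  # header
    wl = BarcodeWhitelist(round_id=round_id, entries=rows, barcode_length=barcode_length)
    wl.check_tolerance(edit_tolerance)
    return wl


def write_whitelist(wl: BarcodeWhitelist, path: str | Path) -> None:
    """Serialize as headerless ``well_id<TAB>sequence`` lines (round-trips
    losslessly through :func:`load_whitelist`)."""
    with open(path, "w") as fh:
        for well, seq in wl.entries:
            fh.write(f"{well}\t{seq}\n")


@dataclass(frozen=True)
class Segment:
    """One interval of read 2: ``[start, start + length)``."""

    kind: str
    start: int
    length: int

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise SchemaError(f"unknown segment kind {self.kind!r}")
        if self.start < 0 or self.length < 1:
            raise SchemaError(f"bad segment bounds: {self}")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class ReadLayout:
    """Segment map of read 2.

    ``segments`` must be strictly ascending in start offset and
    non-overlapping; ``min_read2_length`` is the end of the last segment.
    """

    segments: list[Segment]
    linker_a_sequence: str
    linker_b_sequence: str
    umi_length: int = 10
    barcode_length: int = 8

    def __post_init__(self) -> None:
        if not self.segments:
            raise SchemaError("layout has no segments")
        prev_end = -1
        prev_start = -1
        for seg in self.segments:
            if seg.start <= prev_start:
                raise SchemaError("segments not strictly ascending in start offset")
            if seg.start < prev_end:
                raise SchemaError(
                    f"segment {seg.kind} at {seg.start} overlaps previous "
                    f"segment ending at {prev_end}"
                )
            prev_start, prev_end = seg.start, seg.end
        kinds = [s.kind for s in self.segments]
        if len(set(kinds)) != len(kinds):
            raise SchemaError("duplicate segment kinds in layout")
        for kind, seq in (
            ("linker_a", self.linker_a_sequence),
            ("linker_b", self.linker_b_sequence),
        ):
            seg = self.find(kind)
            if seg is not None and len(seq) != seg.length:
                raise SchemaError(
                    f"{kind} sequence length {len(seq)} != segment length "
                    f"{seg.length}"
                )
        umi = self.find("umi")
        if umi is not None and umi.length != self.umi_length:
            raise SchemaError(
                f"umi segment length {umi.length} != umi_length {self.umi_length}"
            )

    def find(self, kind: str) -> Segment | None:
        for seg in self.segments:
            if seg.kind == kind:
                return seg
        return None

    @property
    def min_read2_length(self) -> int:
        return max(seg.end for seg in self.segments)

    def barcode_segment(self, round_id: int) -> Segment:
        seg = self.find(ROUND_TO_SEGMENT[round_id])
        if seg is None:
            raise SchemaError(f"layout lacks a round-{round_id} barcode segment")
        return seg

    @classmethod
    def default(
        cls,
        linker_a_sequence: str,
        linker_b_sequence: str,
        umi_length: int = 10,
        barcode_length: int = 8,
    ) -> "ReadLayout":
        """Contiguous UMI + bc3 + linker_a + bc2 + linker_b + bc1 layout.

        With the defaults (10-nt UMI, 8-nt barcodes, 30-nt linkers) this
        totals 94 nt, the read-2 length of the sequencing design.
        """
        lengths = {
            "umi": umi_length,
            "bc3": barcode_length,
            "linker_a": len(linker_a_sequence),
            "bc2": barcode_length,
            "linker_b": len(linker_b_sequence),
            "bc1": barcode_length,
        }
        segments = []
        pos = 0
        for kind in SEGMENT_KINDS:
            segments.append(Segment(kind, pos, lengths[kind]))
            pos += lengths[kind]
        return cls(
            segments=segments,
            linker_a_sequence=linker_a_sequence,
            linker_b_sequence=linker_b_sequence,
            umi_length=umi_length,
            barcode_length=barcode_length,
        )


@dataclass
class LayoutReport:
    """Result of cross-checking a layout against the three whitelists."""

    valid: bool
    min_read2_length: int
    messages: list[str] = field(default_factory=list)


def validate_layout(
    layout: ReadLayout, whitelists: Sequence[BarcodeWhitelist]
) -> LayoutReport:
    """Confirm each barcode segment's length matches its round's whitelist.

    Raises :class:`SchemaError` on any mismatch; returns a report with the
    minimum read-2 length otherwise.
    """
    by_round = {wl.round_id: wl for wl in whitelists}
    if set(by_round) != {1, 2, 3}:
        raise SchemaError(
            f"need whitelists for rounds 1, 2, 3; got rounds {sorted(by_round)}"
        )
    messages = []
    for round_id in (1, 2, 3):
        seg = layout.barcode_segment(round_id)
        wl = by_round[round_id]
        if seg.length != wl.barcode_length:
            raise SchemaError(
                f"round {round_id}: segment length {seg.length} != whitelist "
                f"barcode length {wl.barcode_length}"
            )
        messages.append(
            f"round {round_id}: {len(wl)} barcodes, min pairwise distance "
            f"{wl.min_pairwise_distance}"
        )
    return LayoutReport(
        valid=True, min_read2_length=layout.min_read2_length, messages=messages
    )


@dataclass
class DemuxConfig:
    """Run parameters for demultiplexing.

    ``threads``, ``edit_tolerance`` and ``min_reads_per_barcode`` mirror the
    pipeline's -n / -e / -m flags.  ``bin_size`` is the number of read pairs
    per processing bin: bins bound memory use and are the unit of parallel
    work, and because bin boundaries are defined by record index the merged
    output is identical for any thread count.
    """

    threads: int = 1
    edit_tolerance: int = 1
    min_reads_per_barcode: int = 200
    bin_size: int = 1_000_000
    edit_metric: str = "hamming"
    linker_mismatch_allowance: int = 1
    learning_sample_size: int = 10_000
    annotation_delimiter: str = "|"

    def __post_init__(self) -> None:
        if self.threads < 1:
            raise SchemaError("threads must be >= 1")
        if self.edit_tolerance < 0:
            raise SchemaError("edit_tolerance must be >= 0")
        if self.min_reads_per_barcode < 1:
            raise SchemaError("min_reads_per_barcode must be >= 1")
        if self.bin_size < 1:
            raise SchemaError("bin_size must be >= 1")
        if self.edit_metric not in ("hamming", "levenshtein"):
            raise SchemaError(
                f"edit_metric must be 'hamming' or 'levenshtein', "
                f"got {self.edit_metric!r}"
            )
        if self.linker_mismatch_allowance < 0:
            raise SchemaError("linker_mismatch_allowance must be >= 0")
        if self.learning_sample_size < 1:
            raise SchemaError("learning_sample_size must be >= 1")
        if not self.annotation_delimiter:
            raise SchemaError("annotation_delimiter must be non-empty")

    def check_against_layout(self, layout: ReadLayout) -> None:
        if self.edit_tolerance >= layout.barcode_length:
            raise SchemaError(
                f"edit_tolerance {self.edit_tolerance} must be < barcode "
                f"length {layout.barcode_length}"
            )


@dataclass
class RunConfig:
    """Everything one demultiplexing run needs, loadable from a single
    YAML file: whitelist paths, linker sequences, segment geometry and the
    -n/-e/-m parameters."""

    whitelist_paths: dict[int, str]
    layout: ReadLayout
    demux: DemuxConfig
    sublibrary_id: str | None = None

    def load_whitelists(self, base_dir: str | Path | None = None) -> list[BarcodeWhitelist]:
        base = Path(base_dir) if base_dir is not None else Path(".")
        out = []
        for round_id in (1, 2, 3):
            p = Path(self.whitelist_paths[round_id])
            if not p.is_absolute():
                p = base / p
            out.append(
                load_whitelist(
                    p,
                    round_id,
                    barcode_length=self.layout.barcode_length,
                    edit_tolerance=self.demux.edit_tolerance,
                )
            )
        return out

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "whitelists": {f"round{r}": p for r, p in self.whitelist_paths.items()},
            "layout": {
                "umi_length": self.layout.umi_length,
                "barcode_length": self.layout.barcode_length,
                "linker_a_sequence": self.layout.linker_a_sequence,
                "linker_b_sequence": self.layout.linker_b_sequence,
                "segments": [
                    {"kind": s.kind, "start": s.start, "length": s.length}
                    for s in self.layout.segments
                ],
            },
            "demux": {
                "threads": self.demux.threads,
                "edit_tolerance": self.demux.edit_tolerance,
                "min_reads_per_barcode": self.demux.min_reads_per_barcode,
                "bin_size": self.demux.bin_size,
                "edit_metric": self.demux.edit_metric,
                "linker_mismatch_allowance": self.demux.linker_mismatch_allowance,
                "learning_sample_size": self.demux.learning_sample_size,
                "annotation_delimiter": self.demux.annotation_delimiter,
            },
        }
        if self.sublibrary_id is not None:
            doc["sublibrary_id"] = self.sublibrary_id
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        try:
            lay = doc["layout"]
            layout = ReadLayout(
                segments=[
                    Segment(s["kind"], int(s["start"]), int(s["length"]))
                    for s in lay["segments"]
                ],
                linker_a_sequence=lay["linker_a_sequence"],
                linker_b_sequence=lay["linker_b_sequence"],
                umi_length=int(lay.get("umi_length", 10)),
                barcode_length=int(lay.get("barcode_length", 8)),
            )
            demux = DemuxConfig(**doc.get("demux", {}))
            whitelists = {
                int(key.removeprefix("round")): str(p)
                for key, p in doc["whitelists"].items()
            }
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed run config {path}: {exc}") from exc
        return cls(
            whitelist_paths=whitelists,
            layout=layout,
            demux=demux,
            sublibrary_id=doc.get("sublibrary_id"),
        )
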