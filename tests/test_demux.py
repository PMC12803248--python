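"""Extraction, annotation, position learning and the streaming pipeline."""

import gzip

import numpy as np
import pytest

from splitpool.demux import (
    DemuxError,
    LayoutLearningError,
    annotate_mate,
    demultiplex,
    extract_call,
    filter_min_reads,
    iter_read_pairs,
    learn_positions,
    parse_annotated_id,
)
from splitpool.schema import DemuxConfig, SchemaError
from splitpool.simulate import SimulationParams, simulate_library, write_library


class TestExtractCall:
    def test_error_free_read_passes_at_distance_zero(
        self, layout, whitelists, correctors, make_read2
    ):
        (w1, s1), (w2, s2), (w3, s3) = (
            whitelists[0].entries[0], whitelists[1].entries[4], whitelists[2].entries[8]
        )
        call = extract_call(make_read2(s1, s2, s3, "T" * 10), layout, correctors(1))
        assert call.status == "pass"
        assert call.cell_wells == (w1, w2, w3)
        assert all(call.rounds[r].distance_used == 0 for r in (1, 2, 3))
        assert call.umi == "T" * 10

    def test_single_substitution_in_bc2_corrected(
        self, layout, whitelists, correctors, make_read2
    ):
        (_, s1), (w2, s2), (_, s3) = (
            whitelists[0].entries[0], whitelists[1].entries[1], whitelists[2].entries[2]
        )
        mutated = ("T" if s2[3] != "T" else "G").join([s2[:3], s2[4:]])
        call = extract_call(make_read2(s1, mutated, s3), layout, correctors(1))
        assert call.status == "pass"
        assert call.rounds[2].corrected_well_id == w2
        assert call.rounds[2].distance_used == 1
        assert call.rounds[2].corrected_seq == s2

    def test_short_read_fails(self, layout, correctors):
        call = extract_call("A" * 40, layout, correctors(1))
        assert (call.status, call.fail_reason) == ("fail", "read_too_short")

    def test_first_failing_round_sets_reason(
        self, layout, whitelists, correctors, make_read2
    ):
        (_, s1), (_, s2), (_, s3) = (w.entries[0] for w in whitelists)
        read = make_read2("N" * 8, s2, s3)
        call = extract_call(read, layout, correctors(1))
        assert call.fail_reason == "no_match_round1"

    def test_n_in_umi_fails(self, layout, whitelists, correctors, make_read2):
        (_, s1), (_, s2), (_, s3) = (w.entries[0] for w in whitelists)
        call = extract_call(
            make_read2(s1, s2, s3, "TTTTNTTTT" + "T"), layout, correctors(1)
        )
        assert (call.status, call.fail_reason) == ("fail", "umi_invalid")


class TestAnnotation:
    def _passing_call(self, layout, whitelists, correctors, make_read2):
        (_, s1), (_, s2), (_, s3) = (w.entries[0] for w in whitelists)
        return extract_call(make_read2(s1, s2, s3), layout, correctors(0))

    def test_id_format(self, layout, whitelists, correctors, make_read2):
        call = self._passing_call(layout, whitelists, correctors, make_read2)
        w1, w2, w3 = call.cell_wells
        ann = annotate_mate("readX", "ACGT", "IIII", call)
        assert ann.annotated_id == f"readX|{w1}.{w2}.{w3}|{'T' * 10}"
        assert (ann.sequence, ann.qualities) == ("ACGT", "IIII")

    def test_comment_dropped_from_header(
        self, layout, whitelists, correctors, make_read2
    ):
        call = self._passing_call(layout, whitelists, correctors, make_read2)
        ann = annotate_mate("readX 1:N:0:ACGT", "A", "I", call)
        assert ann.annotated_id.startswith("readX|")

    def test_roundtrip_and_sublibrary_tag(
        self, layout, whitelists, correctors, make_read2
    ):
        call = self._passing_call(layout, whitelists, correctors, make_read2)
        ann = annotate_mate("readX", "A", "I", call, sublibrary_id="S2")
        orig, label, umi = parse_annotated_id(ann.annotated_id)
        assert orig == "readX"
        assert label.endswith(".S2")
        assert umi == call.umi

    def test_failed_call_rejected(self, layout, correctors):
        call = extract_call("A" * 40, layout, correctors(1))
        with pytest.raises(ValueError):
            annotate_mate("readX", "A", "I", call)


class TestLearnPositions:
    def test_noiseless_offsets_recovered(self, layout, whitelists, make_read2):
        rng = np.random.default_rng(5)
        reads = [
            make_read2(*(w.entries[rng.integers(len(w))][1] for w in whitelists))
            for _ in range(200)
        ]
        learned = learn_positions(reads, layout, DemuxConfig())
        assert [
            (s.kind, s.start) for s in learned.segments
        ] == [(s.kind, s.start) for s in layout.segments]

    def test_robust_to_5pct_junk(self, layout, whitelists, make_read2):
        rng = np.random.default_rng(6)
        reads = []
        for i in range(400):
            if rng.random() < 0.05:
                reads.append("".join(rng.choice(list("ACGT"), size=94)))
            else:
                reads.append(
                    make_read2(
                        *(w.entries[rng.integers(len(w))][1] for w in whitelists)
                    )
                )
        learned = learn_positions(reads, layout, DemuxConfig())
        assert learned.find("linker_a").start == 18
        assert learned.find("linker_b").start == 56

    def test_absent_linker_raises(self, layout):
        rng = np.random.default_rng(7)
        reads = ["".join(rng.choice(list("ACGT"), size=94)) for _ in range(100)]
        with pytest.raises(LayoutLearningError, match="layout learning failed"):
            learn_positions(reads, layout, DemuxConfig())


def _write_fastq(path, records):
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


class TestDemultiplex:
    def _simulated(self, tmp_path, **kwargs):
        params = SimulationParams(
            n_cells=20, n_genes=10, reads_per_cell=50, molecules_per_cell=15,
            seed=kwargs.pop("seed", 11), **kwargs,
        )
        lib = simulate_library(params)
        paths = write_library(lib, tmp_path / "sim")
        return lib, paths

    def test_three_valid_pairs(self, tmp_path, layout, whitelists, make_read2):
        seqs = [
            make_read2(*(w.entries[i][1] for w in whitelists)) for i in range(3)
        ]
        r1 = tmp_path / "r1.fastq"
        r2 = tmp_path / "r2.fastq"
        _write_fastq(r1, [(f"r{i}", "ACGT" * 10) for i in range(3)])
        _write_fastq(r2, list(zip((f"r{i}" for i in range(3)), seqs)))
        res = demultiplex(
            r1, r2, whitelists, layout, DemuxConfig(),
            output_path=tmp_path / "out.fastq", learn=False,
        )
        assert res.metrics.reads_total == 3
        assert res.metrics.reads_pass == 3
        assert (tmp_path / "out.fastq").read_text().count("@") == 3

    def test_junk_reads_counted_as_failures(self, tmp_path):
        lib, paths = self._simulated(tmp_path, junk_read_fraction=0.1, seed=21)
        cfg = DemuxConfig(edit_tolerance=1, bin_size=200)
        res = demultiplex(
            paths["r1"], paths["r2"], lib.whitelists, lib.layout, cfg,
        )
        total = len(lib.r1_records)
        assert res.metrics.reads_total == total
        assert res.metrics.reads_pass == total - lib.truth.junk_count
        assert sum(res.metrics.reads_fail_by_reason.values()) == lib.truth.junk_count

    def test_thread_count_invariance(self, tmp_path):
        lib, paths = self._simulated(tmp_path, seed=31)
        outputs, metrics = [], []
        for threads in (1, 3):
            out = tmp_path / f"out{threads}.fastq"
            cfg = DemuxConfig(threads=threads, bin_size=97)
            res = demultiplex(
                paths["r1"], paths["r2"], lib.whitelists, lib.layout, cfg,
                output_path=out,
            )
            outputs.append(out.read_bytes())
            metrics.append(res.metrics.to_dict())
        assert outputs[0] == outputs[1]
        assert metrics[0] == metrics[1]

    def test_monotonic_in_tolerance(self, tmp_path):
        lib, paths = self._simulated(
            tmp_path, substitution_error_rate=0.01, seed=41
        )

        def passing(e):
            out = tmp_path / f"e{e}.fastq"
            demultiplex(
                paths["r1"], paths["r2"], lib.whitelists, lib.layout,
                DemuxConfig(edit_tolerance=e), output_path=out,
            )
            return {
                parse_annotated_id(line[1:].rstrip())[0]
                for line in open(out) if line.startswith("@")
            }

        p0, p1 = passing(0), passing(1)
        assert p0 <= p1

    def test_unequal_mate_counts_rejected(self, tmp_path, layout, whitelists):
        r1 = tmp_path / "r1.fastq"
        r2 = tmp_path / "r2.fastq"
        _write_fastq(r1, [("a", "ACGT"), ("b", "ACGT")])
        _write_fastq(r2, [("a", "A" * 94)])
        with pytest.raises(DemuxError, match="unequal record counts"):
            list(iter_read_pairs(r1, r2))


class TestMinReadFilter:
    @pytest.mark.parametrize("m", [1, 3, 200])
    def test_boundary_retains_at_least_m(self, m):
        counts = {"low": m - 1, "at": m, "above": m + 1}
        counts = {k: v for k, v in counts.items() if v > 0}
        retained = filter_min_reads(counts, m)
        assert retained == {"at", "above"}

    def test_m1_retains_everything(self):
        assert filter_min_reads({"a": 1, "b": 5}, 1) == {"a", "b"}

    def test_counts_example(self):
        assert filter_min_reads({"c1": 3, "c2": 2}, 3) == {"c1"}

    def test_invalid_m_rejected(self):
        with pytest.raises(SchemaError):
            filter_min_reads({"a": 1}, 0)

    def test_stream_restriction_and_metrics(self, tmp_path):
        from splitpool.demux import DemuxMetrics

        fq = tmp_path / "ann.fastq"
        lines = []
        for label, n in (("A1.B1.C1", 3), ("A2.B2.C2", 1)):
            for i in range(n):
                lines.append(f"@r{label}{i}|{label}|TTTTTTTTTT\nACGT\n+\nIIII\n")
        fq.write_text("".join(lines))
        metrics = DemuxMetrics()
        retained = filter_min_reads(
            {"A1.B1.C1": 3, "A2.B2.C2": 1}, 2,
            annotated_fastq=fq, output_path=tmp_path / "f.fastq",
            metrics=metrics,
        )
        assert retained == {"A1.B1.C1"}
        out = (tmp_path / "f.fastq").read_text()
        assert out.count("@") == 3 and "A2.B2.C2" not in out
        assert metrics.barcodes_passing_min_reads == 1
        assert metrics.reads_in_passing_barcodes == 3
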