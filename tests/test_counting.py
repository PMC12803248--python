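"""Assignment joining, UMI collapse, matrix construction, QC, MTX I/O."""

import numpy as np
import networkx as nx
import pytest

from splitpool.counting import (
    CountMatrix,
    MatrixFormatError,
    MoleculeRecord,
    build_matrix,
    collapse_umis,
    directional_cluster_count,
    join_assignments,
    load_assignments,
    qc_filter,
    read_mtx,
    write_mtx,
)
from splitpool.schema import SchemaError


class TestJoinAssignments:
    def test_identical_triples_aggregate(self):
        ids = ["r1|A1.B1.C1|TTTTTTTTTT", "r2|A1.B1.C1|TTTTTTTTTT"]
        records, unassigned = join_assignments(ids, {"r1": "g1", "r2": "g1"})
        assert unassigned == 0
        assert records == [
            MoleculeRecord("A1.B1.C1", "g1", "TTTTTTTTTT", 2)
        ]

    def test_unassigned_reads_dropped_and_counted(self):
        ids = ["r1|A1.B1.C1|TTTTTTTTTT", "r2|A1.B1.C1|AAAAAAAAAA"]
        records, unassigned = join_assignments(ids, {"r1": "g1"})
        assert unassigned == 1
        assert len(records) == 1

    def test_empty_table_all_unassigned(self):
        ids = ["r1|A1.B1.C1|TTTTTTTTTT"]
        records, unassigned = join_assignments(ids, {})
        assert (records, unassigned) == ([], 1)

    def test_duplicate_read_id_rejected(self, tmp_path):
        p = tmp_path / "assign.tsv"
        p.write_text("r1\tg1\nr1\tg2\n")
        with pytest.raises(SchemaError, match="duplicate read_id"):
            load_assignments(p)


def nx_directional_oracle(umi_counts):
    """Independent directional-collapse oracle via networkx reachability."""
    g = nx.DiGraph()
    g.add_nodes_from(umi_counts)
    for u in umi_counts:
        for v in umi_counts:
            if u == v:
                continue
            d = sum(a != b for a, b in zip(u, v))
            if d == 1 and umi_counts[u] >= 2 * umi_counts[v] - 1:
                g.add_edge(u, v)
    unassigned = set(umi_counts)
    clusters = 0
    for seed in sorted(umi_counts, key=lambda u: (-umi_counts[u], u)):
        if seed not in unassigned:
            continue
        clusters += 1
        reach = {seed}
        frontier = {seed}
        while frontier:
            nxt = set()
            for node in frontier:
                for succ in g.successors(node):
                    if succ in unassigned and succ not in reach:
                        nxt.add(succ)
            reach |= nxt
            frontier = nxt
        unassigned -= reach
    return clusters


class TestCollapse:
    def test_identical_umis_one_molecule(self):
        recs = [
            MoleculeRecord("c", "g", "AAAAAAAAAA", 1),
            MoleculeRecord("c", "g", "AAAAAAAAAA", 1),
        ]
        assert collapse_umis(recs, "unique") == {("c", "g"): 1}
        assert collapse_umis(recs, "directional") == {("c", "g"): 1}

    def test_satellite_umi_absorbed_directionally(self):
        recs = [
            MoleculeRecord("c", "g", "AAAAAAAAAA", 10),
            MoleculeRecord("c", "g", "AAAAAAAAAT", 1),
        ]
        assert collapse_umis(recs, "unique") == {("c", "g"): 2}
        # 10 >= 2*1 - 1, so the low-count neighbour merges into its parent
        assert collapse_umis(recs, "directional") == {("c", "g"): 1}

    def test_balanced_counts_stay_separate(self):
        counts = {"AAAAAAAAAA": 5, "AAAAAAAAAT": 5}
        # 5 < 2*5 - 1: neither can absorb the other
        assert directional_cluster_count(counts) == 2

    def test_empty_group(self):
        assert collapse_umis([], "unique") == {}
        assert directional_cluster_count({}) == 0

    def test_unequal_umi_lengths_rejected(self):
        recs = [
            MoleculeRecord("c", "g", "AAAAAAAAAA", 1),
            MoleculeRecord("c", "g", "AAAA", 1),
        ]
        with pytest.raises(ValueError, match="unequal length"):
            collapse_umis(recs, "directional")

    def test_directional_matches_oracle_and_unique_bounds_it(self):
        """1,000 random UMI groups, sizes 1-50: implementation equals the
        networkx reachability oracle, and unique >= directional always."""
        rng = np.random.default_rng(2024)
        bases = np.array(list("ACGT"))
        for _ in range(1000):
            size = int(rng.integers(1, 51))
            # draw from a small UMI space so 1-mismatch pairs are common
            core = "".join(rng.choice(bases, size=10))
            umis = {}
            for _ in range(size):
                u = list(core)
                for pos in rng.choice(10, size=int(rng.integers(0, 3)), replace=False):
                    u[pos] = str(rng.choice(bases))
                umis["".join(u)] = umis.get("".join(u), 0) + int(rng.integers(1, 20))
            got = directional_cluster_count(umis)
            assert got == nx_directional_oracle(umis)
            assert len(umis) >= got


class TestBuildMatrix:
    def test_toy_counts(self):
        m = build_matrix({("c1", "g1"): 2, ("c1", "g2"): 1})
        assert m.shape == (2, 1)
        assert m.total() == 3
        assert m.gene_names == ["g1", "g2"]

    def test_empty_counts(self):
        m = build_matrix({})
        assert m.shape == (0, 0)

    def test_order_invariance(self):
        items = [(("c2", "g1"), 3), (("c1", "g2"), 1), (("c1", "g1"), 2)]
        a = build_matrix(dict(items))
        b = build_matrix(dict(reversed(items)))
        assert a.equals(b)


def toy_matrix(cells):
    """cells: {label: {gene: count}} -> CountMatrix."""
    collapsed = {
        (c, g): n for c, genes in cells.items() for g, n in genes.items()
    }
    return build_matrix(collapsed)


class TestQCFilter:
    def test_low_umi_boundary(self):
        filler = {f"fill{i}": {"g1": 600} for i in range(10)}
        m = toy_matrix({"at": {"g1": 500}, "below": {"g1": 499}, **filler})
        out, report = qc_filter(m, min_cells_per_gene=1)
        assert "at" in out.cell_labels and "below" not in out.cell_labels
        assert report.cells_removed_low_umi == 1

    def test_gene_detection_boundary(self):
        cells = {}
        for i in range(10):
            cells[f"c{i}"] = {"gene_in_10": 600}
            if i < 9:
                cells[f"c{i}"]["gene_in_9"] = 600
        out, report = qc_filter(toy_matrix(cells), min_cells_per_gene=10)
        assert out.gene_names == ["gene_in_10"]
        assert report.genes_removed_low_cells == 1

    def test_mito_fraction_boundary(self):
        cells = {
            "keep": {"mt-g": 50, "g1": 950},     # 0.050
            "drop": {"mt-g": 51, "g1": 949},     # 0.051
        }
        for i in range(10):
            cells[f"fill{i}"] = {"mt-g": 10, "g1": 990}
        out, report = qc_filter(
            toy_matrix(cells), mito_gene_set={"mt-g"}, min_cells_per_gene=1
        )
        assert "keep" in out.cell_labels and "drop" not in out.cell_labels
        assert report.cells_removed_high_mito == 1

    def test_high_umi_boundary(self):
        cells = {"keep": {"g1": 15000}, "drop": {"g1": 15001}}
        for i in range(10):
            cells[f"fill{i}"] = {"g1": 600}
        out, report = qc_filter(toy_matrix(cells), min_cells_per_gene=1)
        assert "keep" in out.cell_labels and "drop" not in out.cell_labels
        assert report.cells_removed_high_umi == 1

    def test_empty_mito_set_removes_no_cell_by_mito(self):
        m = toy_matrix({f"c{i}": {"g1": 600} for i in range(10)})
        out, report = qc_filter(m, mito_gene_set=set(), min_cells_per_gene=1)
        assert report.cells_removed_high_mito == 0
        assert out.shape == m.shape

    def test_removals_reconcile_with_dimensions(self):
        rng = np.random.default_rng(3)
        cells = {
            f"c{i}": {
                f"g{j}": int(rng.integers(1, 200))
                for j in rng.choice(30, size=rng.integers(1, 30), replace=False)
            }
            for i in range(40)
        }
        m = toy_matrix(cells)
        out, r = qc_filter(m, mito_gene_set={"g0", "g1"}, min_umis=300,
                           max_umis=2500, min_cells_per_gene=5,
                           max_mito_frac=0.1)
        assert r.input_shape[1] - (
            r.cells_removed_low_umi + r.cells_removed_high_mito
            + r.cells_removed_high_umi
        ) == r.output_shape[1]
        assert r.input_shape[0] - r.genes_removed_low_cells == r.output_shape[0]

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(SchemaError):
            qc_filter(build_matrix({}), min_umis=0)


class TestMtxIO:
    def test_roundtrip_identity(self, tmp_path):
        m = build_matrix({("c1", "g1"): 2, ("c2", "g2"): 1, ("c1", "g3"): 7})
        write_mtx(m, tmp_path)
        assert read_mtx(tmp_path).equals(m)

    def test_empty_matrix_roundtrip(self, tmp_path):
        m = build_matrix({})
        write_mtx(m, tmp_path)
        assert read_mtx(tmp_path).shape == (0, 0)

    def test_out_of_range_entry_rejected(self, tmp_path):
        (tmp_path / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n2 2 1\n3 1 5\n"
        )
        (tmp_path / "features.tsv").write_text("g1\ng2\n")
        (tmp_path / "barcodes.tsv").write_text("c1\nc2\n")
        with pytest.raises(MatrixFormatError):
            read_mtx(tmp_path)

    def test_name_file_dimension_mismatch_rejected(self, tmp_path):
        m = build_matrix({("c1", "g1"): 1})
        write_mtx(m, tmp_path)
        (tmp_path / "features.tsv").write_text("g1\ng2\n")
        with pytest.raises(MatrixFormatError, match="dims"):
            read_mtx(tmp_path)
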