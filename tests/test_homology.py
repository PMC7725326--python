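import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pathtrace import (
    FormatError,
    HomologyMatrix,
    MissingDataError,
    ParameterError,
    aggregate_pangenome,
    count_homologues,
    read_blast_tab,
)


class TestCountHomologues:
    def test_cutoff_filters_hits(self):
        m = count_homologues(
            [("e1", "gA", 1e-10), ("e1", "gB", 1e-3)],
            {"gA": "G", "gB": "G"}, ["e1"], ["G"],
            evalue_cutoff=1e-6,
        )
        assert m.counts.at["e1", "G"] == 1

    def test_distinct_subjects_counted(self):
        m = count_homologues(
            [("e1", "gA", 1e-9), ("e1", "gC", 1e-8)],
            {"gA": "G", "gC": "G"}, ["e1"], ["G"],
        )
        assert m.counts.at["e1", "G"] == 2

    def test_empty_hits_give_zero_matrix(self):
        m = count_homologues([], {}, ["e1", "e2"], ["G", "H"])
        assert m.counts.shape == (2, 2)
        assert (m.values == 0).all()

    def test_duplicate_pairs_deduplicated_best_evalue(self):
        # second HSP for the same pair is weak; the pair still counts once
        m = count_homologues(
            [("e1", "gA", 1e-9), ("e1", "gA", 1e-2), ("e1", "gA", 1e-12)],
            {"gA": "G"}, ["e1"], ["G"],
        )
        assert m.counts.at["e1", "G"] == 1

    def test_unmapped_subject_error_lists_ids(self):
        with pytest.raises(MissingDataError, match="gZ"):
            count_homologues([("e1", "gZ", 1e-9)], {"gA": "G"}, ["e1"], ["G"])

    def test_bad_cutoff(self):
        with pytest.raises(ParameterError):
            count_homologues([], {}, ["e1"], ["G"], evalue_cutoff=0)

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(3)
        hits = [
            (f"e{rng.integers(3)}", f"g{i}", float(10.0 ** -rng.integers(1, 15)))
            for i in range(60)
        ]
        gmap = {f"g{i}": f"G{i % 4}" for i in range(60)}
        enzymes = [f"e{k}" for k in range(3)]
        genomes = [f"G{k}" for k in range(4)]
        loose = count_homologues(hits, gmap, enzymes, genomes, evalue_cutoff=1e-3)
        strict = count_homologues(hits, gmap, enzymes, genomes, evalue_cutoff=1e-9)
        assert (loose.values >= strict.values).all()

    @given(st.integers(0, 10_000))
    def test_order_independent(self, seed):
        rng = np.random.default_rng(seed)
        hits = [
            (f"e{rng.integers(2)}", f"g{rng.integers(8)}", 10.0 ** -float(rng.integers(1, 12)))
            for _ in range(20)
        ]
        gmap = {f"g{i}": f"G{i % 3}" for i in range(8)}
        args = (gmap, ["e0", "e1"], ["G0", "G1", "G2"])
        base = count_homologues(hits, *args)
        perm = [hits[i] for i in rng.permutation(len(hits))]
        assert count_homologues(perm, *args) == base


class TestAggregatePangenome:
    @pytest.fixture
    def matrix(self):
        df = pd.DataFrame(
            {"G1": [2, 0], "G2": [0, 0], "G3": [1, 0]}, index=["e", "f"]
        )
        return HomologyMatrix(df)

    @pytest.mark.parametrize("mode, expected", [("max", 2), ("sum", 3), ("mean", 1.0)])
    def test_modes(self, matrix, mode, expected):
        out = aggregate_pangenome(
            matrix, {"G1": "B", "G2": "B", "G3": "B"}, mode=mode
        )
        assert out.counts.at["e", "B-png"] == expected

    def test_all_zero_members(self, matrix):
        for mode in ("max", "mean", "sum"):
            out = aggregate_pangenome(
                matrix, {"G1": "B", "G2": "B", "G3": "B"}, mode=mode
            )
            assert out.counts.at["f", "B-png"] == 0

    def test_single_member_max_reproduces_column(self, matrix):
        out = aggregate_pangenome(matrix, {"G1": "B"}, mode="max")
        assert (out.counts["B-png"] == matrix.counts["G1"]).all()

    def test_empty_block_error(self, matrix):
        with pytest.raises(MissingDataError):
            aggregate_pangenome(matrix, {"GX": "B"})

    def test_unknown_mode(self, matrix):
        with pytest.raises(ParameterError):
            aggregate_pangenome(matrix, {"G1": "B"}, mode="median")

    def test_virtual_column_lands_in_its_block_run(self, matrix):
        out = aggregate_pangenome(matrix, {"G1": "B", "G2": "B"})
        cols = out.genomes
        b_cols = [c for c in cols if out.blocks.get(c) == "B"]
        idx = [cols.index(c) for c in b_cols]
        assert idx == list(range(min(idx), max(idx) + 1))  # contiguous


class TestMatrixIO:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.integers(0, 9, size=(3, 4)),
            index=[f"e{i}" for i in range(3)],
            columns=[f"G{j}" for j in range(4)],
        )
        m = HomologyMatrix(df)
        path = tmp_path / "m.tsv"
        m.write_tsv(path)
        assert HomologyMatrix.read_tsv(path) == m

    def test_negative_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("enzyme\tG1\ne1\t-3\n")
        with pytest.raises(FormatError, match="negative"):
            HomologyMatrix.read_tsv(path)

    def test_non_numeric_cell_names_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("enzyme\tG1\ne1\t2\ne2\toops\n")
        with pytest.raises(FormatError, match="row 3"):
            HomologyMatrix.read_tsv(path)

    def test_shape_summary_counts_cells(self):
        df = pd.DataFrame(
            np.zeros((86, 182)),
            index=[f"e{i}" for i in range(86)],
            columns=[f"G{j}" for j in range(182)],
        )
        assert HomologyMatrix(df).shape_summary()["n_cells"] == 15652

    def test_blocks_force_contiguous_columns(self):
        df = pd.DataFrame(
            np.zeros((1, 4)), index=["e"], columns=["a1", "b1", "a2", "b2"]
        )
        m = HomologyMatrix(df, blocks={"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert m.genomes == ["a1", "a2", "b1", "b2"]

    def test_duplicate_labels_rejected(self):
        df = pd.DataFrame(np.zeros((2, 1)), index=["e", "e"], columns=["G"])
        with pytest.raises(FormatError):
            HomologyMatrix(df)


def test_read_blast_tab_consumes_columns_1_2_11(tmp_path):
    path = tmp_path / "hits.tsv"
    row = ["q1", "s1", "99.0", "100", "1", "0", "1", "100", "5", "104", "2e-30", "190"]
    path.write_text("\t".join(row) + "\n")
    df = read_blast_tab(path)
    assert list(df.columns) == ["qseqid", "sseqid", "evalue"]
    assert df.iloc[0, 0] == "q1" and df.iloc[0, 1] == "s1"
    assert df.iloc[0, 2] == pytest.approx(2e-30)
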