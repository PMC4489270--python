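"""BLAST tabular parsing, top-hit selection, matrix assembly and filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phyloprofile import (
    BlastHit,
    BlastParseError,
    GenomeManifest,
    ManifestEntry,
    MatrixError,
    build_raw_matrix,
    filter_low_scores,
    filter_sparse_queries,
    read_blast_tab,
    select_top_hits,
)
from phyloprofile.blast_io import read_matrix_tsv, write_matrix_tsv

LINE = "q1\ts9\t88.0\t100\t5\t1\t1\t100\t1\t100\t1e-50\t197.0\n"


def _hit(q="q1", s="s1", g="g1", score=100.0, evalue=1e-10):
    return BlastHit(q, s, evalue, score, g)


class TestReadBlastTab:
    def test_maps_fields(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(LINE)
        (hit,) = read_blast_tab(path, "g1")
        assert hit == BlastHit("q1", "s9", 1e-50, 197.0, "g1")

    def test_comment_only_file_is_empty_list(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("# BLASTP 2.x\n# Query: q1\n")
        assert read_blast_tab(path, "g1") == []

    def test_empty_file_is_empty_list(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("")
        assert read_blast_tab(path, "g1") == []

    def test_order_preserved(self, tmp_path):
        path = tmp_path / "hits.tsv"
        lines = [
            LINE.replace("s9", f"s{i}").replace("197.0", str(100.0 + i))
            for i in range(3)
        ]
        path.write_text("".join(lines))
        hits = read_blast_tab(path, "g1")
        assert [h.subject_id for h in hits] == ["s0", "s1", "s2"]

    @pytest.mark.parametrize(
        "bad", ["q1\ts9\tonly-three-fields\n", LINE.replace("197.0", "xyz")]
    )
    def test_malformed_line_names_line_number(self, tmp_path, bad):
        path = tmp_path / "hits.tsv"
        path.write_text("# header\n" + LINE + bad)
        with pytest.raises(BlastParseError, match=r":3:"):
            read_blast_tab(path, "g1")


class TestSelectTopHits:
    def test_keeps_maximum(self):
        hits = [_hit(score=s) for s in (197.0, 55.0, 20.0)]
        top = select_top_hits(hits)
        assert top[("q1", "g1")].bit_score == 197.0

    def test_tie_keeps_first_occurrence(self):
        hits = [_hit(s="first", score=50.0), _hit(s="second", score=50.0)]
        top = select_top_hits(hits)
        assert top[("q1", "g1")].subject_id == "first"

    def test_matches_naive_grouping_oracle(self):
        rng = np.random.default_rng(42)
        hits = [
            _hit(q=f"q{i}", g=f"g{j}", s=f"s{k}", score=float(rng.integers(1, 500)))
            for i in range(2)
            for j in range(3)
            for k in range(4)
        ]
        rng.shuffle(hits)
        top = select_top_hits(hits)
        assert len(top) == 6
        for (q, g), best in top.items():
            group = [h.bit_score for h in hits if (h.query_id, h.genome_id) == (q, g)]
            assert best.bit_score == max(group)


class TestBuildRawMatrix:
    def test_absent_pairs_are_missing(self, tiny_manifest):
        top = {
            ("p1", "g1"): _hit(),
            ("p1", "g2"): _hit(),
            ("p2", "g1"): _hit(),
            ("p2", "g3"): _hit(),
        }
        mat = build_raw_matrix(top, ["p1", "p2"], tiny_manifest)
        assert mat.shape == (2, 4)
        assert int(mat.isna().sum().sum()) == 4

    def test_empty_top_hits_gives_all_missing(self, tiny_manifest):
        mat = build_raw_matrix({}, ["p1", "p2"], tiny_manifest)
        assert mat.isna().all().all()

    def test_unknown_genome_is_error(self, tiny_manifest):
        with pytest.raises(MatrixError, match="g99"):
            build_raw_matrix({("p1", "g99"): 10.0}, ["p1"], tiny_manifest)

    def test_duplicate_protein_ids_error(self, tiny_manifest):
        with pytest.raises(MatrixError, match="duplicate"):
            build_raw_matrix({}, ["p1", "p1"], tiny_manifest)

    def test_columns_follow_manifest_order(self, tiny_manifest):
        mat = build_raw_matrix({("p1", "g3"): 7.0}, ["p1"], tiny_manifest)
        assert list(mat.columns) == ["g1", "g2", "g3", "g4"]


class TestFilterLowScores:
    def test_threshold_is_strict_below(self, raw_small):
        out = filter_low_scores(raw_small, 50.0)
        assert out.at["p1", "g4"] == 50.0  # exactly 50 survives
        out2 = filter_low_scores(raw_small.replace(50.0, 49.9), 50.0)
        assert np.isnan(out2.at["p1", "g4"])

    def test_zero_threshold_is_identity(self, raw_small):
        pd.testing.assert_frame_equal(filter_low_scores(raw_small, 0.0), raw_small)

    def test_counts_match_per_cell_comparison(self, tiny_manifest):
        mat = build_raw_matrix(
            {("p1", g): s for g, s in zip("g1 g2 g3 g4".split(), [20, 49, 50, 197])},
            ["p1"],
            tiny_manifest,
        )
        out = filter_low_scores(mat, 50.0)
        assert int(out.notna().sum().sum()) == 2

    @given(
        st.lists(st.floats(0, 500, allow_nan=False), min_size=1, max_size=30),
        st.floats(0, 300),
        st.floats(0, 300),
    )
    def test_idempotent_and_monotone(self, scores, t1, t2):
        mat = pd.DataFrame({"g": scores})
        once = filter_low_scores(mat, t1)
        pd.testing.assert_frame_equal(filter_low_scores(once, t1), once)
        lo, hi = sorted([t1, t2])
        n_hi = filter_low_scores(mat, hi).notna().sum().sum()
        n_lo = filter_low_scores(mat, lo).notna().sum().sum()
        assert n_hi <= n_lo


class TestFilterSparseQueries:
    def test_row_below_fraction_removed(self, tiny_manifest):
        mat = build_raw_matrix({("p1", "g1"): 100.0}, ["p1", "p2"], tiny_manifest)
        mat.loc["p2"] = 100.0
        out, removed = filter_sparse_queries(mat, 0.5)
        assert removed == ["p1"] and list(out.index) == ["p2"]

    def test_zero_fraction_removes_nothing(self, raw_small):
        out, removed = filter_sparse_queries(raw_small, 0.0)
        assert removed == [] and out.shape == raw_small.shape

    def test_fractions_against_per_row_oracle(self, tiny_manifest):
        rows = {"a": [1, 0, 0, 0], "b": [1, 1, 0, 0], "c": [1, 1, 1, 1]}
        mat = pd.DataFrame(
            {g: [100.0 if rows[p][j] else np.nan for p in "abc"]
             for j, g in enumerate(tiny_manifest.genome_ids)},
            index=list("abc"),
        )
        out, removed = filter_sparse_queries(mat, 0.5)
        assert set(out.index) == {"b", "c"} and removed == ["a"]

    def test_all_removed_is_error(self, raw_small):
        with pytest.raises(MatrixError, match="min_fraction"):
            filter_sparse_queries(raw_small.mask(raw_small > 0), 0.5)


def test_matrix_tsv_roundtrip_preserves_missing(tmp_path, raw_small):
    path = tmp_path / "m.tsv"
    write_matrix_tsv(raw_small, path)
    back = read_matrix_tsv(path)
    pd.testing.assert_frame_equal(back, raw_small, check_names=False)


def test_manifest_roundtrip_and_grouping(tmp_path, tiny_manifest):
    path = tmp_path / "manifest.tsv"
    tiny_manifest.to_tsv(path)
    back = GenomeManifest.from_tsv(path)
    assert back == tiny_manifest
    assert back.taxon_boundaries() == [2]
    assert [b[1] for b in back.subtaxon_blocks()] == [
        "Vertebrates", "Insects", "Ascomycetes", "Basidiomycetes",
    ]


def test_manifest_rejects_duplicates_and_missing_query():
    e = ManifestEntry
    with pytest.raises(MatrixError, match="duplicate"):
        GenomeManifest((e("g1", "a", "t", "s"), e("g1", "b", "t", "s")), "g1")
    with pytest.raises(MatrixError, match="query genome"):
        GenomeManifest((e("g1", "a", "t", "s"),), "g9")
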