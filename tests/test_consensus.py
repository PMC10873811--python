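"""Levenshtein, similarity matrix, affine-gap alignment, MSA, consensus."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbocr.consensus import (
    GAP,
    AlignmentParams,
    MSAResult,
    SimilarityMatrix,
    build_msa,
    call_consensus,
    default_similarity_matrix,
    levenshtein,
    pairwise_align,
    pre_substitutions,
    prune_outliers,
)
from herbocr.engines import NoiseModel, OCRStream, simulate_ocr
from oracles import best_affine_alignment_enum, levenshtein_dp

MATRIX = default_similarity_matrix()
PARAMS = AlignmentParams()

short_text = st.text(
    alphabet="aAbB1lIO0.,5SzZ |wW ", min_size=0, max_size=10
)


def streams(texts):
    return [OCRStream(t, f"e{i}", "V1_none") for i, t in enumerate(texts)]


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("", "", 0), ("same", "same", 0), ("", "abc", 3),
         ("kitten", "sitting", 3), ("flaw", "lawn", 2)],
    )
    def test_known_distances(self, a, b, expected):
        assert levenshtein(a, b) == expected

    @given(a=short_text, b=short_text)
    def test_matches_dp_oracle_and_metric_axioms(self, a, b):
        d = levenshtein(a, b)
        assert d == levenshtein_dp(a, b)
        assert d == levenshtein(b, a)
        assert (d == 0) == (a == b)

    @given(a=short_text, b=short_text, c=short_text)
    def test_triangle_inequality(self, a, b, c):
        assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


class TestSimilarityMatrix:
    def test_endpoint_scores(self):
        assert MATRIX.score("a", "a") == 2.0  # identical glyphs
        assert MATRIX.score(".", "W") == -2.0  # grossly different shapes
        assert MATRIX.score("l", "1") == 1.0  # lookalike class

    def test_category_defaults(self):
        assert MATRIX.score("a", "b") == 0.0
        assert MATRIX.score("a", "7") == -1.0
        assert MATRIX.score("a", "A") == 1.0  # case pair
        assert MATRIX.score(" ", " ") == 2.0
        assert MATRIX.score(" ", "x") == -2.0

    @given(a=st.characters(min_codepoint=32, max_codepoint=126),
           b=st.characters(min_codepoint=32, max_codepoint=126))
    def test_symmetric_bounded_diagonal(self, a, b):
        s = MATRIX.score(a, b)
        assert -2.0 <= s <= 2.0
        assert s == MATRIX.score(b, a)
        assert MATRIX.score(a, a) == 2.0

    def test_tsv_round_trip_and_validation(self, tmp_path):
        f = tmp_path / "m.tsv"
        f.write_text("l1I|\tthin\nO0o\tround\nthin\tround\t-0.5\n")
        m = SimilarityMatrix.from_tsv(f)
        assert m.score("l", "I") == 1.0
        assert m.score("1", "0") == -0.5
        bad = tmp_path / "bad.tsv"
        bad.write_text("ab\tx\ncd\ty\nx\ty\t9\n")
        with pytest.raises(ValueError, match="outside"):
            SimilarityMatrix.from_tsv(bad)
        dup = tmp_path / "dup.tsv"
        dup.write_text("ab\tx\nbc\ty\n")
        with pytest.raises(ValueError, match="assigned"):
            SimilarityMatrix.from_tsv(dup)

    def test_asymmetric_scores_rejected(self):
        with pytest.raises(ValueError, match="asymmetric"):
            SimilarityMatrix(
                classes={"a": "x", "b": "y"},
                class_scores={("x", "y"): 1.0, ("y", "x"): 0.0},
            )


class TestPairwiseAlign:
    def test_identity_alignment_gapless(self):
        got = pairwise_align("Quercus", "Quercus", MATRIX, PARAMS)
        assert got.a == got.b == "Quercus"
        assert got.score == 2.0 * len("Quercus")

    def test_gap_run_costs_open_plus_extends(self):
        got = pairwise_align("AB", "", MATRIX, PARAMS)
        assert got.score == -3.5  # open -3, one extension -0.5
        assert got.a == "AB" and got.b == GAP * 2

    def test_gap_sentinel_rejected_in_input(self):
        with pytest.raises(ValueError):
            pairwise_align("a" + GAP, "b", MATRIX, PARAMS)

    def test_matches_exhaustive_enumeration(self, rng):
        alpha = "aAbB1lO0. zS5W,"
        for _ in range(150):
            a = "".join(alpha[i] for i in rng.integers(0, len(alpha),
                                                       rng.integers(0, 9)))
            b = "".join(alpha[i] for i in rng.integers(0, len(alpha),
                                                       rng.integers(0, 9)))
            got = pairwise_align(a, b, MATRIX, PARAMS)
            exp = best_affine_alignment_enum(a, b, MATRIX.score,
                                             PARAMS.gap_open, PARAMS.gap_extend)
            assert got.score == pytest.approx(exp, abs=1e-9), (a, b)

    @given(a=short_text, b=short_text)
    @settings(max_examples=60)
    def test_gap_stripping_recovers_inputs(self, a, b):
        got = pairwise_align(a, b, MATRIX, PARAMS)
        assert got.a.replace(GAP, "") == a
        assert got.b.replace(GAP, "") == b
        assert len(got.a) == len(got.b)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            AlignmentParams(gap_open=-0.1, gap_extend=-3.0)


class TestPruneOutliers:
    def test_identical_streams_none_pruned(self):
        surv, pruned = prune_outliers(streams(["abc"] * 5))
        assert len(surv) == 5 and pruned == []

    def test_distant_failure_pruned(self):
        texts = ["Flora of Texas"] * 3 + ["#" * 300]
        surv, pruned = prune_outliers(streams(texts), cutoff=128)
        assert [s.text for s in pruned] == ["#" * 300]
        assert len(surv) == 3

    def test_two_streams_never_pruned(self):
        surv, pruned = prune_outliers(streams(["abc", "#" * 500]), cutoff=10)
        assert len(surv) == 2 and pruned == []

    def test_matches_pairwise_table_oracle(self, rng):
        texts = ["Carex alba", "Carex alba!", "Carex  alba", "Z" * 60, "Carex alha"]
        surv, pruned = prune_outliers(streams(texts), cutoff=20)
        # oracle: full distance table, anchor = argmin pair
        n = len(texts)
        d = [[levenshtein_dp(texts[i], texts[j]) for j in range(n)] for i in range(n)]
        ai, aj = min(((i, j) for i in range(n) for j in range(i + 1, n)),
                     key=lambda p: d[p[0]][p[1]])
        expect_keep = [t for k, t in enumerate(texts)
                       if k in (ai, aj) or min(d[k][ai], d[k][aj]) <= 20]
        assert [s.text for s in surv] == expect_keep

    @given(st.lists(short_text, min_size=1, max_size=6))
    def test_never_removes_more_than_n_minus_2(self, texts):
        surv, pruned = prune_outliers(streams(texts), cutoff=0)
        assert len(surv) >= min(len(texts), 2)
        assert len(pruned) <= max(0, len(texts) - 2)


class TestPreSubstitutions:
    @pytest.mark.parametrize(
        "raw,expected",
        [("Austin , Texas .", "Austin, Texas."),
         ("no change here.", "no change here."),
         ("double  spaces   collapse", "double spaces collapse")],
    )
    def test_default_rules(self, raw, expected):
        assert pre_substitutions(raw) == expected

    @given(short_text)
    def test_idempotent(self, text):
        once = pre_substitutions(text)
        assert pre_substitutions(once) == once


class TestMSA:
    def test_identical_texts_gapless(self):
        msa = build_msa(streams(["Carex"] * 4), MATRIX, PARAMS)
        assert msa.rows == ["Carex"] * 4
        assert msa.column_count == 5

    def test_cat_cot_three_columns(self):
        msa = build_msa(streams(["cat", "cat", "cot"]), MATRIX, PARAMS)
        assert msa.column_count == 3
        assert all(GAP not in r for r in msa.rows)

    def test_single_stream_trivial(self):
        msa = build_msa(streams(["only"]), MATRIX, PARAMS)
        assert msa.rows == ["only"] and msa.seed_index == 0

    @given(st.lists(short_text, min_size=1, max_size=5))
    @settings(max_examples=60)
    def test_gap_stripping_reproduces_every_input(self, texts):
        ss = streams(texts)
        msa = build_msa(ss, MATRIX, PARAMS)
        by_id = dict(zip(msa.stream_ids, msa.rows))
        for s in ss:
            key = f"{s.engine_id}@{s.variant_id}"
            assert by_id[key].replace(GAP, "") == s.text

    def test_rows_equal_length_enforced(self):
        with pytest.raises(ValueError):
            MSAResult(rows=["ab", "abc"], stream_ids=["x", "y"], seed_index=0)


class TestConsensus:
    def test_majority_column_vote_with_support(self):
        msa = build_msa(streams(["cat", "cat", "cot"]), MATRIX, PARAMS)
        cons = call_consensus(msa)
        assert cons.text == "cat"
        assert cons.support == (1.0, 2 / 3, 1.0)

    @pytest.mark.parametrize("n", range(1, 9))
    def test_identical_texts_identity(self, n, label_text):
        msa = build_msa(streams([label_text] * n), MATRIX, PARAMS)
        cons = call_consensus(msa)
        assert cons.text == label_text
        assert all(s == 1.0 for s in cons.support)

    def test_tie_breaks_to_seed_row_symbol(self):
        msa = MSAResult(rows=["ab", "a" + GAP], stream_ids=["s0", "s1"],
                        seed_index=0)
        assert call_consensus(msa).text == "ab"
        msa_rev = MSAResult(rows=["a" + GAP, "ab"], stream_ids=["s1", "s0"],
                            seed_index=0)
        assert call_consensus(msa_rev).text == "a"

    def test_gap_plurality_emits_nothing(self):
        msa = MSAResult(rows=["ab" + GAP, "a" + GAP * 2, "a" + GAP + "c"],
                        stream_ids=list("xyz"), seed_index=1)
        assert call_consensus(msa).text == "a"


class TestRecovery:
    def test_consensus_beats_mean_stream_error(self, label_text):
        """Small-scale ensemble-gain check: consensus CER < mean stream CER."""
        wins = 0
        trials = 10
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            sub, ins, dele = 0.05, 0.015, 0.02
            ss = []
            for k in range(5):
                m = NoiseModel(sub, ins, dele, seed=1000 * seed + k)
                ss.append(simulate_ocr(label_text, m, engine_id=f"sim{k}"))
            cons = call_consensus(build_msa(ss, MATRIX, PARAMS))
            cons_err = levenshtein(cons.text, label_text)
            mean_err = np.mean([levenshtein(s.text, label_text) for s in ss])
            wins += cons_err < mean_err
        assert wins >= 8
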