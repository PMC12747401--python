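import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import pairwise_independent_cost, transport_bruteforce
from sharedness.embeddings import EmbeddingTable
from sharedness.tsi import (
    SIM_TRANSFORMS,
    build_nbow,
    compute_tsi,
    similarity,
    tokenize,
    wmd,
)

token_lists = st.lists(st.sampled_from(["alpha", "beta", "gamma", "nope", "delta"]), max_size=12)


class TestTokenize:
    def test_whitespace_and_punctuation(self):
        assert tokenize("A meeting was held.") == ["a", "meeting", "was", "held"]

    def test_empty(self):
        assert tokenize("") == []

    def test_punctuation_rich(self):
        assert tokenize("well-being: 'good', right?!") == ["well", "being", "good", "right"]

    @given(st.lists(st.from_regex(r"[a-z0-9]+", fullmatch=True), max_size=8))
    def test_round_trip_on_alphanumerics(self, tokens):
        assert tokenize(" ".join(tokens)) == tokens

    def test_plugin_contract(self):
        assert tokenize("A B", tokenizer_plugin=str.split) == ["A", "B"]


class TestBuildNbow:
    def test_count_normalization(self, tiny_embeddings):
        doc = build_nbow(["alpha", "alpha", "beta"], tiny_embeddings)
        weights = dict(zip(doc.support, doc.weights))
        assert weights["alpha"] == pytest.approx(2 / 3)
        assert weights["beta"] == pytest.approx(1 / 3)

    def test_oov_dropped(self, tiny_embeddings):
        doc = build_nbow(["alpha", "unknown_token"], tiny_embeddings)
        assert doc.support == ("alpha",)

    def test_all_oov_is_unusable(self, tiny_embeddings):
        assert not build_nbow(["nope", "nada"], tiny_embeddings).usable

    @given(token_lists)
    def test_weights_sum_to_one(self, tokens):
        emb = EmbeddingTable({t: np.array([float(hash(t) % 7), 1.0]) for t in ["alpha", "beta", "gamma", "delta"]})
        doc = build_nbow(tokens, emb)
        if doc.usable:
            assert float(np.sum(doc.weights)) == pytest.approx(1.0, abs=1e-9)


def _random_docs(rng, emb, max_support=3):
    toks = rng.choice(sorted(emb.vocabulary), size=rng.integers(1, max_support + 1), replace=False)
    return build_nbow(
        [t for t, k in zip(toks, rng.integers(1, 5, len(toks))) for _ in range(k)], emb
    )


class TestWmd:
    def test_identity(self, tiny_embeddings):
        doc = build_nbow(["alpha", "beta", "beta"], tiny_embeddings)
        assert wmd(doc, doc, tiny_embeddings) == pytest.approx(0.0, abs=1e-9)

    def test_single_token_closed_form(self, tiny_embeddings):
        a = build_nbow(["alpha"], tiny_embeddings)
        b = build_nbow(["beta"], tiny_embeddings)
        assert wmd(a, b, tiny_embeddings) == pytest.approx(5.0, abs=1e-9)

    def test_unusable_doc_raises(self, tiny_embeddings):
        a = build_nbow(["alpha"], tiny_embeddings)
        empty = build_nbow(["oov"], tiny_embeddings)
        with pytest.raises(ValueError, match="skip"):
            wmd(a, empty, tiny_embeddings)

    def test_matches_vertex_enumeration(self, tiny_embeddings):
        rng = np.random.default_rng(42)
        for _ in range(50):
            a = _random_docs(rng, tiny_embeddings)
            b = _random_docs(rng, tiny_embeddings)
            C = np.array(
                [[np.linalg.norm(tiny_embeddings[u] - tiny_embeddings[v]) for v in b.support] for u in a.support]
            )
            expected = transport_bruteforce(a.weights, b.weights, C)
            assert wmd(a, b, tiny_embeddings) == pytest.approx(expected, abs=1e-8)

    def test_metric_properties_and_bounds(self, tiny_embeddings):
        rng = np.random.default_rng(7)
        docs = [_random_docs(rng, tiny_embeddings) for _ in range(12)]
        emb = tiny_embeddings
        for a, b in combinations(docs, 2):
            d_ab = wmd(a, b, emb)
            assert d_ab >= 0
            assert wmd(b, a, emb) == pytest.approx(d_ab, abs=1e-9)
            # centroid (word-centroid distance) lower bound, independent coupling upper bound
            ca = a.weights @ emb.matrix(a.support)
            cb = b.weights @ emb.matrix(b.support)
            C = np.array([[np.linalg.norm(emb[u] - emb[v]) for v in b.support] for u in a.support])
            assert d_ab >= np.linalg.norm(ca - cb) - 1e-9
            assert d_ab <= pairwise_independent_cost(a.weights, b.weights, C) + 1e-9
        for a, b, c in combinations(docs, 3):
            assert wmd(a, c, emb) <= wmd(a, b, emb) + wmd(b, c, emb) + 1e-9

    def test_cosine_ground_metric_flag(self, tiny_embeddings):
        a = build_nbow(["gamma"], tiny_embeddings)
        b = build_nbow(["zeta"], tiny_embeddings)
        # opposite unit vectors: cosine distance 2, euclidean 2
        assert wmd(a, b, tiny_embeddings, metric="cosine") == pytest.approx(2.0, abs=1e-9)


class TestSimilarity:
    @pytest.mark.parametrize("transform,expected", [("neg", 0.0), ("inv", 1.0), ("exp", 1.0)])
    def test_zero_distance_is_maximal(self, transform, expected):
        assert similarity(0.0, transform) == expected

    @given(st.floats(0, 50), st.floats(0, 50))
    def test_strictly_decreasing(self, d1, d2):
        if d1 + 1e-6 < d2:
            for name in SIM_TRANSFORMS:
                assert similarity(d1, name) > similarity(d2, name)

    def test_unknown_transform(self):
        with pytest.raises(ValueError, match="unknown transform"):
            similarity(1.0, "sigmoid")

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            similarity(-0.1)


class TestComputeTsi:
    def test_identical_diaries_reach_maximum(self, tiny_embeddings):
        docs = [build_nbow(["alpha", "beta"], tiny_embeddings, member_id=m) for m in "ij"]
        tsi, pairs = compute_tsi(docs, tiny_embeddings)
        assert tsi == pytest.approx(0.0, abs=1e-9)
        assert len(pairs) == 1

    def test_two_members_single_pair(self, tiny_embeddings):
        a = build_nbow(["alpha"], tiny_embeddings, member_id="i")
        b = build_nbow(["beta"], tiny_embeddings, member_id="j")
        tsi, pairs = compute_tsi([a, b], tiny_embeddings)
        assert tsi == pytest.approx(-5.0, abs=1e-9)
        assert pairs[0].similarity == pytest.approx(-pairs[0].distance)

    def test_three_members_average_over_enumerated_pairs(self, tiny_embeddings):
        docs = [
            build_nbow(toks, tiny_embeddings, member_id=str(k))
            for k, toks in enumerate([["alpha"], ["beta", "gamma"], ["delta", "delta", "alpha"]])
        ]
        tsi, pairs = compute_tsi(docs, tiny_embeddings)
        brute = np.mean([-wmd(a, b, tiny_embeddings) for a, b in combinations(docs, 2)])
        assert len(pairs) == 3
        assert tsi == pytest.approx(brute, abs=1e-9)

    def test_fewer_than_two_usable_is_missing(self, tiny_embeddings):
        only = build_nbow(["alpha"], tiny_embeddings)
        unusable = build_nbow(["oov"], tiny_embeddings)
        tsi, pairs = compute_tsi([only, unusable], tiny_embeddings)
        assert math.isnan(tsi) and pairs == []

    def test_member_order_invariance(self, tiny_embeddings):
        docs = [build_nbow([t], tiny_embeddings, member_id=t) for t in ("alpha", "beta", "gamma")]
        t1, _ = compute_tsi(docs, tiny_embeddings)
        t2, _ = compute_tsi(docs[::-1], tiny_embeddings)
        assert t1 == pytest.approx(t2, abs=1e-12)
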