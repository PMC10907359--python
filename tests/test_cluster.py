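import math

import numpy as np
import pytest

from conftest import make_corpus
from helpers import exhaustive_kmeans
from opinionflow.cluster import (
    DimensionLexicon,
    assign_clusters_to_indicators,
    build_word_vectors,
    default_lexicon,
    kmeans,
    synthetic_lexicon,
)
from opinionflow.tfidf import tfidf_scores, top_keywords


class TestWordVectors:
    def test_token_confined_to_one_document(self):
        corpus = make_corpus([["t", "u"], ["u", "v"], ["v"]])
        vecs = build_word_vectors(corpus, ["t"], l2_normalize=False)
        w = 0.5 * math.log(3 / 2)  # tf * ln(D/(1+df)) in doc 1
        assert vecs.matrix[0, 0] == pytest.approx(w)
        assert w > 0
        assert vecs.matrix[0, 1] == 0.0 and vecs.matrix[0, 2] == 0.0

    def test_l2_normalized_vectors_have_unit_norm(self, recovery_corpus):
        table = top_keywords(tfidf_scores(recovery_corpus), 50)
        vecs = build_word_vectors(recovery_corpus, table)
        norms = np.linalg.norm(vecs.matrix, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-12)

    def test_entries_match_per_document_recomputation(self):
        docs = [["a", "a", "b"], ["b", "c"], ["a", "c", "c"]]
        corpus = make_corpus(docs)
        vecs = build_word_vectors(corpus, ["a", "b", "c"], l2_normalize=False)
        for i, tok in enumerate(["a", "b", "c"]):
            df = sum(1 for d in docs if tok in d)
            for j, doc in enumerate(docs):
                tf = doc.count(tok) / len(doc)
                expected = tf * math.log(len(docs) / (1 + df))
                assert vecs.matrix[i, j] == pytest.approx(expected, abs=1e-12)

    def test_absent_keyword_raises_naming_token(self):
        corpus = make_corpus([["a"]])
        with pytest.raises(ValueError, match="ghost"):
            build_word_vectors(corpus, ["a", "ghost"])


class TestKMeans:
    def test_two_clear_clusters_in_one_dimension(self):
        res = kmeans(np.array([0.0, 1.0, 10.0, 11.0]), k=2, seed=0)
        assert res.loss == pytest.approx(1.0, abs=1e-12)
        assert sorted(res.centroids[:, 0]) == pytest.approx([0.5, 10.5])
        assert res.assignments[0] == res.assignments[1]
        assert res.assignments[2] == res.assignments[3]
        assert res.assignments[0] != res.assignments[2]

    def test_single_cluster_centroid_is_mean(self):
        res = kmeans(np.array([0.0, 1.0, 10.0, 11.0]), k=1, seed=0)
        assert res.centroids[0, 0] == pytest.approx(5.5)
        assert res.loss == pytest.approx(101.0)

    def test_k_equals_n_gives_zero_loss(self):
        res = kmeans(np.array([0.0, 1.0, 10.0, 11.0]), k=4, seed=0)
        assert res.loss == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k", [0, 5])
    def test_invalid_k_rejected(self, k):
        with pytest.raises(ValueError):
            kmeans(np.arange(4.0), k=k)

    def test_loss_never_increases_across_iterations(self):
        rng = np.random.default_rng(0)
        x = np.vstack(
            [rng.normal(c, 1.0, size=(30, 3)) for c in (0.0, 5.0, 10.0)]
        )
        res = kmeans(x, k=3, seed=1)
        assert all(
            later <= earlier + 1e-9
            for earlier, later in zip(res.loss_history, res.loss_history[1:])
        )

    def test_final_assignments_are_nearest_centroid(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 2))
        res = kmeans(x, k=4, seed=3)
        d2 = ((x[:, None, :] - res.centroids[None]) ** 2).sum(axis=2)
        assert np.array_equal(res.assignments, d2.argmin(axis=1))

    def test_reported_loss_equals_assignment_distances(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(25, 2))
        res = kmeans(x, k=3, seed=5)
        recomputed = ((x - res.centroids[res.assignments]) ** 2).sum()
        assert res.loss == pytest.approx(recomputed, abs=1e-9)

    @pytest.mark.parametrize("n, k, seed", [(6, 2, 0), (8, 3, 1), (7, 3, 2)])
    def test_matches_exhaustive_partition_optimum(self, n, k, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        res = kmeans(x, k=k, seed=seed, n_restarts=20)
        assert res.loss == pytest.approx(exhaustive_kmeans(x, k), rel=1e-9)

    def test_agrees_with_sklearn_reference(self):
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(7)
        x = np.vstack([rng.normal(c, 0.5, size=(20, 4)) for c in (0, 4, 8)])
        ours = kmeans(x, k=3, seed=1, n_restarts=10)
        ref = sklearn_cluster.KMeans(n_clusters=3, n_init=10, random_state=0).fit(x)
        assert ours.loss == pytest.approx(ref.inertia_, rel=1e-6)


class TestLexicon:
    def test_duplicate_seed_words_rejected(self):
        with pytest.raises(ValueError, match="seed word"):
            DimensionLexicon(
                indicators={"d1": {"i1": ["x"], "i2": ["x"]}}
            )

    def test_json_round_trip(self, tmp_path):
        lex = default_lexicon()
        path = tmp_path / "lex.json"
        lex.to_json(path)
        assert DimensionLexicon.from_json(path).indicators == lex.indicators

    def test_infection_cluster_maps_to_original_event(self):
        # a cluster holding the infection seed words lands on that indicator
        res_tokens = ["cases", "positive", "od_x"]
        from opinionflow.cluster import ClusteringResult

        res = ClusteringResult(
            k=1,
            assignments=np.zeros(3, dtype=int),
            centroids=np.zeros((1, 2)),
            loss=0.0,
            n_iterations=1,
            seed=0,
            tokens=res_tokens,
        )
        mapping = assign_clusters_to_indicators(res, default_lexicon())
        assert mapping[0] == ("original_event", "infections")

    def test_cluster_without_seed_words_is_unassigned(self):
        from opinionflow.cluster import ClusteringResult

        res = ClusteringResult(
            k=1,
            assignments=np.zeros(2, dtype=int),
            centroids=np.zeros((1, 2)),
            loss=0.0,
            n_iterations=1,
            seed=0,
            tokens=["nope", "nada"],
        )
        mapping = assign_clusters_to_indicators(res, default_lexicon())
        assert mapping[0] == ("unassigned", "unassigned")

    def test_synthetic_lexicon_covers_all_dimensions(self, recovery_corpus):
        lex = synthetic_lexicon(recovery_corpus)
        assert set(lex.dimensions) == {
            "original_event",
            "derived_event",
            "public_prediction",
            "public_expectation",
        }
        assert lex.n_indicators == 4
        for dim, _, seeds in lex.items():
            assert all(recovery_corpus.truth[s] == dim for s in seeds)
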