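import itertools

import numpy as np
import pytest
from scipy import stats

from emrkg.evaluation import (
    PhysicianTags,
    binarize_tags,
    load_physician_tags,
    per_disease_precision,
    pool_top_edges,
    pr_vs_reference,
    pr_vs_tags,
    spearman_agreement,
    wilcoxon_compare,
)
from emrkg.graph import KnowledgeGraph
from emrkg.vocabulary import ReferenceEdge, ReferenceGraph


def _reference(pairs):
    return ReferenceGraph(
        edges={ReferenceEdge(d, s, "frequent") for d, s in pairs}
    )


class TestPrVsReference:
    def test_hand_enumerated_points(self):
        ref = _reference([("d", "s1"), ("d", "s2")])
        scores = {("d", "s1"): 0.9, ("d", "s3"): 0.5, ("d", "s2"): 0.3}
        curve = pr_vs_reference(scores, ref, exclude_symptoms=())
        assert (0.9, 1.0, 0.5) in curve.points
        assert (0.3, pytest.approx(2 / 3), 1.0) in curve.points

    def test_perfect_retrieval(self):
        ref = _reference([("d", "s1"), ("d", "s2")])
        scores = {("d", "s1"): 0.9, ("d", "s2"): 0.8}
        curve = pr_vs_reference(scores, ref, exclude_symptoms=())
        t, p, r = curve.points[-1]
        assert p == 1.0 and r == 1.0

    def test_all_reference_excluded_raises(self):
        ref = _reference([("d", "s1"), ("d", "s2")])
        with pytest.raises(ValueError, match="empty"):
            pr_vs_reference({("d", "s1"): 0.5}, ref, exclude_symptoms=("s1", "s2"))

    def test_pain_excluded_by_default(self):
        ref = _reference([("d", "pain"), ("d", "s2")])
        scores = {("d", "pain"): 0.99, ("d", "s2"): 0.5}
        curve = pr_vs_reference(scores, ref)
        # the 'pain' candidate and reference edge are both dropped
        assert curve.points == [(0.5, 1.0, 1.0)]

    def test_invariant_to_duplicate_candidates_and_order(self):
        ref = _reference([("d", "s1")])
        scores_a = {("d", "s1"): 0.9, ("d", "s2"): 0.5}
        scores_b = dict(reversed(list(scores_a.items())))
        a = pr_vs_reference(scores_a, ref, exclude_symptoms=())
        b = pr_vs_reference(scores_b, ref, exclude_symptoms=())
        assert a.points == b.points

    def test_precision_times_retrieved_is_integer(self):
        rng = np.random.default_rng(0)
        pairs = [("d", f"s{i}") for i in range(30)]
        ref = _reference([p for p in pairs if rng.random() < 0.4])
        scores = {p: float(rng.random()) for p in pairs}
        curve = pr_vs_reference(scores, ref, exclude_symptoms=())
        retrieved = 0
        for t, p, r in sorted(curve.points, key=lambda x: -x[0]):
            retrieved = sum(v >= t for v in scores.values())
            tp = p * retrieved
            assert tp == pytest.approx(round(tp), abs=1e-9)


class TestPooling:
    g1 = KnowledgeGraph(edges=[("d", "a", 0.9), ("d", "b", 0.8), ("d", "x", 0.1)])
    g2 = KnowledgeGraph(edges=[("d", "b", 0.7), ("d", "c", 0.6), ("d", "y", 0.1)])

    def test_union_of_top_n(self):
        pool = pool_top_edges([self.g1, self.g2], 2)
        assert pool.pairs == {("d", "a"), ("d", "b"), ("d", "c")}

    def test_same_seed_same_order(self):
        a = pool_top_edges([self.g1, self.g2], 2, seed=5)
        b = pool_top_edges([self.g1, self.g2], 2, seed=5)
        assert a.order == b.order

    def test_reference_edges_included_and_size_bound(self):
        ref = _reference([("d", "z")])
        pool = pool_top_edges([self.g1, self.g2], 2, reference=ref)
        assert ("d", "z") in pool.pairs
        assert len(pool.pairs) <= 2 * 2 * 1 + len(ref.edges)

    def test_provenance_merged(self):
        pool = pool_top_edges([self.g1, self.g2], 2, labels=["m1", "m2"])
        assert pool.provenance[("d", "b")] == {"m1", "m2"}


class TestBinarize:
    tags = PhysicianTags(
        ratings={
            ("d", "s1", "r1"): "always",
            ("d", "s2", "r1"): "sometimes",
            ("d", "s3", "r1"): "rarely",
            ("d", "s4", "r1"): "never",
        }
    )

    def test_rarely_positive_scheme(self):
        binary = binarize_tags(self.tags, "rarely_positive")
        assert binary[("d", "s3", "r1")] == 1
        assert binary[("d", "s4", "r1")] == 0

    def test_rarely_negative_scheme(self):
        binary = binarize_tags(self.tags, "rarely_negative")
        assert binary[("d", "s3", "r1")] == 0
        assert binary[("d", "s2", "r1")] == 1

    def test_unknown_scheme_and_tag_rejected(self):
        with pytest.raises(ValueError):
            binarize_tags(self.tags, "maybe_positive")
        with pytest.raises(ValueError, match="unknown tag"):
            PhysicianTags(ratings={("d", "s", "r"): "possibly"})

    def test_csv_round_trip(self, tmp_path):
        p = tmp_path / "tags.csv"
        p.write_text(
            "disease_id,symptom_id,rater_id,tag\n"
            "d,s1,r1,always\nd,s2,r1,never\n"
        )
        tags = load_physician_tags(p)
        assert tags.for_rater("r1") == {("d", "s1"): "always", ("d", "s2"): "never"}


class TestPrVsTags:
    def test_all_positive_gives_precision_one(self):
        relevance = {("d", "a"): 1, ("d", "b"): 1}
        curve = pr_vs_tags({("d", "a"): 0.9, ("d", "b"): 0.5}, relevance)
        assert all(p == 1.0 for _, p, _ in curve.points)

    def test_hand_enumeration_six_edges(self):
        relevance = {("d", f"s{i}"): int(i % 2 == 0) for i in range(6)}
        scores = {("d", f"s{i}"): (6 - i) / 10 for i in range(6)}
        curve = pr_vs_tags(scores, relevance)
        # positives are s0, s2, s4 at scores 0.6, 0.4, 0.2
        expected = [
            (0.6, 1.0, 1 / 3),
            (0.5, 1 / 2, 1 / 3),
            (0.4, 2 / 3, 2 / 3),
            (0.3, 1 / 2, 2 / 3),
            (0.2, 3 / 5, 1.0),
            (0.1, 1 / 2, 1.0),
        ]
        assert [
            (pytest.approx(t), pytest.approx(p), pytest.approx(r))
            for t, p, r in expected
        ] == curve.points

    def test_pairs_outside_pool_are_irrelevant(self):
        relevance = {("d", "a"): 1}
        curve = pr_vs_tags({("d", "a"): 0.3, ("d", "out"): 0.9}, relevance)
        assert curve.points[0] == (0.9, 0.0, 0.0)

    def test_no_positive_tags_raises(self):
        with pytest.raises(ValueError, match="positive"):
            pr_vs_tags({("d", "a"): 1.0}, {("d", "a"): 0})

    def test_agrees_with_reference_curve_on_same_binary_target(self):
        rng = np.random.default_rng(3)
        pairs = [("d", f"s{i}") for i in range(12)]
        positives = {p for p in pairs if rng.random() < 0.5}
        scores = {p: float(rng.random()) for p in pairs}
        ref = _reference(positives)
        a = pr_vs_reference(scores, ref, exclude_symptoms=())
        b = pr_vs_tags(scores, {p: int(p in positives) for p in pairs})
        assert a.points == b.points

    def test_static_reference_source_yields_two_points(self):
        ref = ReferenceGraph(
            edges={
                ReferenceEdge("d", "s1", "always"),
                ReferenceEdge("d", "s2", "frequent"),
                ReferenceEdge("d", "s3", "frequent"),
            }
        )
        relevance = {("d", "s1"): 1, ("d", "s2"): 1, ("d", "s3"): 0}
        curve = pr_vs_tags(ref.bucket_scores(), relevance)
        assert len(curve.points) == 2  # one per frequency bucket


def _exact_wilcoxon_oracle(diffs):
    """Brute-force sign-flip enumeration of the two-sided p-value."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        np.sum(ranks[np.array(signs, dtype=bool)])
        for signs in itertools.product([0, 1], repeat=len(d))
    ]
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_constant_shift_matches_enumeration(self):
        a = np.arange(8) / 10 + 0.2
        b = np.arange(8) / 10
        res = wilcoxon_compare(a, b)
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(_exact_wilcoxon_oracle(a - b))
        # all-positive differences: the most extreme assignment, p = 2/2^8
        assert res.pvalue == pytest.approx(2 / 2**8)

    def test_symmetric_differences_give_p_one(self):
        a = [0.5, 0.3, 0.5, 0.3, 0.5, 0.3]
        b = [0.3, 0.5, 0.3, 0.5, 0.3, 0.5]
        assert wilcoxon_compare(a, b).pvalue == pytest.approx(1.0)

    def test_identical_vectors_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            wilcoxon_compare([0.1] * 6, [0.1] * 6)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_inputs_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        a = rng.integers(0, 5, n) / 4
        b = rng.integers(0, 5, n) / 4
        if np.all(a == b):
            a[0] += 0.25
        res = wilcoxon_compare(a, b)
        assert res.pvalue == pytest.approx(_exact_wilcoxon_oracle(a - b))

    def test_matches_scipy_on_tie_free_input(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0.2, 1, 15)
        b = rng.normal(0, 1, 15)
        res = wilcoxon_compare(a, b)
        ref = stats.wilcoxon(a, b, method="exact")
        assert res.pvalue == pytest.approx(ref.pvalue)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0.5, 1, 40)
        b = rng.normal(0, 1, 40)
        res = wilcoxon_compare(a, b)
        assert res.method == "normal"
        ref = stats.wilcoxon(a, b, correction=False, method="approx")
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-6)


class TestSpearman:
    def test_identical_vectors_rho_one_everywhere(self):
        a = ["never", "rarely", "sometimes", "always", "rarely", "sometimes"]
        res = spearman_agreement(a, list(a), bootstrap_reps=200, seed=1)
        assert res.rho == pytest.approx(1.0)
        assert res.mean == pytest.approx(1.0)
        assert res.std == pytest.approx(0.0, abs=1e-12)

    def test_reversed_rankings_rho_minus_one(self):
        a = [1, 2, 3, 4, 5]
        res = spearman_agreement(a, a[::-1], bootstrap_reps=10, seed=0)
        assert res.rho == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_agreement([1, 1, 1, 1], [1, 2, 3, 4])

    def test_bootstrap_std_shrinks_with_length(self):
        rng = np.random.default_rng(4)

        def ratings(n):
            base = rng.integers(0, 4, n)
            noisy = np.clip(base + rng.integers(-1, 2, n), 0, 3)
            return base, noisy

        a50, b50 = ratings(50)
        a500, b500 = ratings(500)
        small = spearman_agreement(a50, b50, bootstrap_reps=300, seed=7)
        large = spearman_agreement(a500, b500, bootstrap_reps=300, seed=7)
        assert large.std < small.std


def test_per_disease_precision_matched_budget():
    g = KnowledgeGraph(
        edges=[("d1", "a", 0.9), ("d1", "b", 0.8), ("d2", "a", 0.7), ("d2", "c", 0.2)]
    )
    positives = {("d1", "a"), ("d2", "a"), ("d2", "c")}
    prec = per_disease_precision(g, positives, 2)
    assert prec == {"d1": 0.5, "d2": 1.0}
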