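"""Semantic-distance metrics against brute-force and closed-form oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ftdsim.coherence_metrics import (
    AGGREGATIONS,
    DegenerateVectorError,
    DistanceSeries,
    aggregate,
    compute_narrative_metrics,
    cosine_distance,
    prompt_distance_series,
    sentence_distance_contextual,
    sentence_distance_static_mean,
    sentence_distance_wmd,
    tangentiality_slope,
    word_distance_series,
    word_movers_distance,
    word_movers_distance_exact,
)
from ftdsim.embeddings import encode_sentence_mean
from ftdsim.preprocessing import ProcessedNarrative

from conftest import random_table


def processed(*sentences):
    return ProcessedNarrative(
        tuple(" ".join(s) + "." for s in sentences),
        tuple(tuple(s) for s in sentences),
    )


class TestCosineDistance:
    def test_identical_direction_is_zero(self):
        assert cosine_distance([1.0, 0.0], [1.0, 0.0]) == 0.0
        assert cosine_distance([1.0, 2.0], [2.0, 4.0]) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_is_one(self):
        assert cosine_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_hand_value(self):
        assert cosine_distance([1.0, 1.0], [1.0, 0.0]) == pytest.approx(
            1.0 - 1.0 / np.sqrt(2.0), abs=1e-12
        )

    def test_zero_vector_raises(self):
        with pytest.raises(DegenerateVectorError):
            cosine_distance([0.0, 0.0], [1.0, 0.0])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            cosine_distance([1.0], [1.0, 0.0])

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_range_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        u, v = rng.standard_normal(5), rng.standard_normal(5)
        d = cosine_distance(u, v)
        assert 0.0 <= d <= 2.0
        assert d == pytest.approx(cosine_distance(v, u))


class TestDistanceSeries:
    def test_rejects_out_of_range_values(self):
        with pytest.raises(ValueError):
            DistanceSeries((2.5,), "word_consecutive", "static_mean")
        with pytest.raises(ValueError):
            DistanceSeries((0.1,), "no_such_level", "static_mean")


class TestWordDistanceSeries:
    def test_identical_words_give_zero_distances(self, hand_table):
        p = processed(["king", "king", "king"])
        series = word_distance_series(p, hand_table, "consecutive")
        assert series.values == (0.0, 0.0)

    def test_series_lengths(self, hand_table):
        p = processed(["king", "apple", "up"])
        assert len(word_distance_series(p, hand_table, "consecutive")) == 2
        assert len(word_distance_series(p, hand_table, "all_pairs")) == 3

    def test_oov_words_relink_adjacency(self, hand_table):
        p = processed(["king", "zebra", "apple"])
        series = word_distance_series(p, hand_table, "consecutive")
        assert len(series) == 1
        assert series.n_skipped == 1
        assert series.values[0] == pytest.approx(
            cosine_distance(hand_table.lookup("king"), hand_table.lookup("apple"))
        )

    def test_all_pairs_matches_brute_force(self):
        rng = np.random.default_rng(7)
        table = random_table(rng, n_words=10, dim=6)
        words = list(rng.choice(list(table.vectors), size=10))
        p = processed(words)
        series = word_distance_series(p, table, "all_pairs")
        expected = [
            cosine_distance(table.lookup(a), table.lookup(b))
            for a, b in itertools.combinations(words, 2)
        ]
        np.testing.assert_allclose(series.values, expected, atol=1e-12)

    def test_sentence_scope_restricts_pairs(self, hand_table):
        p = processed(["king", "apple"], ["up", "pear"])
        narrative = word_distance_series(p, hand_table, "all_pairs", scope="narrative")
        within = word_distance_series(p, hand_table, "all_pairs", scope="sentence")
        assert len(narrative) == 6
        assert len(within) == 2

    def test_too_few_words_gives_empty_series(self, hand_table):
        assert len(word_distance_series(processed(["king"]), hand_table)) == 0


class TestSentenceDistanceStaticMean:
    def test_hand_computed_means_and_cosines(self, hand_table):
        p = processed(["king", "apple"], ["queen", "pear"], ["up"])
        series = sentence_distance_static_mean(
            p, hand_table, "consecutive", exclude_shared=False
        )
        m = [
            encode_sentence_mean(list(s), hand_table) for s in p.sentences_words
        ]
        expected = [cosine_distance(m[0], m[1]), cosine_distance(m[1], m[2])]
        np.testing.assert_allclose(series.values, expected, atol=1e-12)

    def test_identical_sentences_skipped_under_exclusion(self, hand_table):
        p = processed(["king", "apple"], ["king", "apple"])
        series = sentence_distance_static_mean(p, hand_table, exclude_shared=True)
        assert len(series) == 0
        assert series.n_skipped == 1

    def test_single_word_sentences_without_exclusion(self, hand_table):
        p = processed(["king"], ["king"])
        series = sentence_distance_static_mean(p, hand_table, exclude_shared=False)
        assert series.values == (0.0,)

    def test_exclusion_never_decreases_distance_on_overlap(self, hand_table):
        # sharing a word pulls both means together; removing it exposes the
        # differing remainder
        p = processed(["king", "apple"], ["king", "up"])
        plain = sentence_distance_static_mean(p, hand_table, exclude_shared=False)
        excl = sentence_distance_static_mean(p, hand_table, exclude_shared=True)
        assert excl.values[0] >= plain.values[0]

    def test_cancelling_pair_counts_as_degenerate(self, hand_table):
        p = processed(["king", "anti"], ["up"])
        series = sentence_distance_static_mean(p, hand_table, exclude_shared=False)
        assert len(series) == 0
        assert series.n_skipped == 1


class TestWordMoversDistance:
    def test_identical_sets_are_zero(self, hand_table):
        assert word_movers_distance(
            ["king", "apple"], ["king", "apple"], hand_table, exclude_shared=False
        ) == pytest.approx(0.0, abs=1e-12)

    def test_single_word_reduces_to_cosine(self, hand_table):
        assert word_movers_distance(
            ["king"], ["queen"], hand_table
        ) == pytest.approx(
            cosine_distance(hand_table.lookup("king"), hand_table.lookup("queen"))
        )

    def test_empty_after_exclusion_is_undefined(self, hand_table):
        assert word_movers_distance(["king"], ["king"], hand_table) is None

    def test_matches_brute_force_nearest_neighbor(self):
        rng = np.random.default_rng(11)
        table = random_table(rng, n_words=12, dim=5)
        words = list(table.vectors)
        a = [words[0], words[1]]
        b = [words[2], words[3], words[4]]
        got = word_movers_distance(a, b, table, exclude_shared=False)
        d = lambda x, y: cosine_distance(table.lookup(x), table.lookup(y))
        a_to_b = np.mean([min(d(x, y) for y in b) for x in a])
        b_to_a = np.mean([min(d(y, x) for x in a) for y in b])
        assert got == pytest.approx((a_to_b + b_to_a) / 2, abs=1e-12)

    def test_relaxed_lower_bounds_full_transport(self):
        # each relaxed direction lower-bounds the optimal-transport cost, so
        # their average does too
        rng = np.random.default_rng(13)
        table = random_table(rng, n_words=20, dim=6)
        words = list(table.vectors)
        for _ in range(20):
            a = list(rng.choice(words, size=rng.integers(1, 5), replace=False))
            b = list(rng.choice(words, size=rng.integers(1, 5), replace=False))
            relaxed = word_movers_distance(a, b, table, exclude_shared=False)
            exact = word_movers_distance_exact(a, b, table)
            assert relaxed <= exact + 1e-9

    def test_bounded_by_max_pairwise_distance(self, hand_table):
        words = [w for w in hand_table.vectors]
        a, b = words[:3], words[3:]
        wmd = word_movers_distance(a, b, hand_table, exclude_shared=False)
        dmax = max(
            cosine_distance(hand_table.lookup(x), hand_table.lookup(y))
            for x in a
            for y in b
        )
        assert wmd <= dmax

    def test_series_counts_undefined_pairs(self, hand_table):
        p = processed(["king"], ["king"], ["apple"])
        series = sentence_distance_wmd(p, hand_table, "consecutive")
        assert series.n_skipped == 1
        assert len(series) == 1


class TestSentenceDistanceContextual:
    def test_identical_sentence_zero(self, hashing_encoder):
        series = sentence_distance_contextual(
            ["the same words.", "the same words."], hashing_encoder
        )
        assert series.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_pair_counting(self, hashing_encoder):
        sents = ["one thing.", "another thing."]
        assert len(sentence_distance_contextual(sents, hashing_encoder, "consecutive")) == 1
        assert len(sentence_distance_contextual(sents, hashing_encoder, "all_pairs")) == 1

    def test_all_pairs_matches_brute_force(self, hashing_encoder):
        sents = [f"sentence number {i} here." for i in range(4)]
        series = sentence_distance_contextual(sents, hashing_encoder, "all_pairs")
        vecs = [hashing_encoder.encode(s) for s in sents]
        expected = [
            cosine_distance(vecs[i], vecs[j])
            for i, j in itertools.combinations(range(4), 2)
        ]
        np.testing.assert_allclose(series.values, expected, atol=1e-12)


class TestAggregate:
    def test_hand_values(self):
        values = (1.0, 2.0, 3.0)
        assert aggregate(values, "mean") == 2.0
        assert aggregate(values, "min") == 1.0
        assert aggregate(values, "max") == 3.0
        assert aggregate(values, "variance") == 1.0

    def test_constant_series_zero_variance(self):
        assert aggregate((0.5, 0.5, 0.5), "variance") == 0.0

    def test_undefined_markers(self):
        assert aggregate((), "mean") is None
        assert aggregate((1.0,), "variance") is None

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            aggregate((1.0,), "median")

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_against_independent_formulas(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random(rng.integers(2, 100)) * 2.0
        n = len(vals)
        mean = sum(vals) / n
        assert aggregate(tuple(vals), "mean") == pytest.approx(mean)
        assert aggregate(tuple(vals), "min") == min(vals)
        assert aggregate(tuple(vals), "max") == max(vals)
        var = sum((v - mean) ** 2 for v in vals) / (n - 1)
        assert aggregate(tuple(vals), "variance") == pytest.approx(var)
        assert (
            aggregate(tuple(vals), "min")
            <= aggregate(tuple(vals), "mean")
            <= aggregate(tuple(vals), "max")
        )


class TestTangentialitySlope:
    def test_flat_series(self, hand_table, monkeypatch):
        slope, first = _slope_from_distances([0.2, 0.2, 0.2])
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert first == pytest.approx(0.2)

    def test_exact_line(self):
        slope, first = _slope_from_distances([0.1, 0.2, 0.3])
        assert slope == pytest.approx(0.1, abs=1e-12)
        assert first == pytest.approx(0.1)

    def test_random_matches_normal_equations(self):
        rng = np.random.default_rng(21)
        d = rng.random(8)
        slope, _ = _slope_from_distances(list(d))
        k = np.arange(1, 9, dtype=float)
        beta = (np.mean(k * d) - k.mean() * d.mean()) / (
            np.mean(k**2) - k.mean() ** 2
        )
        assert slope == pytest.approx(beta, abs=1e-9)

    def test_undefined_with_single_sentence(self, hand_table):
        p = processed(["apple"])
        assert tangentiality_slope("king queen.", p, table=hand_table) is None

    def test_static_and_contextual_paths(self, hand_table, hashing_encoder):
        p = processed(["apple", "pear"], ["up", "king"], ["queen", "pear"])
        res_static = tangentiality_slope("king queen.", p, table=hand_table)
        res_ctx = tangentiality_slope("king queen.", p, encoder=hashing_encoder)
        assert res_static is not None and res_ctx is not None
        ks, ds, skipped = prompt_distance_series(
            "king queen.", p, table=hand_table
        )
        assert list(ks) == [1, 2, 3] and skipped == 0
        assert res_static[1] == pytest.approx(ds[0])

    def test_requires_exactly_one_encoding(self, hand_table, hashing_encoder):
        p = processed(["apple"], ["pear"])
        with pytest.raises(ValueError):
            tangentiality_slope("king.", p)
        with pytest.raises(ValueError):
            tangentiality_slope("king.", p, table=hand_table, encoder=hashing_encoder)


def _slope_from_distances(distances):
    """Fit the OLS slope through a hand-chosen prompt-distance series by
    constructing sentences whose distances to the prompt are exact."""
    # use 2-D geometry: prompt along x-axis; sentence k at angle with
    # cosine 1 - d_k
    from ftdsim.embeddings import EmbeddingTable

    vectors = {"prompt": np.array([1.0, 0.0])}
    sentences = []
    for i, d in enumerate(distances):
        cos = 1.0 - d
        w = f"s{i}"
        vectors[w] = np.array([cos, np.sqrt(max(0.0, 1.0 - cos**2))])
        sentences.append([w])
    table = EmbeddingTable("line", 2, vectors)
    p = ProcessedNarrative(
        tuple(f"{s[0]}." for s in sentences), tuple(tuple(s) for s in sentences)
    )
    return tangentiality_slope("prompt.", p, table=table)


class TestComputeNarrativeMetrics:
    def test_flattened_keys_and_confound_fields(self, hand_table, hashing_encoder):
        p = processed(["king", "apple"], ["queen", "up"], ["pear", "king"])
        m = compute_narrative_metrics(
            p, "king queen.", table=hand_table, encoder=hashing_encoder,
            exclude_shared=False,
        )
        assert "word_consecutive|static_mean|mean" in m.values
        assert "sentence_consecutive|wmd|mean" in m.values
        assert "sentence_consecutive|contextual|mean" in m.values
        assert "tangentiality_slope|static_mean" in m.values
        assert "tangentiality_slope|contextual" in m.values
        assert m.mean_words_per_sentence == 2.0
        assert m.n_sentences == 3
        agg = {k.split("|")[-1] for k in m.values if k.count("|") == 2}
        assert agg == set(AGGREGATIONS) | {"min", "max"}

    def test_sentence_length_confound_direction(self):
        # semantically related sentences (a shared topical core) padded with
        # isotropic filler words: averaging dilutes the shared core, so the
        # static-mean distance inflates with sentence length, while the
        # relaxed WMD — which matches the core words directly — barely moves.
        # This is the mechanism the residualized control corrects for.
        rng = np.random.default_rng(31)

        def mean_dists(k, n=150, dim=16, core=2):
            from ftdsim.embeddings import EmbeddingTable

            sm, wm = [], []
            for _ in range(n):
                words_a = [f"c{j}" for j in range(core)] + [
                    f"a{j}" for j in range(k - core)
                ]
                words_b = [f"c{j}" for j in range(core)] + [
                    f"b{j}" for j in range(k - core)
                ]
                vectors = {
                    w: rng.standard_normal(dim) for w in set(words_a + words_b)
                }
                table = EmbeddingTable("iso", dim, vectors)
                p = processed(words_a, words_b)
                sm.append(
                    sentence_distance_static_mean(
                        p, table, exclude_shared=False
                    ).values[0]
                )
                wm.append(
                    word_movers_distance(words_a, words_b, table, exclude_shared=False)
                )
            return np.mean(sm), np.mean(wm)

        sm5, wm5 = mean_dists(5)
        sm20, wm20 = mean_dists(20)
        assert sm20 - sm5 > 0.1
        assert abs(wm20 - wm5) < 0.15
        assert sm20 - sm5 > 3 * (wm20 - wm5)
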