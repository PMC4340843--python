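"""Naive Bayes classifier: discretization, scoring, R-precision, CV."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from condock.nbc import (
    NBCModel,
    Ranking,
    _bin_index,
    cross_validate,
    ewd_edges,
    r_precision,
    rice_bin_count,
    score,
    score_matrix,
    train,
)
from condock.synthetic import make_complex_feature_tables


class TestRiceRule:
    @pytest.mark.parametrize(
        "n,expected",
        [(1_000_000, 200), (3375, 30), (1, 2), (8, 4), (27, 6)],
    )
    def test_known_values(self, n, expected):
        assert rice_bin_count(n) == expected

    def test_rejects_zero(self):
        with pytest.raises(ValueError):
            rice_bin_count(0)


class TestEwdEdges:
    def test_equal_width_edges_over_range(self):
        edges = ewd_edges(np.array([0.0, 3.0, 10.0]), 5)
        assert np.allclose(edges, [0, 2, 4, 6, 8, 10])

    def test_widths_equal_within_tolerance(self):
        rng = np.random.default_rng(0)
        edges = ewd_edges(rng.normal(size=1000), 37)
        widths = np.diff(edges)
        assert np.ptp(widths) < 1e-9

    @given(
        st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=200),
        st.integers(1, 30),
    )
    @settings(max_examples=50, deadline=None)
    def test_histogram_counts_conserved(self, values, n_bins):
        values = np.array(values)
        edges = ewd_edges(values, n_bins)
        counts = np.bincount(_bin_index(values, edges), minlength=n_bins)
        assert counts.sum() == len(values)

    def test_degenerate_constant_values(self):
        edges = ewd_edges(np.full(10, 4.2), 3)
        idx = _bin_index(np.full(10, 4.2), edges)
        assert edges[0] < 4.2 < edges[-1]
        assert len(np.unique(idx)) == 1


class TestTraining:
    def test_bin_counts_follow_rice_rule(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(16, 1))
        y = np.array([0] * 8 + [1] * 8)
        model = train(x, y)
        assert model.bin_counts == (4, 4)

    def test_probabilities_normalized(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(500, 3))
        y = (rng.random(500) < 0.3).astype(int)
        model = train(x, y)
        for k in (0, 1):
            for i in range(3):
                assert abs(np.exp(model.log_probs[k][i]).sum() - 1.0) < 1e-9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train(np.zeros((5, 1)), np.zeros(5))

    def test_uninformative_feature_reduces_to_prior_ratio(self):
        # same uniform feature distribution in both classes: S(x) is
        # constant in x and equals the log prior ratio up to the constant
        # bin-width correction log(n_bins0/n_bins1) induced by the
        # per-class Rice bin counts
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, size=(20000, 1))
        y = np.concatenate([np.zeros(18000), np.ones(2000)]).astype(int)
        model = train(x, y)
        s = score_matrix(model, rng.uniform(0.2, 0.8, size=(50, 1)))
        expected = math.log(2000 / 18000) + math.log(
            model.bin_counts[0] / model.bin_counts[1]
        )
        assert np.abs(s - expected).max() < 0.35
        assert s.max() - s.min() < 0.5

    def test_json_roundtrip_preserves_scores(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(200, 4))
        y = (rng.random(200) < 0.2).astype(int)
        model = train(x, y)
        again = NBCModel.from_json(model.to_json())
        probe = rng.normal(size=(20, 4))
        assert np.allclose(score_matrix(model, probe), score_matrix(again, probe))


def hand_model(p1, p0, prior1=0.5):
    """One-feature model with a single bin per class and given probabilities."""
    return NBCModel(
        feature_names=["f0"],
        log_priors=np.log([1 - prior1, prior1]),
        edges=[[np.array([0.0, 1.0])], [np.array([0.0, 1.0])]],
        log_probs=[[np.log([p0])], [np.log([p1])]],
        bin_counts=(1, 1),
        class_counts=(1, 1),
    )


class TestScoring:
    def test_hand_log_ratio(self):
        model = hand_model(p1=0.5, p0=0.25)
        assert score(model, np.array([0.5])) == pytest.approx(math.log(2))

    def test_prior_only_when_conditionals_equal(self):
        model = hand_model(p1=0.5, p0=0.5, prior1=0.1)
        assert score(model, np.array([0.5])) == pytest.approx(math.log(0.1 / 0.9))

    def test_dimension_mismatch_rejected(self):
        model = hand_model(0.5, 0.5)
        with pytest.raises(ValueError, match="columns"):
            score_matrix(model, np.zeros((3, 2)))

    def test_matches_brute_force_probability_product(self):
        """Log-sum scores equal the direct product of histogram
        probabilities recomputed from raw counts, on 100 random models."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(40, 200))
            d = int(rng.integers(1, 5))
            x = rng.normal(size=(n, d))
            y = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(int)
            if y.min() == y.max():
                continue
            model = train(x, y)
            probe = rng.normal(size=d)
            # independent product computation from raw counts
            n0, n1 = model.class_counts
            ratio = (y.sum() / n1) / ((n - y.sum()) / n0)  # = 1, priors below
            prod = [1.0, 1.0]
            for k, n_k in ((0, n0), (1, n1)):
                prod[k] *= n_k / n
                for i in range(d):
                    e = model.edges[k][i]
                    vals = x[y == k][:, i]
                    counts, _ = np.histogram(vals, bins=e)
                    # clamp probe into boundary bin
                    b = int(np.clip(np.searchsorted(e, probe[i], side="right") - 1,
                                    0, len(e) - 2))
                    prod[k] *= (counts[b] + 1) / (n_k + len(counts))
            expected = math.log(prod[1]) - math.log(prod[0])
            assert score(model, probe) == pytest.approx(expected, abs=1e-9)

    def test_ranking_invariant_to_prior_rescaling(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(300, 3))
        y = (rng.random(300) < 0.3).astype(int)
        model = train(x, y)
        probe = rng.normal(size=(40, 3))
        s1 = score_matrix(model, probe)
        model.log_priors = model.log_priors + 3.7  # same monotone rescale, both classes
        s2 = score_matrix(model, probe)
        assert np.array_equal(np.argsort(-s1), np.argsort(-s2))


def make_ranking(flags):
    """Ranking whose sorted true/false flags equal ``flags``."""
    n = len(flags)
    pair_ids = [(("A", i, ""), ("B", i, "")) for i in range(n)]
    scores = np.arange(n, 0, -1, dtype=float)
    return Ranking.from_scores(pair_ids, scores, np.array(flags, dtype=bool))


class TestRPrecision:
    def test_first_branch_fraction_in_top_r(self):
        flags = [1, 0, 1, 0] + [0] * 6 + [1, 1]  # R=4, true at ranks 1 and 3
        assert r_precision(make_ranking(flags)) == pytest.approx(0.5)

    def test_second_branch_negative_value(self):
        flags = [0] * 24 + [1] * 10  # R=10, first true at rank 25
        assert r_precision(make_ranking(flags)) == pytest.approx(1 - 25 / 10)

    def test_perfect_ranking_scores_one(self):
        flags = [1] * 5 + [0] * 10
        assert r_precision(make_ranking(flags)) == 1.0

    def test_no_true_contacts_is_error(self):
        with pytest.raises(ValueError, match="no true contacts"):
            r_precision(make_ranking([0, 0, 0]))

    def test_matches_literal_formula_on_random_rankings(self):
        """1000 random rankings against a naive transcription of the
        two-branch definition, including negative second-branch cases."""
        rng = np.random.default_rng(7)
        saw_negative = 0
        for _ in range(1000):
            n = int(rng.integers(5, 120))
            r = int(rng.integers(1, max(2, n // 4)))
            flags = np.zeros(n, dtype=int)
            flags[rng.choice(n, size=r, replace=False)] = 1
            ranking = make_ranking(list(flags))

            is_true = list(flags)
            highest_true = min(i + 1 for i, t in enumerate(is_true) if t)
            if highest_true <= r:
                expected = sum(is_true[k - 1] for k in range(1, r + 1)) / r
            else:
                expected = 1 - highest_true / r
            if expected < 0:
                saw_negative += 1
            assert r_precision(ranking) == pytest.approx(expected)
        assert saw_negative > 50

    def test_equal_scores_ordered_by_pair_id(self):
        pair_ids = [(("B", 2, ""), ("C", 1, "")), (("A", 9, ""), ("B", 1, ""))]
        ranking = Ranking.from_scores(pair_ids, np.zeros(2), np.array([0, 1]))
        assert ranking.entries[0][0] == (("A", 9, ""), ("B", 1, ""))


class TestCrossValidation:
    def test_separable_synthetic_features_reach_one(self):
        # positives carry a constant marker value far outside the negative
        # range: every positive lands in a dense positive-class bin while
        # negatives clamp into an empty one, so separation is strict
        tables = {}
        for c, seed in enumerate((0, 1)):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(300, 1))
            y = np.zeros(300, dtype=int)
            y[:30] = 1
            x[:30, 0] = 10.0
            pair_ids = [(("A", i, ""), ("B", i, "")) for i in range(300)]
            tables[f"c{c}"] = (x, y, pair_ids)
        assert cross_validate(tables, n_folds=2) == pytest.approx(1.0)

    def test_null_matches_independent_random_ranking_simulation(self):
        """At zero shift the classifier ranking is uninformative; its mean
        modified R-precision must match a direct simulation of the metric
        under random rankings (NOT the prevalence: the second branch makes
        the null mean negative at these sizes)."""
        n, prevalence = 800, 0.02
        vals = []
        for seed in range(12):
            tables = make_complex_feature_tables(
                4, n, 6, informative=[0], mean_shift=0.0,
                prevalence=prevalence, seed=seed,
            )
            vals.append(cross_validate(tables, n_folds=4, seed=seed))
        measured = np.mean(vals)

        rng = np.random.default_rng(123)
        r = int(round(prevalence * n))
        sims = []
        for _ in range(3000):
            order = rng.permutation(n)
            flags = np.zeros(n, dtype=int)
            flags[order[:r]] = 1
            highest = int(np.argmax(flags)) + 1
            sims.append(
                flags[:r].mean() if highest <= r else 1 - highest / r
            )
        expected = np.mean(sims)
        spread = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(measured - expected) < 4 * max(spread, 0.05)

    def test_deterministic_under_input_order(self):
        tables = make_complex_feature_tables(
            4, 200, 5, informative=[0], mean_shift=1.0, prevalence=0.05, seed=1
        )
        shuffled = dict(reversed(list(tables.items())))
        assert cross_validate(tables, n_folds=2, seed=9) == cross_validate(
            shuffled, n_folds=2, seed=9
        )

    def test_fewer_complexes_than_folds_rejected(self):
        tables = make_complex_feature_tables(
            2, 100, 3, informative=[0], mean_shift=1.0, prevalence=0.1, seed=0
        )
        with pytest.raises(ValueError, match="folds"):
            cross_validate(tables, n_folds=3)
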