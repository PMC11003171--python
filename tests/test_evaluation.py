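"""Evaluation metrics and perturbation protocols."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pmfgrn as pg
from pmfgrn.containers import ExpressionMatrix, PriorNetwork
from pmfgrn.evaluation import ScoredNetwork, average_precision


def brute_force_ap(scores, labels):
    """Independent AP oracle: explicit sweep over unique score thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    total_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores.tolist()), reverse=True):
        mask = scores >= t
        tp = labels[mask].sum()
        precision = tp / mask.sum()
        recall = tp / total_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def _network(entries, genes=None, tfs=None):
    entries = np.asarray(entries, dtype=float)
    m, k = entries.shape
    genes = genes or [f"g{i}" for i in range(m)]
    tfs = tfs or [f"t{j}" for j in range(k)]
    return PriorNetwork(entries, genes, tfs)


def _scored(scores, genes=None, tfs=None):
    scores = np.asarray(scores, dtype=float)
    m, k = scores.shape
    genes = genes or [f"g{i}" for i in range(m)]
    tfs = tfs or [f"t{j}" for j in range(k)]
    return ScoredNetwork(scores, genes, tfs)


class TestAveragePrecision:
    def test_worked_example(self):
        ap = average_precision([0.9, 0.4, 0.35, 0.1], [1, 0, 1, 0])
        assert ap == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))

    def test_perfect_ranking(self):
        assert average_precision([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_give_positive_rate(self):
        for n, p in [(10, 3), (25, 1), (7, 7)]:
            labels = np.zeros(n)
            labels[:p] = 1
            assert average_precision(np.full(n, 0.5), labels) == pytest.approx(p / n)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_with_ties(self, seed):
        r = np.random.default_rng(seed)
        for _ in range(50):
            n = int(r.integers(2, 26))
            # coarse scores force ties
            scores = r.integers(0, 5, size=n) / 4.0
            labels = (r.random(n) < 0.4).astype(float)
            if labels.sum() == 0:
                labels[int(r.integers(n))] = 1.0
            assert average_precision(scores, labels) == pytest.approx(
                brute_force_ap(scores, labels), abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 6), st.booleans()),
                    min_size=1, max_size=25).filter(
                        lambda xs: any(y for _, y in xs)))
    def test_matches_brute_force_property(self, items):
        scores = np.array([s for s, _ in items], dtype=float)
        labels = np.array([float(y) for _, y in items])
        assert average_precision(scores, labels) == pytest.approx(
            brute_force_ap(scores, labels), abs=1e-12)

    def test_agrees_with_sklearn_when_tie_free(self):
        from sklearn.metrics import average_precision_score
        r = np.random.default_rng(3)
        for _ in range(20):
            n = int(r.integers(5, 30))
            scores = r.random(n)    # continuous: ties have measure zero
            labels = (r.random(n) < 0.5).astype(float)
            if labels.sum() == 0:
                labels[0] = 1.0
            assert average_precision(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            average_precision([0.5, 0.4], [0, 0])


class TestAuprcModes:
    def test_keep_all_ranks_missing_pairs_last(self):
        # gold has a gene the prediction lacks; its pair must rank below all
        pred = _scored([[0.9]], genes=["g0"])
        gold = _network([[1.0], [1.0]], genes=["g0", "g1"])
        # scores: g0 -> 0.9, g1 -> -inf; both positive
        # AP = (1/2)*1 + (1/2)*(2/2) = 1.0 here; make the missing one matter:
        gold2 = _network([[0.0], [1.0]], genes=["g0", "g1"])
        ap = pg.auprc(pred, gold2, mode="keep_all")
        # single positive ranked last of two -> AP = 1/2
        assert ap == pytest.approx(0.5)

    def test_overlap_ignores_non_shared_pairs(self):
        pred = _scored([[0.9]], genes=["g0"])
        gold = _network([[1.0], [0.0]], genes=["g0", "g1"])
        assert pg.auprc(pred, gold, mode="overlap") == 1.0

    def test_modes_agree_on_identical_labels(self, rng):
        scores = rng.random((6, 3))
        entries = (rng.random((6, 3)) < 0.3).astype(float)
        entries[0, 0] = 1.0
        pred = _scored(scores)
        gold = _network(entries)
        assert pg.auprc(pred, gold, "keep_all") == pg.auprc(pred, gold, "overlap")

    def test_ratio_is_auprc_over_positive_rate(self, rng):
        scores = rng.random((5, 4))
        entries = np.zeros((5, 4))
        entries[0, 0] = entries[2, 1] = 1.0
        pred, gold = _scored(scores), _network(entries)
        assert pg.auprc_ratio(pred, gold) == pytest.approx(
            pg.auprc(pred, gold) / 0.1)

    def test_zero_positives_rejected(self):
        with pytest.raises(ValueError):
            pg.auprc(_scored([[0.5]]), _network([[0.0]]))


class TestCalibrationCurve:
    def _summary(self, A_mean, A_var, genes=None, tfs=None):
        A_mean = np.asarray(A_mean, dtype=float)
        m, k = A_mean.shape
        genes = genes or [f"g{i}" for i in range(m)]
        tfs = tfs or [f"t{j}" for j in range(k)]
        return pg.PosteriorSummary(
            A_mean=A_mean, A_var=np.asarray(A_var, dtype=float),
            tfa=np.ones((1, k)), B_mean=np.zeros((m, k)),
            gene_ids=np.array(genes, dtype=object),
            tf_ids=np.array(tfs, dtype=object),
            cell_ids=np.array(["c"], dtype=object))

    def test_cumulative_fractions_and_sizes(self, rng):
        m, k = 10, 4
        summary = self._summary(np.clip(rng.random((m, k)), 0.01, 0.99),
                                rng.random((m, k)))
        gold = _network((rng.random((m, k)) < 0.3).astype(float))
        gold.entries[0, 0] = 1.0
        curve = pg.calibration_curve(summary, gold, n_bins=10)
        np.testing.assert_allclose(curve.bin_fractions, np.arange(1, 11) / 10)
        expected_sizes = np.ceil(np.arange(1, 11) / 10 * m * k).astype(int)
        np.testing.assert_array_equal(curve.bin_sizes, expected_sizes)

    def test_last_bin_equals_overall_overlap_auprc(self, rng):
        m, k = 8, 3
        A_mean = np.clip(rng.random((m, k)), 0.01, 0.99)
        summary = self._summary(A_mean, rng.random((m, k)))
        entries = (rng.random((m, k)) < 0.3).astype(float)
        entries[0, 0] = 1.0
        gold = _network(entries)
        curve = pg.calibration_curve(summary, gold, n_bins=10)
        overall = pg.auprc(ScoredNetwork(A_mean, summary.gene_ids,
                                         summary.tf_ids), gold, "overlap")
        assert curve.bin_auprc[-1] == pytest.approx(overall)

    def test_constructed_low_variance_bin_is_perfect(self):
        # 20 entries: 2 low-variance entries perfectly ranked, the rest noisy
        A_mean = np.full((10, 2), 0.5)
        A_var = np.full((10, 2), 0.5)
        A_mean[0, 0], A_var[0, 0] = 0.99, 0.001     # true edge, certain
        A_mean[0, 1], A_var[0, 1] = 0.01, 0.002     # true non-edge, certain
        entries = np.zeros((10, 2))
        entries[0, 0] = 1.0
        entries[5, 0] = 1.0
        summary = self._summary(A_mean, A_var)
        curve = pg.calibration_curve(summary, _network(entries), n_bins=10)
        assert curve.bin_defined[0]
        assert curve.bin_auprc[0] == 1.0

    def test_bins_without_positives_flagged_not_zero(self):
        A_mean = np.full((5, 2), 0.5)
        A_var = np.arange(10, dtype=float).reshape(5, 2)
        entries = np.zeros((5, 2))
        entries[4, 1] = 1.0     # only positive has the highest variance
        summary = self._summary(A_mean, A_var)
        curve = pg.calibration_curve(summary, _network(entries), n_bins=5)
        assert not curve.bin_defined[0]
        assert np.isnan(curve.bin_auprc[0])
        assert curve.bin_defined[-1]


class TestIoU:
    def test_identical_networks(self, rng):
        scores = rng.random((4, 2))
        a, b = _scored(scores), _scored(scores.copy())
        assert pg.iou_top_edges(a, b, 0.25) == 1.0

    def test_disjoint_top_sets(self):
        a = _scored([[1.0, 0.0], [0.0, 0.0]])
        b = _scored([[0.0, 0.0], [0.0, 1.0]])
        assert pg.iou_top_edges(a, b, 0.25) == 0.0

    def test_one_third_on_toy(self):
        # top-50% of a 2x2 grid -> 2 edges each, overlap 1 => 1/(2+2-1)
        a = _scored([[1.0, 0.9], [0.1, 0.0]])
        b = _scored([[1.0, 0.1], [0.9, 0.0]])
        assert pg.iou_top_edges(a, b, 0.5) == pytest.approx(1 / 3)

    def test_symmetric(self, rng):
        a = _scored(rng.random((5, 3)))
        b = _scored(rng.random((5, 3)))
        assert pg.iou_top_edges(a, b, 0.25) == pg.iou_top_edges(b, a, 0.25)

    def test_label_mismatch_rejected(self):
        a = _scored(np.ones((2, 2)))
        b = _scored(np.ones((2, 2)), genes=["x0", "x1"])
        with pytest.raises(ValueError):
            pg.iou_top_edges(a, b, 0.25)


class TestPriorPerturbations:
    def test_shuffle_preserves_row_multiset(self, rng):
        prior = _network((rng.random((8, 3)) < 0.4).astype(float))
        shuffled = pg.shuffle_prior(prior, seed=4)
        assert sorted(map(tuple, prior.entries.tolist())) == \
               sorted(map(tuple, shuffled.entries.tolist()))
        assert shuffled.n_positives == prior.n_positives
        np.testing.assert_array_equal(shuffled.gene_ids, prior.gene_ids)

    def test_shuffle_deterministic(self, rng):
        prior = _network((rng.random((8, 3)) < 0.4).astype(float))
        a = pg.shuffle_prior(prior, seed=9)
        b = pg.shuffle_prior(prior, seed=9)
        np.testing.assert_array_equal(a.entries, b.entries)

    def test_empty_prior(self, rng):
        prior = _network((rng.random((5, 3)) < 0.5).astype(float))
        empty = pg.empty_prior(prior)
        assert empty.density == 0.0
        np.testing.assert_array_equal(empty.gene_ids, prior.gene_ids)
        np.testing.assert_array_equal(pg.empty_prior(empty).entries, empty.entries)

    def test_inject_noise_densities(self):
        rng = np.random.default_rng(0)
        entries = np.zeros(1000 * 100)
        entries[rng.choice(entries.size, 1000, replace=False)] = 1.0
        prior = _network(entries.reshape(1000, 100))
        assert prior.density == pytest.approx(0.01)
        for level, expected in [(1.0, 0.02), (2.5, 0.035), (5.0, 0.06)]:
            noisy = pg.inject_noise(prior, level, seed=1)
            assert noisy.density == pytest.approx(expected)
            # original positives untouched
            assert (noisy.entries[prior.entries == 1] == 1).all()

    def test_inject_zero_level_identity(self, rng):
        prior = _network((rng.random((6, 4)) < 0.3).astype(float))
        np.testing.assert_array_equal(pg.inject_noise(prior, 0.0, 1).entries,
                                      prior.entries)

    def test_inject_noise_exact_density_property(self, rng):
        for _ in range(10):
            m, k = int(rng.integers(5, 20)), int(rng.integers(2, 8))
            entries = (rng.random((m, k)) < 0.2).astype(float)
            prior = _network(entries)
            if prior.n_positives == 0:
                continue
            level = float(rng.uniform(0, 1.5))
            n_new = int(round(level * prior.n_positives))
            if n_new > (entries == 0).sum():
                continue
            noisy = pg.inject_noise(prior, level, seed=int(rng.integers(1000)))
            assert noisy.n_positives == prior.n_positives + n_new

    def test_inject_noise_insufficient_zeros(self):
        prior = _network(np.array([[1.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            pg.inject_noise(prior, 2.0, seed=0)


class TestDownsampleAndSplit:
    def test_downsample_counts(self, rng):
        W = ExpressionMatrix(rng.integers(0, 5, size=(1000, 4)).astype(float),
                             [f"c{i}" for i in range(1000)],
                             [f"g{j}" for j in range(4)])
        sub = pg.downsample_cells(W, 0.2, seed=0)
        assert sub.n_cells == 200
        np.testing.assert_array_equal(sub.gene_ids, W.gene_ids)
        assert len(set(sub.cell_ids.tolist())) == 200

    def test_downsample_full_fraction(self, tiny_data):
        sub = pg.downsample_cells(tiny_data.W, 1.0, seed=0)
        assert sub.n_cells == tiny_data.W.n_cells

    def test_split_reference_partition(self, rng):
        entries = (rng.random((20, 5)) < 0.3).astype(float)
        entries[0, 0] = 1.0
        gold = _network(entries)
        prior_part, eval_part = pg.split_reference(gold, 0.5, seed=3)
        total = gold.n_positives
        assert prior_part.n_positives == int(round(0.5 * total))
        assert (prior_part.entries * eval_part.entries).sum() == 0
        np.testing.assert_array_equal(prior_part.entries + eval_part.entries,
                                      gold.entries)

    def test_split_reference_cv_ratio(self, rng):
        entries = (rng.random((30, 4)) < 0.4).astype(float)
        entries[0, 0] = 1.0
        gold = _network(entries)
        prior_part, eval_part = pg.split_reference(gold, 0.8, seed=1)
        assert prior_part.n_positives == int(round(0.8 * gold.n_positives))
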