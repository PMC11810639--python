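"""Weight law, loss arithmetic, information content, and metric oracles."""

import numpy as np
import pytest

from megago.objective_metrics import (DEFAULT_GRID, ICTable, aupr, evaluate,
                                      fmax, ic_band, information_content,
                                      label_weights, read_ic_table, smin,
                                      stratified_balance, total_loss,
                                      wce_loss, write_ic_table)
from megago.structures_io import ProteinChain
from megago.tensor import Tensor


# ---------------------------------------------------------------------------
# independent brute-force oracles


def fmax_oracle(y, yhat):
    """Exhaustive sweep over every distinct score value inside (0, 1),
    the domain the decision-threshold grid covers (a zero score means the
    pair is never predicted)."""
    thresholds = np.unique(yhat)
    thresholds = thresholds[(thresholds > 0) & (thresholds < 1)]
    best = 0.0
    truth_counts = y.sum(axis=1)
    for t in thresholds:
        pred = yhat >= t
        precisions, recalls = [], []
        for i in range(y.shape[0]):
            npred = pred[i].sum()
            tp = (pred[i] & (y[i] == 1)).sum()
            if npred > 0:
                precisions.append(tp / npred)
            if truth_counts[i] > 0:
                recalls.append(tp / truth_counts[i])
        if not precisions or not recalls:
            continue
        p, r = np.mean(precisions), np.mean(recalls)
        if p + r > 0:
            best = max(best, 2 * p * r / (p + r))
    return best


def smin_oracle(y, yhat, icv, grid):
    best = np.inf
    for t in grid:
        ru = mi = 0.0
        for i in range(y.shape[0]):
            for j in range(y.shape[1]):
                pred = yhat[i, j] >= t
                if y[i, j] == 1 and not pred:
                    ru += icv[j]
                if y[i, j] == 0 and pred:
                    mi += icv[j]
        ru /= y.shape[0]
        mi /= y.shape[0]
        best = min(best, np.hypot(ru, mi))
    return best


def aupr_oracle(y, yhat):
    """Step-wise area at every distinct score level, descending."""
    yf, sf = y.ravel(), yhat.ravel()
    total_pos = yf.sum()
    levels = np.unique(sf)[::-1]
    area, prev_recall = 0.0, 0.0
    for t in levels:
        pred = sf >= t
        tp = int((pred & (yf == 1)).sum())
        precision = tp / pred.sum()
        recall = tp / total_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


# ---------------------------------------------------------------------------


class TestLabelWeights:
    def test_uniform_counts_give_unit_weights(self):
        lw = label_weights(np.array([7, 7, 7, 7]))
        np.testing.assert_allclose(lw.weights, 1.0)

    def test_worked_triple(self):
        lw = label_weights(np.array([10, 5, 1]))
        np.testing.assert_allclose(lw.weights, [1.0, 16 / 15, 16 / 3])

    def test_clamped_into_unit_to_ten(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            counts = rng.integers(0, 1000, size=rng.integers(1, 40))
            w = label_weights(counts).weights
            assert (w >= 1.0).all() and (w <= 10.0).all()

    def test_never_observed_term_gets_upper_clamp(self):
        lw = label_weights(np.array([5, 0, 5]))
        assert lw.weights[1] == 10.0

    def test_accepts_binary_matrix(self):
        y = np.array([[1, 0], [1, 1], [1, 0]])
        lw = label_weights(y)
        np.testing.assert_array_equal(lw.positives, [3, 1])


class TestWCELoss:
    def test_perfect_prediction_is_nearly_zero(self):
        y = np.array([[1.0, 0.0]])
        lw = label_weights(np.array([1, 1]))
        loss = wce_loss(y, y.copy(), lw)
        assert float(loss.data) < 2 * 1e-7 * 20

    def test_hand_computed_single_sample(self):
        y = np.array([[1.0, 0.0]])
        yhat = np.array([[0.5, 0.5]])
        lw = label_weights(np.array([1, 1]))
        lw.weights[:] = 1.0
        loss = wce_loss(y, yhat, lw, normalization="as_printed")  # Z = 1
        np.testing.assert_allclose(float(loss.data), 2 * np.log(2),
                                   rtol=1e-12)

    def test_doubling_weight_doubles_positive_contribution(self):
        y = np.array([[1.0, 0.0]])
        yhat = np.array([[0.3, 0.5]])
        lw1 = label_weights(np.array([1, 1]))
        lw1.weights[:] = [1.0, 0.0 + 1.0]
        base = float(wce_loss(y, yhat, lw1).data)
        lw2 = label_weights(np.array([1, 1]))
        lw2.weights[:] = [2.0, 1.0]
        doubled = float(wce_loss(y, yhat, lw2).data)
        pos_term = -np.log(0.3)
        np.testing.assert_allclose(doubled - base, pos_term, rtol=1e-10)

    def test_conventional_mode_equals_scalar_loop_bce(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(1, 9))
            m = int(rng.integers(1, 13))
            y = (rng.random((n, m)) < 0.4).astype(float)
            yhat = rng.uniform(0.01, 0.99, (n, m))
            lw = label_weights(np.ones(m))
            loss = float(wce_loss(y, yhat, lw,
                                  normalization="conventional").data)
            ref = 0.0
            for i in range(n):
                for j in range(m):
                    p = min(max(yhat[i, j], 1e-7), 1 - 1e-7)
                    ref -= (y[i, j] * np.log(p)
                            + (1 - y[i, j]) * np.log(1 - p))
            ref /= n * m
            np.testing.assert_allclose(loss, ref, atol=1e-10)

    def test_gradient_flows_through_predictions(self):
        y = np.array([[1.0, 0.0]])
        yhat = Tensor(np.array([[0.4, 0.6]]), requires_grad=True)
        lw = label_weights(np.array([1, 1]))
        wce_loss(y, yhat, lw).backward()
        assert yhat.grad is not None and np.isfinite(yhat.grad).all()


class TestTotalLoss:
    def test_plain_sum(self):
        rep = total_loss({"Main": 1.0, "alpha": 2.0, "beta": 3.0})
        assert rep.total == 6.0

    def test_main_only(self):
        rep = total_loss({"Main": 1.5})
        assert rep.total == 1.5

    def test_invariant_under_branch_ordering(self):
        a = total_loss({"Main": 0.1, "alpha": 0.7, "beta": 0.2}).total
        b = total_loss({"beta": 0.2, "Main": 0.1, "alpha": 0.7}).total
        assert a == b


class TestInformationContent:
    @pytest.mark.parametrize("p,expected", [(1.0, 0.0), (0.25, 2.0),
                                            (2.0 ** -10, 10.0)])
    def test_closed_form(self, p, expected):
        table = information_content(np.array([p]))
        np.testing.assert_allclose(table.ic, expected)

    def test_strictly_decreasing_in_frequency(self):
        rng = np.random.default_rng(2)
        p = np.sort(rng.uniform(1e-6, 1.0, size=100))
        ic = information_content(p).ic
        assert (np.diff(ic) < 0).all()

    def test_zero_frequency_flagged_infinite(self):
        table = information_content(np.array([0.0, 0.5]))
        assert np.isinf(table.ic[0])
        assert table.has_zero_frequency
        assert ic_band(table.ic[0]) == ">10"

    def test_bands(self):
        assert ic_band(4.9) == "<5"
        assert ic_band(5.0) == "5-10"
        assert ic_band(10.0) == "5-10"
        assert ic_band(10.1) == ">10"

    def test_table_round_trip(self, tmp_path):
        table = information_content(np.array([0.5, 0.125]), ["a", "b"])
        path = tmp_path / "ic.tsv"
        write_ic_table(table, path)
        back = read_ic_table(path)
        np.testing.assert_allclose(back.ic, table.ic)
        assert back.terms == table.terms


class TestFmax:
    def test_perfect_scores(self):
        y = np.array([[1, 0], [0, 1]])
        val, _ = fmax(y, y.astype(float))
        assert val == 1.0

    def test_single_protein_hand_case(self):
        y = np.array([[1, 0]])
        yhat = np.array([[0.9, 0.2]])
        val, t = fmax(y, yhat)
        assert val == 1.0
        assert 0.2 < t <= 0.9

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n, m = int(rng.integers(2, 11)), int(rng.integers(2, 9))
            y = (rng.random((n, m)) < 0.35).astype(int)
            if y.sum() == 0:
                y[0, 0] = 1
            yhat = np.round(rng.random((n, m)), 2)
            val, _ = fmax(y, yhat)
            assert abs(val - fmax_oracle(y, yhat)) <= 0.02

    def test_no_truth_raises(self):
        with pytest.raises(ValueError):
            fmax(np.zeros((2, 2), int), np.random.rand(2, 2))


class TestSmin:
    def test_perfect_prediction_zero(self):
        y = np.array([[1, 0], [0, 1]])
        icv = np.array([2.0, 3.0])
        val, _ = smin(y, y.astype(float), icv)
        assert val == 0.0

    def test_predict_nothing_equals_mean_total_ic(self):
        y = np.array([[1, 1, 0], [0, 1, 0]])
        icv = np.array([1.0, 2.0, 4.0])
        yhat = np.zeros((2, 3))
        val, _ = smin(y, yhat, icv)
        expected = ((1.0 + 2.0) + 2.0) / 2  # mean Σ IC of true terms
        np.testing.assert_allclose(val, expected)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(4)
        grid = DEFAULT_GRID[::7]
        for _ in range(10):
            n, m = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            y = (rng.random((n, m)) < 0.4).astype(int)
            if y.sum() == 0:
                y[0, 0] = 1
            yhat = rng.random((n, m))
            icv = rng.uniform(0.1, 8, m)
            val, _ = smin(y, yhat, icv, grid=grid)
            np.testing.assert_allclose(val, smin_oracle(y, yhat, icv, grid),
                                       atol=1e-10)

    def test_dominating_predictor_never_worse(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            y = (rng.random((5, 6)) < 0.4).astype(int)
            if y.sum() == 0:
                y[0, 0] = 1
            icv = rng.uniform(0.5, 5, 6)
            worse = rng.uniform(0, 1, (5, 6))
            # move every score toward the truth → uniformly better
            better = worse + 0.3 * (y - worse)
            s_worse, _ = smin(y, worse, icv)
            s_better, _ = smin(y, better, icv)
            assert s_better <= s_worse + 1e-12

    def test_normalized_scale(self):
        y = np.array([[1, 0], [1, 1]])
        icv = np.array([2.0, 2.0])
        val, _ = smin(y, np.zeros((2, 2)), icv, normalized=True)
        np.testing.assert_allclose(val, 1.0)  # predict-nothing baseline


class TestAUPR:
    def test_perfect_ranking(self):
        y = np.array([[1, 0], [0, 1]])
        yhat = np.array([[0.9, 0.1], [0.2, 0.8]])
        assert aupr(y, yhat) == 1.0

    def test_constant_scores_equal_prevalence(self):
        rng = np.random.default_rng(6)
        y = (rng.random((10, 10)) < 0.3).astype(int)
        val = aupr(y, np.full((10, 10), 0.5))
        np.testing.assert_allclose(val, y.mean())

    def test_matches_rank_based_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            y = (rng.random((6, 5)) < 0.3).astype(int)
            if y.sum() == 0:
                y[0, 0] = 1
            yhat = rng.random((6, 5))
            np.testing.assert_allclose(aupr(y, yhat), aupr_oracle(y, yhat),
                                       atol=1e-9)

    def test_macro_averages_over_annotated_terms(self):
        y = np.array([[1, 0, 0], [0, 0, 1]])
        yhat = np.array([[0.9, 0.5, 0.1], [0.1, 0.5, 0.9]])
        assert aupr(y, yhat, averaging="macro") == 1.0

    def test_zero_positives_raise(self):
        with pytest.raises(ValueError):
            aupr(np.zeros((2, 2), int), np.random.rand(2, 2))


class TestStratifiedBalance:
    def _chains(self, sizes):
        return [ProteinChain("A", "G" * n, np.zeros((n, 3))) for n in sizes]

    def test_downsamples_to_smallest_class(self):
        sizes = [50] * 90 + [200] * 10 + [600] * 10
        out, report = stratified_balance(self._chains(sizes), seed=0)
        assert report["before"] == {"short": 90, "normal": 10, "long": 10}
        assert report["after"] == {"short": 10, "normal": 10, "long": 10}
        assert len(out) == 30

    def test_balanced_input_unchanged(self):
        chains = self._chains([50, 60, 200, 300, 600, 700])
        out, _ = stratified_balance(chains, seed=1)
        assert len(out) == 6

    def test_output_classes_consistent(self):
        from megago.structures_io import classify_length
        sizes = [50] * 5 + [200] * 8 + [600] * 3
        out, report = stratified_balance(self._chains(sizes), seed=2)
        counts = {"short": 0, "normal": 0, "long": 0}
        for chain in out:
            counts[classify_length(chain).value] += 1
        assert counts == report["after"]

    def test_empty_class_raises(self):
        with pytest.raises(ValueError, match="empty"):
            stratified_balance(self._chains([50, 60]), seed=0)


class TestEvaluate:
    def test_stratified_report_totals_match_direct_calls(self):
        rng = np.random.default_rng(8)
        y = (rng.random((12, 6)) < 0.4).astype(int)
        y[0, 0] = 1
        yhat = rng.random((12, 6))
        ic = information_content(np.clip(y.mean(axis=0), 1e-6, 1))
        lengths = [50] * 4 + [200] * 4 + [600] * 4
        report = evaluate(y, yhat, ic=ic, lengths=lengths)
        np.testing.assert_allclose(report.fmax, fmax(y, yhat)[0])
        np.testing.assert_allclose(report.aupr, aupr(y, yhat))
        np.testing.assert_allclose(report.smin, smin(y, yhat, ic)[0])
        assert {"length:short", "length:normal",
                "length:long"} <= set(report.strata)
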