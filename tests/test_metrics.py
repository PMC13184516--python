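"""Scoring: overall, per-entity, exceedance summaries, binary metrics.

Correlations and classification metrics are cross-checked against
independent brute-force implementations (explicit ranks, covariance sums,
threshold sweeps) written here, not against the library path they verify.
"""

import math

import numpy as np
import pandas as pd
import pytest

from drpeval import (
    ResponseType,
    TripletDataset,
    binary_metrics,
    contingency_metrics,
    evaluate,
    fraction_above,
    overall_metrics,
    per_cell_metrics,
    per_drug_metrics,
)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def bf_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))

def bf_ranks(x):
    """Average ranks computed by explicit sorting and tie grouping."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks

def bf_spearman(x, y):
    return bf_pearson(bf_ranks(x), bf_ranks(y))

def bf_rmse(y, p):
    return math.sqrt(np.mean((np.asarray(y) - np.asarray(p)) ** 2))

def bf_mcc(tp, fn, fp, tn):
    num = tp * tn - fp * fn
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return num / den if den else math.nan

def bf_auroc(y, s):
    """Probability a positive outscores a negative (ties count half)."""
    y = np.asarray(y, bool)
    s = np.asarray(s, float)
    pos, neg = s[y], s[~y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _truth(cells, drugs, responses):
    return TripletDataset(
        pd.DataFrame({"cell_id": cells, "drug_id": drugs, "response": responses}),
        ResponseType.LN_IC50,
    )


def _pred(cells, drugs, predicted):
    return pd.DataFrame({"cell_id": cells, "drug_id": drugs, "predicted": predicted})


class TestOverallMetrics:
    def test_identity_predictions(self):
        cells = [f"C{i}" for i in range(5)]
        y = [1.0, 2.0, 3.0, 4.0, 5.0]
        m = overall_metrics(_truth(cells, ["D"] * 5, y), _pred(cells, ["D"] * 5, y))
        assert m["pcc"] == pytest.approx(1.0)
        assert m["scc"] == pytest.approx(1.0)
        assert m["rmse"] == pytest.approx(0.0)
        assert m["mae"] == pytest.approx(0.0)
        assert m["r2"] == pytest.approx(1.0)

    def test_anticorrelated_predictions(self):
        cells = [f"C{i}" for i in range(4)]
        y = [1.0, 2.0, 3.0, 4.0]
        m = overall_metrics(
            _truth(cells, ["D"] * 4, y), _pred(cells, ["D"] * 4, [-v for v in y])
        )
        assert m["pcc"] == pytest.approx(-1.0)
        assert m["scc"] == pytest.approx(-1.0)

    def test_hand_ranked_spearman(self):
        cells = [f"C{i}" for i in range(4)]
        m = overall_metrics(
            _truth(cells, ["D"] * 4, [1, 2, 3, 4]),
            _pred(cells, ["D"] * 4, [2, 1, 4, 3]),
        )
        assert m["scc"] == pytest.approx(0.6)  # 1 - 6*4/(4*15)

    def test_agrees_with_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            y = rng.normal(size=n)
            p = rng.normal(size=n) + 0.5 * y
            if rng.random() < 0.3:  # inject ties
                p = np.round(p, 1)
            cells = [f"C{i}" for i in range(n)]
            m = overall_metrics(_truth(cells, ["D"] * n, y), _pred(cells, ["D"] * n, p))
            assert m["pcc"] == pytest.approx(bf_pearson(y, p), abs=1e-12)
            assert m["scc"] == pytest.approx(bf_spearman(y, p), abs=1e-12)
            assert m["rmse"] == pytest.approx(bf_rmse(y, p), abs=1e-12)

    def test_unmatched_pairs_dropped(self):
        truth = _truth(["C1", "C2", "C3"], ["D"] * 3, [1.0, 2.0, 3.0])
        pred = _pred(["C1", "C2", "C9"], ["D"] * 3, [1.0, 2.0, 9.0])
        m = overall_metrics(truth, pred)
        assert m["n_pairs"] == 2

    def test_too_few_matches_rejected(self):
        truth = _truth(["C1", "C2"], ["D", "D"], [1.0, 2.0])
        with pytest.raises(ValueError, match="matched"):
            overall_metrics(truth, _pred(["C9"], ["D"], [1.0]))

    def test_zero_variance_gives_undefined_correlations(self):
        truth = _truth(["C1", "C2", "C3"], ["D"] * 3, [1.0, 2.0, 3.0])
        m = overall_metrics(truth, _pred(["C1", "C2", "C3"], ["D"] * 3, [5.0] * 3))
        assert math.isnan(m["pcc"]) and math.isnan(m["scc"])
        assert m["rmse"] > 0


class TestPerEntityMetrics:
    def test_per_drug_rank_ignores_offset_overall_rmse_does_not(self):
        cells = [f"C{i}" for i in range(4)]
        rows_t, rows_p = [], []
        for drug, offset in (("A", 0.0), ("B", 10.0)):
            y = np.array([1.0, 2.0, 3.0, 4.0])
            rows_t += [(c, drug, v) for c, v in zip(cells, y)]
            rows_p += [(c, drug, v + offset) for c, v in zip(cells, y)]
        truth = _truth(*zip(*[(r[0], r[1], r[2]) for r in rows_t]))
        pred = _pred(*zip(*[(r[0], r[1], r[2]) for r in rows_p]))
        table = per_drug_metrics(truth, pred)
        assert (table["scc"] == 1.0).all()
        assert overall_metrics(truth, pred)["rmse"] > 5

    def test_min_pairs_marks_undefined(self):
        truth = _truth(["C1", "C2", "C3", "C4"], ["A", "A", "A", "B"],
                       [1.0, 2.0, 3.0, 4.0])
        pred = _pred(["C1", "C2", "C3", "C4"], ["A", "A", "A", "B"],
                     [1.0, 2.0, 3.0, 4.0])
        table = per_drug_metrics(truth, pred, min_pairs=3).set_index("drug_id")
        assert table.loc["A", "scc"] == pytest.approx(1.0)
        assert math.isnan(table.loc["B", "scc"])
        assert table.loc["B", "n_pairs"] == 1

    def test_per_cell_symmetric_grouping(self):
        rng = np.random.default_rng(3)
        n = 60
        cells = [f"C{i % 6}" for i in range(n)]
        drugs = [f"D{i // 6}" for i in range(n)]
        y = rng.normal(size=n)
        p = y + rng.normal(scale=0.5, size=n)
        table = per_cell_metrics(_truth(cells, drugs, y), _pred(cells, drugs, p))
        assert len(table) == 6
        # agreement with brute-force grouping
        df = pd.DataFrame({"cell_id": cells, "y": y, "p": p})
        for cell, grp in df.groupby("cell_id"):
            row = table.set_index("cell_id").loc[cell]
            assert row["scc"] == pytest.approx(bf_spearman(grp["y"], grp["p"]), abs=1e-12)
            assert row["n_pairs"] == len(grp)

    def test_single_cell_dataset_one_row(self):
        truth = _truth(["C"] * 4, ["D1", "D2", "D3", "D4"], [1.0, 2.0, 3.0, 4.0])
        pred = _pred(["C"] * 4, ["D1", "D2", "D3", "D4"], [1.0, 2.0, 3.0, 4.0])
        table = per_cell_metrics(truth, pred)
        assert len(table) == 1 and table["scc"].iloc[0] == pytest.approx(1.0)

    def test_rmse_decomposition_across_drugs(self):
        rng = np.random.default_rng(4)
        n = 80
        cells = [f"C{i}" for i in range(n)]
        drugs = [f"D{i % 4}" for i in range(n)]
        y = rng.normal(size=n)
        p = y + rng.normal(size=n)
        truth, pred = _truth(cells, drugs, y), _pred(cells, drugs, p)
        table = per_drug_metrics(truth, pred)
        overall = overall_metrics(truth, pred)
        lhs = overall["rmse"] ** 2 * n
        rhs = float((table["n_pairs"] * table["rmse"] ** 2).sum())
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestFractionAbove:
    def test_half_above(self):
        t = pd.DataFrame({"drug_id": list("ABCD"), "scc": [0.6, 0.4, 0.9, 0.1]})
        assert fraction_above(t) == pytest.approx(0.5)

    def test_strict_inequality_at_threshold(self):
        t = pd.DataFrame({"drug_id": list("AB"), "scc": [0.5, 0.5]})
        assert fraction_above(t) == 0.0

    def test_undefined_excluded_from_denominator(self):
        t = pd.DataFrame({"drug_id": list("ABC"), "scc": [0.6, math.nan, 0.9]})
        assert fraction_above(t) == pytest.approx(1.0)

    def test_no_scorable_entities_undefined(self):
        t = pd.DataFrame({"drug_id": ["A"], "scc": [math.nan]})
        assert math.isnan(fraction_above(t))


class TestBinaryMetrics:
    @staticmethod
    def _calls_and_scores(y, s):
        n = len(y)
        calls = pd.DataFrame(
            {
                "cell_id": [f"C{i}" for i in range(n)],
                "drug_id": ["D"] * n,
                "call": ["sensitive" if v else "resistant" for v in y],
            }
        )
        scores = _pred([f"C{i}" for i in range(n)], ["D"] * n, s)
        return calls, scores

    def test_perfect_separation(self):
        calls, scores = self._calls_and_scores(
            [1, 1, 1, 0, 0, 0], [0.9, 0.8, 0.7, 0.2, 0.1, 0.3]
        )
        rep = binary_metrics(calls, scores)
        assert rep.auroc == pytest.approx(1.0)
        assert rep.mcc == pytest.approx(1.0)
        assert rep.acc == pytest.approx(1.0)

    def test_printed_contingency_arithmetic(self):
        m = contingency_metrics(tp=8, fn=2, fp=1, tn=9)
        assert m["sen"] == pytest.approx(0.8)
        assert m["spc"] == pytest.approx(0.9)
        assert m["gm"] == pytest.approx(math.sqrt(0.72))
        assert m["dor"] == pytest.approx(36.0)
        assert m["mcc"] == pytest.approx(bf_mcc(8, 2, 1, 9))

    def test_haldane_correction_on_zero_cell(self):
        m = contingency_metrics(tp=5, fn=0, fp=2, tn=3)
        assert m["dor"] == pytest.approx((5.5 * 3.5) / (2.5 * 0.5))

    def test_auroc_matches_bruteforce(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(8, 30))
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            s = np.round(rng.random(n), 1)  # ties on purpose
            calls, scores = self._calls_and_scores(y.astype(int), s)
            rep = binary_metrics(calls, scores)
            assert rep.auroc == pytest.approx(bf_auroc(y, s), abs=1e-12)

    def test_null_scores_auroc_near_half(self):
        rng = np.random.default_rng(21)
        aurocs = []
        for _ in range(200):
            y = np.array([1] * 10 + [0] * 10)
            s = rng.random(20)
            calls, scores = self._calls_and_scores(y, s)
            aurocs.append(binary_metrics(calls, scores).auroc)
        assert abs(np.mean(aurocs) - 0.5) < 0.05

    def test_undefined_calls_excluded_and_counted(self):
        calls, scores = self._calls_and_scores([1, 0, 1, 0], [0.9, 0.1, 0.8, 0.2])
        calls.loc[2, "call"] = "undefined"
        rep = binary_metrics(calls, scores)
        assert rep.n_undefined_calls == 1
        assert rep.tp + rep.fn + rep.fp + rep.tn == 3

    def test_single_class_truth_auroc_undefined(self):
        calls, scores = self._calls_and_scores([1, 1, 1], [0.9, 0.8, 0.7])
        rep = binary_metrics(calls, scores)
        assert math.isnan(rep.auroc)


class TestMetricReport:
    def test_summary_consistent_with_components(self, sparse_screen):
        ds, latents = sparse_screen
        from drpeval import oracle_predictor

        pred = oracle_predictor(latents, noise_sd_pred=0.2, seed=0)(ds.pairs())
        rep = evaluate(ds, pred)
        assert rep.fraction_scc_above == pytest.approx(
            fraction_above(rep.per_drug, "scc", 0.5)
        )
        text = rep.summary()
        assert "per-drug SCC" in text
        assert rep.n_scorable_drugs + rep.n_unscorable_drugs == len(rep.per_drug)
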