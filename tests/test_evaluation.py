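"""Agreement statistics against brute-force pair-counting oracles and
independent library implementations."""

import itertools
import json

import numpy as np
import pytest

from octseg import (
    MetricsReport,
    agreement_stats,
    boundary_iou,
    confusion_matrix,
    evaluate_predictions,
    per_class_metrics,
)
from octseg.evaluation import strength_of_agreement
from octseg.exceptions import DataError

RNG = np.random.default_rng(99)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_stats(cm: np.ndarray) -> dict:
    """All agreement statistics from first principles (python loops)."""
    cm = np.asarray(cm, dtype=float)
    k = cm.shape[0]
    total = cm.sum()
    po = sum(cm[i, i] for i in range(k)) / total
    rows = [cm[i, :].sum() for i in range(k)]
    cols = [cm[:, j].sum() for j in range(k)]
    pe = sum(rows[i] * cols[i] for i in range(k)) / total ** 2
    kappa = (po - pe) / (1 - pe)
    s = (po - 1 / k) / (1 - 1 / k)
    b = sum(cm[i, i] ** 2 for i in range(k)) / sum(rows[i] * cols[i] for i in range(k))

    def c2(x):
        return x * (x - 1) / 2

    sum_ij = sum(c2(cm[i, j]) for i in range(k) for j in range(k))
    sum_r = sum(c2(r) for r in rows)
    sum_c = sum(c2(c) for c in cols)
    exp = sum_r * sum_c / c2(total)
    ari = (sum_ij - exp) / (0.5 * (sum_r + sum_c) - exp)
    return {"accuracy": po, "hamming_loss": 1 - po, "kappa": kappa,
            "bennett_s": s, "bangdiwala_b": b, "ari": ari,
            "chi_squared_df": (k - 1) ** 2}


def ari_by_pair_enumeration(cm: np.ndarray) -> float:
    """ARI by literally enumerating all pixel pairs of the two labelings."""
    truth, pred = [], []
    k = cm.shape[0]
    for i in range(k):
        for j in range(k):
            truth += [i] * int(cm[i, j])
            pred += [j] * int(cm[i, j])
    n = len(truth)
    a = b_ = c = d = 0
    for p, q in itertools.combinations(range(n), 2):
        same_t = truth[p] == truth[q]
        same_p = pred[p] == pred[q]
        if same_t and same_p:
            a += 1
        elif same_t:
            c += 1
        elif same_p:
            d += 1
        else:
            b_ += 1
    n2 = n * (n - 1) / 2
    exp = (a + c) * (a + d) / n2
    maxi = 0.5 * ((a + c) + (a + d))
    return (a - exp) / (maxi - exp)


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        truth = RNG.integers(0, 5, (16, 8))
        cm = confusion_matrix(truth, truth, 5)
        assert cm.sum() == truth.size
        assert np.all(cm == np.diag(np.diag(cm)))

    def test_matches_nested_loop_counting_oracle(self):
        pred = RNG.integers(0, 3, (3, 3))
        truth = RNG.integers(0, 3, (3, 3))
        cm = confusion_matrix(pred, truth, 3)
        want = np.zeros((3, 3), dtype=int)
        for r in range(3):
            for c in range(3):
                want[truth[r, c], pred[r, c]] += 1
        np.testing.assert_array_equal(cm, want)

    def test_shape_mismatch_and_bad_labels_rejected(self):
        with pytest.raises(DataError):
            confusion_matrix(np.zeros((2, 2), int), np.zeros((3, 3), int), 5)
        with pytest.raises(DataError):
            confusion_matrix(np.full((2, 2), 7), np.zeros((2, 2), int), 5)


class TestPerClassMetrics:
    def test_direct_substitution_example(self):
        # TP=2, FP=1, FN=1 for class 0
        cm = np.array([[2, 1], [1, 6]])
        m = per_class_metrics(cm)[0]
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["recall"] == pytest.approx(2 / 3)
        assert m["f1"] == pytest.approx(2 / 3)
        assert m["dice"] == pytest.approx(2 / 3)

    def test_perfect_class_scores_one(self):
        m = per_class_metrics(np.diag([10, 5]))[0]
        assert m["precision"] == m["recall"] == m["f1"] == m["dice"] == 1.0
        assert not m["degenerate"]

    def test_absent_class_degenerate_zero(self):
        cm = np.zeros((3, 3), dtype=int)
        cm[0, 0] = 5
        cm[1, 1] = 5
        m = per_class_metrics(cm)[2]
        assert m["dice"] == 0.0 and m["degenerate"]

    def test_f1_equals_dice_for_every_class(self):
        for _ in range(20):
            cm = RNG.integers(0, 30, (4, 4))
            for m in per_class_metrics(cm):
                assert m["f1"] == pytest.approx(m["dice"], abs=1e-12)


class TestBoundaryIoU:
    def test_identical_masks_score_one(self):
        mask = (np.arange(16)[:, None] // 4 * np.ones(16, int)).astype(int)
        per_class, mean = boundary_iou(mask, mask, band_px=2)
        present = [per_class[k] for k in np.unique(mask)]
        assert all(v == 1.0 for v in present)
        assert mean == 1.0

    def test_disjoint_boundary_bands_score_zero(self):
        a = np.zeros((16, 16), int)
        a[1:4, 1:4] = 1
        b = np.zeros((16, 16), int)
        b[10:14, 10:14] = 1
        per_class, _ = boundary_iou(a, b, band_px=1, n_classes=2)
        assert per_class[1] == 0.0

    def test_shifted_square_matches_band_set_oracle(self):
        def band_oracle(mask, cls, r):
            # enumerate contour pixels, then all pixels within Euclidean r
            contour = set()
            h, w = mask.shape
            for i in range(h):
                for j in range(w):
                    if mask[i, j] != cls:
                        continue
                    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        ii, jj = i + di, j + dj
                        if 0 <= ii < h and 0 <= jj < w and mask[ii, jj] != cls:
                            contour.add((i, j))
            band = set()
            for (ci, cj) in contour:
                for i in range(h):
                    for j in range(w):
                        if (i - ci) ** 2 + (j - cj) ** 2 <= r ** 2:
                            band.add((i, j))
            return band

        a = np.zeros((16, 16), int)
        a[4:9, 4:9] = 1
        b = np.zeros((16, 16), int)
        b[5:10, 4:9] = 1          # shifted down by one pixel
        per_class, _ = boundary_iou(a, b, band_px=2, n_classes=2)
        for cls in (0, 1):
            band_a = band_oracle(a, cls, 2)
            band_b = band_oracle(b, cls, 2)
            want = len(band_a & band_b) / len(band_a | band_b)
            assert per_class[cls] == pytest.approx(want)


class TestAgreementStats:
    def test_perfect_agreement_all_statistics_one(self):
        stats = agreement_stats(np.diag([50, 30, 20, 10, 40]))
        for key in ("accuracy", "kappa", "bennett_s", "bangdiwala_b", "ari"):
            assert stats[key] == pytest.approx(1.0)
        assert stats["hamming_loss"] == 0.0
        assert stats["chi_squared_df"] == 16

    def test_uniform_two_class_table(self):
        stats = agreement_stats(np.full((2, 2), 25))
        assert stats["kappa"] == pytest.approx(0.0)
        assert stats["bennett_s"] == pytest.approx(0.0)
        assert stats["ari"] == pytest.approx(-1 / 98)   # = -0.010204...

    def test_ari_matches_exhaustive_pair_enumeration(self):
        cm = np.array([[6, 2], [1, 5]])
        got = agreement_stats(cm)["ari"]
        assert got == pytest.approx(ari_by_pair_enumeration(cm), abs=1e-12)

    def test_matches_brute_force_oracle_on_random_tables(self):
        for _ in range(100):
            k = int(RNG.integers(2, 6))
            cm = RNG.integers(0, 50, (k, k))
            cm[0, 0] += 1             # keep the table non-degenerate
            got = agreement_stats(cm)
            want = brute_force_stats(cm)
            for key, val in want.items():
                assert got[key] == pytest.approx(val, abs=1e-10), key

    def test_matches_sklearn_on_expanded_labelings(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        truth = RNG.integers(0, 4, 500)
        pred = np.where(RNG.random(500) < 0.8, truth, RNG.integers(0, 4, 500))
        cm = confusion_matrix(pred, truth, 4)
        stats = agreement_stats(cm)
        assert stats["kappa"] == pytest.approx(
            sklearn_metrics.cohen_kappa_score(truth, pred), abs=1e-12)
        assert stats["ari"] == pytest.approx(
            sklearn_metrics.adjusted_rand_score(truth, pred), abs=1e-12)
        assert stats["accuracy"] == pytest.approx(
            sklearn_metrics.accuracy_score(truth, pred), abs=1e-12)

    def test_statistics_degrade_as_diagonal_mass_moves_off(self):
        base = np.diag([40, 40, 40])
        prev = agreement_stats(base)
        for shift in (5, 10, 20):
            cm = np.diag([40 - shift, 40 - shift, 40 - shift])
            cm[0, 1] = cm[1, 2] = cm[2, 0] = shift
            cur = agreement_stats(cm)
            for key in ("accuracy", "kappa", "bennett_s", "bangdiwala_b", "ari"):
                assert cur[key] < prev[key]
            prev = cur

    def test_empty_matrix_rejected(self):
        with pytest.raises(DataError):
            agreement_stats(np.zeros((3, 3)))


class TestReport:
    def _report(self):
        truth = [RNG.integers(0, 5, (16, 8)) for _ in range(3)]
        preds = [np.where(RNG.random((16, 8)) < 0.9, t, (t + 1) % 5)
                 for t in truth]
        return evaluate_predictions(preds, truth, 5)

    def test_report_has_five_per_class_rows(self):
        report = self._report()
        assert len(report.per_class) == 5
        assert report.aggregate["mean_dice"] == pytest.approx(
            np.mean([m["dice"] for m in report.per_class]))

    def test_accuracy_plus_hamming_loss_is_one(self):
        agg = self._report().aggregate
        assert agg["accuracy"] + agg["hamming_loss"] == pytest.approx(1.0)

    def test_json_roundtrip_bit_exact(self, tmp_path):
        report = self._report()
        text = report.to_json(tmp_path / "report.json")
        back = MetricsReport.from_json((tmp_path / "report.json").read_text())
        assert back.to_json() == text
        assert json.loads(text)["aggregate"] == report.aggregate

    def test_strength_of_agreement_bands(self):
        assert strength_of_agreement(0.95) == "Almost Perfect"
        assert strength_of_agreement(0.5) == "Moderate"
        assert strength_of_agreement(-0.2) == "Poor"
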