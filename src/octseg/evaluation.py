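"""Segmentation agreement statistics from pixel-level confusion matrices.

Per-class overlap metrics (precision, recall, F1, Dice), boundary IoU on
2 px boundary bands, and chance-corrected whole-image agreement statistics
(accuracy, Hamming loss, Cohen's kappa, Bennett's S, Bangdiwala's B, the
Adjusted Rand Index, and the chi-squared degrees of freedom (K-1)^2).

The headline numbers are micro-aggregated: one confusion matrix pooled over
every pixel of every image; per-image macro averages are reported alongside.
Zero-denominator cases return 0 together with a degeneracy flag instead of
NaN so aggregation stays stable.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion

from .exceptions import DataError

#: Landis & Koch strength-of-agreement bands for chance-corrected statistics.
LANDIS_KOCH_BANDS = (
    (0.0, "Poor"), (0.01, "Slight"), (0.21, "Fair"), (0.41, "Moderate"),
    (0.61, "Substantial"), (0.81, "Almost Perfect"),
)
#: Bands conventionally used for Bangdiwala's B.
BANGDIWALA_BANDS = (
    (0.0, "Poor"), (0.1, "Weak"), (0.5, "Moderate"), (0.7, "Strong"),
    (0.9, "Very Strong"), (0.99, "Excellent"),
)


def strength_of_agreement(value: float, bands=LANDIS_KOCH_BANDS) -> str:
    label = bands[0][1]
    for lo, name in bands:
        if value >= lo:
            label = name
    return label


# ---------------------------------------------------------------------------
# confusion matrix and per-class metrics
# ---------------------------------------------------------------------------

def confusion_matrix(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> np.ndarray:
    """K x K count table, rows = truth class, columns = predicted class."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise DataError(f"pred size {pred.shape} != truth size {truth.shape}")
    if pred.size == 0:
        raise DataError("empty masks")
    if pred.min() < 0 or pred.max() >= n_classes or truth.min() < 0 \
            or truth.max() >= n_classes:
        raise DataError(f"labels outside [0, {n_classes})")
    idx = truth.astype(np.int64) * n_classes + pred.astype(np.int64)
    return np.bincount(idx, minlength=n_classes * n_classes).reshape(
        n_classes, n_classes)


def per_class_metrics(cm: np.ndarray) -> list[dict]:
    """Precision, recall, F1 and Dice per class from a confusion matrix.

    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R),
    Dice = 2TP/(2TP+FN+FP); zero denominators yield 0 with degenerate=True.
    """
    cm = np.asarray(cm, dtype=float)
    out = []
    for k in range(cm.shape[0]):
        tp = cm[k, k]
        fp = cm[:, k].sum() - tp
        fn = cm[k, :].sum() - tp
        degenerate = (tp + fp + fn) == 0
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall > 0 else 0.0)
        dice = 2 * tp / (2 * tp + fn + fp) if 2 * tp + fn + fp > 0 else 0.0
        out.append({"precision": float(precision), "recall": float(recall),
                    "f1": float(f1), "dice": float(dice),
                    "degenerate": bool(degenerate)})
    return out


# ---------------------------------------------------------------------------
# boundary IoU
# ---------------------------------------------------------------------------

def _boundary_band(binary: np.ndarray, band_px: int) -> np.ndarray:
    """Pixels within band_px (Euclidean disk) of the region's contour.

    The contour is the set of region pixels 4-adjacent to non-region pixels;
    the image frame itself does not count as a boundary.
    """
    if not binary.any():
        return np.zeros_like(binary, dtype=bool)
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
    inner = binary_erosion(binary, cross, border_value=1)
    contour = binary & ~inner
    if band_px <= 0 or not contour.any():
        return contour
    yy, xx = np.mgrid[-band_px:band_px + 1, -band_px:band_px + 1]
    disk = yy ** 2 + xx ** 2 <= band_px ** 2
    return binary_dilation(contour, structure=disk)


def boundary_iou(pred: np.ndarray, truth: np.ndarray, band_px: int = 2,
                 n_classes: int | None = None):
    """Per-class and mean IoU of boundary bands (default 2 px radius).

    The mean runs over classes present in the truth mask; classes whose two
    bands are both empty contribute IoU 0 with a degeneracy flag.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise DataError(f"pred shape {pred.shape} != truth shape {truth.shape}")
    if n_classes is None:
        n_classes = int(max(pred.max(), truth.max())) + 1
    per_class = []
    present = []
    for k in range(n_classes):
        bp = _boundary_band(pred == k, band_px)
        bt = _boundary_band(truth == k, band_px)
        union = (bp | bt).sum()
        iou = float((bp & bt).sum() / union) if union else 0.0
        per_class.append(iou)
        if (truth == k).any():
            present.append(iou)
    mean = float(np.mean(present)) if present else 0.0
    return per_class, mean


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

def agreement_stats(cm: np.ndarray) -> dict:
    """Chance-corrected agreement statistics from a K x K contingency table."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total <= 0:
        raise DataError("empty confusion matrix")
    k = cm.shape[0]
    rows = cm.sum(axis=1)
    cols = cm.sum(axis=0)
    po = np.trace(cm) / total
    pe = float((rows * cols).sum()) / total ** 2
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    bennett_s = (po - 1.0 / k) / (1.0 - 1.0 / k)
    denom_b = float((rows * cols).sum())
    bangdiwala_b = float((np.diag(cm) ** 2).sum()) / denom_b if denom_b else 0.0

    # Adjusted Rand Index by pair counting on the contingency table
    def comb2(x):
        return x * (x - 1.0) / 2.0

    sum_ij = comb2(cm).sum()
    sum_r = comb2(rows).sum()
    sum_c = comb2(cols).sum()
    n2 = comb2(total)
    expected = sum_r * sum_c / n2 if n2 else 0.0
    max_index = 0.5 * (sum_r + sum_c)
    ari = ((sum_ij - expected) / (max_index - expected)
           if max_index != expected else 1.0)

    return {
        "accuracy": float(po),
        "hamming_loss": float(1.0 - po),
        "kappa": float(kappa),
        "bennett_s": float(bennett_s),
        "bangdiwala_b": float(bangdiwala_b),
        "ari": float(ari),
        "chi_squared_df": int((k - 1) ** 2),
    }


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    per_class: list = field(default_factory=list)
    aggregate: dict = field(default_factory=dict)
    macro: dict = field(default_factory=dict)
    soa: dict = field(default_factory=dict)
    class_names: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"per_class": self.per_class, "aggregate": self.aggregate,
                "macro": self.macro, "soa": self.soa,
                "class_names": self.class_names}

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "MetricsReport":
        d = json.loads(text)
        return cls(per_class=d["per_class"], aggregate=d["aggregate"],
                   macro=d["macro"], soa=d["soa"],
                   class_names=d.get("class_names", []))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["class", "precision", "recall", "f1", "dice", "biou"])
            for i, row in enumerate(self.per_class):
                name = self.class_names[i] if i < len(self.class_names) else str(i)
                writer.writerow([name, row["precision"], row["recall"],
                                 row["f1"], row["dice"], row["biou"]])
            writer.writerow([])
            for key, val in sorted(self.aggregate.items()):
                writer.writerow([key, val])

    def summary(self) -> str:
        lines = ["class                precision  recall     f1         dice       biou"]
        for i, row in enumerate(self.per_class):
            name = self.class_names[i] if i < len(self.class_names) else f"class {i}"
            lines.append(f"{name:<20} {row['precision']:<10.4f} {row['recall']:<10.4f}"
                         f" {row['f1']:<10.4f} {row['dice']:<10.4f} {row['biou']:<10.4f}")
        lines.append("")
        for key in ("mean_dice", "mean_biou", "accuracy", "ari", "kappa",
                    "bennett_s", "bangdiwala_b", "hamming_loss", "chi_squared_df"):
            val = self.aggregate[key]
            soa = f"  ({self.soa[key]})" if key in self.soa else ""
            lines.append(f"{key:<16} {val:.5f}{soa}" if isinstance(val, float)
                         else f"{key:<16} {val}")
        return "\n".join(lines)


def evaluate_predictions(preds: list, truths: list, n_classes: int,
                         band_px: int = 2, class_names: list | None = None) -> MetricsReport:
    """Build a MetricsReport from parallel lists of predicted/true masks."""
    if not preds:
        raise DataError("no predictions to evaluate")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    bious = np.zeros(n_classes)
    biou_means = []
    macro_dice = []
    for pred, truth in zip(preds, truths):
        cm += confusion_matrix(pred, truth, n_classes)
        pc, mean_b = boundary_iou(pred, truth, band_px, n_classes)
        bious += np.asarray(pc)
        biou_means.append(mean_b)
        pcm = per_class_metrics(confusion_matrix(pred, truth, n_classes))
        macro_dice.append(float(np.mean([m["dice"] for m in pcm])))
    bious /= len(preds)

    per_class = per_class_metrics(cm)
    for k, row in enumerate(per_class):
        row["biou"] = float(bious[k])
    stats = agreement_stats(cm)
    aggregate = dict(stats)
    aggregate["mean_dice"] = float(np.mean([m["dice"] for m in per_class]))
    aggregate["mean_biou"] = float(np.mean(biou_means))
    soa = {
        "kappa": strength_of_agreement(stats["kappa"]),
        "bennett_s": strength_of_agreement(stats["bennett_s"]),
        "ari": strength_of_agreement(stats["ari"]),
        "bangdiwala_b": strength_of_agreement(stats["bangdiwala_b"], BANGDIWALA_BANDS),
    }
    return MetricsReport(per_class=per_class, aggregate=aggregate,
                         macro={"mean_dice": float(np.mean(macro_dice)),
                                "mean_biou": float(np.mean(biou_means))},
                         soa=soa, class_names=list(class_names or []))


def evaluate_model(model, dataset: list, band_px: int = 2,
                   class_names: list | None = None) -> MetricsReport:
    """Run inference over (image, mask) pairs and compute the full report."""
    if not dataset:
        raise DataError("empty evaluation dataset")
    from .synthetic import CLASS_NAMES
    n_classes = model.config.n_classes
    preds, truths = [], []
    for img, msk in dataset:
        pred = model.predict(np.asarray(img, dtype=np.float32)[None])[0]
        preds.append(pred)
        truths.append(np.asarray(msk))
    if class_names is None and n_classes == len(CLASS_NAMES):
        class_names = list(CLASS_NAMES)
    return evaluate_predictions(preds, truths, n_classes, band_px, class_names)
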