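"""Training protocol for the segmentation network.

The loss is a weighted composite ``alpha*CE + beta*DiceLoss + gamma*EdgeCE``
with default weights (1, 0, 1): CE is mean per-pixel sparse categorical
cross-entropy, DiceLoss is one minus the mean soft Dice, and EdgeCE is the
cross-entropy restricted to pixels within a 2 px band of a label boundary
(the term that drives edge fidelity).

Optimisation uses AdaBound from an initial learning rate of 0.001 with the
optimizer's published defaults.  The learning rate is multiplied by 0.1
whenever the validation loss fails to improve for five consecutive epochs;
training stops early after ten consecutive non-improving epochs, checkpoints
restore the best weights every 100 epochs, and runs are capped at 300
epochs.  Batches hold four images; model selection uses 6-fold
cross-validation.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation

from .architecture import SegmentationModel, _as_nchw
from .exceptions import ArgumentError, DataError, TrainingDivergedError
from .nn import core
from .nn.optim import AdaBound

IMPROVEMENT_TOL = 1e-6   # strict decrease means "below best - tol"


@dataclass(frozen=True)
class TrainConfig:
    loss_weights: tuple = (1.0, 0.0, 1.0)     # (alpha, beta, gamma)
    optimizer: str = "adabound"
    initial_lr: float = 1e-3
    final_lr: float = 0.1
    adabound_gamma: float = 1e-3
    batch_size: int = 4
    lr_factor: float = 0.1
    lr_patience: int = 5
    early_stop_patience: int = 10
    checkpoint_interval: int = 100
    max_epochs: int = 300
    k_folds: int = 6
    boundary_band_px: int = 2
    val_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if any(w < 0 for w in self.loss_weights):
            raise ArgumentError(f"loss weights must be >= 0, got {self.loss_weights}")
        if not (0 < self.lr_factor < 1):
            raise ArgumentError(f"lr_factor must lie in (0, 1), got {self.lr_factor}")
        for name in ("lr_patience", "early_stop_patience", "checkpoint_interval",
                     "max_epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ArgumentError(f"{name} must be > 0")


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_dice: list = field(default_factory=list)
    learning_rate: list = field(default_factory=list)
    checkpoint_events: list = field(default_factory=list)
    stopped_early: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.val_loss)

    def to_dict(self) -> dict:
        return {
            "train_loss": [float(v) for v in self.train_loss],
            "val_loss": [float(v) for v in self.val_loss],
            "val_dice": [float(v) for v in self.val_dice],
            "learning_rate": [float(v) for v in self.learning_rate],
            "checkpoint_events": list(self.checkpoint_events),
            "stopped_early": self.stopped_early,
        }


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def label_boundary_mask(mask: np.ndarray, band_px: int = 2) -> np.ndarray:
    """Boolean map of pixels within ``band_px`` (Chebyshev) of a label change.

    A boundary pixel is one whose 4-neighbourhood contains a different class.
    """
    mask = np.asarray(mask)
    boundary = np.zeros(mask.shape, dtype=bool)
    boundary[:-1, :] |= mask[:-1, :] != mask[1:, :]
    boundary[1:, :] |= mask[1:, :] != mask[:-1, :]
    boundary[:, :-1] |= mask[:, :-1] != mask[:, 1:]
    boundary[:, 1:] |= mask[:, 1:] != mask[:, :-1]
    if band_px > 0 and boundary.any():
        boundary = binary_dilation(
            boundary, structure=np.ones((2 * band_px + 1, 2 * band_px + 1), bool))
    return boundary


def composite_loss(probabilities: np.ndarray, mask: np.ndarray,
                   weights: tuple = (1.0, 0.0, 1.0), band_px: int = 2,
                   eps: float = 1e-12) -> float:
    """Composite loss on predicted probabilities (K, H, W) or (N, K, H, W)."""
    p = np.asarray(probabilities, dtype=float)
    if p.ndim == 3:
        p = p[None]
        mask = np.asarray(mask)[None]
    mask = np.asarray(mask)
    if p.shape[0] != mask.shape[0] or p.shape[2:] != mask.shape[1:]:
        raise DataError(f"probabilities shape {p.shape} does not match mask "
                        f"shape {mask.shape}")
    k = p.shape[1]
    if mask.min() < 0 or mask.max() >= k:
        raise DataError(f"mask contains class ids outside [0, {k})")
    alpha, beta, gamma = weights
    p_true = np.take_along_axis(p, mask[:, None], axis=1)[:, 0]
    nll = -np.log(np.maximum(p_true, eps))
    loss = alpha * float(nll.mean())
    if beta:
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, mask[:, None], 1.0, axis=1)
        inter = (p * onehot).sum(axis=(0, 2, 3))
        union = p.sum(axis=(0, 2, 3)) + onehot.sum(axis=(0, 2, 3))
        dice = (2 * inter + 1e-6) / (union + 1e-6)
        loss += beta * float(1.0 - dice.mean())
    if gamma:
        band = np.stack([label_boundary_mask(m, band_px) for m in mask])
        if band.any():
            loss += gamma * float(nll[band].mean())
    return loss


def _loss_graph(logits, masks: np.ndarray, weights: tuple, band_px: int):
    """Differentiable composite loss on logits, matching composite_loss."""
    alpha, beta, gamma = weights
    n, k, h, w = logits.data.shape
    wmap = np.full(masks.shape, alpha / masks.size, dtype=logits.dtype)
    if gamma:
        band = np.stack([label_boundary_mask(m, band_px) for m in masks])
        nband = band.sum()
        if nband:
            wmap = wmap + band.astype(logits.dtype) * (gamma / nband)
    loss = core.weighted_cross_entropy(logits, masks, wmap)
    if beta:
        loss = core.add(loss, core.mul(core.soft_dice_loss(logits, masks, k), beta))
    return loss


# ---------------------------------------------------------------------------
# schedule policies (pure functions over history)
# ---------------------------------------------------------------------------

def _stagnation_counter(val_losses, patience, factor=None):
    """Replay the plateau logic; returns (lr_multiplier_exponent, counter)."""
    best = np.inf
    counter = 0
    reductions = 0
    for loss in val_losses:
        if loss < best - IMPROVEMENT_TOL:
            best = loss
            counter = 0
        else:
            counter += 1
            if factor is not None and counter >= patience:
                reductions += 1
                counter = 0
    return reductions, counter


def lr_scheduler_step(history: TrainingHistory, config: TrainConfig) -> float:
    """Learning rate implied by the validation-loss history: multiply by
    lr_factor after each run of lr_patience consecutive non-improving epochs."""
    if not history.val_loss:
        raise ArgumentError("history is empty")
    reductions, _ = _stagnation_counter(history.val_loss, config.lr_patience,
                                        config.lr_factor)
    return config.initial_lr * config.lr_factor ** reductions


def early_stopping_check(history: TrainingHistory, config: TrainConfig) -> bool:
    """True when the last early_stop_patience epochs show no strict improvement."""
    if not history.val_loss:
        raise ArgumentError("history is empty")
    _, counter = _stagnation_counter(history.val_loss, config.early_stop_patience)
    return counter >= config.early_stop_patience


def checkpoint_policy(history: TrainingHistory, config: TrainConfig):
    """At multiples of checkpoint_interval, name the epoch whose weights to
    restore: best validation Dice, ties broken by least validation loss.

    Returns ``("restore", epoch_index)`` or None; epoch indices are 0-based.
    """
    epoch = history.n_epochs
    if epoch == 0 or epoch % config.checkpoint_interval:
        return None
    dice = np.asarray(history.val_dice)
    loss = np.asarray(history.val_loss)
    best = np.lexsort((loss, -dice))[0]
    return ("restore", int(best))


def kfold_split(n_items: int, k: int, seed: int = 0):
    """k disjoint validation folds covering range(n_items), sizes within 1."""
    if k < 2:
        raise ArgumentError(f"k must be >= 2, got {k}")
    if n_items < k:
        raise ArgumentError(f"need at least k={k} items, got {n_items}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    perm = rng.permutation(n_items)
    folds = np.array_split(perm, k)
    splits = []
    for i in range(k):
        val = np.sort(folds[i])
        train = np.sort(np.concatenate([folds[j] for j in range(k) if j != i]))
        splits.append((train, val))
    return splits


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _mean_dice(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> float:
    from .evaluation import confusion_matrix, per_class_metrics
    cm = confusion_matrix(pred.reshape(-1), truth.reshape(-1), n_classes)
    return float(np.mean([m["dice"] for m in per_class_metrics(cm)]))


def train_model(model: SegmentationModel, dataset: list,
                config: TrainConfig | None = None, val_data: list | None = None,
                verbose: bool = False):
    """Train *model* on (image, mask) pairs; returns (model, TrainingHistory).

    When *val_data* is None a seeded ``val_fraction`` holdout is split off.
    All randomness (split, shuffling) derives from ``config.seed``; weights
    are whatever the freshly built model holds (training from scratch).
    """
    config = config or TrainConfig()
    config.validate()
    if not dataset:
        raise DataError("empty training dataset")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 23]))

    if val_data is None:
        n_val = max(1, int(round(config.val_fraction * len(dataset))))
        perm = rng.permutation(len(dataset))
        val_data = [dataset[i] for i in perm[:n_val]]
        dataset = [dataset[i] for i in perm[n_val:]]
        if not dataset:
            raise DataError("dataset too small to hold out a validation split")

    x_train = _as_nchw(np.stack([img for img, _ in dataset]))
    y_train = np.stack([msk for _, msk in dataset]).astype(np.int64)
    x_val = _as_nchw(np.stack([img for img, _ in val_data]))
    y_val = np.stack([msk for _, msk in val_data]).astype(np.int64)
    n_classes = model.config.n_classes
    if y_train.max() >= n_classes or y_val.max() >= n_classes:
        raise DataError("mask contains class ids >= n_classes")

    opt = AdaBound(model.parameters(), lr=config.initial_lr,
                   final_lr=config.final_lr, gamma=config.adabound_gamma)
    history = TrainingHistory()
    best_loss = np.inf
    stagnant = 0
    best_state = {"dice": -np.inf, "loss": np.inf, "epoch": -1, "state": None}

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(dataset))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.forward(x_train[idx], train=True)
            loss = _loss_graph(logits, y_train[idx], config.loss_weights,
                               config.boundary_band_px)
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}")
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1

        # validation
        val_probs = model.predict_proba(x_val, batch_size=config.batch_size)
        val_loss = composite_loss(val_probs, y_val, config.loss_weights,
                                  config.boundary_band_px)
        val_pred = val_probs.argmax(axis=1)
        val_dice = _mean_dice(val_pred, y_val, n_classes)

        history.train_loss.append(epoch_loss / max(n_batches, 1))
        history.val_loss.append(float(val_loss))
        history.val_dice.append(float(val_dice))
        history.learning_rate.append(float(opt.lr))
        if verbose:
            print(f"epoch {epoch + 1}: train {history.train_loss[-1]:.4f} "
                  f"val {val_loss:.4f} dice {val_dice:.4f} lr {opt.lr:.2e}")

        if (val_dice, -val_loss) > (best_state["dice"], -best_state["loss"]):
            best_state.update(dice=val_dice, loss=val_loss, epoch=epoch,
                              state=model.state_dict())

        # plateau LR schedule and early stopping share one improvement notion
        if val_loss < best_loss - IMPROVEMENT_TOL:
            best_loss = val_loss
            stagnant = 0
        else:
            stagnant += 1
            if stagnant % config.lr_patience == 0:
                opt.lr *= config.lr_factor
        if stagnant >= config.early_stop_patience:
            history.stopped_early = True
            break

        action = checkpoint_policy(history, config)
        if action is not None and best_state["state"] is not None:
            model.load_state_dict(best_state["state"])
            history.checkpoint_events.append(
                {"epoch": epoch + 1, "restored_epoch": best_state["epoch"] + 1})

    return model, history


def cross_validate(dataset: list, model_factory, config: TrainConfig | None = None):
    """k-fold cross-validation; returns per-fold (history, val metrics dict)."""
    from .evaluation import evaluate_model

    config = config or TrainConfig()
    results = []
    for fold, (train_idx, val_idx) in enumerate(
            kfold_split(len(dataset), config.k_folds, config.seed)):
        model = model_factory()
        train_set = [dataset[i] for i in train_idx]
        val_set = [dataset[i] for i in val_idx]
        model, history = train_model(model, train_set, config, val_data=val_set)
        report = evaluate_model(model, val_set)
        results.append({"fold": fold, "history": history, "report": report})
    return results
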