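"""Within-session training protocol, optimization loop and metrics.

One "repeat" is an independent stratified shuffle of the session into 80%
train pool / 20% test, with 20% of the pool held out for validation.  The
model with the best validation accuracy (earliest epoch on ties) is kept
and scored on the untouched test split.  S&R augmentation is applied to
the training split only; an index-level guard asserts that no test trial
ever reaches augmentation or optimization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split

from .augmentation import AugmentConfig, build_augmented_train_set
from .data import EEGEpochSet
from .model import APCformer, cross_entropy_loss
from .nn import Adam, CosineAnnealingLR

logger = logging.getLogger(__name__)


class ProtocolError(RuntimeError):
    pass


@dataclass
class TrainProtocol:
    """Split ratios, optimizer schedule and repetition settings."""

    test_fraction: float = 0.2
    val_fraction_of_train: float = 0.2
    n_repeats: int = 5
    batch_size: int = 32
    max_epochs: int = 100
    lr: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        for frac in (self.test_fraction, self.val_fraction_of_train):
            if not 0 < frac < 1:
                raise ValueError("split fractions must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class EvalReport:
    """Test-set scorecard: counts, accuracy, chance-corrected agreement."""

    confusion: np.ndarray          # rows = true class, cols = predicted
    accuracy: float
    kappa: float
    n_test: int
    per_repeat_accuracies: list[float] = field(default_factory=list)
    p_value: float | None = None

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "n_test": self.n_test,
            "per_repeat_accuracies": self.per_repeat_accuracies,
            "p_value": self.p_value,
        }


def split_within_session(
    epochs: EEGEpochSet, protocol: TrainProtocol, repeat_index: int = 0
) -> tuple[EEGEpochSet, EEGEpochSet, EEGEpochSet]:
    """Stratified (train, val, test) split, seeded by (seed, repeat_index)."""
    protocol.validate()
    counts = epochs.class_counts()
    if counts.min() < 5:
        raise ProtocolError(
            f"stratified split needs >= 5 trials per class, got {counts.tolist()}"
        )
    rs = int((protocol.seed * 100003 + repeat_index) % (2**31))
    idx = np.arange(epochs.n_trials)
    pool_idx, test_idx = train_test_split(
        idx, test_size=protocol.test_fraction, stratify=epochs.labels,
        random_state=rs,
    )
    train_idx, val_idx = train_test_split(
        pool_idx, test_size=protocol.val_fraction_of_train,
        stratify=epochs.labels[pool_idx], random_state=rs + 1,
    )
    parts = []
    for name, part_idx in (("train", train_idx), ("val", val_idx),
                           ("test", test_idx)):
        sub = epochs.subset_trials(np.sort(part_idx))
        sub.meta["split"] = name
        sub.meta["trial_indices"] = np.sort(part_idx).tolist()
        parts.append(sub)
    return tuple(parts)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _accuracy_on(model: APCformer, split: EEGEpochSet) -> float:
    preds = model.predict(split.data)
    return float((preds == split.labels).mean())


def train(
    model: APCformer,
    train_set: EEGEpochSet,
    val_set: EEGEpochSet,
    protocol: TrainProtocol,
    target_train_accuracy: float | None = None,
) -> tuple[APCformer, dict]:
    """Adam + cosine annealing; returns the best-validation weights.

    ``history`` records per-epoch mean training loss and validation
    accuracy.  ``target_train_accuracy`` optionally stops early once the
    training split is fit to that level (the best-val selection still
    applies).
    """
    protocol.validate()
    if train_set.n_trials == 0:
        raise ProtocolError("empty training set")
    train_ids = set(train_set.meta.get("trial_indices", []))
    val_ids = set(val_set.meta.get("trial_indices", []))
    if train_ids & val_ids:
        raise ProtocolError("train and validation splits overlap")

    x = train_set.data.astype(np.float32)[:, None, :, :]
    y = train_set.labels
    rng = np.random.default_rng(protocol.seed)
    opt = Adam(model.parameters(), lr=protocol.lr)
    sched = CosineAnnealingLR(opt, t_max=protocol.max_epochs)
    history: dict = {"train_loss": [], "val_accuracy": [], "lr": []}
    best_state = model.state_dict()
    best_val = -1.0
    best_epoch = -1
    model.train()
    for epoch in range(protocol.max_epochs):
        losses = []
        for batch_idx in _batches(len(y), protocol.batch_size, rng):
            probs = model(x[batch_idx])
            loss = cross_entropy_loss(probs, y[batch_idx])
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        sched.step()
        val_acc = _accuracy_on(model, val_set)
        model.train()
        history["train_loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(val_acc)
        history["lr"].append(opt.lr)
        if val_acc > best_val:  # strict: earliest epoch wins ties
            best_val = val_acc
            best_epoch = epoch
            best_state = model.state_dict()
        logger.info("epoch %d: loss %.4f, val acc %.3f", epoch,
                    history["train_loss"][-1], val_acc)
        if target_train_accuracy is not None:
            if _accuracy_on(model, train_set) >= target_train_accuracy:
                model.train()
                break
            model.train()
    history["best_epoch"] = best_epoch
    model.load_state_dict(best_state)
    model.eval()
    return model, history


def evaluate(model: APCformer, test_set: EEGEpochSet) -> EvalReport:
    """Confusion matrix, accuracy (trace/n) and Cohen's kappa on a test set."""
    if test_set.n_trials == 0:
        raise ProtocolError("empty test set")
    model.eval()
    preds = model.predict(test_set.data)
    n_classes = model.cfg.n_classes
    conf = confusion_matrix(test_set.labels, preds,
                            labels=np.arange(n_classes))
    return EvalReport(
        confusion=conf,
        accuracy=accuracy_from_confusion(conf),
        kappa=kappa_from_confusion(conf),
        n_test=test_set.n_trials,
    )


def accuracy_from_confusion(confusion: np.ndarray) -> float:
    """Correct predictions over all predictions (multiclass trace/n)."""
    confusion = np.asarray(confusion)
    return float(np.trace(confusion) / confusion.sum())


def kappa_from_confusion(confusion: np.ndarray) -> float:
    """Cohen's kappa: (P_o - P_e) / (1 - P_e), with the chance-agreement
    term P_e from the row/column marginals."""
    confusion = np.asarray(confusion, dtype=float)
    n = confusion.sum()
    p_o = np.trace(confusion) / n
    p_e = float((confusion.sum(axis=1) * confusion.sum(axis=0)).sum() / n**2)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1 - p_e))


def cohen_kappa(p_o: float, p_e: float) -> float:
    """Closed form of the chance-corrected agreement."""
    return (p_o - p_e) / (1 - p_e)


def wilcoxon_compare(acc_a, acc_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired accuracy lists."""
    acc_a = np.asarray(acc_a, dtype=float)
    acc_b = np.asarray(acc_b, dtype=float)
    if acc_a.shape != acc_b.shape or acc_a.ndim != 1 or len(acc_a) < 5:
        raise ValueError("need paired 1-D lists of equal length >= 5")
    diffs = acc_a - acc_b
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; test is degenerate",
                      RuntimeWarning, stacklevel=2)
        return 1.0
    res = stats.wilcoxon(acc_a, acc_b, alternative="two-sided",
                         zero_method="wilcox")
    return float(res.pvalue)


def run_protocol(
    epochs: EEGEpochSet,
    model_factory,
    protocol: TrainProtocol,
    augment: AugmentConfig | None = None,
    target_train_accuracy: float | None = None,
) -> EvalReport:
    """Full repeated within-session evaluation.

    ``model_factory(repeat_index) -> APCformer`` builds a fresh model per
    repeat.  Returns the report of the last repeat with per-repeat test
    accuracies attached; the aggregate accuracy is their mean.
    """
    accs = []
    report = None
    for rep in range(protocol.n_repeats):
        train_set, val_set, test_set = split_within_session(
            epochs, protocol, rep)
        test_ids = set(test_set.meta["trial_indices"])
        if augment is not None:
            train_set = build_augmented_train_set(train_set, augment)
            leaked = test_ids & set(train_set.meta.get("trial_indices", []))
            if leaked:
                raise ProtocolError(f"test trials leaked into training: {leaked}")
        model = model_factory(rep)
        model, _ = train(model, train_set, val_set, protocol,
                         target_train_accuracy=target_train_accuracy)
        report = evaluate(model, test_set)
        accs.append(report.accuracy)
        logger.info("repeat %d: test accuracy %.3f", rep, report.accuracy)
    report.per_repeat_accuracies = accs
    report.accuracy = float(np.mean(accs))
    return report
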