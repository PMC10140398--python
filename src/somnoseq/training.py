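"""Training protocol: sequence construction, fold splitting, the cosine
warm-restart learning schedule, early stopping, and the k-fold
cross-validation driver.

Splits are made at the recording level throughout (including the inner
90/10 train/validation split) so that epochs of one subject never leak
between sets.  Training sequences overlap by 75% (quadrupling the
training data); validation and test sequences do not overlap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .metrics import ConfusionMatrix, MetricsReport, accuracy, cohens_kappa, confusion, evaluate, groupwise_evaluate
from .nn.model import ModelConfig, SleepStager, predict_hypnogram
from .stages import Hypnogram, N_STAGES

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    """Optimization hyperparameters.

    The learning-rate range (1e-3 down to 1e-5), early-stopping
    patience of 20 and cap of 200 training epochs are the protocol
    defaults; the warm-restart cycle (T0, Tmult) follows the standard
    cosine-annealing-with-restarts schedule.
    """

    lr_max: float = 1e-3
    lr_min: float = 1e-5
    max_epochs: int = 200
    patience: int = 20
    seq_len: int = 100
    train_overlap: float = 0.75
    batch_size: int = 8
    restart_period_T0: int = 10
    restart_mult_Tmult: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.lr_min < self.lr_max:
            raise ValueError("need 0 < lr_min < lr_max")
        if not 0 <= self.train_overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        stride = self.seq_len * (1.0 - self.train_overlap)
        if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
            raise ValueError(
                f"seq_len*(1-overlap) = {stride} is not a whole number of epochs")

    @property
    def train_stride(self) -> int:
        return int(round(self.seq_len * (1.0 - self.train_overlap)))


# ---------------------------------------------------------------------------
# Sequence construction
# ---------------------------------------------------------------------------


def make_sequences(
    epochs: np.ndarray,
    labels: np.ndarray,
    seq_len: int,
    overlap: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Window a recording's epochs into fixed-length sequences.

    Parameters
    ----------
    epochs : (n, n_channels, samples) epoch array
    labels : (n,) stage codes
    seq_len, overlap : window length in epochs and fractional overlap;
        the stride ``seq_len*(1-overlap)`` must be a whole number.

    Returns ``(x, y, mask)`` with shapes ``(w, seq_len, samples,
    n_channels)``, ``(w, seq_len)``, ``(w, seq_len)``.  For a recording
    shorter than ``seq_len`` a single window is padded by repeating the
    final epoch; the mask is False on padded positions so they are
    excluded from loss and metrics.
    """
    n = len(epochs)
    if n < 1:
        raise ValueError("need at least one epoch")
    if len(labels) != n:
        raise ValueError("epochs and labels length mismatch")
    stride_f = seq_len * (1.0 - overlap)
    stride = int(round(stride_f))
    if abs(stride_f - stride) > 1e-9 or stride < 1:
        raise ValueError(f"non-integral window stride {stride_f}")
    x = np.transpose(epochs, (0, 2, 1))  # (n, samples, channels)
    if n < seq_len:
        pad = seq_len - n
        xw = np.concatenate([x, np.repeat(x[-1:], pad, axis=0)])[None]
        yw = np.concatenate([labels, np.repeat(labels[-1:], pad)])[None]
        mask = np.zeros((1, seq_len), dtype=bool)
        mask[0, :n] = True
        return xw, yw, mask
    starts = np.arange(0, n - seq_len + 1, stride)
    xw = np.stack([x[s:s + seq_len] for s in starts])
    yw = np.stack([labels[s:s + seq_len] for s in starts])
    return xw, yw, np.ones((len(starts), seq_len), dtype=bool)


def sequence_count(n: int, seq_len: int, overlap: float) -> int:
    """Closed-form window count for n >= seq_len: floor((n-L)/stride)+1."""
    stride = int(round(seq_len * (1.0 - overlap)))
    if n < seq_len:
        return 1
    return (n - seq_len) // stride + 1


# ---------------------------------------------------------------------------
# Fold plan
# ---------------------------------------------------------------------------


@dataclass
class FoldPlan:
    """Recording-level k-fold assignment with inner train/validation split."""

    k: int
    folds: list[dict[str, list[str]]]  # keys: test, train, val
    seed: int

    def validate(self, all_ids: list[str]) -> None:
        """Leakage guard: test folds partition the cohort; within each fold
        train/val/test are pairwise disjoint."""
        test_union: list[str] = []
        for i, f in enumerate(self.folds):
            sets = {k: set(f[k]) for k in ("test", "train", "val")}
            for a in ("test", "train", "val"):
                for b in ("test", "train", "val"):
                    if a < b and sets[a] & sets[b]:
                        raise ValueError(
                            f"fold {i}: {a}/{b} share recordings {sets[a] & sets[b]}")
            test_union += f["test"]
        if sorted(test_union) != sorted(all_ids):
            raise ValueError("test folds do not partition the cohort")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"k": self.k, "seed": self.seed, "folds": self.folds}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldPlan":
        d = json.loads(Path(path).read_text())
        return cls(k=d["k"], folds=d["folds"], seed=d["seed"])


def split_folds(recording_ids: list[str], k: int = 10, seed: int = 0,
                val_fraction: float = 0.10) -> FoldPlan:
    """Shuffle and partition recordings into k near-equal test folds.

    Fold sizes differ by at most one.  Within each fold, the non-test
    recordings are split 90/10 into train/validation from the same
    seeded stream, at the recording level, with at least one validation
    recording.
    """
    ids = list(recording_ids)
    if len(ids) < k:
        raise ValueError(f"cannot split {len(ids)} recordings into {k} folds")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    test_folds = [list(a) for a in np.array_split(np.array(order, dtype=object), k)]
    folds = []
    for test in test_folds:
        rest = [i for i in order if i not in test]
        perm = [rest[i] for i in rng.permutation(len(rest))]
        n_val = max(1, round(val_fraction * len(rest)))
        folds.append({
            "test": [str(t) for t in test],
            "val": [str(v) for v in perm[:n_val]],
            "train": [str(t) for t in perm[n_val:]],
        })
    plan = FoldPlan(k=k, folds=folds, seed=seed)
    plan.validate(ids)
    return plan


# ---------------------------------------------------------------------------
# Learning-rate schedule and finder
# ---------------------------------------------------------------------------


def lr_at(t: int, config: TrainingConfig) -> float:
    """Cosine annealing with warm restarts, evaluated at training epoch t.

    Within a cycle of nominal length T_i the rate is
    ``lr_min + (lr_max - lr_min) * (1 + cos(pi * T_cur / T_i)) / 2``
    with T_cur running over [0, T_i] inclusive (so both endpoints of
    the printed range are attained); the next cycle then starts with
    T_i multiplied by Tmult.
    """
    if t < 0:
        raise ValueError("epoch index must be >= 0")
    T_i = config.restart_period_T0
    rem = t
    while rem > T_i:
        rem -= T_i + 1
        T_i *= config.restart_mult_Tmult
    return config.lr_min + 0.5 * (config.lr_max - config.lr_min) * (
        1.0 + np.cos(np.pi * rem / T_i))


class LrSweepError(RuntimeError):
    def __init__(self, msg: str, curve: list[tuple[float, float]]):
        super().__init__(msg)
        self.curve = curve


def find_lr_range(
    step_fn,
    n_steps: int,
    lr_lo: float = 1e-6,
    lr_hi: float = 1.0,
    smooth: float = 0.05,
    divergence_factor: float = 4.0,
) -> tuple[float, float, list[tuple[float, float]]]:
    """Advisory learning-rate range finder (exponential sweep).

    ``step_fn(lr)`` performs one optimization step at the given rate
    and returns the batch loss.  The rate sweeps log-uniformly from
    ``lr_lo`` to ``lr_hi``; the smoothed-loss curve's steepest descent
    point is returned as the lr_max candidate with 1/100 of it as the
    lr_min candidate.  Purely advisory — protocol defaults stay at
    1e-3/1e-5.
    """
    if n_steps < 50:
        raise ValueError("learning-rate sweep needs at least 50 steps")
    lrs = np.geomspace(lr_lo, lr_hi, n_steps)
    curve: list[tuple[float, float]] = []
    ema = None
    best = np.inf
    for lr in lrs:
        loss = float(step_fn(float(lr)))
        if not np.isfinite(loss):
            raise LrSweepError(f"loss diverged at lr={lr:g}", curve)
        ema = loss if ema is None else smooth * loss + (1 - smooth) * ema
        curve.append((float(lr), ema))
        best = min(best, ema)
        if ema > divergence_factor * best and len(curve) > 10:
            break
    losses = np.array([c[1] for c in curve])
    swept = np.array([c[0] for c in curve])
    if len(curve) < 3 or np.ptp(losses) < 1e-12:
        raise LrSweepError("loss curve flat; sweep uninformative", curve)
    slopes = np.gradient(losses, np.log(swept))
    lr_max = float(swept[int(np.argmin(slopes))])
    return lr_max / 100.0, lr_max, curve


# ---------------------------------------------------------------------------
# Loss, single-fold training, cross-validation
# ---------------------------------------------------------------------------


def masked_cross_entropy(probs: np.ndarray, labels: np.ndarray,
                         mask: np.ndarray) -> float:
    """Mean categorical cross-entropy over non-padded epoch positions."""
    p = np.take_along_axis(probs, labels[..., None], axis=-1)[..., 0]
    p = np.clip(p, 1e-12, None)
    return float(-(np.log(p) * mask).sum() / mask.sum())


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0

    def to_csv(self, path: str | Path) -> None:
        lines = ["epoch,train_loss,val_loss,learning_rate"]
        for i, (tr, vl, lr) in enumerate(zip(
                self.train_loss, self.val_loss, self.learning_rate)):
            lines.append(f"{i},{tr:.6f},{vl:.6f},{lr:.8f}")
        Path(path).write_text("\n".join(lines) + "\n")


class TrainingDivergedError(RuntimeError):
    def __init__(self, msg: str, history: TrainingHistory):
        super().__init__(msg)
        self.history = history


def _forward_loss_grad(model: SleepStager, xb, yb, mb, rng):
    probs = model.forward(xb, training=True, rng=rng)
    onehot = np.eye(N_STAGES, dtype=probs.dtype)[yb]
    nvalid = mb.sum()
    dlogits = (probs - onehot) * mb[..., None] / nvalid
    loss = masked_cross_entropy(probs, yb, mb)
    return loss, dlogits.astype(probs.dtype)


def evaluate_loss(model: SleepStager, x, y, mask, batch_size: int = 8) -> float:
    total, weight = 0.0, 0
    for i in range(0, len(x), batch_size):
        probs = model.forward(x[i:i + batch_size], training=False)
        m = mask[i:i + batch_size]
        total += masked_cross_entropy(probs, y[i:i + batch_size], m) * m.sum()
        weight += m.sum()
    return total / max(weight, 1)


def train_fold(
    model: SleepStager,
    train_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: TrainingConfig,
) -> tuple[SleepStager, TrainingHistory]:
    """Minimize masked cross-entropy with Adam under the warm-restart
    schedule; early-stop on validation loss; restore best weights.

    One "training epoch" is one pass over the shuffled training
    windows; the learning rate is constant within a training epoch,
    following ``lr_at``.
    """
    xt, yt, mt = train_data
    xv, yv, mv = val_data
    if len(xt) == 0 or len(xv) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = model.make_optimizer()
    hist = TrainingHistory()
    best_val = np.inf
    best_weights = model.get_weights()
    for epoch in range(config.max_epochs):
        lr = lr_at(epoch, config)
        order = rng.permutation(len(xt))
        losses = []
        for i in range(0, len(order), config.batch_size):
            sel = order[i:i + config.batch_size]
            loss, dlogits = _forward_loss_grad(
                model, xt[sel], yt[sel], mt[sel], rng)
            if not np.isfinite(loss):
                hist.stopped_epoch = epoch + 1
                raise TrainingDivergedError(
                    f"NaN/inf loss at training epoch {epoch}", hist)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step(lr)
            losses.append(loss)
        val_loss = evaluate_loss(model, xv, yv, mv, config.batch_size)
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(float(val_loss))
        hist.learning_rate.append(float(lr))
        logger.info("epoch %d: train=%.4f val=%.4f lr=%.2e",
                    epoch, hist.train_loss[-1], val_loss, lr)
        if val_loss < best_val:
            best_val = val_loss
            hist.best_epoch = epoch
            best_weights = model.get_weights()
        elif epoch - hist.best_epoch >= config.patience:
            break
    hist.stopped_epoch = len(hist.val_loss)
    model.set_weights(best_weights)
    return model, hist


@dataclass
class CrossValidationResult:
    """Aggregated test-set predictions and reports across all folds."""

    plan: FoldPlan
    predictions: dict[str, Hypnogram]           # per recording, test-time
    references: dict[str, Hypnogram]
    pooled_confusion: ConfusionMatrix
    pooled_report: MetricsReport
    per_fold_reports: list[MetricsReport]
    per_recording: dict[str, dict]              # accuracy / kappa per recording
    group_reports: dict[str, MetricsReport]
    histories: list[TrainingHistory]


def run_cross_validation(
    cohort: list[tuple[np.ndarray, Hypnogram, dict]],
    model_config: ModelConfig,
    training_config: TrainingConfig,
    k: int = 10,
    ids: list[str] | None = None,
    plan: FoldPlan | None = None,
) -> CrossValidationResult:
    """k-fold cross-validation over preprocessed recordings.

    ``cohort`` holds ``(epochs, hypnogram, metadata)`` triples with
    ``epochs`` of shape (n, n_channels, samples_per_epoch), already at
    the working sampling rate.  Each recording is scored exactly once,
    by the fold in which it is a test recording; the pooled confusion
    matrix is the sum over folds.
    """
    if ids is None:
        ids = [meta.get("id", f"rec{i:03d}") for i, (_, _, meta) in enumerate(cohort)]
    by_id = {rid: item for rid, item in zip(ids, cohort)}
    if plan is None:
        plan = split_folds(ids, k=k, seed=training_config.seed)
    else:
        plan.validate(ids)
    seq_len = training_config.seq_len

    def windows(rec_ids, overlap):
        xs, ys, ms = [], [], []
        for rid in rec_ids:
            ep, hyp, _ = by_id[rid]
            x, y, m = make_sequences(ep, hyp.codes, seq_len, overlap)
            xs.append(x)
            ys.append(y)
            ms.append(m)
        return (np.concatenate(xs), np.concatenate(ys), np.concatenate(ms))

    predictions: dict[str, Hypnogram] = {}
    references: dict[str, Hypnogram] = {}
    per_fold_reports = []
    histories = []
    pooled: ConfusionMatrix | None = None
    for fi, fold in enumerate(plan.folds):
        try:
            model = SleepStager(model_config,
                                seed=training_config.seed + 1000 * fi)
            train = windows(fold["train"], training_config.train_overlap)
            val = windows(fold["val"], 0.0)
            model, hist = train_fold(model, train, val, training_config)
            histories.append(hist)
            fold_cm = None
            for rid in fold["test"]:
                ep, hyp, _ = by_id[rid]
                pred = predict_hypnogram(model, ep,
                                         batch_size=training_config.batch_size,
                                         source_id=f"auto-fold{fi}")
                predictions[rid] = pred
                references[rid] = hyp
                cm = confusion(hyp, pred)
                fold_cm = cm if fold_cm is None else fold_cm + cm
            per_fold_reports.append(evaluate(fold_cm))
            pooled = fold_cm if pooled is None else pooled + fold_cm
            logger.info("fold %d: test acc=%.3f kappa=%.3f", fi,
                        per_fold_reports[-1].accuracy, per_fold_reports[-1].kappa)
        except (TrainingDivergedError, ValueError) as e:
            raise RuntimeError(f"fold {fi} failed: {e}") from e

    per_recording = {}
    for rid in ids:
        cm = confusion(references[rid], predictions[rid])
        try:
            kap = cohens_kappa(cm)
        except ValueError:
            kap = float("nan")
        per_recording[rid] = {"accuracy": accuracy(cm), "kappa": kap,
                              "n_epochs": cm.total}
    metadata = {rid: by_id[rid][2] for rid in ids}
    group_reports = groupwise_evaluate(
        {rid: confusion(references[rid], predictions[rid]) for rid in ids},
        metadata)
    return CrossValidationResult(
        plan=plan,
        predictions=predictions,
        references=references,
        pooled_confusion=pooled,
        pooled_report=evaluate(pooled),
        per_fold_reports=per_fold_reports,
        per_recording=per_recording,
        group_reports=group_reports,
        histories=histories,
    )
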