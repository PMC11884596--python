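"""Training loops, transfer-learning strategies, distillation and metrics.

Training follows the validated recipe: AdamW, binary cross entropy,
dropout-regularized classifier, five-fold cross-validation on the training
split with early stopping on validation AUROC, and final reporting on the
held-out test split.  The regulatory-type task (does phosphorylation induce
or inhibit enzyme activity?) is small, so four strategies are provided:
training from scratch, multi-task training with a joint loss (the sum of
the two per-task cross entropies), transferring every non-classifier
parameter, and transferring the entire model before fine-tuning.

A sequence-only student MLP can be distilled from a trained teacher: it
sees nothing but sequence-embedding query tokens and is fitted to the
teacher's output probabilities, trading the structure branch away for
deployment convenience.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import average_precision_score, roc_auc_score

from .autodiff import AdamW, Tensor
from .curation import SplitAssignment
from .model import (
    CLASSIFIER_PREFIX,
    FusionConfig,
    Sample,
    bce_loss,
    clone_params,
    forward,
    init_params,
)

logger = logging.getLogger(__name__)

TRANSFER_MODES = ("scratch", "multitask", "transfer_embed_only", "transfer_all")
REG_HEAD_PREFIX = "reg_head."

PLDDT_BIN_EDGES = (30.0, 50.0, 70.0, 90.0)
PLDDT_BIN_NAMES = (
    "pLDDT < 30",
    "30 < pLDDT < 50",
    "50 < pLDDT < 70",
    "70 < pLDDT < 90",
    "pLDDT > 90",
)


@dataclass
class TrainConfig:
    batch_size: int = 128
    learning_rate: float = 1e-4
    epochs: int = 50
    early_stopping_patience: int = 5
    weight_decay: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs, self.early_stopping_patience) < 1:
            raise ValueError("batch_size, epochs and patience must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    auroc: float | None
    aupr: float | None
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc, "aupr": self.aupr, "accuracy": self.accuracy,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "mcc": self.mcc,
            "counts": vars(self.counts),
        }


def confusion_counts(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Counts at the strictly-greater decision threshold."""
    labels = np.asarray(labels, int)
    pred = (np.asarray(scores, float) > threshold).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (labels == 1))),
        tn=int(np.sum((pred == 0) & (labels == 0))),
        fp=int(np.sum((pred == 1) & (labels == 0))),
        fn=int(np.sum((pred == 0) & (labels == 1))),
    )


def compute_metrics(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """The seven-classification-metric report.

    Accuracy, precision, recall, F1 and MCC come straight from the
    confusion counts; ratios with zero denominators are defined as 0
    (standard convention).  AUROC/AUPR need both classes; with a
    single-class label vector they are reported as None with a warning.
    """
    labels = np.asarray(labels, int)
    scores = np.asarray(scores, float)
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    c = confusion_counts(labels, scores, threshold)
    accuracy = (c.tp + c.tn) / c.total if c.total else 0.0
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    denom = np.sqrt(
        float(c.tp + c.fn) * (c.tn + c.fp) * (c.tp + c.fp) * (c.tn + c.fn)
    )
    mcc = ((c.tp * c.tn - c.fp * c.fn) / denom) if denom else 0.0
    if len(np.unique(labels)) < 2:
        warnings.warn("single-class labels: AUROC/AUPR undefined", stacklevel=2)
        auroc = aupr = None
    else:
        auroc = float(roc_auc_score(labels, scores))
        aupr = float(average_precision_score(labels, scores))
    return MetricsReport(auroc, aupr, accuracy, precision, recall, f1, float(mcc), c)


def stratified_plddt_eval(
    labels: np.ndarray,
    scores: np.ndarray,
    plddt_values: np.ndarray,
    edges: tuple[float, ...] = PLDDT_BIN_EDGES,
) -> dict[str, float | None]:
    """Recall within pLDDT strata; bins are half-open [lower, upper).

    Bins with no positive sites are reported as None.
    """
    labels = np.asarray(labels, int)
    scores = np.asarray(scores, float)
    plddt = np.asarray(plddt_values, float)
    bin_idx = np.digitize(plddt, edges, right=False)
    names = PLDDT_BIN_NAMES if edges == PLDDT_BIN_EDGES else tuple(
        f"bin{i}" for i in range(len(edges) + 1)
    )
    out: dict[str, float | None] = {}
    for b, name in enumerate(names):
        mask = bin_idx == b
        pos = labels[mask] == 1
        if not pos.any():
            out[name] = None
            continue
        # recall only needs the positives; AUROC may be undefined in a bin
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            out[name] = compute_metrics(labels[mask], scores[mask]).recall
    return out


def spearman_score_plddt(
    scores: np.ndarray, plddt_values: np.ndarray
) -> float | None:
    """Spearman rank correlation with average-rank tie handling."""
    scores = np.asarray(scores, float)
    plddt = np.asarray(plddt_values, float)
    if len(scores) < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(scores == scores[0]) or np.all(plddt == plddt[0]):
        warnings.warn("constant input: Spearman undefined", stacklevel=2)
        return None
    return float(spearmanr(scores, plddt).statistic)


# ---------------------------------------------------------------------------
# core training loop
# ---------------------------------------------------------------------------

def predict_scores(
    samples: list[Sample],
    indices: np.ndarray,
    params: dict[str, Tensor],
    config: FusionConfig,
    head: str = CLASSIFIER_PREFIX,
) -> np.ndarray:
    """Eval-mode probabilities for a subset of samples."""
    return np.array(
        [float(forward(samples[i], params, config, head=head).data[0]) for i in indices]
    )


@dataclass
class TrainHistory:
    epoch_loss: list[float] = field(default_factory=list)
    val_auroc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False


def _batch_step(
    batch: list[Sample],
    params: dict[str, Tensor],
    optimizer: AdamW,
    config: FusionConfig,
    rng: np.random.Generator,
    head: str = CLASSIFIER_PREFIX,
    targets: np.ndarray | None = None,
    extra: tuple[list[Sample], str, np.ndarray] | None = None,
) -> float:
    """One optimizer step on a minibatch; returns the batch loss.

    ``targets`` overrides the samples' own labels (used for distillation
    soft targets); ``extra`` carries a second-task batch for multi-task
    training, whose loss is added to the first.
    """
    optimizer.zero_grad()
    total = 0.0
    scale = 1.0 / len(batch)
    for i, sample in enumerate(batch):
        y = sample.label if targets is None else targets[i]
        prob = forward(sample, params, config, train=True, rng=rng, head=head)
        loss = bce_loss(y, prob)
        total += float(loss.data) * scale
        loss.backward(scale)
    if extra is not None:
        extra_batch, extra_head, extra_targets = extra
        scale2 = 1.0 / len(extra_batch)
        for i, sample in enumerate(extra_batch):
            y = sample.label if extra_targets is None else extra_targets[i]
            prob = forward(sample, params, config, train=True, rng=rng, head=extra_head)
            loss = bce_loss(y, prob)
            total += float(loss.data) * scale2
            loss.backward(scale2)
    optimizer.step()
    return total


def train_model(
    samples: list[Sample],
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    fusion_config: FusionConfig,
    train_config: TrainConfig,
    params: dict[str, Tensor] | None = None,
    head: str = CLASSIFIER_PREFIX,
    restore_best: bool = True,
) -> tuple[dict[str, Tensor], TrainHistory]:
    """Fit on ``train_idx`` with early stopping on validation AUROC.

    The returned parameters are those of the best validation epoch, never a
    later, worse one.  ``restore_best=False`` disables both early stopping
    and best-epoch restoration and returns the final-epoch parameters —
    the right protocol when the validation signal is meaningless by design
    (the label-shuffle control), where selecting a "best" epoch on noise
    would resurrect the transient, partially initialized model.
    """
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("empty training or validation fold")
    params = params if params is not None else init_params(fusion_config)
    optimizer = AdamW(
        params,
        lr=train_config.learning_rate,
        weight_decay=train_config.weight_decay,
    )
    rng = np.random.default_rng([train_config.seed, 77])
    history = TrainHistory()
    best = (-np.inf, None)
    stale = 0
    val_labels = np.array([samples[i].label for i in val_idx])
    for epoch in range(train_config.epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), train_config.batch_size):
            batch = [samples[i] for i in order[start : start + train_config.batch_size]]
            epoch_loss += _batch_step(batch, params, optimizer, fusion_config, rng, head)
            n_batches += 1
        history.epoch_loss.append(epoch_loss / max(n_batches, 1))
        val_scores = predict_scores(samples, val_idx, params, fusion_config, head)
        report = compute_metrics(val_labels, val_scores)
        auroc = report.auroc if report.auroc is not None else 0.0
        history.val_auroc.append(auroc)
        logger.debug("epoch %d loss %.4f val AUROC %.4f", epoch, history.epoch_loss[-1], auroc)
        if auroc > best[0]:
            best = (auroc, clone_params(params) if restore_best else None)
            history.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if restore_best and stale >= train_config.early_stopping_patience:
                history.stopped_early = True
                break
    if not restore_best:
        return params, history
    assert best[1] is not None
    return best[1], history


@dataclass
class FoldResult:
    fold: int
    params: dict[str, Tensor]
    history: TrainHistory
    val_auroc: float
    test_metrics: MetricsReport


def train_cv(
    samples: list[Sample],
    assignment: SplitAssignment,
    fusion_config: FusionConfig,
    train_config: TrainConfig,
    n_folds: int = 5,
) -> list[FoldResult]:
    """Five-fold cross-validation; each fold reports on the held-out test set."""
    test_idx = assignment.test_indices
    test_labels = np.array([samples[i].label for i in test_idx])
    results: list[FoldResult] = []
    for fold in range(n_folds):
        params, history = train_model(
            samples,
            assignment.train_fold(fold),
            assignment.val_fold(fold),
            fusion_config,
            train_config,
        )
        scores = predict_scores(samples, test_idx, params, fusion_config)
        results.append(
            FoldResult(
                fold=fold,
                params=params,
                history=history,
                val_auroc=max(history.val_auroc),
                test_metrics=compute_metrics(test_labels, scores),
            )
        )
    return results


def best_fold(results: list[FoldResult]) -> FoldResult:
    return max(results, key=lambda r: r.val_auroc)


def mean_test_auroc(results: list[FoldResult]) -> float:
    return float(np.mean([r.test_metrics.auroc for r in results]))


# ---------------------------------------------------------------------------
# transfer learning
# ---------------------------------------------------------------------------

def transfer_init(
    teacher_params: dict[str, Tensor],
    fusion_config: FusionConfig,
    mode: str,
    seed: int = 1,
) -> dict[str, Tensor]:
    """Initial parameters for the regulatory-type model under one strategy.

    ``transfer_all`` copies every teacher tensor; ``transfer_embed_only``
    copies everything except the classifier, which is freshly initialized;
    ``scratch`` ignores the teacher entirely.
    """
    if mode not in ("scratch", "transfer_embed_only", "transfer_all"):
        raise ValueError(f"bad transfer mode {mode!r}")
    fresh = init_params(
        FusionConfig(**{**vars(fusion_config), "seed": seed})
    )
    if mode == "scratch":
        return fresh
    out = clone_params(teacher_params)
    if mode == "transfer_embed_only":
        for key in list(out):
            if key.startswith(CLASSIFIER_PREFIX):
                out[key] = fresh[key]
    for key, tensor in out.items():
        if tensor.data.shape != teacher_params[key].data.shape:
            raise ValueError(f"incompatible shape for {key}")
    return out


def finetune(
    teacher_params: dict[str, Tensor],
    fusion_config: FusionConfig,
    enzyme_samples: list[Sample],
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    mode: str,
    train_config: TrainConfig,
    main_samples: list[Sample] | None = None,
    main_train_idx: np.ndarray | None = None,
) -> tuple[dict[str, Tensor], TrainHistory]:
    """Fit the regulatory-type model (positive class = induced).

    ``multitask`` optimizes the joint loss — the sum of the functional-task
    and regulatory-task cross entropies — with a second classifier head on
    the shared trunk, and requires ``main_samples``/``main_train_idx``.
    """
    if mode not in TRANSFER_MODES:
        raise ValueError(f"bad transfer mode {mode!r}")
    if mode == "multitask":
        if main_samples is None or main_train_idx is None:
            raise ValueError("multitask needs the functional-task samples")
        return _train_multitask(
            enzyme_samples, train_idx, val_idx, main_samples, main_train_idx,
            fusion_config, train_config,
        )
    params = transfer_init(teacher_params, fusion_config, mode, seed=train_config.seed + 1)
    return train_model(
        enzyme_samples, train_idx, val_idx, fusion_config, train_config, params=params
    )


def _train_multitask(
    enzyme_samples: list[Sample],
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    main_samples: list[Sample],
    main_train_idx: np.ndarray,
    fusion_config: FusionConfig,
    train_config: TrainConfig,
) -> tuple[dict[str, Tensor], TrainHistory]:
    params = init_params(fusion_config)
    # second head for the regulatory task, same widths as the main classifier
    fresh = init_params(
        FusionConfig(**{**vars(fusion_config), "seed": fusion_config.seed + 101})
    )
    for key in list(fresh):
        if key.startswith(CLASSIFIER_PREFIX):
            params[REG_HEAD_PREFIX + key[len(CLASSIFIER_PREFIX):]] = fresh[key]
    optimizer = AdamW(
        params, lr=train_config.learning_rate, weight_decay=train_config.weight_decay
    )
    rng = np.random.default_rng([train_config.seed, 78])
    history = TrainHistory()
    best = (-np.inf, None)
    stale = 0
    val_labels = np.array([enzyme_samples[i].label for i in val_idx])
    for epoch in range(train_config.epochs):
        order = rng.permutation(train_idx)
        main_order = rng.permutation(main_train_idx)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), train_config.batch_size):
            batch = [enzyme_samples[i] for i in order[start : start + train_config.batch_size]]
            # cycle through the (larger) functional-task set
            mstart = (start * len(main_order) // max(len(order), 1)) % len(main_order)
            midx = [
                main_order[(mstart + k) % len(main_order)]
                for k in range(train_config.batch_size)
            ]
            main_batch = [main_samples[i] for i in midx]
            epoch_loss += _batch_step(
                main_batch, params, optimizer, fusion_config, rng,
                head=CLASSIFIER_PREFIX,
                extra=(batch, REG_HEAD_PREFIX, None),
            )
            n_batches += 1
        history.epoch_loss.append(epoch_loss / max(n_batches, 1))
        scores = predict_scores(
            enzyme_samples, val_idx, params, fusion_config, head=REG_HEAD_PREFIX
        )
        report = compute_metrics(val_labels, scores)
        auroc = report.auroc if report.auroc is not None else 0.0
        history.val_auroc.append(auroc)
        if auroc > best[0]:
            best = (auroc, clone_params(params))
            history.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= train_config.early_stopping_patience:
                history.stopped_early = True
                break
    assert best[1] is not None
    # expose the regulatory head under the standard classifier name
    final = best[1]
    for key in list(final):
        if key.startswith(REG_HEAD_PREFIX):
            final[CLASSIFIER_PREFIX + key[len(REG_HEAD_PREFIX):]] = final[key]
    return final, history


def multitask_joint_loss(
    main_batch: list[Sample],
    enzyme_batch: list[Sample],
    params: dict[str, Tensor],
    config: FusionConfig,
) -> tuple[float, float, float]:
    """(joint, main, enzyme) eval-mode losses on a fixed batch pair.

    The joint loss is by definition the sum of the two per-task BCE losses;
    this helper recomputes each independently so tests can assert it.
    """
    def task_loss(batch: list[Sample], head: str) -> float:
        losses = [
            float(bce_loss(s.label, forward(s, params, config, head=head)).data)
            for s in batch
        ]
        return float(np.mean(losses))

    main = task_loss(main_batch, CLASSIFIER_PREFIX)
    enzyme = task_loss(enzyme_batch, REG_HEAD_PREFIX)
    return main + enzyme, main, enzyme


# ---------------------------------------------------------------------------
# knowledge distillation
# ---------------------------------------------------------------------------

def init_student(
    input_dim: int, widths: tuple[int, ...] = (256, 256, 512), seed: int = 0
) -> dict[str, Tensor]:
    """A plain three-hidden-layer MLP over flattened sequence-query tokens."""
    rng = np.random.default_rng(seed)
    params: dict[str, Tensor] = {}
    dims = (input_dim, *widths, 1)
    for layer, (d_in, d_out) in enumerate(zip(dims[:-1], dims[1:])):
        if layer == len(dims) - 2:
            # zero output layer: a fresh student predicts exactly 0.5
            w = np.zeros((d_in, d_out))
        else:
            w = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
        params[f"mlp{layer}.w"] = Tensor(w, requires_grad=True)
        params[f"mlp{layer}.b"] = Tensor(np.zeros(d_out), requires_grad=True)
    return params


def student_forward(x: np.ndarray, params: dict[str, Tensor]) -> Tensor:
    """Batch probabilities from the student MLP; ``x`` is (n, input_dim)."""
    h = Tensor(np.atleast_2d(x))
    n_layers = len(params) // 2
    for layer in range(n_layers):
        h = h @ params[f"mlp{layer}.w"] + params[f"mlp{layer}.b"]
        if layer < n_layers - 1:
            h = h.relu()
    return h.reshape(-1).sigmoid()


def distill_student(
    teacher_scores: np.ndarray,
    student_inputs: np.ndarray,
    widths: tuple[int, ...] = (256, 256, 512),
    train_config: TrainConfig | None = None,
) -> dict[str, Tensor]:
    """Fit the student to the teacher's soft probabilities.

    ``student_inputs`` must be built from sequence embeddings only — the
    whole point of the student is that it never sees a structure graph.
    """
    train_config = train_config or TrainConfig()
    teacher_scores = np.asarray(teacher_scores, float)
    student_inputs = np.asarray(student_inputs, float)
    if len(teacher_scores) != len(student_inputs):
        raise ValueError("inputs and soft targets differ in length")
    params = init_student(student_inputs.shape[1], widths, seed=train_config.seed)
    optimizer = AdamW(
        params, lr=train_config.learning_rate, weight_decay=train_config.weight_decay
    )
    rng = np.random.default_rng([train_config.seed, 79])
    n = len(student_inputs)
    for _epoch in range(train_config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            optimizer.zero_grad()
            probs = student_forward(student_inputs[idx], params)
            loss = bce_loss(teacher_scores[idx], probs)
            loss.backward()
            optimizer.step()
    return params


def student_predict(x: np.ndarray, params: dict[str, Tensor]) -> np.ndarray:
    return student_forward(x, params).data
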