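"""Cross-validated training and the five-metric evaluation.

Subjects are split into stratified k folds (default 10).  One model is
trained per fold with Adam on the softmax cross-entropy and evaluated on the
held-out subjects; accuracy, precision, recall, specificity and F1 are
reported per fold and as mean +/- SD across folds.  The case class (label 1)
is the positive class throughout.  Each fold's trained model is retained
together with its per-layer node-gate matrices, computed in inference mode
on that fold's training subjects and separated by diagnostic group, which
the saliency module consolidates into salient-ROI sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .graphs import BrainGraph
from .nn import Adam, GinClassifier, ModelConfig, ModelState
from .saliency import NodeWeightRecord, node_weight_from_gates

logger = logging.getLogger("connectogin")


@dataclass
class TrainConfig:
    learning_rate: float = 0.005
    n_epochs: int = 200
    batch_size: int = 32
    n_folds: int = 10
    seed: int = 0
    weight_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray
                         ) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclass
class FoldMetrics:
    """Single-fold metrics, as percentages in [0, 100].

    A ratio with a zero denominator is reported as 0 and its name listed in
    ``undefined`` rather than propagating NaN.
    """

    acc: float
    pre: float
    rec: float
    spe: float
    f1: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {"acc": self.acc, "pre": self.pre, "rec": self.rec,
                "spe": self.spe, "f1": self.f1}


METRIC_NAMES = ("acc", "pre", "rec", "spe", "f1")


@dataclass
class MetricsReport:
    """Per-fold metric vectors with their across-fold mean and SD."""

    per_fold: list[FoldMetrics]

    def values(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.per_fold])

    def mean(self, name: str) -> float:
        return float(self.values(name).mean())

    def sd(self, name: str) -> float:
        return float(self.values(name).std(ddof=1)) if len(self.per_fold) > 1 else 0.0

    def summary(self) -> dict[str, dict[str, float]]:
        return {name: {"mean": self.mean(name), "sd": self.sd(name)}
                for name in METRIC_NAMES}


def compute_metrics(c: ConfusionCounts) -> FoldMetrics:
    """Accuracy, precision, recall, specificity and F1 from confusion counts."""
    if c.total <= 0:
        raise ValueError("confusion counts are empty")
    undefined = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = (c.tp + c.tn) / c.total
    pre = ratio(c.tp, c.tp + c.fp, "pre")
    rec = ratio(c.tp, c.tp + c.fn, "rec")
    spe = ratio(c.tn, c.tn + c.fp, "spe")
    if pre + rec == 0:
        undefined.append("f1")
        f1 = 0.0
    else:
        f1 = 2.0 * pre * rec / (pre + rec)
    return FoldMetrics(acc=100 * acc, pre=100 * pre, rec=100 * rec,
                       spe=100 * spe, f1=100 * f1, undefined=tuple(undefined))


def stratified_kfold_split(labels, n_folds: int, seed: int
                           ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified folds preserving the class ratio per fold."""
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present")
    if n_folds > counts.min():
        raise ValueError(
            f"n_folds={n_folds} exceeds minority-class count {counts.min()}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr.copy(), te.copy())
            for tr, te in skf.split(np.zeros_like(labels), labels)]


def _adjacency_stack(graphs: list[BrainGraph], dtype) -> np.ndarray:
    n = graphs[0].n_nodes
    adj = np.empty((len(graphs), n, n), dtype=dtype)
    for i, g in enumerate(graphs):
        if g.n_nodes != n:
            raise ValueError("all graphs in a cohort must share the node count")
        adj[i] = g.adjacency(dtype=dtype)
    return adj


def train_fold(
    graphs: list[BrainGraph],
    train_idx: np.ndarray,
    config: TrainConfig,
    model_config: ModelConfig,
    fold_seed: int | None = None,
    adj: np.ndarray | None = None,
) -> tuple[GinClassifier, list[float]]:
    """Train one model on the given subjects; returns (model, loss trace)."""
    train_idx = np.asarray(train_idx, dtype=int)
    labels = np.array([graphs[i].label for i in train_idx], dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    if adj is None:
        adj = _adjacency_stack(graphs, model_config.np_dtype)
    seed = config.seed if fold_seed is None else fold_seed
    init_seed = int(np.random.SeedSequence([seed, 7]).generate_state(1)[0] % (2**31))
    model = GinClassifier(model_config, seed=init_seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    opt = Adam(model.state.params, lr=config.learning_rate,
               weight_decay=config.weight_decay)
    trace: list[float] = []
    for epoch in range(config.n_epochs):
        order = rng.permutation(train_idx.size)
        epoch_loss = 0.0
        for start in range(0, train_idx.size, config.batch_size):
            batch = train_idx[order[start:start + config.batch_size]]
            loss, grads = model.loss_and_grad(
                adj[batch], np.array([graphs[i].label for i in batch]), rng=rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch start {start}; "
                    f"lr={config.learning_rate}")
            if config.learning_rate > 0:
                opt.step(grads)
            epoch_loss += loss * batch.size
        trace.append(epoch_loss / train_idx.size)
    return model, trace


def _batched_forward(model: GinClassifier, adj: np.ndarray, batch_size: int):
    logits = []
    gates = None
    for start in range(0, adj.shape[0], batch_size):
        lg, gt, _ = model.forward(adj[start:start + batch_size], training=False)
        logits.append(lg)
        if gates is None:
            gates = [[g] for g in gt]
        else:
            for acc, g in zip(gates, gt):
                acc.append(g)
    return np.concatenate(logits), [np.concatenate(g) for g in gates]


@dataclass
class CVResult:
    report: MetricsReport
    confusions: list[ConfusionCounts]
    fold_states: list[ModelState]
    gate_records: list[NodeWeightRecord]
    splits: list[tuple[np.ndarray, np.ndarray]]
    loss_traces: list[list[float]] = field(default_factory=list)


def run_cv(graphs: list[BrainGraph], train_config: TrainConfig,
           model_config: ModelConfig) -> CVResult:
    """Stratified k-fold cross-validation of the GIN classifier.

    Graph construction happens upstream with global (label-blind) settings,
    so no learned state ever sees a held-out subject: each fold's model is
    fit on its training indices only and evaluated once on the held-out
    split.  Node-gate records for saliency are taken from the trained model
    applied to that fold's *training* subjects, split by diagnostic group.
    """
    labels = np.array([g.label for g in graphs], dtype=int)
    splits = stratified_kfold_split(labels, train_config.n_folds,
                                    train_config.seed)
    adj = _adjacency_stack(graphs, model_config.np_dtype)
    per_fold: list[FoldMetrics] = []
    confusions: list[ConfusionCounts] = []
    states: list[ModelState] = []
    records: list[NodeWeightRecord] = []
    traces: list[list[float]] = []
    for fold, (tr, te) in enumerate(splits):
        model, trace = train_fold(
            graphs, tr, train_config, model_config,
            fold_seed=train_config.seed * 1009 + fold, adj=adj)
        traces.append(trace)
        logits, _ = _batched_forward(model, adj[te], train_config.batch_size)
        pred = (logits[:, 1] > logits[:, 0]).astype(int)
        conf = ConfusionCounts.from_predictions(labels[te], pred)
        confusions.append(conf)
        fm = compute_metrics(conf)
        per_fold.append(fm)
        states.append(model.state)
        logger.info("fold %d/%d: acc=%.2f%% (TP=%d FP=%d TN=%d FN=%d)",
                    fold + 1, len(splits), fm.acc, conf.tp, conf.fp,
                    conf.tn, conf.fn)
        # gate records on training subjects, by group
        for group, lab in (("control", 0), ("case", 1)):
            members = tr[labels[tr] == lab]
            _, gates = _batched_forward(model, adj[members],
                                        train_config.batch_size)
            for k, gate_stack in enumerate(gates):
                records.append(NodeWeightRecord(
                    fold=fold + 1, layer=k + 1, group=group,
                    weights=node_weight_from_gates(gate_stack)))
    report = MetricsReport(per_fold=per_fold)
    logger.info("CV mean acc=%.2f%% +/- %.2f%%", report.mean("acc"),
                report.sd("acc"))
    return CVResult(report=report, confusions=confusions, fold_states=states,
                    gate_records=records, splits=splits, loss_traces=traces)
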