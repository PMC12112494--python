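"""Training loop, evaluation metrics and the multi-seed protocol.

Metrics follow the exact printed forms: AUC is the pairwise probability that
a positive outranks a negative (ties count one half), and AP is a
*trapezoidal* approximation of the precision-recall curve over the distinct
score thresholds — deliberately different from the step-wise average
precision in common toolkits.  The PR polyline is anchored at recall 0 with
the precision of the highest threshold, so a perfectly separated ranking
scores exactly 1.

The protocol trains once per seed with the train/valid partition reshuffled
per seed and the test set held fixed, reporting mean +/- std per metric in
percent, plus the per-pair inter-class attention weights of the test pairs
for heatmap-style inspection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from . import nn
from .decoder_model import LinkPredictor, ModelConfig, PairBatch
from .metapath import build_store, enumerate_common_types, enumerate_node_specific_types
from .schema import (
    EdgeSplit,
    HeteroGraph,
    build_training_graph,
    make_splits,
    resplit_train_valid,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _split_scores(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def auc(scores, labels) -> float:
    """Exact pairwise AUC: mean of I(s_i > t_j) + 0.5 I(s_i = t_j).

    Computed via average ranks, which is algebraically identical to the
    double loop (ties contribute one half).
    """
    pos, neg = _split_scores(scores, labels)
    ranks = rankdata(np.concatenate([pos, neg]), method="average")
    m = len(pos)
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * len(neg)))


def ap(scores, labels) -> float:
    """Trapezoidal area under the precision-recall polyline.

    Thresholds are the distinct scores in descending order; a sample is
    predicted positive when its score >= threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    _split_scores(scores, labels)  # validates both classes present
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    cum_tp = np.cumsum(y_sorted)
    n_pos = cum_tp[-1]
    # last index of each distinct descending score = the >= threshold cut
    is_last = np.ones(len(s_sorted), dtype=bool)
    is_last[:-1] = s_sorted[:-1] != s_sorted[1:]
    idx = np.flatnonzero(is_last)
    tp = cum_tp[idx].astype(np.float64)
    pred = (idx + 1).astype(np.float64)
    precision = tp / pred
    recall = tp / n_pos
    # anchor at recall 0 with the first threshold's precision
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0]], precision])
    return float(np.sum((recall[1:] - recall[:-1]) * (precision[1:] + precision[:-1]) / 2.0))


def confusion(scores, labels, threshold: float = 0.5) -> dict[str, int]:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pred = scores >= threshold
    actual = labels == 1
    return {
        "TP": int(np.sum(pred & actual)),
        "TN": int(np.sum(~pred & ~actual)),
        "FP": int(np.sum(pred & ~actual)),
        "FN": int(np.sum(~pred & actual)),
    }


def precision_recall_f1(scores, labels, threshold: float = 0.5) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); degenerate cases -> 0."""
    c = confusion(scores, labels, threshold)
    tp, fp, fn = c["TP"], c["FP"], c["FN"]
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision reported as 0", stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def evaluate(scores, labels, threshold: float = 0.5) -> dict:
    p, r, f1 = precision_recall_f1(scores, labels, threshold)
    return {
        "AUC": auc(scores, labels),
        "AP": ap(scores, labels),
        "precision": p,
        "recall": r,
        "F1": f1,
        "confusion": confusion(scores, labels, threshold),
    }


# ---------------------------------------------------------------------------
# configuration / report containers
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    lr: float = 5e-3
    weight_decay: float = 1e-4
    epochs: int = 200
    patience: int = 20
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    split_seed: int = 0
    ratios: tuple[float, float, float] = (0.75, 0.10, 0.15)
    threshold: float = 0.5
    cap: int = 32
    model: ModelConfig = field(default_factory=ModelConfig)
    resample_negatives: bool = False  # per-epoch negative resampling (off by default)
    max_common_len: int = 3
    log_every: int = 0

    def __post_init__(self):
        if not self.seeds:
            raise ValueError("at least one seed is required")
        if self.patience > self.epochs:
            raise ValueError("patience must not exceed epochs")


@dataclass
class MetricReport:
    """Mean +/- std (percent) per metric over seeds, plus per-seed detail."""

    mean: dict[str, float]
    std: dict[str, float]
    per_seed: list[dict]
    beta_export: list[dict]
    common_class_names: list[str]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: LinkPredictor
    log: list[dict]
    best_epoch: int
    best_valid_auc: float


def train(
    model: LinkPredictor,
    train_batch: PairBatch,
    valid_batch: PairBatch,
    config: TrainConfig,
    train_batch_factory=None,
) -> TrainResult:
    """BCE-with-logits training with early stopping on validation AUC.

    ``train_batch_factory(epoch)``, when given, replaces the training batch
    each epoch (used by the optional negative-resampling mode).
    """
    if len(train_batch.pairs) == 0:
        raise ValueError("empty training split")
    params = model.parameters()
    opt = nn.Adam(params, lr=config.lr, weight_decay=config.weight_decay)
    best = {"auc": -np.inf, "epoch": -1, "params": None}
    log: list[dict] = []
    stall = 0
    for epoch in range(config.epochs):
        if train_batch_factory is not None and epoch > 0:
            train_batch = train_batch_factory(epoch)
        opt.zero_grad()
        logits, _ = model.forward(train_batch)
        loss = nn.bce_with_logits(logits, train_batch.labels)
        loss.backward()
        opt.step()
        valid_scores = model.predict(valid_batch)
        val_auc = auc(valid_scores, valid_batch.labels)
        log.append({"epoch": epoch, "loss": float(loss.data), "valid_auc": val_auc})
        if config.log_every and epoch % config.log_every == 0:
            logger.info("epoch %d loss %.4f valid AUC %.4f", epoch, loss.data, val_auc)
        if val_auc > best["auc"]:
            best = {
                "auc": val_auc,
                "epoch": epoch,
                "params": [p.data.copy() for p in params],
            }
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    if best["params"] is not None:
        for p, data in zip(params, best["params"]):
            p.data = data
    return TrainResult(model=model, log=log, best_epoch=best["epoch"], best_valid_auc=best["auc"])


def _make_batches(
    model: LinkPredictor, store, split: EdgeSplit
) -> dict[str, PairBatch]:
    batches = {}
    for part in ("train", "valid", "test"):
        pairs, labels = split.pairs(part)
        batches[part] = model.prepare_batch(store, pairs, labels)
    return batches


def run_single(
    graph: HeteroGraph,
    split: EdgeSplit,
    config: TrainConfig,
    seed: int,
) -> tuple[dict, LinkPredictor, PairBatch]:
    """Train on one split instance and evaluate on its test set."""
    training_graph = build_training_graph(graph, split)
    node_types = enumerate_node_specific_types(graph.schema)
    common_types = enumerate_common_types(graph.schema, max_len=config.max_common_len)
    all_pairs = split.positives() + split.negatives()
    store = build_store(
        training_graph, node_types, common_types, all_pairs, cap=config.cap, seed=seed
    )
    model = LinkPredictor(training_graph, node_types, common_types, config.model, seed=seed)
    batches = _make_batches(model, store, split)
    factory = None
    if config.resample_negatives:
        pos_set = set(split.positives())
        held_neg = set(split.valid_neg) | set(split.test_neg)
        candidates = [
            (m, d)
            for m in range(graph.num_nodes("miRNA"))
            for d in range(graph.num_nodes("disease"))
            if (m, d) not in pos_set and (m, d) not in held_neg
        ]
        rng = np.random.default_rng(seed)

        def factory(epoch):
            idx = rng.choice(len(candidates), size=len(split.train_pos), replace=False)
            negs = sorted(candidates[i] for i in idx)
            pairs = split.train_pos + negs
            labels = np.array([1] * len(split.train_pos) + [0] * len(negs))
            neg_store = build_store(
                training_graph, (), common_types, negs, cap=config.cap, seed=seed
            )
            neg_store.data.update(store.data)
            return model.prepare_batch(neg_store, pairs, labels)

    result = train(model, batches["train"], batches["valid"], config, train_batch_factory=factory)
    test_scores = model.predict(batches["test"])
    metrics = evaluate(test_scores, batches["test"].labels, config.threshold)
    metrics["best_epoch"] = result.best_epoch
    metrics["valid_AUC"] = result.best_valid_auc
    return metrics, model, batches["test"]


def run_protocol(graph: HeteroGraph, config: TrainConfig) -> MetricReport:
    """Multi-seed protocol: fixed test set, per-seed train/valid reshuffle."""
    base_split = make_splits(graph, config.ratios, seed=config.split_seed)
    per_seed = []
    beta_export: list[dict] = []
    common_names: list[str] = []
    for seed in config.seeds:
        split = resplit_train_valid(base_split, seed)
        metrics, model, test_batch = run_single(graph, split, config, seed)
        metrics["seed"] = seed
        per_seed.append(metrics)
        logger.info(
            "seed %d: test AUC %.4f AP %.4f", seed, metrics["AUC"], metrics["AP"]
        )
        if model.config.use_link:
            _, diag = model.forward(test_batch)
            common_names = [t.name for t in model.common_types]
            for (m, d), label, beta in zip(
                test_batch.pairs, test_batch.labels, diag["beta_common"]
            ):
                beta_export.append(
                    {
                        "seed": seed,
                        "pair": f"{graph.nodes['miRNA'][m]}|{graph.nodes['disease'][d]}",
                        "label": int(label),
                        "beta": [float(b) for b in beta],
                    }
                )
    keys = ("AUC", "AP", "precision", "recall", "F1")
    mean = {k: float(np.mean([m[k] for m in per_seed]) * 100) for k in keys}
    std = {k: float(np.std([m[k] for m in per_seed]) * 100) for k in keys}
    return MetricReport(
        mean=mean, std=std, per_seed=per_seed, beta_export=beta_export,
        common_class_names=common_names,
    )


def write_beta_export(report: MetricReport, path) -> None:
    """TSV ``pair_id  label  beta_1 ... beta_M`` with a metapath-name header."""
    with open(path, "w", encoding="utf-8") as fh:
        header = ["pair_id", "label"] + report.common_class_names
        fh.write("\t".join(header) + "\n")
        for row in report.beta_export:
            fields = [row["pair"], str(row["label"])] + [f"{b:.6f}" for b in row["beta"]]
            fh.write("\t".join(fields) + "\n")
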