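"""Dataset-level training, repeated evaluation, and the ablation harness.

These functions drive :class:`~deeparc.estimator.DeepARCClassifier` over a
:class:`~deeparc.sequences.LabeledSequenceSet` with its fixed
train/test/validation splits: fit on the training split with per-epoch
checkpointing against the validation split, report metrics on the held-out
test split only. ``repeat_evaluate`` reruns the whole training with derived
seeds (the repeated-runs reading of "three cross-validation tests" over a
fixed split); a literal stratified k-fold is available behind ``kfold=True``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .estimator import DeepARCClassifier, derive_seed
from .metrics import METRIC_COLUMNS, MetricsReport, evaluate
from .network import ModelSpec
from .sequences import LabeledSequenceSet


@dataclasses.dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 0.001
    epochs: int = 20
    batch_size: int = 64
    n_repeats: int = 3
    seed: int = 0
    lr_step: int = 20
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError(f"only the adam optimizer is supported, got {self.optimizer!r}")
        for key in ("learning_rate", "epochs", "batch_size", "n_repeats", "lr_step"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key} must be positive")


@dataclasses.dataclass
class RunResult:
    """One training run: loss curves, held-out test metrics, and attention."""

    train_loss: list[float]
    val_loss: list[float]
    test_metrics: MetricsReport
    test_scores: np.ndarray
    test_ids: list[str]
    seed: int
    estimator: DeepARCClassifier
    attention_mean: np.ndarray | None = None  # averaged over positive test windows


def _check_splits(dataset: LabeledSequenceSet) -> None:
    ids = {s: set(dataset.subset(s).ids()) for s in ("train", "test", "validation")}
    for a in ids:
        for b in ids:
            if a < b and ids[a] & ids[b]:
                raise ValueError(f"record ids shared between {a} and {b} splits")
    for s in ("train", "test", "validation"):
        if not ids[s]:
            raise ValueError(f"dataset has no {s} split")


def _make_estimator(spec: ModelSpec, cfg: TrainConfig, seed: int,
                    embedding: str, **embed_kw) -> DeepARCClassifier:
    return DeepARCClassifier(
        architecture=spec.architecture, embedding=embedding,
        cnn_layers=spec.cnn_layers, kernel_size=spec.kernel_size,
        padding=spec.padding, stride=spec.stride, cnn_channels=spec.cnn_channels,
        bilstm_hidden=spec.bilstm_hidden, attention_dim=spec.attention_dim,
        dense_neurons=spec.dense_neurons, dropout=spec.dropout, merge=spec.merge,
        learning_rate=cfg.learning_rate, epochs=cfg.epochs,
        batch_size=cfg.batch_size, lr_step=cfg.lr_step, threshold=cfg.threshold,
        random_state=seed, **embed_kw)


def train(dataset: LabeledSequenceSet, spec: ModelSpec | None = None,
          cfg: TrainConfig | None = None, embedding: str = "positional",
          collect_attention: bool = True, **embed_kw) -> RunResult:
    """Train on the dataset's train split, checkpoint on validation loss,
    report metrics on the test split."""
    spec = spec or ModelSpec()
    cfg = cfg or TrainConfig()
    _check_splits(dataset)
    tr, te, va = (dataset.subset(s) for s in ("train", "test", "validation"))
    if len(np.unique(tr.labels())) < 2:
        raise ValueError("training split must contain both classes")

    est = _make_estimator(spec, cfg, cfg.seed, embedding, **embed_kw)
    est.fit(tr.sequences(), tr.labels(),
            validation_data=(va.sequences(), va.labels()))

    scores = est.predict_proba(te.sequences())[:, 1]
    report = evaluate(scores, te.labels(), cfg.threshold)
    attention_mean = None
    if collect_attention and spec.has_attention:
        pos = [r.sequence for r in te if r.label == 1]
        if pos:
            attention_mean = est.attention(pos).mean(axis=0)
    return RunResult(train_loss=est.history_["train_loss"],
                     val_loss=est.history_["val_loss"],
                     test_metrics=report, test_scores=scores, test_ids=te.ids(),
                     seed=cfg.seed, estimator=est, attention_mean=attention_mean)


def repeat_evaluate(dataset: LabeledSequenceSet, spec: ModelSpec | None = None,
                    cfg: TrainConfig | None = None, embedding: str = "positional",
                    kfold: bool = False, **embed_kw
                    ) -> tuple[pd.DataFrame, list[RunResult]]:
    """``n_repeats`` independent trainings with derived seeds; returns the
    mean and standard deviation of each metric plus the individual runs."""
    spec = spec or ModelSpec()
    cfg = cfg or TrainConfig()
    results: list[RunResult] = []
    if kfold:
        results = _kfold_runs(dataset, spec, cfg, embedding, **embed_kw)
    else:
        for rep in range(cfg.n_repeats):
            rep_cfg = dataclasses.replace(cfg, seed=derive_seed(cfg.seed, f"repeat{rep}"))
            results.append(train(dataset, spec, rep_cfg, embedding,
                                 collect_attention=False, **embed_kw))
    rows = [{"Sen": r.test_metrics.sen, "Spe": r.test_metrics.spe,
             "Acc": r.test_metrics.acc, "MCC": r.test_metrics.mcc,
             "AUC": r.test_metrics.auc} for r in results]
    frame = pd.DataFrame(rows)
    summary = pd.DataFrame({"mean": frame.mean(), "sd": frame.std(ddof=1 if len(frame) > 1 else 0)})
    return summary, results


def _kfold_runs(dataset, spec, cfg, embedding, **embed_kw) -> list["RunResult"]:
    """Literal stratified k-fold over all records (k = n_repeats)."""
    seqs = np.array(dataset.sequences(), dtype=object)
    y = dataset.labels()
    ids = np.array(dataset.ids(), dtype=object)
    skf = StratifiedKFold(n_splits=cfg.n_repeats, shuffle=True, random_state=cfg.seed % (2 ** 31))
    results = []
    for fold, (tr_idx, te_idx) in enumerate(skf.split(seqs, y)):
        seed = derive_seed(cfg.seed, f"fold{fold}")
        est = _make_estimator(spec, cfg, seed, embedding, **embed_kw)
        est.fit(list(seqs[tr_idx]), y[tr_idx])
        scores = est.predict_proba(list(seqs[te_idx]))[:, 1]
        results.append(RunResult(
            train_loss=est.history_["train_loss"], val_loss=est.history_["val_loss"],
            test_metrics=evaluate(scores, y[te_idx], cfg.threshold),
            test_scores=scores, test_ids=list(ids[te_idx]), seed=seed, estimator=est))
    return results


def ablation_grid(dataset: LabeledSequenceSet,
                  architectures: list[str] | list[ModelSpec],
                  embeddings: list[str],
                  cfg: TrainConfig | None = None,
                  out_tsv=None, **embed_kw) -> pd.DataFrame:
    """Run every (architecture, embedding) cell on identical splits and return
    a table with the standard Sen/Spe/Acc/MCC/AUC column layout."""
    cfg = cfg or TrainConfig()
    _check_splits(dataset)
    rows = []
    shared_test_ids: list[str] | None = None
    for arch in architectures:
        spec = arch if isinstance(arch, ModelSpec) else ModelSpec(architecture=arch)
        for emb in embeddings:
            result = train(dataset, spec, cfg, emb, collect_attention=False, **embed_kw)
            if shared_test_ids is None:
                shared_test_ids = result.test_ids
            elif result.test_ids != shared_test_ids:
                raise RuntimeError("ablation cells evaluated on different test ids")
            row = {"Model": spec.architecture, "Embedding": emb}
            row.update(result.test_metrics.as_row())
            rows.append(row)
    frame = pd.DataFrame(rows, columns=["Model", "Embedding", *METRIC_COLUMNS])
    if out_tsv is not None:
        frame.to_csv(out_tsv, sep="\t", index=False)
    return frame
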