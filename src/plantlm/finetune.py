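"""IA3 parameter-efficient fine-tuning and evaluation statistics.

Fine-tuning freezes the pre-trained backbone, injects all-ones multiplicative
rescaling vectors (attention keys/values and MLP intermediate activations),
replaces the language-model head with a task head on the mean-pooled final
hidden state, and updates only the rescaling vectors and head — roughly 1% of
model parameters at the published scale, and exactly the identity map before
any update.

Evaluation covers AUROC/AUPRC for classification, R^2 (squared Pearson
correlation, i.e. the coefficient of determination of a linear fit between
predicted and observed) for regression, and pairwise-tissue log-fold-change
correlation / sign-agreement for multi-tissue expression models.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .model import (Adam, InvalidConfigError, ParameterAccounting, TaskHeadSpec,
                    TransformerLM, parameter_accounting)
from .tokenizer import TokenSequence

logger = logging.getLogger(__name__)


class SplitLeakageError(ValueError):
    pass


class UndefinedMetricError(ValueError):
    pass


def attach_ia3(model: TransformerLM, head: TaskHeadSpec | None = None,
               unfreeze_last_k: int = 0, head_seed: int = 0) -> ParameterAccounting:
    """Add identity-initialized IA3 adapters (and optionally a task head).

    With all-ones adapters the model's outputs are bit-identical to the base
    model. Returns the symbolic accounting for the resulting tuning mode.
    """
    if unfreeze_last_k > model.config.num_layers:
        raise InvalidConfigError("unfreeze_last_k exceeds num_layers")
    model.attach_ia3()
    if head is not None:
        model.attach_head(head, seed=head_seed)
    mode = "ia3_unfreeze_last_k" if unfreeze_last_k else "ia3_frozen"
    return parameter_accounting(model.config, mode, head=head,
                                unfreeze_last_k=unfreeze_last_k)


@dataclass
class SupervisedExample:
    id: str
    tokens: TokenSequence
    target: np.ndarray | float
    split: str  # train | validation | test


@dataclass
class SupervisedDataset:
    examples: list[SupervisedExample]

    def split(self, name: str) -> list[SupervisedExample]:
        return [e for e in self.examples if e.split == name]

    def audit_splits(self) -> None:
        seen: dict[str, str] = {}
        for e in self.examples:
            if e.id in seen and seen[e.id] != e.split:
                raise SplitLeakageError(f"id {e.id!r} appears in {seen[e.id]} and {e.split}")
            seen[e.id] = e.split


def _batched(examples, batch_size):
    for i in range(0, len(examples), batch_size):
        yield examples[i:i + batch_size]


def _stack(batch):
    ids = np.stack([e.tokens.ids for e in batch])
    spec = np.stack([e.tokens.is_special for e in batch])
    targets = np.stack([np.atleast_1d(np.asarray(e.target, dtype=np.float64))
                        for e in batch])
    return ids, spec, targets


def predict_dataset(model: TransformerLM, examples: Sequence[SupervisedExample],
                    batch_size: int = 32) -> np.ndarray:
    outs = [model.predict(*_stack(b)[:2]) for b in _batched(list(examples), batch_size)]
    return np.concatenate(outs, axis=0)


def finetune(model: TransformerLM, dataset: SupervisedDataset, task: TaskHeadSpec,
             epochs: int = 10, seed: int = 0, lr: float = 3e-2,
             batch_size: int = 32, unfreeze_last_k: int = 0,
             patience: int | None = None, lr_decay: str = "none",
             em_rounds: int = 3) -> dict:
    """IA3 fine-tuning with a frozen backbone; returns validation/test metrics.

    The best-validation-loss parameter snapshot (trainable subset only) is
    restored at the end; ``patience`` enables early stopping on validation
    loss, and ``lr_decay='cosine'`` anneals the learning rate. With
    ``epochs=0`` the untrained head is evaluated as a baseline.

    For binary detection heads (``pooling='detection'``), gradient training
    of the multiple-instance objective is followed by ``em_rounds`` of
    EM-style hardening: the highest-scoring pair of each positive window is
    pseudo-labeled positive, all pairs of negative windows negative, and the
    pair scorer is refit as a convex logistic problem on the frozen
    features. This sharpens the credit assignment that the soft-max pooling
    gradient leaves diffuse; the round with the best validation ranking is
    kept.
    """
    dataset.audit_splits()
    attach_ia3(model, head=task, unfreeze_last_k=unfreeze_last_k, head_seed=seed)
    mode = "ia3_unfreeze_last_k" if unfreeze_last_k else "ia3_frozen"
    trainable = model.trainable_names(mode, unfreeze_last_k)
    opt = Adam(trainable)
    rng = np.random.default_rng(seed)
    train = dataset.split("train")
    val = dataset.split("validation") or dataset.split("train")
    if not train:
        raise ValueError("empty training split")

    def val_loss():
        tot, n = 0.0, 0
        for b in _batched(val, batch_size):
            ids, spec, targets = _stack(b)
            preds = model.predict(ids, spec)
            if task.is_classification:
                p = np.clip(preds, 1e-12, 1 - 1e-12)
                tot += float(-(targets * np.log(p) + (1 - targets) * np.log1p(-p)).sum())
            else:
                tot += float(((preds - targets) ** 2).sum())
            n += targets.size
        return tot / n

    best = {n: model.params[n].copy() for n in trainable}
    best_loss = val_loss()
    bad_epochs = 0
    steps_per_epoch = int(np.ceil(len(train) / batch_size))
    total_steps = max(1, epochs * steps_per_epoch)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(len(train))
        for b in _batched([train[i] for i in order], batch_size):
            ids, spec, targets = _stack(b)
            loss, grads = model.head_loss_and_grads(ids, spec, targets)
            if not np.isfinite(loss):
                raise RuntimeError("fine-tuning diverged (non-finite loss)")
            if lr_decay == "cosine":
                lr_t = lr * 0.5 * (1.0 + np.cos(np.pi * step / total_steps))
            else:
                lr_t = lr
            opt.step(model.params, grads, lr_t)
            step += 1
        vl = val_loss()
        if vl < best_loss:
            best_loss = vl
            best = {n: model.params[n].copy() for n in trainable}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if patience is not None and bad_epochs > patience:
                break
    model.params.update(best)

    if (task.pooling == "detection" and task.kind == "binary_classification"
            and epochs > 0 and em_rounds > 0):
        _em_harden_detection_head(model, train, val, em_rounds)

    metrics = {"validation_loss": best_loss}
    for split_name in ("validation", "test"):
        ex = dataset.split(split_name)
        if ex:
            preds = predict_dataset(model, ex, batch_size)
            targets = np.stack([np.atleast_1d(np.asarray(e.target, float)) for e in ex])
            try:
                metrics[split_name] = compute_metrics(preds, targets, task)
            except UndefinedMetricError:
                pass
    return metrics


def _pair_features(model: TransformerLM, examples: Sequence[SupervisedExample],
                   batch_size: int = 32):
    """Width-2 pair features concat(h_t, h_{t+1}) per window, from the
    (adapter-modulated) hidden states the detection head reads."""
    feats, groups = [], []
    for gi_base in range(0, len(examples), batch_size):
        batch = examples[gi_base:gi_base + batch_size]
        ids, spec, _ = _stack(batch)
        ids2, pad = model._prep(ids, spec)
        c = model._forward(ids2, pad)
        h = model._head_input(c)
        for j, e in enumerate(batch):
            nons = ~e.tokens.is_special
            pv = nons[:-1] & nons[1:]
            pairs = np.concatenate([h[j, :-1], h[j, 1:]], axis=1)[pv]
            feats.append(pairs)
            groups.append(np.full(len(pairs), gi_base + j))
    return np.vstack(feats), np.concatenate(groups)


def _em_harden_detection_head(model: TransformerLM,
                              train: Sequence[SupervisedExample],
                              val: Sequence[SupervisedExample],
                              em_rounds: int) -> None:
    from sklearn.linear_model import LogisticRegression

    Ftr, Gtr = _pair_features(model, train)
    ytr = np.array([float(np.ravel(e.target)[0]) for e in train])
    Fva, Gva = _pair_features(model, val)
    yva = np.array([float(np.ravel(e.target)[0]) for e in val])
    w = model.params["head.w"][:, 0].astype(np.float64).copy()
    b = float(model.params["head.b"][0])

    def val_auroc(w_, b_):
        sc = Fva @ w_ + b_
        win = np.array([sc[Gva == g].max() for g in range(len(yva))])
        if len(np.unique(yva)) < 2:
            return 0.5
        return roc_auc_score(yva, win)

    best_w, best_b, best_score = w, b, val_auroc(w, b)
    for _ in range(em_rounds):
        s = Ftr @ w + b
        pseudo = np.zeros(len(s))
        for g in np.flatnonzero(ytr == 1):
            idx = np.flatnonzero(Gtr == g)
            pseudo[idx[np.argmax(s[idx])]] = 1.0
        clf = LogisticRegression(max_iter=3000, C=10.0).fit(Ftr, pseudo)
        w = clf.coef_[0]
        b = float(clf.intercept_[0])
        score = val_auroc(w, b)
        if score > best_score:
            best_w, best_b, best_score = w.copy(), b, score
    model.params["head.w"] = best_w[:, None].astype(model.params["head.w"].dtype)
    model.params["head.b"] = np.array([best_b], dtype=model.params["head.b"].dtype)


def compute_metrics(predictions: np.ndarray, targets: np.ndarray,
                    task: TaskHeadSpec) -> dict[str, float]:
    """AUROC/AUPRC for classification tasks, R^2 for regression tasks.

    R^2 is the squared Pearson correlation between predicted and observed
    values (the coefficient of determination of the linear fit). Multi-output
    tasks report the per-output mean.
    """
    predictions = np.asarray(predictions, float)
    targets = np.asarray(targets, float)
    if predictions.ndim == 1:
        predictions = predictions[:, None]
    if targets.ndim == 1:
        targets = targets[:, None]
    if task.is_classification:
        aurocs, auprcs = [], []
        for j in range(targets.shape[1]):
            y, s = targets[:, j], predictions[:, j]
            if len(np.unique(y)) < 2:
                raise UndefinedMetricError(f"output {j}: single-class targets")
            aurocs.append(roc_auc_score(y, s))
            auprcs.append(average_precision_score(y, s))
        return {"auroc": float(np.mean(aurocs)), "auprc": float(np.mean(auprcs))}
    r2s = []
    for j in range(targets.shape[1]):
        y, p = targets[:, j], predictions[:, j]
        if np.std(y) == 0 or np.std(p) == 0:
            raise UndefinedMetricError(f"output {j}: constant values")
        r2s.append(stats.pearsonr(p, y).statistic ** 2)
    return {"r2": float(np.mean(r2s))}


def tissue_lfc_eval(observed: pd.DataFrame, predicted: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-tissue log-fold-change agreement between two genes x tissues
    matrices on the log2 scale.

    For each unordered tissue pair, the per-gene LFC is the difference of the
    two tissue columns. Reports the Pearson correlation of observed vs
    predicted LFC and the fraction of genes whose predicted LFC sign matches
    the observed sign; genes with an observed or predicted LFC of exactly
    zero are excluded from the direction denominator and counted.
    """
    if list(observed.columns) != list(predicted.columns) or \
            list(observed.index) != list(predicted.index):
        raise ValueError("observed and predicted must share genes and tissues")
    if observed.shape[1] < 2:
        raise ValueError("need at least 2 tissues for pairwise comparisons")
    rows = []
    for a, b in itertools.combinations(observed.columns, 2):
        obs = (observed[a] - observed[b]).to_numpy()
        pred = (predicted[a] - predicted[b]).to_numpy()
        corr = (stats.pearsonr(obs, pred).statistic
                if np.std(obs) > 0 and np.std(pred) > 0 else np.nan)
        usable = (np.sign(obs) != 0) & (np.sign(pred) != 0)
        n_excluded = int((~usable).sum())
        direction = (float(np.mean(np.sign(obs[usable]) == np.sign(pred[usable])))
                     if usable.any() else np.nan)
        rows.append({"tissue_a": a, "tissue_b": b, "lfc_correlation": corr,
                     "direction_accuracy": direction, "n_excluded": n_excluded,
                     "n_genes": len(obs)})
    return pd.DataFrame(rows)
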