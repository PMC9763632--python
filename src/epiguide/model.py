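"""Training, gene-grouped splitting, evaluation metrics, baselines, ablations.

Splits are always grouped by gene: all sgRNAs of one gene land on the same
side of every train/validation/test boundary, because guides of a gene share
the target and per-gene normalization — ungrouped splits would leak.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import spearmanr
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold, GroupShuffleSplit

from .encode import SampleSet, SEQUENCE_CHANNELS
from .nn import Adam, CasCNN, ModelConfig, build_model, loss_and_grad


@dataclass
class SplitPlan:
    train_fraction: float = 0.9
    cv_folds_eval: int = 10
    cv_folds_hpo: int = 5
    seed: int = 0
    val_fraction: float = 0.1   # of the training side, for early stopping


@dataclass
class EvalReport:
    auc: Optional[float] = None
    spearman: Optional[float] = None
    mse: Optional[float] = None
    cosine_similarity: Optional[float] = None
    n_train: int = 0
    n_test: int = 0
    per_fold: List[dict] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "auc": self.auc,
            "spearman": self.spearman,
            "mse": self.mse,
            "cosine_similarity": self.cosine_similarity,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


# ----------------------------------------------------------------------- metrics


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC-AUC via the mid-rank statistic (ties handled by average rank)."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels/scores length mismatch")
    if len(np.unique(labels)) != 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def auc_bruteforce(labels: np.ndarray, scores: np.ndarray) -> float:
    """Independent O(n^2) pairwise-counting AUC (ties count 1/2); oracle for
    small inputs."""
    labels = np.asarray(labels, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return float(wins / (len(pos) * len(neg)))


def evaluate(predictions: np.ndarray, truths: np.ndarray, task: str) -> EvalReport:
    """Spearman (average-rank ties), MSE, cosine similarity, and — when the
    truths are binary — ROC-AUC, all on the same prediction vector.

    All-constant predictions make Spearman undefined; it is reported as
    missing (None) rather than NaN-propagated.
    """
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if predictions.shape != truths.shape:
        raise ValueError("predictions/truths length mismatch")
    rep = EvalReport(n_test=len(truths))
    if np.ptp(predictions) == 0.0 or np.ptp(truths) == 0.0:
        rep.spearman = None
    else:
        rep.spearman = float(spearmanr(predictions, truths).statistic)
    rep.mse = float(np.mean((predictions - truths) ** 2))
    denom = np.linalg.norm(predictions) * np.linalg.norm(truths)
    rep.cosine_similarity = float(predictions @ truths / denom) if denom > 0 else None
    if task == "classification" or set(np.unique(truths)) <= {0.0, 1.0}:
        if len(np.unique(truths)) == 2:
            rep.auc = auc_score(truths, predictions)
    return rep


# ------------------------------------------------------------------------ splits


def grouped_train_test_split(
    genes: Sequence[str], split: SplitPlan
) -> Tuple[np.ndarray, np.ndarray]:
    """Gene-grouped train/test indices at split.train_fraction."""
    gss = GroupShuffleSplit(
        n_splits=1, train_size=split.train_fraction, random_state=split.seed
    )
    train_idx, test_idx = next(gss.split(np.zeros(len(genes)), groups=genes))
    return train_idx, test_idx


def grouped_kfold(genes: Sequence[str], n_folds: int, seed: int = 0):
    """Gene-grouped K folds (shuffled gene assignment, seeded)."""
    rng = np.random.default_rng(seed)
    uniq = list(dict.fromkeys(genes))
    shuffled = {g: int(i) for g, i in zip(uniq, rng.permutation(len(uniq)))}
    keys = np.array([shuffled[g] for g in genes])
    gkf = GroupKFold(n_splits=n_folds)
    yield from gkf.split(np.zeros(len(genes)), groups=keys)


def split_hash(train_idx: np.ndarray, test_idx: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.asarray(train_idx, dtype=np.int64).tobytes())
    h.update(b"|")
    h.update(np.asarray(test_idx, dtype=np.int64).tobytes())
    return h.hexdigest()


# --------------------------------------------------------------------- training


@dataclass
class TrainedModel:
    net: CasCNN
    channels: Tuple[str, ...]
    history: List[dict] = field(default_factory=list)
    split_hash: str = ""

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict(X)

    def save(self, directory) -> None:
        self.net.save(directory)
        from pathlib import Path

        with open(Path(directory) / "manifest.json", "w") as fh:
            json.dump(
                {"channels": list(self.channels), "split_hash": self.split_hash,
                 "history": self.history},
                fh, indent=2,
            )

    @classmethod
    def load(cls, directory) -> "TrainedModel":
        from pathlib import Path

        net = CasCNN.load(directory)
        with open(Path(directory) / "manifest.json") as fh:
            man = json.load(fh)
        return cls(net=net, channels=tuple(man["channels"]),
                   history=man["history"], split_hash=man["split_hash"])


def _targets_for_task(samples: SampleSet, task: str) -> np.ndarray:
    return samples.labels if task == "classification" else samples.targets


def _usable(samples: SampleSet, task: str) -> SampleSet:
    y = _targets_for_task(samples, task)
    return samples.subset(np.flatnonzero(~np.isnan(y)))


def _val_metric(net: CasCNN, X: np.ndarray, y: np.ndarray, task: str) -> float:
    pred = net.predict(X)
    if task == "classification":
        if len(np.unique(y)) < 2:
            raise ValueError("validation fold contains a single class")
        return auc_score(y, pred)
    if np.ptp(pred) == 0.0:
        return -np.inf
    return float(spearmanr(pred, y).statistic)


def fit_network(
    net: CasCNN,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: ModelConfig,
) -> List[dict]:
    """Adam + minibatches + early stopping on the validation objective
    (AUC for classification, Spearman for regression); restores the best
    checkpoint seen. Returns the per-epoch history."""
    rng = np.random.default_rng(cfg.seed + 1)
    dropout_rng = np.random.default_rng(cfg.seed + 2)
    opt = Adam(net.params, lr=cfg.learning_rate)
    best_metric, best_state, since_best = -np.inf, None, 0
    history: List[dict] = []
    n = X_train.shape[0]
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss, nb = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            raw, cache = net.forward(X_train[idx], training=True, dropout_rng=dropout_rng)
            loss, draw = loss_and_grad(raw, y_train[idx], cfg.task)
            grads, _ = net.backward(draw, cache)
            opt.step(net.params, grads)
            epoch_loss += loss
            nb += 1
        metric = _val_metric(net, X_val, y_val, cfg.task)
        history.append({"epoch": epoch, "train_loss": epoch_loss / nb, "val_metric": metric})
        if metric > best_metric:
            best_metric, best_state, since_best = metric, net.state_dict(), 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if best_state is not None:
        net.load_state_dict(best_state)
    return history


def train(
    samples: SampleSet,
    split: SplitPlan,
    cfg: ModelConfig,
) -> Tuple[TrainedModel, EvalReport]:
    """Gene-grouped 9:1 split, early-stopped training, held-out evaluation."""
    usable = _usable(samples, cfg.task)
    y = _targets_for_task(usable, cfg.task)
    train_idx, test_idx = grouped_train_test_split(usable.genes, split)
    tr, te = usable.subset(train_idx), usable.subset(test_idx)
    # carve a validation slice out of the training side for early stopping
    vplan = SplitPlan(train_fraction=1.0 - split.val_fraction, seed=split.seed + 1)
    fit_idx, val_idx = grouped_train_test_split(tr.genes, vplan)
    fit, val = tr.subset(fit_idx), tr.subset(val_idx)

    net, _ = build_model(usable.X.shape[1:], cfg)
    y_fit = _targets_for_task(fit, cfg.task)
    y_val = _targets_for_task(val, cfg.task)
    history = fit_network(net, fit.X, y_fit, val.X, y_val, cfg)

    pred = net.predict(te.X)
    report = evaluate(pred, _targets_for_task(te, cfg.task), cfg.task)
    report.n_train = len(tr)
    report.n_test = len(te)
    model = TrainedModel(
        net=net, channels=usable.channels,
        history=history, split_hash=split_hash(train_idx, test_idx),
    )
    return model, report


def cross_validate(
    samples: SampleSet, split: SplitPlan, cfg: ModelConfig, n_folds: Optional[int] = None
) -> EvalReport:
    """Gene-grouped K-fold cross-validation; fold metrics averaged with
    s.e.m. recorded per fold."""
    n_folds = n_folds or split.cv_folds_eval
    usable = _usable(samples, cfg.task)
    genes = np.array(usable.genes)
    report = EvalReport()
    metrics: Dict[str, List[float]] = {"auc": [], "spearman": [], "mse": [], "cosine_similarity": []}
    for fold, (tr_idx, te_idx) in enumerate(grouped_kfold(usable.genes, n_folds, split.seed)):
        assert not set(genes[tr_idx]) & set(genes[te_idx]), "gene leakage across folds"
        fold_cfg = dataclasses.replace(cfg, seed=cfg.seed + fold)
        tr, te = usable.subset(tr_idx), usable.subset(te_idx)
        vplan = SplitPlan(train_fraction=1.0 - split.val_fraction, seed=split.seed + fold)
        fit_idx, val_idx = grouped_train_test_split(tr.genes, vplan)
        fit, val = tr.subset(fit_idx), tr.subset(val_idx)
        net, _ = build_model(usable.X.shape[1:], fold_cfg)
        fit_network(net, fit.X, _targets_for_task(fit, cfg.task),
                    val.X, _targets_for_task(val, cfg.task), fold_cfg)
        rep = evaluate(net.predict(te.X), _targets_for_task(te, cfg.task), cfg.task)
        report.per_fold.append(rep.summary())
        for key in metrics:
            v = getattr(rep, key)
            if v is not None:
                metrics[key].append(v)
    for key, vals in metrics.items():
        if vals:
            setattr(report, key, float(np.mean(vals)))
    report.n_train = len(usable)
    return report


# --------------------------------------------------------------------- baselines


def _flatten(samples: SampleSet) -> np.ndarray:
    return samples.X.reshape(samples.X.shape[0], -1)


def baseline_models(
    samples: SampleSet,
    split: SplitPlan,
    task: str,
    seed: int = 0,
    names: Sequence[str] = ("random_forest", "gradient_boosting"),
) -> Dict[str, EvalReport]:
    """Random Forest and Gradient Boosting on flattened input matrices, same
    gene-grouped split and metrics as the CNN. Each report carries the split
    hash so harnesses can assert the comparison used identical folds."""
    usable = _usable(samples, task)
    y = _targets_for_task(usable, task)
    train_idx, test_idx = grouped_train_test_split(usable.genes, split)
    shash = split_hash(train_idx, test_idx)
    Xtr, Xte = _flatten(usable.subset(train_idx)), _flatten(usable.subset(test_idx))
    ytr, yte = y[train_idx], y[test_idx]

    zoo = {
        "random_forest": (
            RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
            if task == "classification"
            else RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1)
        ),
        "gradient_boosting": (
            GradientBoostingClassifier(random_state=seed)
            if task == "classification"
            else GradientBoostingRegressor(random_state=seed)
        ),
    }
    out: Dict[str, EvalReport] = {}
    for name in names:
        est = zoo[name]
        est.fit(Xtr, ytr)
        pred = est.predict_proba(Xte)[:, 1] if task == "classification" else est.predict(Xte)
        rep = evaluate(pred, yte, task)
        rep.n_train, rep.n_test = len(ytr), len(yte)
        rep.per_fold.append({"split_hash": shash})
        out[name] = rep
    return out


def pwm_oracle(samples: SampleSet, split: SplitPlan, task: str = "classification") -> EvalReport:
    """Position-weight-matrix oracle: logistic (or linear) model on the
    one-hot sequence channels only. Since the planted simulator generates
    activity as a linear function of positional base indicators plus noise,
    this is a near-Bayes reference for sequence-driven signal."""
    seq_samples = samples.channel_subset(SEQUENCE_CHANNELS)
    usable = _usable(seq_samples, task)
    y = _targets_for_task(usable, task)
    train_idx, test_idx = grouped_train_test_split(usable.genes, split)
    Xtr, Xte = _flatten(usable.subset(train_idx)), _flatten(usable.subset(test_idx))
    if task == "classification":
        est = LogisticRegression(max_iter=2000, C=1.0)
        est.fit(Xtr, y[train_idx])
        pred = est.predict_proba(Xte)[:, 1]
    else:
        from sklearn.linear_model import Ridge

        est = Ridge(alpha=1.0)
        est.fit(Xtr, y[train_idx])
        pred = est.predict(Xte)
    rep = evaluate(pred, y[test_idx], task)
    rep.n_train, rep.n_test = len(train_idx), len(test_idx)
    rep.per_fold.append({"split_hash": split_hash(train_idx, test_idx)})
    return rep


# --------------------------------------------------------------------- ablations


def ablation_sweep(
    samples: SampleSet,
    split: SplitPlan,
    cfg: ModelConfig,
    subsets: Optional[Dict[str, Sequence[str]]] = None,
) -> Dict[str, EvalReport]:
    """Train one model per channel subset (seq-only, seq+one epigenetic
    group, full) and report each on the same gene-grouped split."""
    from .annotate import FEATURE_SLOTS

    if subsets is None:
        seq = list(SEQUENCE_CHANNELS)
        tss = list(FEATURE_SLOTS[:4])
        subsets = {
            "seq": seq,
            "seq+TSS": seq + tss,
            "seq+ATAC": seq + ["atac"],
            "seq+Methylation": seq + ["methylation"],
            "seq+RNA": seq + ["expression"],
            "full": seq + list(FEATURE_SLOTS),
        }
    out = {}
    for name, channels in subsets.items():
        sub = samples.channel_subset(channels)
        _, rep = train(sub, split, cfg)
        out[name] = rep
    return out
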