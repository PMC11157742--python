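"""Fine-tuning heads and task evaluation.

Classification fine-tunes an MLP head on the joint embedding with softmax
cross-entropy; survival fine-tunes a scalar-hazard head with the negative
Cox log partial likelihood (Breslow ties, closed risk sets T_j >= T_i;
larger hazard means higher risk and earlier expected event).  During
fine-tuning only the task loss is optimized; the backbone is either frozen
entirely or updated jointly, with cross-encoders targeting modalities absent
from the fine-tuning data always frozen.

Evaluation wraps the field-standard implementations: lifelines for the
concordance index and log-rank test, scikit-learn for classification
metrics, AUC and silhouette.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats as sps
from sklearn.metrics import (precision_recall_fscore_support, roc_auc_score,
                             silhouette_score)
from sklearn.model_selection import train_test_split

from .autodiff import MLP, Adam, Tensor
from .core import FusionModel
from .io_prep import BINARY, CONTINUOUS, MultiOmicsDataset
from .losses import softmax_ce_t

logger = logging.getLogger(__name__)


@dataclass
class FineTuneConfig:
    max_epochs: int = 100
    lr: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 64
    patience: int = 10
    head_hidden: int = 32
    val_fraction: float = 0.2
    seed: int = 0


@dataclass
class FreezePolicy:
    """Which backbone parameters may move during fine-tuning.

    ``freeze_backbone``: only the head trains.  ``full_finetune``: backbone
    trains too, except the always-frozen cross-encoders that target
    modalities entirely missing from the fine-tuning dataset (they preserve
    pretrained cross-modal inference quality).
    """

    mode: str = "full_finetune"

    def __post_init__(self):
        if self.mode not in ("freeze_backbone", "full_finetune"):
            raise ValueError("mode must be freeze_backbone or full_finetune")


# -- losses ---------------------------------------------------------------

def ce_classification_loss(logits: np.ndarray, true_class: np.ndarray) -> float:
    """Batch-averaged -log softmax(logits)[true_class]."""
    logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    y = np.asarray(true_class, dtype=int).reshape(-1)
    C = logits.shape[1]
    if ((y < 0) | (y >= C)).any():
        raise ValueError(f"class labels must lie in 0..{C - 1}")
    return softmax_ce_t(Tensor(logits), y).item()


def cox_loss_t(h: Tensor, time: np.ndarray, event: np.ndarray) -> Tensor:
    """Differentiable negative Cox log partial likelihood (Breslow ties).

    ``loss = -sum over events i of [h_i - log sum_{j: T_j >= T_i} exp(h_j)]``.
    """
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event, dtype=int).reshape(-1)
    if event.sum() == 0:
        raise ValueError("Cox partial likelihood is empty: no uncensored records")
    h = h if h.data.ndim == 1 else h.reshape(-1)
    risk = (time[None, :] >= time[:, None]).astype(np.float64)  # R[i, j]
    m = float(h.data.max())
    exp_h = (h - m).exp()
    log_risk_sum = (Tensor(risk) @ exp_h).log() + m
    per_event = (h - log_risk_sum) * Tensor(event.astype(np.float64))
    return -per_event.sum()


def cox_loss(hazards: np.ndarray, records: pd.DataFrame) -> float:
    """Negative Cox log partial likelihood over (time, event) records."""
    h = np.asarray(hazards, dtype=np.float64).reshape(-1)
    return cox_loss_t(Tensor(h), records["time"].to_numpy(), records["event"].to_numpy()).item()


# -- survival metrics ------------------------------------------------------

def concordance_index(hazards: np.ndarray, records: pd.DataFrame) -> float:
    """Harrell's C-index with the convention that larger hazard implies
    earlier event; hazard ties count 0.5."""
    h = np.asarray(hazards, dtype=np.float64).reshape(-1)
    t = records["time"].to_numpy(dtype=np.float64)
    e = records["event"].to_numpy(dtype=int)
    if e.sum() == 0:
        raise ValueError("no comparable pairs: all records censored")
    # lifelines scores predicted *survival* time: negate the hazard
    try:
        return float(_lifelines_cindex(t, -h, e))
    except ZeroDivisionError as exc:
        raise ValueError("no comparable pairs in the records") from exc


def stratify_and_logrank(hazards: np.ndarray,
                         records: pd.DataFrame) -> Tuple[np.ndarray, float, float]:
    """Median-hazard split into low/high risk plus two-sample log-rank test.

    Ties at the median go to the low-risk group.  Returns
    (group labels with 1 = high risk, chi-square statistic, p-value).
    """
    h = np.asarray(hazards, dtype=np.float64).reshape(-1)
    if len(h) < 4:
        raise ValueError("need at least 4 samples to stratify")
    groups = (h > np.median(h)).astype(int)
    if groups.sum() == 0 or groups.sum() == len(groups):
        raise ValueError("median split produced an empty group")
    t = records["time"].to_numpy(dtype=np.float64)
    e = records["event"].to_numpy(dtype=int)
    res = logrank_test(t[groups == 0], t[groups == 1],
                       event_observed_A=e[groups == 0], event_observed_B=e[groups == 1])
    return groups, float(res.test_statistic), float(res.p_value)


def km_curve(records: pd.DataFrame, groups: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier survival estimates per risk group for external plotting."""
    from lifelines import KaplanMeierFitter
    frames = []
    for g in np.unique(groups):
        sel = groups == g
        km = KaplanMeierFitter().fit(records["time"][sel], records["event"][sel])
        df = km.survival_function_.reset_index()
        df.columns = ["time", "survival"]
        df["group"] = g
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# -- classification / imputation / clustering metrics ----------------------

def classification_metrics(predicted: np.ndarray, true: np.ndarray) -> Dict:
    """Accuracy plus macro and per-class precision/recall/F1 (undefined
    per-class precision reported as 0)."""
    pred = np.asarray(predicted)
    y = np.asarray(true)
    if len(pred) == 0 or len(pred) != len(y):
        raise ValueError("label vectors must be nonempty and equal-length")
    labels = np.unique(np.concatenate([y, pred]))
    p, r, f, _ = precision_recall_fscore_support(y, pred, labels=labels, zero_division=0)
    return {
        "accuracy": float((pred == y).mean()),
        "precision_macro": float(p.mean()),
        "recall_macro": float(r.mean()),
        "f1_macro": float(f.mean()),
        "per_class": {str(lab): {"precision": float(pi), "recall": float(ri), "f1": float(fi)}
                      for lab, pi, ri, fi in zip(labels, p, r, f)},
    }


def imputation_metrics(x_true: np.ndarray, x_imputed: np.ndarray, kind: str) -> Dict:
    """Per-feature imputation quality, averaged over evaluable features.

    Continuous: R^2 (1 - SS_res/SS_tot) and Pearson r.  Binary: rank AUC of
    imputed probabilities against the true 0/1 status.  Features with
    constant truth are skipped and logged.
    """
    xt = np.asarray(x_true, dtype=np.float64)
    xi = np.asarray(x_imputed, dtype=np.float64)
    if xt.shape != xi.shape:
        raise ValueError("shapes must match")
    if kind == CONTINUOUS:
        r2s, rs = [], []
        for j in range(xt.shape[1]):
            col = xt[:, j]
            ss_tot = ((col - col.mean()) ** 2).sum()
            if ss_tot == 0:
                logger.info("imputation_metrics: constant truth feature %d skipped", j)
                continue
            ss_res = ((col - xi[:, j]) ** 2).sum()
            r2s.append(1.0 - ss_res / ss_tot)
            # a (numerically) constant imputation has undefined correlation
            pred_sd = xi[:, j].std()
            if pred_sd > 1e-12 * (1.0 + np.abs(xi[:, j]).max()):
                rs.append(sps.pearsonr(col, xi[:, j])[0])
            else:
                rs.append(0.0)
        return {"r2": float(np.mean(r2s)), "pearson_r": float(np.mean(rs)),
                "n_features": len(r2s)}
    if kind == BINARY:
        aucs = []
        for j in range(xt.shape[1]):
            col = xt[:, j]
            if len(np.unique(col)) < 2:
                logger.info("imputation_metrics: single-class feature %d skipped", j)
                continue
            aucs.append(roc_auc_score(col, xi[:, j]))
        return {"auc": float(np.mean(aucs)), "n_features": len(aucs)}
    raise ValueError(f"unknown kind {kind!r}")


def silhouette(embeddings: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette (Euclidean distance) of the labelled embedding."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    return float(silhouette_score(np.asarray(embeddings), labels))


# -- fine-tuning -----------------------------------------------------------

def _always_frozen_components(model: FusionModel, presence_mask: np.ndarray) -> List[str]:
    missing = [k for j, k in enumerate(model.order) if presence_mask[:, j].sum() == 0]
    frozen = []
    for (src, tgt) in model.cross_enc:
        if tgt in missing:
            frozen.append(f"cross_enc.{src}->{tgt}")
    return frozen


def _backbone_params(model: FusionModel, policy: FreezePolicy,
                     presence_mask: np.ndarray):
    if policy.mode == "freeze_backbone":
        return []
    return model.generator_parameters(
        exclude=_always_frozen_components(model, presence_mask))


def _embed_t(model: FusionModel, ds: MultiOmicsDataset, idx: np.ndarray) -> Tensor:
    X = {k: ds.modalities[k].values[idx] for k in model.order}
    fwd = model.forward_batch(X, ds.presence_mask[idx], sample=False)
    return fwd["joint_embedding"]


def _finetune_loop(model: FusionModel, head: MLP, ds: MultiOmicsDataset,
                   loss_of_idx, policy: FreezePolicy, config: FineTuneConfig,
                   stratify: Optional[np.ndarray]) -> None:
    """Shared mini-batch loop with early stopping on the validation loss."""
    n = ds.n_samples
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 911]))
    idx_all = np.arange(n)
    train_idx, val_idx = train_test_split(
        idx_all, test_size=config.val_fraction, random_state=config.seed,
        stratify=stratify)
    params = head.parameters() + _backbone_params(model, policy, ds.presence_mask)
    opt = Adam(params, lr=config.lr, weight_decay=config.weight_decay)
    best_val = np.inf
    best_state = [p.data.copy() for p in params]
    since = 0
    for _ in range(config.max_epochs):
        order = rng.permutation(train_idx)
        for start in range(0, len(order), config.batch_size):
            bidx = order[start:start + config.batch_size]
            loss = loss_of_idx(bidx)
            if loss is None:
                continue
            opt.zero_grad()
            loss.backward()
            opt.step()
        vloss = loss_of_idx(val_idx)
        v = np.inf if vloss is None else vloss.item()
        if not np.isfinite(v):
            raise FloatingPointError("fine-tuning diverged (non-finite validation loss)")
        if v < best_val - 1e-12:
            best_val = v
            best_state = [p.data.copy() for p in params]
            since = 0
        else:
            since += 1
            if since >= config.patience:
                break
    for p, s in zip(params, best_state):
        p.data = s


def finetune_classifier(model: FusionModel, dataset: MultiOmicsDataset,
                        labels: Optional[np.ndarray] = None,
                        policy: Optional[FreezePolicy] = None,
                        config: Optional[FineTuneConfig] = None) -> MLP:
    """Fine-tune an MLP classification head (and optionally the backbone)
    on subtype labels with softmax cross-entropy only."""
    policy = policy or FreezePolicy()
    config = config or FineTuneConfig()
    y = np.asarray(labels if labels is not None else dataset.clinical["subtype"], dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("classification fine-tuning needs >= 2 classes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    head = MLP([model.embedding_dim, config.head_hidden, len(classes)], rng)

    before = {k: v.copy() for k, v in model.state_dict().items()} \
        if policy.mode == "freeze_backbone" else None

    def loss_of_idx(idx):
        emb = _embed_t(model, dataset, idx)
        if policy.mode == "freeze_backbone":
            emb = emb.detach()
        return softmax_ce_t(head(emb), y[idx])

    _finetune_loop(model, head, dataset, loss_of_idx, policy, config, stratify=y)
    if before is not None:
        after = model.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)
    return head


def finetune_survival(model: FusionModel, dataset: MultiOmicsDataset,
                      records: Optional[pd.DataFrame] = None,
                      policy: Optional[FreezePolicy] = None,
                      config: Optional[FineTuneConfig] = None) -> MLP:
    """Fine-tune a scalar hazard head by minimizing the Cox loss."""
    policy = policy or FreezePolicy()
    config = config or FineTuneConfig()
    rec = records if records is not None else dataset.clinical[["time", "event"]]
    time = rec["time"].to_numpy(dtype=np.float64)
    event = rec["event"].to_numpy(dtype=int)
    if event.sum() == 0:
        raise ValueError("all records censored: Cox fine-tuning impossible")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    head = MLP([model.embedding_dim, config.head_hidden, 1], rng)

    def loss_of_idx(idx):
        if event[idx].sum() == 0:
            return None
        emb = _embed_t(model, dataset, idx)
        if policy.mode == "freeze_backbone":
            emb = emb.detach()
        h = head(emb).reshape(-1)
        # normalize by event count so batch size does not rescale the loss
        return cox_loss_t(h, time[idx], event[idx]) / float(event[idx].sum())

    _finetune_loop(model, head, dataset, loss_of_idx, policy, config, stratify=event)
    return head


def predict_hazard(model: FusionModel, head: MLP, dataset: MultiOmicsDataset) -> np.ndarray:
    emb = _embed_t(model, dataset, np.arange(dataset.n_samples))
    return head(emb.detach()).data[:, 0]


def predict_classes(model: FusionModel, head: MLP, dataset: MultiOmicsDataset) -> np.ndarray:
    return np.argmax(predict_logits(model, head, dataset), axis=1)


def predict_logits(model: FusionModel, head: MLP, dataset: MultiOmicsDataset) -> np.ndarray:
    emb = _embed_t(model, dataset, np.arange(dataset.n_samples))
    return head(emb.detach()).data
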