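"""Pretraining loop: per-sample modality masking, alternating adversarial
updates, early stopping, and LogME-based checkpoint selection.

The masking strategy draws, for every sample in a batch, one modality index
uniformly at random and hides that modality, so the cross-modal inference
path (PoE over the remaining modalities, reconstruction of the hidden one)
is exercised on every batch.  Samples that arrive with only a single
observed modality are left unmasked.

Checkpoints are scored with LogME — the log marginal evidence of a linear
model from the validation joint embeddings to one-hot subtype targets,
maximized over its two precision hyperparameters by the standard
fixed-point iteration — and the best-scoring epoch's parameters are
returned.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Adam, Tensor
from .core import FusionModel
from .io_prep import MultiOmicsDataset, split_folds_by_subtype
from .losses import (LossWeights, _elbo_t, bce_with_logits_t,
                     contrastive_loss_t, kl_diag_t, softmax_ce_t, uniform_ce_t)


@dataclass
class TrainConfig:
    """Optimizer and schedule settings.

    Defaults mirror the published pretraining recipe (Adam, main path
    lr 1e-5 / weight decay 1e-4, discriminator lr 1e-4 / weight decay 5e-4,
    at most 100 epochs with early stopping, per-epoch learning-rate decay).
    Desk-scale runs typically raise ``lr_main``.
    """

    max_epochs: int = 100
    lr_main: float = 1e-5
    wd_main: float = 1e-4
    lr_dis: float = 1e-4
    wd_dis: float = 5e-4
    batch_size: int = 64
    patience: int = 10
    seed: int = 0
    mask_strategy: str = "single"  # or "none"
    lr_decay: float = 0.99
    val_fold: int = 0
    n_folds: int = 5
    #: "logme" scores checkpoints by label transferability of the validation
    #: embeddings (the transfer-learning recipe); "val_loss" by the
    #: validation objective, appropriate when the goal is reconstruction /
    #: imputation quality rather than downstream transfer
    checkpoint_metric: str = "logme"

    def __post_init__(self):
        if min(self.lr_main, self.lr_dis) <= 0 or self.batch_size < 1:
            raise ValueError("rates and batch_size must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")
        if self.mask_strategy not in ("single", "none"):
            raise ValueError("mask_strategy must be 'single' or 'none'")
        if self.checkpoint_metric not in ("logme", "val_loss"):
            raise ValueError("checkpoint_metric must be 'logme' or 'val_loss'")


@dataclass
class Checkpoint:
    state: Dict[str, np.ndarray]
    epoch: int
    score: float
    config_hash: str


@dataclass
class TrainingHistory:
    epochs: List[Dict] = field(default_factory=list)
    checkpoints: List[Checkpoint] = field(default_factory=list)
    stopped_epoch: int = -1

    def write_jsonl(self, path) -> None:
        with Path(path).open("w") as fh:
            for rec in self.epochs:
                fh.write(json.dumps(rec) + "\n")


def sample_modality_mask(batch_size: int, n_modalities: int = 4,
                         rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Per sample, draw one modality uniformly and mask it (0); all other
    entries are 1, so every row keeps ``n_modalities - 1`` present."""
    if n_modalities < 2:
        raise ValueError("masking needs >= 2 modalities")
    rng = rng or np.random.default_rng()
    mask = np.ones((batch_size, n_modalities))
    hidden = rng.integers(0, n_modalities, size=batch_size)
    mask[np.arange(batch_size), hidden] = 0.0
    return mask


# -- LogME -----------------------------------------------------------------

def _logme_single(sigma: np.ndarray, z2: np.ndarray, res_x2: float, n: int,
                  max_iter: int = 200, tol: float = 1e-6) -> float:
    """Evidence for one target column given the design's squared singular
    values ``sigma`` and projected target ``z2 = (U^T y)^2``."""
    alpha, beta = 1.0, 1.0
    k = len(sigma)
    for _ in range(max_iter):
        t = alpha / beta
        gamma = float((sigma / (sigma + t)).sum())
        m2 = float((sigma * z2 / (sigma + t) ** 2).sum())
        res2 = float((z2 / (1.0 + sigma / t) ** 2).sum()) + res_x2
        alpha_new = gamma / (m2 + 1e-12)
        beta_new = (n - gamma) / (res2 + 1e-12)
        if abs(alpha_new - alpha) / alpha < tol and abs(beta_new - beta) / beta < tol:
            alpha, beta = alpha_new, beta_new
            break
        alpha, beta = alpha_new, beta_new
    t = alpha / beta
    m2 = float((sigma * z2 / (sigma + t) ** 2).sum())
    res2 = float((z2 / (1.0 + sigma / t) ** 2).sum()) + res_x2
    evidence = 0.5 * (n * np.log(beta) + k * np.log(alpha)
                      - beta * res2 - alpha * m2
                      - float(np.log(alpha + beta * sigma).sum())
                      - n * np.log(2 * np.pi))
    return evidence / n


def logme_score(embeddings: np.ndarray, labels: np.ndarray) -> float:
    """LogME transferability score of fixed embeddings for the given labels.

    One-hot targets; the per-class log evidence (per sample) is averaged over
    classes.  Higher is better.  Deterministic.
    """
    F = np.asarray(embeddings, dtype=np.float64)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("logme_score needs >= 2 classes")
    n = F.shape[0]
    u, s, _ = np.linalg.svd(F, full_matrices=False)
    sigma = s**2
    scores = []
    for c in classes:
        yc = (y == c).astype(np.float64)
        z = u.T @ yc
        z2 = z**2
        res_x2 = max(float((yc**2).sum() - z2.sum()), 0.0)
        scores.append(_logme_single(sigma, z2, res_x2, n))
    return float(np.mean(scores))


def select_best_checkpoint(history: TrainingHistory) -> Checkpoint:
    """Checkpoint with maximal selection score; ties go to the earliest epoch."""
    if not history.checkpoints:
        raise ValueError("no checkpoints with selection scores recorded")
    best = history.checkpoints[0]
    for ck in history.checkpoints[1:]:
        if ck.score > best.score:
            best = ck
    return best


# -- batch loss assembly ---------------------------------------------------

def _batch_losses(model: FusionModel, X: Dict[str, np.ndarray], mask: np.ndarray,
                  truth_mask: np.ndarray, labels: Optional[np.ndarray],
                  weights: LossWeights, rng: Optional[np.random.Generator],
                  sample: bool) -> Tuple[Tensor, Dict, Dict[str, Tensor]]:
    """Assemble the generator-side objective on one batch.

    ``mask`` gates what encoders may see (dataset presence AND training
    mask); ``truth_mask`` marks where ground-truth data exists for
    reconstruction targets (dataset presence only).
    """
    eps = None
    if sample and rng is not None:
        eps = {"self": {}, "cross": {}}
        for k in model.order:
            d = model.specs[k].latent_dim
            eps["self"][k] = rng.standard_normal((mask.shape[0], d))
            eps["cross"][k] = rng.standard_normal((mask.shape[0], d))
    fwd = model.forward_batch(X, mask, eps=eps, sample=sample)

    prior = {k: (Tensor(np.zeros((1, model.specs[k].latent_dim))),
                 Tensor(np.ones((1, model.specs[k].latent_dim)))) for k in model.order}

    parts: Dict[str, Dict[str, Tensor]] = {"self_elbo": {}, "cross_elbo": {}, "cross_kl": {}}
    xt = {k: Tensor(np.asarray(X[k], dtype=np.float64)) for k in model.order}
    for j, k in enumerate(model.order):
        spec = model.specs[k]
        kl_scale = 1.0 / spec.input_dim if weights.normalize_kl else 1.0
        align_scale = 1.0 / spec.latent_dim if weights.normalize_kl else 1.0
        mu, sc = fwd["self"][k]
        parts["self_elbo"][k] = _elbo_t(xt[k], fwd["recon_self"][k], mu, sc,
                                        *prior[k], sample_weight=mask[:, j],
                                        kl_scale=kl_scale)
        # cross terms need ground truth for the target and >= 1 real source
        has_src = (fwd["cross_n_sources"][k].reshape(-1) > 0).astype(np.float64)
        w_cross = truth_mask[:, j] * has_src
        jmu, jsc = fwd["cross"][k]
        parts["cross_elbo"][k] = _elbo_t(xt[k], fwd["recon_cross"][k], jmu, jsc,
                                         *prior[k], sample_weight=w_cross,
                                         kl_scale=kl_scale)
        kl_align = kl_diag_t(jmu, jsc, mu, sc)
        denom = max(w_cross.sum(), 1.0)
        parts["cross_kl"][k] = align_scale * (kl_align * Tensor(w_cross)).sum() / denom

    n_mod = len(model.order)
    self_elbo = sum(parts["self_elbo"].values()) / n_mod
    cross_elbo = sum(parts["cross_elbo"].values()) / n_mod
    cross_kl = sum(parts["cross_kl"].values()) / n_mod

    if labels is not None and weights.lambda_con > 0:
        l_pos, l_neg, l_con = contrastive_loss_t(fwd["joint_embedding"], labels, weights)
    else:
        l_pos = l_neg = l_con = Tensor(0.0)

    # generator fooling terms (non-saturating): self/cross reconstructions
    # pushed toward the "original" label; source predictions toward uniform
    gen_adv = Tensor(0.0)
    if weights.lambda_dis > 0 and model.disc_source:
        for k in model.order:
            logits_fake = model.disc_recon[k](fwd["recon_self"][k]).reshape(-1)
            gen_adv = gen_adv + bce_with_logits_t(logits_fake, 1)
            gen_adv = gen_adv + uniform_ce_t(model.disc_source[k](fwd["recon_cross"][k]))
        gen_adv = gen_adv / n_mod

    l_cross = weights.lambda_cross_elbo * cross_elbo + weights.lambda_cross_kl * cross_kl
    total = (weights.lambda_self * self_elbo
             + weights.lambda_cross * l_cross
             + weights.lambda_con * l_con
             + weights.lambda_dis * gen_adv)
    scalars = {
        "self_elbo": {k: v.item() for k, v in parts["self_elbo"].items()},
        "cross_elbo": {k: v.item() for k, v in parts["cross_elbo"].items()},
        "cross_kl": {k: v.item() for k, v in parts["cross_kl"].items()},
        "con_pos": l_pos.item(), "con_neg": l_neg.item(), "con": l_con.item(),
        "gen_adv": gen_adv.item(),
    }
    return total, scalars, fwd


def _discriminator_loss_t(model: FusionModel, X: Dict[str, np.ndarray],
                          fwd: Dict, truth_mask: np.ndarray) -> Tensor:
    """Discriminator CE on detached reconstructions: real -> 1, fake -> 0,
    cross reconstructions -> their true (single-source proxy) class.

    The source-classification term follows the printed objective: the
    discriminator of target k sees cross reconstructions and predicts which
    source produced them.  With PoE the reconstruction mixes all sources, so
    the class target used is the first observed source, which suffices as an
    adversarial signal at desk scale.
    """
    loss = Tensor(0.0)
    n_mod = len(model.order)
    for j, k in enumerate(model.order):
        w = truth_mask[:, j]
        if w.sum() == 0:
            continue
        real_logits = model.disc_recon[k](Tensor(np.asarray(X[k], dtype=np.float64))).reshape(-1)
        fake_logits = model.disc_recon[k](fwd["recon_self"][k].detach()).reshape(-1)
        loss = loss + bce_with_logits_t(real_logits, 1) + bce_with_logits_t(fake_logits, 0)
        if model.disc_source:
            sources = model.cross_sources(k)
            src_cols = [model.order.index(s) for s in sources]
            present = fwd["mask"][:, src_cols]
            first_src = np.argmax(present, axis=1)
            has_src = present.sum(axis=1) > 0
            logits = model.disc_source[k](fwd["recon_cross"][k].detach())
            loss = loss + softmax_ce_t(logits, first_src,
                                       sample_weight=has_src.astype(np.float64) * w)
    return loss / n_mod


def _stratified_batches(labels: np.ndarray, batch_size: int,
                        rng: np.random.Generator) -> List[np.ndarray]:
    """Shuffled batches with classes interleaved so most batches contain
    both positives and negatives for the contrastive term."""
    order = []
    queues = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        queues.append(list(idx))
    while any(queues):
        for q in queues:
            if q:
                order.append(q.pop())
    order = np.array(order)
    return [order[i:i + batch_size] for i in range(0, len(order), batch_size)]


def pretrain(dataset: MultiOmicsDataset, model: FusionModel,
             config: Optional[TrainConfig] = None,
             weights: Optional[LossWeights] = None) -> Tuple[FusionModel, TrainingHistory]:
    """Pretrain the fusion model on an aligned multi-omics dataset.

    One fold (``config.val_fold`` of ``config.n_folds`` stratified folds) is
    held out for validation-loss early stopping and LogME checkpoint
    scoring.  Alternates a generator step and (when ``lambda_dis > 0``) a
    discriminator step per batch.  Fully seeded and deterministic.
    """
    config = config or TrainConfig()
    weights = weights or LossWeights()
    labels_all = np.asarray(dataset.clinical["subtype"])
    if weights.lambda_con > 0 and len(np.unique(labels_all)) < 2:
        raise ValueError("contrastive loss needs >= 2 subtypes")

    folds = split_folds_by_subtype(dataset, k=config.n_folds, seed=config.seed)
    train_idx, val_idx = folds[config.val_fold]
    ds_train = dataset.subset(train_idx)
    ds_val = dataset.subset(val_idx)
    y_train = labels_all[train_idx]
    y_val = labels_all[val_idx]

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2027]))
    opt_gen = Adam(model.generator_parameters(), lr=config.lr_main,
                   weight_decay=config.wd_main)
    opt_dis = Adam(model.discriminator_parameters(), lr=config.lr_dis,
                   weight_decay=config.wd_dis)

    Xtr = {k: ds_train.modalities[k].values for k in model.order}
    Xva = {k: ds_val.modalities[k].values for k in model.order}
    n_mod = len(model.order)

    history = TrainingHistory()
    best_val = np.inf
    best_score = -np.inf
    since_improve = 0

    for epoch in range(config.max_epochs):
        batches = _stratified_batches(y_train, config.batch_size, rng)
        train_total = 0.0
        n_batches = 0
        for idx in batches:
            Xb = {k: Xtr[k][idx] for k in model.order}
            presence = ds_train.presence_mask[idx]
            if config.mask_strategy == "single" and n_mod >= 2:
                tmask = sample_modality_mask(len(idx), n_mod, rng)
                eff = presence * tmask
                none_left = eff.sum(axis=1) < 1
                eff[none_left] = presence[none_left]
            else:
                eff = presence
            total, scalars, fwd = _batch_losses(
                model, Xb, eff, presence, y_train[idx], weights, rng, sample=True)
            if not np.isfinite(total.item()):
                bad = {k: v for k, v in scalars.items()
                       if isinstance(v, float) and not np.isfinite(v)}
                raise FloatingPointError(f"pretraining diverged (non-finite loss): {bad or scalars}")
            opt_gen.zero_grad()
            total.backward()
            opt_gen.step()
            train_total += total.item()
            n_batches += 1
            if weights.lambda_dis > 0:
                dloss = _discriminator_loss_t(model, Xb, fwd, presence)
                opt_dis.zero_grad()
                dloss.backward()
                opt_dis.step()
        opt_gen.lr *= config.lr_decay

        val_total_t, val_scalars, _ = _batch_losses(
            model, Xva, ds_val.presence_mask, ds_val.presence_mask,
            y_val, weights, rng=None, sample=False)
        val_total = val_total_t.item()
        emb_val = model.joint_embedding(Xva, ds_val.presence_mask).joint_embedding
        try:
            logme = logme_score(emb_val, y_val)
        except ValueError:
            logme = -np.inf
        score = logme if config.checkpoint_metric == "logme" else -val_total
        rec = {"epoch": epoch, "train_total_min": train_total / max(n_batches, 1),
               "val_total_min": val_total, "logme": logme}
        rec.update({f"val_{k}": v for k, v in val_scalars.items()
                    if np.ndim(v) == 0})
        history.epochs.append(rec)
        if score > best_score:
            best_score = score
            history.checkpoints = [Checkpoint(copy.deepcopy(model.state_dict()),
                                              epoch, score, model.config_hash())]
        if val_total < best_val - 1e-12:
            best_val = val_total
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                history.stopped_epoch = epoch
                break
    if history.stopped_epoch < 0:
        history.stopped_epoch = len(history.epochs) - 1

    best = select_best_checkpoint(history)
    model.load_state_dict(best.state)
    return model, history
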