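"""Training objectives: self/cross ELBO losses, alignment KL, discriminator
cross-entropy, supervised contrastive loss, and the combined objective.

Conventions
-----------
* KL terms are summed over latent dimensions, reconstruction error is a mean
  over features; both are then averaged over the batch.  The mean-over-
  features reduction keeps the default loss weights transferable across
  modalities of different dimensionality.
* The contrastive loss uses cosine similarity.  Minimizing
  ``L_con = [lambda_pos * (1 - S_pos) + lambda_neg * S_neg] / tau``
  drives within-subtype similarity up and between-subtype similarity down;
  ``tau`` acts as a single outer scale on the distance constraints.
* The adversarial pair is realized as standard alternating GAN steps: the
  discriminator minimizes its cross-entropy, the generators minimize a
  non-saturating fooling term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple, Union

import numpy as np

from .autodiff import Tensor, logsumexp
from .core import GaussianPosterior

ArrayLike = Union[np.ndarray, Tensor]


@dataclass
class LossWeights:
    """Weights balancing the pretraining objective's components."""

    lambda_self: float = 1.0
    lambda_cross: float = 1.0
    lambda_cross_elbo: float = 1.0
    lambda_cross_kl: float = 0.1
    lambda_dis: float = 0.1
    lambda_con: float = 0.1
    lambda_pos: float = 1.0
    lambda_neg: float = 1.0
    tau: float = 0.5
    #: scale KL terms to the reconstruction's per-feature scale during
    #: training (KL-to-prior divided by n_features, alignment KL by
    #: latent_dim); False reproduces the unscaled textbook objective, which
    #: at mean-MSE reduction lets the KL dominate and collapse the posterior
    normalize_kl: bool = True

    def __post_init__(self):
        for name in ("lambda_self", "lambda_cross", "lambda_cross_elbo", "lambda_cross_kl",
                     "lambda_dis", "lambda_con", "lambda_pos", "lambda_neg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


def _t(x: ArrayLike) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


# -- KL divergence ---------------------------------------------------------

def kl_diag_t(mu_q: Tensor, sc_q: Tensor, mu_p: Tensor, sc_p: Tensor) -> Tensor:
    """Per-sample KL(q || p) between diagonal Gaussians, summed over the last
    axis.  Returns an [n]-tensor (or scalar for 1-D inputs)."""
    var_q = sc_q**2.0
    var_p = sc_p**2.0
    term = sc_p.log() - sc_q.log() + (var_q + (mu_q - mu_p) ** 2.0) / (2.0 * var_p) - 0.5
    return term.sum(axis=-1)


def kl_diag_gaussian(q: GaussianPosterior, p: GaussianPosterior) -> float:
    """Closed-form KL(q || p), summed over dimensions (single posterior pair)."""
    if q.mean.shape != p.mean.shape:
        raise ValueError("posteriors must share a shape")
    out = kl_diag_t(_t(q.mean), _t(q.scale), _t(p.mean), _t(p.scale))
    return float(np.sum(out.data)) if out.data.ndim else out.item()


def standard_normal_like(mean: np.ndarray) -> GaussianPosterior:
    return GaussianPosterior(np.zeros_like(mean), np.ones_like(mean))


# -- ELBO losses -----------------------------------------------------------

def _elbo_t(x: Tensor, xhat: Tensor, mu: Tensor, sc: Tensor,
            mu_p: Tensor, sc_p: Tensor, sample_weight: Optional[np.ndarray],
            kl_scale: float = 1.0) -> Tensor:
    mse = ((x - xhat) ** 2.0).mean(axis=-1)
    kl = kl_diag_t(mu, sc, mu_p, sc_p)
    per_sample = mse + kl_scale * kl
    if sample_weight is None:
        return per_sample.mean()
    w = np.asarray(sample_weight, dtype=np.float64).reshape(-1)
    denom = max(w.sum(), 1.0)
    return (per_sample * Tensor(w)).sum() / denom


def self_elbo_loss(x: ArrayLike, xhat: ArrayLike, posterior: GaussianPosterior,
                   prior: Optional[GaussianPosterior] = None) -> float:
    """MSE(x, x_hat) + KL(posterior || prior), batch-averaged.

    ``prior`` defaults to the standard normal.
    """
    xt, xh = _t(x), _t(xhat)
    if xt.shape != xh.shape:
        raise ValueError("x and x_hat must share a shape")
    if prior is None:
        prior = standard_normal_like(posterior.mean)
    out = _elbo_t(_atleast2d(xt), _atleast2d(xh),
                  _atleast2d(_t(posterior.mean)), _atleast2d(_t(posterior.scale)),
                  _atleast2d(_t(prior.mean)), _atleast2d(_t(prior.scale)), None)
    return out.item()


def cross_elbo_loss(x_target: ArrayLike, xhat_cross: ArrayLike,
                    joint_cross_posterior: GaussianPosterior,
                    prior: Optional[GaussianPosterior] = None) -> float:
    """Negated cross-modal ELBO: reconstruction of the target modality from
    the PoE latent plus KL(joint || prior).  Structurally the self-ELBO with
    the cross posterior substituted."""
    return self_elbo_loss(x_target, xhat_cross, joint_cross_posterior, prior)


def cross_alignment_kl(joint_cross_posterior: GaussianPosterior,
                       self_posterior: GaussianPosterior) -> float:
    """KL(joint_cross || self): aligns the cross joint posterior to the
    self posterior (note the argument order; KL is asymmetric)."""
    return kl_diag_gaussian(joint_cross_posterior, self_posterior)


def _atleast2d(t: Tensor) -> Tensor:
    return t.reshape(1, -1) if t.data.ndim == 1 else t


# -- discriminator loss ----------------------------------------------------

def discriminator_loss(real_probs: ArrayLike, fake_probs: ArrayLike,
                       source_probs: Optional[ArrayLike] = None,
                       true_sources: Optional[ArrayLike] = None) -> float:
    """CE(real -> 1) + CE(fake -> 0) + CE(source prediction -> true source),
    each batch-averaged then summed."""
    real = np.asarray(real_probs, dtype=np.float64).reshape(-1)
    fake = np.asarray(fake_probs, dtype=np.float64).reshape(-1)
    for arr, lab in ((real, "real"), (fake, "fake")):
        if ((arr <= 0) | (arr >= 1)).any():
            raise ValueError(f"{lab} probabilities must lie strictly in (0, 1)")
    loss = float(-np.log(real).mean() - np.log(1.0 - fake).mean())
    if source_probs is not None:
        sp = np.atleast_2d(np.asarray(source_probs, dtype=np.float64))
        if not np.allclose(sp.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("source probability rows must sum to 1")
        idx = np.asarray(true_sources, dtype=int).reshape(-1)
        loss += float(-np.log(sp[np.arange(len(idx)), idx]).mean())
    return loss


# -- contrastive loss ------------------------------------------------------

def _pair_masks(labels: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(len(labels), dtype=bool)
    return same & off, (~same) & off


def contrastive_loss_t(embeddings: Tensor, labels: np.ndarray,
                       weights: LossWeights) -> Tuple[Tensor, Tensor, Tensor]:
    """Differentiable contrastive loss on a batch of embeddings.

    Returns ``(L_pos, L_neg, L_con)`` where ``L_pos = (1 - S_pos)/tau`` and
    ``L_neg = S_neg/tau`` with S_* mean cosine similarities over within- and
    between-subtype pairs; a term with no pairs contributes zero.
    """
    labels = np.asarray(labels)
    n = embeddings.shape[0]
    if n == 0:
        raise ValueError("contrastive loss needs a nonempty batch")
    norm = (((embeddings**2.0).sum(axis=1, keepdims=True)) + 1e-12) ** 0.5
    unit = embeddings / norm
    sim = unit @ _transpose(unit)
    pos_mask, neg_mask = _pair_masks(labels)
    zero = Tensor(0.0)
    if pos_mask.any():
        s_pos = (sim * Tensor(pos_mask.astype(np.float64))).sum() / pos_mask.sum()
        l_pos = (1.0 - s_pos) / weights.tau
    else:
        l_pos = zero
    if neg_mask.any():
        s_neg = (sim * Tensor(neg_mask.astype(np.float64))).sum() / neg_mask.sum()
        l_neg = s_neg / weights.tau
    else:
        l_neg = zero
    l_con = weights.lambda_pos * l_pos + weights.lambda_neg * l_neg
    return l_pos, l_neg, l_con


def _transpose(t: Tensor) -> Tensor:
    out = Tensor(t.data.T, parents=(t,))
    if out.requires_grad:
        out._backward = lambda g: t._accumulate(g.T)
    return out


def contrastive_loss(embeddings: ArrayLike, subtype_labels: ArrayLike,
                     weights: Optional[LossWeights] = None) -> Tuple[float, float, float]:
    weights = weights or LossWeights()
    lp, ln, lc = contrastive_loss_t(_t(embeddings), np.asarray(subtype_labels), weights)
    return lp.item(), ln.item(), lc.item()


# -- combined objective ----------------------------------------------------

def pretrain_objective(parts: Dict[str, float], weights: LossWeights) -> Tuple[float, float]:
    """Combine component losses into (total_min, total_max).

    ``parts`` must contain ``self_elbo``, ``cross_elbo``, ``cross_kl``,
    ``con`` and ``dis`` (scalars, already batch-reduced); ``gen_adv`` (the
    generators' fooling term) is optional and defaults to 0.  total_min is
    minimized by encoders/decoders, total_max's component by the
    discriminators (via their own CE minimization in the alternating loop).
    """
    required = ("self_elbo", "cross_elbo", "cross_kl", "con", "dis")
    missing = [k for k in required if k not in parts]
    if missing:
        raise ValueError(f"missing loss components: {missing}")
    l_cross = (weights.lambda_cross_elbo * parts["cross_elbo"]
               + weights.lambda_cross_kl * parts["cross_kl"])
    total_min = (weights.lambda_self * parts["self_elbo"]
                 + weights.lambda_cross * l_cross
                 + weights.lambda_con * parts["con"]
                 + weights.lambda_dis * parts.get("gen_adv", 0.0))
    total_max = weights.lambda_dis * parts["dis"]
    return total_min, total_max


@dataclass
class LossReport:
    """Named per-batch/per-epoch scalar losses."""

    self_elbo: Dict[str, float]
    cross_elbo: Dict[str, float]
    cross_kl: Dict[str, float]
    dis: float
    con_pos: float
    con_neg: float
    con: float
    gen_adv: float
    total_min: float
    total_max: float

    def to_dict(self) -> Dict[str, float]:
        out: Dict[str, float] = {}
        for k, v in self.self_elbo.items():
            out[f"self_elbo.{k}"] = v
        for k, v in self.cross_elbo.items():
            out[f"cross_elbo.{k}"] = v
        for k, v in self.cross_kl.items():
            out[f"cross_kl.{k}"] = v
        out.update(dis=self.dis, con_pos=self.con_pos, con_neg=self.con_neg,
                   con=self.con, gen_adv=self.gen_adv,
                   total_min=self.total_min, total_max=self.total_max)
        return out


# -- tensor-side helpers used by the training loop -------------------------

def bce_with_logits_t(logits: Tensor, target: float) -> Tensor:
    """Mean binary cross-entropy from logits; target is 0 or 1 for the batch."""
    # softplus(-x) = -log sigmoid(x); softplus(x) = -log(1 - sigmoid(x))
    x = logits if logits.data.ndim == 1 else logits.reshape(-1)
    if target == 1:
        per = _softplus_t(-x)
    else:
        per = _softplus_t(x)
    return per.mean()


def _softplus_t(x: Tensor) -> Tensor:
    from .autodiff import softplus
    return softplus(x)


def softmax_ce_t(logits: Tensor, targets: np.ndarray,
                 sample_weight: Optional[np.ndarray] = None) -> Tensor:
    """Mean cross-entropy of integer targets from logits [n, C]."""
    lse = logsumexp(logits, axis=1)
    idx = np.asarray(targets, dtype=int)
    picked = (logits * Tensor(np.eye(logits.shape[1])[idx])).sum(axis=1)
    per = lse - picked
    if sample_weight is None:
        return per.mean()
    w = np.asarray(sample_weight, dtype=np.float64).reshape(-1)
    return (per * Tensor(w)).sum() / max(w.sum(), 1.0)


def uniform_ce_t(logits: Tensor) -> Tensor:
    """Cross-entropy toward the uniform distribution (generator fooling term
    for the source discriminator)."""
    lse = logsumexp(logits, axis=1)
    return (lse - logits.mean(axis=1)).mean()
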