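"""The fusion model: self- and cross-modal variational encoders, decoders,
product-of-experts (PoE) latent fusion, embedding fusion and discriminators.

Each modality k has
  * a self-encoder  q(z_k | x_k)  producing a diagonal Gaussian posterior,
  * a decoder       p(x_k | z_k)  shared between the self and cross paths,
  * one cross-encoder q(z_k | x_k') per source modality k' != k,
  * a real-vs-reconstructed discriminator, and
  * a source-modality discriminator over cross-reconstructions of k.

For a sample with observed modality set V, the cross posterior of modality k
is the PoE product of the marginal posteriors q(z_k | x_k') over observed
sources k' in V \\ {k}: precisions add, means are precision-weighted.  The
fused per-modality embedding is [z_self, z_cross] when k is observed and
[z_cross, z_cross] when it is missing, so the concatenated sample embedding
has a fixed dimension regardless of the missingness pattern.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import MLP, Parameter, Tensor, concat, sigmoid

GAUSSIAN = "gaussian"
BERNOULLI = "bernoulli"

_SCALE_FLOOR = 1e-6


@dataclass
class ModalitySpec:
    """Architecture settings for one modality's encoders/decoder."""

    name: str
    input_dim: int
    latent_dim: int = 64
    hidden_dims: List[int] = field(default_factory=lambda: [256])
    likelihood: str = GAUSSIAN

    def __post_init__(self):
        if self.input_dim < 1 or self.latent_dim < 1:
            raise ValueError(f"{self.name}: dims must be positive")
        if not self.hidden_dims:
            raise ValueError(f"{self.name}: hidden_dims must be nonempty")
        if self.likelihood not in (GAUSSIAN, BERNOULLI):
            raise ValueError(f"{self.name}: unknown likelihood {self.likelihood!r}")


@dataclass
class GaussianPosterior:
    """Diagonal Gaussian q(z) = N(mean, diag(scale^2))."""

    mean: np.ndarray
    scale: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.scale = np.asarray(self.scale, dtype=np.float64)
        if self.mean.shape != self.scale.shape:
            raise ValueError("mean and scale must share a shape")
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.scale))):
            raise ValueError("posterior has non-finite entries")
        if np.any(self.scale <= 0):
            raise ValueError("posterior scale must be strictly positive")


@dataclass
class FusionState:
    """Per-sample fusion result in deterministic (posterior-mean) mode."""

    z_self: Dict[str, Optional[np.ndarray]]
    z_cross: Dict[str, np.ndarray]
    z_fusion: Dict[str, np.ndarray]
    joint_embedding: np.ndarray


def poe_fuse(experts: Sequence[GaussianPosterior]) -> GaussianPosterior:
    """Closed-form product of diagonal-Gaussian experts.

    Joint precision is the sum of expert precisions; the joint mean is the
    precision-weighted average of expert means.  No prior expert is added.
    """
    if len(experts) == 0:
        raise ValueError("poe_fuse requires at least one expert")
    shapes = {e.mean.shape for e in experts}
    if len(shapes) != 1:
        raise ValueError("experts must share latent_dim")
    prec = np.stack([1.0 / e.scale**2 for e in experts]).sum(axis=0)
    weighted = np.stack([e.mean / e.scale**2 for e in experts]).sum(axis=0)
    return GaussianPosterior(mean=weighted / prec, scale=1.0 / np.sqrt(prec))


def reparameterize(posterior: GaussianPosterior, eps: np.ndarray) -> np.ndarray:
    """z = mean + scale * eps, elementwise."""
    eps = np.asarray(eps, dtype=np.float64)
    if eps.shape != posterior.mean.shape:
        raise ValueError("eps shape must match the posterior")
    return posterior.mean + posterior.scale * eps


def fuse_modality_embedding(z_self: Optional[np.ndarray], z_cross: Optional[np.ndarray]) -> np.ndarray:
    """Concatenate [z_self, z_cross]; a missing modality's self slot is filled
    with z_cross so the fused length is always 2 * latent_dim."""
    if z_cross is None:
        raise ValueError("z_cross must always be available")
    first = z_cross if z_self is None else z_self
    return np.concatenate([first, z_cross], axis=-1)


def _as_2d(x: np.ndarray) -> Tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        return x[None, :], True
    return x, False


class FusionModel:
    """Multi-modal VAE with PoE cross-modal fusion and discriminators."""

    def __init__(self, specs: Sequence[ModalitySpec], disc_hidden: int = 128,
                 seed: int = 0, poe_prior_expert: bool = False):
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError("modality names must be unique")
        if len(names) < 1:
            raise ValueError("at least one modality is required")
        self.specs: Dict[str, ModalitySpec] = {s.name: s for s in specs}
        self.order: List[str] = names
        self.disc_hidden = disc_hidden
        self.seed = seed
        self.poe_prior_expert = poe_prior_expert
        rng = np.random.default_rng(np.random.SeedSequence(seed))

        self.self_enc: Dict[str, MLP] = {}
        self.dec: Dict[str, MLP] = {}
        self.cross_enc: Dict[Tuple[str, str], MLP] = {}
        self.disc_recon: Dict[str, MLP] = {}
        self.disc_source: Dict[str, MLP] = {}
        for s in specs:
            self.self_enc[s.name] = MLP([s.input_dim, *s.hidden_dims, 2 * s.latent_dim], rng)
            self.dec[s.name] = MLP([s.latent_dim, *reversed(s.hidden_dims), s.input_dim], rng)
        for tgt in specs:
            for src in specs:
                if src.name == tgt.name:
                    continue
                self.cross_enc[(src.name, tgt.name)] = MLP(
                    [src.input_dim, *tgt.hidden_dims, 2 * tgt.latent_dim], rng)
        if len(specs) >= 2:
            for s in specs:
                self.disc_recon[s.name] = MLP([s.input_dim, disc_hidden, 1], rng)
                self.disc_source[s.name] = MLP([s.input_dim, disc_hidden, len(specs) - 1], rng)
        else:
            self.disc_recon[specs[0].name] = MLP([specs[0].input_dim, disc_hidden, 1], rng)

    # -- parameter plumbing -------------------------------------------------
    def _components(self) -> Dict[str, MLP]:
        comp: Dict[str, MLP] = {}
        for k in self.order:
            comp[f"self_enc.{k}"] = self.self_enc[k]
            comp[f"dec.{k}"] = self.dec[k]
        for (src, tgt), net in self.cross_enc.items():
            comp[f"cross_enc.{src}->{tgt}"] = net
        for k, net in self.disc_recon.items():
            comp[f"disc_recon.{k}"] = net
        for k, net in self.disc_source.items():
            comp[f"disc_source.{k}"] = net
        return comp

    def generator_parameters(self, exclude: Sequence[str] = ()) -> List[Parameter]:
        """Encoder/decoder parameters (everything except discriminators).

        ``exclude`` names components (e.g. ``cross_enc.a->b``) to leave out —
        used by freeze policies.
        """
        params = []
        for name, net in self._components().items():
            if name.startswith("disc_") or name in exclude:
                continue
            params.extend(net.parameters())
        return params

    def discriminator_parameters(self) -> List[Parameter]:
        return [p for name, net in self._components().items()
                if name.startswith("disc_") for p in net.parameters()]

    def state_dict(self) -> Dict[str, np.ndarray]:
        out = {}
        for cname, net in self._components().items():
            for i, layer in enumerate(net.layers):
                out[f"{cname}.layer{i}.W"] = layer.W.data
                out[f"{cname}.layer{i}.b"] = layer.b.data
        return out

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for cname, net in self._components().items():
            for i, layer in enumerate(net.layers):
                layer.W.data = np.array(state[f"{cname}.layer{i}.W"], dtype=np.float64)
                layer.b.data = np.array(state[f"{cname}.layer{i}.b"], dtype=np.float64)

    def config_hash(self) -> str:
        cfg = {
            "specs": [[s.name, s.input_dim, s.latent_dim, list(s.hidden_dims), s.likelihood]
                      for s in (self.specs[k] for k in self.order)],
            "disc_hidden": self.disc_hidden,
            "poe_prior_expert": self.poe_prior_expert,
        }
        return hashlib.sha256(json.dumps(cfg).encode()).hexdigest()[:16]

    def save(self, path) -> None:
        """Checkpoint: parameters + specs + config hash + init seed."""
        meta = {
            "specs": [[s.name, s.input_dim, s.latent_dim, list(s.hidden_dims), s.likelihood]
                      for s in (self.specs[k] for k in self.order)],
            "disc_hidden": self.disc_hidden,
            "seed": self.seed,
            "poe_prior_expert": self.poe_prior_expert,
            "config_hash": self.config_hash(),
        }
        arrays = {k.replace("->", "__to__"): v for k, v in self.state_dict().items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "FusionModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k.replace("__to__", "->"): data[k] for k in data.files if k != "__meta__"}
        specs = [ModalitySpec(n, i, l, h, lk) for n, i, l, h, lk in meta["specs"]]
        model = cls(specs, disc_hidden=meta["disc_hidden"], seed=meta["seed"],
                    poe_prior_expert=meta["poe_prior_expert"])
        if model.config_hash() != meta["config_hash"]:
            raise ValueError("checkpoint config hash mismatch")
        model.load_state_dict(state)
        return model

    # -- tensor-level forward pieces ----------------------------------------
    def _posterior_from_net(self, net: MLP, x: Tensor, latent_dim: int) -> Tuple[Tensor, Tensor]:
        out = net(x)
        mu = out[:, :latent_dim]
        logvar = out[:, latent_dim:]
        scale = (logvar * 0.5).exp() + _SCALE_FLOOR
        return mu, scale

    def _encode_self_t(self, x: Tensor, name: str) -> Tuple[Tensor, Tensor]:
        spec = self.specs[name]
        if x.shape[-1] != spec.input_dim:
            raise ValueError(f"{name}: expected {spec.input_dim} features, got {x.shape[-1]}")
        return self._posterior_from_net(self.self_enc[name], x, spec.latent_dim)

    def _encode_cross_t(self, x: Tensor, source: str, target: str) -> Tuple[Tensor, Tensor]:
        if source == target:
            raise ValueError("cross encoding requires source != target")
        if (source, target) not in self.cross_enc:
            raise ValueError(f"no cross encoder {source}->{target}")
        if x.shape[-1] != self.specs[source].input_dim:
            raise ValueError(f"{source}: dimension mismatch")
        return self._posterior_from_net(self.cross_enc[(source, target)], x,
                                        self.specs[target].latent_dim)

    def _decode_t(self, z: Tensor, name: str) -> Tensor:
        spec = self.specs[name]
        if z.shape[-1] != spec.latent_dim:
            raise ValueError(f"{name}: expected latent dim {spec.latent_dim}, got {z.shape[-1]}")
        out = self.dec[name](z)
        if spec.likelihood == BERNOULLI:
            out = sigmoid(out)
        return out

    def _poe_t(self, mus: List[Tensor], scales: List[Tensor],
               weights: List[np.ndarray]) -> Tuple[Tensor, Tensor]:
        """Mask-weighted PoE over batched experts.

        ``weights[e]`` is an [n, 1] 0/1 array gating expert ``e`` per sample.
        Rows must have at least one active expert.
        """
        prec_sum = None
        wmean_sum = None
        for mu, sc, w in zip(mus, scales, weights):
            wt = Tensor(w)
            prec = wt * sc**-2.0
            term = prec * mu
            prec_sum = prec if prec_sum is None else prec_sum + prec
            wmean_sum = term if wmean_sum is None else wmean_sum + term
        if self.poe_prior_expert:
            prec_sum = prec_sum + 1.0
            # prior mean is zero: no contribution to the weighted-mean sum
        joint_var = prec_sum**-1.0
        joint_mu = wmean_sum * joint_var
        return joint_mu, joint_var.sqrt()

    def forward_batch(self, X: Dict[str, np.ndarray], mask: np.ndarray,
                      eps: Optional[Dict[str, Dict[str, np.ndarray]]] = None,
                      sample: bool = False) -> Dict:
        """Full forward pass over a batch.

        ``mask[:, j]`` gates modality ``order[j]``.  For every modality the
        self posterior, self reconstruction, PoE cross posterior, cross
        reconstruction and fused embedding are computed; loss code weights
        the per-sample terms by the mask.  ``sample=True`` draws latents via
        the reparameterization trick (``eps`` injectable for tests),
        otherwise posterior means are used.
        """
        mask = np.asarray(mask, dtype=np.float64)
        n = mask.shape[0]
        if mask.shape != (n, len(self.order)):
            raise ValueError("mask shape must be (batch, n_modalities)")
        if mask.sum(axis=1).min() < 1:
            raise ValueError("every sample needs >= 1 present modality")
        xt = {k: Tensor(np.asarray(X[k], dtype=np.float64)) for k in self.order}

        out: Dict = {"mask": mask, "self": {}, "cross": {}, "z_self": {}, "z_cross": {},
                     "recon_self": {}, "recon_cross": {}, "z_fusion": {}}
        rng = None
        if sample and eps is None:
            rng = np.random.default_rng()

        def draw(name, kind, shape):
            if not sample:
                return None
            if eps is not None:
                return eps[kind][name]
            return rng.standard_normal(shape)

        for k in self.order:
            mu, sc = self._encode_self_t(xt[k], k)
            out["self"][k] = (mu, sc)
            e = draw(k, "self", mu.shape)
            z = mu + sc * Tensor(e) if e is not None else mu
            out["z_self"][k] = z
            out["recon_self"][k] = self._decode_t(z, k)

        for j, k in enumerate(self.order):
            sources = [s for s in self.order if s != k]
            mus, scales, weights = [], [], []
            for s in sources:
                cmu, csc = self._encode_cross_t(xt[s], s, k)
                mus.append(cmu)
                scales.append(csc)
                weights.append(mask[:, [self.order.index(s)]])
            n_src = np.sum(np.concatenate(weights, axis=1), axis=1, keepdims=True) if weights else np.zeros((n, 1))
            if not sources or (n_src == 0).any():
                # a present modality with no observed sources falls back to
                # its own self posterior (cross losses are skipped for it)
                smu, ssc = out["self"][k]
                fallback = (n_src == 0).astype(np.float64)
                mus.append(smu)
                scales.append(ssc)
                weights.append(fallback)
            jmu, jsc = self._poe_t(mus, scales, weights)
            out["cross"][k] = (jmu, jsc)
            out["cross_n_sources"] = out.get("cross_n_sources", {})
            out["cross_n_sources"][k] = n_src
            e = draw(k, "cross", jmu.shape)
            zc = jmu + jsc * Tensor(e) if e is not None else jmu
            out["z_cross"][k] = zc
            out["recon_cross"][k] = self._decode_t(zc, k)

            m_col = Tensor(mask[:, [j]])
            fused_first = m_col * out["z_self"][k] + (1.0 - m_col) * zc
            out["z_fusion"][k] = concat([fused_first, zc], axis=1)

        out["joint_embedding"] = concat([out["z_fusion"][k] for k in self.order], axis=1)
        return out

    # -- public numpy-facing operations -------------------------------------
    def encode_self(self, x: np.ndarray, name: str) -> GaussianPosterior:
        x2, squeeze = _as_2d(x)
        mu, sc = self._encode_self_t(Tensor(x2), name)
        m, s = mu.data, sc.data
        return GaussianPosterior(m[0] if squeeze else m, s[0] if squeeze else s)

    def encode_cross(self, x: np.ndarray, source: str, target: str) -> GaussianPosterior:
        x2, squeeze = _as_2d(x)
        mu, sc = self._encode_cross_t(Tensor(x2), source, target)
        m, s = mu.data, sc.data
        return GaussianPosterior(m[0] if squeeze else m, s[0] if squeeze else s)

    def decode(self, z: np.ndarray, name: str) -> np.ndarray:
        z2, squeeze = _as_2d(z)
        out = self._decode_t(Tensor(z2), name).data
        return out[0] if squeeze else out

    def discriminate_reconstruction(self, x: np.ndarray, name: str) -> np.ndarray:
        x2, squeeze = _as_2d(x)
        if x2.shape[1] != self.specs[name].input_dim:
            raise ValueError(f"{name}: dimension mismatch")
        p = sigmoid(self.disc_recon[name](Tensor(x2))).data[:, 0]
        return float(p[0]) if squeeze else p

    def discriminate_source_modality(self, x: np.ndarray, target: str) -> np.ndarray:
        x2, squeeze = _as_2d(x)
        if x2.shape[1] != self.specs[target].input_dim:
            raise ValueError(f"{target}: dimension mismatch")
        logits = self.disc_source[target](Tensor(x2)).data
        logits = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        return p[0] if squeeze else p

    def cross_sources(self, target: str) -> List[str]:
        """Ordered possible source modalities for a target (disc_source classes)."""
        return [s for s in self.order if s != target]

    def joint_embedding(self, X: Dict[str, np.ndarray], mask: np.ndarray) -> FusionState:
        """Deterministic (posterior-mean) fusion of a batch."""
        fwd = self.forward_batch(X, mask, sample=False)
        mask = np.asarray(mask, dtype=np.float64)
        z_self = {}
        for j, k in enumerate(self.order):
            zs = fwd["z_self"][k].data.copy()
            z_self[k] = np.where(mask[:, [j]] > 0, zs, np.nan)
        return FusionState(
            z_self=z_self,
            z_cross={k: fwd["z_cross"][k].data for k in self.order},
            z_fusion={k: fwd["z_fusion"][k].data for k in self.order},
            joint_embedding=fwd["joint_embedding"].data,
        )

    @property
    def embedding_dim(self) -> int:
        return sum(2 * self.specs[k].latent_dim for k in self.order)
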