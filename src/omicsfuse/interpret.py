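"""Integrated-gradients attribution, group importance and modality-level
attribution.

``IG_i(x) = (x_i - x'_i) * integral_0^1 df/dx_i (x' + a (x - x')) da``
approximated with a midpoint Riemann sum over ``steps`` points.  For a
sample group S, the group importance of feature g is the mean absolute IG,
``I(g) = mean_{x in S} |IG_g(x)|``; modality attribution is the signed sum
of IG over a modality's features per sample, averaged over the group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .core import FusionModel


@dataclass
class AttributionResult:
    """IG attributions for a sample group, per modality."""

    ig: Dict[str, np.ndarray]          # modality -> [n_samples, n_features]
    baseline: Dict[str, np.ndarray]    # modality -> [n_features]
    steps: int
    target: str
    feature_ids: Dict[str, List[str]]

    def group_importance_frame(self) -> pd.DataFrame:
        rows = []
        for mod, ig in self.ig.items():
            imp = group_importance(ig)
            signed = ig.mean(axis=0)
            for fid, i_g, s in zip(self.feature_ids[mod], imp, signed):
                rows.append({"feature_id": fid, "modality": mod,
                             "importance": i_g, "mean_signed_ig": s})
        return pd.DataFrame(rows)


def integrated_gradients(func: Callable[[Tensor], Tensor], x: np.ndarray,
                         baseline: Optional[np.ndarray] = None,
                         steps: int = 128) -> np.ndarray:
    """Midpoint-rule integrated gradients of a scalar-per-sample function.

    ``func`` maps a [m, d] tensor to an [m] (or [m, 1]) tensor; ``x`` is
    [n, d] (or [d]).  Returns IG of the same shape as ``x``.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 1
    x2 = x[None, :] if squeeze else x
    base = np.zeros_like(x2[0]) if baseline is None else np.asarray(baseline, dtype=np.float64)
    if base.shape != x2[0].shape:
        raise ValueError("baseline shape must match the input features")
    n, d = x2.shape
    alphas = (np.arange(steps) + 0.5) / steps
    points = base[None, None, :] + alphas[:, None, None] * (x2 - base)[None, :, :]
    pts = Tensor(points.reshape(steps * n, d), requires_grad=True)
    out = func(pts)
    if out.data.ndim == 2 and out.data.shape[1] == 1:
        out = out.reshape(-1)
    if out.data.ndim != 1 or out.data.shape[0] != steps * n:
        raise ValueError("func must return one scalar per input row")
    out.sum().backward()
    grads = pts.grad.reshape(steps, n, d).mean(axis=0)
    ig = (x2 - base) * grads
    return ig[0] if squeeze else ig


def group_importance(ig_values: np.ndarray) -> np.ndarray:
    """I(g) = mean over the sample group of |IG_g|, per feature."""
    ig = np.atleast_2d(np.asarray(ig_values, dtype=np.float64))
    if ig.shape[0] == 0:
        raise ValueError("empty sample group")
    return np.abs(ig).mean(axis=0)


def modality_attribution(ig_by_modality: Dict[str, np.ndarray]) -> Dict[str, float]:
    """Signed per-sample sum of IG within each modality, group-averaged."""
    return {mod: float(np.atleast_2d(ig).sum(axis=1).mean())
            for mod, ig in ig_by_modality.items()}


def rank_features(importance: Dict[str, float], top_k: Optional[int] = None) -> List[str]:
    """Feature IDs in descending importance; ties broken lexicographically."""
    items = sorted(importance.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        if top_k > len(items):
            raise ValueError("top_k exceeds the number of features")
        items = items[:top_k]
    return [k for k, _ in items]


def attribute_model(model: FusionModel, head, X: Dict[str, np.ndarray],
                    mask: np.ndarray, target: str = "hazard",
                    class_index: Optional[int] = None,
                    baselines: Optional[Dict[str, np.ndarray]] = None,
                    steps: int = 128,
                    feature_ids: Optional[Dict[str, List[str]]] = None,
                    use_softmax: bool = False) -> AttributionResult:
    """IG of a fine-tuned model's output w.r.t. the concatenated inputs.

    ``target`` is ``"hazard"`` (scalar head output) or ``"class"`` (the
    pre-softmax logit of ``class_index``; ``use_softmax=True`` attributes
    the softmax probability instead).  The per-sample presence pattern is
    held fixed along the integration path.
    """
    order = model.order
    dims = [model.specs[k].input_dim for k in order]
    splits = np.cumsum(dims)[:-1]
    n = np.asarray(X[order[0]]).shape[0]
    mask = np.asarray(mask, dtype=np.float64)
    flat_x = np.concatenate([np.asarray(X[k], dtype=np.float64) for k in order], axis=1)
    if baselines is None:
        baselines = {k: np.zeros(model.specs[k].input_dim) for k in order}
    flat_base = np.concatenate([np.asarray(baselines[k], dtype=np.float64) for k in order])

    def func(pts: Tensor) -> Tensor:
        m = pts.shape[0]
        reps = m // n
        big_mask = np.repeat(mask[None, :, :], reps, axis=0).reshape(m, len(order))
        Xd, start = {}, 0
        for k, d in zip(order, dims):
            Xd[k] = pts[:, start:start + d]
            start += d
        emb = _joint_embedding_from_tensors(model, Xd, big_mask)
        out = head(emb)
        if target == "hazard":
            return out.reshape(-1)
        if class_index is None:
            raise ValueError("class attribution needs class_index")
        if use_softmax:
            from .autodiff import logsumexp
            return (out[:, class_index] - logsumexp(out, axis=1)).exp()
        return out[:, class_index]

    ig_flat = integrated_gradients(func, flat_x, flat_base, steps=steps)
    pieces = np.split(ig_flat, splits, axis=1)
    fids = feature_ids or {k: [f"{k}_f{i}" for i in range(d)] for k, d in zip(order, dims)}
    return AttributionResult(
        ig={k: p for k, p in zip(order, pieces)},
        baseline={k: b for k, b in zip(order, np.split(flat_base, splits))},
        steps=steps,
        target=target if target == "hazard" else f"class:{class_index}",
        feature_ids=fids,
    )


def _joint_embedding_from_tensors(model: FusionModel, Xd: Dict[str, Tensor],
                                  mask: np.ndarray) -> Tensor:
    """Deterministic joint embedding with gradient flow to the inputs."""
    from .autodiff import concat
    out_fusion = []
    self_post = {k: model._encode_self_t(Xd[k], k) for k in model.order}
    for j, k in enumerate(model.order):
        mus, scales, weights = [], [], []
        for s in model.order:
            if s == k:
                continue
            cmu, csc = model._encode_cross_t(Xd[s], s, k)
            mus.append(cmu)
            scales.append(csc)
            weights.append(mask[:, [model.order.index(s)]])
        n_src = np.sum(np.concatenate(weights, axis=1), axis=1, keepdims=True) if weights \
            else np.zeros((mask.shape[0], 1))
        if not mus or (n_src == 0).any():
            smu, ssc = self_post[k]
            mus.append(smu)
            scales.append(ssc)
            weights.append((n_src == 0).astype(np.float64))
        jmu, _ = model._poe_t(mus, scales, weights)
        m_col = Tensor(mask[:, [j]])
        fused_first = m_col * self_post[k][0] + (1.0 - m_col) * jmu
        out_fusion.append(concat([fused_first, jmu], axis=1))
    return concat(out_fusion, axis=1)


def export_attributions(result: AttributionResult, tsv_path, json_path=None) -> None:
    """Write the per-feature TSV and per-modality JSON summary."""
    import json as _json
    from pathlib import Path
    result.group_importance_frame().to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(_json.dumps(modality_attribution(result.ig), indent=2))
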