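"""Synthetic multi-omics generator with known ground truth.

The generator emulates the structure of a paired pan-cancer multi-omics
corpus: every sample carries a shared low-dimensional latent state (subtype
mean + standard-normal draw); each continuous modality is a modality-specific
linear map of that state plus Gaussian noise; a binary mutation-like modality
is Bernoulli(sigmoid(latent . loading)); right-censored survival times are
driven by a latent linear risk score.  The linear-Gaussian design is chosen
so closed-form oracles (least squares, rank, silhouette) exist for every
downstream claim.

Randomness is split into independent child streams (latent, per-modality
noise, missingness, censoring) spawned from one seed, so sub-experiments stay
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .io_prep import BINARY, CONTINUOUS, MultiOmicsDataset, OmicsMatrix


class SimConfigError(ValueError):
    """Raised when a simulation config field is invalid."""


@dataclass
class ModalitySim:
    """Generation settings for one synthetic modality."""

    name: str
    n_features: int
    kind: str = CONTINUOUS
    noise_sd: float = 0.1
    missing_rate: float = 0.0


@dataclass
class SimConfig:
    n_samples: int = 500
    n_subtypes: int = 2
    latent_dim_true: int = 8
    modalities: List[ModalitySim] = field(default_factory=lambda: [
        ModalitySim("expression", 100, CONTINUOUS, noise_sd=0.1),
        ModalitySim("methylation", 80, CONTINUOUS, noise_sd=0.1),
    ])
    subtype_shift: float = 2.0
    censor_rate: float = 0.3
    risk_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise SimConfigError("n_samples must be positive")
        if self.n_subtypes < 1:
            raise SimConfigError("n_subtypes must be positive")
        if self.n_samples < self.n_subtypes:
            raise SimConfigError("n_samples must be >= n_subtypes")
        if self.latent_dim_true < 1:
            raise SimConfigError("latent_dim_true must be positive")
        if not self.modalities:
            raise SimConfigError("modalities must be nonempty")
        names = [m.name for m in self.modalities]
        if len(set(names)) != len(names):
            raise SimConfigError("modality names must be unique")
        for m in self.modalities:
            if m.n_features < 1:
                raise SimConfigError(f"{m.name}: n_features must be positive")
            if m.kind not in (CONTINUOUS, BINARY):
                raise SimConfigError(f"{m.name}: kind must be continuous or binary")
            if m.noise_sd < 0:
                raise SimConfigError(f"{m.name}: noise_sd must be >= 0")
            if not 0.0 <= m.missing_rate <= 1.0:
                raise SimConfigError(f"{m.name}: missing_rate must be in [0, 1]")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise SimConfigError("censor_rate must be in [0, 1]")
        if self.subtype_shift < 0:
            raise SimConfigError("subtype_shift must be >= 0")


@dataclass
class GroundTruth:
    latent_factors: np.ndarray                # [n_samples, latent_dim_true]
    loading_maps: Dict[str, np.ndarray]       # name -> [latent_dim_true, n_features]
    subtype_labels: np.ndarray                # [n_samples] ints in 0..n_subtypes-1
    risk_weights: np.ndarray                  # [latent_dim_true]

    @property
    def log_risk(self) -> np.ndarray:
        return self.latent_factors @ self.risk_weights


def _streams(seed: int, n_modalities: int):
    """Independent child generators derived from one seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(4 + n_modalities)
    return {
        "latent": np.random.default_rng(children[0]),
        "loadings": np.random.default_rng(children[1]),
        "missing": np.random.default_rng(children[2]),
        "survival": np.random.default_rng(children[3]),
        "noise": [np.random.default_rng(c) for c in children[4:]],
    }


def simulate_multiomics(config: SimConfig) -> Tuple[MultiOmicsDataset, GroundTruth]:
    """Generate an aligned multi-omics dataset plus its generating ground truth.

    Samples get balanced subtype labels (shuffled), latent states
    ``subtype_mean + N(0, I)``, and per-modality observations through fixed
    random linear maps.  Missingness configured per modality is applied with
    the guarantee that every sample keeps at least one present modality.
    """
    config.validate()
    rng = _streams(config.seed, len(config.modalities))
    n, d = config.n_samples, config.latent_dim_true

    labels = np.arange(n) % config.n_subtypes
    rng["latent"].shuffle(labels)
    subtype_means = config.subtype_shift * rng["latent"].standard_normal((config.n_subtypes, d))
    latent = subtype_means[labels] + rng["latent"].standard_normal((n, d))

    sample_ids = [f"S{i:05d}" for i in range(n)]
    modalities: Dict[str, OmicsMatrix] = {}
    loadings: Dict[str, np.ndarray] = {}
    for j, spec in enumerate(config.modalities):
        load = rng["loadings"].standard_normal((d, spec.n_features)) / np.sqrt(d)
        loadings[spec.name] = load
        signal = latent @ load
        noise_rng = rng["noise"][j]
        if spec.kind == CONTINUOUS:
            values = signal + spec.noise_sd * noise_rng.standard_normal(signal.shape)
        else:
            p = 1.0 / (1.0 + np.exp(-signal))
            values = (noise_rng.random(signal.shape) < p).astype(np.float64)
        feature_ids = [f"{spec.name}_f{k}" for k in range(spec.n_features)]
        modalities[spec.name] = OmicsMatrix(spec.name, sample_ids, feature_ids, values, spec.kind)

    truth = GroundTruth(
        latent_factors=latent,
        loading_maps=loadings,
        subtype_labels=labels,
        risk_weights=config.risk_scale
        * rng["loadings"].standard_normal(d) / np.sqrt(d),
    )
    clinical = pd.DataFrame({"sample_id": sample_ids, "subtype": labels})
    dataset = MultiOmicsDataset(
        modalities=modalities,
        presence_mask=np.ones((n, len(modalities))),
        clinical=clinical,
    )
    rates = {m.name: m.missing_rate for m in config.modalities}
    if any(r > 0 for r in rates.values()):
        dataset = apply_missingness(dataset, rates, rng=rng["missing"])
    return dataset, truth


def simulate_survival(truth: GroundTruth, censor_rate: float, seed: Optional[int] = None,
                      baseline_rate: float = 0.1,
                      rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw right-censored exponential survival from the latent risk score.

    Event times are Exponential with rate ``baseline_rate * exp(log_risk)``.
    Censoring is independent of the covariates: each sample is censored with
    probability ``censor_rate``, and a censored sample's observed time is
    uniform on (0, event time).  Returns columns ``sample_id``-free
    (``time``, ``event``) aligned to the truth's sample order.
    """
    if not 0.0 <= censor_rate <= 1.0:
        raise SimConfigError("censor_rate must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(0 if seed is None else seed))
    lr = truth.log_risk
    rate = baseline_rate * np.exp(lr)
    t_event = rng.exponential(1.0 / rate)
    censored = rng.random(len(t_event)) < censor_rate
    u = rng.random(len(t_event))
    time = np.where(censored, u * t_event, t_event)
    event = (~censored).astype(int)
    return pd.DataFrame({"time": time, "event": event})


def attach_survival(dataset: MultiOmicsDataset, truth: GroundTruth,
                    censor_rate: float, seed: int = 0) -> MultiOmicsDataset:
    """Return a dataset whose clinical table includes ``time`` and ``event``."""
    surv = simulate_survival(truth, censor_rate, seed=seed)
    clinical = dataset.clinical.copy()
    clinical["time"] = surv["time"].to_numpy()
    clinical["event"] = surv["event"].to_numpy()
    return MultiOmicsDataset(dataset.modalities, dataset.presence_mask, clinical)


def apply_missingness(dataset: MultiOmicsDataset, missing_rates: Dict[str, float],
                      seed: Optional[int] = None,
                      rng: Optional[np.random.Generator] = None) -> MultiOmicsDataset:
    """Mask modalities at the given per-modality Bernoulli rates.

    Masked entries are flagged in the presence mask, never zero-filled at the
    data layer (stored rows are untouched; consumers must respect the mask).
    Every sample keeps at least one present modality: if the draw would
    remove all, one masked modality is re-opened uniformly at random.
    """
    names = dataset.modality_names
    for name, rate in missing_rates.items():
        if name not in names:
            raise SimConfigError(f"unknown modality {name!r}")
        if not 0.0 <= rate <= 1.0:
            raise SimConfigError(f"{name}: missing_rate must be in [0, 1]")
    if all(missing_rates.get(n, 0.0) >= 1.0 for n in names):
        raise SimConfigError("missing rates would leave samples with zero modalities")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(0 if seed is None else seed))
    mask = dataset.presence_mask.copy()
    for j, name in enumerate(names):
        rate = missing_rates.get(name, 0.0)
        if rate <= 0:
            continue
        drop = rng.random(dataset.n_samples) < rate
        mask[:, j] = np.where(drop, 0.0, mask[:, j])
    empty = np.flatnonzero(mask.sum(axis=1) == 0)
    for i in empty:
        candidates = [j for j, name in enumerate(names)
                      if dataset.presence_mask[i, j] == 1 and missing_rates.get(name, 0.0) < 1.0]
        if not candidates:
            raise SimConfigError(f"sample {dataset.sample_ids[i]} left with zero modalities")
        mask[i, int(rng.choice(candidates))] = 1.0
    return MultiOmicsDataset(dataset.modalities, mask, dataset.clinical)
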