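"""Scikit-learn-style estimators wrapping the fusion model.

:class:`MultiOmicsVAE` is the pretraining backbone (a transformer: ``fit``
learns the self/cross VAEs, ``transform`` returns joint sample embeddings,
``impute`` cross-reconstructs a modality).  :class:`SubtypeClassifier` and
:class:`CoxRiskFineTuner` fine-tune task heads on top of a fitted backbone.
All follow sklearn conventions (``get_params``/``set_params``, fitted
attributes with trailing underscores) so they compose with sklearn model
selection; ``X`` is a :class:`~omicsfuse.io_prep.MultiOmicsDataset` rather
than a plain array.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .core import BERNOULLI, GAUSSIAN, FusionModel, ModalitySpec
from .io_prep import BINARY, MultiOmicsDataset
from .losses import LossWeights
from .tasks import (FineTuneConfig, FreezePolicy, concordance_index,
                    finetune_classifier, finetune_survival, predict_hazard,
                    predict_logits)
from .train import TrainConfig, pretrain


def _specs_from_dataset(dataset: MultiOmicsDataset, latent_dim: int,
                        hidden_dim: int) -> List[ModalitySpec]:
    specs = []
    for name, mat in dataset.modalities.items():
        specs.append(ModalitySpec(
            name=name, input_dim=mat.n_features, latent_dim=latent_dim,
            hidden_dims=[hidden_dim],
            likelihood=BERNOULLI if mat.kind == BINARY else GAUSSIAN))
    return specs


class MultiOmicsVAE(TransformerMixin, BaseEstimator):
    """Multi-modal VAE backbone with PoE cross-modal fusion.

    Parameters mirror the pretraining recipe; ``fit`` runs masked
    adversarial/contrastive pretraining, ``transform`` yields the fixed-
    dimension joint embedding (``2 * latent_dim`` per modality) under any
    missingness pattern.
    """

    def __init__(self, latent_dim: int = 16, hidden_dim: int = 64,
                 disc_hidden: int = 64, max_epochs: int = 30,
                 batch_size: int = 64, lr_main: float = 3e-3,
                 lr_dis: float = 1e-3, patience: int = 10,
                 mask_strategy: str = "single", lr_decay: float = 0.99,
                 lambda_self: float = 1.0, lambda_cross: float = 1.0,
                 lambda_cross_elbo: float = 1.0, lambda_cross_kl: float = 0.1,
                 lambda_dis: float = 0.1, lambda_con: float = 0.1,
                 lambda_pos: float = 1.0, lambda_neg: float = 1.0,
                 tau: float = 0.5, poe_prior_expert: bool = False,
                 checkpoint_metric: str = "logme", seed: int = 0):
        self.latent_dim = latent_dim
        self.hidden_dim = hidden_dim
        self.disc_hidden = disc_hidden
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.lr_main = lr_main
        self.lr_dis = lr_dis
        self.patience = patience
        self.mask_strategy = mask_strategy
        self.lr_decay = lr_decay
        self.lambda_self = lambda_self
        self.lambda_cross = lambda_cross
        self.lambda_cross_elbo = lambda_cross_elbo
        self.lambda_cross_kl = lambda_cross_kl
        self.lambda_dis = lambda_dis
        self.lambda_con = lambda_con
        self.lambda_pos = lambda_pos
        self.lambda_neg = lambda_neg
        self.tau = tau
        self.poe_prior_expert = poe_prior_expert
        self.checkpoint_metric = checkpoint_metric
        self.seed = seed

    # -- config assembly ---------------------------------------------------
    def _weights(self) -> LossWeights:
        return LossWeights(
            lambda_self=self.lambda_self, lambda_cross=self.lambda_cross,
            lambda_cross_elbo=self.lambda_cross_elbo,
            lambda_cross_kl=self.lambda_cross_kl, lambda_dis=self.lambda_dis,
            lambda_con=self.lambda_con, lambda_pos=self.lambda_pos,
            lambda_neg=self.lambda_neg, tau=self.tau)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            max_epochs=self.max_epochs, lr_main=self.lr_main, lr_dis=self.lr_dis,
            batch_size=self.batch_size, patience=min(self.patience, self.max_epochs),
            seed=self.seed, mask_strategy=self.mask_strategy, lr_decay=self.lr_decay,
            checkpoint_metric=self.checkpoint_metric)

    def fit(self, X: MultiOmicsDataset, y=None) -> "MultiOmicsVAE":
        specs = _specs_from_dataset(X, self.latent_dim, self.hidden_dim)
        model = FusionModel(specs, disc_hidden=self.disc_hidden, seed=self.seed,
                            poe_prior_expert=self.poe_prior_expert)
        self.model_, self.history_ = pretrain(X, model, self._train_config(),
                                              self._weights())
        self.modality_names_ = list(model.order)
        self.embedding_dim_ = model.embedding_dim
        return self

    def transform(self, X: MultiOmicsDataset) -> np.ndarray:
        check_is_fitted(self, "model_")
        Xd = {k: X.modalities[k].values for k in self.modality_names_}
        return self.model_.joint_embedding(Xd, X.presence_mask).joint_embedding

    def impute(self, X: MultiOmicsDataset, target: str,
               exclude_target_as_source: bool = True) -> np.ndarray:
        """Cross-modal reconstruction of ``target`` from the other observed
        modalities (PoE posterior mean through the shared decoder)."""
        check_is_fitted(self, "model_")
        mask = X.presence_mask.copy()
        if exclude_target_as_source:
            j = self.modality_names_.index(target)
            mask[:, j] = 0.0
            if (mask.sum(axis=1) < 1).any():
                raise ValueError("some samples have no source modality for imputation")
        Xd = {k: X.modalities[k].values for k in self.modality_names_}
        fwd = self.model_.forward_batch(Xd, mask, sample=False)
        return fwd["recon_cross"][target].data


class SubtypeClassifier(ClassifierMixin, BaseEstimator):
    """MLP classification head fine-tuned on a pretrained backbone."""

    def __init__(self, backbone: Optional[MultiOmicsVAE] = None,
                 freeze: str = "full_finetune", max_epochs: int = 60,
                 lr: float = 1e-3, head_hidden: int = 32, batch_size: int = 64,
                 patience: int = 10, seed: int = 0):
        self.backbone = backbone
        self.freeze = freeze
        self.max_epochs = max_epochs
        self.lr = lr
        self.head_hidden = head_hidden
        self.batch_size = batch_size
        self.patience = patience
        self.seed = seed

    def fit(self, X: MultiOmicsDataset, y=None) -> "SubtypeClassifier":
        if self.backbone is None or not hasattr(self.backbone, "model_"):
            raise ValueError("backbone must be a fitted MultiOmicsVAE")
        labels = np.asarray(y if y is not None else X.clinical["subtype"], dtype=int)
        self.classes_ = np.unique(labels)
        self._y_index = {c: i for i, c in enumerate(self.classes_)}
        y_enc = np.array([self._y_index[c] for c in labels])
        cfg = FineTuneConfig(max_epochs=self.max_epochs, lr=self.lr,
                             head_hidden=self.head_hidden, batch_size=self.batch_size,
                             patience=self.patience, seed=self.seed)
        self.head_ = finetune_classifier(
            self.backbone.model_, X, labels=y_enc,
            policy=FreezePolicy("freeze_backbone" if self.freeze == "freeze_backbone"
                                else "full_finetune"),
            config=cfg)
        return self

    def decision_function(self, X: MultiOmicsDataset) -> np.ndarray:
        check_is_fitted(self, "head_")
        return predict_logits(self.backbone.model_, self.head_, X)

    def predict_proba(self, X: MultiOmicsDataset) -> np.ndarray:
        logits = self.decision_function(X)
        logits = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: MultiOmicsDataset) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


class CoxRiskFineTuner(BaseEstimator):
    """Scalar-hazard head fine-tuned with the Cox partial likelihood."""

    def __init__(self, backbone: Optional[MultiOmicsVAE] = None,
                 freeze: str = "full_finetune", max_epochs: int = 60,
                 lr: float = 1e-3, head_hidden: int = 32, batch_size: int = 64,
                 patience: int = 10, seed: int = 0):
        self.backbone = backbone
        self.freeze = freeze
        self.max_epochs = max_epochs
        self.lr = lr
        self.head_hidden = head_hidden
        self.batch_size = batch_size
        self.patience = patience
        self.seed = seed

    def fit(self, X: MultiOmicsDataset, y: Optional[pd.DataFrame] = None) -> "CoxRiskFineTuner":
        if self.backbone is None or not hasattr(self.backbone, "model_"):
            raise ValueError("backbone must be a fitted MultiOmicsVAE")
        records = y if y is not None else X.clinical[["time", "event"]]
        cfg = FineTuneConfig(max_epochs=self.max_epochs, lr=self.lr,
                             head_hidden=self.head_hidden, batch_size=self.batch_size,
                             patience=self.patience, seed=self.seed)
        self.head_ = finetune_survival(
            self.backbone.model_, X, records=records,
            policy=FreezePolicy("freeze_backbone" if self.freeze == "freeze_backbone"
                                else "full_finetune"),
            config=cfg)
        return self

    def predict(self, X: MultiOmicsDataset) -> np.ndarray:
        """Predicted hazard score (larger = higher risk)."""
        check_is_fitted(self, "head_")
        return predict_hazard(self.backbone.model_, self.head_, X)

    def score(self, X: MultiOmicsDataset, y: Optional[pd.DataFrame] = None) -> float:
        records = y if y is not None else X.clinical[["time", "event"]]
        return concordance_index(self.predict(X), records)
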