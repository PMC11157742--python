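# omicsfuse

Multi-omics representation learning for oncology with **missing-modality
inference**. `omicsfuse` pretrains a hybrid of self-modal and cross-modal
variational autoencoders on paired tumor omics layers (expression,
methylation, CNV, mutation status), fuses their latent posteriors with a
**product of experts (PoE)**, and fine-tunes the resulting joint embeddings
for cancer-subtype classification and Cox survival prediction, with
integrated-gradients feature attribution on top. It is aimed at
computational-oncology researchers who want a tested, fully seeded,
CPU-friendly implementation of this model family together with a synthetic
multi-omics generator whose ground truth makes every stage verifiable.

## The model

For each omics layer *k* with input **x**ₖ:

- a **self-encoder** produces a diagonal Gaussian posterior
  *q*(**z**ₖ | **x**ₖ) = N(μ, diag(δ²)), sampled via the reparameterization
  trick **z** = μ + δ ∘ ε;
- a **cross-encoder** per ordered pair (k′ → k) produces *q*(**z**ₖ | **x**ₖ′),
  and the posteriors from all observed sources are fused by the PoE product —
  precisions add, means are precision-weighted:
  Λ = Σₖ′ δₖ′⁻², μ\* = Λ⁻¹ Σₖ′ δₖ′⁻² μₖ′;
- a **shared decoder** reconstructs **x**ₖ from either latent (self or cross
  path), so a missing layer can be imputed from the observed ones;
- the fused per-modality embedding is [**z**ₖ,self ⊕ **z**ₖ,cross]
  (**z**ₖ,cross fills both slots when the layer is missing), and the
  sample-level joint embedding concatenates all modalities — its dimension is
  independent of the missingness pattern.

Pretraining minimizes
λ_self·L_self + λ_cross·(λ_ce·L_cross-elbo + λ_kl·L_cross-kl) + λ_con·L_con,
where L_self / L_cross-elbo are negated ELBOs (MSE reconstruction + KL to the
standard-normal prior), L_cross-kl aligns the cross joint posterior to the
self posterior, and L_con is a supervised contrastive term on cosine
similarities (pull within-subtype pairs together, push between-subtype pairs
apart). Per-modality discriminators (real-vs-reconstructed, and
source-modality prediction on cross reconstructions) are trained adversarially
in alternating steps. During pretraining one modality per sample is masked
uniformly at random so the cross-inference path is exercised on every batch;
checkpoints are scored with **LogME** on validation embeddings.

Fine-tuning attaches an MLP head to the joint embedding: softmax
cross-entropy for subtype classification, or a scalar hazard *h* trained with
the negative Cox log partial likelihood
−Σ_{i:Eᵢ=1} [hᵢ − log Σ_{j:Tⱼ≥Tᵢ} exp(hⱼ)] (Breslow ties) for survival,
evaluated with Harrell's C-index, median-risk stratification and the
log-rank test. Attribution uses integrated gradients
IGᵢ = (xᵢ−x′ᵢ)·∫₀¹ ∂f/∂xᵢ dα (midpoint rule), aggregated to group importance
I(g) = mean |IG_g| and per-modality signed sums.

All networks run on a small numpy reverse-mode autodiff engine included in
the package (`omicsfuse.autodiff`), gradient-checked against finite
differences — no GPU or deep-learning framework required.

## Worked example

```python
import numpy as np
from sklearn.model_selection import train_test_split
from omicsfuse import (SimConfig, ModalitySim, simulate_multiomics,
                       MultiOmicsVAE, SubtypeClassifier,
                       classification_metrics, imputation_metrics)

cfg = SimConfig(n_samples=500, n_subtypes=2, latent_dim_true=8,
                modalities=[ModalitySim("expression", 100, noise_sd=0.01),
                            ModalitySim("methylation", 80, noise_sd=0.01)],
                subtype_shift=2.0, seed=1)
dataset, truth = simulate_multiomics(cfg)
tr, te = train_test_split(np.arange(500), test_size=0.2, random_state=0,
                          stratify=truth.subtype_labels)

vae = MultiOmicsVAE(latent_dim=16, hidden_dim=64, max_epochs=50,
                    checkpoint_metric="val_loss", seed=0)
vae.fit(dataset.subset(tr))

test = dataset.subset(te)
recon = vae.impute(test, "methylation")   # from expression only
print(imputation_metrics(test.modalities["methylation"].values,
                         recon, "continuous")["r2"])
# 0.7163  -> the held-out methylation layer is reconstructed from
#            expression alone with ~72% of its variance explained

clf = SubtypeClassifier(vae, max_epochs=30, seed=0).fit(dataset.subset(tr))
y = test.clinical["subtype"].to_numpy()
print(classification_metrics(clf.predict(test), y)["f1_macro"])
# 1.0     -> held-out subtypes are perfectly recovered on this
#            well-separated simulation
```

The same pipeline is available from the shell:

```bash
omicsfuse simulate --config sim.yaml --seed 1 --out data/
omicsfuse pretrain --data data/ --max-epochs 50 --out run/
omicsfuse finetune --checkpoint run/checkpoint.npz --data data/ --task survival --out surv/
omicsfuse impute   --checkpoint run/checkpoint.npz --data data/ --target methylation --out imp/
omicsfuse interpret --checkpoint run/checkpoint.npz --data data/ --survival --out attr/
```

Every output directory contains the resolved configuration and seed, so any
artifact is reproducible from its own `run_config.json`.

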