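# Methods

## Model

`omicsfuse` implements a multi-modal variational autoencoder family for
paired tumor omics layers. Each modality *k* (dimension *d*ₖ) has a
self-encoder MLP [*d*ₖ → hidden → (μ, log σ²)] with leaky-ReLU activations,
a mirrored decoder [latent → hidden → *d*ₖ], and one cross-encoder per
ordered source modality k′ ≠ k mapping **x**ₖ′ to a posterior over *k*'s
latent space. Posterior scales are δ = exp(½ log σ²) + 1e−6 (the additive
floor guards against underflow). The decoder is shared between the self and
cross reconstruction paths, which ties the two latent spaces to a single
generative model and is what makes cross-modal imputation coherent.

Cross posteriors from observed sources are combined by the closed-form
product of diagonal Gaussians (precisions add; means precision-weighted).
No unit-Gaussian prior expert is included by default — the joint cross
posterior is the product of the marginal posteriors only — but
`poe_prior_expert=True` adds one. Two degenerate cases have fixed,
documented conventions:

* a **missing** modality's fused embedding is [z_cross, z_cross], keeping the
  concatenated joint embedding at Σₖ 2·latentₖ dimensions under every
  missingness pattern (any downstream head requires a fixed input width);
* a **present** modality with an empty cross-source set (only that modality
  observed) uses its own self posterior in the cross slot, and its
  cross-reconstruction and alignment losses are skipped for those samples.

Binary (mutation-like) modalities use a sigmoid decoder head; their
reconstruction term is the same mean-squared error as continuous modalities
by default, with cross-entropy available via the likelihood setting.

## Training objective

Per batch the generator-side loss is

L = λ_self·L_self + λ_cross·(λ_ce·L_cross-elbo + λ_kl·L_cross-kl)
  + λ_con·L_con + λ_dis·L_fool

with defaults λ_self = 1, λ_cross = 1, λ_ce = 1, λ_kl = 0.1, λ_con = 0.1,
λ_dis = 0.1, τ = 0.5, λ_pos = λ_neg = 1. Reconstruction error is a mean over
features and batch, so weights transfer across modalities of different
dimensionality. **KL scaling:** with mean-MSE reduction, a KL term summed
over latent dimensions numerically dominates and collapses the posterior
(we observed cross-modal R² ≈ −4 under the unscaled objective at desk
scale). Training therefore scales the KL-to-prior by 1/*d*ₖ and the
alignment KL by 1/latent_dim, putting all terms on the per-feature scale;
`LossWeights(normalize_kl=False)` restores the unscaled textbook form. The
standalone loss functions (`self_elbo_loss`, `cross_elbo_loss`, …) always
compute the literal unscaled quantities.

The contrastive term uses cosine similarity on the concatenated joint
embedding: L_con = [λ_pos·(1 − S̄_pos) + λ_neg·S̄_neg]/τ, where S̄_pos/S̄_neg
are mean similarities over within-/between-subtype pairs and a term with no
pairs contributes zero. Minimizing this drives within-subtype similarity to
1 and between-subtype similarity down, which is the stated intent of
subtype-supervised contrastive pretraining; τ acts as one outer scale
(a τ appearing in both a sum's numerator and its normalizing count cancels).

The adversarial pair is realized as standard alternating steps: each
discriminator (one real-vs-reconstructed binary classifier per modality,
one source-modality classifier over cross reconstructions per target)
minimizes its cross-entropy on detached reconstructions; the generators add
a non-saturating fooling term (reconstructions pushed toward the "original"
label, source predictions toward uniform). Because a PoE cross
reconstruction mixes all observed sources, the source-classification target
is the first observed source — a proxy that suffices as an adversarial
signal at the scales used here.

## Pretraining loop

Adam throughout; published defaults are kept in `TrainConfig` (main path
lr 1e−5 / weight decay 1e−4, discriminator lr 1e−4 / weight decay 5e−4,
≤100 epochs, early stopping); the per-epoch multiplicative lr decay is 0.99
(the schedule shape is otherwise unspecified, so the simplest smooth choice
was taken). Desk-scale runs raise the main learning rate (the estimator
default is 3e−3) — at lr 1e−5 a few hundred Adam steps cannot leave the
initialization basin. One stratified fold of five is held out for
validation; batches interleave subtypes so contrastive pairs exist in most
batches. Per sample, one modality index is drawn uniformly and masked (a
sample arriving with a single observed modality is left unmasked), so the
PoE inference path trains on every batch. Masked modalities contribute no
self-ELBO and are excluded from PoE source sets; their encoders receive
exactly zero gradient from those samples.

Checkpoints are scored every epoch with **LogME** — the log marginal
evidence of a Bayesian linear model from validation embeddings to one-hot
labels, maximized over its two precision hyperparameters by the standard
fixed-point iteration, averaged over classes and normalized per sample.
The best-scoring epoch's parameters are returned; ties go to the earliest
epoch. One caveat discovered on the linear-Gaussian simulation: a *random*
encoder's embeddings are already linearly label-separable there, so LogME
can peak at the first epoch and select a model that cannot reconstruct.
LogME remains the default (it targets transfer tasks, which is its purpose);
`checkpoint_metric="val_loss"` selects by the validation objective instead
and is the right choice when the goal is imputation/reconstruction quality.

## Fine-tuning

An MLP head (default one hidden layer of 32) consumes the joint embedding.
Classification minimizes softmax cross-entropy only; survival minimizes the
negative Cox log partial likelihood with Breslow tie handling and closed
risk sets R(Tᵢ) = {j : Tⱼ ≥ Tᵢ}, normalized by the batch event count so
batch size does not rescale the loss. Larger hazard means higher risk and
earlier expected event; Harrell's C-index (hazard ties 0.5) follows the
same orientation, and risk groups are split at the median hazard with
median ties assigned to the low-risk group. `FreezePolicy` either freezes
the whole backbone or fine-tunes it jointly; cross-encoders targeting
modalities absent from the entire fine-tuning dataset are always frozen to
preserve pretrained cross-modal inference. Early stopping monitors a 20%
validation split of the fine-tuning data.

## Interpretation

Integrated gradients with a midpoint Riemann rule (default 128 steps;
midpoint is O(1/steps²) accurate where the endpoint rules are O(1/steps)).
The default baseline is the zero vector per modality (feature means
available via configuration). Classification attributes the pre-softmax
logit of the chosen class (saturation-free; softmax probability behind a
flag), survival attributes the hazard score. The per-sample presence
pattern is held fixed along the integration path. Group importance is the
mean absolute IG over a sample group; modality attribution is the signed
per-sample sum within each modality, group-averaged — so modality
attributions add up to the completeness sum.

## Synthetic data

The generator emulates a paired pan-cancer corpus with known ground truth:
balanced subtype labels; latent state = subtype mean (drawn
N(0, shift²·I)) + standard-normal draw; continuous modalities = latent ×
fixed random loading (scaled 1/√d) + Gaussian noise; binary modalities =
Bernoulli(sigmoid(latent × loading)). Survival times are exponential with
rate 0.1·exp(latent·w); censoring is an independent Bernoulli(censor_rate)
indicator with censored times drawn uniform on (0, T), which hits the
requested censoring fraction exactly in expectation. Per-modality
missingness is Bernoulli with the guarantee that every sample keeps one
observed modality; masked entries are flagged in the presence mask, never
zero-filled. Separate RNG streams (latent, loadings, per-modality noise,
missingness, censoring) are spawned from one seed.

This linear-Gaussian design makes closed-form oracles available (ordinary
least squares between modalities, matrix rank, silhouette of the true
latent), which is what the test-suite asserts against. It deliberately does
**not** reproduce real TCGA marginals, batch effects, count noise, or
nonlinear inter-omics maps — passing tests demonstrate correct mechanics
and signal recovery under the generative assumptions, not performance on
real cohorts.

## Preprocessing filters

Expression: keep genes with per-feature SD strictly above 1.0 (direction
configurable — the filter is a variance-based informativeness screen).
Mutation: keep genes mutated in ≥1% of samples (inclusive). Methylation:
drop probes with beta < 0.3 in strictly more than 90% of samples. CNV: keep
segments with zero-fraction strictly below 5%, mean |log-ratio| strictly
above 0.20 and coefficient of variation (SD/|mean|; +∞ at mean zero)
strictly above 0.20. All filters preserve feature order, leave the sample
axis untouched, and are idempotent. Fold splitting is stratified by subtype
with rare classes (<k members) pooled into the largest stratum.

## Problem sizes used by the verification runs

The acceptance script and end-to-end tests run at sizes chosen to exercise
every code path on one CPU in minutes: 500 samples × (100 + 80) features
for cross-modal recovery (latent 16, hidden 64, ≤100 epochs, validation-loss
checkpointing); 1000 samples with 30% censoring for survival recovery plus
five 400-sample null-signal controls; oracle comparisons use 10–100 random
instances each (10⁶ Monte-Carlo draws for the KL check, 10⁵-point grids for
the PoE density product).

## Known limitations

* Dense numpy MLPs only; no convolutional or attention encoders, no GPU.
* The adversarial component uses a single-source proxy label for the source
  discriminator (see above).
* Harrell's C-index only (not Uno's censoring-adjusted variant); Breslow
  ties only in the Cox loss.
* The generator's linearity means high metric values here do not transfer
  claims to real cohorts; it is a correctness instrument, not a benchmark.
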