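# Methods

## Model and clustering objective

`decembr` trains predictive models of neural responses whose per-neuron
parameters — the readout weight vectors z_i ∈ R^K — are treated as
functional embeddings, and shapes those embeddings into clusters during
training. The mixture over embeddings is a J-component multivariate
Student's-t mixture with equal fixed mixing weights 1/J, per-cluster
centers μ_j, per-cluster **diagonal** scale matrices Σ_j, and a single
shared degrees-of-freedom parameter ν:

    f_TMM(z) = (1/J) Σ_j f_t(z; μ_j, Σ_j, ν)

ν defaults to 2.1, just above the ν > 2 threshold at which the component
variance ν/(ν−2)·Σ exists; the heavy tails make the E-step robust to
outlying embeddings. ν is never updated. Soft assignments q_ij are the
posterior responsibilities under equal weights; the latent scales

    u_ij = (ν + K) / (ν + (z_i − μ_j)ᵀ Σ_j⁻¹ (z_i − μ_j))

are the posterior means of the Gamma variable in the shape–rate
representation f_t = ∫ N(z; μ, Σ/u)·Gamma(u; ν/2, ν/2) du, which is also
how the synthetic generator draws exact t-mixture samples.

The clustering loss is the KL divergence between the sharpened target P
and Q, Σ_ij p_ij log(p_ij/q_ij) with p_ij ∝ q_ij²/f_j and f_j = Σ_i q_ij.
P is recomputed every batch and treated as a constant (stop-gradient):
differentiating through the target destabilizes self-training. Gradients
with respect to the embeddings flow only through Q; cluster parameters
receive no gradients at all — they are updated purely by EM.

## Training loop

1. **Pretraining** — the predictive model is trained on its own loss for m
   epochs (MSE for the linear toy model; Poisson loss `(1/N) Σ (r̂ − r log r̂)`
   plus a small L2 penalty (1e-4) on readout weights for the core–readout
   model). The L2 penalty is a deliberately plain regularizer for the
   readout weights.
2. **Initialization** — k-means (10 restarts, seeded, best inertia) on the
   pretrained embeddings gives the centers; the per-dimension within-cluster
   variances give the scale diagonals.
3. **Joint loop** — per minibatch: E-step over all N embeddings, M-step
   over all N embeddings (the closed-form weighted-mean and weighted-scatter
   updates, the scale update using the freshly updated center), then one
   gradient step on `w_model·L_model(batch) + β·L_cluster`. The E/M steps
   run over the full population because embeddings exist for every neuron
   regardless of which stimuli are in the batch.

The optimizer is Adam (NumPy implementation; gradients of the conv core,
bilinear readout and losses are derived analytically and verified against
finite differences in the test suite). Each training phase gets a fresh
optimizer instance, and minibatch shuffles are drawn from streams named by
the absolute epoch index — so a β = 0 joint phase is bit-identical to
continued pretraining over the same epochs. A plateau scheduler halves the
learning rate when the validation loss stalls (patience 5), with optional
early stopping (patience 10, used for the synthetic population runs).

β is either fixed or chosen once at clustering start as
`10^round(log10(|L_model| / L_cluster))` — the order of magnitude that puts
the weighted clustering loss on the scale of the model loss. The magnitude
is used because the Poisson loss can be negative at small scale. If the
clustering loss is zero or infinite at initialization the configured
fallback is used with a warning.

### Numerical choices

- All densities and responsibilities in log space; Q and P are normalized
  by one shared max-subtracted softmax path, so in the exactly-degenerate
  configuration (all centers and scales identical) Q and P are bitwise
  equal and the KL loss is exactly zero.
- Scale diagonals are clamped from below at `clamp_floor` (default 1e-6,
  matching the covariance regularization of the GMM baseline): in high
  dimensions the M-step can otherwise produce vanishing variances and
  ill-conditioned densities. The clamp is a heuristic stability device.
- KL is clamped at ≥ 0 (Gibbs' inequality; rounding can otherwise produce
  −1e-45-scale values when P ≈ Q).
- A cluster whose total responsibility falls below 1e-8·N has its center
  re-seeded at the worst-explained embedding, with a warning.
- MAP ties break toward the lowest cluster index.
- Readout positions are clipped into [−1, 1]² after every update;
  bilinear interpolation at exact grid nodes returns the node value.

## The unit-scale ablation (collapse demonstration)

`dec_unit_scale_fit` reproduces the failure mode that motivates the
adaptive scales. It runs the same loop with the soft-assignment kernel
fixed at unit scale (t-kernel with ν = 1) and center updates that are the
plain responsibility-weighted means of all embeddings (the center update
with the latent scales frozen at 1); the scale matrices are never adapted.
The *only* difference from the full method is therefore the learned scale.
When two tight clusters sit closer together than the unit kernel can
resolve, the q's drift toward uniform, each weighted mean moves toward the
global mean, and the centers merge — the degenerate KL = 0 optimum
(uniform Q and P) is an absorbing state. On the toy population the centers
merge within ~20 iterations.

We found that *gradient-descent* center updates on this KL objective do
not reach the degenerate optimum from a k-means initialization on this toy
(the cross-cluster terms of the gradient repel the centers; we verified
this with finite-difference gradients for both KL directions, with and
without target sharpening, and with gradients flowing through P). The
weighted-mean form above is the formulation of the ablation under which
the collapse is an intrinsic property of the fixed unit scale, which is
the scientific point being demonstrated.

## Synthetic data

**Toy linear population** (defaults): 8000 stimuli uniform on (−1,1)³⁰;
2500 linear neurons y_i = z_iᵀx in two groups — 2000 with
z = 1 + U(−1/300, 1/300) per coordinate and 500 with z = 1.5 + U(−1/120,
1/120); responses are noise-free (the response law is exactly the inner
product), and all fields are overridable. The toy protocol pretrains 25
epochs (Adam, lr 0.01, batch 256) and then optimizes **only** the
clustering KL loss for 25 more with J = 2. Training uses all stimuli, with
the trailing 10% also monitored for validation. Expected outcome: MAP
cluster sizes 2000/500 and learned center norms √30 ≈ 5.477 and
√(30·1.5²) ≈ 8.216.

**Planted-cluster Poisson population**: N = 300 neurons with true readout
weights drawn from 3 planted clusters in R⁸ (centers separated by 4
within-cluster spreads of 0.15), receptive-field positions uniform in
[−1,1]², rates from a fixed randomly-initialized convolutional core applied
to 1000 white-noise 16×16 images. The per-neuron drive is standardized to
std 2 before the softplus and the rates normalized to a mean of 2
spikes/image, so every neuron is strongly stimulus-modulated; responses
are Poisson counts. These sizes were chosen for single-CPU scale.

Trained models initialize their readout positions at the stored
receptive-field positions plus Gaussian jitter of 0.05 (a "retinotopic
estimate", as real pipelines derive from a separate RF-mapping scan);
positions remain learnable. Without an informed initialization the
position search dominates the optimization at this scale and no embedding
structure is recoverable within a desk-scale budget.

The consistency protocol mirrors the evaluation design for real data: per
model seed, a baseline model is trained to convergence on the Poisson loss
alone (80 epochs, Adam lr 0.01, batch 32, early stopping patience 10) — its
embeddings feed the GMM baseline and its held-out correlation is the β = 0
reference — and the joint clustering phase then *continues* training that
converged model for up to 30 more epochs. The clustering strength is chosen
once per dataset: the order-of-magnitude rule proposes β in the 10–100
range here, and β = 10 is the largest value that leaves validation
correlation essentially unchanged, which is the selection criterion; larger
β trades correlation for sharper clusters. Only the model seed varies
across the three runs entering the cross-seed ARI.

What the generators do **not** emulate: calcium-imaging noise and
temporal dynamics, behavioral covariates, overdispersion beyond Poisson,
eye movements, and realistic cortical receptive-field structure. Passing
tests on these data show that the algorithm does what it claims on data
matching its own assumptions — not that mouse V1 has (or lacks) functional
cell types.

## Evaluation

- **ARI** — chance-corrected pair-counting agreement; cross-seed
  consistency is the mean pairwise ARI over models differing only in seed.
- **Baselines** — diagonal-covariance GMM with 1e-6 covariance floor and a
  fixed clustering seed, fitted on the converged β = 0 model's embeddings;
  k-means with a single seeded initialization (so its initialization
  sensitivity is surfaced, not averaged away).
- **Hungarian alignment** for confusion matrices.
- **Performance** — per-neuron Pearson correlation between predicted and
  observed responses across held-out images, averaged over neurons;
  constant neurons are excluded with a warning rather than zero-filled.
- **t-SNE** (figures only): perplexity N/100, learning rate 1, early
  exaggeration N/10.

## Known limitations

- J must be chosen in advance; no model-selection machinery is provided.
- The scale clamp is heuristic; very high-dimensional embeddings with few
  neurons will overfit Σ_j.
- The miniature two-layer core is a stand-in exposing an H×W×K feature
  space; it is far smaller than production cores, and conclusions about
  full-scale models' predictive performance do not transfer.
- With ν = 2.1 the t-mixture's tails are heavy enough that even the
  Bayes-optimal assignment mislabels a noticeable fraction of points
  unless clusters are separated by tens of scale units; MAP-vs-truth ARI
  on t-mixture draws is bounded accordingly.
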