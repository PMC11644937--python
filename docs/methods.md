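# Methods

This note records the modelling choices behind `ehrsynth`: what is assumed,
what is configurable, what the synthetic cohort does and does not emulate,
and where the design was genuinely open.

## Data representation

A table is *k* continuous plus *l* categorical columns. Continuous columns
are rarely Gaussian in clinical data — they are multimodal (HbA1c splits
into non-diabetic and diabetic modes) or heavy-tailed (calcium scores) — so
min–max or z-scoring misrepresents them. Instead each continuous column is
fitted with a Bayesian Gaussian mixture (`sklearn.mixture.
BayesianGaussianMixture`: up to `max_modes = 10` components, Dirichlet
weight-concentration prior `1/max_modes`, one initialization, at most 500
iterations, tolerance 1e-3, seeded). Components with posterior weight below
`1e-3` are pruned and the weights renormalized; the Bayesian prior shrinks
unused components toward zero, so the retained count adapts to the data. A
constant column degenerates to a single component with standard deviation
pinned at the floor `σ_floor = 1e-6`.

Each cell is standardized by its most responsible component (argmax of the
responsibilities, ties to the lowest index) and clipped to ±0.99. With a
single-σ denominator the clip binds for roughly a third of the draws from
any one component; this truncation is accepted as the price of a bounded
network range, and all round-trip guarantees are stated for unclipped
cells. The flat row fed to the critic is `[v, onehot(mode)]` per continuous
column plus categorical one-hots — the *hard* mode assignment, with the
soft responsibility vector retained alongside in `TransformedTable` for
inspection. The soft-posterior alternative (feeding responsibilities
instead of the one-hot) is a documented open alternative, not implemented
as the default, because the hard assignment is what makes inversion exact.

Categorical vocabularies are sorted lexicographically rather than by first
appearance so one-hot layouts are reproducible across runs and machines.
Missing values are an error by default; rows can be dropped upstream, but
no imputation is attempted.

## Networks

*Generator.* The noise vector (z_dim = 128) is sliced evenly across k
continuous sub-networks and one categorical trunk. A continuous sub-network
sees `[z-slice ‖ onehot(k) ‖ (μ_k, σ_k)]` with (μ_k, σ_k) standardized by
the column's overall mixture mean/std (computed from the metadata, not the
data); two dense layers of width 64 with LeakyReLU(0.2), batch
normalization and dropout 0.2 feed a 0.99·tanh head. Conditioning by
concatenation was chosen over additive noise modification because it is the
simplest differentiable mechanism that exposes the component identity and
scale to the network; it is a config point, not a claim of equivalence to
any other scheme. The categorical trunk embeds each column's sampled class
(embedding dim `min(8, n_classes)`), concatenates with the noise slice,
and applies dense(64)/ReLU/batch-norm/dropout/dense(64) before per-column
softmax heads. Class indices are sampled from the empirical training
frequencies; a learned free token was the alternative and was not taken,
to keep rare-class frequencies anchored to the data.

*Critic.* Minibatch discrimination (16 kernels of dimension 8) is applied
first, appending to each row its summed exp(−L1) similarity to the rest of
the batch in learned projections — a collapsed batch produces conspicuous
similarity statistics the critic can exploit. Then dense layers of widths
256 and 128, each spectrally normalized, with LeakyReLU(0.2), batch
normalization and dropout 0.3, and a final spectrally-normalized linear
scalar head with no activation. Scores are oriented so that *higher means
more likely synthetic*; both losses are written against this convention.
Batch normalization inside a spectrally-normalized critic weakens the
Lipschitz bound; it is kept as the default architecture but can be disabled
with `CriticSpec(batchnorm=False)`.

*Spectral normalization.* One power iteration per training forward with a
persistent left-iterate `u` per layer (five at evaluation). The estimate
σ̂ = uᵀWv enters the autodiff graph, so gradients flow through the
normalization. Power iteration converges geometrically at rate
(σ₂/σ₁)²; tests therefore check the σ = 1 ± 1e-3 contract on the converged
state, after repeated iterations, not after a single call on a fresh
matrix.

## Training

Wasserstein loss by default: the critic minimizes mean D(real) − mean
D(fake), the generator minimizes mean D(fake). This avoids the saturation
of a cross-entropy critic; the Lipschitz constraint comes from spectral
normalization alone (no gradient penalty). The binary-cross-entropy mode
passes the score through a logistic link with label 1 = real and uses the
non-saturating generator objective.

Defaults: Adam with learning rate 2e-4 and betas (0.5, 0.9); batch size 32;
one critic step per generator step; 300 epochs. None of these is
sacrosanct; they are declared defaults chosen as typical for adversarial
training at this scale (a few thousand optimizer steps on a 218-row
table). Real batches are drawn without replacement per epoch; any trailing
batch of fewer than two rows is skipped because minibatch discrimination
is undefined for a single row. Conditions are re-sampled fresh for every
batch. A single master seed fans out via `numpy.random.SeedSequence` into
named streams (mixture fit, parameter init, condition sampling, noise,
batching, dropout), so a run is reproducible bit for bit. Non-finite
training statistics abort the run rather than silently continuing.

The networks run on the package's own reverse-mode autodiff engine over
numpy (`ehrsynth.nn`): the model sizes involved (dense widths ≤ 256,
batches of 32) make framework overheads irrelevant, and the engine keeps
the dependency surface to the scientific Python stack. Every custom
operator — including the minibatch-similarity kernel and the
spectral-normalization path — is gradient-checked against central finite
differences in the test suite.

## Evaluation

KS statistics are computed on raw (untransformed) values via
`scipy.stats.ks_2samp`, whose statistic is exactly the supremum gap between
the two empirical CDFs evaluated at the pooled points; the tests verify
this against a brute-force double-ECDF oracle. The Jaccard coefficient
compares the *sets* of observed categories (so it measures coverage of the
vocabulary, not frequency agreement; the frequency comparison lives in the
exported count CSVs). The correlation preservation rate — share of
continuous pairs with |r_real − r_synth| ≤ τ, default τ = 0.1, τ always
reported — is this package's own construction; published "preservation"
percentages computed under unknown definitions are not comparable to it
numerically. Constant columns are excluded from correlation analysis with
a warning.

## The synthetic reference cohort

The generator emulates a restricted cardiovascular cohort's *schema and
qualitative shape*, never its values: 218 records by default, an exact
round(0.766·n) male count, ages drawn from a two-component mixture
truncated strictly above 30 years, height drawn by sex, weight linear in
height plus residual, BMI computed as WT/(HT/100)² (never drawn), bimodal
HbA1c (5.6 ± 0.35 vs 8.6 ± 1.2 %), log-normal LDL with total cholesterol
as LDL plus a non-LDL offset, follow-up measurements built from baseline
deviations scaled for a target correlation of 0.6, a 40% zero-inflated
log-normal calcium score, three ordered kidney-function classes, and
binary diagnoses with prevalences from 7% (rheumatoid arthritis, prior
stroke ~8%) to 72% (hypertension). Units: years, kg, cm, mmHg, mmol/L, %.

All parameters are invented and recorded in `CohortGroundTruth`; analytic
marginal means are stored where tractable (including the truncation
correction for age) and set to `None` for nonlinearly derived columns,
which the moment-recovery tests then skip. What passing tests on this
cohort demonstrate is that the pipeline handles multimodality, heavy
tails, class imbalance and baseline/follow-up dependence; they say nothing
about fidelity to the real hospital population, and no clinical claim
should be hung on the cohort's numbers.

## Problem sizes and numerical choices

The adversarial end-to-end check trains 300 epochs at batch size 32 on the
218-row cohort for three seeds and requires the median trained mean-KS to
beat the untrained generator's — an improvement-over-initialization
criterion that is robust to the stochasticity of GAN training. Typical
results: untrained mean KS ≈ 0.31–0.33, trained ≈ 0.17–0.19. Mixture
recovery is checked at n = 1000 with 5σ-separated components, the scale at
which a Bayesian mixture's posterior is decisive. Ties in any argmax break
to the lowest index. BCE probabilities are clamped at ε = 1e-7.

## Known limitations

- The clip at ±0.99σ truncates within-component tails; extreme values of a
  component are not reproducible by construction.
- Correlation *between* columns is learned only implicitly through the
  critic; there is no explicit dependence objective, and pairwise
  preservation is accordingly the weakest metric (≈ 60% of pairs within
  ±0.1 on the worked example).
- The Jaccard metric is insensitive to frequency distortion within the
  observed category set.
- Training-by-sampling over discrete columns (conditioning the *real*
  batch on the sampled category) is deliberately out of scope; rare-class
  fidelity relies on empirical-frequency condition sampling alone.
- Single-threaded CPU training only; the intended scale is hundreds to a
  few thousand rows.
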