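# Methods

## Problem setting

`jointomics` learns a joint low-dimensional representation of paired
multi-omics measurements: N samples (bulk tumors or single cells), each
observed in M modalities — gene expression, DNA methylation, copy number,
chromatin accessibility, surface protein counts — with the m-th modality a
vector x_i^m of length D_m. The joint latent vector z_i in R^d (d = 32 by
default) should carry the information shared by the modalities; the package
then evaluates how useful that latent space is for cross-modal imputation,
coherent generation, and downstream classification.

## Observation models

Each modality declares a likelihood family through its `ModalitySpec`; the
likelihood factorizes over features, and every reconstruction or imputation
score is the feature-averaged log-likelihood

    LL(x_i^m, z_i) = (1/D_m) * sum_j log p(x_ij^m | z_i),

so modalities of different dimensionality contribute on the same scale.

| family          | use case                    | parameterization |
|-----------------|-----------------------------|------------------|
| gaussian        | standardized expression     | mean; sd fixed to 1 (per-feature sd optional) |
| bernoulli       | binarized ATAC peaks        | probability via squashed sigmoid |
| categorical     | 5-level copy-number calls   | per-feature softmax over K levels |
| beta            | methylation beta values     | (mean, concentration); a = mean*conc, b = (1-mean)*conc |
| negbin          | RNA counts                  | mean–dispersion form; dispersion phi per FEATURE, shared across samples, optimized with the network weights |
| negbin_mixture  | ADT protein counts          | background NB(mu, phi) + foreground NB(alpha*mu, phi), alpha > 1 via 1 + softplus, per-cell mixing pi via sigmoid; mu and phi are free per-feature parameters, alpha and pi are decoder outputs |

Numerical guards: beta observations must be pre-clipped into (0,1) with
`clip_beta_values` (0 -> eps, 1 -> 1-eps, eps = 1e-6 by default); decoder
probabilities are squashed into (1e-6, 1-1e-6); posterior scales and
dispersions get softplus links with a 1e-4 floor; the NB mixture is
evaluated in log-space via log-add-exp. The categorical log-mass is computed
as `sum(onehot * log(probs + (1 - onehot)))`, which tolerates exact zeros in
unselected cells.

## Model zoo

All five flavors share diagonal-Gaussian (Laplace for MoE) posteriors
q(z|x) = N(mu(x), diag(sigma(x)^2)) produced by MLP encoders, and one MLP
decoder per modality. Losses per sample:

- **ccVAE** (early integration): one encoder on the concatenation;
  loss = -sum_m LL(x^m, z) + KL(q(z|x) || p(z)), one reparameterized draw.
  A missing modality is zero-filled in the featurized input at encode time.
- **CGVAE** (cross-generating): per-modality encoders; all M x M
  (encoder draw, decoder) reconstruction terms, per-modality KL terms, and a
  squared 2-Wasserstein coupling W2^2(q_m, q_n) = sum_j (mu_mj-mu_nj)^2 +
  (sigma_mj-sigma_nj)^2 over all pairs. The squared form is used because it
  is differentiable everywhere.
- **PoE** (product of experts): unimodal posteriors fused with the prior by
  precision weighting (closed form for diagonal Gaussians). Training draws
  from each unimodal posterior and from the fused posterior, decodes every
  draw with every decoder, and adds the KL of each used posterior (equal
  weighting of the unimodal and joint terms).
- **MoE** (mixture of experts): Laplace posteriors and prior. For each
  component m, a single reparameterized draw scores
  sum_n LL(x^n, z_m) + log p(z_m) - log q_mix(z_m) with
  q_mix = (1/M) sum q_m; the loss is the negative component average. The
  DReG estimator (default) detaches the mixture density's parameters while
  keeping the path through z — with one importance draw this is exactly the
  doubly-reparameterized gradient, identical in value to the plain pathwise
  estimator and lower-variance in the posterior parameters (verified in the
  test suite). Laplace KL to Laplace(0,1) is closed-form per dimension:
  |mu| + b*exp(-|mu|/b) - log b - 1.
- **refvae** (reference encoder): one encoder on a designated reference
  modality, one decoder per modality; reconstruction + KL. Only the
  reference can be encoded; encoding any other modality raises a capability
  error, and imputation toward the reference from another modality is
  therefore impossible.

Multi-modality encoding conventions at inference: PoE uses the precision
product; ccVAE its single encoder; CGVAE averages per-modality posterior
locations and scales (configurable to a PoE-style product) since the W2 term
already drives the posteriors together; MoE returns the moment-matched
(mean/variance) Laplace of the uniform mixture. Imputation always pushes the
posterior MEAN (never a draw) through the target decoder, so it is a
deterministic function of (model, data).

## Training

Adam (lr 1e-3, batch 128 by default), one reparameterized draw per loss term
per step, early stopping on a per-epoch validation loss computed with a
seed-derived deterministic draw; the parameters of the epoch with the lowest
validation loss are restored. All randomness (initialization, shuffling,
draws) derives from `NetworkConfig.seed` through spawned `SeedSequence`s, so
train -> encode -> impute is bitwise reproducible. Decoder output biases and
NB dispersions are warm-started from per-feature training moments (count
decoders start near the marginal means), which substantially shortens the
burn-in of the count models. A small validation-loss grid over depth
(0–3 hidden layers) x dropout {0, 0.2} x batch-norm {on, off} is available
as `grid_search`.

Because no GPU framework is assumed, the package ships a minimal
vectorized reverse-mode autodiff engine (`jointomics.autodiff`) over numpy
float64 arrays; all five losses pass central finite-difference gradient
checks at 1e-4 relative tolerance, and the engine also drives the GLM
fitting below.

## Linear baselines

- `pca_fit_transform`: top-k principal components (k = 32 to match the
  latent dimension), deterministic sign convention (largest-|loading|
  element positive).
- `glm_fit`: family-appropriate GLM with canonical links
  (identity / logit / softmax / logit-mean / log-mean), fitted by L-BFGS on
  the autodiff gradient of the ridge-penalized mean log-likelihood
  (default ridge 1e-4, configurable to 0; intercepts unpenalized and
  warm-started at the marginal fit). NB dispersions enter the same objective
  as log-phi parameters. The recorded log-likelihood trace is monotone.
- `oos_extension`: wraps ANY externally computed factor matrix Z (e.g. from
  a linear factor-analysis tool) with OLS encode maps (per modality and for
  the concatenation) and GLM decode maps, giving it the same encode/impute
  interface as the VAEs.
- Baseline imputers: `GLMImputer` (direct source-to-target regression, no
  latent space) and `MeanImputer` (per-feature training statistics,
  method-of-moments for beta/NB).

## Evaluation

- **Imputation** (`imputation_eval`): per-test-sample feature-averaged
  log-likelihood of the held-out modality given the imputed parameters;
  samples further than 1.5 x IQR from the MEDIAN are flagged as outliers
  (the rule is deliberately median-centred; the factor and centring are
  configurable).
- **Paired tests**: two-sided Wilcoxon signed-rank per method-vs-baseline
  comparison, Holm step-down adjustment across the methods of one
  source->target task.
- **Generation coherence** (`coherence_eval`): n = 2000 draws from the
  prior, each decoded by every decoder; decoded parameters collapse to point
  profiles (gaussian/beta mean, bernoulli probability, categorical argmax
  level, NB mean, mixture mean (1-pi)mu + pi*alpha*mu); independently
  trained per-modality classifiers (two-layer perceptrons on featurized
  profiles, epoch chosen on validation loss, held-out accuracy reported so
  unusable classifiers can be rejected) predict a class for each decoding;
  coherence is the fraction of draws on which all classifiers agree.
- **Downstream classification** (`downstream_classify`): linear SVM with the
  L2 weight selected on validation MCC over
  {1e-4, 1e-3, 0.01, 0.1, 0.5, 1, 2, 5, 10, 20}, or an MLP with 64 hidden
  units, lr 1e-4, 150 epochs, best epoch on validation loss. Reported: test
  MCC, 95% percentile CI from 100 bootstrap resamples of the test samples,
  and per-class F1 over classes present in the test split.
- **Impute-then-classify** (`impute_then_classify`): the missing modality is
  imputed as its decoder point profile, both modalities are projected onto
  32-component PCA maps fitted on training data, concatenated and fed to the
  multimodal classifier; agreement is the fraction of test samples receiving
  the same class as with both modalities measured.

## Joint-signal factor test

For models that can encode each modality separately, each latent coordinate
j is tested per modality m: the KSG k-nearest-neighbour estimator (k = 3,
via scikit-learn's `mutual_info_regression`) measures MI between coordinate
j of the joint embedding posterior means and coordinate j of the
single-modality posterior means. A permutation null (shuffling the sample
pairing, default 1000 permutations; p = (1 + #exceedances)/(1 + n_perm)) and
Holm adjustment across factors within each modality yield significance
calls; a factor is **joint** if significant for all modalities,
**specific:<modality>** if for exactly one, **uninformative** if for none.
MI is deliberately defined between 1-D embedding coordinates (not between a
factor and the raw high-dimensional modality): it keeps the test applicable
exactly to encoders that embed each modality separately and makes the
permutation null cheap. Note the arithmetic constraint
(1 + n_perm) > n_factors / alpha for Holm to be able to reject at all;
n_perm = 199 supports up to 9 factors at alpha = 0.05.

## Synthetic data

The generator plants a latent matrix with three kinds of blocks: shared
factors drawn around per-class centers (class structure lives ONLY in the
shared block, so cross-modal classification and coherence are achievable by
construction), per-modality specific factors, and optional uninformative
factors that load on nothing. Factor-to-parameter maps are linear or pass
through one tanh layer (`nonlinearity="tanh"`), and observations are drawn
per family (NB via gamma–Poisson with per-feature lognormal base means and
uniform dispersions in (0.5, 2); the ADT-like mixture uses lognormal
background means around 20, a Bernoulli(0.5) foreground indicator and
alpha = 1 + exp(0.5 * clipped eta)). Defaults: class-center spread 2
(3 for the well-separated `gaussian-pair` preset), loading scale 1, beta
concentration 10. An 80/10/10 class-stratified split (largest-remainder
rounding) is attached. Presets: `gaussian-pair`, `tcga-like` (gaussian +
beta + categorical), `citeseq-like` (NB + NB mixture), `atac-like`
(NB + bernoulli).

`planted_factor_benchmark` additionally returns the factor answer key and a
reference linear embedding whose per-modality encoders recover exactly the
factor blocks visible to that modality. The obvious alternative — OLS of the
full factor matrix on each modality — is wrong for this purpose: both
modalities would fit the same in-sample noise of unloaded factors, their
encodings would correlate spuriously, and uninformative factors would test
as joint. The visible-block construction avoids that leak and is what the
factor-recovery checks use.

What the generator does NOT emulate: library-size variation and batch
effects, gene–gene correlation beyond the low-rank structure, zero
inflation, realistic marginal shapes of real TCGA/CITE-seq data. Passing
tests therefore certify the algorithms and their orderings under controlled
low-rank conditions, not performance on any real dataset.

## Problem sizes used in the checks

The bundled test-suite and acceptance-script runs use scaled-down study
conditions chosen to keep a CPU-only run comfortable: the nonlinear count
benchmark trains on 2000 samples (script: 1200) with 16 latent dimensions
and one 64-unit hidden layer for up to 150 epochs; classification checks use
the 2000-sample gaussian pair and coherence the 2000-sample (script:
1200-sample) gaussian pair; factor recovery uses 8 planted factors with 199
permutations. These sizes
are the package's own defaults for its synthetic benchmarks.

## Known limitations

- MoE importance weighting uses one draw per component (K = 1); the IWAE
  tightening for K > 1 is not implemented.
- The gaussian likelihood defaults to fixed unit variance (inputs are
  assumed standardized); a learned per-feature sd is available via
  `learn_gaussian_sd` but not exercised by the benchmarks.
- `oos_extension` assumes the external factorization is row-aligned with
  the train split and linear; no shrinkage beyond ridge is applied.
- Survival analysis, marker-gene derivation, genome-annotation-driven
  feature grouping and wall-clock scalability benchmarking are out of scope.
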