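# jointomics

Joint-embedding variational autoencoders for **paired multi-omics**, with the
modality-appropriate likelihoods, linear baselines and evaluation suite needed
to compare them fairly.

Paired multi-omics experiments measure several modalities — gene expression,
DNA methylation, copy number, chromatin accessibility, surface proteins — on
the same samples or cells. A *joint embedding* maps every modality of sample
i into one latent vector z_i in R^d that carries their shared signal. This
package implements five VAE-style architectures over a common interface:

| flavor   | idea |
|----------|------|
| `ccvae`  | early integration: one encoder on the concatenated modalities (zero-fill at encode time when one is missing) |
| `cgvae`  | per-modality encoders cross-reconstructing every modality, with a squared 2-Wasserstein penalty pulling the posteriors together |
| `poe`    | product of experts: precision-weighted fusion of per-modality Gaussian posteriors with the prior |
| `moe`    | mixture of experts with Laplace latents and the DReG gradient estimator |
| `refvae` | single encoder on a designated reference modality, one decoder per modality |

Each modality declares its observation model: gaussian (standardized
expression), bernoulli (binarized ATAC), 5-level categorical (copy-number
calls), beta (methylation, with boundary clipping), negative binomial with
per-feature dispersion (RNA counts), or a two-component NB mixture
(background + alpha-fold foreground) for protein counts. The reconstruction
and imputation score everywhere is the feature-averaged log-likelihood
LL(x^m, z) = (1/D_m) Σ_j log p(x^m_j | z).

Around the models: PCA / GLM / train-mean baselines (including an
out-of-sample wrapper for externally computed linear factorizations),
cross-modal imputation scoring with Wilcoxon + Holm statistics, generation
coherence, SVM/MLP downstream classification with bootstrap CIs,
impute-then-classify agreement, and a mutual-information test labeling each
latent factor joint / modality-specific / uninformative. A synthetic
generator with planted shared and specific factors makes the whole pipeline
testable without downloads. Details: [docs/methods.md](docs/methods.md).

Training runs on a small bundled numpy autodiff engine — no GPU framework
required; CPU minutes suffice for the bundled benchmarks.

## Worked example

```python
import numpy as np
from jointomics import (NetworkConfig, generate, preset_config, train,
                        GLMImputer, imputation_eval, paired_test)

# paired RNA (negative binomial) + protein (NB mixture) with 6 cell classes
cfg = preset_config("citeseq-like", n_samples=2000, seed=0)
cfg.nonlinearity = "tanh"            # nonlinear factor-to-parameter maps
dataset, truth = generate(cfg)

model = train("poe", dataset, NetworkConfig(latent_dim=16, hidden_layers=[64],
                                            max_epochs=150, seed=100))
print(model.summary())

glm = GLMImputer.fit(dataset)        # direct regression baseline
r_poe = imputation_eval(model, dataset, source=[0], target=1)  # ADT from RNA
r_glm = imputation_eval(glm,   dataset, source=[0], target=1)
print(f"median LL  poe: {r_poe.median:.3f}   glm: {r_glm.median:.3f}")
print(f"wilcoxon p = {paired_test(r_poe.ll, r_glm.ll):.2e}")
```

Output from this exact run:

```
Joint embedding results
=======================
flavor:            poe
modalities:        rna(negbin, D=300), adt(negbin_mixture, D=40)
latent dim:        16 (gaussian)
hidden layers:     [64]
parameters:        53304
epochs run:        150
best epoch:        149
best val loss:     24.243023
median LL  poe: -4.188   glm: -4.335
wilcoxon p = 1.62e-30
```

The median per-cell log-likelihood of the held-out protein profiles is
higher (better) for the product-of-experts model than for the GLM baseline,
and the paired Wilcoxon test says the per-cell differences are systematic —
on this nonlinear synthetic benchmark the latent-space imputation beats
direct linear regression.

The same objects drive the rest of the suite: `model.encode(...)` /
`model.impute(...)` / `model.sample_prior_decode(...)`,
`coherence_eval`, `downstream_classify`, `impute_then_classify`,
`classify_factors`. A command-line interface wraps the pipeline:

```sh
jointomics simulate --preset citeseq-like --n 2000 --seed 0 --out data/
jointomics train --data data/ --flavor poe --seed 1 --out poe.npz
jointomics evaluate impute --ckpt poe.npz --data data/ --source 0 --target 1 --seed 1
jointomics run --config run.yaml --out results/   # full pipeline from YAML
```

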