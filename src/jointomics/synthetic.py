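"""Synthetic paired multi-omics generator with planted latent structure.

Samples carry a latent vector split into blocks: SHARED factors (drawn
around per-class centers, so all class signal is cross-modal by
construction), per-modality SPECIFIC factors (independent standard normals)
and optional UNINFORMATIVE factors that load on nothing.  Each modality maps
its visible factors (shared + own specific block) through a linear — or
one-tanh-layer — map to natural parameters, then samples observations from
its declared likelihood family:

==================  ======================================================
gaussian            x = eta + N(0, 1)
bernoulli           x ~ Bern(sigmoid(eta))
categorical         x ~ Cat(softmax over K per-feature logit channels)
beta                x ~ Beta(mean=sigmoid(eta), concentration fixed), clipped
negbin              x ~ NB(mu = base_mean * exp(0.7 * clip(eta)), phi per feature)
negbin_mixture      x ~ (1-F) NB(mu, phi) + F NB(alpha mu, phi),
                    alpha = 1 + exp(0.5 * clip(eta)), F ~ Bern(foreground rate)
==================  ======================================================

Conditional on the latent vector the modalities are independent; cross-modal
dependence flows only through the shared block.  Everything is deterministic
given the seed, and an 80/10/10 class-stratified split is attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, softmax

from .data import (
    ModalitySpec,
    MultiOmicsDataset,
    clip_beta_values,
    make_split,
)

PRESETS = ("gaussian-pair", "tcga-like", "citeseq-like", "atac-like")


@dataclass
class SyntheticConfig:
    """Conditions for one simulated paired dataset.

    ``modalities`` lists (name, dim, family) triples.  ``class_spread`` is the
    standard deviation of class centers in the shared block; ``loading_scale``
    scales the factor-to-natural-parameter maps.
    """

    n_samples: int = 1000
    n_classes: int = 4
    n_shared: int = 4
    n_specific: int = 2
    n_uninformative: int = 0
    modalities: list = field(default_factory=lambda: [("mod1", 100, "gaussian"),
                                                      ("mod2", 80, "gaussian")])
    class_spread: float = 2.0
    loading_scale: float = 1.0
    dispersion_range: tuple = (0.5, 2.0)
    foreground_rate: float = 0.5
    beta_concentration: float = 10.0
    nonlinearity: str = "none"  # 'none' | 'tanh'
    fractions: tuple = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if self.n_shared < 1 or self.n_specific < 0 or self.n_uninformative < 0:
            raise ValueError("need n_shared >= 1 and nonnegative block sizes")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.nonlinearity not in ("none", "tanh"):
            raise ValueError("nonlinearity must be 'none' or 'tanh'")
        for name, dim, fam in self.modalities:
            ModalitySpec(name=name, dim=dim, family=fam)  # validates


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    Z: np.ndarray                    # (N, total latent dims)
    labels: np.ndarray
    blocks: dict                     # block name -> column indices into Z
    loadings: dict                   # modality name -> map description
    class_centers: np.ndarray

    def factor_labels(self) -> list[str]:
        out = [""] * self.Z.shape[1]
        for name, idx in self.blocks.items():
            for i in idx:
                out[i] = name
        return out


def _natural_params(F: np.ndarray, d_out: int, scale: float, nonlinearity: str,
                    rng: np.random.Generator):
    """Map factors to natural parameters; returns (eta, description)."""
    p = F.shape[1]
    if nonlinearity == "none":
        W = rng.normal(0.0, scale / np.sqrt(p), size=(p, d_out))
        return F @ W, {"kind": "linear", "W": W}
    h_width = max(2 * p, 8)
    W1 = rng.normal(0.0, 1.5 / np.sqrt(p), size=(p, h_width))
    W2 = rng.normal(0.0, scale / np.sqrt(h_width), size=(h_width, d_out))
    return np.tanh(F @ W1) @ W2, {"kind": "tanh", "W1": W1, "W2": W2}


def generate(config: SyntheticConfig):
    """Simulate a paired dataset; returns (MultiOmicsDataset, SyntheticTruth)."""
    rng = np.random.default_rng(config.seed)
    N, K = config.n_samples, config.n_classes
    labels = rng.integers(0, K, size=N)
    centers = rng.normal(0.0, config.class_spread, size=(K, config.n_shared))
    Z_shared = centers[labels] + rng.standard_normal((N, config.n_shared))
    blocks = {"shared": list(range(config.n_shared))}
    cols = [Z_shared]
    offset = config.n_shared
    spec_blocks = {}
    for name, _, _ in config.modalities:
        Zs = rng.standard_normal((N, config.n_specific))
        spec_blocks[name] = Zs
        blocks[f"specific:{name}"] = list(range(offset, offset + config.n_specific))
        offset += config.n_specific
        cols.append(Zs)
    if config.n_uninformative:
        Zu = rng.standard_normal((N, config.n_uninformative))
        blocks["uninformative"] = list(range(offset, offset + config.n_uninformative))
        cols.append(Zu)
    Z = np.concatenate(cols, axis=1)

    modalities = []
    loadings = {}
    for name, dim, fam in config.modalities:
        spec = ModalitySpec(name=name, dim=dim, family=fam)
        F = np.concatenate([Z_shared, spec_blocks[name]], axis=1)
        if fam == "categorical":
            eta, desc = _natural_params(F, dim * spec.n_categories,
                                        config.loading_scale, config.nonlinearity, rng)
            logits = eta.reshape(N, dim, spec.n_categories)
            probs = softmax(logits, axis=-1)
            u = rng.random((N, dim, 1))
            X = (probs.cumsum(axis=-1) < u).sum(axis=-1).astype(float)
        else:
            eta, desc = _natural_params(F, dim, config.loading_scale,
                                        config.nonlinearity, rng)
            if fam == "gaussian":
                X = eta + rng.standard_normal((N, dim))
            elif fam == "bernoulli":
                X = rng.binomial(1, expit(eta)).astype(float)
            elif fam == "beta":
                mean = np.clip(expit(eta), 1e-4, 1 - 1e-4)
                a = mean * config.beta_concentration
                b = (1.0 - mean) * config.beta_concentration
                X = clip_beta_values(rng.beta(a, b), spec.epsilon)
            elif fam == "negbin":
                base = rng.lognormal(np.log(5.0), 1.0, size=dim)
                phi = rng.uniform(*config.dispersion_range, size=dim)
                mu = base * np.exp(0.7 * np.clip(eta, -3.0, 3.0))
                lam = rng.gamma(shape=phi, scale=mu / phi)
                X = rng.poisson(lam).astype(float)
                desc.update({"base_mean": base, "dispersion": phi})
            else:  # negbin_mixture
                base = rng.lognormal(np.log(20.0), 1.0, size=dim)
                phi = rng.uniform(*config.dispersion_range, size=dim)
                alpha = 1.0 + np.exp(0.5 * np.clip(eta, -3.0, 3.0))
                fg = rng.binomial(1, config.foreground_rate, size=(N, dim))
                mu = base * np.where(fg == 1, alpha, 1.0)
                lam = rng.gamma(shape=phi, scale=mu / phi)
                X = rng.poisson(lam).astype(float)
                desc.update({"base_mean": base, "dispersion": phi,
                             "foreground": fg, "fold_change": alpha})
        loadings[name] = desc
        modalities.append((spec, X))

    split = make_split(labels, N, config.fractions,
                       seed=int(np.random.default_rng([config.seed, 71]).integers(2 ** 31)))
    dataset = MultiOmicsDataset(
        modalities=modalities,
        labels=labels,
        split=split.assignment,
    )
    truth = SyntheticTruth(Z=Z, labels=labels, blocks=blocks, loadings=loadings,
                           class_centers=centers)
    return dataset, truth


class PlantedLinearEmbedding:
    """Reference encoder for the planted benchmark.

    Per-modality ordinary-least-squares maps recover, from that modality's
    featurized profile, exactly the factor blocks the generator made visible
    to it (shared + its own specific block); every other latent coordinate
    encodes to zero.  Joint encoding uses the concatenated features of the
    available modalities and the union of their visible blocks.  Plain OLS on
    the full factor matrix would NOT work here: both modalities would fit the
    same in-sample noise of unloaded factors and their predictions would
    correlate spuriously.
    """

    flavor = "planted-linear"

    def __init__(self, dataset: MultiOmicsDataset, truth: SyntheticTruth,
                 ridge: float = 1e-8):
        from .models import encoder_input

        self._encoder_input = encoder_input
        self.specs = dataset.specs
        tr = dataset.split_subset("train") if dataset.split is not None else dataset
        tr_mask = (dataset.split == "train") if dataset.split is not None \
            else np.ones(dataset.n_samples, bool)
        Z = truth.Z[tr_mask]
        self.d = Z.shape[1]
        self.visible = {}
        feats = []
        for spec, X in tr.modalities:
            cols = list(truth.blocks.get("shared", []))
            cols += list(truth.blocks.get(f"specific:{spec.name}", []))
            self.visible[spec.name] = sorted(cols)
            feats.append(encoder_input(X, spec))

        def ols(H, cols):
            Hd = np.concatenate([H, np.ones((H.shape[0], 1))], axis=1)
            G = Hd.T @ Hd + ridge * np.eye(Hd.shape[1])
            return np.linalg.solve(G, Hd.T @ Z[:, cols])

        self.maps = [ols(H, self.visible[spec.name])
                     for H, spec in zip(feats, self.specs)]
        all_cols = sorted(set().union(*self.visible.values()))
        self.joint_cols = all_cols
        self.joint_map = ols(np.concatenate(feats, axis=1), all_cols)

    def encode(self, Xs, available=None):
        from .distributions import LatentPosterior

        M = len(self.specs)
        if available is None:
            available = [m for m in range(M) if Xs[m] is not None]
        available = sorted(int(a) for a in available)
        feats = [self._encoder_input(Xs[m], self.specs[m]) for m in available]
        n = feats[0].shape[0]
        loc = np.zeros((n, self.d))
        if len(available) == M:
            H = np.concatenate(feats, axis=1)
            Hd = np.concatenate([H, np.ones((n, 1))], axis=1)
            loc[:, self.joint_cols] = Hd @ self.joint_map
        else:
            for m, H in zip(available, feats):
                Hd = np.concatenate([H, np.ones((n, 1))], axis=1)
                loc[:, self.visible[self.specs[m].name]] += Hd @ self.maps[m]
        return LatentPosterior(loc, np.ones_like(loc), "gaussian")


@dataclass
class PlantedFactorBenchmark:
    """Dataset + factor answer key for the joint/specific/uninformative test."""

    dataset: MultiOmicsDataset
    truth: SyntheticTruth
    answer_key: list[str]  # per Z column: 'joint' | 'specific:<name>' | 'uninformative'
    expected_ordering: str = (
        "shared-factor signal is imputable across modalities; "
        "specific-factor signal is not"
    )

    def linear_embedding(self) -> PlantedLinearEmbedding:
        """Fitted reference encoder whose factor structure matches the key."""
        return PlantedLinearEmbedding(self.dataset, self.truth)


def planted_factor_benchmark(config: SyntheticConfig) -> PlantedFactorBenchmark:
    """Generate a dataset whose factor blocks serve as an answer key.

    Requires at least one shared and one specific factor; the key labels each
    latent column 'joint' (shared block), 'specific:<modality>' or
    'uninformative'.
    """
    if config.n_shared < 1 or config.n_specific < 1:
        raise ValueError("planted benchmark needs n_shared >= 1 and n_specific >= 1")
    dataset, truth = generate(config)
    key = []
    for lab in truth.factor_labels():
        key.append("joint" if lab == "shared" else lab)
    return PlantedFactorBenchmark(dataset=dataset, truth=truth, answer_key=key)


def preset_config(name: str, n_samples: int = 2000, seed: int = 0) -> SyntheticConfig:
    """Named study conditions covering all likelihood families."""
    if name == "gaussian-pair":
        return SyntheticConfig(
            n_samples=n_samples, n_classes=4, n_shared=4, n_specific=2,
            modalities=[("mod1", 100, "gaussian"), ("mod2", 80, "gaussian")],
            class_spread=3.0, seed=seed,
        )
    if name == "tcga-like":
        return SyntheticConfig(
            n_samples=n_samples, n_classes=8, n_shared=4, n_specific=2,
            modalities=[("ge", 200, "gaussian"), ("me", 100, "beta"),
                        ("cnv", 50, "categorical")],
            class_spread=2.0, seed=seed,
        )
    if name == "citeseq-like":
        return SyntheticConfig(
            n_samples=n_samples, n_classes=6, n_shared=4, n_specific=2,
            modalities=[("rna", 300, "negbin"), ("adt", 40, "negbin_mixture")],
            class_spread=2.0, seed=seed,
        )
    if name == "atac-like":
        return SyntheticConfig(
            n_samples=n_samples, n_classes=6, n_shared=4, n_specific=2,
            modalities=[("rna", 300, "negbin"), ("atac", 200, "bernoulli")],
            class_spread=2.0, seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}; expected one of {PRESETS}")
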