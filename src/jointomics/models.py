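"""Joint-embedding VAE flavors, their losses, training and inference.

Five flavors share one Model/Results interface:

``ccvae``
    Early integration: one encoder on the concatenation of all modalities,
    one decoder per modality.  A missing modality is zero-filled at encode
    time.  Loss: negative feature-averaged reconstruction log-likelihood of
    every modality from a single reparameterized draw, plus KL(q || prior).
``cgvae``
    Cross-generating VAE: one encoder per modality; every encoder's draw is
    decoded by every decoder (M x M reconstruction terms), plus per-modality
    KL terms and a squared 2-Wasserstein penalty pulling each pair of
    per-modality posteriors together.
``poe``
    Product of experts: per-modality Gaussian posteriors are fused with the
    prior by precision weighting.  Training draws from each unimodal
    posterior and from the fused posterior, decodes every draw with every
    decoder, and adds the KL of every used posterior to the prior.
``moe``
    Mixture of experts with Laplace posteriors and prior.  The objective
    averages, over mixture components, the single-draw importance bound
    log p(x|z) + log p(z) - log q_mix(z); the DReG option removes the score
    contribution of the mixture density's parameters (the K=1 doubly
    reparameterized estimator), changing gradients but not the loss value.
``refvae``
    Reference-encoder VAE (the paired simplification of UniPort): a single
    encoder on a designated reference modality and one decoder per modality.
    Only the reference modality can be encoded.

Model usage follows the statsmodels convention::

    model = JointEmbedding(dataset, flavor="poe", config=NetworkConfig(seed=0))
    res = model.fit()            # JointEmbeddingResults
    q = res.encode([x1, None])   # posterior from modality 0 alone
    params = res.impute([x1, None], source=[0], target=1)
    print(res.summary())
"""

from __future__ import annotations

import copy
import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import autodiff as ad
from . import likelihoods as lk
from .data import CapabilityError, ModalitySpec, MultiOmicsDataset
from .distributions import (
    LatentPosterior,
    kl_to_prior,
    moe_mixture_log_density,
    poe_combine,
    prior_like,
    w2_diag_gaussian,
)
from .nn import MLP, Adam
from .autodiff import Tensor

FLAVORS = ("ccvae", "cgvae", "poe", "moe", "refvae")
_PROB_EPS = 1e-6
_SCALE_FLOOR = 1e-4


@dataclass
class NetworkConfig:
    """Architecture and optimization settings shared by all flavors.

    ``hidden_layers`` lists hidden widths (0-3 layers); ``latent_dim`` is d.
    Optimization uses Adam; the epoch with the lowest validation loss is
    kept.  ``cgvae_multimodal`` selects how CGVAE combines per-modality
    posteriors when several modalities are available at encode time
    ('average' of locations/scales, or 'poe' product).
    """

    latent_dim: int = 32
    hidden_layers: list = field(default_factory=lambda: [64])
    activation: str = "relu"
    dropout: float = 0.0
    batch_norm: bool = False
    learning_rate: float = 1e-3
    max_epochs: int = 100
    batch_size: int = 128
    early_stopping_patience: int = 10
    seed: int = 0
    learn_gaussian_sd: bool = False
    moe_estimator: str = "dreg"  # 'dreg' | 'reparam'
    cgvae_multimodal: str = "average"  # 'average' | 'poe'

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if any(w < 1 for w in self.hidden_layers):
            raise ValueError("hidden layer widths must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.moe_estimator not in ("dreg", "reparam"):
            raise ValueError("moe_estimator must be 'dreg' or 'reparam'")
        if self.cgvae_multimodal not in ("average", "poe"):
            raise ValueError("cgvae_multimodal must be 'average' or 'poe'")


# ----------------------------------------------------------------------
# encoder input featurization
def encoder_input_dim(spec: ModalitySpec) -> int:
    return spec.dim * spec.n_categories if spec.family == "categorical" else spec.dim


def encoder_input(X: np.ndarray, spec: ModalitySpec) -> np.ndarray:
    """Featurize raw modality values for the encoders: categorical levels are
    one-hot expanded, counts are log1p-stabilized, others pass through."""
    X = np.asarray(X, dtype=float)
    if spec.family == "categorical":
        onehot = np.eye(spec.n_categories)[X.astype(int)]
        return onehot.reshape(X.shape[0], -1)
    if spec.family in ("negbin", "negbin_mixture"):
        return np.log1p(X)
    return X


# ----------------------------------------------------------------------
class Encoder:
    """MLP producing a diagonal posterior: loc and softplus-floored scale."""

    def __init__(self, d_in: int, config: NetworkConfig, rng: np.random.Generator,
                 family: str = "gaussian"):
        self.net = MLP(d_in, list(config.hidden_layers), 2 * config.latent_dim, rng,
                       activation=config.activation, dropout=config.dropout,
                       batch_norm=config.batch_norm)
        self.d = config.latent_dim
        self.family = family

    def parameters(self):
        return self.net.parameters()

    def forward(self, x, *, train=False, rng=None, numpy=False) -> LatentPosterior:
        out = self.net.forward(x, train=train, rng=rng, numpy=numpy)
        if numpy:
            loc, raw = out[:, : self.d], out[:, self.d:]
            scale = np.logaddexp(0.0, raw) + _SCALE_FLOOR
        else:
            loc = out[:, : self.d]
            scale = ad.softplus(out[:, self.d:]) + _SCALE_FLOOR
        return LatentPosterior(loc, scale, self.family)


def _squash_prob(raw):
    """Sigmoid squashed into (eps, 1-eps) so logs stay finite."""
    return _PROB_EPS + (1.0 - 2.0 * _PROB_EPS) * ad.sigmoid(raw)


def _softmax_last(raw):
    shift = ad.value_of(raw).max(axis=-1, keepdims=True)  # constant wrt params
    e = ad.exp(raw - shift)
    p = e / ad.sum_(e, axis=-1, keepdims=True)
    K = ad.value_of(raw).shape[-1]
    return (p + _PROB_EPS) * (1.0 / (1.0 + K * _PROB_EPS))


class Decoder:
    """MLP mapping latents to the modality's likelihood parameters."""

    def __init__(self, spec: ModalitySpec, config: NetworkConfig,
                 rng: np.random.Generator):
        self.spec = spec
        fam = spec.family
        D, K = spec.dim, spec.n_categories
        width = {"gaussian": D, "bernoulli": D, "categorical": D * K,
                 "beta": 2 * D, "negbin": D, "negbin_mixture": 2 * D}[fam]
        self.net = MLP(config.latent_dim, list(config.hidden_layers), width, rng,
                       activation=config.activation, dropout=config.dropout,
                       batch_norm=config.batch_norm)
        self.extra: dict[str, Tensor] = {}
        if fam == "gaussian" and config.learn_gaussian_sd:
            self.extra["log_sd"] = Tensor(np.zeros(D))
        if fam == "negbin":
            self.extra["raw_phi"] = Tensor(np.zeros(D))
        if fam == "negbin_mixture":
            self.extra["raw_mu"] = Tensor(np.log(np.expm1(1.0)) * np.ones(D))
            self.extra["raw_phi"] = Tensor(np.zeros(D))

    def parameters(self):
        return self.net.parameters() + list(self.extra.values())

    def forward(self, z, *, train=False, rng=None, numpy=False):
        spec = self.spec
        D = spec.dim
        out = self.net.forward(z, train=train, rng=rng, numpy=numpy)

        def ex(name):
            t = self.extra[name]
            return t.value if numpy else t

        fam = spec.family
        if fam == "gaussian":
            if "log_sd" in self.extra:
                sd = ad.exp(ex("log_sd")) + _SCALE_FLOOR
            else:
                sd = 1.0
            return lk.GaussianParams(mean=out, sd=sd)
        if fam == "bernoulli":
            return lk.BernoulliParams(prob=_squash_prob(out))
        if fam == "categorical":
            raw = out.reshape((ad.value_of(out).shape[0], D, spec.n_categories))
            return lk.CategoricalParams(probs=_softmax_last(raw))
        if fam == "beta":
            mean = _squash_prob(out[:, :D])
            conc = ad.softplus(out[:, D:]) + _SCALE_FLOOR
            return lk.BetaParams(mean=mean, concentration=conc)
        if fam == "negbin":
            mu = ad.softplus(out) + _PROB_EPS
            phi = ad.softplus(ex("raw_phi")) + _SCALE_FLOOR
            return lk.NegBinParams(mean=mu, dispersion=phi)
        # negbin_mixture: decoder yields per-cell fold-change and mixing;
        # background mean and dispersion are free per-feature parameters.
        alpha = 1.0 + ad.softplus(out[:, :D])
        pi = _squash_prob(out[:, D:])
        mu = ad.softplus(ex("raw_mu")) + _PROB_EPS
        phi = ad.softplus(ex("raw_phi")) + _SCALE_FLOOR
        return lk.NegBinMixtureParams(mean=mu, fold_change=alpha, dispersion=phi,
                                      mixing=pi)


# ----------------------------------------------------------------------
class _Networks:
    """Encoder/decoder bundle for one flavor."""

    def __init__(self, flavor: str, specs: list[ModalitySpec], config: NetworkConfig,
                 rng: np.random.Generator, reference_modality: int = 0):
        self.flavor = flavor
        self.specs = specs
        self.config = config
        self.reference_modality = reference_modality
        self.latent_family = "laplace" if flavor == "moe" else "gaussian"
        if flavor == "ccvae":
            d_in = sum(encoder_input_dim(s) for s in specs)
            self.encoders = [Encoder(d_in, config, rng, self.latent_family)]
        elif flavor == "refvae":
            d_in = encoder_input_dim(specs[reference_modality])
            self.encoders = [Encoder(d_in, config, rng, self.latent_family)]
        else:
            self.encoders = [Encoder(encoder_input_dim(s), config, rng, self.latent_family)
                             for s in specs]
        self.decoders = [Decoder(s, config, rng) for s in specs]

    def parameters(self):
        params = []
        for e in self.encoders:
            params.extend(e.parameters())
        for d in self.decoders:
            params.extend(d.parameters())
        return params

    def init_from_data(self, Xs: list[np.ndarray]) -> None:
        """Warm-start decoder output biases (and NB dispersions) from the
        per-feature training moments, so count decoders start near the
        marginal means instead of at softplus(0)."""
        for dec, (spec, X) in zip(self.decoders, zip(self.specs, Xs)):
            mean = X.mean(axis=0)
            var = X.var(axis=0)
            b = dec.net.out.b.value
            fam = spec.family
            if fam == "gaussian":
                b[:] = mean
            elif fam == "bernoulli":
                p = np.clip(mean, 1e-4, 1 - 1e-4)
                b[:] = np.log(p / (1 - p))
            elif fam == "categorical":
                K = spec.n_categories
                freqs = np.stack([(X == k).mean(axis=0) for k in range(K)], axis=-1)
                b[:] = np.log(freqs + 1e-4).ravel()
            elif fam == "beta":
                m = np.clip(mean, 1e-4, 1 - 1e-4)
                b[: spec.dim] = np.log(m / (1 - m))
            elif fam == "negbin":
                b[:] = np.log(np.expm1(np.clip(mean, 1e-3, None)) + 1e-8)
                excess = np.clip(var - mean, 1e-6, None)
                phi = np.clip(np.clip(mean, 1e-6, None) ** 2 / excess, 1e-2, 1e4)
                dec.extra["raw_phi"].value = np.log(np.expm1(phi))
            elif fam == "negbin_mixture":
                dec.extra["raw_mu"].value = np.log(
                    np.expm1(np.clip(mean, 1e-3, None)) + 1e-8)
                excess = np.clip(var - mean, 1e-6, None)
                phi = np.clip(np.clip(mean, 1e-6, None) ** 2 / excess, 1e-2, 1e4)
                dec.extra["raw_phi"].value = np.log(np.expm1(phi))

    def unimodal_posteriors(self, Xs, *, train=False, rng=None, numpy=False):
        """One posterior per modality (cgvae/poe/moe flavors)."""
        qs = []
        for m, (spec, X) in enumerate(zip(self.specs, Xs)):
            h = encoder_input(X, spec)
            qs.append(self.encoders[m].forward(h, train=train, rng=rng, numpy=numpy))
        return qs


# ----------------------------------------------------------------------
# losses; `collect` gathers per-term sums for decomposition contracts
def _recon_terms(nets: _Networks, z, Xs, *, train, rng, collect=None, tag=""):
    total = 0.0
    for m, (dec, X) in enumerate(zip(nets.decoders, Xs)):
        params = dec.forward(z, train=train, rng=rng)
        ll = lk.feature_mean_ll(X, params, nets.specs[m])
        term = ad.sum_(ll)
        if collect is not None:
            collect.setdefault("recon", []).append((f"{tag}->dec{m}", float(ad.value_of(term))))
        total = total + term
    return total


def _add_kl(collect, tag, value):
    if collect is not None:
        collect.setdefault("kl", []).append((tag, float(ad.value_of(value))))


def loss_ccvae(nets: _Networks, Xs, rng, *, train=False, collect=None):
    """Early-integration loss: -sum_m LL + KL, summed over the batch."""
    h = np.concatenate([encoder_input(X, s) for s, X in zip(nets.specs, Xs)], axis=1)
    q = nets.encoders[0].forward(h, train=train, rng=rng)
    z = q.rsample(rng)
    recon = _recon_terms(nets, z, Xs, train=train, rng=rng, collect=collect, tag="enc")
    kl = ad.sum_(kl_to_prior(q))
    _add_kl(collect, "q(z|x)", kl)
    loss = -recon + kl
    _check_finite(loss)
    return loss


def loss_cgvae(nets: _Networks, Xs, rng, *, train=False, collect=None):
    """All M x M cross-reconstruction terms + per-modality KL + pairwise W2^2."""
    M = len(nets.specs)
    if M < 2:
        raise ValueError("cgvae requires at least two modalities")
    qs = nets.unimodal_posteriors(Xs, train=train, rng=rng)
    loss = 0.0
    for n, q in enumerate(qs):
        z = q.rsample(rng)
        loss = loss - _recon_terms(nets, z, Xs, train=train, rng=rng,
                                   collect=collect, tag=f"enc{n}")
        kl = ad.sum_(kl_to_prior(q))
        _add_kl(collect, f"q(z|x{n})", kl)
        loss = loss + kl
    for a in range(M - 1):
        for b in range(a + 1, M):
            w2 = ad.sum_(w2_diag_gaussian(qs[a], qs[b]))
            if collect is not None:
                collect.setdefault("w2", []).append((f"({a},{b})", float(ad.value_of(w2))))
            loss = loss + w2
    _check_finite(loss)
    return loss


def loss_poe(nets: _Networks, Xs, rng, *, train=False, collect=None):
    """Draws from each unimodal posterior and the product posterior, all
    decoded by all decoders; KL of every used posterior to the prior."""
    qs = nets.unimodal_posteriors(Xs, train=train, rng=rng)
    q_joint = poe_combine(qs, include_prior=True)
    loss = 0.0
    for name, q in [(f"q(z|x{m})", q) for m, q in enumerate(qs)] + [("q(z|all)", q_joint)]:
        z = q.rsample(rng)
        loss = loss - _recon_terms(nets, z, Xs, train=train, rng=rng,
                                   collect=collect, tag=name)
        kl = ad.sum_(kl_to_prior(q))
        _add_kl(collect, name, kl)
        loss = loss + kl
    _check_finite(loss)
    return loss


def loss_moe(nets: _Networks, Xs, rng, *, train=False, collect=None,
             estimator: str | None = None):
    """Mixture-of-experts bound with Laplace latents.

    For each component m, one reparameterized draw z_m scores
    sum_n LL(x_n, z_m) + log p(z_m) - log q_mix(z_m); the loss is the
    negative average over components, summed over the batch.  With
    ``estimator='dreg'`` the mixture density's parameters are detached
    (same value, lower-variance posterior gradients).
    """
    estimator = estimator or nets.config.moe_estimator
    qs = nets.unimodal_posteriors(Xs, train=train, rng=rng)
    M = len(qs)
    prior = prior_like(ad.value_of(qs[0].loc).shape[0], qs[0].d, nets.latent_family)
    loss = 0.0
    for m, q in enumerate(qs):
        z = q.rsample(rng)
        recon = _recon_terms(nets, z, Xs, train=train, rng=rng,
                             collect=collect, tag=f"comp{m}")
        log_pz = prior.log_density(z)
        log_qmix = moe_mixture_log_density(qs, z, detach_params=(estimator == "dreg"))
        rate = ad.sum_(log_qmix - log_pz)
        _add_kl(collect, f"comp{m}:logq-logp", rate)
        loss = loss + (-recon + rate) * (1.0 / M)
    _check_finite(loss)
    return loss


def loss_refvae(nets: _Networks, Xs, rng, *, train=False, collect=None):
    """Encode the reference modality only; decode all modalities."""
    r = nets.reference_modality
    h = encoder_input(Xs[r], nets.specs[r])
    q = nets.encoders[0].forward(h, train=train, rng=rng)
    z = q.rsample(rng)
    recon = _recon_terms(nets, z, Xs, train=train, rng=rng, collect=collect, tag="ref")
    kl = ad.sum_(kl_to_prior(q))
    _add_kl(collect, "q(z|ref)", kl)
    loss = -recon + kl
    _check_finite(loss)
    return loss


LOSSES = {"ccvae": loss_ccvae, "cgvae": loss_cgvae, "poe": loss_poe,
          "moe": loss_moe, "refvae": loss_refvae}


class TrainingError(RuntimeError):
    pass


def _check_finite(loss):
    if not np.isfinite(ad.value_of(loss)):
        raise TrainingError("loss is not finite")


# ----------------------------------------------------------------------
class JointEmbedding:
    """Joint-embedding model over a :class:`MultiOmicsDataset`.

    Parameters
    ----------
    dataset : MultiOmicsDataset
        Paired data with train and val splits assigned.
    flavor : str
        One of ``ccvae``, ``cgvae``, ``poe``, ``moe``, ``refvae``.
    config : NetworkConfig, optional
    reference_modality : int
        Index of the encoded modality for ``refvae``.
    """

    def __init__(self, dataset: MultiOmicsDataset, flavor: str,
                 config: NetworkConfig | None = None, reference_modality: int = 0):
        if flavor not in FLAVORS:
            raise ValueError(f"unknown flavor {flavor!r}; expected one of {FLAVORS}")
        self.dataset = dataset
        self.flavor = flavor
        self.config = config or NetworkConfig()
        self.reference_modality = reference_modality

    def fit(self, verbose: bool = False) -> "JointEmbeddingResults":
        ds, cfg = self.dataset, self.config
        if ds.split is None:
            raise ValueError("dataset needs a train/val split before fitting")
        train_idx = np.flatnonzero(ds.split == "train")
        val_idx = np.flatnonzero(ds.split == "val")
        if len(train_idx) == 0 or len(val_idx) == 0:
            raise ValueError("both train and val splits must be non-empty")

        root = np.random.SeedSequence(cfg.seed)
        init_ss, shuffle_ss, draw_ss = root.spawn(3)
        nets = _Networks(self.flavor, ds.specs, cfg,
                         np.random.default_rng(init_ss), self.reference_modality)
        nets.init_from_data([X[train_idx] for _, X in ds.modalities])
        loss_fn = LOSSES[self.flavor]
        params = nets.parameters()
        opt = Adam(params, lr=cfg.learning_rate)
        shuffle_rng = np.random.default_rng(shuffle_ss)
        draw_rng = np.random.default_rng(draw_ss)

        Xtr = [X[train_idx] for _, X in ds.modalities]
        Xva = [X[val_idx] for _, X in ds.modalities]
        n_train = len(train_idx)
        best_val = np.inf
        best_state = None
        best_epoch = -1
        history = []
        patience_left = cfg.early_stopping_patience
        for epoch in range(cfg.max_epochs):
            order = shuffle_rng.permutation(n_train)
            epoch_loss = 0.0
            for start in range(0, n_train, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                Xb = [X[idx] for X in Xtr]
                opt.zero_grad()
                loss = loss_fn(nets, Xb, draw_rng, train=True)
                scaled = loss * (1.0 / len(idx))
                scaled.backward()
                opt.step()
                epoch_loss += float(ad.value_of(loss))
            # deterministic validation draw per epoch
            val_rng = np.random.default_rng([cfg.seed, epoch, 9173])
            val_loss = float(ad.value_of(loss_fn(nets, Xva, val_rng, train=False)))
            val_loss /= len(val_idx)
            train_loss = epoch_loss / n_train
            history.append((epoch, train_loss, val_loss))
            if verbose:
                print(f"epoch {epoch}: train {train_loss:.4f} val {val_loss:.4f}")
            if val_loss < best_val:
                best_val = val_loss
                best_epoch = epoch
                best_state = [p.value.copy() for p in params]
                best_running = [
                    (np.array(nrm.running_mean), np.array(nrm.running_var))
                    for enc in nets.encoders for nrm in enc.net.norms if nrm is not None
                ] + [
                    (np.array(nrm.running_mean), np.array(nrm.running_var))
                    for dec in nets.decoders for nrm in dec.net.norms if nrm is not None
                ]
                patience_left = cfg.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
        # restore the epoch with minimum validation loss
        for p, v in zip(params, best_state):
            p.value = v
        norms = [nrm for enc in nets.encoders for nrm in enc.net.norms if nrm is not None]
        norms += [nrm for dec in nets.decoders for nrm in dec.net.norms if nrm is not None]
        for nrm, (m, v) in zip(norms, best_running):
            nrm.running_mean, nrm.running_var = m, v
        hist = pd.DataFrame(history, columns=["epoch", "train_loss", "val_loss"])
        return JointEmbeddingResults(
            flavor=self.flavor, specs=ds.specs, config=cfg, networks=nets,
            history=hist, best_epoch=best_epoch, best_val_loss=best_val,
            reference_modality=self.reference_modality,
        )


def train(flavor: str, dataset: MultiOmicsDataset, config: NetworkConfig | None = None,
          reference_modality: int = 0, verbose: bool = False) -> "JointEmbeddingResults":
    """Functional wrapper around :class:`JointEmbedding` + ``fit``."""
    return JointEmbedding(dataset, flavor, config, reference_modality).fit(verbose=verbose)


# ----------------------------------------------------------------------
@dataclass
class JointEmbeddingResults:
    """Fitted joint-embedding model: encode/impute/generate plus training
    history and a summary table."""

    flavor: str
    specs: list[ModalitySpec]
    config: NetworkConfig
    networks: _Networks
    history: pd.DataFrame
    best_epoch: int
    best_val_loss: float
    reference_modality: int = 0

    # -- inference -----------------------------------------------------
    @property
    def latent_family(self) -> str:
        return self.networks.latent_family

    def _resolve_available(self, Xs, available):
        M = len(self.specs)
        if available is None:
            available = [m for m in range(M) if Xs[m] is not None]
        available = sorted(int(a) for a in available)
        if not available:
            raise ValueError("at least one modality must be available")
        for a in available:
            if Xs[a] is None:
                raise ValueError(f"modality {a} declared available but not given")
        return available

    def encode(self, Xs, available=None) -> LatentPosterior:
        """Posterior q(z | available modalities).

        ``Xs`` is a list of per-modality matrices aligned with the specs;
        entries for unavailable modalities may be None.
        """
        available = self._resolve_available(Xs, available)
        nets = self.networks
        if self.flavor == "refvae":
            r = self.reference_modality
            if r not in available:
                raise CapabilityError(
                    "refvae can only encode its reference modality "
                    f"(index {r}); got {available}"
                )
            h = encoder_input(Xs[r], self.specs[r])
            return nets.encoders[0].forward(h, numpy=True)
        if self.flavor == "ccvae":
            # zero-fill missing modalities in the featurized space
            n = next(np.asarray(Xs[a]).shape[0] for a in available)
            parts = []
            for m, spec in enumerate(self.specs):
                if Xs[m] is not None and m in available:
                    parts.append(encoder_input(Xs[m], spec))
                else:
                    parts.append(np.zeros((n, encoder_input_dim(spec))))
            return nets.encoders[0].forward(np.concatenate(parts, axis=1), numpy=True)
        qs = []
        for m in available:
            h = encoder_input(Xs[m], self.specs[m])
            qs.append(nets.encoders[m].forward(h, numpy=True))
        if len(qs) == 1:
            return qs[0]
        if self.flavor == "poe":
            return poe_combine(qs, include_prior=True)
        if self.flavor == "cgvae":
            if self.config.cgvae_multimodal == "poe":
                return poe_combine(qs, include_prior=True)
            loc = np.mean([q.loc for q in qs], axis=0)
            scale = np.mean([q.scale for q in qs], axis=0)
            return LatentPosterior(loc, scale, "gaussian")
        # moe: moment-matched uniform mixture
        locs = np.stack([q.loc for q in qs])
        scales = np.stack([q.scale for q in qs])
        var = 2.0 * scales ** 2  # Laplace variance = 2 b^2
        loc = locs.mean(axis=0)
        mix_var = (var + locs ** 2).mean(axis=0) - loc ** 2
        b = np.sqrt(np.maximum(mix_var, _SCALE_FLOOR ** 2) / 2.0)
        return LatentPosterior(loc, b, "laplace")

    def impute(self, Xs, source, target):
        """Deterministic cross-modal imputation: the MEAN of the posterior
        given the source modalities is passed through the target decoder;
        returns the decoder's distribution parameters (plain arrays)."""
        source = [int(s) for s in (source if np.iterable(source) else [source])]
        target = int(target)
        if self.flavor == "refvae" and target == self.reference_modality:
            # legal only when encoding the reference itself
            pass
        q = self.encode(Xs, available=source)
        z = np.asarray(ad.value_of(q.loc))
        return self.networks.decoders[target].forward(z, numpy=True)

    def sample_prior_decode(self, n: int, rng: np.random.Generator | int | None = None):
        """Draw n latents from the prior and decode with every decoder.

        Returns ``(z, [params_m for each modality])``; draws are shared
        across decoders.
        """
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        d = self.config.latent_dim
        if n == 0:
            z = np.zeros((0, d))
            return z, [dec.forward(z, numpy=True) for dec in self.networks.decoders]
        z = prior_like(n, d, self.latent_family).numpy().rsample(rng)
        return z, [dec.forward(z, numpy=True) for dec in self.networks.decoders]

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        n_params = sum(p.value.size for p in self.networks.parameters())
        lines = [
            "Joint embedding results",
            "=======================",
            f"flavor:            {self.flavor}",
            f"modalities:        " + ", ".join(
                f"{s.name}({s.family}, D={s.dim})" for s in self.specs),
            f"latent dim:        {self.config.latent_dim} ({self.latent_family})",
            f"hidden layers:     {self.config.hidden_layers}",
            f"parameters:        {n_params}",
            f"epochs run:        {len(self.history)}",
            f"best epoch:        {self.best_epoch}",
            f"best val loss:     {self.best_val_loss:.6f}",
        ]
        if self.flavor == "refvae":
            lines.append(f"reference:         {self.specs[self.reference_modality].name}")
        return "\n".join(lines)

    def plot_history(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["train_loss"], label="train")
        ax.plot(self.history["epoch"], self.history["val_loss"], label="val")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss per sample")
        ax.legend()
        return ax

    # -- checkpointing -------------------------------------------------
    def save(self, path: str) -> None:
        """Single-file checkpoint: JSON architecture header + parameter blobs."""
        header = {
            "flavor": self.flavor,
            "reference_modality": self.reference_modality,
            "best_epoch": self.best_epoch,
            "best_val_loss": self.best_val_loss,
            "config": asdict(self.config),
            "specs": [
                {"name": s.name, "dim": s.dim, "family": s.family,
                 "n_categories": s.n_categories, "epsilon": s.epsilon}
                for s in self.specs
            ],
        }
        arrays = {}
        for i, enc in enumerate(self.networks.encoders):
            for j, a in enumerate(enc.net.state_arrays()):
                arrays[f"enc{i}_{j}"] = a
        for i, dec in enumerate(self.networks.decoders):
            for j, a in enumerate(dec.net.state_arrays()):
                arrays[f"dec{i}_{j}"] = a
            for name, t in dec.extra.items():
                arrays[f"dec{i}_extra_{name}"] = t.value
        hist_csv = self.history.to_csv(index=False)
        np.savez(path, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
                 history=np.frombuffer(hist_csv.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "JointEmbeddingResults":
        with np.load(path) as z:
            header = json.loads(bytes(z["header"]).decode())
            hist = pd.read_csv(io.StringIO(bytes(z["history"]).decode()))
            specs = [ModalitySpec(**s) for s in header["specs"]]
            config = NetworkConfig(**header["config"])
            nets = _Networks(header["flavor"], specs, config,
                             np.random.default_rng(0), header["reference_modality"])
            for i, enc in enumerate(nets.encoders):
                arrs = []
                j = 0
                while f"enc{i}_{j}" in z:
                    arrs.append(z[f"enc{i}_{j}"])
                    j += 1
                enc.net.load_state_arrays(arrs)
            for i, dec in enumerate(nets.decoders):
                arrs = []
                j = 0
                while f"dec{i}_{j}" in z:
                    arrs.append(z[f"dec{i}_{j}"])
                    j += 1
                dec.net.load_state_arrays(arrs)
                for name, t in dec.extra.items():
                    t.value = np.asarray(z[f"dec{i}_extra_{name}"])
        return cls(flavor=header["flavor"], specs=specs, config=config, networks=nets,
                   history=hist, best_epoch=header["best_epoch"],
                   best_val_loss=header["best_val_loss"],
                   reference_modality=header["reference_modality"])


# ----------------------------------------------------------------------
def grid_search(dataset: MultiOmicsDataset, flavor: str,
                base: NetworkConfig | None = None,
                hidden_options=((), (64,), (64, 64), (64, 64, 64)),
                dropout_options=(0.0, 0.2), batch_norm_options=(False, True),
                reference_modality: int = 0, verbose: bool = False):
    """Small validation-loss grid over depth x dropout x batch-norm.

    Returns ``(best_results, table)`` where table rows hold each
    configuration and its best validation loss.
    """
    base = base or NetworkConfig()
    rows = []
    best = None
    for hidden in hidden_options:
        for dr in dropout_options:
            for bn in batch_norm_options:
                cfg = copy.deepcopy(base)
                cfg.hidden_layers = list(hidden)
                cfg.dropout = dr
                cfg.batch_norm = bn
                res = train(flavor, dataset, cfg, reference_modality)
                rows.append({"hidden": str(list(hidden)), "dropout": dr,
                             "batch_norm": bn, "val_loss": res.best_val_loss})
                if verbose:
                    print(rows[-1])
                if best is None or res.best_val_loss < best.best_val_loss:
                    best = res
    return best, pd.DataFrame(rows)
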