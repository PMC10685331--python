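"""Per-family log-likelihoods and the feature-averaged reconstruction score.

Each modality's observation model factorizes over features; the score used
throughout (reconstruction loss during training and imputation metric at
evaluation) is the arithmetic MEAN of the per-feature log-likelihoods, so
modalities of different dimensionality contribute on a comparable scale.

Families and parameterizations
------------------------------
gaussian         N(mean, sd^2); sd defaults to 1 for standardized inputs.
bernoulli        Bern(prob).
categorical      Cat(probs) over K levels per feature (probs shape (..., D, K)).
beta             Beta(a, b) with a = mean * concentration, b = (1-mean) * concentration.
negbin           mean-dispersion form:
                 p(k) = Gamma(k+phi) / (Gamma(phi) k!) * (phi/(phi+mu))^phi * (mu/(phi+mu))^k;
                 dispersion phi is shared per feature across samples.
negbin_mixture   two negative-binomial components sharing phi: a background with
                 mean mu and a foreground with mean alpha*mu (alpha > 1), mixed
                 with foreground probability pi per sample-feature (the totalVI
                 protein-count model).

All functions accept plain ndarrays or autodiff Tensors in the parameter
slots (observations are always plain arrays), so the same code serves
evaluation and gradient-based training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from . import autodiff as ad
from .data import ModalitySpec, ValidationError, validate_support

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class GaussianParams:
    mean: Any
    sd: Any = 1.0
    family = "gaussian"


@dataclass
class BernoulliParams:
    prob: Any
    family = "bernoulli"


@dataclass
class CategoricalParams:
    probs: Any  # (..., D, K), rows summing to 1 over K
    family = "categorical"


@dataclass
class BetaParams:
    mean: Any
    concentration: Any
    family = "beta"


@dataclass
class NegBinParams:
    mean: Any          # per sample-feature
    dispersion: Any    # per FEATURE, shared across samples
    family = "negbin"


@dataclass
class NegBinMixtureParams:
    mean: Any          # background mean, per feature (broadcastable)
    fold_change: Any   # alpha > 1, per sample-feature
    dispersion: Any    # per feature
    mixing: Any        # foreground probability pi in (0,1), per sample-feature
    family = "negbin_mixture"


def _negbin_logpmf(k, mu, phi):
    """Log-pmf of NB in mean-dispersion form, autodiff-compatible in (mu, phi)."""
    return (
        ad.lgamma(k + phi)
        - ad.lgamma(phi)
        - ad.lgamma(k + 1.0)
        + phi * (ad.log(phi) - ad.log(phi + mu))
        + k * (ad.log(mu) - ad.log(phi + mu))
    )


def log_prob_gaussian(x, params: GaussianParams):
    sd = params.sd
    z = (x - params.mean) / sd
    return -0.5 * LOG_2PI - ad.log(sd) - 0.5 * z ** 2 + np.zeros_like(x)


def log_prob_bernoulli(x, params: BernoulliParams):
    p = params.prob
    return x * ad.log(p) + (1.0 - x) * ad.log(1.0 - p)


def log_prob_categorical(x, params: CategoricalParams, n_categories: int):
    # one-hot the observed level; the product with log-probs avoids a gather
    # op.  Adding (1 - onehot) inside the log leaves selected entries
    # untouched and maps unselected ones to log(p + 1), which the zero
    # one-hot weight annihilates — so exact zeros in unselected cells are safe.
    x = np.asarray(x)
    onehot = np.eye(n_categories)[x.astype(int)]  # (..., D, K)
    return ad.sum_(onehot * ad.log(params.probs + (1.0 - onehot)), axis=-1)


def log_prob_beta(x, params: BetaParams):
    x = np.asarray(x, dtype=float)
    if ((x <= 0.0) | (x >= 1.0)).any():
        raise ValidationError(
            "beta observations must lie strictly inside (0, 1); "
            "apply clip_beta_values first"
        )
    a = params.mean * params.concentration
    b = (1.0 - params.mean) * params.concentration
    betaln = ad.lgamma(a) + ad.lgamma(b) - ad.lgamma(a + b)
    return (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x) - betaln


def log_prob_negbin(x, params: NegBinParams):
    return _negbin_logpmf(np.asarray(x, dtype=float), params.mean, params.dispersion)


def log_prob_negbin_mixture(x, params: NegBinMixtureParams):
    """log( (1-pi) NB(x; mu, phi) + pi NB(x; alpha mu, phi) ), in log-space."""
    alpha_v = ad.value_of(params.fold_change)
    if (alpha_v <= 1.0).any():
        raise ValidationError("negbin_mixture fold-change alpha must be > 1")
    x = np.asarray(x, dtype=float)
    log_bg = _negbin_logpmf(x, params.mean, params.dispersion)
    log_fg = _negbin_logpmf(x, params.fold_change * params.mean, params.dispersion)
    pi = params.mixing
    return ad.logaddexp(ad.log(1.0 - pi) + log_bg, ad.log(pi) + log_fg)


def log_prob(x, params, spec: ModalitySpec):
    """Per-feature log-likelihood vector (shape of ``x`` minus the K axis)."""
    if params.family != spec.family:
        raise ValueError(f"params family {params.family!r} != spec family {spec.family!r}")
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != spec.dim:
        raise ValueError(f"observation has {x.shape[-1]} features, spec declares {spec.dim}")
    if spec.family == "beta" and ((x <= 0.0) | (x >= 1.0)).any():
        raise ValidationError(
            "beta observations on the boundary; apply clip_beta_values first"
        )
    validate_support(np.atleast_2d(x), spec)
    if spec.family == "gaussian":
        return log_prob_gaussian(x, params)
    if spec.family == "bernoulli":
        return log_prob_bernoulli(x, params)
    if spec.family == "categorical":
        return log_prob_categorical(x, params, spec.n_categories)
    if spec.family == "beta":
        return log_prob_beta(x, params)
    if spec.family == "negbin":
        return log_prob_negbin(x, params)
    return log_prob_negbin_mixture(x, params)


def feature_mean_ll(x, params, spec: ModalitySpec):
    """Feature-averaged log-likelihood: mean over the D_m per-feature terms.

    This is the reconstruction score used by every loss and evaluation; it is
    invariant to feature order and scales as a mean, not a sum.
    """
    return ad.mean_(log_prob(x, params, spec), axis=-1)


# alias used in evaluation code, emphasizing its role as the imputation metric
eq_average_ll = feature_mean_ll


def point_profile(params) -> np.ndarray:
    """Collapse decoder distribution parameters to a point profile.

    gaussian -> mean; bernoulli -> probability; categorical -> argmax one-hot;
    beta -> mean; negbin -> mean; negbin_mixture -> mixture mean
    (1-pi) mu + pi alpha mu.  Used when decoded distributions feed classifiers.
    """
    if params.family == "gaussian":
        return np.asarray(ad.value_of(params.mean))
    if params.family == "bernoulli":
        return np.asarray(ad.value_of(params.prob))
    if params.family == "categorical":
        probs = np.asarray(ad.value_of(params.probs))
        arg = probs.argmax(axis=-1)
        return np.asarray(arg, dtype=float)
    if params.family == "beta":
        return np.asarray(ad.value_of(params.mean))
    if params.family == "negbin":
        return np.broadcast_to(
            np.asarray(ad.value_of(params.mean)), np.shape(ad.value_of(params.mean))
        ).copy()
    mu = ad.value_of(params.mean)
    pi = ad.value_of(params.mixing)
    alpha = ad.value_of(params.fold_change)
    return (1.0 - pi) * mu + pi * alpha * mu
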