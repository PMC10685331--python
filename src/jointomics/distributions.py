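"""Latent posterior containers and their algebra.

Diagonal Gaussian (or Laplace, for the mixture-of-experts flavor) posteriors
q(z|x) per sample, with closed-form KL to the standard prior, the squared
second-order Wasserstein distance between diagonal Gaussians, the
product-of-experts precision-weighted fusion, and mixture sampling.

Functions accept loc/scale as ndarrays or autodiff Tensors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from . import autodiff as ad

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class LatentPosterior:
    """Per-sample location/scale of q(z|.), family 'gaussian' or 'laplace'."""

    loc: Any    # (N, d)
    scale: Any  # (N, d), strictly positive
    family: str = "gaussian"

    def __post_init__(self):
        if self.family not in ("gaussian", "laplace"):
            raise ValueError(f"unknown latent family {self.family!r}")
        if (ad.value_of(self.scale) <= 0).any():
            raise ValueError("posterior scale must be strictly positive")

    @property
    def d(self) -> int:
        return ad.value_of(self.loc).shape[-1]

    def detach(self) -> "LatentPosterior":
        return LatentPosterior(ad.detach(self.loc), ad.detach(self.scale), self.family)

    def numpy(self) -> "LatentPosterior":
        return LatentPosterior(ad.value_of(self.loc), ad.value_of(self.scale), self.family)

    # ------------------------------------------------------------------
    def rsample(self, rng: np.random.Generator):
        """One reparameterized draw per sample: noise is drawn outside the
        graph, so the draw is differentiable in (loc, scale)."""
        shape = ad.value_of(self.loc).shape
        if self.family == "gaussian":
            eps = rng.standard_normal(shape)
        else:
            u = rng.uniform(-0.5 + 1e-12, 0.5 - 1e-12, size=shape)
            eps = -np.sign(u) * np.log1p(-2.0 * np.abs(u))
        return self.loc + self.scale * eps

    def log_density(self, z):
        """Per-sample log q(z), summed over latent dimensions."""
        if self.family == "gaussian":
            t = (z - self.loc) / self.scale
            per_dim = -0.5 * LOG_2PI - ad.log(self.scale) - 0.5 * t ** 2
        else:
            per_dim = -ad.log(2.0 * self.scale) - ad.absolute(z - self.loc) / self.scale
        return ad.sum_(per_dim, axis=-1)


def prior_like(n: int, d: int, family: str = "gaussian") -> LatentPosterior:
    """Standard prior (N(0,1) or Laplace(0,1)) broadcast to n samples."""
    return LatentPosterior(np.zeros((n, d)), np.ones((n, d)), family)


def kl_to_prior(q: LatentPosterior):
    """Closed-form KL(q || standard prior), per sample (summed over dims).

    Gaussian: 0.5 * (scale^2 + loc^2 - 1 - 2 log scale) per dimension.
    Laplace vs Laplace(0,1): |loc| + scale * exp(-|loc|/scale) - log scale - 1.
    """
    loc, scale = q.loc, q.scale
    if q.family == "gaussian":
        per_dim = 0.5 * (scale ** 2 + loc ** 2 - 1.0) - ad.log(scale)
    else:
        a = ad.absolute(loc)
        per_dim = a + scale * ad.exp(-a / scale) - ad.log(scale) - 1.0
    return ad.sum_(per_dim, axis=-1)


def w2_diag_gaussian(q1: LatentPosterior, q2: LatentPosterior):
    """Squared 2-Wasserstein distance between diagonal Gaussians, per sample:
    sum_j (loc1_j - loc2_j)^2 + (scale1_j - scale2_j)^2."""
    if q1.family != "gaussian" or q2.family != "gaussian":
        raise ValueError("w2_diag_gaussian requires gaussian posteriors")
    if q1.d != q2.d:
        raise ValueError("posteriors have different latent dimension")
    return ad.sum_((q1.loc - q2.loc) ** 2 + (q1.scale - q2.scale) ** 2, axis=-1)


def poe_combine(posteriors: list[LatentPosterior], include_prior: bool = True,
                n: int | None = None, d: int | None = None) -> LatentPosterior:
    """Product-of-experts fusion of diagonal Gaussian posteriors.

    Multiplying the expert densities (and, by default, the standard-normal
    prior) yields another diagonal Gaussian with precision equal to the sum
    of expert precisions and precision-weighted mean.  With no experts the
    result is the prior itself; shape must then be given via ``n`` and ``d``.
    """
    if not posteriors:
        if not include_prior:
            raise ValueError("poe_combine needs at least one posterior or the prior")
        if n is None or d is None:
            raise ValueError("poe_combine with no experts needs explicit n and d")
        return prior_like(n, d, "gaussian")
    for q in posteriors:
        if q.family != "gaussian":
            raise ValueError("poe_combine requires gaussian posteriors")
    precision = 1.0 if include_prior else 0.0
    weighted_loc = 0.0
    for q in posteriors:
        tau = q.scale ** -2
        precision = tau + precision
        weighted_loc = tau * q.loc + weighted_loc
    loc = weighted_loc / precision
    scale = precision ** -0.5
    return LatentPosterior(loc, scale, "gaussian")


def moe_sample(posteriors: list[LatentPosterior], n_draws: int,
               rng: np.random.Generator):
    """Sample a uniform mixture of per-modality posteriors.

    Each draw picks a component uniformly at random and then samples it via
    reparameterization.  Returns ``(draws, component_indices)`` with draws of
    shape (n_draws, N, d); component indices allow stratified variants.
    """
    if not posteriors:
        raise ValueError("moe_sample needs at least one component")
    fam = posteriors[0].family
    d = posteriors[0].d
    for q in posteriors:
        if q.family != fam or q.d != d:
            raise ValueError("mixture components must share family and dimension")
    comp = rng.integers(0, len(posteriors), size=n_draws)
    draws = []
    for c in comp:
        draws.append(ad.value_of(posteriors[c].numpy().rsample(rng)))
    return np.stack(draws, axis=0), comp


def moe_mixture_log_density(posteriors: list[LatentPosterior], z, detach_params: bool = False):
    """log( (1/M) sum_m q_m(z) ), per sample.

    With ``detach_params`` the density parameters are cut from the autodiff
    graph while the path through ``z`` is kept — the K=1 doubly
    reparameterized (DReG) gradient estimator.
    """
    terms = None
    for q in posteriors:
        qq = q.detach() if detach_params else q
        lp = qq.log_density(z)
        terms = lp if terms is None else ad.logaddexp(terms, lp)
    return terms - np.log(len(posteriors))
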