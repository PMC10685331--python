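"""Linear baselines: PCA features, GLM cross-modal regression, and the
out-of-sample wrapper that turns any externally computed linear factorization
into an encode/impute model.

GLMs use the canonical link of each likelihood family (identity/gaussian,
logit/bernoulli, softmax/categorical, logit-mean/beta, log-mean/negbin) and
are fitted by maximizing the penalized log-likelihood with L-BFGS driven by
autodiff gradients, so every family — including the negative binomial, whose
per-feature dispersion enters the objective as log-phi parameters — is
handled by one monotone (line-searched) optimizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.decomposition import PCA

from . import autodiff as ad
from . import likelihoods as lk
from .autodiff import Tensor
from .data import ModalitySpec, MultiOmicsDataset
from .models import encoder_input

_SCALE_FLOOR = 1e-4
_PROB_EPS = 1e-6


# ----------------------------------------------------------------------
@dataclass
class PCAMaps:
    """Fitted top-k principal axes with a deterministic sign convention."""

    mean: np.ndarray
    components: np.ndarray  # (k, D)
    explained_variance: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.components.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return scores @ self.components + self.mean


def pca_fit_transform(X: np.ndarray, k: int = 32):
    """Top-k PCA scores with the largest-|loading| element of each component
    made positive (reproducible across platforms)."""
    X = np.asarray(X, dtype=float)
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(N, D) = {min(X.shape)}")
    p = PCA(n_components=k, svd_solver="full").fit(X)
    comps = p.components_.copy()
    flip = np.sign(comps[np.arange(k), np.abs(comps).argmax(axis=1)])
    flip[flip == 0] = 1.0
    comps *= flip[:, None]
    maps = PCAMaps(mean=p.mean_, components=comps,
                   explained_variance=p.explained_variance_)
    return maps, maps.transform(X)


# ----------------------------------------------------------------------
# GLM: linear predictor -> family parameters
def _glm_params(eta, spec: ModalitySpec, extra: dict):
    fam = spec.family
    if fam == "gaussian":
        return lk.GaussianParams(mean=eta, sd=1.0)
    if fam == "bernoulli":
        p = _PROB_EPS + (1 - 2 * _PROB_EPS) * ad.sigmoid(eta)
        return lk.BernoulliParams(prob=p)
    if fam == "categorical":
        n = ad.value_of(eta).shape[0]
        raw = eta.reshape((n, spec.dim, spec.n_categories))
        shift = ad.value_of(raw).max(axis=-1, keepdims=True)
        e = ad.exp(raw - shift)
        p = e / ad.sum_(e, axis=-1, keepdims=True)
        p = (p + _PROB_EPS) * (1.0 / (1.0 + spec.n_categories * _PROB_EPS))
        return lk.CategoricalParams(probs=p)
    if fam == "beta":
        D = spec.dim
        mean = _PROB_EPS + (1 - 2 * _PROB_EPS) * ad.sigmoid(eta[:, :D])
        conc = ad.softplus(eta[:, D:]) + _SCALE_FLOOR
        return lk.BetaParams(mean=mean, concentration=conc)
    if fam == "negbin":
        mu = ad.exp(eta) + _PROB_EPS
        phi = ad.softplus(extra["raw_phi"]) + _SCALE_FLOOR
        return lk.NegBinParams(mean=mu, dispersion=phi)
    # negbin_mixture
    D = spec.dim
    alpha = 1.0 + ad.softplus(eta[:, :D])
    pi = _PROB_EPS + (1 - 2 * _PROB_EPS) * ad.sigmoid(eta[:, D:])
    mu = ad.softplus(extra["raw_mu"]) + _PROB_EPS
    phi = ad.softplus(extra["raw_phi"]) + _SCALE_FLOOR
    return lk.NegBinMixtureParams(mean=mu, fold_change=alpha, dispersion=phi, mixing=pi)


def _glm_eta_width(spec: ModalitySpec) -> int:
    return {"gaussian": spec.dim, "bernoulli": spec.dim,
            "categorical": spec.dim * spec.n_categories,
            "beta": 2 * spec.dim, "negbin": spec.dim,
            "negbin_mixture": 2 * spec.dim}[spec.family]


@dataclass
class GLMMap:
    """Fitted GLM from a design matrix to one modality's parameters."""

    spec: ModalitySpec
    coef: np.ndarray       # (d_in + 1, eta_width), last row = intercept
    extra: dict = field(default_factory=dict)
    ll_history: list = field(default_factory=list)
    converged: bool = True

    def predict_params(self, X_source: np.ndarray):
        X = np.asarray(X_source, dtype=float)
        eta = X @ self.coef[:-1] + self.coef[-1]
        return _glm_params(eta, self.spec, self.extra)


def glm_fit(X_source: np.ndarray, X_target: np.ndarray, target_spec: ModalitySpec,
            ridge: float = 1e-4, max_iter: int = 500) -> GLMMap:
    """Maximum-likelihood GLM from ``X_source`` to ``X_target``'s family.

    The objective is the mean per-sample feature-averaged log-likelihood
    minus ``ridge * ||coef||^2`` (intercept unpenalized), maximized by
    L-BFGS-B; the recorded log-likelihood trace is non-decreasing.  For the
    gaussian family with ``ridge=0`` this coincides with least squares.
    """
    X = np.asarray(X_source, dtype=float)
    Y = np.asarray(X_target, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("source and target must have paired rows")
    n, d_in = X.shape
    width = _glm_eta_width(target_spec)
    Xd = np.concatenate([X, np.ones((n, 1))], axis=1)

    extra_shapes = {}
    if target_spec.family == "negbin":
        extra_shapes["raw_phi"] = target_spec.dim
    elif target_spec.family == "negbin_mixture":
        extra_shapes["raw_mu"] = target_spec.dim
        extra_shapes["raw_phi"] = target_spec.dim

    n_coef = (d_in + 1) * width
    sizes = [n_coef] + [extra_shapes[k] for k in sorted(extra_shapes)]
    total = sum(sizes)
    x0 = np.zeros(total)
    # warm-start the intercept (and dispersion) at the marginal fit
    mean = Y.mean(axis=0)
    var = Y.var(axis=0)
    intercept = np.zeros(width)
    fam = target_spec.family
    if fam == "gaussian":
        intercept[:] = mean
    elif fam == "bernoulli":
        p = np.clip(mean, 1e-4, 1 - 1e-4)
        intercept[:] = np.log(p / (1 - p))
    elif fam == "categorical":
        K = target_spec.n_categories
        freqs = np.stack([(Y == k).mean(axis=0) for k in range(K)], axis=-1)
        intercept[:] = np.log(freqs + 1e-4).ravel()
    elif fam == "beta":
        m = np.clip(mean, 1e-4, 1 - 1e-4)
        intercept[: target_spec.dim] = np.log(m / (1 - m))
    elif fam == "negbin":
        intercept[:] = np.log(np.clip(mean, 1e-3, None))
    extras0 = {}
    if fam in ("negbin", "negbin_mixture"):
        excess = np.clip(var - mean, 1e-6, None)
        phi = np.clip(np.clip(mean, 1e-6, None) ** 2 / excess, 1e-2, 1e4)
        extras0["raw_phi"] = np.log(np.expm1(phi))
    if fam == "negbin_mixture":
        extras0["raw_mu"] = np.log(np.expm1(np.clip(mean, 1e-3, None)) + 1e-8)
    x0[:n_coef] = np.concatenate([np.zeros((d_in, width)), intercept[None]],
                                 axis=0).ravel()
    off = n_coef
    for k in sorted(extra_shapes):
        if k in extras0:
            x0[off: off + extra_shapes[k]] = extras0[k]
        off += extra_shapes[k]
    ll_history: list[float] = []

    def unpack(theta):
        coef = Tensor(theta[:n_coef].reshape(d_in + 1, width))
        extra = {}
        off = n_coef
        for k in sorted(extra_shapes):
            extra[k] = Tensor(theta[off: off + extra_shapes[k]])
            off += extra_shapes[k]
        return coef, extra

    def objective(theta):
        coef, extra = unpack(theta)
        eta = ad.matmul(Xd, coef)
        params = _glm_params(eta, target_spec, extra)
        ll = ad.mean_(lk.feature_mean_ll(Y, params, target_spec))
        penalty = ridge * ad.sum_(coef[:-1] ** 2)
        obj = -(ll - penalty)
        obj.backward()
        grads = [coef.grad.ravel()]
        for k in sorted(extra_shapes):
            grads.append(extra[k].grad.ravel())
        return float(ad.value_of(obj)), np.concatenate(grads)

    def callback(theta):
        coef, extra = unpack(theta)
        eta = Xd @ coef.value
        params = _glm_params(eta, target_spec, extra={k: v.value for k, v in extra.items()}
                             if extra else {})
        ll_history.append(float(np.mean(lk.feature_mean_ll(Y, params, target_spec))))

    res = optimize.minimize(objective, x0, jac=True, method="L-BFGS-B",
                            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9},
                            callback=callback)
    if not res.success:
        warnings.warn(
            f"GLM fit did not fully converge ({res.message}); "
            f"final gradient norm {np.linalg.norm(res.jac):.3e}"
        )
    coef, extra = unpack(res.x)
    return GLMMap(spec=target_spec, coef=coef.value,
                  extra={k: Tensor(v.value) for k, v in extra.items()},
                  ll_history=ll_history, converged=bool(res.success))


# ----------------------------------------------------------------------
@dataclass
class LinearMaps:
    """Per-modality encode matrices and decode GLMs wrapping a factorization."""

    specs: list[ModalitySpec]
    encode_maps: list[np.ndarray]        # each (D_feat + 1, d), featurized input
    encode_concat: np.ndarray            # (sum D_feat + 1, d)
    decode_glms: list[GLMMap]
    latent_dim: int
    flavor: str = "linear"
    latent_family: str = "gaussian"

    def _featurize(self, X, m):
        return encoder_input(X, self.specs[m])

    def encode(self, Xs, available=None):
        """Latent point estimates from the available modalities.

        Returns a degenerate posterior-like object exposing ``loc`` (OLS
        prediction) with unit scale, matching the VAE encode contract.
        """
        from .distributions import LatentPosterior

        M = len(self.specs)
        if available is None:
            available = [m for m in range(M) if Xs[m] is not None]
        available = sorted(int(a) for a in available)
        if not available:
            raise ValueError("at least one modality must be available")
        if len(available) == M:
            H = np.concatenate([self._featurize(Xs[m], m) for m in range(M)], axis=1)
            Hd = np.concatenate([H, np.ones((H.shape[0], 1))], axis=1)
            loc = Hd @ self.encode_concat
        else:
            locs = []
            for m in available:
                H = self._featurize(Xs[m], m)
                Hd = np.concatenate([H, np.ones((H.shape[0], 1))], axis=1)
                locs.append(Hd @ self.encode_maps[m])
            loc = np.mean(locs, axis=0)
        return LatentPosterior(loc, np.ones_like(loc), "gaussian")

    def impute(self, Xs, source, target):
        source = [int(s) for s in (source if np.iterable(source) else [source])]
        q = self.encode(Xs, available=source)
        return self.decode_glms[int(target)].predict_params(q.loc)

    def decode(self, Z):
        return [g.predict_params(Z) for g in self.decode_glms]


def oos_extension(Z_train: np.ndarray, dataset: MultiOmicsDataset,
                  ridge: float = 1e-4, decoder_ridge: float = 1e-4) -> LinearMaps:
    """Out-of-sample extension of an externally produced factorization.

    ``Z_train`` must be row-aligned with the dataset's train split.  Encoding
    maps are ordinary least squares from each (featurized) modality — and
    from the concatenation — to Z; decoding maps are family-appropriate GLMs
    from Z to each modality.  The result supports the same encode/impute
    contracts as the VAE results objects.
    """
    Z = np.asarray(Z_train, dtype=float)
    if Z.ndim != 2 or Z.shape[1] == 0:
        raise ValueError("Z_train must be a non-empty N x d matrix")
    if dataset.split is None:
        raise ValueError("dataset needs a split; Z_train aligns with the train rows")
    tr = dataset.split_subset("train")
    if Z.shape[0] != tr.n_samples:
        raise ValueError(
            f"Z_train has {Z.shape[0]} rows; train split has {tr.n_samples}"
        )

    def ols(H, Z):
        Hd = np.concatenate([H, np.ones((H.shape[0], 1))], axis=1)
        try:
            B, *_ = np.linalg.lstsq(Hd, Z, rcond=None)
            if not np.isfinite(B).all():
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            warnings.warn("rank-deficient encode regression; using ridge fallback")
            G = Hd.T @ Hd + ridge * np.eye(Hd.shape[1])
            B = np.linalg.solve(G, Hd.T @ Z)
        return B

    feats = [encoder_input(X, spec) for spec, X in tr.modalities]
    encode_maps = [ols(H, Z) for H in feats]
    encode_concat = ols(np.concatenate(feats, axis=1), Z)
    decode_glms = [glm_fit(Z, X, spec, ridge=decoder_ridge)
                   for spec, X in tr.modalities]
    return LinearMaps(specs=tr.specs, encode_maps=encode_maps,
                      encode_concat=encode_concat, decode_glms=decode_glms,
                      latent_dim=Z.shape[1])


# ----------------------------------------------------------------------
@dataclass
class GLMImputer:
    """Direct regression baseline from one modality to another (no latent)."""

    glms: dict  # (source m, target m) -> GLMMap
    specs: list[ModalitySpec]
    flavor: str = "glm"

    @classmethod
    def fit(cls, dataset: MultiOmicsDataset, pairs=None, ridge: float = 1e-4,
            max_iter: int = 500):
        tr = dataset.split_subset("train") if dataset.split is not None else dataset
        M = tr.n_modalities
        if pairs is None:
            pairs = [(s, t) for s in range(M) for t in range(M) if s != t]
        glms = {}
        for s, t in pairs:
            H = encoder_input(tr.matrix(s), tr.specs[s])
            glms[(s, t)] = glm_fit(H, tr.matrix(t), tr.specs[t], ridge=ridge,
                                   max_iter=max_iter)
        return cls(glms=glms, specs=tr.specs)

    def impute(self, Xs, source, target):
        source = [int(s) for s in (source if np.iterable(source) else [source])]
        if len(source) != 1:
            raise ValueError("GLM baseline imputes from a single source modality")
        s, t = source[0], int(target)
        if (s, t) not in self.glms:
            raise KeyError(f"no GLM fitted for {s}->{t}")
        H = encoder_input(Xs[s], self.specs[s])
        return self.glms[(s, t)].predict_params(H)


@dataclass
class MeanImputer:
    """Predicts per-feature training statistics regardless of the input.

    gaussian -> train means; bernoulli -> train frequencies; categorical ->
    empirical level frequencies; beta -> method-of-moments (mean,
    concentration); negbin -> method-of-moments (mean, dispersion);
    negbin_mixture -> a single NB disguised as a degenerate mixture.
    """

    params_by_modality: list
    specs: list[ModalitySpec]
    flavor: str = "train-mean"

    @classmethod
    def fit(cls, dataset: MultiOmicsDataset):
        tr = dataset.split_subset("train") if dataset.split is not None else dataset
        out = []
        for spec, X in tr.modalities:
            mean = X.mean(axis=0)
            var = X.var(axis=0)
            if spec.family == "gaussian":
                out.append(lk.GaussianParams(mean=mean, sd=1.0))
            elif spec.family == "bernoulli":
                p = np.clip(mean, _PROB_EPS, 1 - _PROB_EPS)
                out.append(lk.BernoulliParams(prob=p))
            elif spec.family == "categorical":
                K = spec.n_categories
                probs = np.stack([(X == k).mean(axis=0) for k in range(K)], axis=-1)
                probs = (probs + _PROB_EPS) / (1 + K * _PROB_EPS)
                out.append(lk.CategoricalParams(probs=probs))
            elif spec.family == "beta":
                m = np.clip(mean, _PROB_EPS, 1 - _PROB_EPS)
                v = np.clip(var, 1e-10, None)
                conc = np.clip(m * (1 - m) / v - 1.0, _SCALE_FLOOR, None)
                out.append(lk.BetaParams(mean=m, concentration=conc))
            elif spec.family == "negbin":
                mu = np.clip(mean, _PROB_EPS, None)
                excess = np.clip(var - mu, 1e-8, None)
                phi = np.clip(mu ** 2 / excess, _SCALE_FLOOR, 1e6)
                out.append(lk.NegBinParams(mean=mu, dispersion=phi))
            else:
                mu = np.clip(mean, _PROB_EPS, None)
                excess = np.clip(var - mu, 1e-8, None)
                phi = np.clip(mu ** 2 / excess, _SCALE_FLOOR, 1e6)
                out.append(lk.NegBinMixtureParams(
                    mean=mu, fold_change=np.full_like(mu, 1.0 + 1e-6),
                    dispersion=phi, mixing=np.full_like(mu, 0.5)))
        return cls(params_by_modality=out, specs=tr.specs)

    def impute(self, Xs, source, target):
        t = int(target)
        params = self.params_by_modality[t]
        # broadcast the stored parameters to the request's sample count
        source = [int(s) for s in (source if np.iterable(source) else [source])]
        n = np.asarray(Xs[source[0]]).shape[0]
        import dataclasses as _dc

        def tile(v):
            v = np.asarray(ad.value_of(v))
            if v.ndim == 0:
                return float(v)
            return np.broadcast_to(v, (n,) + v.shape).copy()

        kwargs = {f.name: tile(getattr(params, f.name)) for f in _dc.fields(params)}
        if params.family in ("negbin", "negbin_mixture"):
            kwargs["dispersion"] = np.asarray(ad.value_of(params.dispersion))
        return type(params)(**kwargs)
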