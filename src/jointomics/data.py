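"""Domain types and I/O for paired multi-omics matrices.

A dataset is a set of per-sample matrices, one per modality, with identical
row order (paired samples).  Each modality declares its observation model
through a :class:`ModalitySpec` (``gaussian``, ``bernoulli``, ``categorical``,
``beta``, ``negbin`` or ``negbin_mixture``); matrix entries are validated
against the family's support on read.

Dense matrices are CSV/TSV with the first column holding sample ids and the
header row holding feature names.  Sparse matrices use MatrixMarket
coordinate format in the 10x convention (features as rows) with
``features.tsv`` / ``barcodes.tsv`` sidecars.  Labels and splits are
two-column TSVs keyed by sample id.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

FAMILIES = ("gaussian", "bernoulli", "categorical", "beta", "negbin", "negbin_mixture")
COUNT_FAMILIES = ("negbin", "negbin_mixture")
SPLIT_NAMES = ("train", "val", "test")


class ValidationError(ValueError):
    """Raised when matrix entries violate the declared family's support."""


class FormatError(ValueError):
    """Raised on malformed files (dimension or name mismatches)."""


class CapabilityError(RuntimeError):
    """Raised when a model flavor cannot perform the requested encode/impute."""


@dataclass(frozen=True)
class ModalitySpec:
    """Name, dimensionality and likelihood family of one modality.

    ``n_categories`` applies to the categorical family only (default 5, the
    GISTIC2-style discretization of copy number into five levels);
    ``epsilon`` is the boundary clip for beta-distributed values.
    """

    name: str
    dim: int
    family: str
    n_categories: int = 5
    epsilon: float = 1e-6

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.family == "categorical" and self.n_categories < 2:
            raise ValueError("categorical family requires n_categories >= 2")
        if not (0.0 < self.epsilon < 0.5):
            raise ValueError("epsilon must lie strictly inside (0, 0.5)")


def validate_support(X: np.ndarray, spec: ModalitySpec) -> None:
    """Check every entry of ``X`` against ``spec.family``'s support.

    Raises :class:`ValidationError` naming the first offending (row, col).
    """
    X = np.asarray(X)
    fam = spec.family
    if fam == "gaussian":
        bad = ~np.isfinite(X)
    elif fam == "bernoulli":
        bad = ~np.isin(X, (0, 1))
    elif fam == "categorical":
        bad = (X != np.floor(X)) | (X < 0) | (X >= spec.n_categories)
    elif fam == "beta":
        bad = ~((X > 0.0) & (X < 1.0))
    else:  # counts
        bad = (X != np.floor(X)) | (X < 0) | ~np.isfinite(X)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"value {X[r, c]!r} at (row={r}, col={c}) outside support of "
            f"family {fam!r} for modality {spec.name!r}"
        )


@dataclass
class MultiOmicsDataset:
    """N paired samples across M modalities, with optional labels and split."""

    modalities: list[tuple[ModalitySpec, np.ndarray]]
    sample_ids: list[str] | None = None
    labels: np.ndarray | None = None
    split: np.ndarray | None = None  # entries in {"train","val","test"}
    feature_names: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        ns = {X.shape[0] for _, X in self.modalities}
        if len(ns) != 1:
            raise ValueError(f"modalities disagree on sample count: {sorted(ns)}")
        for spec, X in self.modalities:
            if X.shape[1] != spec.dim:
                raise ValueError(
                    f"modality {spec.name!r}: matrix has {X.shape[1]} features, spec says {spec.dim}"
                )
            validate_support(X, spec)
        if self.sample_ids is None:
            self.sample_ids = [f"sample{i}" for i in range(self.n_samples)]
        if self.labels is not None and len(self.labels) != self.n_samples:
            raise ValueError("labels length does not match sample count")
        if self.split is not None and len(self.split) != self.n_samples:
            raise ValueError("split length does not match sample count")

    @property
    def n_samples(self) -> int:
        return self.modalities[0][1].shape[0]

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    @property
    def specs(self) -> list[ModalitySpec]:
        return [spec for spec, _ in self.modalities]

    def matrix(self, name_or_index) -> np.ndarray:
        return self.modalities[self.modality_index(name_or_index)][1]

    def modality_index(self, name_or_index) -> int:
        if isinstance(name_or_index, (int, np.integer)):
            return int(name_or_index)
        for i, (spec, _) in enumerate(self.modalities):
            if spec.name == name_or_index:
                return i
        raise KeyError(f"no modality named {name_or_index!r}")

    def subset(self, mask_or_idx) -> "MultiOmicsDataset":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return MultiOmicsDataset(
            modalities=[(spec, X[idx]) for spec, X in self.modalities],
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=None if self.labels is None else self.labels[idx],
            split=None if self.split is None else self.split[idx],
            feature_names=self.feature_names,
        )

    def split_subset(self, which: str) -> "MultiOmicsDataset":
        if self.split is None:
            raise ValueError("dataset has no split assignment")
        if which not in SPLIT_NAMES:
            raise ValueError(f"split must be one of {SPLIT_NAMES}")
        return self.subset(self.split == which)

    def with_split(self, split: "SplitAssignment | np.ndarray") -> "MultiOmicsDataset":
        arr = split.assignment if isinstance(split, SplitAssignment) else np.asarray(split)
        out = MultiOmicsDataset(
            modalities=self.modalities,
            sample_ids=self.sample_ids,
            labels=self.labels,
            split=np.asarray(arr),
            feature_names=self.feature_names,
        )
        return out


@dataclass
class SplitAssignment:
    """Per-sample train/val/test assignment."""

    assignment: np.ndarray  # array of str in SPLIT_NAMES
    fractions: tuple[float, float, float]
    seed: int
    stratified: bool = False

    def indices(self, which: str) -> np.ndarray:
        return np.flatnonzero(self.assignment == which)


# ----------------------------------------------------------------------
# readers / writers
def read_modality(path: str, format: str, spec: ModalitySpec):
    """Read one modality matrix and validate it against ``spec``.

    Returns ``(matrix, sample_ids, feature_names)``.  For ``mtx``, the file
    must sit next to ``features.tsv`` and ``barcodes.tsv`` sidecars and uses
    the 10x convention (features as rows); the returned matrix is dense
    samples x features.
    """
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        X = df.to_numpy(dtype=float)
        sample_ids = [str(s) for s in df.index]
        feature_names = [str(c) for c in df.columns]
    elif format == "mtx":
        d = os.path.dirname(os.path.abspath(path))
        feat_path = os.path.join(d, "features.tsv")
        bc_path = os.path.join(d, "barcodes.tsv")
        for p in (feat_path, bc_path):
            if not os.path.exists(p):
                raise FormatError(f"MTX sidecar missing: {p}")
        M = spio.mmread(path)
        feature_names = pd.read_csv(feat_path, sep="\t", header=None)[0].astype(str).tolist()
        sample_ids = pd.read_csv(bc_path, sep="\t", header=None)[0].astype(str).tolist()
        M = M.toarray() if sparse.issparse(M) else np.asarray(M)
        if M.shape != (len(feature_names), len(sample_ids)):
            raise FormatError(
                f"MTX shape {M.shape} does not match sidecars "
                f"({len(feature_names)} features, {len(sample_ids)} barcodes)"
            )
        X = M.T.astype(float)
    else:
        raise ValueError(f"unknown format {format!r}")
    if X.shape[1] != spec.dim:
        raise FormatError(
            f"{path}: {X.shape[1]} features but spec {spec.name!r} declares {spec.dim}"
        )
    validate_support(X, spec)
    return X, sample_ids, feature_names


def write_modality(path: str, X: np.ndarray, format: str,
                   sample_ids=None, feature_names=None) -> None:
    X = np.asarray(X)
    n, d = X.shape
    if sample_ids is None:
        sample_ids = [f"sample{i}" for i in range(n)]
    if feature_names is None:
        feature_names = [f"feature{j}" for j in range(d)]
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.DataFrame(X, index=sample_ids, columns=feature_names)
        df.index.name = "sample_id"
        df.to_csv(path, sep=sep)
    elif format == "mtx":
        d_ = os.path.dirname(os.path.abspath(path))
        os.makedirs(d_, exist_ok=True)
        spio.mmwrite(path, sparse.coo_matrix(X.T))
        pd.Series(feature_names).to_csv(os.path.join(d_, "features.tsv"),
                                        sep="\t", header=False, index=False)
        pd.Series(sample_ids).to_csv(os.path.join(d_, "barcodes.tsv"),
                                     sep="\t", header=False, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels(path: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "label"])
    return df.set_index("sample_id")["label"]


def write_labels(path: str, sample_ids, labels) -> None:
    pd.DataFrame({"sample_id": sample_ids, "label": labels}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_split(path: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "split"])
    bad = ~df["split"].isin(SPLIT_NAMES)
    if bad.any():
        raise FormatError(f"unknown split value {df['split'][bad].iloc[0]!r}")
    return df.set_index("sample_id")["split"]


def write_split(path: str, sample_ids, split) -> None:
    pd.DataFrame({"sample_id": sample_ids, "split": split}).to_csv(
        path, sep="\t", header=False, index=False
    )


# ----------------------------------------------------------------------
# preprocessing transforms
def select_top_variable(X: np.ndarray, k: int) -> np.ndarray:
    """Indices of the ``k`` features with the largest median absolute deviation.

    MAD is median(|x - median(x)|), unscaled.  Ties break by ascending
    original feature index; the returned indices are sorted by decreasing MAD.
    """
    X = np.asarray(X, dtype=float)
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds the number of features {X.shape[1]}")
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    # stable sort on negated MAD => descending MAD, ties by ascending index
    order = np.argsort(-mad, kind="stable")
    return order[:k]


def clip_beta_values(X: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    """Map 0 -> eps and 1 -> 1 - eps so beta log-densities stay finite."""
    X = np.asarray(X, dtype=float)
    if ((X < 0) | (X > 1)).any():
        r, c = np.argwhere((X < 0) | (X > 1))[0]
        raise ValidationError(f"value {X[r, c]!r} at (row={r}, col={c}) outside [0, 1]")
    out = X.copy()
    out[out == 0.0] = epsilon
    out[out == 1.0] = 1.0 - epsilon
    return out


def binarize_counts(X: np.ndarray) -> np.ndarray:
    """0 reads -> 0, at least 1 read -> 1."""
    X = np.asarray(X)
    if (X < 0).any():
        r, c = np.argwhere(X < 0)[0]
        raise ValidationError(f"negative count {X[r, c]!r} at (row={r}, col={c})")
    return (X > 0).astype(float)


def _largest_remainder(n: int, fractions) -> np.ndarray:
    """Deterministic integer split sizes summing to n (largest-remainder)."""
    fr = np.asarray(fractions, dtype=float)
    raw = fr * n
    base = np.floor(raw).astype(int)
    rem = raw - base
    short = n - base.sum()
    # assign leftover units to the largest remainders; ties to earlier parts
    order = np.argsort(-rem, kind="stable")
    for i in order[:short]:
        base[i] += 1
    return base


def make_split(labels, n: int, fractions=(0.8, 0.1, 0.1), seed: int = 0) -> SplitAssignment:
    """Random train/val/test partition, stratified per class when labels given.

    Deterministic given ``seed``.  Stratification keeps each class's per-split
    proportions within one sample of the requested fractions.  A class with
    fewer samples than nonzero split parts is assigned greedily to the parts
    with the largest fractions (with a warning).
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions) or not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must be three nonnegative values summing to 1")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=object)

    def assign(idx):
        idx = rng.permutation(idx)
        n_parts = sum(f > 0 for f in fractions)
        if 0 < len(idx) < n_parts:
            warnings.warn(
                f"class with {len(idx)} samples cannot populate all {n_parts} split parts; "
                "assigning greedily largest-fraction-first"
            )
            by_fraction = np.argsort(-np.asarray(fractions), kind="stable")
            for i, part in zip(idx, by_fraction):
                assignment[i] = SPLIT_NAMES[part]
            return
        sizes = _largest_remainder(len(idx), fractions)
        bounds = np.cumsum(sizes)
        assignment[idx[: bounds[0]]] = "train"
        assignment[idx[bounds[0]: bounds[1]]] = "val"
        assignment[idx[bounds[1]:]] = "test"

    if labels is None:
        assign(np.arange(n))
        stratified = False
    else:
        labels = np.asarray(labels)
        if len(labels) != n:
            raise ValueError("labels length does not match n")
        for cls in np.unique(labels):
            assign(np.flatnonzero(labels == cls))
        stratified = True
    return SplitAssignment(
        assignment=assignment.astype(str), fractions=fractions, seed=seed,
        stratified=stratified,
    )


# ----------------------------------------------------------------------
# dataset directory layout
def write_dataset(dirpath: str, dataset: MultiOmicsDataset, format: str = "csv") -> None:
    """Write a dataset as one matrix file per modality plus label/split TSVs
    and a small YAML manifest of the modality specs."""
    import yaml

    os.makedirs(dirpath, exist_ok=True)
    manifest = {"format": format, "modalities": []}
    for spec, X in dataset.modalities:
        if format == "mtx":
            sub = os.path.join(dirpath, spec.name)
            os.makedirs(sub, exist_ok=True)
            fname = os.path.join(sub, "matrix.mtx")
        else:
            fname = os.path.join(dirpath, f"{spec.name}.{format}")
        write_modality(fname, X, format, sample_ids=dataset.sample_ids,
                       feature_names=dataset.feature_names.get(spec.name))
        manifest["modalities"].append(
            {"name": spec.name, "dim": spec.dim, "family": spec.family,
             "n_categories": spec.n_categories, "epsilon": spec.epsilon,
             "path": os.path.relpath(fname, dirpath)}
        )
    if dataset.labels is not None:
        write_labels(os.path.join(dirpath, "labels.tsv"), dataset.sample_ids, dataset.labels)
        manifest["labels"] = "labels.tsv"
    if dataset.split is not None:
        write_split(os.path.join(dirpath, "split.tsv"), dataset.sample_ids, dataset.split)
        manifest["split"] = "split.tsv"
    with open(os.path.join(dirpath, "dataset.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_dataset(dirpath: str) -> MultiOmicsDataset:
    import yaml

    with open(os.path.join(dirpath, "dataset.yaml")) as fh:
        manifest = yaml.safe_load(fh)
    fmt = manifest["format"]
    modalities = []
    sample_ids = None
    feature_names = {}
    for m in manifest["modalities"]:
        spec = ModalitySpec(name=m["name"], dim=m["dim"], family=m["family"],
                            n_categories=m.get("n_categories", 5),
                            epsilon=m.get("epsilon", 1e-6))
        X, sids, fnames = read_modality(os.path.join(dirpath, m["path"]), fmt, spec)
        if sample_ids is not None and sids != sample_ids:
            raise FormatError(f"modality {spec.name!r} has mismatched sample ids")
        sample_ids = sids
        feature_names[spec.name] = fnames
        modalities.append((spec, X))
    labels = split = None
    if manifest.get("labels"):
        labels = read_labels(os.path.join(dirpath, manifest["labels"])).reindex(sample_ids).to_numpy()
    if manifest.get("split"):
        split = read_split(os.path.join(dirpath, manifest["split"])).reindex(sample_ids).to_numpy()
    return MultiOmicsDataset(modalities=modalities, sample_ids=sample_ids,
                             labels=labels, split=split, feature_names=feature_names)
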