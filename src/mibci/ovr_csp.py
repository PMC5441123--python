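"""One-versus-rest common spatial patterns (CSP) over the four MI classes.

For each class c the generalized eigenproblem of (Sigma_c, Sigma_c +
Sigma_rest) is solved; the simultaneous diagonalization pairs eigenvalues so
that lambda(c) + lambda(rest) = 1 for every filter.  Filters at both ends of
the spectrum carry the most class-discriminative variance; their
log-variance projections are the classifier features.

Both input pathways are supported: raw selected band components (cspW_Data)
and temporal-ICA components (cspW_IC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .synth import MI_CLASSES

LOG_FLOOR = 1e-12


def _epoch_data(ep) -> np.ndarray:
    if isinstance(ep, np.ndarray):
        return np.atleast_2d(ep)
    if hasattr(ep, "mi_class"):        # Epoch-like
        return ep.data
    return np.atleast_2d(np.asarray(ep, float))


def class_covariance(epochs) -> np.ndarray:
    """Average trace-normalized spatial covariance, sum_e (XX'/tr XX') / n."""
    if len(epochs) < 2:
        raise ValueError("need at least 2 epochs per class")
    acc = None
    for ep in epochs:
        X = _epoch_data(ep)
        C = X @ X.T
        tr = np.trace(C)
        if tr <= 0:
            raise ValueError("zero-variance epoch")
        acc = C / tr if acc is None else acc + C / tr
    return acc / len(epochs)


@dataclass
class CSPFilterSet:
    """Per-class spatial filters from the one-versus-rest decomposition.

    ``per_class[c]`` = (filters, eigenvalues): the full C x C filter matrix
    (rows are filters, sorted by eigenvalue descending, each row's
    largest-magnitude entry positive) and the eigenvalues in [0, 1].  The
    first and last ``n_pairs`` rows of each class's filters are retained for
    feature extraction.
    """

    per_class: dict
    n_pairs: int = 2

    @property
    def classes(self) -> list:
        return list(self.per_class)

    @property
    def n_channels(self) -> int:
        return next(iter(self.per_class.values()))[0].shape[1]

    @property
    def feature_length(self) -> int:
        return len(self.per_class) * 2 * self.n_pairs

    def retained(self, cls) -> np.ndarray:
        """First and last n_pairs filters of class ``cls`` (2*n_pairs x C)."""
        F, _ = self.per_class[cls]
        return np.vstack([F[: self.n_pairs], F[-self.n_pairs:]])


@dataclass
class FeatureVector:
    values: np.ndarray
    label: str = "unknown"

    def __post_init__(self):
        self.values = np.asarray(self.values, float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")


def _fix_signs(F: np.ndarray) -> np.ndarray:
    signs = np.sign(F[np.arange(F.shape[0]), np.argmax(np.abs(F), axis=1)])
    signs[signs == 0] = 1.0
    return F * signs[:, None]


def fit_ovr_csp(epochs_by_class: dict, n_pairs: int = 2, *,
                composite: str = "sum", shrinkage: float = 1e-6) -> CSPFilterSet:
    """Fit one CSP filter set per class against the rest.

    ``composite="sum"`` solves eig(Sigma_c, Sigma_c + Sigma_rest), whose
    eigenvalue pairs sum to one exactly; ``composite="rest"`` solves the
    alternative eig(Sigma_c, Sigma_rest).  The rest covariance is the
    unweighted mean of the other classes' covariances (balanced by class).
    A singular composite matrix is regularized by ``shrinkage`` toward a
    scaled identity, with a warning.
    """
    classes = [c for c in MI_CLASSES if c in epochs_by_class] or list(epochs_by_class)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    covs = {c: class_covariance(epochs_by_class[c]) for c in classes}
    per_class = {}
    for c in classes:
        rest = np.mean([covs[o] for o in classes if o != c], axis=0)
        B = covs[c] + rest if composite == "sum" else rest
        target = covs[c]
        try:
            np.linalg.cholesky(B)
        except np.linalg.LinAlgError:
            warnings.warn(f"singular composite covariance for class {c}; "
                          f"applying shrinkage {shrinkage}")
            gamma = shrinkage * np.trace(B) / B.shape[0]
            B = B + gamma * np.eye(B.shape[0])
        w, V = linalg.eigh(target, B)      # ascending; V' B V = I
        order = np.argsort(-w)
        w, V = w[order], V[:, order]
        F = _fix_signs(V.T)
        per_class[c] = (F, np.clip(w, 0.0, 1.0) if composite == "sum" else w)
    return CSPFilterSet(per_class, n_pairs)


def extract_features(filters: CSPFilterSet, epoch) -> FeatureVector:
    """Log of trace-normalized projection variances through every class model.

    Per class model, the epoch is projected onto the retained filters; each
    feature is log(var_i / sum_j var_j).  Zero-variance projections are
    floored at log(1e-12) and flagged with a warning.
    """
    X = _epoch_data(epoch)
    if X.shape[0] != filters.n_channels:
        raise ValueError(f"epoch has {X.shape[0]} channels, "
                         f"filters expect {filters.n_channels}")
    label = getattr(epoch, "mi_class", "unknown")
    feats = []
    for c in filters.classes:
        proj = filters.retained(c) @ X
        v = proj.var(axis=1)
        tot = v.sum()
        if tot <= 0:
            warnings.warn("zero-variance projection; flooring features")
            feats.extend([np.log(LOG_FLOOR)] * len(v))
            continue
        feats.extend(np.log(np.maximum(v / tot, LOG_FLOOR)))
    return FeatureVector(np.array(feats), label)


def first_last_gap(filters: CSPFilterSet, epochs, cls) -> float:
    """Mean over epochs of var(first filter proj) - var(last filter proj).

    Raw (non-log) variance units of the class ``cls`` model — the quantity
    used to compare the separability delivered by the two input pathways.
    """
    if not len(epochs):
        raise ValueError("need at least one epoch")
    F, _ = filters.per_class[cls]
    gaps = []
    for ep in epochs:
        X = _epoch_data(ep)
        first = F[0] @ X
        last = F[-1] @ X
        gaps.append(first.var() - last.var())
    return float(np.mean(gaps))


def fisher_ratio(features: list) -> float:
    """Between/within-class variance ratio of feature vectors (diagnostic)."""
    by_class = {}
    for f in features:
        by_class.setdefault(f.label, []).append(f.values)
    mus = {c: np.mean(v, axis=0) for c, v in by_class.items()}
    grand = np.mean([f.values for f in features], axis=0)
    between = np.mean([np.sum((mus[c] - grand) ** 2) for c in by_class])
    within = np.mean([np.sum((np.array(v) - mus[c]) ** 2, axis=1).mean()
                      for c, v in by_class.items()])
    return float(between / max(within, 1e-12))
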