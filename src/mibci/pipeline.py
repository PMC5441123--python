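"""Offline training pipeline, cross-validated pathway comparison, ERD/ERS index.

Orchestrates: preprocessing -> characteristic-component selection ->
temporal ICA -> one-versus-rest CSP (both input pathways: raw band
components, ``cspW_Data``; ICA components, ``cspW_IC``) -> classifier
training; and the repeated stratified k-fold comparison of the two pathways
across classifiers.
"""

from __future__ import annotations

import hashlib
import json
import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import ovr_csp, preprocessing, selection, swnn, synth, temporal_ica
from .preprocessing import Epoch

DEFAULT_CONFIG = {
    "epoch": {"window": [0.0, 4.0], "baseline_s": 0.5},
    "filterbank": {"low": 0.0, "high": 60.0, "width": 2.0, "order": 10, "rp": 0.5},
    "selection": {"top_k": 10, "screen": True, "aggregate": "pairwise"},
    "ica": {"order": 6, "lr": 0.05, "max_iter": 500, "tol": 1e-6,
            "refit_every": 1, "max_samples": 100_000},
    "csp": {"n_pairs": 2, "composite": "sum"},
    "classifier": {"name": "swnn", "pathway": "ic", "epochs": 300, "lr": 0.01},
}


def _merge(base: dict, override: dict) -> dict:
    out = {}
    for k, v in base.items():
        if isinstance(v, dict):
            out[k] = _merge(v, override.get(k, {}))
        else:
            out[k] = override.get(k, v)
    return out


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# Feature construction
# --------------------------------------------------------------------------

def component_epochs(epochs, comp_selection, *, order: int = 10,
                     rp: float = 0.5):
    """Stack each epoch's selected (electrode, band) components into C x T.

    Returns ``(arrays, labels)`` where ``arrays[e]`` holds the C selected
    narrowband signals of epoch ``e``.  One filter design per band, applied
    forward-backward across all epochs at once.
    """
    keys = comp_selection.keys if hasattr(comp_selection, "keys") else list(comp_selection)
    if not len(epochs):
        return [], []
    fs = epochs[0].fs
    ch_names = epochs[0].ch_names
    X = np.stack([ep.data for ep in epochs])             # E x C x T
    out = np.empty((X.shape[0], len(keys), X.shape[2]))
    for k, (el, band) in enumerate(keys):
        sos = preprocessing._design_band(band[0], band[1], fs, order, rp)
        ci = ch_names.index(el)
        out[:, k, :] = sps.sosfiltfilt(sos, X[:, ci, :], axis=-1)
    labels = [ep.mi_class for ep in epochs]
    return list(out), labels


def _group_by_class(arrays, labels) -> dict:
    groups = {}
    for x, lab in zip(arrays, labels):
        groups.setdefault(lab, []).append(x)
    return groups


def features_matrix(filters, arrays, labels=None):
    """Feature matrix (n_epochs x feature_length) through a CSP filter set."""
    feats = [ovr_csp.extract_features(filters, x) for x in arrays]
    X = np.array([f.values for f in feats])
    y = np.array(labels) if labels is not None else None
    return X, y


# --------------------------------------------------------------------------
# Classifier roster
# --------------------------------------------------------------------------

class _KernelLSClassifier:
    """Least-squares classifier with an RBF kernel (one-hot kernel ridge)."""

    def __init__(self, alpha: float = 1.0, gamma=None):
        self.alpha, self.gamma = alpha, gamma

    def fit(self, X, y):
        from sklearn.kernel_ridge import KernelRidge

        self.classes_ = np.unique(y)
        T = np.array([(y == c).astype(float) for c in self.classes_]).T
        self.model_ = KernelRidge(alpha=self.alpha, kernel="rbf", gamma=self.gamma)
        self.model_.fit(X, T)
        return self

    def predict(self, X):
        return self.classes_[np.argmax(self.model_.predict(X), axis=1)]


def make_classifier(name: str, seed: int = 0, **kwargs):
    """Factory for the benchmark roster: swnn | mlp | rbf_svm | ls_svm."""
    if name == "swnn":
        return swnn.SWNN(seed=seed, epochs=kwargs.get("epochs", 300),
                         lr=kwargs.get("lr", 0.01),
                         rewire_p=kwargs.get("rewire_p", 0.1))
    if name == "mlp":
        from sklearn.neural_network import MLPClassifier

        return MLPClassifier(hidden_layer_sizes=(8,) * 10, activation="tanh",
                             max_iter=800, random_state=seed)
    if name == "rbf_svm":
        from sklearn.svm import SVC

        return SVC(kernel="rbf", C=kwargs.get("C", 1.0), random_state=seed)
    if name == "ls_svm":
        return _KernelLSClassifier(alpha=kwargs.get("alpha", 1.0))
    raise ValueError(f"unknown classifier {name!r}")


# --------------------------------------------------------------------------
# Training pipeline
# --------------------------------------------------------------------------

@dataclass
class PipelineArtifacts:
    """Everything the online decoder needs, learned offline."""

    selection: selection.ComponentSelection
    ica: temporal_ica.UnmixingModel
    csp_data: ovr_csp.CSPFilterSet
    csp_ic: ovr_csp.CSPFilterSet
    classifier: object
    config: dict
    config_hash: str = ""
    montage: synth.MontageSpec = None

    def __post_init__(self):
        if not self.config_hash:
            self.config_hash = config_hash(self.config)

    def save(self, path) -> None:
        with open(path, "wb") as f:
            pickle.dump(self, f)

    @classmethod
    def load(cls, path) -> "PipelineArtifacts":
        with open(path, "rb") as f:
            return pickle.load(f)

    # -- online decoding -----------------------------------------------------

    def predict_window(self, window: np.ndarray, fs: float = None) -> str:
        """Decode one EEG window (n_eeg x n) to an MI class or idle."""
        fs = fs or self.montage.fs
        ep = Epoch(window, "unknown", fs, self.montage.eeg_labels)
        ep = preprocessing.car_filter(ep)
        fb = self.config["filterbank"]
        arrays, _ = component_epochs([ep], self.selection,
                                     order=fb["order"], rp=fb["rp"])
        x = arrays[0]
        if self.config["classifier"]["pathway"] == "ic":
            x = self.ica.transform(x)
            filters = self.csp_ic
        else:
            filters = self.csp_data
        feats = ovr_csp.extract_features(filters, x)
        return self.classifier.predict(np.atleast_2d(feats.values))[0]

    def decoder(self):
        """Callable suitable for :func:`mibci.game.run_session`."""
        return lambda window, state, t: self.predict_window(window)


def train_pipeline(recordings, config: dict = None, seed: int = 0) -> PipelineArtifacts:
    """Run the full offline path on one participant's recordings.

    preprocessing (notch, EOG regression, epoching with CAR + baseline) ->
    R-squared component selection -> temporal ICA -> OVR-CSP on both
    pathways -> classifier training on the configured pathway.  Deterministic
    for a fixed seed.
    """
    config = _merge(DEFAULT_CONFIG, config or {})
    if isinstance(recordings, synth.Recording):
        recordings = [recordings]
    rng = np.random.default_rng(seed)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as e:
            raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e

    epochs = []
    for rec in recordings:
        rec = stage("notch", preprocessing.notch_filter, rec)
        rec = stage("eog_regression", preprocessing.regress_out_eog, rec)
        epochs.extend(stage(
            "epoching", preprocessing.extract_epochs, rec,
            tuple(config["epoch"]["window"]), include_idle=True,
            baseline_s=config["epoch"]["baseline_s"]))
    mi_epochs = [ep for ep in epochs if ep.mi_class != "idle"]
    classes = {ep.mi_class for ep in mi_epochs}
    if classes != set(synth.MI_CLASSES):
        raise RuntimeError(f"pipeline stage 'epoching' failed: need all 4 MI "
                           f"classes, got {sorted(classes)}")

    fb = config["filterbank"]
    rsmap = stage("ranking", selection.rank_components, epochs,
                  low=fb["low"], high=fb["high"], width=fb["width"],
                  order=fb["order"], rp=fb["rp"],
                  aggregate=config["selection"]["aggregate"])
    sel = stage("selection", selection.select_components, rsmap,
                config["selection"]["top_k"], config["selection"]["screen"])

    arrays, labels = stage("components", component_epochs, mi_epochs, sel,
                           order=fb["order"], rp=fb["rp"])

    ica_cfg = config["ica"]
    max_samp = int(ica_cfg["max_samples"])
    concat = np.hstack(arrays)
    if concat.shape[1] > max_samp:
        concat = concat[:, :max_samp]
    ica = stage("ica", temporal_ica.fit_unmixing, concat,
                ica_cfg["order"], lr=ica_cfg["lr"],
                max_iter=ica_cfg["max_iter"], tol=ica_cfg["tol"],
                refit_every=ica_cfg["refit_every"],
                seed=int(rng.integers(2 ** 31)))
    ic_arrays = [ica.transform(x) for x in arrays]

    csp_cfg = config["csp"]
    csp_data = stage("csp_data", ovr_csp.fit_ovr_csp,
                     _group_by_class(arrays, labels),
                     csp_cfg["n_pairs"], composite=csp_cfg["composite"])
    csp_ic = stage("csp_ic", ovr_csp.fit_ovr_csp,
                   _group_by_class(ic_arrays, labels),
                   csp_cfg["n_pairs"], composite=csp_cfg["composite"])

    clf_cfg = config["classifier"]
    use = ic_arrays if clf_cfg["pathway"] == "ic" else arrays
    filters = csp_ic if clf_cfg["pathway"] == "ic" else csp_data
    X, y = features_matrix(filters, use, labels)
    clf = make_classifier(clf_cfg["name"], seed=int(rng.integers(2 ** 31)),
                          epochs=clf_cfg.get("epochs", 300),
                          lr=clf_cfg.get("lr", 0.01))
    stage("classifier", clf.fit, X, y)

    montage = recordings[0].montage
    return PipelineArtifacts(sel, ica, csp_data, csp_ic, clf, config,
                             montage=montage)


# --------------------------------------------------------------------------
# Cross-validation
# --------------------------------------------------------------------------

@dataclass
class CVReport:
    """Accuracies (percent) per (pathway, classifier) over repeated CV."""

    results: dict = field(default_factory=dict)   # (pathway, clf) -> dict
    repeats: int = 10
    folds: int = 10

    def mean(self, pathway: str, classifier: str) -> float:
        return self.results[(pathway, classifier)]["mean"]

    def table(self) -> pd.DataFrame:
        rows = []
        for (pathway, clf), r in self.results.items():
            rows.append({"pathway": pathway, "classifier": clf,
                         "mean_acc": r["mean"], "sd_acc": r["sd"]})
        return pd.DataFrame(rows)

    def paired_records(self, pathway: str, classifier: str) -> np.ndarray:
        return np.array(self.results[(pathway, classifier)]["per_fold"])

    def paired_test(self, classifier: str, pathway_a: str = "ic",
                    pathway_b: str = "data"):
        """Paired t-test on per-fold accuracies between the two pathways."""
        from scipy import stats

        a = self.paired_records(pathway_a, classifier)
        b = self.paired_records(pathway_b, classifier)
        return stats.ttest_rel(a, b)

    def to_json(self, path=None):
        payload = {
            f"{p}|{c}": {k: v for k, v in r.items()}
            for (p, c), r in self.results.items()
        }
        s = json.dumps(payload, indent=1, default=float)
        if path:
            with open(path, "w") as f:
                f.write(s)
        return s


def cross_validate(features_by_pathway: dict, classifiers=("swnn",),
                   repeats: int = 10, folds: int = 10, seed: int = 0,
                   classifier_kwargs: dict = None) -> CVReport:
    """Repeated stratified k-fold accuracy per pathway and classifier.

    ``features_by_pathway`` maps pathway name -> (X, y).  Folds are
    stratified by class with a fresh seeded shuffle per repeat; identical
    fold assignments are used for every pathway and classifier so per-fold
    records are paired.  A class smaller than ``folds`` reduces the fold
    count with a warning.
    """
    from sklearn.model_selection import StratifiedKFold

    classifier_kwargs = classifier_kwargs or {}
    report = CVReport({}, repeats, folds)
    some_y = next(iter(features_by_pathway.values()))[1]
    _, counts = np.unique(some_y, return_counts=True)
    k = min(folds, counts.min())
    if k < folds:
        warnings.warn(f"smallest class has {counts.min()} epochs; "
                      f"reducing folds {folds} -> {k}")
    report.folds = int(k)

    rng = np.random.default_rng(seed)
    fold_plans = []
    for _ in range(repeats):
        skf = StratifiedKFold(n_splits=int(k), shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        fold_plans.append(list(skf.split(np.zeros(len(some_y)), some_y)))

    for pathway, (X, y) in features_by_pathway.items():
        X, y = np.asarray(X, float), np.asarray(y)
        for name in classifiers:
            per_fold = []
            for r, plan in enumerate(fold_plans):
                for f, (tr, te) in enumerate(plan):
                    clf = make_classifier(name, seed=seed + 1000 * r + f,
                                          **classifier_kwargs.get(name, {}))
                    clf.fit(X[tr], y[tr])
                    pred = np.asarray(clf.predict(X[te]))
                    per_fold.append(100.0 * np.mean(pred == y[te]))
            report.results[(pathway, name)] = {
                "mean": float(np.mean(per_fold)),
                "sd": float(np.std(per_fold, ddof=1)),
                "per_fold": per_fold,
            }
    return report


# --------------------------------------------------------------------------
# ERD/ERS quantification
# --------------------------------------------------------------------------

def erds_index(epochs, idle_epochs, component, *, order: int = 10,
               rp: float = 0.5) -> float:
    """Relative band-power change of MI epochs against the idle baseline.

    (mean MI power - mean idle power) / mean idle power for the given
    (electrode, band) component; negative values are ERD, positive ERS.
    """
    if not len(epochs) or not len(idle_epochs):
        raise ValueError("need non-empty MI and idle epoch sets")
    el, band = component

    def mean_power(eps):
        arrays, _ = component_epochs(eps, [(el, tuple(band))], order=order, rp=rp)
        return float(np.mean([np.mean(x ** 2) for x in arrays]))

    p_mi = mean_power(epochs)
    p_idle = mean_power(idle_epochs)
    if p_idle <= 0:
        raise ValueError("idle power is zero; index undefined")
    return (p_mi - p_idle) / p_idle
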