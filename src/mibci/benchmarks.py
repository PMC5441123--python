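"""Reference synthetic benchmarks shared by the CLI, tests and scripts.

These functions pin the study conditions of the package's evaluation suite:
scaled-down synthetic participants small enough to run on one CPU in
minutes, while keeping the protocol's structure (4 balanced classes,
blank/MI trial flow, planted ERD/ERS sources, artifacts).
"""

from __future__ import annotations

import numpy as np

from . import ovr_csp, pipeline, preprocessing, selection, synth, temporal_ica

#: Scaled-down participant used by the pathway and chance-level benchmarks:
#: 250 Hz, 2 runs x 10 reps/class = 80 trials (20 per class), mu/beta
#: filterbank only.  The full-protocol defaults (1000 Hz, 240 trials,
#: 0-60 Hz) remain the package defaults.
BENCH_CONFIG = {
    "filterbank": {"low": 4.0, "high": 32.0, "width": 2.0, "order": 10, "rp": 0.5},
    "selection": {"top_k": 10, "screen": True},
    "ica": {"order": 6, "max_iter": 200, "max_samples": 80_000},
    "csp": {"n_pairs": 2},
    "classifier": {"epochs": 200},
}


def make_participant(seed: int, *, fs: float = 250.0, n_sessions: int = 1,
                     runs: int = 2, reps: int = 10,
                     profile: str = "player1") -> synth.Recording:
    """One scaled-down synthetic participant recording."""
    montage = synth.MontageSpec(fs=fs)
    return synth.simulate_recording(n_sessions, runs, reps, montage=montage,
                                    profile=profile, seed=seed)


def participant_features(seed: int, *, reps: int = 10, fs: float = 250.0):
    """Train-side features for both CSP pathways of one participant.

    Returns a dict with the feature matrices per pathway, the labels, the
    fitted CSP filter sets, component epoch arrays and the selection —
    everything the pathway comparison and chance-level analyses need.
    """
    rec = make_participant(seed, fs=fs, reps=reps)
    rec = preprocessing.notch_filter(rec)
    rec = preprocessing.regress_out_eog(rec)
    epochs = preprocessing.extract_epochs(rec, (0.0, 4.0), include_idle=True)
    mi = [ep for ep in epochs if ep.mi_class != "idle"]

    fb = BENCH_CONFIG["filterbank"]
    rsmap = selection.rank_components(epochs, low=fb["low"], high=fb["high"],
                                      width=fb["width"], order=fb["order"])
    sel = selection.select_components(rsmap, BENCH_CONFIG["selection"]["top_k"],
                                      BENCH_CONFIG["selection"]["screen"])
    arrays, labels = pipeline.component_epochs(mi, sel, order=fb["order"])

    ica_cfg = BENCH_CONFIG["ica"]
    concat = np.hstack(arrays)[:, : ica_cfg["max_samples"]]
    ica = temporal_ica.fit_unmixing(concat, ica_cfg["order"],
                                    max_iter=ica_cfg["max_iter"], seed=seed)
    ic_arrays = [ica.transform(x) for x in arrays]

    n_pairs = BENCH_CONFIG["csp"]["n_pairs"]
    by_class = pipeline._group_by_class(arrays, labels)
    by_class_ic = pipeline._group_by_class(ic_arrays, labels)
    csp_data = ovr_csp.fit_ovr_csp(by_class, n_pairs)
    csp_ic = ovr_csp.fit_ovr_csp(by_class_ic, n_pairs)
    X_data, y = pipeline.features_matrix(csp_data, arrays, labels)
    X_ic, _ = pipeline.features_matrix(csp_ic, ic_arrays, labels)
    return {
        "recording": rec, "epochs": epochs, "selection": sel,
        "arrays": arrays, "ic_arrays": ic_arrays, "labels": np.array(labels),
        "csp_data": csp_data, "csp_ic": csp_ic, "ica": ica,
        "X_data": X_data, "X_ic": X_ic, "y": y,
    }


def pathway_benchmark(seed: int, *, classifier: str = "swnn",
                      repeats: int = 2, folds: int = 4,
                      clf_epochs: int = 200) -> dict:
    """One Monte-Carlo draw of the cspW_Data vs cspW_IC comparison.

    Computes cross-validated accuracy for both pathways plus the first-last
    CSP feature-variance gap (foot-model, foot epochs), mirroring the
    pathway evaluation design.
    """
    feats = participant_features(seed)
    report = pipeline.cross_validate(
        {"data": (feats["X_data"], feats["y"]), "ic": (feats["X_ic"], feats["y"])},
        classifiers=(classifier,), repeats=repeats, folds=folds, seed=seed,
        classifier_kwargs={classifier: {"epochs": clf_epochs}}
        if classifier == "swnn" else None)
    cls = "foot"
    sel_data = [x for x, l in zip(feats["arrays"], feats["labels"]) if l == cls]
    sel_ic = [x for x, l in zip(feats["ic_arrays"], feats["labels"]) if l == cls]
    return {
        "seed": seed,
        "acc_data": report.mean("data", classifier),
        "acc_ic": report.mean("ic", classifier),
        "gap_data": ovr_csp.first_last_gap(feats["csp_data"], sel_data, cls),
        "gap_ic": ovr_csp.first_last_gap(feats["csp_ic"], sel_ic, cls),
        "n_trials": int(len(feats["y"])),
    }


def mvar_recovery_rmse(seed: int, *, M: int = 3, order: int = 2,
                       T: int = 10_000, sigma: float = 0.1) -> float:
    """Coefficient RMSE of the least-squares MVAR fit on simulated data.

    Draws a random stable coefficient set (rejection-sampled on the spectral
    radius of the companion matrix), simulates T samples, refits, and returns
    the root-mean-square error against the generating coefficients.
    """
    rng = np.random.default_rng(seed)
    while True:
        A = 0.25 * rng.standard_normal((order, M, M))
        A[0] += 0.3 * np.eye(M)
        top = np.hstack(list(A))
        companion = np.vstack([top, np.eye(M * (order - 1), M * order)])
        if np.max(np.abs(np.linalg.eigvals(companion))) < 0.95:
            break
    X = np.zeros((M, T))
    E = sigma * rng.standard_normal((M, T))
    for t in range(order, T):
        X[:, t] = sum(A[k] @ X[:, t - 1 - k] for k in range(order)) + E[:, t]
    fit = temporal_ica.fit_mvar(X, order)
    return float(np.sqrt(np.mean((fit.coeffs - A) ** 2)))


def chance_level_cv(seed: int, *, classifier: str = "ls_svm", repeats: int = 2,
                    folds: int = 5) -> float:
    """Cross-validated accuracy (percent) under label permutation, n = 240.

    The full-protocol trial count (2 sessions x 2 runs x 15 reps = 240
    trials) with the class labels randomly permuted; 4 balanced classes put
    forced-choice chance at 25 percent.  The default classifier always picks
    one of the four classes — the SWNN would fall *below* 25 here because its
    idle output codes are never correct.
    """
    feats = participant_features(seed, reps=15)
    rng = np.random.default_rng(seed)
    accs = []
    for p in range(3):          # average over permutation draws
        y_perm = rng.permutation(feats["y"])
        report = pipeline.cross_validate(
            {"data": (feats["X_data"], y_perm)}, classifiers=(classifier,),
            repeats=repeats, folds=folds, seed=seed + p,
            classifier_kwargs={classifier: {"epochs": 150}}
            if classifier == "swnn" else None)
        accs.append(report.mean("data", classifier))
    return float(np.mean(accs))


#: Planted class modulations of the default "player1" source profile:
#: (electrode, band, MI class, ERD(-1) or ERS(+1)).
PLANTED_MODULATIONS = (
    ("Cz", (8.0, 10.0), "foot", -1), ("Cz", (10.0, 12.0), "foot", -1),
    ("Cz", (8.0, 10.0), "tongue", +1), ("Cz", (10.0, 12.0), "tongue", +1),
    ("C3", (12.0, 14.0), "right_hand", -1), ("C3", (14.0, 16.0), "right_hand", -1),
    ("C4", (12.0, 14.0), "left_hand", -1), ("C4", (14.0, 16.0), "left_hand", -1),
    ("Fz", (14.0, 16.0), "tongue", +1),
    ("F4", (20.0, 22.0), "right_hand", +1),
    ("T7", (24.0, 26.0), "left_hand", +1),
)


def erds_sign_benchmark(seed: int, *, reps: int = 6, fs: float = 250.0) -> dict:
    """Fraction of planted modulations whose ERD/ERS index sign is recovered."""
    montage = synth.MontageSpec(fs=fs)
    rec = synth.simulate_recording(1, 1, reps, montage=montage, seed=seed)
    rec = preprocessing.notch_filter(rec)
    epochs = preprocessing.extract_epochs(rec, (0.0, 4.0), include_idle=True)
    idle = [ep for ep in epochs if ep.mi_class == "idle"]
    matches, indices = [], {}
    for el, band, cls, sign in PLANTED_MODULATIONS:
        mi = [ep for ep in epochs if ep.mi_class == cls]
        idx = pipeline.erds_index(mi, idle, (el, band))
        indices[f"{el} {band} {cls}"] = idx
        matches.append(np.sign(idx) == sign)
    return {"seed": seed, "match_rate": float(np.mean(matches)),
            "indices": indices}


def ica_separation_benchmark(seed: int, *, n_sources: int = 3, T: int = 20_000,
                             ar_order: int = 4, innovations: str = "laplace",
                             distinct_spectra: bool = True) -> dict:
    """Amari separation error on one random AR mixture.

    Generates ``n_sources`` independent stable AR processes (heavy-tailed
    Laplace or Gaussian innovations), mixes them with a random
    well-conditioned matrix, and unmixes with the temporal ICA.  Returns the
    Amari index of (separator x mixing) plus the one a sample-wise
    (temporal-structure-blind) FastICA achieves on the same mixture.
    """
    rng = np.random.default_rng(seed)
    S = np.empty((n_sources, T))
    from scipy import signal as sps
    for i in range(n_sources):
        if innovations == "laplace":
            # resonant AR(2) at distinct frequencies, padded to ar_order
            centers = np.linspace(0.05, 0.4, n_sources)
            a = synth._pad(synth.ar2_coeffs(centers[i], 1.0, radius=0.95), ar_order)
            e = rng.laplace(scale=1 / np.sqrt(2), size=T)
        else:
            # broad low-pass AR(1) spectra: Gaussian sources that differ only
            # in their spectral decay, the case sample-wise ICA cannot solve
            poles = np.linspace(0.3, 0.85, n_sources) if distinct_spectra \
                else np.full(n_sources, 0.6)
            a = synth._pad(np.array([poles[i]]), ar_order)
            e = rng.standard_normal(T)
        S[i] = sps.lfilter([1.0], np.r_[1.0, -a], e)
    while True:
        A = rng.standard_normal((n_sources, n_sources))
        if np.linalg.cond(A) < 20:
            break
    X = A @ S

    model = temporal_ica.fit_unmixing(X, ar_order, seed=seed, max_iter=400)
    amari = temporal_ica.amari_index(model.separator @ A)

    from sklearn.decomposition import FastICA
    fica = FastICA(n_components=n_sources, random_state=seed, max_iter=1000,
                   tol=1e-6, whiten="unit-variance")
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        fica.fit(X.T)
    amari_blind = temporal_ica.amari_index(fica.components_ @ A)
    return {"seed": seed, "amari_temporal": amari, "amari_blind": amari_blind}
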