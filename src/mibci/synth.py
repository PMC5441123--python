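"""Synthetic EEG/EOG generation for motor-imagery BCI experiments.

Generates multichannel recordings with the statistical structure the decoding
pipeline assumes: latent autoregressive (AR) sources with class-dependent
band-power modulation (ERD/ERS), a linear forward mixing onto a 25-electrode
scalp montage, 50 Hz line interference, white sensor noise, and single/double
eye blinks on four EOG channels.  The trial scheduler reproduces the standard
cue-paced protocol: 2 s blank, 4 s of motor imagery, four classes balanced
within each run, randomized order.

Everything is deterministic given a seed, so downstream stages are testable
without any recorded data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

MI_CLASSES = ("right_hand", "left_hand", "foot", "tongue")

#: 25 scalp sites (10-20 system) used by default, plus 4 EOG electrodes.
DEFAULT_EEG_LABELS = (
    "Fp1", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T7", "C3", "Cz", "C4", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P3", "Pz", "P4",
)
DEFAULT_EOG_LABELS = ("HEOG-L", "HEOG-R", "VEOG-U", "VEOG-D")

# Planar electrode coordinates (arbitrary head units) used to model spatial
# leakage of each latent source onto neighbouring electrodes.
_GRID_POS = {
    "Fp1": (-1, 4), "Fp2": (1, 4),
    "F7": (-3, 2.8), "F3": (-1.5, 2.8), "Fz": (0, 2.8), "F4": (1.5, 2.8), "F8": (3, 2.8),
    "FT7": (-3, 1.4), "FC3": (-1.5, 1.4), "FCz": (0, 1.4), "FC4": (1.5, 1.4), "FT8": (3, 1.4),
    "T7": (-3, 0), "C3": (-1.5, 0), "Cz": (0, 0), "C4": (1.5, 0), "T8": (3, 0),
    "TP7": (-3, -1.4), "CP3": (-1.5, -1.4), "CPz": (0, -1.4), "CP4": (1.5, -1.4), "TP8": (3, -1.4),
    "P3": (-1.5, -2.8), "Pz": (0, -2.8), "P4": (1.5, -2.8),
}


class ScheduleError(ValueError):
    """Invalid trial-schedule configuration."""


class UnstableModelError(ValueError):
    """Source model has an unstable AR polynomial."""


@dataclass(frozen=True)
class MontageSpec:
    """Channel layout and sampling configuration of a recording."""

    eeg_labels: tuple = DEFAULT_EEG_LABELS
    eog_labels: tuple = DEFAULT_EOG_LABELS
    reference_label: str = "A1"
    fs: float = 1000.0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        labels = tuple(self.eeg_labels) + tuple(self.eog_labels)
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        object.__setattr__(self, "eeg_labels", tuple(self.eeg_labels))
        object.__setattr__(self, "eog_labels", tuple(self.eog_labels))

    @property
    def n_eeg(self) -> int:
        return len(self.eeg_labels)

    @property
    def n_eog(self) -> int:
        return len(self.eog_labels)

    @property
    def ch_names(self) -> tuple:
        return self.eeg_labels + self.eog_labels


@dataclass(frozen=True)
class ScheduleEntry:
    session: int
    run: int
    trial_index: int
    mi_class: str
    onset_s: float


@dataclass
class TrialSchedule:
    """Ordered cue schedule: blank interval, then a fixed MI epoch per trial."""

    entries: list
    blank_s: float = 2.0
    mi_s: float = 4.0
    inter_run_gap_s: float = 10.0

    def __len__(self) -> int:
        return len(self.entries)

    def class_counts(self) -> dict:
        counts = {c: 0 for c in MI_CLASSES}
        for e in self.entries:
            counts[e.mi_class] += 1
        return counts

    @property
    def duration_s(self) -> float:
        """Total recording length needed to contain every trial."""
        last = self.entries[-1]
        return last.onset_s + self.mi_s + self.blank_s

    def to_dict(self) -> dict:
        return {
            "blank_s": self.blank_s,
            "mi_s": self.mi_s,
            "inter_run_gap_s": self.inter_run_gap_s,
            "entries": [dataclasses.asdict(e) for e in self.entries],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialSchedule":
        entries = [ScheduleEntry(**e) for e in d["entries"]]
        return cls(entries, d["blank_s"], d["mi_s"], d.get("inter_run_gap_s", 10.0))


def build_schedule(n_sessions: int = 2, runs_per_session: int = 2,
                   reps_per_class: int = 15, seed: int = 0, *,
                   blank_s: float = 2.0, mi_s: float = 4.0,
                   inter_run_gap_s: float = 10.0) -> TrialSchedule:
    """Build the randomized cue schedule of the MI training protocol.

    Within every run each of the four classes appears exactly
    ``reps_per_class`` times in a seeded random order.  The default
    configuration (2 sessions x 2 runs x 15 reps) yields 240 trials,
    60 per class.
    """
    for name, v in [("n_sessions", n_sessions), ("runs_per_session", runs_per_session),
                    ("reps_per_class", reps_per_class)]:
        if int(v) != v or v < 1:
            raise ScheduleError(f"{name} must be a positive integer, got {v!r}")
    rng = np.random.default_rng(seed)
    entries = []
    t = 0.0
    trial_len = blank_s + mi_s
    for sess in range(n_sessions):
        for run in range(runs_per_session):
            classes = np.repeat(np.arange(4), reps_per_class)
            rng.shuffle(classes)
            for i, ci in enumerate(classes):
                onset = t + i * trial_len + blank_s
                entries.append(ScheduleEntry(sess, run, i, MI_CLASSES[ci], onset))
            t += len(classes) * trial_len + inter_run_gap_s
    return TrialSchedule(entries, blank_s, mi_s, inter_run_gap_s)


@dataclass
class SourceModel:
    """Latent AR source model with class-dependent innovation gains.

    Each of the M sources follows a stationary univariate AR(P) process driven
    by independent innovations.  During an MI epoch of class ``c`` the
    innovation scale of source ``i`` is multiplied by
    ``class_modulation[c][i]``: values below 1 produce ERD (band-power
    decrease), above 1 produce ERS.  ``mixing`` is the M x n_eeg forward
    matrix projecting sources onto the scalp.
    """

    ar_coeffs: np.ndarray          # (M, P) univariate AR coefficients per source
    innovation_scale: np.ndarray   # (M,) sigma per source, in uV
    class_modulation: dict         # class -> (M,) multiplicative gains
    mixing: np.ndarray             # (M, n_eeg)
    innovation_dist: tuple = None  # per-source "gaussian" | "laplace"
    source_names: tuple = None     # descriptive, e.g. "Cz 8-12 Hz"

    def __post_init__(self):
        self.ar_coeffs = np.atleast_2d(np.asarray(self.ar_coeffs, float))
        self.innovation_scale = np.asarray(self.innovation_scale, float)
        self.mixing = np.atleast_2d(np.asarray(self.mixing, float))
        if self.innovation_dist is None:
            self.innovation_dist = ("gaussian",) * self.n_sources
        if np.linalg.matrix_rank(self.mixing) < self.n_sources:
            raise ValueError("mixing matrix must have full row rank")

    @property
    def n_sources(self) -> int:
        return self.ar_coeffs.shape[0]

    @property
    def order(self) -> int:
        return self.ar_coeffs.shape[1]

    def check_stability(self) -> None:
        """Raise :class:`UnstableModelError` listing any offending roots."""
        bad = []
        for i, a in enumerate(self.ar_coeffs):
            poly = np.r_[1.0, -a]          # 1 - a1 z^-1 - ... - aP z^-P
            roots = np.roots(poly) if len(a) else np.array([])
            if np.any(np.abs(roots) >= 1.0):
                bad.append((i, roots[np.abs(roots) >= 1.0]))
        if bad:
            msg = "; ".join(f"source {i}: |roots| = {np.abs(r)}" for i, r in bad)
            raise UnstableModelError(f"unstable AR polynomial(s): {msg}")


def ar2_coeffs(center_hz: float, fs: float, radius: float = 0.97) -> np.ndarray:
    """AR(2) coefficients of a resonator peaked at ``center_hz``."""
    w = 2 * np.pi * center_hz / fs
    return np.array([2 * radius * np.cos(w), -radius ** 2])


def _pad(a: np.ndarray, order: int) -> np.ndarray:
    out = np.zeros(order)
    out[: len(a)] = a
    return out


def default_source_model(montage: MontageSpec = None, profile: str = "player1",
                         seed: int = 0, order: int = 6) -> SourceModel:
    """Default 8-source "Player-1-like" model.

    Six narrowband resonant sources sit at sensorimotor/frontal electrodes in
    mu/beta bands with physiologically-signed class gains (contralateral ERD
    for hand imagery, central ERD for foot, midline ERS for tongue), plus one
    unmodulated posterior alpha source and one broadband heavy-tailed
    background source standing in for non-neural activity.
    """
    montage = montage or MontageSpec()
    fs = montage.fs
    rng = np.random.default_rng(seed)
    neutral = {c: 1.0 for c in MI_CLASSES}

    # (name, electrode, center freq, radius, sigma uV, per-class gains, dist)
    if profile == "player1":
        specs = [
            ("Cz 8-12 Hz", "Cz", 10.0, 0.97, 2.5,
             {**neutral, "foot": 0.5, "tongue": 1.5}, "gaussian"),
            ("C3 12-16 Hz", "C3", 14.0, 0.97, 2.5,
             {**neutral, "right_hand": 0.5}, "gaussian"),
            ("C4 12-16 Hz", "C4", 14.0, 0.97, 2.5,
             {**neutral, "left_hand": 0.5}, "gaussian"),
            ("Fz 14-16 Hz", "Fz", 15.0, 0.975, 1.5,
             {**neutral, "tongue": 1.4}, "gaussian"),
            ("F4 20-22 Hz", "F4", 21.0, 0.97, 1.2,
             {**neutral, "right_hand": 1.3}, "gaussian"),
            ("T7 24-26 Hz", "T7", 25.0, 0.97, 1.2,
             {**neutral, "left_hand": 1.3}, "gaussian"),
            ("Pz alpha bg", "Pz", 10.5, 0.96, 3.0, dict(neutral), "gaussian"),
            ("broadband bg", None, None, None, 6.0, dict(neutral), "laplace"),
        ]
    elif profile == "random":
        electrodes = rng.choice(montage.eeg_labels, size=6, replace=False)
        specs = []
        for k, el in enumerate(electrodes):
            f = float(rng.uniform(8, 28))
            cls = MI_CLASSES[k % 4]
            gain = float(rng.choice([0.5, 1.5]))
            specs.append((f"{el} ~{f:.0f} Hz", el, f, 0.97, 2.5,
                          {**neutral, cls: gain}, "gaussian"))
        specs.append(("Pz alpha bg", "Pz", 10.5, 0.96, 3.0, dict(neutral), "gaussian"))
        specs.append(("broadband bg", None, None, None, 6.0, dict(neutral), "laplace"))
    else:
        raise ValueError(f"unknown profile {profile!r}")

    M = len(specs)
    coeffs = np.zeros((M, order))
    sigma = np.zeros(M)
    mixing = np.zeros((M, montage.n_eeg))
    mods = {c: np.ones(M) for c in MI_CLASSES}
    dists, names = [], []
    pos = np.array([_GRID_POS.get(l, (0.0, 0.0)) for l in montage.eeg_labels])
    for i, (name, el, f0, radius, sig, gains, dist) in enumerate(specs):
        if f0 is not None:
            coeffs[i] = _pad(ar2_coeffs(f0, fs, radius), order)
        else:
            coeffs[i] = _pad(np.array([0.95]), order)   # pink-ish broadband
        sigma[i] = sig
        for c in MI_CLASSES:
            mods[c][i] = gains[c]
        if el is not None:
            d = np.linalg.norm(pos - np.array(_GRID_POS[el]), axis=1)
            mixing[i] = np.exp(-(d / 1.6) ** 2)          # spatial leakage
        else:
            mixing[i] = rng.uniform(0.3, 1.0, montage.n_eeg)
        dists.append(dist)
        names.append(name)
    model = SourceModel(coeffs, sigma, mods, mixing,
                        innovation_dist=tuple(dists), source_names=tuple(names))
    model.check_stability()
    return model


def _class_gain_tracks(model: SourceModel, schedule: TrialSchedule,
                       fs: float, n_samples: int) -> np.ndarray:
    """Per-sample innovation gain for each source (1 outside MI epochs)."""
    g = np.ones((model.n_sources, n_samples))
    for e in schedule.entries:
        i0 = int(round(e.onset_s * fs))
        i1 = min(int(round((e.onset_s + schedule.mi_s) * fs)), n_samples)
        g[:, i0:i1] = model.class_modulation[e.mi_class][:, None]
    return g


def simulate_sources(model: SourceModel, schedule: TrialSchedule, seed: int = 0,
                     fs: float = 1000.0, n_samples: int = None) -> np.ndarray:
    """Simulate the M x T latent source matrix.

    Innovations are independent across sources; during an MI epoch of class c
    the innovation scale of source i is multiplied by the class gain, so epoch
    band power scales with the squared gain.
    """
    model.check_stability()
    if n_samples is None:
        n_samples = int(round(schedule.duration_s * fs))
    rng = np.random.default_rng(seed)
    gains = _class_gain_tracks(model, schedule, fs, n_samples)
    S = np.empty((model.n_sources, n_samples))
    for i in range(model.n_sources):
        if model.innovation_dist[i] == "laplace":
            innov = rng.laplace(scale=1 / np.sqrt(2), size=n_samples)
        else:
            innov = rng.standard_normal(n_samples)
        innov *= model.innovation_scale[i] * gains[i]
        a = model.ar_coeffs[i]
        S[i] = sps.lfilter([1.0], np.r_[1.0, -a], innov)
    return S


@dataclass(frozen=True)
class BlinkTruth:
    time_s: float
    kind: str   # "single" | "double"


@dataclass
class Recording:
    """Continuous multichannel recording (uV) with ground-truth annotations."""

    data: np.ndarray          # (n_eeg + n_eog) x T
    montage: MontageSpec
    events: TrialSchedule
    blink_truth: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, float))
        n_ch = self.montage.n_eeg + self.montage.n_eog
        if self.data.shape[0] != n_ch:
            raise ValueError(
                f"data has {self.data.shape[0]} channels, montage expects {n_ch}")
        if self.events is not None and len(self.events):
            last = self.events.entries[-1]
            if (last.onset_s + self.events.mi_s) * self.montage.fs > self.n_samples + 1:
                raise ValueError("scheduled trials extend past end of recording")

    @property
    def fs(self) -> float:
        return self.montage.fs

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def eeg(self) -> np.ndarray:
        return self.data[: self.montage.n_eeg]

    @property
    def eog(self) -> np.ndarray:
        return self.data[self.montage.n_eeg:]

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(data, self.montage, self.events, list(self.blink_truth))


def blink_template(fs: float, duration_s: float = 0.3, amplitude: float = 150.0) -> np.ndarray:
    """Biphasic blink pulse: dominant positive lobe, small negative rebound."""
    n = int(round(duration_s * fs))
    t = np.linspace(0, 1, n)
    pulse = np.sin(np.pi * t) ** 2
    rebound = -0.25 * np.sin(2 * np.pi * t) * (t > 0.5)
    return amplitude * (pulse + rebound)


def render_recording(model: SourceModel, schedule: TrialSchedule,
                     montage: MontageSpec = None, *,
                     line_noise_amp: float = 5.0,
                     blink_rate_per_min: float = 6.0,
                     sensor_noise_sd: float = 2.0,
                     blink_amplitude: float = 150.0,
                     double_blink_frac: float = 0.3,
                     seed: int = 0) -> Recording:
    """Render a full recording: mixed sources + artifacts + annotations.

    data = mixing' x sources + 50 Hz line interference + blink templates on
    the EOG channels (with 30% leakage onto fronto-polar EEG) + white sensor
    noise.  The simulated reference-channel signal is subtracted from every
    EEG channel, so stored data is already referenced.
    """
    montage = montage or MontageSpec()
    if model.mixing.shape[1] != montage.n_eeg:
        raise ValueError(
            f"mixing width {model.mixing.shape[1]} != montage EEG count {montage.n_eeg}")
    fs = montage.fs
    rng = np.random.default_rng(seed)
    S = simulate_sources(model, schedule, seed=int(rng.integers(2 ** 31)), fs=fs)
    T = S.shape[1]
    n_eeg, n_eog = montage.n_eeg, montage.n_eog

    eeg = model.mixing.T @ S
    # reference electrode activity, common to all channels after referencing
    ref = sps.lfilter([1.0], [1.0, -0.9], rng.standard_normal(T)) * 0.8
    eeg -= ref

    data = np.zeros((n_eeg + n_eog, T))
    data[:n_eeg] = eeg
    # resting EOG baseline: slow noise
    for k in range(n_eog):
        data[n_eeg + k] = sps.lfilter([1.0], [1.0, -0.98], rng.standard_normal(T)) * 1.0

    # eye blinks
    blink_truth = []
    if blink_rate_per_min > 0:
        n_blinks = rng.poisson(blink_rate_per_min * T / fs / 60.0)
        tpl = blink_template(fs, amplitude=blink_amplitude)
        times = np.sort(rng.uniform(1.0, T / fs - 2.0, size=n_blinks))
        # enforce a minimum separation so events stay distinct
        keep = np.r_[True, np.diff(times) > 1.5] if n_blinks else np.array([], bool)
        times = times[keep]
        veog_u = [i for i, l in enumerate(montage.eog_labels) if l == "VEOG-U"]
        veog_d = [i for i, l in enumerate(montage.eog_labels) if l == "VEOG-D"]
        frontal = [i for i, l in enumerate(montage.eeg_labels) if l.startswith("Fp")]
        for t0 in times:
            kind = "double" if rng.random() < double_blink_frac else "single"
            offsets = [0.0, 0.4] if kind == "double" else [0.0]
            for off in offsets:
                i0 = int(round((t0 + off) * fs))
                sl = slice(i0, min(i0 + len(tpl), T))
                seg = tpl[: sl.stop - sl.start]
                for ch in veog_u:
                    data[n_eeg + ch, sl] += seg
                for ch in veog_d:
                    data[n_eeg + ch, sl] -= 0.8 * seg
                for ch in frontal:
                    data[ch, sl] += 0.3 * seg
            blink_truth.append(BlinkTruth(float(t0), kind))

    if line_noise_amp > 0:
        t = np.arange(T) / fs
        phases = rng.uniform(0, 2 * np.pi, n_eeg + n_eog)
        data += line_noise_amp * np.sin(2 * np.pi * 50.0 * t[None, :] + phases[:, None])

    if sensor_noise_sd > 0:
        data += sensor_noise_sd * rng.standard_normal(data.shape)

    return Recording(data, montage, schedule, blink_truth)


def simulate_recording(n_sessions: int = 2, runs_per_session: int = 2,
                       reps_per_class: int = 15, *, profile: str = "player1",
                       montage: MontageSpec = None, seed: int = 0,
                       **render_kwargs) -> Recording:
    """Convenience wrapper: schedule + default model + rendering, one seed."""
    montage = montage or MontageSpec()
    rng = np.random.default_rng(seed)
    schedule = build_schedule(n_sessions, runs_per_session, reps_per_class,
                              seed=int(rng.integers(2 ** 31)))
    model = default_source_model(montage, profile=profile,
                                 seed=int(rng.integers(2 ** 31)))
    return render_recording(model, schedule, montage,
                            seed=int(rng.integers(2 ** 31)), **render_kwargs)
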