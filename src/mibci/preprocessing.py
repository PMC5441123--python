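"""Preprocessing: notch, EOG regression, CAR, epoching, Chebyshev filterbank.

All filters are applied forward-backward (zero phase).  The filterbank
decomposes each epoch into narrowband (electrode, band) components, the atoms
that feature selection ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synth import Recording


@dataclass
class Epoch:
    """One trial's multichannel EEG segment, labeled by MI class or ``idle``."""

    data: np.ndarray            # n_ch x n_samples, uV
    mi_class: str               # one of MI_CLASSES or "idle"
    fs: float
    ch_names: tuple
    window: tuple = (0.0, 4.0)  # seconds relative to cue onset
    participant: str = ""

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, float))
        self.ch_names = tuple(self.ch_names)
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("channel count does not match ch_names")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.ch_names.index(name)]


@dataclass
class BandComponent:
    """A single narrowband (electrode, band) signal cut from one epoch."""

    electrode: str
    band: tuple                 # (low_hz, high_hz)
    signal: np.ndarray          # 1-D
    fs: float
    epoch_ref: object = None    # provenance: source Epoch or index

    def __post_init__(self):
        self.signal = np.asarray(self.signal, float).ravel()
        lo, hi = self.band
        if not (0 <= lo < hi):
            raise ValueError(f"invalid band {self.band}")


def notch_filter(rec: Recording, center_hz: float = 50.0, q: float = 40.0) -> Recording:
    """Zero-phase IIR notch removing line interference at ``center_hz``.

    Q = 40 keeps the forward-backward passband ripple under 1 dB outside
    center +/- 2 Hz while attenuating the center far beyond 30 dB; residual
    output on a pure line tone is edge ringing only and vanishes with
    recording length.
    """
    if center_hz >= rec.fs / 2:
        raise ValueError(f"notch center {center_hz} Hz >= Nyquist {rec.fs / 2} Hz")
    b, a = sps.iirnotch(center_hz, q, fs=rec.fs)
    return rec.copy_with(sps.filtfilt(b, a, rec.data, axis=-1))


def regress_out_eog(rec: Recording) -> Recording:
    """Remove the least-squares projection of each EEG channel onto the EOG.

    A documented, transparent stand-in for online ocular artifact rejection:
    ordinary least squares of EEG on the EOG channels, residuals kept.  EOG
    channels are left untouched so blink detection still works downstream.
    """
    eog = rec.eog
    if eog.shape[0] < 1:
        raise ValueError("at least one EOG channel required")
    if np.allclose(eog, 0):
        warnings.warn("all EOG channels are zero; EOG regression is a no-op")
        return rec.copy_with(rec.data.copy())
    X = eog.T                                    # T x n_eog
    beta, *_ = np.linalg.lstsq(X, rec.eeg.T, rcond=None)
    clean = rec.data.copy()
    clean[: rec.montage.n_eeg] = (rec.eeg.T - X @ beta).T
    return rec.copy_with(clean)


def car_filter(epoch: Epoch) -> Epoch:
    """Common average reference: subtract the per-sample channel mean."""
    if epoch.data.shape[0] < 2:
        raise ValueError("CAR requires at least 2 channels")
    data = epoch.data - epoch.data.mean(axis=0, keepdims=True)
    return Epoch(data, epoch.mi_class, epoch.fs, epoch.ch_names,
                 epoch.window, epoch.participant)


def extract_epochs(rec: Recording, window: tuple = (0.0, 4.0), *,
                   include_idle: bool = False, idle_margin_s: float = 0.1,
                   baseline_s: float = 0.5, apply_car: bool = True,
                   participant: str = "") -> list:
    """Cut one MI epoch per scheduled trial; optionally idle epochs from blanks.

    Each epoch is the EEG-only segment ``window`` (seconds relative to cue
    onset), baseline-corrected by subtracting the per-channel mean of the
    ``baseline_s`` seconds preceding the cue, then (by default) CAR filtered.
    Idle epochs are cut from the inter-trial blank preceding each cue, shrunk
    by ``idle_margin_s`` on both sides, and labeled ``"idle"``.
    """
    if rec.events is None:
        return []
    fs = rec.fs
    n_eeg = rec.montage.n_eeg
    eeg = rec.eeg
    epochs = []

    def cut(onset_s, start, stop, label):
        i0 = int(round((onset_s + start) * fs))
        i1 = int(round((onset_s + stop) * fs))
        if i0 < 0 or i1 > rec.n_samples:
            raise ValueError(
                f"epoch window [{start}, {stop}] s at onset {onset_s:.2f} s "
                f"falls outside the recording")
        seg = eeg[:, i0:i1].copy()
        b0 = int(round((onset_s - baseline_s) * fs))
        if baseline_s > 0 and b0 >= 0:
            seg -= eeg[:, b0:int(round(onset_s * fs))].mean(axis=1, keepdims=True)
        ep = Epoch(seg, label, fs, rec.montage.eeg_labels, (start, stop), participant)
        return car_filter(ep) if apply_car and n_eeg >= 2 else ep

    for e in rec.events.entries:
        epochs.append(cut(e.onset_s, window[0], window[1], e.mi_class))
        if include_idle:
            blank = rec.events.blank_s
            epochs.append(cut(e.onset_s, -(blank - idle_margin_s),
                              -idle_margin_s, "idle"))
    return epochs


def band_edges(low: float = 0.0, high: float = 60.0, width: float = 2.0) -> list:
    """Contiguous band tiling of [low, high); lowest edge clamped to 0.5 Hz."""
    n = (high - low) / width
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"width {width} must divide range {high - low}")
    edges = []
    for k in range(int(round(n))):
        lo = low + k * width
        edges.append((max(lo, 0.5), lo + width))
    return edges


def _design_band(lo: float, hi: float, fs: float, order: int, rp: float):
    if order < 2:
        raise ValueError("filter order must be >= 2")
    sos = sps.cheby1(max(order // 2, 1), rp, [lo, hi], btype="bandpass",
                     fs=fs, output="sos")
    # stability check on second-order sections
    for sec in sos:
        z = np.roots(sec[3:])
        if np.any(np.abs(z) >= 1.0):
            raise ValueError(
                f"unstable Chebyshev design for band ({lo}, {hi}) Hz at order "
                f"{order}; try a lower order or wider band")
    return sos


def bandpass_component(epoch: Epoch, electrode: str, band: tuple,
                       order: int = 10, rp: float = 0.5) -> BandComponent:
    """Extract one (electrode, band) narrowband component from an epoch."""
    sos = _design_band(band[0], band[1], epoch.fs, order, rp)
    sig = sps.sosfiltfilt(sos, epoch.channel(electrode))
    return BandComponent(electrode, tuple(band), sig, epoch.fs, epoch_ref=epoch)


def filterbank(epoch: Epoch, low: float = 0.0, high: float = 60.0,
               width: float = 2.0, order: int = 10, rp: float = 0.5) -> list:
    """Decompose an epoch into all (electrode, band) components.

    Chebyshev type-I bandpass designs (``order`` = final bandpass order,
    passband ripple ``rp`` dB) applied forward-backward as second-order
    sections; bands tile [low, high) in ``width``-Hz steps.  For the default
    25-channel montage and 0-60 Hz range this yields 750 components.
    """
    comps = []
    for band in band_edges(low, high, width):
        sos = _design_band(band[0], band[1], epoch.fs, order, rp)
        filt = sps.sosfiltfilt(sos, epoch.data, axis=-1)
        for i, ch in enumerate(epoch.ch_names):
            comps.append(BandComponent(ch, band, filt[i], epoch.fs, epoch_ref=epoch))
    return comps


def band_power_table(epochs: list, bands: list, order: int = 10,
                     rp: float = 0.5) -> np.ndarray:
    """Mean-square narrowband power for every (epoch, channel, band).

    Vectorized over epochs and channels (one filter design and one
    forward-backward pass per band), returning an array of shape
    ``(n_epochs, n_channels, n_bands)`` in uV^2.  All epochs must share
    length, channel order and sampling rate.
    """
    X = np.stack([ep.data for ep in epochs])        # E x C x T
    fs = epochs[0].fs
    out = np.empty(X.shape[:2] + (len(bands),))
    for k, band in enumerate(bands):
        sos = _design_band(band[0], band[1], fs, order, rp)
        out[..., k] = np.mean(sps.sosfiltfilt(sos, X, axis=-1) ** 2, axis=-1)
    return out
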