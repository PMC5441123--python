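"""Characteristic-component selection by between-class R-squared.

Every (electrode, band) narrowband component is scored by the squared
point-biserial correlation between its per-epoch band power and the binary
task label, averaged over the 6 pairs of the 4 MI classes.  The top-scoring
components are optionally screened for ERD/ERS plausibility: a component is
kept only if its power moves relative to idle in the direction sensorimotor
physiology predicts (power decrease for hand/foot imagery, increase allowed
for tongue).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocessing import BandComponent, band_edges, band_power_table
from .synth import MI_CLASSES


def spectral_power(comp) -> float:
    """Band-limited power of a narrowband component: mean squared amplitude."""
    sig = comp.signal if isinstance(comp, BandComponent) else np.asarray(comp, float)
    if sig.size == 0:
        raise ValueError("empty component signal")
    return float(np.mean(np.square(sig)))


def r_squared(powers_a, powers_b) -> float:
    """Squared point-biserial correlation between power and group label.

    Equals the squared Pearson correlation of the pooled power values against
    a binary group indicator; lies in [0, 1].  Zero total variance is defined
    as 0 (no separability information).
    """
    a = np.asarray(powers_a, float)
    b = np.asarray(powers_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 power values per group")
    x = np.concatenate([a, b])
    y = np.concatenate([np.zeros(a.size), np.ones(b.size)])
    vx = x.var()
    if vx <= 0:
        return 0.0
    r = np.mean((x - x.mean()) * (y - y.mean())) / np.sqrt(vx * y.var())
    return float(min(r * r, 1.0))


@dataclass
class RSquaredMap:
    """Per-component separability scores.

    ``scores`` maps (electrode, band) -> mean R-squared over class pairs;
    ``per_pair`` additionally resolves the individual class pairs.
    ``class_power`` keeps the mean per-class (and idle, when available) epoch
    power of each component for downstream ERD/ERS screening.
    """

    scores: dict
    per_pair: dict = field(default_factory=dict)
    class_power: dict = field(default_factory=dict)

    def top(self, k: int) -> list:
        return rank_order(self.scores)[:k]


def rank_order(scores: dict) -> list:
    """Deterministic ranking: score desc, then lower band, then electrode name."""
    return sorted(scores, key=lambda key: (-scores[key], key[1][0], key[0]))


def rank_components(epochs: list, *, low: float = 0.0, high: float = 60.0,
                    width: float = 2.0, order: int = 10, rp: float = 0.5,
                    aggregate: str = "pairwise") -> RSquaredMap:
    """Score every (electrode, band) component across a set of labeled epochs.

    For each component the per-epoch band powers are grouped by MI class and
    an R-squared value is computed for each of the 6 class pairs (or, with
    ``aggregate="ovr"``, each one-vs-rest contrast); the component's score is
    the mean.  Classes with fewer than 2 epochs are excluded from pairing
    with a warning.  Idle-labeled epochs never enter the scores but their
    mean power is recorded for ERD/ERS screening.
    """
    mi_epochs = [ep for ep in epochs if ep.mi_class != "idle"]
    idle_epochs = [ep for ep in epochs if ep.mi_class == "idle"]
    labels = [ep.mi_class for ep in mi_epochs]
    present = [c for c in MI_CLASSES if labels.count(c) >= 2]
    skipped = [c for c in MI_CLASSES if 0 < labels.count(c) < 2]
    if skipped:
        warnings.warn(f"classes with <2 epochs excluded from pairing: {skipped}")
    if len(present) < 2:
        raise ValueError("need at least 2 classes with >= 2 epochs each")

    bands = band_edges(low, high, width)
    ch_names = mi_epochs[0].ch_names
    P = band_power_table(mi_epochs, bands, order, rp)       # E x C x B
    idx = {c: [i for i, l in enumerate(labels) if l == c] for c in present}
    P_idle = band_power_table(idle_epochs, bands, order, rp) if idle_epochs else None

    if aggregate == "pairwise":
        contrasts = list(itertools.combinations(present, 2))
    elif aggregate == "ovr":
        contrasts = [(c, "rest") for c in present]
    else:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")

    scores, per_pair, class_power = {}, {}, {}
    for ci, ch in enumerate(ch_names):
        for bi, band in enumerate(bands):
            key = (ch, band)
            vals = []
            for c_a, c_b in contrasts:
                pa = P[idx[c_a], ci, bi]
                if c_b == "rest":
                    others = [i for c in present if c != c_a for i in idx[c]]
                    pb = P[others, ci, bi]
                else:
                    pb = P[idx[c_b], ci, bi]
                r2 = r_squared(pa, pb)
                per_pair[(ch, band, c_a, c_b)] = r2
                vals.append(r2)
            scores[key] = float(np.mean(vals))
            cp = {c: float(P[idx[c], ci, bi].mean()) for c in present}
            if P_idle is not None:
                cp["idle"] = float(P_idle[:, ci, bi].mean())
            class_power[key] = cp
    return RSquaredMap(scores, per_pair, class_power)


@dataclass
class ComponentSelection:
    """Ranked characteristic components plus screening bookkeeping."""

    selected: list                       # [(electrode, band, score), ...]
    screen_notes: dict = field(default_factory=dict)

    @property
    def keys(self) -> list:
        return [(el, band) for el, band, _ in self.selected]

    def to_dict(self) -> dict:
        return {
            "selected": [[el, list(band), score] for el, band, score in self.selected],
            "screen_notes": {f"{el} {band}": note
                             for (el, band), note in self.screen_notes.items()},
        }


# Expected power direction vs idle, per class, used by the screening rule:
# hand/foot imagery should *suppress* mu/beta power (ERD, direction -1);
# for tongue imagery a power increase (ERS, +1) is the accepted signature.
_EXPECTED_DIRECTION = {"right_hand": -1, "left_hand": -1, "foot": -1, "tongue": +1}


def _passes_screen(class_power: dict) -> tuple:
    idle = class_power.get("idle")
    if idle is None or idle <= 0:
        return True, "no idle baseline; screening skipped"
    for cls, direction in _EXPECTED_DIRECTION.items():
        if cls not in class_power:
            continue
        rel = (class_power[cls] - idle) / idle
        if direction * rel > 0:
            kind = "ERD" if direction < 0 else "ERS"
            return True, f"{kind} vs idle for {cls} ({rel:+.2f})"
    return False, "no class moves power in the ERD/ERS-consistent direction"


def select_components(rsmap: RSquaredMap, top_k: int = 10,
                      screen: bool = True) -> ComponentSelection:
    """Pick the top-k components by mean R-squared, then ERD/ERS-screen them.

    Ties break deterministically by (lower band, electrode name).  If
    screening would drop every candidate, the top-1 is kept with a warning.
    """
    if not rsmap.scores:
        raise ValueError("empty score map")
    ranked = rsmap.top(top_k)
    selected, notes = [], {}
    for key in ranked:
        ok, note = (True, "screening disabled")
        if screen:
            ok, note = _passes_screen(rsmap.class_power.get(key, {}))
        notes[key] = ("kept: " if ok else "dropped: ") + note
        if ok:
            selected.append((key[0], key[1], rsmap.scores[key]))
    if not selected:
        warnings.warn("ERD/ERS screening removed every component; keeping top-1")
        key = ranked[0]
        selected = [(key[0], key[1], rsmap.scores[key])]
        notes[key] = "kept: forced (screening removed all)"
    return ComponentSelection(selected, notes)
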