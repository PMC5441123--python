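"""R-squared component scoring, ranking and ERD/ERS screening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mibci import preprocessing as pp
from mibci import selection, synth


class TestSpectralPower:
    def test_sinusoid_power_half(self):
        t = np.arange(5000) / 1000.0
        comp = pp.BandComponent("Cz", (8, 10), np.sin(2 * np.pi * 9 * t), 1000.0)
        assert selection.spectral_power(comp) == pytest.approx(0.5, rel=0.02)

    def test_zero_signal(self):
        comp = pp.BandComponent("Cz", (8, 10), np.zeros(100), 1000.0)
        assert selection.spectral_power(comp) == 0.0

    def test_bandlimited_white_noise_power(self, rng):
        """Flat-spectrum oracle: band power ~ sigma^2 * bandwidth / Nyquist."""
        fs, sigma2 = 1000.0, 4.0
        x = np.sqrt(sigma2) * rng.standard_normal(200_000)
        ep = pp.Epoch(x[None, :], "idle", fs, ("Cz",))
        comp = pp.bandpass_component(ep, "Cz", (20, 22))
        expected = sigma2 * 2.0 / (fs / 2)
        assert selection.spectral_power(comp) == pytest.approx(expected, rel=0.15)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            selection.spectral_power(np.array([]))


class TestRSquared:
    def test_identical_distributions_zero(self):
        assert selection.r_squared([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_separation_one(self):
        assert selection.r_squared([1, 1, 1], [2, 2, 2]) == pytest.approx(1.0)

    def test_matches_bruteforce_pearson(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        x = np.array(a + b)
        y = np.array([0, 0, 0, 1, 1, 1])
        expected = np.corrcoef(x, y)[0, 1] ** 2
        assert selection.r_squared(a, b) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_defined_as_zero(self):
        assert selection.r_squared([5, 5], [5, 5]) == 0.0

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=12),
           st.lists(st.floats(-50, 50), min_size=3, max_size=12),
           st.floats(0.1, 10), st.floats(-5, 5))
    @settings(max_examples=40, deadline=None)
    def test_affine_invariance(self, a, b, scale, shift):
        r0 = selection.r_squared(a, b)
        r1 = selection.r_squared(np.array(a) * scale + shift,
                                 np.array(b) * scale + shift)
        assert r1 == pytest.approx(r0, abs=1e-8)
        assert 0.0 <= r0 <= 1.0


def _planted_epochs(rng, n_per_class=12, fs=250.0, erd_class="right_hand",
                    electrode="C3", freq=10.0):
    """Epochs where only (electrode, 10-12 Hz) power separates one class."""
    from scipy import signal as sps
    labels = ("C3", "Cz", "C4")
    eps = []
    sos = sps.butter(2, [freq - 1, freq + 1], btype="bandpass", fs=fs,
                     output="sos")
    for cls in synth.MI_CLASSES:
        for _ in range(n_per_class):
            data = rng.standard_normal((3, 1000))
            tone = sps.sosfilt(sos, rng.standard_normal(1000)) * 20
            if cls != erd_class:
                data[labels.index(electrode)] += tone   # ERD: suppressed for class
            eps.append(pp.Epoch(data, cls, fs, labels))
    return eps


class TestRankAndSelect:
    def test_planted_component_ranks_first(self, rng):
        eps = _planted_epochs(rng)
        rsmap = selection.rank_components(eps, low=4, high=30, width=2, order=6)
        top = rsmap.top(1)[0]
        assert top[0] == "C3" and top[1][0] in (8, 10)

    def test_pure_noise_scores_low(self, rng):
        eps = [pp.Epoch(rng.standard_normal((3, 500)), cls, 250.0,
                        ("C3", "Cz", "C4"))
               for cls in synth.MI_CLASSES for _ in range(60)]
        rsmap = selection.rank_components(eps, low=8, high=16, width=2, order=6)
        assert max(rsmap.scores.values()) < 0.2

    def test_single_class_rejected(self, rng):
        eps = [pp.Epoch(rng.standard_normal((2, 300)), "foot", 250.0, ("a", "b"))
               for _ in range(5)]
        with pytest.raises(ValueError, match="2 classes"):
            selection.rank_components(eps, low=8, high=12, width=2, order=4)

    def test_epoch_order_invariance(self, rng):
        eps = _planted_epochs(rng, n_per_class=6)
        r1 = selection.rank_components(eps, low=8, high=14, width=2, order=6)
        perm = list(rng.permutation(len(eps)))
        r2 = selection.rank_components([eps[i] for i in perm],
                                       low=8, high=14, width=2, order=6)
        for k in r1.scores:
            assert r1.scores[k] == pytest.approx(r2.scores[k], rel=1e-9)

    def test_top_k_selection(self, rng):
        eps = _planted_epochs(rng, n_per_class=6)
        rsmap = selection.rank_components(eps, low=8, high=16, width=2, order=6)
        sel = selection.select_components(rsmap, top_k=10, screen=False)
        assert len(sel.selected) == 10
        scores = [s for _, _, s in sel.selected]
        assert scores == sorted(scores, reverse=True)

    def test_tie_break_deterministic(self):
        scores = {(el, (lo, lo + 2)): 0.5
                  for el in ("C4", "C3") for lo in (10, 8)}
        rsmap = selection.RSquaredMap(scores)
        sel = selection.select_components(rsmap, top_k=3, screen=False)
        assert sel.keys == [("C3", (8, 10)), ("C4", (8, 10)), ("C3", (10, 12))]

    def test_screening_bookkeeping(self):
        # 3 of 5 components move the wrong way vs idle -> dropped and flagged
        scores, class_power = {}, {}
        for i in range(5):
            key = (f"C{i}", (8.0, 10.0))
            scores[key] = 0.9 - 0.1 * i
            if i < 2:   # ERD for a hand class: kept
                class_power[key] = {"right_hand": 0.5, "left_hand": 1.0,
                                    "foot": 1.0, "tongue": 1.0, "idle": 1.0}
            else:       # ERS for hands, ERD for tongue: dropped
                class_power[key] = {"right_hand": 2.0, "left_hand": 2.0,
                                    "foot": 2.0, "tongue": 0.5, "idle": 1.0}
        rsmap = selection.RSquaredMap(scores, {}, class_power)
        sel = selection.select_components(rsmap, top_k=5, screen=True)
        assert len(sel.selected) == 2
        dropped = [n for n in sel.screen_notes.values() if n.startswith("dropped")]
        assert len(dropped) == 3

    def test_screening_never_empties_selection(self):
        key = ("Cz", (8.0, 10.0))
        rsmap = selection.RSquaredMap(
            {key: 0.4},
            class_power={key: {"right_hand": 2.0, "left_hand": 2.0,
                               "foot": 2.0, "tongue": 0.5, "idle": 1.0}})
        with pytest.warns(UserWarning, match="keeping top-1"):
            sel = selection.select_components(rsmap, top_k=1, screen=True)
        assert len(sel.selected) == 1

    def test_planted_recall_on_default_profile(self, medium_recording):
        """Selected set should recover planted (electrode, band) pairs."""
        eps = pp.extract_epochs(medium_recording, (0, 4), include_idle=True)
        rsmap = selection.rank_components(eps, low=4, high=32, width=2, order=10)
        sel = selection.select_components(rsmap, top_k=10, screen=True)
        planted = {("Cz", (8, 10)), ("Cz", (10, 12)), ("C3", (12, 14)),
                   ("C3", (14, 16)), ("C4", (12, 14)), ("C4", (14, 16))}
        hits = planted & {(el, b) for el, b in sel.keys}
        assert len(hits) >= 2
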