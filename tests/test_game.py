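"""Headless 3D Tetris engine, blink detection, session runner, screen score."""

import numpy as np
import pytest

from mibci import game, synth
from mibci.fsa import FSAInput, FSAState
from mibci.game import BlinkEvent, GameConfig


def _state(shapes=("tripod",), seed=0, **kw):
    cfg = GameConfig(shapes=shapes, **kw)
    return game.new_game(cfg, seed=seed)


class TestBlinkDetection:
    def test_flat_signal_no_events(self):
        assert game.detect_blinks(np.zeros(5000), fs=250.0) == []

    def test_two_pulses_400ms_apart_is_one_double(self):
        from scipy import signal as sps
        fs = 250.0
        rng = np.random.default_rng(0)
        # realistic resting-EOG noise floor: slow AR drift, sd ~5 uV
        sig = sps.lfilter([1.0], [1.0, -0.98], rng.standard_normal(int(20 * fs)))
        tpl = synth.blink_template(fs)
        for off in (0.0, 0.4):
            i0 = int((10 + off) * fs)
            sig[i0: i0 + len(tpl)] += tpl
        events = game.detect_blinks(sig, fs=fs)
        assert len(events) == 1 and events[0].kind == "double"
        assert abs(events[0].time_s - 10.15) < 0.2

    def test_sensitivity_and_false_alarms_on_synthetic_truth(self):
        montage = synth.MontageSpec(fs=250.0)
        rec = synth.simulate_recording(1, 2, 10, montage=montage, seed=21)
        events = game.detect_blinks(rec)
        truth = rec.blink_truth
        assert truth, "generator should have planted blinks"
        hits = sum(any(abs(e.time_s - b.time_s) < 0.25 and e.kind == b.kind
                       for e in events) for b in truth)
        assert hits / len(truth) >= 0.95
        false = sum(not any(abs(e.time_s - b.time_s) < 0.6 for b in truth)
                    for e in events)
        assert false <= rec.duration_s / 60.0


class TestRotation:
    def test_double_blinks_cycle_axes(self):
        st = _state()
        assert st.rotation_axis == 0
        for expected in (1, 2, 0):
            game.apply_rotation(st, BlinkEvent(0.0, "double"))
            assert st.rotation_axis == expected

    def test_four_singles_identity(self):
        st = _state()
        before = np.sort(st.block_cells(), axis=0).copy()
        for _ in range(4):
            game.apply_rotation(st, BlinkEvent(0.0, "single"))
        after = np.sort(st.block_cells(), axis=0)
        assert np.array_equal(
            np.sort(before.view("i8,i8,i8").ravel()),
            np.sort(after.view("i8,i8,i8").ravel()))

    def test_blocked_rotation_is_noop(self):
        st = _state(shapes=("tetromino_i",), width=4, depth=1)
        st.rotation_axis = 2          # rotating the I into the depth wall
        offsets = st.offsets.copy()
        game.apply_rotation(st, BlinkEvent(0.0, "single"))
        assert np.array_equal(st.offsets, offsets)
        assert ("rotation_blocked", st.fsa, st.fsa) in st.event_log


class TestEngine:
    def test_spawn_enters_new_block_state(self):
        st = _state()
        assert st.fsa is FSAState.N_B

    def test_free_fall_lands_at_shadow(self):
        st = _state(shapes=("cube1",), fall_rate=2.0)
        shadow = st.shadow_cell().copy()
        events = []
        for _ in range(100):
            events += game.game_tick(st, 0.25)
            if FSAInput.FALLEN in events:
                break
        assert FSAInput.FALLEN in events
        x, y, z = shadow
        assert st.grid[x, y, z]

    def test_landing_time_matches_kinematics(self):
        st = _state(shapes=("cube1",), layers=20, fall_rate=0.5)
        drop = st.cell[2]
        t, dt = 0.0, 0.25
        while not any(e is FSAInput.FALLEN for e in game.game_tick(st, dt)):
            t += dt
            assert t < 1000
        assert t + dt == pytest.approx(drop / 0.5, abs=1.0)

    def test_full_layer_clears_and_scores(self):
        st = _state(shapes=("cube1",), width=2, depth=2)
        st.grid[:, :, 0] = True
        st.grid[0, 0, 0] = False      # hole the falling cube will fill
        st.grid[1, 1, 1] = True       # a cell above the nearly-full layer
        st.cell = np.array([0, 0, 3])
        st.fall_acc = 0.0
        st.speed[:] = 0
        # drop straight down onto (0,0): fills layer 0 -> clear
        for _ in range(40):
            ev = game.game_tick(st, 0.5)
            if FSAInput.FALLEN in ev:
                break
        assert st.score == 1
        # layer cleared: the cell formerly at z=1 moved down to z=0
        assert st.grid[1, 1, 0] and st.grid.sum() == 1

    def test_touch_event_zeroes_speed(self):
        st = _state(shapes=("cube1",), width=4, depth=4, fall_rate=0.01)
        st.fsa = FSAState.V_ZERO
        events = game.game_tick(st, 1.0, [FSAInput.LEFT])   # vx = +1
        assert st.speed[0] == 1.0
        hit = []
        for _ in range(10):
            hit += game.game_tick(st, 1.0)
            if FSAInput.TOUCH in hit:
                break
        assert FSAInput.TOUCH in hit
        assert st.fsa is FSAState.V_ZERO and np.all(st.speed == 0)

    def test_cell_conservation(self):
        """Settled cells change only by +|block| on landing or -W*D per clear."""
        st = _state(shapes=("domino",), width=3, depth=3, seed=4, fall_rate=4.0)
        prev = st.grid.sum()
        rng = np.random.default_rng(0)
        while not st.game_over:
            sym = rng.choice([FSAInput.LEFT, FSAInput.RIGHT, FSAInput.TON,
                              FSAInput.FOOT, FSAInput.NULL])
            ev = game.game_tick(st, 0.25, [sym])
            now = st.grid.sum()
            if FSAInput.FALLEN in ev:
                delta = now - prev
                assert delta == 2 or (2 - delta) % 9 == 0
            prev = now

    def test_game_over_reaches_reset(self):
        st = _state(shapes=("cube1",), width=2, depth=2, layers=4)
        while not st.game_over:
            game.game_tick(st, 0.5)
        assert st.fsa is FSAState.RESET


def _oracle_decoder(targets):
    """Command toward the current block's target (x, y) cell.

    Emits idle right after a spawn: the control automaton leaves the
    new-block state only on a Null symbol (no directional command).
    """
    def decode(window, state, t):
        if state.offsets is None or state.fsa is FSAState.N_B:
            return "idle"
        tx, ty = targets[(state.block_count - 1) % len(targets)]
        dx, dy = tx - state.cell[0], ty - state.cell[1]
        if abs(dx) >= abs(dy) and dx != 0:
            return "left_hand" if dx > 0 else "right_hand"
        if dy != 0:
            return "foot" if dy > 0 else "tongue"
        return "idle"
    return decode


def _random_decoder(seed):
    rng = np.random.default_rng(seed)
    labels = list(synth.MI_CLASSES) + ["idle"]
    return lambda window, state, t: rng.choice(labels)


class TestRunSession:
    CFG = dict(width=2, depth=2, layers=20, shapes=("cube1",), fall_rate=1.0)

    def test_oracle_beats_random(self):
        targets = [(0, 0), (1, 0), (0, 1), (1, 1)]
        oracle_scores, random_scores = [], []
        for seed in range(10):
            cfg = GameConfig(**self.CFG)
            log = game.run_session(_oracle_decoder(targets), None,
                                   config=cfg, seed=seed, duration_s=600)
            oracle_scores.append(log.final_score)
            cfg = GameConfig(**self.CFG)
            log = game.run_session(_random_decoder(seed), None,
                                   config=cfg, seed=seed, duration_s=600)
            random_scores.append(log.final_score)
        assert np.mean(oracle_scores) > np.mean(random_scores)

    def test_idle_decoder_lands_at_spawn_shadow(self):
        cfg = GameConfig(width=4, depth=4, layers=6, shapes=("cube1",),
                         fall_rate=1.0)
        log = game.run_session(lambda w, s, t: "idle", None, config=cfg,
                               seed=0, duration_s=120)
        assert log.final_score == 0

    def test_session_determinism(self, small_recording):
        dec = _random_decoder(5)

        def run():
            return game.run_session(
                _oracle_decoder([(0, 0)]), small_recording,
                config=GameConfig(**self.CFG), seed=3)
        a, b = run(), run()
        assert [e["fsa"] for e in a.entries] == [e["fsa"] for e in b.entries]
        assert a.final_score == b.final_score

    def test_log_roundtrip(self, tmp_path):
        cfg = GameConfig(**self.CFG)
        log = game.run_session(_random_decoder(1), None, config=cfg,
                               seed=1, duration_s=60)
        p = tmp_path / "session.jsonl"
        log.to_jsonl(p)
        back = game.SessionLog.from_jsonl(p)
        assert back.entries == log.entries
        assert back.final_score == log.final_score


class TestScreenGameScore:
    def test_balanced_is_zero(self):
        labels = ["right_hand", "left_hand", "foot", "tongue"] * 25
        assert game.screen_game_score(labels) == pytest.approx(0.0)

    def test_single_class_worked_value(self):
        # direct arithmetic: std of {100, 0, 0, 0} = sqrt(3*25^2+75^2)/2
        assert game.screen_game_score(["foot"] * 7) == pytest.approx(43.30, abs=0.01)

    def test_40_30_20_10(self):
        labels = (["right_hand"] * 40 + ["left_hand"] * 30 + ["foot"] * 20
                  + ["tongue"] * 10)
        assert game.screen_game_score(labels) == pytest.approx(11.18, abs=0.01)

    def test_idle_excluded_from_denominator(self):
        labels = ["right_hand", "left_hand", "foot", "tongue"] * 5 + ["idle"] * 80
        assert game.screen_game_score(labels) == pytest.approx(0.0)

    def test_all_idle_flagged(self):
        with pytest.warns(UserWarning, match="idle"):
            assert np.isnan(game.screen_game_score(["idle"] * 4))
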