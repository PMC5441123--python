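"""Headless 3D Tetris engine with FSA shared control and blink EOG commands.

Block groups fall at a constant rate into a W x D x 20-layer space.  Decoded
MI commands drive the finite-state automaton of :mod:`mibci.fsa`, whose state
adjusts the lateral speed vector; blink commands from the EOG rotate the
block (single blink) or advance the rotation axis in an X-Y-Z loop (double
blink).  Filling a layer clears it and scores one unit; stacking past the
remaining layers with gaps costs a layer; the run ends (Cross -> Reset) when
the final layer is lost or a block protrudes from the space.

Also provides the 2D Screen Game evaluation score: the population standard
deviation of the four MI-class occurrence percentages over a time window.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .fsa import CLASS_SYMBOL, STATE_DIRECTION, FSAInput, FSAState, fsa_step
from .synth import MI_CLASSES, Recording


# --------------------------------------------------------------------------
# Blink detection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BlinkEvent:
    time_s: float
    kind: str          # "single" | "double"


def detect_blinks(eog, fs: float = None, *, threshold_mads: float = 4.0,
                  refractory_s: float = 0.2, double_window_s: float = 0.6,
                  band=(0.5, 15.0)) -> list:
    """Detect single/double blinks on the vertical EOG.

    The channel is band-passed to the blink band, peaks above
    ``threshold_mads`` robust standard deviations (Gaussian-scaled median
    absolute deviation) are located with a refractory gap, and two peaks
    within ``double_window_s`` merge into one double-blink event.
    """
    if isinstance(eog, Recording):
        rec = eog
        fs = rec.fs
        labels = rec.montage.eog_labels
        idx = labels.index("VEOG-U") if "VEOG-U" in labels else 0
        sig = rec.eog[idx]
    else:
        sig = np.asarray(eog, float)
        if sig.ndim > 1:
            sig = sig[0]
        if fs is None:
            raise ValueError("fs required when passing a raw signal")
    if sig.size == 0 or np.allclose(sig, sig.flat[0]):
        return []
    lo = max(band[0], 1e-3)
    hi = min(band[1], 0.45 * fs)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, sig)
    mad = np.median(np.abs(filt - np.median(filt)))
    thr = threshold_mads * 1.4826 * mad
    if thr <= 0:
        return []
    peaks, _ = sps.find_peaks(filt, height=thr,
                              distance=max(int(refractory_s * fs), 1))
    times = peaks / fs
    events = []
    i = 0
    while i < len(times):
        if i + 1 < len(times) and times[i + 1] - times[i] <= double_window_s:
            events.append(BlinkEvent(float(times[i]), "double"))
            i += 2
        else:
            events.append(BlinkEvent(float(times[i]), "single"))
            i += 1
    return events


# --------------------------------------------------------------------------
# Engine
# --------------------------------------------------------------------------

#: Polycube shapes (cell offsets) of the block groups.
SHAPES = {
    "cube1": [(0, 0, 0)],
    "domino": [(0, 0, 0), (1, 0, 0)],
    "tromino_i": [(0, 0, 0), (1, 0, 0), (2, 0, 0)],
    "tromino_l": [(0, 0, 0), (1, 0, 0), (0, 1, 0)],
    "tetromino_i": [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)],
    "square": [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)],
    "tetromino_l": [(0, 0, 0), (1, 0, 0), (2, 0, 0), (0, 1, 0)],
    "tripod": [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)],
}

_AXES = "XYZ"


@dataclass
class GameConfig:
    width: int = 6
    depth: int = 6
    layers: int = 20
    dvx: float = 1.0            # speed increment, cells/s
    dvy: float = 1.0
    fall_rate: float = 0.5      # layers/s
    shapes: tuple = tuple(SHAPES)
    layer_loss: str = "topmost_gaps"   # or "none"
    control_mode: str = "speed"        # or "step"


@dataclass
class GameState:
    """Complete engine state; advanced by :func:`game_tick`."""

    config: GameConfig
    rng: np.random.Generator
    grid: np.ndarray = None                 # (W, D, L) bool, z index 0 = bottom
    offsets: np.ndarray = None              # active block cells, (n, 3) int
    cell: np.ndarray = None                 # active block anchor (x, y, z) int
    acc: np.ndarray = None                  # fractional lateral displacement
    fall_acc: float = 0.0
    rotation_axis: int = 0                  # 0=X, 1=Y, 2=Z
    speed: np.ndarray = None                # (vx, vy) cells/s
    fsa: FSAState = FSAState.START
    score: int = 0
    layers_remaining: int = None
    block_count: int = 0
    game_over: bool = False
    event_log: list = field(default_factory=list)

    def __post_init__(self):
        c = self.config
        if self.grid is None:
            self.grid = np.zeros((c.width, c.depth, c.layers), dtype=bool)
        if self.layers_remaining is None:
            self.layers_remaining = c.layers
        if self.speed is None:
            self.speed = np.zeros(2)
        if self.acc is None:
            self.acc = np.zeros(2)

    # -- geometry helpers ---------------------------------------------------

    def block_cells(self, offsets=None, cell=None) -> np.ndarray:
        offsets = self.offsets if offsets is None else offsets
        cell = self.cell if cell is None else cell
        return offsets + cell

    def collides(self, offsets=None, cell=None) -> bool:
        cells = self.block_cells(offsets, cell)
        c = self.config
        if (np.any(cells[:, 0] < 0) or np.any(cells[:, 0] >= c.width)
                or np.any(cells[:, 1] < 0) or np.any(cells[:, 1] >= c.depth)
                or np.any(cells[:, 2] < 0)):
            return True
        inside = cells[cells[:, 2] < c.layers]
        return bool(np.any(self.grid[inside[:, 0], inside[:, 1], inside[:, 2]]))

    def stack_height(self) -> int:
        occupied = np.flatnonzero(self.grid.any(axis=(0, 1)))
        return int(occupied.max()) + 1 if occupied.size else 0

    def shadow_cell(self) -> np.ndarray:
        """Landing anchor if the block fell straight down from here."""
        cell = self.cell.copy()
        while not self.collides(cell=cell - (0, 0, 1)) and cell[2] > 0:
            cell = cell - (0, 0, 1)
        # also stop when resting on the floor
        probe = cell - (0, 0, 1)
        if not self.collides(cell=probe):
            return probe + (0, 0, 1)
        return cell


def new_game(config: GameConfig = None, seed: int = 0) -> GameState:
    state = GameState(config or GameConfig(), np.random.default_rng(seed))
    spawn_block(state)
    return state


def spawn_block(state: GameState) -> list:
    """Drop a new block group at the top; FSA enters N_B."""
    c = state.config
    name = state.rng.choice(list(c.shapes))
    offsets = np.array(SHAPES[name], int)
    ext = offsets.max(axis=0) + 1
    x = (c.width - ext[0]) // 2
    y = (c.depth - ext[1]) // 2
    z = c.layers - ext[2]
    state.offsets = offsets
    state.cell = np.array([x, y, z], int)
    state.acc[:] = 0.0
    state.fall_acc = 0.0
    state.speed[:] = 0.0
    state.block_count += 1
    events = []
    if state.collides():
        events.append(FSAInput.CROSS)
        _feed(state, FSAInput.CROSS)
    else:
        state.fsa = FSAState.N_B
    return events


def _feed(state: GameState, symbol: FSAInput) -> None:
    prev = state.fsa
    state.fsa = fsa_step(prev, symbol)
    state.event_log.append((symbol, prev, state.fsa))
    # speed semantics of the control states
    if state.fsa is FSAState.V_ZERO:
        state.speed[:] = 0.0
    elif state.fsa in STATE_DIRECTION:
        d = np.array(STATE_DIRECTION[state.fsa], float)
        inc = d * (state.config.dvx, state.config.dvy)
        if symbol in (FSAInput.LEFT, FSAInput.RIGHT, FSAInput.TON,
                      FSAInput.FOOT, FSAInput.P_PLUS):
            state.speed += np.abs(inc) * np.sign(d)
        elif symbol is FSAInput.P_MINUS_MOVING:
            new = state.speed - np.abs(inc) * np.sign(d)
            # decrement never reverses direction
            new[np.sign(new) != np.sign(state.speed)] = 0.0
            state.speed = new
    if state.fsa is FSAState.RESET:
        state.game_over = True


def apply_rotation(state: GameState, blink: BlinkEvent) -> None:
    """Double blink advances the rotation axis X->Y->Z->X; single rotates.

    A single blink rotates the active block 90 degrees about the current axis
    (integer lattice rotation about the block's own anchor); rotations that
    would collide or leave the space are no-ops (logged).
    """
    if state.offsets is None or state.game_over:
        return
    if blink.kind == "double":
        state.rotation_axis = (state.rotation_axis + 1) % 3
        return
    axis = state.rotation_axis
    o = state.offsets.copy()
    a, b = [d for d in range(3) if d != axis]
    # 90-degree rotation in the (a, b) plane: (u, v) -> (v, -u), re-anchored
    o[:, a], o[:, b] = o[:, b].copy(), -o[:, a].copy()
    o -= o.min(axis=0)
    if state.collides(offsets=o):
        state.event_log.append(("rotation_blocked", state.fsa, state.fsa))
        return
    state.offsets = o


def _settle(state: GameState) -> list:
    """Fix the active block into the grid; clear layers; apply layer loss."""
    c = state.config
    events = []
    cells = state.block_cells()
    protrudes = np.any(cells[:, 2] >= state.layers_remaining)
    inside = cells[cells[:, 2] < c.layers]
    state.grid[inside[:, 0], inside[:, 1], inside[:, 2]] = True
    events.append(FSAInput.FALLEN)
    _feed(state, FSAInput.FALLEN)

    full = np.flatnonzero(state.grid.all(axis=(0, 1)))
    for z in sorted(full, reverse=True):
        state.grid[:, :, z:-1] = state.grid[:, :, z + 1:]
        state.grid[:, :, -1] = False
        state.score += 1

    if c.layer_loss == "topmost_gaps" and not len(full):
        h = state.stack_height()
        if h > 0 and not state.grid[:, :, h - 1].all():
            state.layers_remaining -= 1

    if protrudes or state.stack_height() > state.layers_remaining \
            or state.layers_remaining <= 0:
        events.append(FSAInput.CROSS)
        _feed(state, FSAInput.CROSS)
        state.offsets = None
        return events

    events.extend(spawn_block(state))
    return events


def game_tick(state: GameState, dt: float, commands=()) -> list:
    """Advance the engine by ``dt`` seconds; returns the emitted events.

    Commands (FSA input symbols) are fed to the automaton first; lateral
    speed then integrates into cell moves (wall or stack contact emits
    Touch), and the constant fall rate into down-steps; landing emits Fallen,
    settles the block, clears full layers and spawns the next block.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if state.game_over:
        return []
    events = []
    for sym in commands:
        events.append(sym)
        _feed(state, sym)
        if state.game_over:
            return events
    if state.offsets is None:
        return events

    if state.config.control_mode == "speed":
        state.acc += state.speed * dt
    # "step" mode: each directional command moved one cell at _feed time via
    # speed increments consumed below in a single-step quantum
    for ax in (0, 1):
        while abs(state.acc[ax]) >= 1.0:
            step = int(np.sign(state.acc[ax]))
            state.acc[ax] -= step
            move = np.zeros(3, int)
            move[ax] = step
            if state.collides(cell=state.cell + move):
                events.append(FSAInput.TOUCH)
                _feed(state, FSAInput.TOUCH)
                state.acc[:] = 0.0
                break
            state.cell = state.cell + move

    def resting():
        return state.cell[2] == 0 or state.collides(cell=state.cell + (0, 0, -1))

    state.fall_acc += state.config.fall_rate * dt
    while state.fall_acc >= 1.0 and not state.game_over:
        state.fall_acc -= 1.0
        if resting():
            events.extend(_settle(state))
            break
        state.cell = state.cell + (0, 0, -1)
        if resting():                     # settle on arrival at rest
            events.extend(_settle(state))
            break
    return events


# --------------------------------------------------------------------------
# Online session
# --------------------------------------------------------------------------

@dataclass
class SessionLog:
    """Per-window decode/FSA/score trace of one run."""

    entries: list = field(default_factory=list)
    final_score: int = 0
    blocks: int = 0

    def to_jsonl(self, path) -> None:
        with open(path, "w") as f:
            for e in self.entries:
                f.write(json.dumps(e) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "SessionLog":
        entries = [json.loads(line) for line in open(path)]
        final = entries[-1]["score"] if entries else 0
        blocks = entries[-1]["blocks"] if entries else 0
        return cls(entries, final, blocks)


def run_session(decoder, recording: Recording = None, *,
                config: GameConfig = None, seed: int = 0,
                duration_s: float = None, window_s: float = 1.0,
                hop_s: float = 0.25) -> SessionLog:
    """Run one game under sliding-window decoding of a recording.

    ``decoder`` is called as ``decoder(window, state, t)`` where ``window``
    is the EEG slice of the last ``window_s`` seconds (or None when no
    recording is given) and must return an MI class label or ``"idle"``.
    Each decoded label maps to its directional FSA symbol; the per-second
    count of the current label yields the P=, P+ or P- symbol; an idle
    decode yields Null.  Blink events detected on the EOG are routed to
    rotation commands.  The run ends at Reset (Cross) or when the input is
    exhausted.
    """
    if recording is None and duration_s is None:
        raise ValueError("need a recording or an explicit duration")
    total = recording.duration_s if recording is not None else duration_s
    blinks = detect_blinks(recording) if recording is not None else []
    state = new_game(config, seed=seed)
    log = SessionLog()
    hops_per_window = max(int(round(window_s / hop_s)), 1)
    labels = []
    bi = 0
    t = window_s
    while t <= total and not state.game_over:
        if recording is not None:
            i1 = int(round(t * recording.fs))
            i0 = i1 - int(round(window_s * recording.fs))
            window = recording.eeg[:, i0:i1]
        else:
            window = None
        label = decoder(window, state, t)
        labels.append(label)
        commands = []
        if label in CLASS_SYMBOL:
            commands.append(CLASS_SYMBOL[label])
            now = labels[-hops_per_window:]
            prev = labels[-2 * hops_per_window: -hops_per_window]
            c_now, c_prev = now.count(label), prev.count(label)
            if c_now > c_prev:
                commands.append(FSAInput.P_PLUS)
            elif c_now < c_prev and np.any(state.speed != 0):
                commands.append(FSAInput.P_MINUS_MOVING)
            else:
                commands.append(FSAInput.P_EQ)
        else:
            commands.append(FSAInput.NULL)
        while bi < len(blinks) and blinks[bi].time_s <= t:
            apply_rotation(state, blinks[bi])
            bi += 1
        events = game_tick(state, hop_s, commands)
        log.entries.append({
            "t": round(t, 6), "label": label, "fsa": state.fsa.value,
            "events": [e.value if isinstance(e, FSAInput) else str(e)
                       for e in events],
            "score": state.score, "blocks": state.block_count,
            "layers_remaining": state.layers_remaining,
            "speed": [float(v) for v in state.speed],
        })
        t += hop_s
    log.final_score = state.score
    log.blocks = state.block_count
    return log


# --------------------------------------------------------------------------
# 2D Screen Game score
# --------------------------------------------------------------------------

def screen_game_score(labels, window_s: float = None) -> float:
    """Population SD of the four MI-class occurrence percentages.

    Idle labels are excluded from the denominator.  Perfectly balanced
    commands score 0 (the Screen Game's target); all commands in one class
    score sqrt(3 * 25^2 + 75^2)/2 = 43.30.  An all-idle window is undefined
    and returns NaN with a warning.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("need at least one label")
    counts = np.array([labels.count(c) for c in MI_CLASSES], float)
    total = counts.sum()
    if total == 0:
        warnings.warn("window contains only idle labels; score undefined")
        return float("nan")
    pct = 100.0 * counts / total
    return float(np.std(pct))
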