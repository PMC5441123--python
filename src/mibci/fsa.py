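"""Finite-state automaton for shared movement/speed control.

The automaton M = (Q, Sigma, delta, q, F) translates decoded MI commands and
their per-second occurrence statistics into speed adjustments of the falling
block group.  States are the eight control conditions {Start, N_B (new
block), Vc+dVx, Vc-dVx, Vc+dVy, Vc-dVy, Vc=0, Reset}; the input alphabet is
{P=, P+, P- && Vc>0, Cross, Fallen, Touch, Null, ton, foot, left, right}.
``Start`` and ``Vc=0`` behave identically for directional input (they share a
column of the transition table); table cells left empty are self-loops.
``Touch`` zeroes the speed from every state and ``Cross`` resets from every
state; ``Reset`` is absorbing until the engine starts a new run.
"""

from __future__ import annotations

from enum import Enum


class FSAState(Enum):
    START = "Start"
    N_B = "N_B"
    VX_PLUS = "Vc+dVx"
    VX_MINUS = "Vc-dVx"
    VY_PLUS = "Vc+dVy"
    VY_MINUS = "Vc-dVy"
    V_ZERO = "Vc=0"
    RESET = "Reset"


class FSAInput(Enum):
    LEFT = "left"
    RIGHT = "right"
    TON = "ton"
    FOOT = "foot"
    P_EQ = "P="
    P_PLUS = "P+"
    P_MINUS_MOVING = "P- && Vc>0"
    TOUCH = "Touch"
    FALLEN = "Fallen"
    CROSS = "Cross"
    NULL = "Null"


_S = FSAState
_I = FSAInput

# Transition table; omitted (state, input) pairs are self-loops.  Columns of
# the published table: [Start / Vc=0, Vc+dVx, Vc-dVx, Vc+dVy, Vc-dVy, N_B];
# the Start and Vc=0 states share one column.
_MOVING = (_S.VX_PLUS, _S.VX_MINUS, _S.VY_PLUS, _S.VY_MINUS)
_TABLE = {}

for st in (_S.START, _S.V_ZERO):
    _TABLE[(st, _I.LEFT)] = _S.VX_PLUS
    _TABLE[(st, _I.RIGHT)] = _S.VX_MINUS
    _TABLE[(st, _I.TON)] = _S.VY_MINUS
    _TABLE[(st, _I.FOOT)] = _S.VY_PLUS

for st in _MOVING:
    if st is not _S.VX_PLUS:
        _TABLE[(st, _I.LEFT)] = _S.VX_PLUS
    if st is not _S.VX_MINUS:
        _TABLE[(st, _I.RIGHT)] = _S.VX_MINUS
    if st is not _S.VY_MINUS:
        _TABLE[(st, _I.TON)] = _S.VY_MINUS
    if st is not _S.VY_PLUS:
        _TABLE[(st, _I.FOOT)] = _S.VY_PLUS
    # reinforcement of the current speed state by the per-second counters
    for sym in (_I.P_EQ, _I.P_PLUS, _I.P_MINUS_MOVING):
        _TABLE[(st, sym)] = st
    _TABLE[(st, _I.FALLEN)] = _S.N_B

# Touch zeroes the speed and Cross resets from *every* state.  The engine
# ends the run as soon as Reset is entered, so these universal rows cannot
# pull a finished run back into play.
for st in _S:
    _TABLE[(st, _I.TOUCH)] = _S.V_ZERO
    _TABLE[(st, _I.CROSS)] = _S.RESET

_TABLE[(_S.N_B, _I.NULL)] = _S.V_ZERO


def fsa_step(state: FSAState, symbol: FSAInput) -> FSAState:
    """Total transition function; undefined table cells are self-loops."""
    return _TABLE.get((state, symbol), state)


#: Direction of one speed increment per FSA speed state, in grid cells.
STATE_DIRECTION = {
    _S.VX_PLUS: (1, 0),
    _S.VX_MINUS: (-1, 0),
    _S.VY_PLUS: (0, 1),
    _S.VY_MINUS: (0, -1),
}

#: Decoded MI class -> FSA input symbol.
CLASS_SYMBOL = {
    "left_hand": _I.LEFT,
    "right_hand": _I.RIGHT,
    "tongue": _I.TON,
    "foot": _I.FOOT,
}


def mi_to_direction(mi_class: str):
    """Map an MI class to its movement axis direction (unit grid vector).

    Foot -> +y (Foot Plane), tongue -> -y, left hand -> +x, right hand -> -x;
    the idle state carries no command and returns None.
    """
    if mi_class == "idle":
        return None
    sym = CLASS_SYMBOL.get(mi_class)
    if sym is None:
        raise ValueError(f"unknown MI class {mi_class!r}")
    return STATE_DIRECTION[fsa_step(FSAState.START, sym)]
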