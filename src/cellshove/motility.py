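"""The three movement rules: gentleman exclusion, simple shoving, smart shoving.

A mover that targets an occupied site may push the occupant and the whole
contiguous run of agents behind it one site along the move direction, up to the
first vacancy.  Horizontal shoves always go through (the far agent may be pushed
off an absorbing vertical boundary); vertical shoves fail when the column is
occupied all the way to the reflecting horizontal boundary.  Gentlemen never
shove; simple shovers shove in a uniformly drawn direction and abort when it is
infeasible; smart shovers scan all four directions and execute a feasible move
of minimal shoving effort (number of displaced agents), breaking ties uniformly
at random in the fixed scan order up, down, left, right — they never abort.

By default a *voluntary* horizontal step off the lattice also removes the agent
(absorbing vertical boundaries, matching shoved exits); set
``horizontal_exit=False`` to abort such steps instead.  Voluntary vertical
steps off the lattice are always aborted (reflecting horizontal boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .lattice import Direction, LatticeState, Personality


@dataclass(frozen=True)
class ShovePlan:
    """Feasibility, direction, and displaced-agent count of a candidate shove.

    ``displaced_count`` is 0 iff the target site is vacant (or the mover itself
    would step off the lattice); ``exits_lattice`` marks plans whose far chain
    end (or the mover, for a voluntary boundary step) leaves through a vertical
    boundary.
    """

    direction: Direction
    displaced_count: int
    feasible: bool
    exits_lattice: bool


@dataclass(frozen=True)
class MoveOutcome:
    """Result of one motility attempt."""

    status: str                 # "moved" or "aborted"
    displaced_count: int = 0
    exited_count: int = 0       # agents removed through a vertical boundary

    def __post_init__(self):
        if self.status == "aborted" and (self.displaced_count or self.exited_count):
            raise ValueError("aborted moves displace and remove nobody")


def shove_extent(state: LatticeState, origin: tuple[int, int],
                 direction: Direction, horizontal_exit: bool = True) -> ShovePlan:
    """Plan the shove for the agent at ``origin`` (1-based) moving ``direction``:
    the maximal contiguous occupied run starting at the target site, truncated
    at the first vacancy or the lattice edge."""
    if state.is_vacant(origin):
        raise ValueError(f"no agent at origin {origin}")
    n, feas, ex = K.plan_move(state.grid, origin[0] - 1, origin[1] - 1,
                              int(direction), horizontal_exit)
    return ShovePlan(Direction(direction), int(n), bool(feas), bool(ex))


def execute_move(state: LatticeState, origin: tuple[int, int],
                 plan: ShovePlan) -> MoveOutcome:
    """Carry out a feasible plan: the mover takes the target site, each
    displaced agent shifts one site preserving color and order, and the far
    chain agent is removed when the plan exits the lattice."""
    if not plan.feasible:
        raise ValueError("cannot execute an infeasible plan")
    if state.is_vacant(origin):
        raise ValueError(f"no agent at origin {origin}")
    removed = K.execute_move(state.grid, state.ax, state.ay, state.alive,
                             origin[0] - 1, origin[1] - 1, int(plan.direction),
                             plan.displaced_count, plan.exits_lattice)
    exited = int(removed >= 0)
    if exited:
        state.refresh_counts()
    return MoveOutcome("moved", plan.displaced_count, exited)


def attempt_move(state: LatticeState, origin: tuple[int, int],
                 personality: Personality, rng: np.random.Generator,
                 horizontal_exit: bool = True) -> MoveOutcome:
    """One motility attempt by the agent at ``origin`` under its personality's
    rule.  Consumes exactly one uniform draw from ``rng`` (the direction choice,
    or the smart shover's tie-break)."""
    if state.is_vacant(origin):
        raise ValueError(f"no agent at origin {origin}")
    aid = int(state.grid[origin[0] - 1, origin[1] - 1])
    ok, n, removed = K.attempt_move(state.grid, state.ax, state.ay, state.acolor,
                                    state.alive, aid, int(personality),
                                    horizontal_exit, rng)
    if not ok:
        return MoveOutcome("aborted")
    exited = int(removed >= 0)
    if exited:
        state.refresh_counts()
    return MoveOutcome("moved", int(n), exited)
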