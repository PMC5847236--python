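"""Numba-jitted update kernels for the lattice exclusion/shoving process.

All rules live here once; the public modules (`motility`, `injection`, `engine`)
are thin wrappers.  Conventions used throughout the kernels:

* coordinates are 0-based internally (the public API is 1-based),
* ``grid[x, y]`` holds the agent id occupying a site, or -1 when vacant,
* agent attribute arrays (``ax``, ``ay``, ``acolor``, ``alive``) are indexed by id,
* directions are encoded 0=up(+y), 1=down(-y), 2=left(-x), 3=right(+x); this fixed
  enumeration order is also the tie-break scan order for minimum-effort moves,
* all randomness comes from a ``numpy.random.Generator`` passed in, so runs are a
  pure function of the seed.

Color codes: 0 empty, 1 red (invader), 2 green (resident).
Personality codes: 0 gentleman, 1 simple shover, 2 smart shover.
"""

import numpy as np
from numba import njit

# direction -> (dx, dy); order up, down, left, right
_DX = np.array([0, 0, -1, 1], dtype=np.int64)
_DY = np.array([1, -1, 0, 0], dtype=np.int64)

GENTLEMAN = 0
SIMPLE_SHOVER = 1
SMART_SHOVER = 2

EMPTY = 0
RED = 1
GREEN = 2

_BIG = 1 << 30


@njit(cache=True)
def scan_run(grid, x0, y0, d):
    """Length of the contiguous occupied run starting AT (x0, y0) inclusive,
    walking in direction ``d`` until the first vacancy or the lattice edge.

    Returns (count, hit_boundary): hit_boundary is True when the run is
    terminated by the lattice edge rather than a vacancy.
    """
    Lx, Ly = grid.shape
    dx, dy = _DX[d], _DY[d]
    n = 0
    x, y = x0, y0
    while 0 <= x < Lx and 0 <= y < Ly and grid[x, y] >= 0:
        n += 1
        x += dx
        y += dy
    hit = not (0 <= x < Lx and 0 <= y < Ly)
    return n, hit


@njit(cache=True)
def plan_move(grid, x, y, d, horizontal_exit):
    """Shove plan for an agent at (x, y) attempting direction ``d``.

    Returns (displaced_count, feasible, exits_lattice).  ``displaced_count`` is
    the number of agents that would be pushed; ``exits_lattice`` is True when the
    far end of the pushed chain (or the mover itself, for a voluntary step off a
    vertical boundary) leaves the lattice.  Vertical chains blocked all the way
    to a horizontal boundary are infeasible; horizontal chains always go through
    (agents may be pushed out at x-boundaries).  A voluntary horizontal step off
    the lattice is an exit when ``horizontal_exit`` is set, otherwise infeasible.
    Voluntary vertical steps off the lattice are always infeasible (reflecting
    horizontal boundaries).
    """
    Lx, Ly = grid.shape
    horizontal = d >= 2
    tx, ty = x + _DX[d], y + _DY[d]
    if not (0 <= tx < Lx and 0 <= ty < Ly):
        if horizontal and horizontal_exit:
            return 0, True, True
        return 0, False, False
    n, hit = scan_run(grid, tx, ty, d)
    if n == 0:
        return 0, True, False
    if hit:
        if horizontal:
            return n, True, True
        return n, False, False
    return n, True, False


@njit(cache=True)
def shove_chain(grid, ax, ay, alive, x0, y0, d, n, exits):
    """Shift the chain of ``n`` agents rooted at (x0, y0) (inclusive) one step
    along ``d``; when ``exits`` the far agent is removed instead of shifted.
    Leaves (x0, y0) vacant.  Returns the id of the removed agent, or -1.
    """
    dx, dy = _DX[d], _DY[d]
    removed = -1
    last = n - 1
    if exits:
        fx, fy = x0 + last * dx, y0 + last * dy
        removed = grid[fx, fy]
        alive[removed] = False
        grid[fx, fy] = -1
        last -= 1
    for k in range(last, -1, -1):
        sx, sy = x0 + k * dx, y0 + k * dy
        aid = grid[sx, sy]
        grid[sx + dx, sy + dy] = aid
        grid[sx, sy] = -1
        ax[aid] = sx + dx
        ay[aid] = sy + dy
    return removed


@njit(cache=True)
def execute_move(grid, ax, ay, alive, x, y, d, count, exits):
    """Carry out a feasible plan for the mover at (x, y).

    Returns the id of the agent removed through a vertical (x) boundary, or -1.
    With count == 0 and exits, the mover itself steps off the lattice.
    """
    dx, dy = _DX[d], _DY[d]
    if count == 0 and exits:
        aid = grid[x, y]
        alive[aid] = False
        grid[x, y] = -1
        return aid
    removed = -1
    if count > 0:
        removed = shove_chain(grid, ax, ay, alive, x + dx, y + dy, d, count, exits)
    aid = grid[x, y]
    grid[x + dx, y + dy] = aid
    grid[x, y] = -1
    ax[aid] = x + dx
    ay[aid] = y + dy
    return removed


@njit(cache=True)
def attempt_move(grid, ax, ay, acolor, alive, aid, personality, horizontal_exit, rng):
    """One motility attempt by agent ``aid`` per its personality.

    Returns (moved, displaced_count, removed_id):
      moved          1 on success, 0 on abort,
      displaced_count number of agents pushed by the executed move,
      removed_id     id of the agent that left the lattice (possibly the mover), or -1.
    Consumes exactly one uniform draw (direction choice, or tie-break for smart
    shovers, which scan all four directions deterministically).
    """
    x, y = ax[aid], ay[aid]
    if personality == SMART_SHOVER:
        # minimum shoving effort over feasible directions; vacant targets and
        # voluntary horizontal exits count as effort 0 (the cheapest possible)
        best = _BIG
        for d in range(4):
            n, feas, ex = plan_move(grid, x, y, d, horizontal_exit)
            if feas and n < best:
                best = n
        # a horizontal direction is always feasible, so best < _BIG
        m = 0
        for d in range(4):
            n, feas, ex = plan_move(grid, x, y, d, horizontal_exit)
            if feas and n == best:
                m += 1
        pick = int(rng.random() * m)
        k = 0
        for d in range(4):
            n, feas, ex = plan_move(grid, x, y, d, horizontal_exit)
            if feas and n == best:
                if k == pick:
                    removed = execute_move(grid, ax, ay, alive, x, y, d, n, ex)
                    return 1, n, removed
                k += 1
        return 0, 0, -1  # unreachable
    d = int(rng.random() * 4)
    n, feas, ex = plan_move(grid, x, y, d, horizontal_exit)
    if personality == GENTLEMAN:
        if not feas or n > 0:
            return 0, 0, -1
    elif not feas:
        return 0, 0, -1
    removed = execute_move(grid, ax, ay, alive, x, y, d, n, ex)
    return 1, n, removed


@njit(cache=True)
def motility_sweep(grid, ax, ay, acolor, alive, start_ids,
                   resident_personality, invader_personality, horizontal_exit, rng):
    """One time step's motility phase: len(start_ids) sequential uniform-with-
    replacement draws from the step-start agent list; draws landing on agents
    that have since exited are skipped (the selection event is still consumed).

    Returns (moved, aborts_red, aborts_green, exits_red, exits_green).
    """
    N = start_ids.size
    moved = 0
    aborts_r = 0
    aborts_g = 0
    exits_r = 0
    exits_g = 0
    for _ in range(N):
        j = int(rng.random() * N)
        aid = start_ids[j]
        if not alive[aid]:
            continue
        pers = invader_personality if acolor[aid] == RED else resident_personality
        ok, n, removed = attempt_move(grid, ax, ay, acolor, alive, aid,
                                      pers, horizontal_exit, rng)
        if ok:
            moved += 1
            if removed >= 0:
                if acolor[removed] == RED:
                    exits_r += 1
                else:
                    exits_g += 1
        else:
            if acolor[aid] == RED:
                aborts_r += 1
            else:
                aborts_g += 1
    return moved, aborts_r, aborts_g, exits_r, exits_g


@njit(cache=True)
def inject_attempt(grid, ax, ay, acolor, alive, n_agents,
                   sites_x, sites_y, personality, rng):
    """One invasion attempt: draw a site uniformly from the region; if vacant a
    red agent (id ``n_agents``) is placed there; if occupied the invader's
    personality decides (gentleman aborts; simple shover shoves the resident
    chain in a random direction, aborting on blocked vertical columns; smart
    shover shoves in the feasible minimum-effort direction and always succeeds).

    Returns (success, n_agents, removed_id).
    """
    k = int(rng.random() * sites_x.size)
    x, y = sites_x[k], sites_y[k]
    removed = -1
    if grid[x, y] >= 0:
        if personality == GENTLEMAN:
            return 0, n_agents, -1
        if personality == SIMPLE_SHOVER:
            d = int(rng.random() * 4)
            n, hit = scan_run(grid, x, y, d)
            horizontal = d >= 2
            if hit and not horizontal:
                return 0, n_agents, -1
            removed = shove_chain(grid, ax, ay, alive, x, y, d, n, hit)
        else:  # smart shover: minimum displaced chain among feasible directions
            best = _BIG
            for d in range(4):
                n, hit = scan_run(grid, x, y, d)
                if hit and d < 2:
                    continue
                if n < best:
                    best = n
            m = 0
            for d in range(4):
                n, hit = scan_run(grid, x, y, d)
                if hit and d < 2:
                    continue
                if n == best:
                    m += 1
            pick = int(rng.random() * m)
            kk = 0
            for d in range(4):
                n, hit = scan_run(grid, x, y, d)
                if hit and d < 2:
                    continue
                if n == best:
                    if kk == pick:
                        removed = shove_chain(grid, ax, ay, alive, x, y, d, n, hit)
                        break
                    kk += 1
    aid = n_agents
    grid[x, y] = aid
    ax[aid] = x
    ay[aid] = y
    acolor[aid] = RED
    alive[aid] = True
    return 1, n_agents + 1, removed


@njit(cache=True)
def inject_step(grid, ax, ay, acolor, alive, n_agents,
                sites_x, sites_y, attempts, personality, rng):
    """``attempts`` sequential invasion attempts (sites drawn independently with
    replacement).  Returns (successes, n_agents, exits_red, exits_green)."""
    succ = 0
    exits_r = 0
    exits_g = 0
    for _ in range(attempts):
        ok, n_agents, removed = inject_attempt(
            grid, ax, ay, acolor, alive, n_agents, sites_x, sites_y, personality, rng)
        succ += ok
        if removed >= 0:
            if acolor[removed] == RED:
                exits_r += 1
            else:
                exits_g += 1
    return succ, n_agents, exits_r, exits_g
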