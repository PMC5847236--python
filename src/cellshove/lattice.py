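"""Lattice geometry, agent colors/personalities, and the occupancy state.

The domain is a finite rectangular lattice of ``Lx`` x ``Ly`` sites with 1-based
integer coordinates (x, y), 1 <= x <= Lx, 1 <= y <= Ly.  Each site holds at most
one agent.  Green agents are the residents present at t = 0 (seeded uniformly at
concentration ``c_G``); red agents are invaders injected later.  Vertical
boundaries (x = 1, x = Lx) are absorbing — agents pushed or stepping across them
leave the system permanently; horizontal boundaries (y = 1, y = Ly) reflect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import numpy as np

from . import _kernels as K


class Direction(IntEnum):
    """The four lattice directions; UP/DOWN are vertical (±y), LEFT/RIGHT
    horizontal (±x).  The enumeration order is the documented tie-break scan
    order for minimum-effort moves."""

    UP = 0
    DOWN = 1
    LEFT = 2
    RIGHT = 3

    @property
    def is_horizontal(self) -> bool:
        return self in (Direction.LEFT, Direction.RIGHT)

    @property
    def step(self) -> tuple[int, int]:
        return (int(K._DX[self]), int(K._DY[self]))


class Personality(IntEnum):
    """Motility rule of an agent species: strict exclusion (GENTLEMAN), random
    shoving (SIMPLE_SHOVER), or minimum-effort shoving (SMART_SHOVER)."""

    GENTLEMAN = 0
    SIMPLE_SHOVER = 1
    SMART_SHOVER = 2


class Color(IntEnum):
    """RED marks invaders, GREEN the original residents."""

    RED = 1
    GREEN = 2


@dataclass(frozen=True)
class LatticeConfig:
    """Lattice dimensions, default 200 x 20."""

    Lx: int = 200
    Ly: int = 20

    def __post_init__(self):
        if self.Lx < 1 or self.Ly < 1:
            raise ValueError(f"lattice dimensions must be >= 1, got {self.Lx}x{self.Ly}")

    @property
    def n_sites(self) -> int:
        return self.Lx * self.Ly


def neighbor(config: LatticeConfig, site: tuple[int, int], direction: Direction):
    """Coordinate one lattice spacing from ``site`` in ``direction`` (1-based).

    Returns (coord, in_lattice); ``coord`` may lie outside [1,Lx]x[1,Ly], in
    which case ``in_lattice`` is False.
    """
    x, y = site
    if not (1 <= x <= config.Lx and 1 <= y <= config.Ly):
        raise ValueError(f"site {site} is outside the {config.Lx}x{config.Ly} lattice")
    dx, dy = Direction(direction).step
    nx, ny = x + dx, y + dy
    return (nx, ny), (1 <= nx <= config.Lx and 1 <= ny <= config.Ly)


class LatticeState:
    """Occupancy state of one realization.

    Internally agents are tracked by id: ``grid[x-1, y-1]`` holds the id of the
    occupant (or -1), and per-id arrays hold coordinates, color and alive flags.
    Exited agents keep their id but are flagged dead.  Cached per-color counts
    are maintained by every operation and can be audited with :meth:`validate`.
    """

    def __init__(self, config: LatticeConfig, capacity: int | None = None):
        self.config = config
        if capacity is None:
            capacity = config.n_sites
        capacity = max(capacity, 1)
        self.grid = np.full((config.Lx, config.Ly), -1, dtype=np.int64)
        self.ax = np.zeros(capacity, dtype=np.int64)
        self.ay = np.zeros(capacity, dtype=np.int64)
        self.acolor = np.zeros(capacity, dtype=np.int64)
        self.alive = np.zeros(capacity, dtype=np.bool_)
        self.n_agents = 0          # ids handed out so far (incl. dead)
        self.n_red = 0
        self.n_green = 0

    # -- construction -----------------------------------------------------

    def _grow(self, need: int) -> None:
        if need <= self.ax.size:
            return
        new = max(need, 2 * self.ax.size)
        for name in ("ax", "ay", "acolor"):
            arr = getattr(self, name)
            g = np.zeros(new, dtype=arr.dtype)
            g[: arr.size] = arr
            setattr(self, name, g)
        g = np.zeros(new, dtype=np.bool_)
        g[: self.alive.size] = self.alive
        self.alive = g

    def place(self, site: tuple[int, int], color: Color) -> int:
        """Put a new agent of ``color`` on a vacant ``site`` (1-based)."""
        x, y = site[0] - 1, site[1] - 1
        if self.grid[x, y] >= 0:
            raise ValueError(f"site {site} is already occupied")
        self._grow(self.n_agents + 1)
        aid = self.n_agents
        self.grid[x, y] = aid
        self.ax[aid] = x
        self.ay[aid] = y
        self.acolor[aid] = int(color)
        self.alive[aid] = True
        self.n_agents += 1
        if color == Color.RED:
            self.n_red += 1
        else:
            self.n_green += 1
        return aid

    # -- queries ----------------------------------------------------------

    def color_at(self, site: tuple[int, int]) -> Color | None:
        aid = self.grid[site[0] - 1, site[1] - 1]
        return None if aid < 0 else Color(int(self.acolor[aid]))

    def is_vacant(self, site: tuple[int, int]) -> bool:
        return self.grid[site[0] - 1, site[1] - 1] < 0

    @property
    def counts(self) -> dict[str, int]:
        return {"red": self.n_red, "green": self.n_green,
                "total": self.n_red + self.n_green}

    def occupancy_grid(self) -> np.ndarray:
        """(Lx, Ly) int8 grid of color codes: 0 empty, 1 red, 2 green."""
        out = np.zeros(self.grid.shape, dtype=np.int8)
        occ = self.grid >= 0
        out[occ] = self.acolor[self.grid[occ]].astype(np.int8)
        return out

    def validate(self) -> None:
        """Audit cached counters and the site<->agent maps; raises on mismatch."""
        occ = self.occupancy_grid()
        n_red = int((occ == 1).sum())
        n_green = int((occ == 2).sum())
        if (n_red, n_green) != (self.n_red, self.n_green):
            raise AssertionError(
                f"cached counts ({self.n_red},{self.n_green}) != scan ({n_red},{n_green})")
        live = np.flatnonzero(self.alive[: self.n_agents])
        if live.size != n_red + n_green:
            raise AssertionError("alive flags disagree with the grid")
        for aid in live:
            if self.grid[self.ax[aid], self.ay[aid]] != aid:
                raise AssertionError(f"agent {aid} coordinate desynchronized")

    def copy(self) -> "LatticeState":
        new = LatticeState(self.config, capacity=self.ax.size)
        new.grid = self.grid.copy()
        new.ax = self.ax.copy()
        new.ay = self.ay.copy()
        new.acolor = self.acolor.copy()
        new.alive = self.alive.copy()
        new.n_agents = self.n_agents
        new.n_red = self.n_red
        new.n_green = self.n_green
        return new

    def refresh_counts(self) -> None:
        """Recompute cached per-color counts from the alive flags (used by the
        engine after kernel sweeps)."""
        live = self.alive[: self.n_agents]
        cols = self.acolor[: self.n_agents][live]
        self.n_red = int((cols == 1).sum())
        self.n_green = int((cols == 2).sum())


def seed_uniform_green(config: LatticeConfig, c_G: float, rng: np.random.Generator,
                       exact_count: bool = False, capacity: int | None = None,
                       ) -> LatticeState:
    """Seed residents uniformly at concentration ``c_G``.

    By default every site independently holds a green agent with probability
    ``c_G`` (Bernoulli occupancy, the i.i.d. reading of a uniform initial
    concentration).  With ``exact_count`` exactly round(c_G * Lx * Ly) greens are
    placed on a uniform random subset of sites.
    """
    if not 0.0 <= c_G <= 1.0:
        raise ValueError(f"c_G must lie in [0, 1], got {c_G}")
    state = LatticeState(config, capacity=capacity)
    if exact_count:
        n = int(round(c_G * config.n_sites))
        flat = rng.permutation(config.n_sites)[:n]
        mask = np.zeros(config.n_sites, dtype=bool)
        mask[flat] = True
        mask = mask.reshape(config.Lx, config.Ly)
    else:
        mask = rng.random((config.Lx, config.Ly)) < c_G
    xs, ys = np.nonzero(mask)
    n = xs.size
    state._grow(n)
    ids = np.arange(n)
    state.grid[xs, ys] = ids
    state.ax[:n] = xs
    state.ay[:n] = ys
    state.acolor[:n] = int(Color.GREEN)
    state.alive[:n] = True
    state.n_agents = n
    state.n_green = int(n)
    return state


def column_occupancy(state: LatticeState, color: Color | None = None) -> np.ndarray:
    """Per-column occupancy fraction: entry x-1 is (# matching agents in column
    x) / Ly, in [0, 1].  ``color=None`` counts agents of either color."""
    occ = state.occupancy_grid()
    if color is None:
        m = occ > 0
    else:
        m = occ == int(color)
    return m.sum(axis=1) / state.config.Ly


def save_snapshot(state: LatticeState, path: str | Path, time: int,
                  extra: dict | None = None) -> tuple[Path, Path]:
    """Write a plain-text grid dump (CSV, Ly rows x Lx columns, codes 0/1/2 for
    empty/red/green) plus a JSON sidecar with the config and time stamp.

    Row r of the CSV (0-based from the top) is lattice row y = Ly - r, so the
    upper horizontal boundary prints first; columns left to right are x = 1..Lx.
    """
    path = Path(path)
    occ = state.occupancy_grid()           # (Lx, Ly)
    rows = occ.T[::-1]                     # (Ly, Lx), top row = y = Ly
    csv_path = path.with_suffix(".csv")
    np.savetxt(csv_path, rows, fmt="%d", delimiter=",")
    meta = {
        "time": int(time),
        "Lx": state.config.Lx,
        "Ly": state.config.Ly,
        "codes": {"0": "empty", "1": "red", "2": "green"},
        "coordinates": "1-based inclusive on both axes; CSV row 1 is y=Ly, "
                       "CSV column 1 is x=1",
        "counts": state.counts,
    }
    if extra:
        meta.update(extra)
    json_path = path.with_suffix(".json")
    json_path.write_text(json.dumps(meta, indent=1))
    return csv_path, json_path
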