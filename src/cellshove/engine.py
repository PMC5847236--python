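"""Advances one realization through discrete time.

Per time step: with N agents present at the step start, N sequential
uniform-with-replacement draws are made from the step-start agent list and each
drawn agent immediately attempts a move under its personality (an agent may be
drawn several times or not at all; draws landing on agents that exited earlier
in the step are skipped).  Injection then runs once.  Agents injected mid-step
become eligible for selection from the next step.  The motility-first ordering
is the default and can be flipped with ``injection_first`` for sensitivity
checks (the paper-style scenarios are insensitive to it).

A realization is a pure function of its :class:`SimulationConfig`, including
the seed: identical configs give bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as K
from .injection import InjectionConfig
from .lattice import (Color, LatticeConfig, LatticeState, Personality,
                      column_occupancy, seed_uniform_green)


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of one agent-based realization."""

    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    c_G: float = 0.0
    resident_personality: Personality = Personality.GENTLEMAN
    injection: InjectionConfig | None = field(default_factory=InjectionConfig)
    t_max: int = 250
    record_times: tuple[int, ...] = (50, 100, 250)
    seed: int = 0
    exact_count_seeding: bool = False
    horizontal_exit: bool = True
    injection_first: bool = False

    def __post_init__(self):
        if not 0.0 <= self.c_G <= 1.0:
            raise ValueError(f"c_G must lie in [0, 1], got {self.c_G}")
        if self.t_max < 0:
            raise ValueError(f"t_max must be >= 0, got {self.t_max}")
        bad = [t for t in self.record_times if not 0 <= t <= self.t_max]
        if bad:
            raise ValueError(f"record_times {bad} outside [0, t_max={self.t_max}]")
        if self.injection is not None:
            r = self.injection.region
            if (r.x_range[0] < 1 or r.x_range[1] > self.lattice.Lx
                    or r.y_range[0] < 1 or r.y_range[1] > self.lattice.Ly):
                raise ValueError(
                    f"injection region x{r.x_range} y{r.y_range} does not fit the "
                    f"{self.lattice.Lx}x{self.lattice.Ly} lattice")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class StepDiagnostics:
    """Bookkeeping for one time step."""

    n_selected: int = 0
    moved: int = 0
    aborts: dict = field(default_factory=dict)       # personality name -> count
    exits: int = 0                                   # agents lost at x-boundaries
    injected: int = 0                                # successful entries


@dataclass
class Trajectory:
    """Snapshots at the record times plus per-step counts and abort tallies."""

    config: SimulationConfig
    times: np.ndarray                  # 0..t_max
    red: np.ndarray
    green: np.ndarray
    snapshots: dict                    # time -> LatticeState copy
    abort_tally: dict                  # personality name -> total aborted moves
    injected: np.ndarray               # successful entries per step (index = t)
    exits: np.ndarray                  # boundary losses per step (index = t)

    @property
    def total(self) -> np.ndarray:
        return self.red + self.green

    def profile(self, t: int, color: Color | None = None) -> np.ndarray:
        return column_occupancy(self.snapshots[t], color)


def _personality_of(cfg: SimulationConfig) -> tuple[int, int]:
    res = int(cfg.resident_personality)
    inv = int(cfg.injection.invader_personality) if cfg.injection else res
    return res, inv


def run_step(state: LatticeState, cfg: SimulationConfig,
             rng: np.random.Generator) -> StepDiagnostics:
    """Advance ``state`` by one time step in place."""
    diag = StepDiagnostics(aborts={p.name.lower(): 0 for p in Personality})
    res_pers, inv_pers = _personality_of(cfg)

    def motility():
        start_ids = np.flatnonzero(state.alive[: state.n_agents])
        diag.n_selected = start_ids.size
        if start_ids.size == 0:
            return
        moved, ab_r, ab_g, ex_r, ex_g = K.motility_sweep(
            state.grid, state.ax, state.ay, state.acolor, state.alive,
            start_ids, res_pers, inv_pers, cfg.horizontal_exit, rng)
        diag.moved += int(moved)
        diag.exits += int(ex_r + ex_g)
        diag.aborts[Personality(inv_pers).name.lower()] += int(ab_r)
        diag.aborts[Personality(res_pers).name.lower()] += int(ab_g)
        state.n_red -= int(ex_r)
        state.n_green -= int(ex_g)

    def injection():
        if cfg.injection is None:
            return
        sx, sy = cfg.injection.region.site_arrays()
        state._grow(state.n_agents + cfg.injection.attempts_per_step)
        succ, n_agents, ex_r, ex_g = K.inject_step(
            state.grid, state.ax, state.ay, state.acolor, state.alive,
            state.n_agents, sx, sy, cfg.injection.attempts_per_step,
            inv_pers, rng)
        state.n_agents = int(n_agents)
        state.n_red += int(succ) - int(ex_r)
        state.n_green -= int(ex_g)
        diag.injected += int(succ)
        diag.exits += int(ex_r + ex_g)
        if inv_pers == K.GENTLEMAN:
            diag.aborts["gentleman"] += cfg.injection.attempts_per_step - int(succ)
        elif inv_pers == K.SIMPLE_SHOVER:
            diag.aborts["simple_shover"] += cfg.injection.attempts_per_step - int(succ)

    if cfg.injection_first:
        injection()
        motility()
    else:
        motility()
        injection()
    return diag


def initial_state(cfg: SimulationConfig, rng: np.random.Generator) -> LatticeState:
    attempts = cfg.injection.attempts_per_step if cfg.injection else 0
    capacity = cfg.lattice.n_sites + attempts * max(cfg.t_max, 1) + 4
    return seed_uniform_green(cfg.lattice, cfg.c_G, rng,
                              exact_count=cfg.exact_count_seeding,
                              capacity=capacity)


def run_realization(cfg: SimulationConfig,
                    seed: int | np.random.SeedSequence | None = None) -> Trajectory:
    """Run one realization; ``seed`` (default ``cfg.seed``) fixes all randomness."""
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    state = initial_state(cfg, rng)

    T = cfg.t_max
    red = np.zeros(T + 1, dtype=np.int64)
    green = np.zeros(T + 1, dtype=np.int64)
    injected = np.zeros(T + 1, dtype=np.int64)
    exits = np.zeros(T + 1, dtype=np.int64)
    red[0], green[0] = state.n_red, state.n_green
    snapshots: dict[int, LatticeState] = {}
    record = set(cfg.record_times)
    if 0 in record:
        snapshots[0] = state.copy()
    abort_tally = {p.name.lower(): 0 for p in Personality}

    for t in range(1, T + 1):
        before = state.n_red + state.n_green
        diag = run_step(state, cfg, rng)
        red[t], green[t] = state.n_red, state.n_green
        injected[t], exits[t] = diag.injected, diag.exits
        for k, v in diag.aborts.items():
            abort_tally[k] += v
        # conservation audit: count(t) = count(t-1) + entries - boundary losses
        if red[t] + green[t] != before + diag.injected - diag.exits:
            raise AssertionError(f"agent bookkeeping violated at t={t}")
        if t in record:
            snapshots[t] = state.copy()

    return Trajectory(cfg, np.arange(T + 1), red, green, snapshots,
                      abort_tally, injected, exits)
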