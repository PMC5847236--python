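"""Invasion-region geometries and the per-step injection protocol.

Red invaders enter through one of three regions of the default 200 x 20 domain:
a 2D band (x in [90,109], all rows), the horizontal midline (x in [90,109],
y = 10), or the upper horizontal boundary (x in [90,109], y = 20).  Each time
step a fixed number of entry attempts (default 4) draw a site uniformly with
replacement from the region; a vacant site is occupied by a new red agent, and
an occupied one is handled per the invader's personality, mirroring its
motility rule: gentlemen abort, simple shovers shove the resident chain in a
uniformly drawn direction (aborting on vertical columns blocked to the
boundary), smart shovers shove along a feasible minimum-effort direction and
therefore always succeed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .lattice import LatticeConfig, LatticeState, Personality

#: region bounds shared by all three geometries (continuum notation [Zl, Zr])
ZL, ZR = 90, 109

REGION_KINDS = ("band_2d", "midline", "upper_horizontal")


@dataclass(frozen=True)
class InjectionRegion:
    """A named invasion geometry resolved to its set of candidate sites."""

    kind: str
    x_range: tuple[int, int]
    y_range: tuple[int, int]

    @classmethod
    def from_kind(cls, kind: str, lattice: LatticeConfig = LatticeConfig()
                  ) -> "InjectionRegion":
        if kind == "band_2d":
            return cls(kind, (ZL, ZR), (1, lattice.Ly))
        if kind == "midline":
            y = lattice.Ly // 2
            return cls(kind, (ZL, ZR), (y, y))
        if kind == "upper_horizontal":
            return cls(kind, (ZL, ZR), (lattice.Ly, lattice.Ly))
        raise ValueError(f"unknown region kind {kind!r}; expected one of {REGION_KINDS} "
                         "or use a custom x/y range directly")

    @property
    def n_sites(self) -> int:
        return ((self.x_range[1] - self.x_range[0] + 1)
                * (self.y_range[1] - self.y_range[0] + 1))

    def site_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based (x, y) coordinate arrays of all region sites, x-major."""
        xs = np.arange(self.x_range[0] - 1, self.x_range[1])
        ys = np.arange(self.y_range[0] - 1, self.y_range[1])
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return gx.ravel(), gy.ravel()

    def sites(self) -> set[tuple[int, int]]:
        gx, gy = self.site_arrays()
        return {(int(x) + 1, int(y) + 1) for x, y in zip(gx, gy)}


@dataclass(frozen=True)
class InjectionConfig:
    """Invasion protocol: region, invader personality, attempts per step."""

    region: InjectionRegion = field(
        default_factory=lambda: InjectionRegion.from_kind("band_2d"))
    invader_personality: Personality = Personality.SIMPLE_SHOVER
    attempts_per_step: int = 4

    def __post_init__(self):
        if self.attempts_per_step < 1:
            raise ValueError("attempts_per_step must be >= 1")


def inject_step(state: LatticeState, cfg: InjectionConfig,
                rng: np.random.Generator) -> int:
    """Run one step's entry attempts; returns the number of successful entries.
    New red agents appear on the drawn sites; residents may be shoved, possibly
    off an absorbing vertical boundary."""
    sx, sy = cfg.region.site_arrays()
    state._grow(state.n_agents + cfg.attempts_per_step)
    succ, n_agents, _, _ = K.inject_step(
        state.grid, state.ax, state.ay, state.acolor, state.alive,
        state.n_agents, sx, sy, cfg.attempts_per_step,
        int(cfg.invader_personality), rng)
    state.n_agents = int(n_agents)
    state.refresh_counts()
    return int(succ)
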