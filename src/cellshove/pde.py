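"""Mean-field continuum limit of the shoving lattice model, in 1D along x.

Under the mean-field closure (site occupancies independent), the occupancy
fractions R(x,t) of invaders and G(x,t) of residents obey nonlinear
advection–diffusion equations.  With both species simple shovers
(C = R + G the total occupancy):

    dR/dt = D0 d/dx [ D(C) dR/dx + R V(C) dC/dx ] + S_R
    dG/dt = D0 d/dx [ D(C) dG/dx + G V(C) dC/dx ]

    D(C) = 1/(1-C),      V(C) = (3-C)/(1-C)^3.

With gentlemen residents and simple-shover invaders, only the invaders can
push, so the pusher density in the displacement terms is R rather than C and
the coefficients change on both equations:

    dR/dt = D0 d/dx [ D(R,C) dR/dx + R V(R,C) dC/dx ] + S_R
    dG/dt = D0 d/dx [ A(R,C) dG/dx + G ( B(C) dR/dx + (1 + V(R,C)) dC/dx ) ]

    D(R,C) = 1 + 2R(2-C)/(1-C)^2,   V(R,C) = R (3-C)/(1-C)^3,
    A(R,C) = (1-C) + R/(1-C),       B(C)   = (3-C)/(1-C)^2.

These forms follow from the gradient expansion of the lattice master equation
under the mean-field closure: a gentleman at x is carried across a bond either
by its own exclusion-limited hop or by the push of a shover chain reaching it,
whose probability is the geometric sum sum_m R(x-m) prod_{l<m} C(x-l).
Consistency limits (all covered by tests): at R = 0 the G equation reduces to
linear diffusion of a plain exclusion process; at G = 0 both mixed equations
collapse to the single-species shover law with effective diffusivity
(1+C)/(1-C)^3, the same limit the two-shover system gives; and the species
diffusion matrix of the mixed system stays positive-definite (replacing
D(R,C) with the two-shover D(C) loses parabolicity once R is appreciable and
the integration blows up in finite time).

The injection of invaders appears as a source on R,

    S_R = P_entry H(C) E(x),

with E(x) the indicator of the invasion interval [Zl, Zr] (an additional
factor (1-C) applies for gentlemen invaders, whose entry attempts abort on
occupied sites) and H the crowding switch: entries succeed while C < 1 and are
impossible at full occupancy.  For the stiff integrator H is smoothed over a
width ``eps_H`` below full occupancy.

On the source normalization: the lattice protocol injects ``attempts`` cells
per step uniformly over a region of ``w`` columns spanning all ``Ly`` rows, so
the column-averaged occupancy gain per column per step is
attempts/(w*Ly) = 4/(20*20) = 0.01 — numerically equal to the per-site entry
probability P_entry = attempts/(w*Ly) because the band spans every row.  An
extra 1/Ly prefactor on top of the per-site P_entry would inject 20x too
little mass (0.2 cells per step instead of 4) and makes continuum-vs-lattice
agreement impossible; it belongs with a per-*column* entry rate
(attempts/w = 0.2), with which it gives the same 0.01.

Numerics: method of lines on a uniform node grid, conservative central (finite
volume) differencing with arithmetic-mean face coefficients, stiff adaptive
implicit integration (LSODA with a banded Jacobian).  Boundary conditions at
x = 0 and x = L are homogeneous Dirichlet R = G = 0 by default (matching the
absorbing vertical lattice boundaries); homogeneous Neumann is available via
``bc="neumann"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .ensemble import EnsembleSummary
from .lattice import Color

SYSTEMS = ("two_shovers", "gentlemen_residents")


@dataclass(frozen=True)
class PDEConfig:
    """Continuum-model parameters.

    ``D0`` is the base diffusivity of the underlying unbiased 4-direction walk
    with unit spacing and one move attempt per agent per time step, D0 = 1/4.
    ``P_entry`` = attempts_per_step / region size = 4/400 = 0.01 for the 2D-band
    protocol; for the band this per-site probability equals the column-averaged
    source density attempts/(w*Ly) (see the module docstring).  ``Ly`` is kept
    for that normalization bookkeeping.
    """

    length: float = 200.0
    dx: float = 0.1
    D0: float = 0.25
    Ly: int = 20
    P_entry: float = 0.01
    Zl: float = 90.0
    Zr: float = 109.0
    c_G: float = 0.0
    invader: str = "simple_shover"     # "simple_shover" | "gentleman"
    output_times: tuple[float, ...] = (50.0, 100.0, 250.0)
    bc: str = "dirichlet"              # "dirichlet" | "neumann"
    eps_H: float = 1e-3
    rtol: float = 1e-6
    atol: float = 1e-9

    def __post_init__(self):
        if not (0 < self.dx <= 1):
            raise ValueError(f"dx must lie in (0, 1], got {self.dx}")
        if not self.Zl < self.Zr:
            raise ValueError("Zl must be < Zr")
        if self.bc not in ("dirichlet", "neumann"):
            raise ValueError(f"unknown bc {self.bc!r}")
        if self.invader not in ("simple_shover", "gentleman", "smart_shover"):
            raise ValueError(f"unknown invader {self.invader!r}")
        if any(t < 0 for t in self.output_times):
            raise ValueError("output_times must be >= 0")

    @property
    def grid(self) -> np.ndarray:
        n = int(round(self.length / self.dx))
        return np.linspace(0.0, self.length, n + 1)

    def with_(self, **kw) -> "PDEConfig":
        return replace(self, **kw)


@dataclass
class PDEFields:
    """Concentration profiles on the x-grid at one time."""

    x: np.ndarray
    R: np.ndarray
    G: np.ndarray
    t: float = 0.0

    @property
    def C(self) -> np.ndarray:
        return self.R + self.G

    def bound_violation(self) -> float:
        """How far the fields stray outside [0, 1] (diagnostic; the state is
        never clipped)."""
        lo = min(self.R.min(), self.G.min(), 0.0)
        hi = max(self.C.max(), 1.0)
        return max(-lo, hi - 1.0)


# regularization floor for 1-C inside flux coefficients; the H switch already
# shuts the source off as C -> 1, this only guards the stiff solver's trial steps
_EPS_REG = 1e-6


def _om(C):
    return np.maximum(1.0 - C, _EPS_REG)


def D_single(C):
    """Mean-field diffusivity factor D(C) = 1/(1-C) of the shover flux."""
    C = np.asarray(C, dtype=float)
    if np.any(C >= 1.0):
        raise ValueError("D(C) is singular at C >= 1")
    return 1.0 / (1.0 - C)


def V_single(C):
    """Mean-field advection factor V(C) = (3-C)/(1-C)^3 of the shover flux."""
    C = np.asarray(C, dtype=float)
    if np.any(C >= 1.0):
        raise ValueError("V(C) is singular at C >= 1")
    return (3.0 - C) / (1.0 - C) ** 3


def V_cross(R, C):
    """Cross-advection factor V(R,C) = R (3-C)/(1-C)^3 of the gentlemen-resident
    system."""
    C = np.asarray(C, dtype=float)
    if np.any(C >= 1.0):
        raise ValueError("V(R,C) is singular at C >= 1")
    return np.asarray(R, dtype=float) * (3.0 - C) / (1.0 - C) ** 3


def D_cross(R, C):
    """Invader diffusivity factor D(R,C) = 1 + 2R(2-C)/(1-C)^2 of the
    gentlemen-resident system (pushers are the invaders only)."""
    C = np.asarray(C, dtype=float)
    if np.any(C >= 1.0):
        raise ValueError("D(R,C) is singular at C >= 1")
    return 1.0 + 2.0 * np.asarray(R, dtype=float) * (2.0 - C) / (1.0 - C) ** 2


def source_SR(x, C, cfg: PDEConfig):
    """Injection source P_entry H(C) E(x), with P_entry the per-site entry
    probability per time step (see the module docstring for the
    normalization); the crowding switch H is smoothed over ``eps_H`` below
    full occupancy, and gentlemen invaders carry the extra abort factor
    (1-C)."""
    x = np.asarray(x, dtype=float)
    C = np.asarray(C, dtype=float)
    E = ((x >= cfg.Zl) & (x <= cfg.Zr)).astype(float)
    H = np.clip((1.0 - C) / cfg.eps_H, 0.0, 1.0)
    S = cfg.P_entry * H * E
    if cfg.invader == "gentleman":
        S = S * np.clip(1.0 - C, 0.0, 1.0)
    return S


def _fluxes(R, G, cfg: PDEConfig, system: str):
    """Face fluxes (F_R, F_G) on the staggered grid (arithmetic-mean face
    coefficients), positive in +x."""
    C = R + G
    Rf = 0.5 * (R[1:] + R[:-1])
    Gf = 0.5 * (G[1:] + G[:-1])
    Cf = Rf + Gf
    dRdx = np.diff(R) / cfg.dx
    dGdx = np.diff(G) / cfg.dx
    dCdx = dRdx + dGdx
    om = _om(Cf)
    Vf = (3.0 - Cf) / om ** 3
    if system == "two_shovers":
        Df = 1.0 / om
        F_R = cfg.D0 * (Df * dRdx + Rf * Vf * dCdx)
        F_G = cfg.D0 * (Df * dGdx + Gf * Vf * dCdx)
    elif system == "gentlemen_residents":
        Dm = 1.0 + 2.0 * Rf * (2.0 - Cf) / om ** 2
        Vrc = Rf * Vf
        F_R = cfg.D0 * (Dm * dRdx + Rf * Vrc * dCdx)
        A = (1.0 - Cf) + Rf / om
        B = (3.0 - Cf) / om ** 2
        F_G = cfg.D0 * (A * dGdx + Gf * (B * dRdx + (1.0 + Vrc) * dCdx))
    else:
        raise ValueError(f"unknown system {system!r}; expected one of {SYSTEMS}")
    return F_R, F_G


def _rhs(R, G, cfg: PDEConfig, system: str):
    """Semi-discrete right-hand side (dR/dt, dG/dt) on the node grid."""
    if not (np.all(np.isfinite(R)) and np.all(np.isfinite(G))):
        bad = np.nonzero(~(np.isfinite(R) & np.isfinite(G)))[0]
        raise FloatingPointError(f"non-finite state at grid nodes {bad[:5]}")
    x = cfg.grid
    F_R, F_G = _fluxes(R, G, cfg, system)
    S = source_SR(x, R + G, cfg)
    dR = np.zeros_like(R)
    dG = np.zeros_like(G)
    dR[1:-1] = np.diff(F_R) / cfg.dx + S[1:-1]
    dG[1:-1] = np.diff(F_G) / cfg.dx
    if cfg.bc == "neumann":
        # half control volumes at the ends, zero boundary flux
        half = cfg.dx / 2.0
        dR[0] = F_R[0] / half + S[0]
        dR[-1] = -F_R[-1] / half + S[-1]
        dG[0] = F_G[0] / half
        dG[-1] = -F_G[-1] / half
    # dirichlet: boundary nodes pinned (dR = dG = 0 there)
    return dR, dG


def rhs_two_shovers(fields: PDEFields, cfg: PDEConfig):
    """Time-derivative fields for the two-simple-shover system."""
    dR, dG = _rhs(fields.R, fields.G, cfg, "two_shovers")
    return PDEFields(fields.x, dR, dG, fields.t)


def rhs_gentlemen_residents(fields: PDEFields, cfg: PDEConfig):
    """Time-derivative fields for gentlemen residents + shover invaders."""
    dR, dG = _rhs(fields.R, fields.G, cfg, "gentlemen_residents")
    return PDEFields(fields.x, dR, dG, fields.t)


def mass_balance_residual(fields: PDEFields, cfg: PDEConfig, system: str) -> float:
    """Relative residual of the discrete mass balance

        d/dt integral(R+G) = integral(S_R) - net boundary outflux,

    evaluated on the semi-discrete right-hand side.  Conservative differencing
    makes this hold to rounding, so the residual certifies the discretization.
    """
    R, G = fields.R, fields.G
    x = cfg.grid
    F_R, F_G = _fluxes(R, G, cfg, system)
    S = source_SR(x, R + G, cfg)
    dR, dG = _rhs(R, G, cfg, system)
    if cfg.bc == "neumann":
        vol = np.full(x.size, cfg.dx)
        vol[0] = vol[-1] = cfg.dx / 2.0
        dmass = np.sum((dR + dG) * vol)
        src = np.sum(S * vol)
        outflux = 0.0
    else:
        # Dirichlet: interior nodes only; flux through the faces next to the
        # pinned boundary nodes leaves the accounted mass
        dmass = np.sum((dR + dG)[1:-1]) * cfg.dx
        src = np.sum(S[1:-1]) * cfg.dx
        outflux = (F_R[0] + F_G[0]) - (F_R[-1] + F_G[-1])
    scale = max(abs(dmass), abs(src), abs(outflux), 1e-12)
    return abs(dmass - (src - outflux)) / scale


@dataclass
class PDESolution:
    """Solution profiles at the requested output times."""

    config: PDEConfig
    system: str
    times: np.ndarray
    x: np.ndarray
    R: np.ndarray                       # (n_times, n_nodes)
    G: np.ndarray

    def at(self, t: float) -> PDEFields:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-9:
            raise ValueError(f"time {t} not among output times {self.times}")
        return PDEFields(self.x, self.R[i].copy(), self.G[i].copy(), float(t))

    def frame(self, t: float) -> pd.DataFrame:
        f = self.at(t)
        return pd.DataFrame({"x": f.x, "R": f.R, "G": f.G, "C": f.C})


def solve(cfg: PDEConfig, system: str = "gentlemen_residents",
          initial: PDEFields | None = None) -> PDESolution:
    """Integrate the selected system with LSODA (adaptive, stiff-capable,
    banded Jacobian) and report the profiles at ``cfg.output_times``.

    The default initial data is the paper-style invasion scenario: R = 0 and a
    uniform resident background G = c_G (zeroed at pinned Dirichlet boundary
    nodes).
    """
    if system not in SYSTEMS:
        raise ValueError(f"unknown system {system!r}; expected one of {SYSTEMS}")
    x = cfg.grid
    n = x.size
    if initial is None:
        R0 = np.zeros(n)
        G0 = np.full(n, float(cfg.c_G))
        if cfg.bc == "dirichlet":
            G0[0] = G0[-1] = 0.0
    else:
        R0, G0 = initial.R.copy(), initial.G.copy()

    def fun(t, y):
        R = y[0::2]
        G = y[1::2]
        dR, dG = _rhs(R, G, cfg, system)
        out = np.empty_like(y)
        out[0::2] = dR
        out[1::2] = dG
        return out

    y0 = np.empty(2 * n)
    y0[0::2] = R0
    y0[1::2] = G0
    times = np.array(sorted(set(float(t) for t in cfg.output_times)))
    t_end = float(times[-1]) if times.size else 0.0
    t_eval = times[times > 0]
    if t_end <= 0.0:
        sol_R = R0[None, :].repeat(max(times.size, 1), axis=0)
        return PDESolution(cfg, system, times, x, sol_R, G0[None, :].repeat(max(times.size, 1), axis=0))
    sol = solve_ivp(fun, (0.0, t_end), y0, method="LSODA", t_eval=t_eval,
                    rtol=cfg.rtol, atol=cfg.atol, lband=3, uband=3)
    if not sol.success:
        raise RuntimeError(f"PDE solver failed: {sol.message}; "
                           f"last valid time t={sol.t[-1] if sol.t.size else 0.0}")
    R = np.empty((times.size, n))
    G = np.empty((times.size, n))
    j = 0
    for i, t in enumerate(times):
        if t == 0.0:
            R[i], G[i] = R0, G0
        else:
            R[i] = sol.y[0::2, j]
            G[i] = sol.y[1::2, j]
            j += 1
    return PDESolution(cfg, system, times, x, R, G)


def grid_refinement_check(cfg: PDEConfig, system: str, t: float | None = None) -> float:
    """Max-norm relative change of the (R, G) profiles at the final output time
    when the grid spacing is halved — the grid-independence diagnostic."""
    if t is None:
        t = max(cfg.output_times)
    coarse = solve(cfg.with_(output_times=(t,)), system).at(t)
    fine = solve(cfg.with_(dx=cfg.dx / 2, output_times=(t,)), system).at(t)
    Rf = np.interp(coarse.x, fine.x, fine.R)
    Gf = np.interp(coarse.x, fine.x, fine.G)
    scale = max(np.abs(fine.C).max(), 1e-12)
    return float(max(np.abs(coarse.R - Rf).max(), np.abs(coarse.G - Gf).max()) / scale)


@dataclass
class DiscrepancyReport:
    """Continuum-vs-ensemble gaps at one time, per species and total."""

    t: float
    max_abs: dict
    rms: dict
    x_at_max: dict

    def to_dict(self) -> dict:
        return {"t": self.t, "max_abs": self.max_abs, "rms": self.rms,
                "x_at_max": self.x_at_max}


def compare_to_ensemble(pde: PDEFields | PDESolution, summary: EnsembleSummary,
                        t: float) -> DiscrepancyReport:
    """Max-norm and L2 (RMS) differences between the continuum profiles and the
    ensemble-mean occupancy profiles at time ``t``, per species, with the
    location of each maximum gap.  The ensemble's integer column profile is
    interpolated onto the PDE grid; the metric is symmetric in its arguments.
    """
    if isinstance(pde, PDESolution):
        pde = pde.at(t)
    elif abs(pde.t - t) > 1e-9:
        raise ValueError(f"PDE fields are at t={pde.t}, not requested t={t}")
    if t not in set(int(v) for v in summary.times):
        raise ValueError(f"t={t} not among ensemble record times {summary.times}")
    xs = summary.x.astype(float)
    sel = (pde.x >= xs[0]) & (pde.x <= xs[-1])
    xg = pde.x[sel]
    max_abs, rms, x_at = {}, {}, {}
    for name, p_cont, p_abm in (
        ("red", pde.R[sel], np.interp(xg, xs, summary.profile(Color.RED, t))),
        ("green", pde.G[sel], np.interp(xg, xs, summary.profile(Color.GREEN, t))),
        ("total", pde.C[sel], np.interp(xg, xs, summary.profile(None, t))),
    ):
        d = np.abs(p_cont - p_abm)
        i = int(np.argmax(d))
        max_abs[name] = float(d[i])
        rms[name] = float(np.sqrt(np.mean(d ** 2)))
        x_at[name] = float(xg[i])
    return DiscrepancyReport(float(t), max_abs, rms, x_at)
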