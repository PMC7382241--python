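"""Two-step ternary-complex equilibrium model.

A presenter protein P binds a small-molecule ligand L, and only the binary
complex PL engages the target T:

    P + L  ⇌ PL     K1 = [P][L] / [PL]      (binary dissociation constant)
    PL + T ⇌ PLT    K2 = [PL][T] / [PLT]    (ternary dissociation constant)

Direct L·T binding is excluded from the model: the compound alone shows no
measurable target engagement, so all target recruitment flows through PL.
The solver reduces the coupled mass balances to nested monotone 1-D root
searches (brentq), which is unconditionally convergent on the physical
bracket; an optional competitor ligand C (P + C ⇌ PC, K3) models chemical
reversal of ternary-complex formation by an inert pocket binder, and an
optional direct L + T ⇌ LT arm (K_LT, disabled by default) supports
exploring hook-effect regimes where the ligand saturates both proteins
separately — in the default two-step model ternary occupancy is monotone
non-decreasing in total ligand and plateaus instead of hooking.

Concentrations are molar throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import ConvergenceError

__all__ = ["EquilibriumSystem", "EquilibriumState", "solve_equilibrium",
           "titration_curve"]

_RESIDUAL_TOL = 1e-9


@dataclass
class EquilibriumSystem:
    """Totals and dissociation constants of the P/L/T (+ optional competitor) system."""

    P0: float
    L0: float
    T0: float
    K1_binary: float
    K2_ternary: float
    C0: float = 0.0           # competitor total (0 = no competition)
    K3_competitor: float = 1.0
    K_LT: float = float("inf")  # direct L·T dissociation; inf = no direct binding

    def __post_init__(self) -> None:
        for label, v in (("P0", self.P0), ("L0", self.L0), ("T0", self.T0),
                         ("C0", self.C0)):
            if v < 0:
                raise ValueError(f"{label} must be >= 0, got {v}")
        for label, v in (("K1_binary", self.K1_binary),
                         ("K2_ternary", self.K2_ternary),
                         ("K3_competitor", self.K3_competitor),
                         ("K_LT", self.K_LT)):
            if not v > 0:
                raise ValueError(f"{label} must be > 0, got {v}")


@dataclass
class EquilibriumState:
    P: float
    L: float
    T: float
    PL: float
    PLT: float
    PC: float = 0.0
    LT: float = 0.0
    fraction_ternary: float = 0.0
    residuals: dict = field(default_factory=dict)


def _free_p(sys: EquilibriumSystem, l: float, t: float, c: float) -> float:
    return sys.P0 / (1.0 + l / sys.K1_binary
                     + l * t / (sys.K1_binary * sys.K2_ternary)
                     + c / sys.K3_competitor)


def _solve_c(sys: EquilibriumSystem, l: float, t: float) -> float:
    if sys.C0 == 0.0:
        return 0.0
    # C0 = c (1 + p(c)/K3); monotone increasing in c
    def g(c: float) -> float:
        return c * (1.0 + _free_p(sys, l, t, c) / sys.K3_competitor) - sys.C0
    return brentq(g, 0.0, sys.C0, xtol=1e-300, rtol=8.9e-16, maxiter=300)


def _solve_t(sys: EquilibriumSystem, l: float) -> tuple[float, float]:
    if sys.T0 == 0.0:
        return 0.0, _solve_c(sys, l, 0.0)
    # T0 = t (1 + p(t) l / (K1 K2)); monotone increasing in t
    def f(t: float) -> float:
        c = _solve_c(sys, l, t)
        p = _free_p(sys, l, t, c)
        return t * (1.0 + p * l / (sys.K1_binary * sys.K2_ternary)
                    + l / sys.K_LT) - sys.T0
    t = brentq(f, 0.0, sys.T0, xtol=1e-300, rtol=8.9e-16, maxiter=300)
    return t, _solve_c(sys, l, t)


def solve_equilibrium(sys: EquilibriumSystem) -> EquilibriumState:
    """Unique physical equilibrium state under mass balance.

    The ligand balance g(l) = l + [PL] + [PLT] - L0 is strictly increasing
    in free l, so the outer bracket [0, L0] contains exactly one root; the
    inner t- and c-balances are likewise monotone.  All returned residuals
    are below 1e-9 relative.
    """
    if sys.L0 == 0.0:
        # no ligand: only P/C and free T species
        c = _solve_c(sys, 0.0, sys.T0)
        p = _free_p(sys, 0.0, sys.T0, c)
        state = EquilibriumState(P=p, L=0.0, T=sys.T0, PL=0.0, PLT=0.0,
                                 PC=sys.C0 - c if sys.C0 else 0.0)
        state.residuals = _residuals(sys, state)
        return state

    def g(l: float) -> float:
        t, c = _solve_t(sys, l)
        p = _free_p(sys, l, t, c)
        pl = p * l / sys.K1_binary
        plt = pl * t / sys.K2_ternary
        return l + pl + plt + l * t / sys.K_LT - sys.L0

    l = brentq(g, 0.0, sys.L0, xtol=1e-300, rtol=8.9e-16, maxiter=300)
    t, c = _solve_t(sys, l)
    p = _free_p(sys, l, t, c)
    pl = p * l / sys.K1_binary
    plt = pl * t / sys.K2_ternary
    pc = p * c / sys.K3_competitor
    lt = l * t / sys.K_LT
    state = EquilibriumState(
        P=p, L=l, T=t, PL=pl, PLT=plt, PC=pc, LT=lt,
        fraction_ternary=plt / sys.T0 if sys.T0 > 0 else 0.0,
    )
    state.residuals = _residuals(sys, state)
    worst = max(state.residuals.values())
    if worst > _RESIDUAL_TOL:
        raise ConvergenceError(
            f"mass-balance residual {worst:.3e} exceeds {_RESIDUAL_TOL}; "
            f"residuals={state.residuals}")
    return state


def _residuals(sys: EquilibriumSystem, st: EquilibriumState) -> dict:
    def rel(err: float, total: float) -> float:
        return abs(err) / total if total > 0 else abs(err)

    c_free = sys.C0 - st.PC
    return {
        "P": rel(st.P + st.PL + st.PLT + st.PC - sys.P0, sys.P0),
        "L": rel(st.L + st.PL + st.PLT + st.LT - sys.L0, sys.L0),
        "T": rel(st.T + st.PLT + st.LT - sys.T0, sys.T0),
        "C": rel(st.PC * sys.K3_competitor - st.P * c_free, sys.C0 * sys.K3_competitor),
    }


def titration_curve(
    sys: EquilibriumSystem, l0_values: np.ndarray
) -> tuple[np.ndarray, float]:
    """fraction_ternary over a ligand-dose sweep, plus the dose of the maximum.

    Sweeping L0 from far below to far above the protein totals produces the
    characteristic hook: ternary occupancy rises with dose, peaks, then
    falls as excess free ligand saturates P into binary PL that outcompetes
    the ternary species.
    """
    l0_values = np.asarray(l0_values, dtype=float)
    if l0_values.size == 0:
        raise ValueError("empty L0 sweep")
    if np.any(l0_values <= 0):
        raise ValueError("sweep values must be > 0")
    fractions = np.empty(l0_values.size)
    for i, l0 in enumerate(l0_values):
        s = EquilibriumSystem(sys.P0, float(l0), sys.T0, sys.K1_binary,
                              sys.K2_ternary, sys.C0, sys.K3_competitor,
                              sys.K_LT)
        fractions[i] = solve_equilibrium(s).fraction_ternary
    peak_l0 = float(l0_values[int(np.argmax(fractions))])
    return fractions, peak_l0
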