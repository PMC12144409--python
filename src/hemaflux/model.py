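"""Simulation and observation of the three-origin HSC differentiation model.

The normalized state carries 12 compartments for each of the three origins
(donor D, competitor C, recipient R): LT- and ST-HSC pools ``L``/``S``,
progenitors ``Y[i]`` for the four lineages, mature myeloid counts ``Z[i]``
(i = N, E, P), and the B-cell maturation chain ``EB1 -> EB2 -> ZB`` (a
two-stage eclipse phase giving an Erlang-distributed delay before mature
B cells appear).

LT pools grow logistically against the shared crowding term sum_j L_j; ST
pools against sum_j S_j / KS plus the influx ``pLS * L``.  Myeloid
progenitors receive both the bypass flux ``pL_i * L`` and the canonical flux
``pS_i * S``; B progenitors only the latter.  Recipient cells have every
production rate zero and their mature cells decay at ``deltaR``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import _integrate
from ._integrate import NSTATE, NTHETA
from .params import (
    LINEAGES,
    AgeGroup,
    IndividualParameters,
    Lineage,
    Origin,
    PopulationParameters,
    Scenario,
)

__all__ = [
    "COMPARTMENTS",
    "state_index",
    "initial_state",
    "steady_state",
    "pack_rates",
    "derivative",
    "simulate",
    "Trajectory",
    "SimulationError",
    "observe_chimerism",
    "chimerism_shares",
    "observe_cbc",
    "estimate_recipient_steady",
]

COMPARTMENTS = ("L", "S", "YN", "YE", "YP", "YB", "ZN", "ZE", "ZP", "EB1", "EB2", "ZB")
_ORIGIN_IDX = {Origin.D: 0, Origin.C: 1, Origin.R: 2}
_COMP_IDX = {name: i for i, name in enumerate(COMPARTMENTS)}
_LIN_IDX = {Lineage.N: 0, Lineage.E: 1, Lineage.P: 2, Lineage.B: 3}


class SimulationError(RuntimeError):
    """Raised when the integrator fails; carries solver diagnostics."""


def state_index(origin: Origin, comp: str) -> int:
    """Flat index of a compartment, e.g. ``state_index(Origin.D, "ZP")``."""
    return 12 * _ORIGIN_IDX[Origin(origin)] + _COMP_IDX[comp]


def pack_rates(pop: PopulationParameters, ind: Optional[IndividualParameters]) -> np.ndarray:
    """Pack population + donor-scaled rates into the flat theta vector.

    Donor rates are population rates times the individual scaling factors;
    competitor rates are the population values; every recipient production
    rate is zero and recipient death uses ``deltaR``.
    """
    theta = np.zeros(NTHETA)
    for j, origin in enumerate((Origin.D, Origin.C, Origin.R)):
        b = 15 * j
        if origin is Origin.R:
            for i, lin in enumerate(LINEAGES):
                theta[b + 11 + i] = pop.deltaR[lin]
            continue
        scale = (lambda psi: ind.scale.get(psi, 1.0)) if (ind is not None and origin is Origin.D) else (lambda psi: 1.0)
        theta[b + 0] = pop.rL * scale("rL")
        theta[b + 1] = pop.rS * scale("rS")
        theta[b + 2] = pop.pLS * scale("pLS")
        for i, lin in enumerate(LINEAGES):
            theta[b + 3 + i] = pop.pL[lin] * (scale(f"pL{lin.value}") if lin is not Lineage.B else 1.0)
            theta[b + 7 + i] = pop.pS[lin] * scale(f"pS{lin.value}")
            theta[b + 11 + i] = pop.delta[lin]
    for i, lin in enumerate(LINEAGES):
        theta[45 + i] = pop.d[lin]
        theta[49 + i] = pop.alpha[lin]
    theta[53] = pop.KS
    return theta


def initial_state(ind: IndividualParameters, pop: PopulationParameters) -> np.ndarray:
    """State at transplantation (t = 0).

    The donor starts as a single cell: ``L_D = 1/Lstar`` (single-LT),
    ``S_D = 1/Sstar`` (single-ST) or nothing (BM assay).  The competitor
    bone-marrow graft carries small HSC pools ``LC0``/``SC0`` and a full
    complement of progenitors (``Y_iC = 1``) but no mature cells.  The
    irradiated recipient retains only its mature cells at steady state.
    """
    y0 = np.zeros(NSTATE)
    scen = Scenario(ind.scenario)
    if scen is Scenario.single_LT:
        y0[state_index(Origin.D, "L")] = 1.0 / pop.Lstar
    elif scen is Scenario.single_ST:
        y0[state_index(Origin.D, "S")] = 1.0 / pop.Sstar
    elif scen is Scenario.BM:
        pass
    else:  # pragma: no cover - Scenario() already validates
        raise ValueError(f"unknown scenario {ind.scenario!r}")
    y0[state_index(Origin.C, "L")] = ind.LC0
    y0[state_index(Origin.C, "S")] = ind.SC0
    for lin in LINEAGES:
        y0[state_index(Origin.C, f"Y{lin.value}")] = 1.0
    for lin in (Lineage.N, Lineage.E, Lineage.P):
        y0[state_index(Origin.R, f"Z{lin.value}")] = pop.Zstar[lin]
    y0[state_index(Origin.R, "ZB")] = pop.Zstar[Lineage.B]
    return y0


def steady_state(pop: PopulationParameters) -> np.ndarray:
    """Competitor-only fixed point of the normalized model.

    (L, S, Y_i) = (1, 1, 1), Z_i = Zstar_i, and the B chain at
    EB1 = EB2 = alpha_B, ZB = Zstar_B; donor and recipient empty.
    """
    y = np.zeros(NSTATE)
    y[state_index(Origin.C, "L")] = 1.0
    y[state_index(Origin.C, "S")] = 1.0
    for lin in LINEAGES:
        y[state_index(Origin.C, f"Y{lin.value}")] = 1.0
    for lin in (Lineage.N, Lineage.E, Lineage.P):
        y[state_index(Origin.C, f"Z{lin.value}")] = pop.Zstar[lin]
    y[state_index(Origin.C, "EB1")] = pop.alpha[Lineage.B]
    y[state_index(Origin.C, "EB2")] = pop.alpha[Lineage.B]
    y[state_index(Origin.C, "ZB")] = pop.Zstar[Lineage.B]
    return y


def derivative(
    state: np.ndarray,
    pop: PopulationParameters,
    ind: Optional[IndividualParameters] = None,
    t: float = 0.0,
) -> np.ndarray:
    """Time derivative of the 36-component state."""
    theta = pack_rates(pop, ind)
    out = np.zeros(NSTATE)
    _integrate.rhs(t, np.asarray(state, dtype=float), theta, out)
    return out


@dataclass
class Trajectory:
    """Time course of the 36-component state at requested weeks."""

    times: np.ndarray
    states: np.ndarray  # (n_times, 36)
    solver_meta: Dict[str, object] = field(default_factory=dict)

    def component(self, origin: Origin, comp: str) -> np.ndarray:
        return self.states[:, state_index(origin, comp)]

    def to_frame(self, individual_id: str = "") -> pd.DataFrame:
        """Long-format export: individual_id, week, origin, compartment, value."""
        rows = []
        for origin in Origin:
            for comp in COMPARTMENTS:
                col = self.component(origin, comp)
                for t, v in zip(self.times, col):
                    rows.append((individual_id, float(t), origin.value, comp, float(v)))
        return pd.DataFrame(rows, columns=["individual_id", "week", "origin", "compartment", "value"])


def simulate(
    ind: IndividualParameters,
    pop: PopulationParameters,
    times: Sequence[float],
    y0: Optional[np.ndarray] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "dopri",
) -> Trajectory:
    """Integrate the model from transplantation and sample at ``times`` (weeks).

    ``method="dopri"`` uses the compiled adaptive Dormand-Prince pair;
    ``method="lsoda"`` routes through :func:`scipy.integrate.solve_ivp` as an
    implicit-capable reference path.  Tiny negative values (within solver
    tolerance) are floored to zero; larger violations raise
    :class:`SimulationError`.
    """
    t_eval = np.asarray(times, dtype=float)
    if t_eval.ndim != 1 or len(t_eval) == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(t_eval) <= 0) or t_eval[0] < 0:
        raise ValueError("times must be nonnegative and strictly increasing")
    theta = pack_rates(pop, ind)
    if y0 is None:
        y0 = initial_state(ind, pop)
    y0 = np.asarray(y0, dtype=float)
    if method == "dopri":
        ys, status, nsteps, nreject = _integrate.integrate(theta, y0, t_eval, rtol, atol)
        meta = {"method": "dopri5", "rtol": rtol, "atol": atol, "nsteps": int(nsteps), "nreject": int(nreject)}
        if status != 0:
            reason = "step size underflow" if status == 1 else "negative state beyond tolerance"
            raise SimulationError(f"integration failed ({reason}); meta={meta}")
    elif method == "lsoda":
        from scipy.integrate import solve_ivp

        def f(t, y):
            out = np.zeros(NSTATE)
            _integrate.rhs(t, y, theta, out)
            return out

        span_end = float(t_eval[-1]) if t_eval[-1] > 0 else 1e-12
        sol = solve_ivp(f, (0.0, span_end), y0, t_eval=t_eval, method="LSODA", rtol=rtol, atol=atol)
        meta = {"method": "lsoda", "rtol": rtol, "atol": atol, "nsteps": int(sol.nfev)}
        if not sol.success:
            raise SimulationError(f"LSODA failed: {sol.message}; meta={meta}")
        ys = sol.y.T.copy()
        floor = -(atol + rtol * np.abs(ys).max())
        if ys.min() < min(floor, -1e-9):
            raise SimulationError(f"negative state beyond tolerance ({ys.min():.3e}); meta={meta}")
        ys[ys < 0] = 0.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return Trajectory(times=t_eval, states=ys, solver_meta=meta)


def chimerism_shares(traj: Trajectory, lineage: Lineage, scenario: Scenario) -> Dict[Origin, np.ndarray]:
    """Percentage share of each origin among the measurable mature cells.

    N and B measurements distinguish donor from competitor only (surface
    markers); E and P include the recipient's residual cells.  Undefined
    points (no measurable cells at all) are NaN — "no cells" is reported as
    missing, never as 0.
    """
    lineage = Lineage(lineage)
    comp = "ZB" if lineage is Lineage.B else f"Z{lineage.value}"
    zd = traj.component(Origin.D, comp)
    zc = traj.component(Origin.C, comp)
    include_r = lineage in (Lineage.E, Lineage.P)
    zr = traj.component(Origin.R, comp) if include_r else np.zeros_like(zd)
    total = zd + zc + zr
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = {
            Origin.D: np.where(total > 0, 100.0 * zd / total, np.nan),
            Origin.C: np.where(total > 0, 100.0 * zc / total, np.nan),
            Origin.R: np.where(total > 0, 100.0 * zr / total, np.nan) if include_r else np.full_like(zd, np.nan),
        }
    return shares


def observe_chimerism(traj: Trajectory, lineage: Lineage, scenario: Scenario) -> np.ndarray:
    """Donor chimerism in % for single-cell assays; recipient share for BM.

    Single-cell scenarios: ``100 * Z_iD / (Z_iD + Z_iC)`` for i = N, B and
    ``100 * Z_iD / (Z_iD + Z_iC + Z_iR)`` for i = E, P.  The BM assay
    measures the decaying recipient share ``100 * Z_iR / (Z_iC + Z_iR)``
    (defined for E and P only).
    """
    scenario = Scenario(scenario)
    lineage = Lineage(lineage)
    if scenario is Scenario.BM:
        if lineage not in (Lineage.E, Lineage.P):
            raise ValueError("BM recipient chimerism is measured for E and P only")
        comp = f"Z{lineage.value}"
        zc = traj.component(Origin.C, comp)
        zr = traj.component(Origin.R, comp)
        total = zc + zr
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, 100.0 * zr / total, np.nan)
    return chimerism_shares(traj, lineage, scenario)[Origin.D]


def observe_cbc(traj: Trajectory, lineage: Lineage) -> np.ndarray:
    """Total measurable mature cells: D + C (N, B) or D + C + R (E, P)."""
    lineage = Lineage(lineage)
    comp = "ZB" if lineage is Lineage.B else f"Z{lineage.value}"
    total = traj.component(Origin.D, comp) + traj.component(Origin.C, comp)
    if lineage in (Lineage.E, Lineage.P):
        total = total + traj.component(Origin.R, comp)
    return total


def estimate_recipient_steady(cbc: pd.DataFrame, weeks=(20.0, 24.0)) -> Dict[Lineage, float]:
    """Steady-state mature counts from late CBC values.

    Per lineage, the arithmetic mean of the CBC records at weeks 20 and 24
    (whichever are present; both absent is an error).
    """
    if "kind" in cbc.columns:
        cbc = cbc[cbc["kind"] == "cbc"]
    out: Dict[Lineage, float] = {}
    for lin in LINEAGES:
        sel = cbc[(cbc["lineage"] == lin.value) & (cbc["week"].isin(list(weeks)))]
        if sel.empty:
            raise ValueError(f"no CBC records at weeks {weeks} for lineage {lin.value}")
        out[lin] = float(sel["value"].mean())
    return out
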