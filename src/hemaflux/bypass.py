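"""Influx series, bypass dependency and the stable/dropped x high/low classes.

*Influx* is the instantaneous production rate flowing from one donor
compartment into the next: ``pLS * L_D`` into the ST pool, ``pL_i * L_D``
(bypass) and ``pS_i * S_D`` into progenitors, and ``alpha_i * d_i * Y_iD``
(myeloid) or ``dB * EB2_D`` (B, out of the eclipse chain) into mature cells.

*Bypass dependency* of a myeloid lineage is the fraction of progenitor influx
arriving via the direct LT route:
``pL_i L_D / (pL_i L_D + pS_i S_D)``.  A clone whose platelet dependency
falls below 20% at any evaluated week is *dropped* (else *stable*); one whose
week-24 dependency is below 50% is *low* (else *high*).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .model import Trajectory, Origin, simulate
from .params import (
    LINEAGES,
    MYELOID,
    IndividualParameters,
    Lineage,
    PopulationParameters,
)

__all__ = [
    "InfluxSeries",
    "BypassClassification",
    "influx_series",
    "bypass_dependency",
    "classify_bypass",
    "lineage_ratio",
    "compare_groups",
    "DEFAULT_DEPENDENCY_GRID",
]

# "any time point": weekly grid over the 24-week assay; week 0 is excluded
# because the donor has produced nothing yet (0/0).
DEFAULT_DEPENDENCY_GRID: Tuple[float, ...] = tuple(float(w) for w in range(1, 25))

_EPS = 1e-300


@dataclass
class InfluxSeries:
    """Donor production rates per week, one entry per time point."""

    times: np.ndarray
    into_ST: np.ndarray
    progenitor_from_LT: Dict[Lineage, np.ndarray]
    progenitor_from_ST: Dict[Lineage, np.ndarray]
    mature: Dict[Lineage, np.ndarray]

    def to_frame(self, individual_id: str = "") -> pd.DataFrame:
        rows = []
        for t_idx, t in enumerate(self.times):
            rows.append((individual_id, float(t), "into_ST", float(self.into_ST[t_idx])))
            for lin in LINEAGES:
                rows.append((individual_id, float(t), f"progenitor_from_LT[{lin.value}]",
                             float(self.progenitor_from_LT[lin][t_idx])))
                rows.append((individual_id, float(t), f"progenitor_from_ST[{lin.value}]",
                             float(self.progenitor_from_ST[lin][t_idx])))
                rows.append((individual_id, float(t), f"mature[{lin.value}]", float(self.mature[lin][t_idx])))
        return pd.DataFrame(rows, columns=["individual_id", "week", "quantity", "value"])


@dataclass
class BypassClassification:
    """stable/dropped x high/low label with the supporting statistics."""

    stability: str  # "stable" | "dropped"
    level: str  # "high" | "low"
    min_dependency: float
    dependency_at_24: float
    evaluation_grid: Tuple[float, ...]

    @property
    def label(self) -> str:
        return f"{self.stability}-{self.level}"


def influx_series(
    traj: Trajectory,
    ind: IndividualParameters,
    pop: PopulationParameters,
) -> InfluxSeries:
    """Donor influx at the trajectory's time points.

    Mature B influx uses the eclipse-chain output ``dB * EB2_D``, not the
    progenitor pool directly.
    """
    L = traj.component(Origin.D, "L")
    S = traj.component(Origin.D, "S")
    pLS_d = ind.donor_psi(pop, "pLS")
    from_LT: Dict[Lineage, np.ndarray] = {}
    from_ST: Dict[Lineage, np.ndarray] = {}
    mature: Dict[Lineage, np.ndarray] = {}
    for lin in LINEAGES:
        pL_d = pop.pL[lin] * (ind.scale.get(f"pL{lin.value}", 1.0) if lin is not Lineage.B else 1.0)
        pS_d = pop.pS[lin] * ind.scale.get(f"pS{lin.value}", 1.0)
        from_LT[lin] = pL_d * L
        from_ST[lin] = pS_d * S
        if lin is Lineage.B:
            mature[lin] = pop.d[lin] * traj.component(Origin.D, "EB2")
        else:
            mature[lin] = pop.alpha[lin] * pop.d[lin] * traj.component(Origin.D, f"Y{lin.value}")
    return InfluxSeries(
        times=np.asarray(traj.times, dtype=float),
        into_ST=pLS_d * L,
        progenitor_from_LT=from_LT,
        progenitor_from_ST=from_ST,
        mature=mature,
    )


def bypass_dependency(influx: InfluxSeries, lineage: Lineage) -> np.ndarray:
    """Fraction of a myeloid lineage's progenitor influx taking the bypass.

    NaN where both routes are numerically zero (a 0/0 carries no pathway
    information); raises for the B lineage, which has no bypass.
    """
    lineage = Lineage(lineage)
    if lineage not in MYELOID:
        raise ValueError("bypass dependency is defined for myeloid lineages only")
    num = influx.progenitor_from_LT[lineage]
    den = num + influx.progenitor_from_ST[lineage]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > _EPS, num / np.where(den > _EPS, den, 1.0), np.nan)


def classify_bypass(
    dependency: np.ndarray,
    times: Sequence[float],
    evaluation_grid: Sequence[float] = DEFAULT_DEPENDENCY_GRID,
    dropped_threshold: float = 0.20,
    low_threshold: float = 0.50,
    week24: float = 24.0,
) -> BypassClassification:
    """Classify a dependency series into stable/dropped x high/low.

    ``dropped`` iff the minimum over the evaluation grid is strictly below
    20%; ``low`` iff the week-24 value is strictly below 50% (boundary values
    are stable/high).  Undefined (NaN) grid points are excluded from the
    minimum; a missing week-24 value is an error.
    """
    times = np.asarray(times, dtype=float)
    dependency = np.asarray(dependency, dtype=float)
    grid = [w for w in evaluation_grid]
    pos = {float(t): i for i, t in enumerate(times)}
    missing = [w for w in grid + [week24] if float(w) not in pos]
    if missing:
        raise ValueError(f"dependency series does not cover weeks {missing}")
    d24 = dependency[pos[float(week24)]]
    if np.isnan(d24):
        raise ValueError("dependency at week 24 is undefined")
    grid_vals = np.array([dependency[pos[float(w)]] for w in grid])
    defined = grid_vals[~np.isnan(grid_vals)]
    if defined.size == 0:
        raise ValueError("dependency undefined on the whole evaluation grid")
    dmin = float(defined.min())
    return BypassClassification(
        stability="dropped" if dmin < dropped_threshold else "stable",
        level="low" if d24 < low_threshold else "high",
        min_dependency=dmin,
        dependency_at_24=float(d24),
        evaluation_grid=tuple(float(w) for w in grid),
    )


def lineage_ratio(influx: InfluxSeries, t: float = 24.0) -> Dict[Lineage, float]:
    """Myeloid-to-B mature production ratios at time ``t`` (default week 24).

    ``alpha_i d_i Y_iD(t) / (dB EB2_D(t))`` for i = N, E, P; infinite when B
    production is zero.
    """
    pos = {float(w): i for i, w in enumerate(influx.times)}
    if float(t) not in pos:
        raise ValueError(f"influx series has no entry at week {t}")
    k = pos[float(t)]
    b = influx.mature[Lineage.B][k]
    out: Dict[Lineage, float] = {}
    for lin in MYELOID:
        out[lin] = float(influx.mature[lin][k] / b) if b > 0 else float("inf")
    return out


def compare_groups(
    values: Sequence[float],
    labels: Sequence[str],
    m_tests: int = 1,
    log10_transform: bool = False,
) -> Tuple[float, float, float]:
    """Two-sided Student's t-test young vs aged with Bonferroni correction.

    Returns ``(t, p_raw, p_adjusted)`` with ``p_adjusted = min(1, m * p)``.
    Set ``log10_transform`` when comparing quantities the study summarizes as
    log-scale means (influxes, production ratios).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    young = values[labels == "young"]
    aged = values[labels == "aged"]
    if len(young) < 2 or len(aged) < 2:
        raise ValueError("need at least two values per age group")
    if log10_transform:
        young = np.log10(young)
        aged = np.log10(aged)
    t, p = stats.ttest_ind(young, aged, equal_var=True)
    if np.allclose(young.var(ddof=1) + aged.var(ddof=1), 0.0) and np.isclose(young.mean(), aged.mean()):
        t, p = 0.0, 1.0
    return float(t), float(p), float(min(1.0, m_tests * p))


def classify_individual(
    ind: IndividualParameters,
    pop: PopulationParameters,
    lineage: Lineage = Lineage.P,
    evaluation_grid: Sequence[float] = DEFAULT_DEPENDENCY_GRID,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> BypassClassification:
    """Simulate one mouse and classify its bypass dependency (default: platelets)."""
    times = sorted(set(float(w) for w in evaluation_grid) | {24.0})
    traj = simulate(ind, pop, times, rtol=rtol, atol=atol)
    influx = influx_series(traj, ind, pop)
    dep = bypass_dependency(influx, lineage)
    return classify_bypass(dep, times, evaluation_grid=evaluation_grid)
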