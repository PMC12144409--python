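"""Synthetic transplantation cohorts.

Emulates the statistical design of the single-cell / bone-marrow
transplantation study: per-mouse donor scaling factors drawn log-normally
around population rates with additive aged-group covariates on the log scale,
log-normal competitor initial compartments, logit-normal chimerism noise,
log-normal CBC noise, and left-censoring of chimerism at the 0.001%
detection limit.  The default cohort mirrors the study's assay counts
(53/22 young/aged single-LT, 28/11 single-ST, 10 BM mice) and observation
schedules (chimerism weeks 2, 3, 4, 8, 12, 16, 24).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import Trajectory, observe_cbc, observe_chimerism, simulate
from .params import (
    ALL_PSI,
    LINEAGES,
    ST_PSI,
    AgeGroup,
    IndividualParameters,
    Lineage,
    PopulationParameters,
    Scenario,
)

__all__ = [
    "CohortDesign",
    "OBSERVATION_COLUMNS",
    "scenario_psi",
    "sample_individual",
    "noisy_observations",
    "apply_detection_limit",
    "generate_cohort",
]

OBSERVATION_COLUMNS = [
    "individual_id",
    "age_group",
    "scenario",
    "lineage",
    "week",
    "kind",
    "value",
    "censored",
    "limit",
]

_CELL_ORDER: Tuple[Tuple[Scenario, AgeGroup], ...] = (
    (Scenario.single_LT, AgeGroup.young),
    (Scenario.single_LT, AgeGroup.aged),
    (Scenario.single_ST, AgeGroup.young),
    (Scenario.single_ST, AgeGroup.aged),
    (Scenario.BM, AgeGroup.young),
)

_CELL_TAG = {
    (Scenario.single_LT, AgeGroup.young): "LTy",
    (Scenario.single_LT, AgeGroup.aged): "LTa",
    (Scenario.single_ST, AgeGroup.young): "STy",
    (Scenario.single_ST, AgeGroup.aged): "STa",
    (Scenario.BM, AgeGroup.young): "BM",
}


@dataclass
class CohortDesign:
    """Assay counts and observation schedules of one synthetic cohort.

    ``counts`` / ``cbc_counts`` are keyed by (scenario, age group); CBC is
    collected for the first ``cbc_counts`` mice of each cell.  BM mice yield
    recipient-decay chimerism for E and P at ``bm_weeks`` instead.
    """

    counts: Dict[Tuple[Scenario, AgeGroup], int] = field(
        default_factory=lambda: {
            (Scenario.single_LT, AgeGroup.young): 53,
            (Scenario.single_LT, AgeGroup.aged): 22,
            (Scenario.single_ST, AgeGroup.young): 28,
            (Scenario.single_ST, AgeGroup.aged): 11,
            (Scenario.BM, AgeGroup.young): 10,
        }
    )
    cbc_counts: Dict[Tuple[Scenario, AgeGroup], int] = field(
        default_factory=lambda: {
            (Scenario.single_LT, AgeGroup.young): 10,
            (Scenario.single_LT, AgeGroup.aged): 7,
            (Scenario.single_ST, AgeGroup.young): 6,
            (Scenario.single_ST, AgeGroup.aged): 7,
            (Scenario.BM, AgeGroup.young): 0,
        }
    )
    chimerism_weeks: Tuple[float, ...] = (2.0, 3.0, 4.0, 8.0, 12.0, 16.0, 24.0)
    cbc_weeks: Tuple[float, ...] = (4.0, 8.0, 12.0, 16.0, 20.0, 24.0)
    bm_weeks: Tuple[float, ...] = (2.0, 3.0, 4.0, 8.0)
    detection_limit: float = 0.001  # percent
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("cohort counts must be nonnegative")
        if self.detection_limit <= 0:
            raise ValueError("detection_limit must be positive")
        for sched in (self.chimerism_weeks, self.cbc_weeks, self.bm_weeks):
            if any(w <= 0 for w in sched):
                raise ValueError("observation weeks must be positive")

    def to_dict(self) -> Dict:
        return {
            "counts": {f"{s.value}:{a.value}": n for (s, a), n in self.counts.items()},
            "cbc_counts": {f"{s.value}:{a.value}": n for (s, a), n in self.cbc_counts.items()},
            "chimerism_weeks": list(self.chimerism_weeks),
            "cbc_weeks": list(self.cbc_weeks),
            "bm_weeks": list(self.bm_weeks),
            "detection_limit": self.detection_limit,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "CohortDesign":
        def parse_counts(m):
            out = {}
            for key, n in m.items():
                s, a = key.split(":")
                out[(Scenario(s), AgeGroup(a))] = int(n)
            return out

        kw = {}
        if "counts" in d:
            kw["counts"] = parse_counts(d["counts"])
        if "cbc_counts" in d:
            kw["cbc_counts"] = parse_counts(d["cbc_counts"])
        for name in ("chimerism_weeks", "cbc_weeks", "bm_weeks"):
            if name in d:
                kw[name] = tuple(float(w) for w in d[name])
        for name in ("detection_limit", "seed"):
            if name in d:
                kw[name] = d[name]
        return cls(**kw)


def scenario_psi(scenario: Scenario) -> Tuple[str, ...]:
    """Donor scaling parameters that exist for a scenario's donor."""
    scenario = Scenario(scenario)
    if scenario is Scenario.single_LT:
        return ALL_PSI
    if scenario is Scenario.single_ST:
        return ST_PSI
    return ()


def sample_individual(
    pop: PopulationParameters,
    age_group: AgeGroup,
    scenario: Scenario,
    rng: np.random.Generator,
    individual_id: str = "",
) -> IndividualParameters:
    """Draw one mouse's donor scaling factors and competitor pools.

    log(scale_psi) = beta_psi * 1{aged} + eta,  eta ~ N(0, omega_psi^2);
    LC0/SC0 are log-normal around their population medians with scale
    ``omega_phi``.  Draws follow the declared psi order, so a seed fully
    determines the cohort.
    """
    age_group = AgeGroup(age_group)
    scenario = Scenario(scenario)
    scale: Dict[str, float] = {}
    for psi in scenario_psi(scenario):
        if psi not in pop.omega:
            raise ValueError(f"omega[{psi}] is not defined")
        mu = pop.beta.get(psi, 0.0) if age_group is AgeGroup.aged else 0.0
        eta = rng.normal(0.0, pop.omega[psi]) if pop.omega[psi] > 0 else 0.0
        scale[psi] = float(np.exp(mu + eta))
    lc0 = pop.LC0_pop * float(np.exp(rng.normal(0.0, pop.omega_phi))) if pop.omega_phi > 0 else pop.LC0_pop
    sc0 = pop.SC0_pop * float(np.exp(rng.normal(0.0, pop.omega_phi))) if pop.omega_phi > 0 else pop.SC0_pop
    return IndividualParameters(
        scale=scale, LC0=lc0, SC0=sc0, age_group=age_group, scenario=scenario, individual_id=individual_id
    )


def _logit_pct(x: np.ndarray) -> np.ndarray:
    return np.log(x / (100.0 - x))


def _expit_pct(x: np.ndarray) -> np.ndarray:
    return 100.0 / (1.0 + np.exp(-x))


def noisy_observations(
    traj: Trajectory,
    ind: IndividualParameters,
    pop: PopulationParameters,
    chimerism_weeks: Sequence[float],
    cbc_weeks: Optional[Sequence[float]],
    rng: np.random.Generator,
    detection_limit: float = 0.001,
) -> pd.DataFrame:
    """Observe one trajectory under the logit-/log-normal error model.

    Chimerism noise acts on log-odds of the percentage; CBC noise on the log
    count.  Predicted chimerism is clipped to [1e-6, 100 - 1e-6] before the
    logit (a donor clone that has produced no cells yet would otherwise be
    degenerate).  Censoring is applied afterwards by
    :func:`apply_detection_limit`.
    """
    scen = Scenario(ind.scenario)
    week_pos = {float(w): k for k, w in enumerate(traj.times)}
    rows = []
    if scen is Scenario.BM:
        kinds = [("recipient_chimerism", (Lineage.E, Lineage.P), chimerism_weeks)]
    else:
        kinds = [("chimerism", LINEAGES, chimerism_weeks)]
    for kind, lineages, weeks in kinds:
        for lin in lineages:
            f = observe_chimerism(traj, lin, scen)
            for w in weeks:
                fi = f[week_pos[float(w)]]
                fi = np.clip(np.nan_to_num(fi, nan=0.0), 1e-6, 100.0 - 1e-6)
                y = float(_expit_pct(_logit_pct(fi) + pop.aF[lin] * rng.normal()))
                rows.append(
                    (ind.individual_id, ind.age_group.value, scen.value, lin.value, float(w), kind, y, False, detection_limit)
                )
    if cbc_weeks:
        for lin in LINEAGES:
            f = observe_cbc(traj, lin)
            for w in cbc_weeks:
                fi = max(f[week_pos[float(w)]], 1e-12)
                y = float(np.exp(np.log(fi) + pop.aT[lin] * rng.normal()))
                rows.append(
                    (ind.individual_id, ind.age_group.value, scen.value, lin.value, float(w), "cbc", y, False, detection_limit)
                )
    df = pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)
    return apply_detection_limit(df, detection_limit)


def apply_detection_limit(records: pd.DataFrame, limit: float = 0.001) -> pd.DataFrame:
    """Left-censor chimerism records strictly below the detection limit (%).

    Censored rows carry ``value = limit``; the boundary value itself stays
    uncensored (strict "<").  CBC records are untouched.
    """
    out = records.copy()
    is_chim = out["kind"].isin(["chimerism", "recipient_chimerism"])
    below = is_chim & (out["value"] < limit)
    out.loc[below, "censored"] = True
    out.loc[below, "value"] = limit
    out.loc[is_chim, "limit"] = limit
    return out


def generate_cohort(
    design: CohortDesign,
    pop: PopulationParameters,
    rng: Optional[np.random.Generator] = None,
    simulate_kwargs: Optional[Dict] = None,
) -> Tuple[pd.DataFrame, Dict[str, IndividualParameters]]:
    """Sample, simulate, observe and censor a full cohort.

    Returns the long-format observation table and the ground-truth individual
    parameters keyed by individual id; bit-reproducible from ``design.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    simulate_kwargs = simulate_kwargs or {}
    tables = []
    truth: Dict[str, IndividualParameters] = {}
    for cell in _CELL_ORDER:
        scen, age = cell
        n = design.counts.get(cell, 0)
        n_cbc = design.cbc_counts.get(cell, 0)
        for k in range(n):
            iid = f"{_CELL_TAG[cell]}-{k + 1:03d}"
            ind = sample_individual(pop, age, scen, rng, individual_id=iid)
            truth[iid] = ind
            if scen is Scenario.BM:
                chim_weeks: Sequence[float] = design.bm_weeks
                cbc_weeks: Optional[Sequence[float]] = None
            else:
                chim_weeks = design.chimerism_weeks
                cbc_weeks = design.cbc_weeks if k < n_cbc else None
            all_weeks = sorted(set(map(float, chim_weeks)) | set(map(float, cbc_weeks or ())))
            try:
                traj = simulate(ind, pop, all_weeks, **simulate_kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with context
                raise RuntimeError(f"simulation failed for individual {iid}") from exc
            tables.append(
                noisy_observations(traj, ind, pop, chim_weeks, cbc_weeks, rng, design.detection_limit)
            )
    obs = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=OBSERVATION_COLUMNS)
    )
    return obs, truth


def truth_to_frame(truth: Dict[str, IndividualParameters]) -> pd.DataFrame:
    """Ground-truth table: one row per mouse, one column per scaling factor."""
    rows = []
    for iid, ind in truth.items():
        row = {"individual_id": iid, "age_group": ind.age_group.value, "scenario": ind.scenario.value,
               "LC0": ind.LC0, "SC0": ind.SC0}
        for psi in ALL_PSI:
            row[psi] = ind.scale.get(psi, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
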