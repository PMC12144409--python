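"""Parameter containers for the HSC differentiation model.

The model tracks two stem-cell compartments (long-term LT and short-term ST
HSCs), four lineages of progenitors and mature cells — neutrophils/monocytes
(N), erythrocytes (E), platelets (P) and B cells (B) — and three cell origins
competing in one host: the transplanted donor clone (D), co-transplanted
whole-bone-marrow competitor cells (C) and the irradiated recipient's residual
mature cells (R).

All rates are per week.  The model is written on a normalized scale on which
the competitor steady state is (L, S, Y_i) = (1, 1, 1) and mature-cell counts
Z_i stay on the cell-count scale of the complete blood count (CBC).  The
steady-state constraints pin three parameter groups::

    d_i   = pL_i + pS_i          progenitor differentiation rate
    alpha_i = delta_i * Zstar_i / d_i     mature-cell expansion factor
    KS    = rS / (pLS + rS)      normalized ST carrying capacity

`complete_parameters` fills these derived entries from the free ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "Lineage",
    "Origin",
    "AgeGroup",
    "Scenario",
    "LINEAGES",
    "MYELOID",
    "LT_PSI",
    "ST_PSI",
    "ALL_PSI",
    "PopulationParameters",
    "IndividualParameters",
    "complete_parameters",
    "default_population",
]


class Lineage(str, Enum):
    """Blood-cell lineage index: the B lineage has no bypass production."""

    N = "N"  # neutrophils / monocytes
    E = "E"  # erythrocytes
    P = "P"  # platelets
    B = "B"  # B cells


class Origin(str, Enum):
    """Cell origin: donor clone, competitor bone marrow, recipient host."""

    D = "D"
    C = "C"
    R = "R"


class AgeGroup(str, Enum):
    young = "young"
    aged = "aged"


class Scenario(str, Enum):
    """Transplantation design of one mouse."""

    single_LT = "single_LT"  # one long-term HSC + competitor bone marrow
    single_ST = "single_ST"  # one short-term HSC + competitor bone marrow
    BM = "BM"  # labelled bone marrow only (recipient-decay assay)


LINEAGES = (Lineage.N, Lineage.E, Lineage.P, Lineage.B)
MYELOID = (Lineage.N, Lineage.E, Lineage.P)

# Donor scaling parameters psi, in declared draw order.  LT-set parameters
# exist only for single-LT donors; ST-set parameters for LT and ST donors.
LT_PSI = ("rL", "pLS", "pLN", "pLE", "pLP")
ST_PSI = ("rS", "pSN", "pSE", "pSP", "pSB")
ALL_PSI = LT_PSI + ST_PSI


def _ldict(**kw: float) -> Dict[Lineage, float]:
    return {Lineage(k): float(v) for k, v in kw.items()}


@dataclass
class PopulationParameters:
    """Population-level rates, constraints, covariates and noise scales.

    Free rates: ``rL``, ``rS`` (logistic self-renewal), ``pLS`` (LT→ST
    production), ``pL[i]`` (bypass production LT→progenitor; ``pL[B] == 0``),
    ``pS[i]`` (ST→progenitor production), ``delta[i]`` / ``deltaR[i]``
    (mature-cell death, donor+competitor / recipient), ``Zstar[i]``
    (steady-state mature counts).  Derived: ``d``, ``alpha``, ``KS``.

    ``beta[psi]`` are additive aged-group covariates on the log scale and
    ``omega[psi]`` the random-effect standard deviations of the donor scaling
    factors; ``omega_phi`` governs the unknown competitor initial compartments
    ``LC0_pop``/``SC0_pop``.  ``aF[i]`` / ``aT[i]`` are the observation-error
    scales of logit-chimerism and log-CBC.
    """

    rL: float
    rS: float
    pLS: float
    pL: Dict[Lineage, float]
    pS: Dict[Lineage, float]
    delta: Dict[Lineage, float]
    deltaR: Dict[Lineage, float]
    Zstar: Dict[Lineage, float]
    Lstar: float
    Sstar: float
    LC0_pop: float
    SC0_pop: float
    beta: Dict[str, float] = field(default_factory=dict)
    omega: Dict[str, float] = field(default_factory=dict)
    omega_phi: float = 0.0
    aF: Dict[Lineage, float] = field(default_factory=lambda: _ldict(N=0.3, E=0.3, P=0.3, B=0.3))
    aT: Dict[Lineage, float] = field(default_factory=lambda: _ldict(N=0.15, E=0.15, P=0.15, B=0.15))
    # derived (filled by complete_parameters)
    d: Dict[Lineage, float] = field(default_factory=dict)
    alpha: Dict[Lineage, float] = field(default_factory=dict)
    KS: float = float("nan")

    # -- psi accessors -----------------------------------------------------
    def get_psi(self, psi: str) -> float:
        if psi == "rL":
            return self.rL
        if psi == "rS":
            return self.rS
        if psi == "pLS":
            return self.pLS
        if psi.startswith("pL"):
            return self.pL[Lineage(psi[2])]
        if psi.startswith("pS"):
            return self.pS[Lineage(psi[2])]
        raise KeyError(psi)

    def set_psi(self, psi: str, value: float) -> None:
        if psi == "rL":
            self.rL = value
        elif psi == "rS":
            self.rS = value
        elif psi == "pLS":
            self.pLS = value
        elif psi.startswith("pL"):
            self.pL[Lineage(psi[2])] = value
        elif psi.startswith("pS"):
            self.pS[Lineage(psi[2])] = value
        else:
            raise KeyError(psi)

    def copy(self) -> "PopulationParameters":
        return replace(
            self,
            pL=dict(self.pL),
            pS=dict(self.pS),
            delta=dict(self.delta),
            deltaR=dict(self.deltaR),
            Zstar=dict(self.Zstar),
            beta=dict(self.beta),
            omega=dict(self.omega),
            aF=dict(self.aF),
            aT=dict(self.aT),
            d=dict(self.d),
            alpha=dict(self.alpha),
        )

    # -- flat serialization ------------------------------------------------
    def to_flat(self) -> Dict[str, float]:
        """Flat key → value map; keys follow the field names (``pL[N]`` etc.)."""
        out: Dict[str, float] = {
            "rL": self.rL,
            "rS": self.rS,
            "pLS": self.pLS,
            "Lstar": self.Lstar,
            "Sstar": self.Sstar,
            "LC0_pop": self.LC0_pop,
            "SC0_pop": self.SC0_pop,
            "omega_phi": self.omega_phi,
            "KS": self.KS,
        }
        for name, dic in (
            ("pL", self.pL),
            ("pS", self.pS),
            ("delta", self.delta),
            ("deltaR", self.deltaR),
            ("Zstar", self.Zstar),
            ("d", self.d),
            ("alpha", self.alpha),
            ("aF", self.aF),
            ("aT", self.aT),
        ):
            for lin, v in dic.items():
                out[f"{name}[{lin.value}]"] = v
        for name, dic in (("beta", self.beta), ("omega", self.omega)):
            for psi, v in dic.items():
                out[f"{name}[{psi}]"] = v
        return out

    @classmethod
    def from_flat(cls, flat: Mapping[str, float]) -> "PopulationParameters":
        dicts: Dict[str, Dict] = {
            k: {} for k in ("pL", "pS", "delta", "deltaR", "Zstar", "d", "alpha", "aF", "aT", "beta", "omega")
        }
        scalars: Dict[str, float] = {}
        for key, v in flat.items():
            if "[" in key:
                name, idx = key[:-1].split("[")
                if name in ("beta", "omega"):
                    dicts[name][idx] = float(v)
                else:
                    dicts[name][Lineage(idx)] = float(v)
            else:
                scalars[key] = float(v)
        return cls(
            rL=scalars["rL"],
            rS=scalars["rS"],
            pLS=scalars["pLS"],
            pL=dicts["pL"],
            pS=dicts["pS"],
            delta=dicts["delta"],
            deltaR=dicts["deltaR"],
            Zstar=dicts["Zstar"],
            Lstar=scalars["Lstar"],
            Sstar=scalars["Sstar"],
            LC0_pop=scalars["LC0_pop"],
            SC0_pop=scalars["SC0_pop"],
            beta=dicts["beta"],
            omega=dicts["omega"],
            omega_phi=scalars.get("omega_phi", 0.0),
            aF=dicts["aF"] or _ldict(N=0.3, E=0.3, P=0.3, B=0.3),
            aT=dicts["aT"] or _ldict(N=0.15, E=0.15, P=0.15, B=0.15),
            d=dicts["d"],
            alpha=dicts["alpha"],
            KS=scalars.get("KS", float("nan")),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_flat(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PopulationParameters":
        with open(path) as fh:
            return cls.from_flat(json.load(fh))

    def to_csv(self, path) -> None:
        flat = self.to_flat()
        # shortest-round-trip float strings so reading back is bit-exact
        pd.DataFrame({"key": list(flat), "value": [repr(float(v)) for v in flat.values()]}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "PopulationParameters":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls.from_flat(dict(zip(df["key"], df["value"])))


@dataclass
class IndividualParameters:
    """Per-mouse donor scaling factors and competitor initial compartments.

    ``scale[psi]`` multiplies the population rate for the donor clone
    (competitor cells always use population values); ``LC0``/``SC0`` are this
    mouse's competitor LT/ST initial sizes on the normalized scale.
    """

    scale: Dict[str, float]
    LC0: float
    SC0: float
    age_group: AgeGroup
    scenario: Scenario
    individual_id: str = ""

    def __post_init__(self) -> None:
        bad = [k for k, v in self.scale.items() if not v > 0]
        if bad or not self.LC0 > 0 or not self.SC0 > 0:
            raise ValueError(f"scales and initial compartments must be > 0 (bad: {bad})")

    def donor_psi(self, pop: PopulationParameters, psi: str) -> float:
        return pop.get_psi(psi) * self.scale.get(psi, 1.0)


class ParameterValidationError(ValueError):
    pass


_REQUIRED_POSITIVE = ("rL", "rS", "pLS", "Lstar", "Sstar", "LC0_pop", "SC0_pop")


def complete_parameters(raw: PopulationParameters) -> PopulationParameters:
    """Fill the derived parameters from the steady-state identities.

    Forces ``pL[B] = 0`` (only the myeloid lineages have a bypass route) and
    sets ``d_i = pL_i + pS_i``, ``alpha_i = delta_i * Zstar_i / d_i`` and
    ``KS = rS / (pLS + rS)``.  Raises :class:`ParameterValidationError` naming
    the offending field for any nonpositive required rate.
    """
    pop = raw.copy()
    for name in _REQUIRED_POSITIVE:
        v = getattr(pop, name)
        if not np.isfinite(v) or v <= 0:
            raise ParameterValidationError(f"parameter {name!r} must be positive, got {v}")
    pop.pL.setdefault(Lineage.B, 0.0)
    if pop.pL[Lineage.B] != 0.0:
        raise ParameterValidationError("pL[B] must be 0: the B lineage has no bypass route")
    for lin in LINEAGES:
        for dic, name in ((pop.pS, "pS"), (pop.delta, "delta"), (pop.Zstar, "Zstar")):
            if lin not in dic or dic[lin] <= 0:
                raise ParameterValidationError(f"parameter {name}[{lin.value}] must be positive")
        if lin in MYELOID and (lin not in pop.pL or pop.pL[lin] <= 0):
            raise ParameterValidationError(f"parameter pL[{lin.value}] must be positive")
        pop.deltaR.setdefault(lin, pop.delta[lin])
        if pop.deltaR[lin] <= 0:
            raise ParameterValidationError(f"parameter deltaR[{lin.value}] must be positive")
    pop.d = {lin: pop.pL[lin] + pop.pS[lin] for lin in LINEAGES}
    pop.alpha = {lin: pop.delta[lin] * pop.Zstar[lin] / pop.d[lin] for lin in LINEAGES}
    pop.KS = pop.rS / (pop.pLS + pop.rS)
    return pop


def default_population(
    beta: Optional[Dict[str, float]] = None,
    omega: Optional[Dict[str, float]] = None,
) -> PopulationParameters:
    """Reference population parameter set used by the synthetic cohorts.

    Growth rates and the LT/ST normalization constants take the published
    young-population estimates (rL 2.39/wk, rS 2.84/wk, Lstar 1.07e7,
    Sstar 3.34e7).  Production, death and steady-state count defaults are
    chosen to reproduce the qualitative physiology: early platelet output via
    the bypass (pL[P] comparable to pS[P]), negligible N/E bypass (~1e-7/wk),
    a delayed B-cell rise, mature-cell lifespans of roughly 1 day (N), 6 weeks
    (E), 5 days (P) and 3 weeks (B), and murine CBC steady states per uL.
    Aged covariates use the published multiplicative factors where printed.
    """
    if beta is None:
        beta = {
            "rL": float(np.log(0.780)),
            "pLS": float(np.log(1.5)),
            "pLN": float(np.log(0.5)),
            "pLE": float(np.log(0.5)),
            "pLP": float(np.log(1.44)),
            "rS": float(np.log(1.18)),
            "pSN": float(np.log(0.260)),
            "pSE": float(np.log(0.512)),
            "pSP": float(np.log(0.431)),
            "pSB": float(np.log(0.3)),
        }
    if omega is None:
        omega = {psi: 0.3 for psi in ALL_PSI}
    pop = PopulationParameters(
        rL=2.39,
        rS=2.84,
        pLS=1.0,
        pL=_ldict(N=1e-7, E=1e-7, P=1.5, B=0.0),
        pS=_ldict(N=2.0, E=2.0, P=1.0, B=1.5),
        delta=_ldict(N=7.0, E=0.17, P=1.4, B=0.35),
        deltaR=_ldict(N=7.0, E=0.30, P=1.0, B=0.35),
        Zstar=_ldict(N=1.5e3, E=9.0e6, P=1.0e6, B=4.0e3),
        Lstar=1.07e7,
        Sstar=3.34e7,
        LC0_pop=1e-6,
        SC0_pop=1e-6,
        beta=beta,
        omega=omega,
        omega_phi=0.5,
    )
    return complete_parameters(pop)
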