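"""Reading, writing and validating the pipeline's tabular artifacts.

Long-format CSV is the single tabular interchange; JSON holds nested results
(fit summaries, ROC curves); YAML or JSON configure the pipeline.  Weeks are
floats and chimerism is in percent (0-100), never fractions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from .cohort import OBSERVATION_COLUMNS, CohortDesign

logger = logging.getLogger("hemaflux")

__all__ = [
    "read_observations",
    "write_observations",
    "ValidationReport",
    "PipelineConfig",
    "load_config",
]

_REQUIRED = ["individual_id", "lineage", "week", "kind", "value"]
_KINDS = {"chimerism", "cbc", "recipient_chimerism"}


@dataclass
class ValidationReport:
    n_rows: int
    n_rejected: int
    rejected_reasons: List[str] = field(default_factory=list)
    counts: Optional[pd.DataFrame] = None

    def __str__(self) -> str:
        return f"{self.n_rows} rows loaded, {self.n_rejected} rejected"


def write_observations(obs: pd.DataFrame, path) -> None:
    obs.to_csv(path, index=False)


def read_observations(path) -> Tuple[pd.DataFrame, ValidationReport]:
    """Load and validate a long-format observation table.

    Unknown columns are ignored with a warning; rows with chimerism outside
    [0, 100], nonpositive CBC or an unknown kind are rejected row-wise and
    reported.  Returns the typed table and a validation report with
    per-scenario/lineage/week counts.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("empty observation file %s", path)
        return pd.DataFrame(columns=OBSERVATION_COLUMNS), ValidationReport(0, 0, ["empty file"])
    if df.empty and not set(_REQUIRED) <= set(df.columns):
        logger.warning("empty observation file %s", path)
        return pd.DataFrame(columns=OBSERVATION_COLUMNS), ValidationReport(0, 0, ["empty file"])
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    unknown = [c for c in df.columns if c not in OBSERVATION_COLUMNS]
    if unknown:
        logger.warning("ignoring unknown columns: %s", unknown)
        df = df.drop(columns=unknown)
    for col, default in (("age_group", "young"), ("scenario", "single_LT"), ("censored", False), ("limit", 0.001)):
        if col not in df.columns:
            df[col] = default
    df["week"] = df["week"].astype(float)
    df["value"] = df["value"].astype(float)
    df["censored"] = df["censored"].astype(bool)
    reasons: List[str] = []
    ok = pd.Series(True, index=df.index)
    bad_kind = ~df["kind"].isin(_KINDS)
    if bad_kind.any():
        reasons.append(f"{int(bad_kind.sum())} rows with unknown kind")
        ok &= ~bad_kind
    is_chim = df["kind"].isin(["chimerism", "recipient_chimerism"])
    bad_chim = is_chim & ((df["value"] < 0) | (df["value"] > 100))
    if bad_chim.any():
        reasons.append(f"{int(bad_chim.sum())} chimerism rows outside [0, 100]")
        ok &= ~bad_chim
    bad_cbc = (df["kind"] == "cbc") & (df["value"] <= 0)
    if bad_cbc.any():
        reasons.append(f"{int(bad_cbc.sum())} nonpositive CBC rows")
        ok &= ~bad_cbc
    clean = df[ok].reset_index(drop=True)[OBSERVATION_COLUMNS]
    counts = clean.groupby(["scenario", "kind", "lineage"]).size().reset_index(name="n") if len(clean) else None
    report = ValidationReport(n_rows=len(clean), n_rejected=int((~ok).sum()), rejected_reasons=reasons, counts=counts)
    if len(clean) == 0:
        logger.warning("observation table %s contains no valid rows", path)
    for r in reasons:
        logger.warning("%s: %s", path, r)
    return clean, report


@dataclass
class PipelineConfig:
    """Paths, model/inference/metric/scan options for the CLI pipeline."""

    dataset: Optional[str] = None
    outdir: str = "hemaflux_out"
    seed: int = 0
    design: Dict = field(default_factory=dict)
    population: Optional[str] = None  # path to a population parameter CSV/JSON
    solver: Dict = field(default_factory=lambda: {"rtol": 1e-8, "atol": 1e-10})
    inference: Dict = field(default_factory=dict)
    metrics: Dict = field(default_factory=dict)
    scan: Dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})

    def cohort_design(self) -> CohortDesign:
        design = dict(self.design)
        design.setdefault("seed", self.seed)
        return CohortDesign.from_dict(design)


def load_config(path) -> PipelineConfig:
    """Load a YAML or JSON pipeline configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return PipelineConfig.from_dict(data or {})
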