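"""File formats, the packaged cohort fixture, and run configuration.

Formats are deliberately plain: event tables, cohort tables and mutation
matrices are CSV; configuration is YAML (or JSON — YAML is a superset);
reports are JSON.  The 23-patient cohort fixture is packaged as CSV and
checked against a recorded SHA-256 on load, and is transcribed as printed —
including its documented internal inconsistencies — never "corrected".
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from ctcflow.channels import CHANNELS
from ctcflow.cohort import assign_groups
from ctcflow.errors import FixtureIntegrityError, ValidationError

__all__ = [
    "AnalysisConfig",
    "load_config",
    "load_cohort_csv",
    "load_table2_fixture",
    "read_events_csv",
    "write_cohort_csv",
    "write_events_csv",
]

_FIXTURE_NAME = "cohort_table.csv"
_FIXTURE_SHA256 = (
    "1600f029a5e2fb37649446ec4316c916b453fa0fd9320f09e92e6729a1a09a12"
)

EVENT_COLUMNS = ["event_id", *CHANNELS]

COHORT_COLUMNS = [
    "patient_id",
    "ihc_score",
    "fish_ratio",
    "ctc_count",
    "ctc_her2_intensity",
    "emt_index",
    "pfs_months",
    "pfs_event",
    "therapy",
]


def load_table2_fixture() -> pd.DataFrame:
    """The packaged 23-patient cohort table.

    Returns a cohort DataFrame with tissue status, CTC count, mean CTC HER2
    intensity, CTC HER2 status (as printed; cross-checked against the > 56
    rule on load), EMT-index, and derived ``group`` / ``a_prime`` columns.
    """
    ref = resources.files("ctcflow.data").joinpath(_FIXTURE_NAME)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureIntegrityError(
            f"packaged fixture checksum mismatch: {digest}"
        )
    frame = pd.read_csv(ref.open("r"))
    if len(frame) != 23:
        raise FixtureIntegrityError(
            f"fixture must have 23 rows, found {len(frame)}"
        )
    recomputed = np.where(
        frame["ctc_her2_intensity"] > 56, "positive", "negative"
    )
    if not (recomputed == frame["ctc_her2_status"]).all():
        raise FixtureIntegrityError(
            "printed CTC HER2 status disagrees with the > 56 rule"
        )
    frame = frame.rename(columns={"case": "patient_id"})
    frame["patient_id"] = frame["patient_id"].map(lambda c: f"case{c:02d}")
    return assign_groups(frame)


def read_events_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"event CSV lacks columns {missing}")
    frame.attrs["compensated"] = False
    return frame


def write_events_csv(events: pd.DataFrame, path) -> None:
    cols = EVENT_COLUMNS + (
        ["truth_pop"] if "truth_pop" in events.columns else []
    )
    events[cols].to_csv(path, index=False)


def load_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table in the external schema (empty fields = missing)."""
    frame = pd.read_csv(path, dtype={"ihc_score": str})
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"cohort CSV lacks columns {missing}")
    return frame


def write_cohort_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

class ThresholdConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mu_neg: float = 50.0
    sigma_neg: float = 23.7
    mu_pos: float = 76.0
    sigma_pos: float = 46.1


class GateConfig(BaseModel):
    """Gate cutoffs in arbitrary fluorescence units."""

    model_config = ConfigDict(extra="forbid")
    ck_cut: float = 40.0
    cd45_cut: float = 40.0
    hoechst_cut: float = 50.0
    carryover_loss: float = Field(0.0, ge=0.0, lt=1.0)


class EventSimConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_events: int = Field(100_000, ge=1)
    ctc_fraction: float = Field(1e-4, gt=0.0, lt=1.0)
    ctc_her2_median: float = 100.0
    ctc_emt_index: float = 0.17


class CohortSimConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_patients: int = Field(27, ge=1)
    coupling: float = Field(0.765, ge=-1.0, le=1.0)
    censoring_fraction: float = Field(0.25, ge=0.0, lt=1.0)


class AnalysisConfig(BaseModel):
    """Top-level run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    cohort_source: Literal["fixture", "csv", "simulate"] = "fixture"
    cohort_csv: Optional[str] = None  # required when cohort_source == "csv"
    threshold: ThresholdConfig = ThresholdConfig()
    gates: GateConfig = GateConfig()
    event_sim: EventSimConfig = EventSimConfig()
    cohort_sim: CohortSimConfig = CohortSimConfig()
    multiplicity: Literal["none", "holm"] = "none"

    def sha256(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def load_config(path: str | Path | None) -> AnalysisConfig:
    if path is None:
        return AnalysisConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return AnalysisConfig.model_validate(data)
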