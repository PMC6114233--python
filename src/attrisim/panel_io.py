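"""Long-format panel and config serialization.

Panels travel as plain CSV, one row per participant-phase, empty field as
the missing-value sentinel; study settings as YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import StudyConfig

PANEL_COLUMNS = [
    "participant_id",
    "phase",
    "time",
    "age_cat",
    "grade",
    "education",
    "smoking",
    "outcome",
    "status",
    "attrition_flag",
    "observed_outcome",
    "observed_exposure",
]

_INT_COLS = ["participant_id", "phase", "attrition_flag", "observed_outcome", "observed_exposure"]
_FLOAT_COLS = ["time", "age_cat", "grade", "education", "smoking", "outcome"]


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, index=False, na_rep="")


def read_panel(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"status": "string"})
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"panel file lacks columns: {sorted(missing)}")
    for c in _INT_COLS:
        df[c] = df[c].astype(np.int64)
    for c in _FLOAT_COLS:
        df[c] = df[c].astype(float)
    return df[PANEL_COLUMNS]


def write_config(config: StudyConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def read_config(path: str | Path) -> StudyConfig:
    with open(path) as fh:
        return StudyConfig.from_dict(yaml.safe_load(fh))
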