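"""On-disk formats: trial CSVs, design JSON, pattern containers."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .rsa import PatternDataset
from .task_design import TRIAL_COLUMNS, TaskDesign, TrialSequence

__all__ = [
    "write_trials",
    "read_trials",
    "write_design",
    "read_design",
    "write_patterns",
    "read_patterns",
]


def write_trials(sequence: TrialSequence, path: str | Path) -> None:
    sequence.trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path: str | Path, design: TaskDesign) -> TrialSequence:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if df["correct"].notna().any():
        df["correct"] = df["correct"].astype("boolean").astype(object)
    return TrialSequence(df[TRIAL_COLUMNS], design)


def write_design(design: TaskDesign, path: str | Path) -> None:
    Path(path).write_text(json.dumps(design.to_dict(), indent=2))


def read_design(path: str | Path) -> TaskDesign:
    return TaskDesign.from_dict(json.loads(Path(path).read_text()))


def write_patterns(patterns: PatternDataset, stem: str | Path) -> None:
    """Store a pattern dataset as <stem>.npz plus a <stem>.json sidecar with
    the condition labels."""
    stem = Path(stem)
    np.savez(
        stem.with_suffix(".npz"),
        estimates=patterns.estimates,
        residuals=patterns.residuals,
    )
    stem.with_suffix(".json").write_text(
        json.dumps({"conditions": [list(c) for c in patterns.conditions]})
    )


def read_patterns(stem: str | Path) -> PatternDataset:
    stem = Path(stem)
    with np.load(stem.with_suffix(".npz")) as npz:
        estimates = npz["estimates"]
        residuals = npz["residuals"]
    meta = json.loads(stem.with_suffix(".json").read_text())
    return PatternDataset(
        estimates, residuals, [tuple(c) for c in meta["conditions"]]
    )
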