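"""CSV interchange and pipeline configuration.

Trial-level sessions and participant-level cohort tables travel as
headered UTF-8 CSV; the pipeline configuration is a YAML file whose
``task``, ``mcmc`` and ``generative`` blocks mirror the corresponding
config dataclasses field for field.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import GenerativeConfig
from .inference import MCMCConfig
from .task import STIMULI, Session, TaskConfig, TrialRecord

SESSION_COLUMNS = [
    "participant_id",
    "trial",
    "choice",
    "outcome",
    "correct_stimulus",
    "reversal",
    "responded",
    "rt_ms",
]

__all__ = [
    "SESSION_COLUMNS",
    "PipelineConfig",
    "read_sessions",
    "write_sessions",
    "read_cohort",
    "write_cohort",
    "load_config",
    "write_manifest",
]


class SchemaError(ValueError):
    """A CSV row violated the interchange schema."""


def write_sessions(sessions: list[Session], path) -> None:
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "trial": t.trial_index,
                    "choice": t.choice,
                    "outcome": int(t.outcome),
                    "correct_stimulus": t.correct_stimulus_at_trial,
                    "reversal": int(t.reversal_occurred_after),
                    "responded": int(t.responded),
                    "rt_ms": t.rt_ms,
                }
            )
    pd.DataFrame(rows, columns=SESSION_COLUMNS).to_csv(path, index=False)


def read_sessions(path, config: TaskConfig | None = None) -> list[Session]:
    """Load trial-level CSV into Sessions, validating the schema.

    Malformed rows are reported with their (1-based, header-exclusive)
    line numbers. Outcomes must equal the configured win/loss codes and
    trial indices must run 1..n within each participant.
    """
    df = pd.read_csv(path)
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    config = config or TaskConfig()
    valid_outcomes = {config.win_value, config.loss_value}
    sessions = []
    for pid, grp in df.groupby("participant_id", sort=False):
        records = []
        for expected_t, (row_idx, row) in enumerate(grp.iterrows(), start=1):
            line = row_idx + 1
            if row["choice"] not in STIMULI or row["correct_stimulus"] not in STIMULI:
                raise SchemaError(f"{path} row {line}: bad stimulus id")
            if float(row["outcome"]) not in valid_outcomes:
                raise SchemaError(
                    f"{path} row {line}: outcome {row['outcome']} not in {sorted(valid_outcomes)}"
                )
            if int(row["trial"]) != expected_t:
                raise SchemaError(
                    f"{path} row {line}: trial index {row['trial']} != expected {expected_t}"
                )
            records.append(
                TrialRecord(
                    trial_index=expected_t,
                    choice=row["choice"],
                    outcome=float(row["outcome"]),
                    correct_stimulus_at_trial=row["correct_stimulus"],
                    was_correct_choice=row["choice"] == row["correct_stimulus"],
                    reversal_occurred_after=bool(int(row["reversal"])),
                    responded=bool(int(row["responded"])),
                    rt_ms=float(row["rt_ms"]),
                )
            )
        sessions.append(Session(participant_id=str(pid), trials=records, config=config))
    return sessions


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path, n_items: int = 4) -> pd.DataFrame:
    """Load a cohort table, validating scale ranges and the composite."""
    df = pd.read_csv(path)
    item_cols = [f"h{j + 1}" for j in range(n_items)]
    required = ["participant_id", *item_cols, "hardship_composite", "income", "age", "gender"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in item_cols:
        bad = df.index[(df[col] < 1) | (df[col] > 5)]
        if len(bad):
            raise SchemaError(f"{path} row {bad[0] + 2}: {col} outside 1-5")
    bad = df.index[(df["income"] < 1) | (df["income"] > 7)]
    if len(bad):
        raise SchemaError(f"{path} row {bad[0] + 2}: income outside 1-7")
    recomputed = df[item_cols].sum(axis=1)
    mismatch = df.index[recomputed != df["hardship_composite"]]
    if len(mismatch):
        raise SchemaError(
            f"{path} row {mismatch[0] + 2}: hardship_composite does not equal the item sum"
        )
    return df


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PipelineConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    generative: GenerativeConfig = field(default_factory=GenerativeConfig)
    censor_nonresponse: bool = False
    seed: int | None = None


def _build(cls, block: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = {}
    for key, value in block.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    return cls(**coerced)


def load_config(path) -> PipelineConfig:
    """Read a YAML pipeline config; blocks mirror the config dataclasses."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    analysis = raw.get("analysis", {})
    return PipelineConfig(
        task=_build(TaskConfig, raw.get("task", {})),
        mcmc=_build(MCMCConfig, raw.get("mcmc", {})),
        generative=_build(GenerativeConfig, raw.get("generative", {})),
        censor_nonresponse=bool(analysis.get("censor_nonresponse", False)),
        seed=raw.get("seed"),
    )


def write_manifest(path, config: PipelineConfig, seed, extra: dict | None = None) -> None:
    """Record config + seed + versions so a run can be reproduced."""
    import revlearn

    payload = {
        "seed": seed,
        "versions": {"revlearn": revlearn.__version__, "numpy": np.__version__},
        "config": {
            "task": dataclasses.asdict(config.task),
            "mcmc": dataclasses.asdict(config.mcmc),
            "generative": dataclasses.asdict(config.generative),
            "analysis": {"censor_nonresponse": config.censor_nonresponse},
        },
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
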