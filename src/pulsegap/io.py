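"""Trial-table CSV schema, validation, and the external-data adapter.

The tidy trial table is the interchange format between every stage of the
pipeline: one row per subject x trial.  Column order and dtypes are frozen
here; `read_trials` validates the schema and raises errors that name the
offending column or row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "write_schedule",
    "read_schedule",
    "adapt_external_table",
]

#: frozen trial-table schema (column -> pandas dtype used on write)
TRIAL_COLUMNS: dict[str, str] = {
    "subject_id": "string",
    "experiment": "int64",
    "block": "int64",
    "trial_index": "int64",
    "modality": "string",
    "rate_hz": "float64",
    "noise_level": "float64",
    "gap_ms": "float64",
    "dp_first": "object",
    "ipi_sequence": "string",
    "response": "string",
    "correct": "bool",
    "rt_ms": "float64",
    "pulses_observed": "int64",
    "seed": "int64",
}

SCHEDULE_COLUMNS = (
    "experiment",
    "block",
    "trial_index",
    "modality",
    "rate_hz",
    "noise_level",
    "gap_ms",
    "dp_first",
    "ipi_sequence",
    "seed",
)

_VALID_MODALITIES = {"V", "T", "VT"}
_VALID_RESPONSES = {"slow", "fast", "first", "second", "none"}


def _validate(table: pd.DataFrame, path: str | Path | None = None) -> pd.DataFrame:
    where = f" in {path}" if path else ""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table{where} is missing column(s): {', '.join(missing)}")
    bad_mod = ~table["modality"].isin(_VALID_MODALITIES)
    if bad_mod.any():
        row = int(table.index[bad_mod][0])
        raise ValueError(
            f"invalid modality {table.loc[row, 'modality']!r} at row {row}{where}; "
            f"expected one of {sorted(_VALID_MODALITIES)}"
        )
    bad_resp = ~table["response"].isin(_VALID_RESPONSES)
    if bad_resp.any():
        row = int(table.index[bad_resp][0])
        raise ValueError(
            f"invalid response {table.loc[row, 'response']!r} at row {row}{where}"
        )
    rt = table["rt_ms"].to_numpy(dtype=float)
    neg = np.flatnonzero(rt < 0)
    if len(neg):
        raise ValueError(f"negative rt_ms at row {int(neg[0])}{where}")
    none_with_rt = (table["response"] == "none") & table["rt_ms"].notna()
    if none_with_rt.any():
        row = int(table.index[none_with_rt][0])
        raise ValueError(f"row {row}{where}: response 'none' cannot carry an rt_ms")
    return table


def write_trials(table: pd.DataFrame, path: str | Path) -> None:
    """Write a validated trial table to CSV with the frozen column order."""
    table = table.copy()
    for col in TRIAL_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    table = table[list(TRIAL_COLUMNS)]
    _validate(table)
    table.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and schema-validate a trial-table CSV (lossless round trip)."""
    table = pd.read_csv(
        path,
        dtype={
            "subject_id": "string",
            "modality": "string",
            "ipi_sequence": "string",
            "response": "string",
        },
    )
    _validate(table, path)
    table["ipi_sequence"] = table["ipi_sequence"].fillna("")
    table["correct"] = table["correct"].astype(bool)
    return table


def write_schedule(schedule, path: str | Path) -> None:
    """Write an ExperimentSchedule's trial list to CSV."""
    df = schedule.trials[list(SCHEDULE_COLUMNS)]
    df.to_csv(path, index=False)


def read_schedule(path: str | Path):
    """Read a schedule CSV back into an ExperimentSchedule."""
    from .stimuli import ExperimentSchedule

    df = pd.read_csv(path, dtype={"modality": "string", "ipi_sequence": "string"})
    missing = [c for c in SCHEDULE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"schedule {path} is missing column(s): {', '.join(missing)}")
    df["ipi_sequence"] = df["ipi_sequence"].fillna("")
    experiment = int(df["experiment"].iloc[0])
    seed = int(df["seed"].iloc[0])
    return ExperimentSchedule(experiment=experiment, trials=df, seed=seed)


#: default column mapping for externally deposited trial data -> our schema.
#: The deposit's exact headers are not verifiable offline, so the mapping is
#: a documented, overridable guess; unmapped required columns raise clearly.
DEFAULT_EXTERNAL_MAPPING: dict[str, str] = {
    "subject": "subject_id",
    "participant": "subject_id",
    "block": "block",
    "trial": "trial_index",
    "modality": "modality",
    "rate": "rate_hz",
    "noise": "noise_level",
    "gap": "gap_ms",
    "response": "response",
    "resp": "response",
    "rt": "rt_ms",
    "correct": "correct",
    "acc": "correct",
}


def adapt_external_table(
    raw: pd.DataFrame, experiment: int, mapping: dict[str, str] | None = None
) -> pd.DataFrame:
    """Map an externally formatted per-trial table onto the frozen schema.

    ``mapping`` maps source column names to our names and overrides/extends
    the documented default guesses.  Missing optional columns are filled with
    neutral values; missing required columns raise with their names.
    """
    colmap = dict(DEFAULT_EXTERNAL_MAPPING)
    if mapping:
        colmap.update(mapping)
    renamed = raw.rename(columns={k: v for k, v in colmap.items() if k in raw.columns})
    required = ["subject_id", "modality", "response"]
    required += ["rate_hz", "noise_level"] if experiment == 1 else ["gap_ms"]
    missing = [c for c in required if c not in renamed.columns]
    if missing:
        raise ValueError(
            f"external table lacks required column(s) {missing}; "
            "supply a column mapping for them"
        )
    out = pd.DataFrame()
    out["subject_id"] = renamed["subject_id"].astype("string")
    out["experiment"] = experiment
    out["block"] = renamed.get("block", pd.Series(0, index=renamed.index)).astype(int)
    out["trial_index"] = renamed.get(
        "trial_index", pd.Series(np.arange(len(renamed)), index=renamed.index)
    ).astype(int)
    out["modality"] = renamed["modality"].astype("string").str.upper()
    out["rate_hz"] = pd.to_numeric(renamed.get("rate_hz", np.nan), errors="coerce")
    out["noise_level"] = pd.to_numeric(renamed.get("noise_level", np.nan), errors="coerce")
    out["gap_ms"] = pd.to_numeric(renamed.get("gap_ms", np.nan), errors="coerce")
    out["dp_first"] = renamed.get("dp_first", np.nan)
    out["ipi_sequence"] = renamed.get("ipi_sequence", "").fillna("") if "ipi_sequence" in renamed else ""
    out["response"] = renamed["response"].astype("string").str.lower().fillna("none")
    if "correct" in renamed:
        out["correct"] = renamed["correct"].astype(float).fillna(0).astype(bool)
    elif experiment == 1:
        out["correct"] = out["response"] == np.where(out["rate_hz"] == 4, "slow", "fast")
    else:
        raise ValueError("external gap-task table needs a 'correct' (or mapped) column")
    out["rt_ms"] = pd.to_numeric(renamed.get("rt_ms", np.nan), errors="coerce")
    out.loc[out["response"] == "none", "rt_ms"] = np.nan
    out["pulses_observed"] = renamed.get("pulses_observed", 0)
    out["seed"] = -1
    return _validate(out)
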