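"""Observation CSV I/O with validation, plus model/config JSON helpers."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .simulate import SOURCE_OBSERVED, ObservationSet


class ObservationParseError(ValueError):
    """Malformed observation file; message lists the offending lines."""


REQUIRED_COLUMNS = ("crl_mm", "ga_weeks")
VALID_SOURCES = {"observed", "simulated_low", "simulated_high", "simulated"}


def read_observations(path) -> ObservationSet:
    """Read a crl_mm/ga_weeks[/source] CSV into an ObservationSet.

    Rows must be numeric and strictly positive; violations are reported
    with their 1-based data line numbers (header is line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ObservationParseError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    problems: list[str] = []
    for col in REQUIRED_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values <= 0)
        for idx in df.index[bad]:
            problems.append(
                f"line {idx + 2}: {col}={df.loc[idx, col]!r} "
                "(must be a number > 0)"
            )
        df[col] = values
    if "source" in df.columns:
        bad_src = ~df["source"].isin(VALID_SOURCES)
        for idx in df.index[bad_src]:
            problems.append(f"line {idx + 2}: source={df.loc[idx, 'source']!r}")
    else:
        df["source"] = SOURCE_OBSERVED
    if problems:
        raise ObservationParseError(
            f"{path}: {len(problems)} malformed row(s):\n  " + "\n  ".join(problems)
        )
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return ObservationSet(df[["crl_mm", "ga_weeks", "source"]], meta)


def write_observations(obs: ObservationSet, path, sidecar: bool = True) -> None:
    """Write CSV (full float precision) and a JSON metadata sidecar."""
    path = Path(path)
    obs.data.to_csv(path, index=False, float_format="%.17g")
    if sidecar and obs.metadata:
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta_path.write_text(json.dumps(obs.metadata, indent=2, default=str))


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
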