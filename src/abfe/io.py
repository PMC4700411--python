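"""Energy-table and configuration file handling.

Per-window reduced potentials travel as plain TSV tables: a header row
``state	u_<label>...`` followed by one row per sample, the first column
naming the sampling state and the remaining columns holding the sample's
reduced potential evaluated at every state of the schedule.  An xvg-style
dialect (comment lines starting with ``#`` or ``@``, no header) is also
accepted.  Temperature is always supplied in configuration, never inferred
from the files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .mbar import ReducedPotentialData

try:
    import tomllib
except ModuleNotFoundError:  # pragma: no cover - py<3.11
    import tomli as tomllib

__all__ = [
    "EnergyTable",
    "ParseError",
    "read_energy_table",
    "write_energy_table",
    "energy_table_to_data",
    "load_config",
]


class ParseError(ValueError):
    """Malformed energy table; the message names the offending line."""


@dataclass
class EnergyTable:
    """Parsed energy table: sampling-state labels and cross-evaluations.

    ``sampling_state`` has one entry per row (sample); ``u`` is the
    (n_samples, n_states) matrix of reduced potentials; ``state_labels``
    orders the evaluated states (schedule order).
    """

    sampling_state: list[str]
    u: np.ndarray
    state_labels: list[str]


def read_energy_table(path: str | Path, dialect: str = "tsv") -> EnergyTable:
    """Read a per-window reduced-potential table.

    Parameters
    ----------
    path : path
    dialect : {"tsv", "xvg"}
        ``tsv`` expects a header row starting with ``state``; ``xvg``
        has no header and skips lines beginning with ``#`` or ``@``.

    Raises
    ------
    ParseError
        On ragged rows or non-numeric cells, naming the line number.
    """
    if dialect not in ("tsv", "xvg"):
        raise ParseError(f"unknown dialect {dialect!r}")
    path = Path(path)
    labels: list[str] | None = None
    states: list[str] = []
    rows: list[list[float]] = []
    n_cols: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if dialect == "xvg" and line.lstrip().startswith(("#", "@")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if dialect == "tsv" and labels is None and not rows:
                if fields[0] != "state":
                    raise ParseError(
                        f"{path}:1: expected header starting with 'state', got {fields[0]!r}"
                    )
                labels = [c.removeprefix("u_") for c in fields[1:]]
                n_cols = len(fields)
                continue
            if n_cols is None:
                n_cols = len(fields)
            if len(fields) != n_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_cols} columns, found {len(fields)}"
                )
            try:
                values = [float(v) for v in fields[1:]]
            except ValueError as err:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({err})") from None
            if not all(np.isfinite(values)):
                raise ParseError(f"{path}:{lineno}: non-finite reduced potential")
            states.append(fields[0])
            rows.append(values)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    if labels is None:
        labels = [str(i) for i in range(n_cols - 1)]
    return EnergyTable(
        sampling_state=states,
        u=np.array(rows, dtype=np.float64),
        state_labels=labels,
    )


def write_energy_table(path: str | Path, table: EnergyTable) -> None:
    """Write an energy table in the TSV dialect (value round-trip safe)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("state\t" + "\t".join(f"u_{c}" for c in table.state_labels) + "\n")
        for state, row in zip(table.sampling_state, table.u):
            fh.write(state + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def energy_table_to_data(
    table: EnergyTable, temperature_K: float
) -> ReducedPotentialData:
    """Group table rows by sampling state into MBAR-ready data.

    States follow the order of ``state_labels``; states without samples
    contribute N_k = 0.
    """
    rows_per_state = []
    states = np.asarray(table.sampling_state)
    for label in table.state_labels:
        rows_per_state.append(table.u[states == label])
    return ReducedPotentialData.from_sample_lists(
        rows_per_state,
        temperature_K=temperature_K,
        state_labels=list(table.state_labels),
    )


def load_config(path: str | Path) -> dict:
    """Load a run configuration from TOML or YAML (one schema, both
    syntaxes)."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_json_report(path: str | Path | None, payload: dict) -> str:
    """Serialize a report with sorted keys; write to ``path`` if given."""
    text = json.dumps(payload, sort_keys=True, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
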