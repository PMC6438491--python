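"""Readers and writers shared by the command-line tools.

Subject-level data travels as CSV with header ``subject_id,regime,F,L[,D]``;
parameter records, frequencies, networks and results as flat YAML/JSON
documents.  Floats are serialized as plain decimal text via ``repr`` (the
shortest round-tripping representation), so write-then-read preserves values
exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .causal_net import DiscreteBayesNet
from .model_core import InterventionRegime, LCAParameters
from .simulate import DATASET_COLUMNS, REGIMES, ObservedFrequencies

__all__ = [
    "RunConfig",
    "DatasetParseError",
    "read_dataset",
    "write_dataset",
    "read_params",
    "write_results",
    "read_record",
    "read_frequencies",
    "read_network",
]


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of a CLI run; flags win over the config file."""

    subcommand: str
    seed: Optional[int] = None
    solver_tol: float = 1e-9
    grid_size: int = 21
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.seed is not None and (int(self.seed) != self.seed or self.seed < 0):
            raise ValueError("seed must be a non-negative integer")
        if self.solver_tol <= 0 or self.grid_size <= 0:
            raise ValueError("tolerances and grid sizes must be strictly positive")


class DatasetParseError(ValueError):
    """A subject table failed validation; the message lists offending lines."""


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a subject-level CSV table.

    Requires the columns ``subject_id, regime, F, L`` (``D`` optional);
    every F/L/D value must be exactly 0 or 1 and every regime tag pre/post.
    Malformed rows are reported with their 1-based file line numbers.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetParseError(f"{path}: missing columns {missing}")
    problems: list[str] = []
    binary_cols = ["F", "L"] + (["D"] if "D" in frame.columns else [])
    for col in binary_cols:
        bad = ~frame[col].isin([0, 1])
        for idx in frame.index[bad]:
            # +2: one for the header line, one for 0-based indexing
            problems.append(f"line {idx + 2}: {col}={frame.at[idx, col]} is not 0/1")
    bad_regime = ~frame["regime"].isin(REGIMES)
    for idx in frame.index[bad_regime]:
        problems.append(
            f"line {idx + 2}: regime={frame.at[idx, 'regime']!r} is not pre/post"
        )
    if problems:
        raise DatasetParseError(f"{path}: " + "; ".join(problems))
    return frame


def write_dataset(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def _to_plain(obj):
    """Recursively convert results to YAML/JSON-safe builtins."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return [_to_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        if math.isinf(v) or math.isnan(v):
            return repr(v)
        return v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, dict):
        return {_to_plain(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def write_results(record, path) -> None:
    """Serialize a result record (dataclass or mapping) as YAML or JSON.

    The format follows the file suffix (``.json`` for JSON, anything else is
    YAML); numbers round-trip exactly.
    """
    path = Path(path)
    plain = _to_plain(record)
    if path.suffix == ".json":
        path.write_text(json.dumps(plain, indent=2, default=repr) + "\n")
    else:
        path.write_text(yaml.safe_dump(plain, sort_keys=False))


def read_record(path) -> dict:
    """Read a flat YAML/JSON record back as a dictionary."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_params(path) -> tuple[LCAParameters, Optional[InterventionRegime]]:
    """Read a flat parameter record.

    Keys: delta, phi0, phi1, lambda0, lambda1, optionally delta_prime and
    direction.  Returns the observational parameters and, when delta_prime is
    present, the intervention regime.
    """
    record = read_record(path)
    params = LCAParameters.from_dict(record)
    regime = None
    if "delta_prime" in record:
        regime = InterventionRegime(
            delta_prime=record["delta_prime"],
            direction=record.get("direction", "unconstrained"),
        )
    return params, regime


def read_frequencies(path) -> ObservedFrequencies:
    record = read_record(path)
    return ObservedFrequencies(
        r00=record["r00"],
        r01=record["r01"],
        r10=record["r10"],
        r11=record["r11"],
        t=record["t"],
        regime=record["regime"],
    )


def read_network(path) -> DiscreteBayesNet:
    """Read a network description: node names, parent lists, and tables.

    Format::

        nodes: [D, F, L]
        parents: {D: [], F: [D], L: [D]}
        cpts:
          D: [0.4, 0.6]            # flat, parent assignments lexicographic
          F: [[0.8, 0.2], [0.3, 0.7]]
    """
    record = read_record(path)
    nodes = tuple(record["nodes"])
    parents = {n: tuple(record.get("parents", {}).get(n, ())) for n in nodes}
    cpts = {}
    for n in nodes:
        table = np.asarray(record["cpts"][n], dtype=float)
        cpts[n] = table.reshape((2,) * len(parents[n]) + (2,))
    return DiscreteBayesNet(nodes=nodes, parents=parents, cpts=cpts)
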