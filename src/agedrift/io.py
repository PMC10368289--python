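"""Serialization: sample/population CSV, profile CSV, JSON manifests.

Abundance tables use a two-column CSV schema (variant_id, count) with a
JSON sidecar holding the simulation parameters and seed.  Validation is
strict: malformed rows are reported with their line number, counts must be
positive integers, duplicate variant ids are rejected.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import pandas as pd

from .core import (ParameterError, Population, SampleConfiguration,
                   SimParams, VariantFrequencyTable)
from .diversity import DEFAULT_Q_GRID, DiversityProfile

__all__ = ["read_sample_csv", "write_table_csv", "write_population_csv",
           "read_grid", "write_profile_csv", "read_profile_csv", "write_json"]


class SchemaError(ParameterError):
    """Malformed input file (message carries the offending line number)."""


def read_sample_csv(path) -> SampleConfiguration:
    """Read a (variant_id, count) CSV into a canonical configuration."""
    path = Path(path)
    counts = []
    seen = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["variant_id", "count"]:
            raise SchemaError(f"{path}: line 1: expected header 'variant_id,count'")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            if len(row) < 2:
                raise SchemaError(f"{path}: line {lineno}: expected 2 columns")
            vid = row[0].strip()
            if vid in seen:
                raise SchemaError(f"{path}: line {lineno}: duplicate variant_id {vid!r}")
            seen.add(vid)
            try:
                count = int(row[1])
            except ValueError:
                raise SchemaError(
                    f"{path}: line {lineno}: count must be an integer, got {row[1]!r}") from None
            if count < 1:
                raise SchemaError(f"{path}: line {lineno}: count must be >= 1, got {count}")
            counts.append(count)
    if not counts:
        raise SchemaError(f"{path}: no data rows")
    return SampleConfiguration.from_counts(counts)


def write_table_csv(table, path, params: SimParams | None = None,
                    seed=None, step_index=None) -> None:
    """Write an abundance table (or configuration) plus a JSON sidecar."""
    path = Path(path)
    if isinstance(table, SampleConfiguration):
        pairs = list(enumerate(table.counts))
    elif isinstance(table, VariantFrequencyTable):
        pairs = list(zip(table.labels.tolist(), table.counts.tolist()))
    else:
        raise ParameterError(f"cannot serialize {type(table).__name__}")
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["variant_id", "count"])
        writer.writerows(pairs)
    sidecar = {"params": params.to_dict() if params else None,
               "seed": seed, "step_index": step_index}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def write_population_csv(pop: Population, path, params: SimParams | None = None,
                         seed=None) -> None:
    write_table_csv(pop.frequency_table(), path, params=params, seed=seed,
                    step_index=pop.step_index)


def write_profile_csv(profiles, path, labels=None) -> None:
    """Write diversity profiles as rows: n, q0, ..., q3 (+ optional label)."""
    path = Path(path)
    if isinstance(profiles, DiversityProfile):
        profiles = [profiles]
    rows = []
    for i, prof in enumerate(profiles):
        row = {"n": prof.n}
        row.update(dict(zip(prof.feature_names(), prof.values)))
        if labels is not None:
            row["label"] = labels[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profile_csv(path) -> list[DiversityProfile]:
    path = Path(path)
    df = pd.read_csv(path)
    feats = [f"q{q:g}" for q in DEFAULT_Q_GRID]
    missing = [f for f in feats if f not in df.columns] + \
              [c for c in ("n",) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return [DiversityProfile(tuple(DEFAULT_Q_GRID),
                             tuple(row[f] for f in feats), int(row["n"]))
            for _, row in df.iterrows()]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float))


def read_grid(path) -> dict:
    """Read an experiment grid file: JSON with a 'grid' list of
    constellations plus optional settings (n_reps, sample_sizes, alpha...)."""
    path = Path(path)
    spec = json.loads(path.read_text())
    if "grid" not in spec or not isinstance(spec["grid"], list):
        raise SchemaError(f"{path}: expected a JSON object with a 'grid' list")
    for i, cell in enumerate(spec["grid"]):
        if "p_death" not in cell:
            raise SchemaError(f"{path}: grid entry {i} lacks 'p_death'")
    return spec
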