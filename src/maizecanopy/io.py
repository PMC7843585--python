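"""Delimited-text readers and writers.

The measurement table is the package's exchange format: long-form CSV with
a header row and columns label, density (plants m⁻²), replicate, rank,
organ (one of the six organ codes) and value (cm).  Organ-size profiles
travel in the same format (one pseudo-replicate per rank/organ).
Validation is collected per row and reported together, naming the
offending rows.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .density_response import MODELED_RANKS, OrganDim, ResponseParams, params_from_text, params_to_text
from .canopy_geometry import BaseProfile

log = logging.getLogger("maizecanopy")

MEASUREMENT_COLUMNS = ["label", "density", "replicate", "rank", "organ", "value"]

_VALID_ORGANS = {o.value for o in OrganDim}


class MeasurementValidationError(ValueError):
    """One or more measurement rows failed validation."""

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        lines = "; ".join(f"row {r}: {msg}" for r, msg in problems)
        super().__init__(f"{len(problems)} invalid measurement row(s): {lines}")


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a long-form measurement CSV.

    Row numbers in error messages are 1-based data rows (the header is row
    0).  All invalid rows are collected and reported in one exception.
    """
    table = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise MeasurementValidationError(
            [(0, f"missing required column(s) {missing}")]
        )
    problems: list[tuple[int, str]] = []
    for idx, rec in table.iterrows():
        row = int(idx) + 1
        if rec["organ"] not in _VALID_ORGANS:
            problems.append((row, f"unknown organ code {rec['organ']!r}"))
        try:
            if float(rec["density"]) <= 0:
                problems.append((row, f"non-positive density {rec['density']}"))
        except (TypeError, ValueError):
            problems.append((row, f"non-numeric density {rec['density']!r}"))
        try:
            if int(rec["rank"]) < 1:
                problems.append((row, f"rank {rec['rank']} below 1"))
        except (TypeError, ValueError):
            problems.append((row, f"non-integer rank {rec['rank']!r}"))
        try:
            if float(rec["value"]) < 0:
                problems.append((row, f"negative value {rec['value']}"))
        except (TypeError, ValueError):
            problems.append((row, f"non-numeric value {rec['value']!r}"))
    if problems:
        raise MeasurementValidationError(problems)
    table["density"] = table["density"].astype(float)
    table["replicate"] = table["replicate"].astype(int)
    table["rank"] = table["rank"].astype(int)
    table["value"] = table["value"].astype(float)
    return table[MEASUREMENT_COLUMNS]


def write_measurements(table: pd.DataFrame, path) -> None:
    """Write a measurement table as CSV; write->read is the identity."""
    table[MEASUREMENT_COLUMNS].to_csv(path, index=False)


def profile_to_table(profile: BaseProfile, label: str = "profile") -> pd.DataFrame:
    """A profile as a single-replicate measurement table."""
    rows = [
        {
            "label": label,
            "density": profile.density,
            "replicate": 1,
            "rank": rank,
            "organ": organ.value,
            "value": size,
        }
        for (rank, organ), size in sorted(
            profile.entries.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
        )
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def profile_from_table(table: pd.DataFrame, density: float | None = None) -> BaseProfile:
    """Reconstruct a profile from a measurement table at one density.

    Replicates are averaged per (rank, organ).  If ``density`` is omitted
    the table must contain exactly one density.
    """
    if density is None:
        densities = sorted(table["density"].unique())
        if len(densities) != 1:
            raise ValueError(
                f"table holds densities {densities}; pass the one to extract"
            )
        density = float(densities[0])
    sub = table[np.isclose(table["density"].astype(float), density)]
    if sub.empty:
        raise ValueError(f"no rows at density {density}")
    means = sub.groupby(["rank", "organ"])["value"].mean()
    entries = {
        (int(rank), OrganDim(organ)): float(v)
        for (rank, organ), v in means.items()
        if int(rank) in MODELED_RANKS
    }
    return BaseProfile(density=density, entries=entries)


def write_profile(profile: BaseProfile, path, label: str = "profile") -> None:
    write_measurements(profile_to_table(profile, label), path)


def read_profile(path, density: float | None = None) -> BaseProfile:
    return profile_from_table(read_measurements(path), density)


def read_params(path) -> ResponseParams:
    """Read a response parameterization from a flat key-value text file."""
    return params_from_text(Path(path).read_text())


def write_params(params: ResponseParams, path) -> None:
    Path(path).write_text(params_to_text(params))
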