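"""Organ-size response of maize to increased plant density.

The core empirical model: the percent change Y of a final organ dimension
(relative to its size at the reference density of 4.5 plants m⁻²) is a
function of plant density and phytomer position.  Phytomers are split into
three groups:

* lower group, ranks 6–11:    Y = A·ln(x) + B·PP + C
* ear phytomer, rank 12:      Y = D·x + E
* upper group, ranks 13–18:   Y = A·ln(x) + B·PP + C

where PP is the phytomer rank and x is the density regressor.  By default
x is the density *increment* above the reference (x = PD − 4.5); the
absolute density can be selected via ``regressor_mode="absolute"``.

Coefficients differ per organ dimension (six dimensions: lamina length and
maximum width, sheath length and average width, internode length and
diameter).  :func:`default_params` returns the published calibration for
the hybrid Zhengdan 958; :func:`fit_group` refits coefficients from
relative-change observations by ordinary least squares.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids circular import
    from .canopy_geometry import BaseProfile

log = logging.getLogger("maizecanopy")

#: Reference plant density (plants m⁻²) at which organ sizes are the base.
REFERENCE_DENSITY = 4.5

#: Phytomer ranks carrying modelled morphology (lower ranks senesce early).
MODELED_RANKS = tuple(range(6, 19))

#: Density treatments of the underlying field trial (plants m⁻²).
TRIAL_DENSITIES = (4.5, 6.0, 7.5, 9.0, 15.0)

#: Highest density the calibration covers; beyond it we extrapolate.
MAX_CALIBRATED_DENSITY = 15.0


class RankDomainError(ValueError):
    """Phytomer rank outside the modelled range 6–18."""


class RegressorDomainError(ValueError):
    """Density regressor not positive where a logarithm is required."""


class SingularDesignError(ValueError):
    """Regression design matrix is rank-deficient (degenerate data)."""


class MissingEntryError(KeyError):
    """A profile is missing required (rank, organ) entries."""

    def __init__(self, missing: Sequence[tuple[int, "OrganDim"]]):
        self.missing = list(missing)
        super().__init__(
            "profile is missing entries: "
            + ", ".join(f"(rank {r}, {o.value})" for r, o in self.missing)
        )


class OrganDim(enum.Enum):
    """The six measured final organ dimensions, all in cm."""

    LL = "LL"  #: lamina (leaf blade) length
    LW = "LW"  #: lamina maximum width
    SL = "SL"  #: sheath length
    SW = "SW"  #: sheath average width
    IL = "IL"  #: internode length
    ID = "ID"  #: internode diameter

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class DensityLevel:
    """A plant density (plants m⁻²) paired with the reference density."""

    density: float
    reference_density: float = REFERENCE_DENSITY

    def __post_init__(self) -> None:
        if self.density <= 0 or self.reference_density <= 0:
            raise ValueError("densities must be positive")
        if self.density < self.reference_density:
            raise ValueError(
                f"density {self.density} below reference "
                f"{self.reference_density}: the response model only covers "
                "densities at or above the reference"
            )

    @property
    def increment(self) -> float:
        """Density increase x = PD − reference (plants m⁻²)."""
        return self.density - self.reference_density


@dataclass(frozen=True)
class GroupParams:
    """Log+linear coefficients for a grouped phytomer range.

    A multiplies ln(regressor), B is percent per rank, C the intercept (%).
    """

    A: float
    B: float
    C: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.A, self.B, self.C)):
            raise ValueError("coefficients must be finite")


@dataclass(frozen=True)
class EarParams:
    """Linear coefficients for the ear phytomer: Y = D·x + E (percent)."""

    D: float
    E: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.D, self.E)):
            raise ValueError("coefficients must be finite")


@dataclass(frozen=True)
class OrganResponse:
    """The three parameter groups of one organ dimension."""

    lower: GroupParams  # ranks 6–11
    ear: EarParams  # the ear rank (12)
    upper: GroupParams  # ranks 13–18


@dataclass(frozen=True)
class ResponseParams:
    """Complete density-response parameterization (6 organs × 3 groups)."""

    organs: Mapping[OrganDim, OrganResponse]
    ear_rank: int = 12
    regressor_mode: str = "increment"  # or "absolute"

    LOWER_RANKS = tuple(range(6, 12))
    UPPER_RANKS = tuple(range(13, 19))

    def __post_init__(self) -> None:
        missing = [o for o in OrganDim if o not in self.organs]
        if missing:
            raise ValueError(f"missing organ parameterizations: {missing}")
        if not (max(self.LOWER_RANKS) < self.ear_rank < min(self.UPPER_RANKS)):
            raise ValueError(
                f"ear_rank {self.ear_rank} must lie strictly between the "
                "lower and upper rank groups"
            )
        if self.regressor_mode not in ("increment", "absolute"):
            raise ValueError(f"unknown regressor_mode {self.regressor_mode!r}")

    def lower(self, organ: OrganDim) -> GroupParams:
        return self.organs[organ].lower

    def ear(self, organ: OrganDim) -> EarParams:
        return self.organs[organ].ear

    def upper(self, organ: OrganDim) -> GroupParams:
        return self.organs[organ].upper


@dataclass(frozen=True)
class FitResult:
    """Outcome of an ordinary-least-squares coefficient fit."""

    params: GroupParams | EarParams
    r_squared: float
    n_points: int
    residual_sse: float


# --- default (published) parameterization -------------------------------

_TABLE_GROUPED: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    # organ: ((A, B, C) ranks 6-11, (A, B, C) ranks 13-18)
    "LL": ((2.99, 0.12, 0.32), (-7.09, -2.36, 39.64)),
    "LW": ((-4.34, 0.80, 7.07), (-8.71, 0.73, 13.93)),
    "SL": ((0.73, -2.46, 21.63), (-4.49, 0.61, 8.41)),
    "SW": ((-8.99, -0.24, 4.92), (-9.41, 0.09, 1.55)),
    "IL": ((4.94, -2.01, 18.61), (2.91, -2.06, 32.08)),
    "ID": ((-7.69, -0.53, -11.36), (-9.66, 0.07, -8.52)),
}

_TABLE_EAR: dict[str, tuple[float, float]] = {
    # organ: (D, E) at the ear phytomer
    "LL": (0.11, 1.70),
    "LW": (-1.17, -1.78),
    "SL": (-0.86, -0.12),
    "SW": (-1.93, 2.83),
    "IL": (0.54, 0.73),
    "ID": (-1.63, -9.53),
}


def default_params() -> ResponseParams:
    """Published density-response coefficients for hybrid ZD958.

    Calibrated from a 2016 field trial at densities 4.5–15 plants m⁻²;
    constants of the package, never re-derived at run time.
    """
    organs = {
        organ: OrganResponse(
            lower=GroupParams(*_TABLE_GROUPED[organ.value][0]),
            ear=EarParams(*_TABLE_EAR[organ.value]),
            upper=GroupParams(*_TABLE_GROUPED[organ.value][1]),
        )
        for organ in OrganDim
    }
    return ResponseParams(organs=organs)


# --- evaluation ----------------------------------------------------------


def _regressor(level: DensityLevel, params: ResponseParams) -> float:
    if params.regressor_mode == "absolute":
        return level.density
    return level.increment


def relative_change(
    organ: OrganDim,
    rank: int,
    level: DensityLevel,
    params: ResponseParams | None = None,
) -> float:
    """Signed percent change of an organ dimension at a given density.

    Returns Y (%) relative to the reference-density size.  At the reference
    density exactly, returns 0 by contract (the equations are bypassed;
    under increment mode their log term would be undefined there).

    Raises
    ------
    RankDomainError
        If ``rank`` is outside 6–18.
    RegressorDomainError
        If the regressor is ≤ 0 for a grouped (log-term) rank.
    """
    if params is None:
        params = default_params()
    if rank not in MODELED_RANKS:
        raise RankDomainError(
            f"rank {rank} outside modelled range "
            f"{MODELED_RANKS[0]}–{MODELED_RANKS[-1]}"
        )
    if level.density == level.reference_density:
        return 0.0
    if level.density > MAX_CALIBRATED_DENSITY:
        log.warning(
            "density %.3g plants/m^2 exceeds the calibrated maximum %.3g; "
            "extrapolating",
            level.density,
            MAX_CALIBRATED_DENSITY,
        )
    x = _regressor(level, params)
    if rank == params.ear_rank:
        p = params.ear(organ)
        return p.D * x + p.E
    g = params.lower(organ) if rank <= max(ResponseParams.LOWER_RANKS) else params.upper(organ)
    if x <= 0:
        raise RegressorDomainError(
            f"regressor x={x} must be positive for the log term "
            f"(density {level.density}, mode {params.regressor_mode})"
        )
    return g.A * math.log(x) + g.B * rank + g.C


def apply_response(
    base: "BaseProfile",
    level: DensityLevel,
    params: ResponseParams | None = None,
) -> "BaseProfile":
    """Predict a full organ-size profile at ``level`` from the base profile.

    Each predicted size is ``base × (1 + Y/100)`` with Y from
    :func:`relative_change`; sizes floor at zero.  The returned profile is
    flagged with the target density.  At the reference density the output
    equals the base exactly.
    """
    if params is None:
        params = default_params()
    missing = [
        (r, o) for r in MODELED_RANKS for o in OrganDim if (r, o) not in base.entries
    ]
    if missing:
        raise MissingEntryError(missing)
    if level.density == level.reference_density:
        return base.with_entries(dict(base.entries), density=level.density)
    entries = {}
    for (rank, organ), size in base.entries.items():
        if rank not in MODELED_RANKS:
            entries[(rank, organ)] = size
            continue
        y = relative_change(organ, rank, level, params)
        entries[(rank, organ)] = max(0.0, size * (1.0 + y / 100.0))
    return base.with_entries(entries, density=level.density)


# --- fitting --------------------------------------------------------------


def fit_group(
    observations: Iterable[tuple[float, int, float]],
    model: str = "grouped",
) -> FitResult:
    """Fit response coefficients by ordinary least squares.

    Parameters
    ----------
    observations
        Triples ``(x, rank, y)``: density regressor, phytomer rank and
        observed percent change.
    model
        ``"grouped"`` fits Y = A·ln(x) + B·rank + C; ``"ear"`` fits
        Y = D·x + E (rank is ignored).

    Returns
    -------
    FitResult
        Coefficients, coefficient of determination R² = 1 − SSE/SST,
        residual sum of squares and the number of points.

    Notes
    -----
    The fit is unweighted and unregularized.  With SST = 0 (constant y),
    R² is defined as 1 when the residuals vanish and −inf otherwise.
    """
    obs = list(observations)
    x = np.array([o[0] for o in obs], dtype=float)
    rank = np.array([o[1] for o in obs], dtype=float)
    y = np.array([o[2] for o in obs], dtype=float)
    n = len(obs)

    if model == "grouped":
        if np.any(x <= 0):
            raise RegressorDomainError("grouped model needs x > 0 for ln(x)")
        if n < 3 or len(np.unique(x)) < 2 or len(np.unique(rank)) < 2:
            raise SingularDesignError(
                "grouped fit needs >= 3 points spanning >= 2 distinct x "
                "and >= 2 distinct ranks"
            )
        design = np.column_stack([np.log(x), rank, np.ones(n)])
    elif model == "ear":
        if n < 2 or len(np.unique(x)) < 2:
            raise SingularDesignError("ear fit needs >= 2 distinct x values")
        design = np.column_stack([x, np.ones(n)])
    else:
        raise ValueError(f"unknown model {model!r}")

    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularDesignError("design matrix is rank-deficient")

    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst > 0:
        r2 = 1.0 - sse / sst
    else:
        r2 = 1.0 if sse <= 1e-24 * max(1.0, float(y @ y)) else -math.inf

    if model == "grouped":
        params: GroupParams | EarParams = GroupParams(*map(float, coef))
    else:
        params = EarParams(*map(float, coef))
    return FitResult(params=params, r_squared=r2, n_points=n, residual_sse=sse)


def standard_errors(
    observations: Iterable[tuple[float, int, float]],
    model: str = "grouped",
) -> np.ndarray:
    """Standard errors of the OLS coefficients from ``fit_group``.

    Classical homoskedastic errors: sqrt of the diagonal of
    s²·(XᵀX)⁻¹ with s² = SSE/(n − p).
    """
    obs = list(observations)
    x = np.array([o[0] for o in obs], dtype=float)
    rank = np.array([o[1] for o in obs], dtype=float)
    y = np.array([o[2] for o in obs], dtype=float)
    if model == "grouped":
        design = np.column_stack([np.log(x), rank, np.ones(len(obs))])
    else:
        design = np.column_stack([x, np.ones(len(obs))])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = len(obs) - design.shape[1]
    if dof <= 0:
        return np.full(design.shape[1], np.nan)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(design.T @ design)
    return np.sqrt(np.diag(cov))


def percent_changes(
    table: pd.DataFrame,
    reference_density: float = REFERENCE_DENSITY,
    regressor_mode: str = "increment",
    reference_profile: "BaseProfile | None" = None,
) -> pd.DataFrame:
    """Per-rank percent changes of a measurement table vs its reference.

    Replicates are averaged per (density, rank, organ); the change of each
    elevated-density mean relative to the reference is expressed in
    percent.  The reference denominators come from the table's own rows at
    ``reference_density``, or — when the calibration profile is known
    separately — from ``reference_profile``'s entries.  Output columns:
    ``organ``, ``rank``, ``density``, ``x`` (regressor) and ``y`` (percent
    change) — the long-form input :func:`fit_group` consumes.
    """
    means = (
        table.groupby(["density", "rank", "organ"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    if reference_profile is not None:
        ref_map = {
            (r, o.value): v for (r, o), v in reference_profile.entries.items()
        }
    else:
        ref = means[np.isclose(means["density"], reference_density)]
        if ref.empty:
            raise ValueError(
                f"table has no rows at the reference density {reference_density}"
            )
        ref_map = {
            (r, o): v for r, o, v in zip(ref["rank"], ref["organ"], ref["value"])
        }
    rows = []
    for _, rec in means.iterrows():
        if np.isclose(rec["density"], reference_density):
            continue
        base = ref_map.get((rec["rank"], rec["organ"]))
        if base is None or base == 0:
            continue
        x = (
            rec["density"]
            if regressor_mode == "absolute"
            else rec["density"] - reference_density
        )
        rows.append(
            {
                "organ": rec["organ"],
                "rank": int(rec["rank"]),
                "density": float(rec["density"]),
                "x": float(x),
                "y": 100.0 * (rec["value"] - base) / base,
            }
        )
    return pd.DataFrame(rows, columns=["organ", "rank", "density", "x", "y"])


def fit_all_groups(changes: pd.DataFrame, ear_rank: int = 12) -> ResponseParams:
    """Refit the full parameterization from a percent-change table.

    ``changes`` is the output of :func:`percent_changes`.  Returns a
    :class:`ResponseParams` with one OLS fit per (organ, group).
    """
    organs = {}
    for organ in OrganDim:
        sub = changes[changes["organ"] == organ.value]
        lower = sub[sub["rank"].between(6, 11)]
        upper = sub[sub["rank"].between(13, 18)]
        ear = sub[sub["rank"] == ear_rank]
        lo = fit_group(zip(lower["x"], lower["rank"], lower["y"]), "grouped")
        up = fit_group(zip(upper["x"], upper["rank"], upper["y"]), "grouped")
        ea = fit_group(zip(ear["x"], ear["rank"], ear["y"]), "ear")
        organs[organ] = OrganResponse(lower=lo.params, ear=ea.params, upper=up.params)
    return ResponseParams(organs=organs, ear_rank=ear_rank)


# --- plain-text parameter serialization ----------------------------------


def params_to_text(params: ResponseParams) -> str:
    """Serialize a parameterization to flat key-value text.

    Float values are written with ``repr`` so the round-trip through
    :func:`params_from_text` is bit-exact.
    """
    lines = [
        f"ear_rank = {params.ear_rank}",
        f"regressor_mode = {params.regressor_mode}",
    ]
    for organ in OrganDim:
        resp = params.organs[organ]
        code = organ.value
        for name, val in (
            ("lower.A", resp.lower.A),
            ("lower.B", resp.lower.B),
            ("lower.C", resp.lower.C),
            ("ear.D", resp.ear.D),
            ("ear.E", resp.ear.E),
            ("upper.A", resp.upper.A),
            ("upper.B", resp.upper.B),
            ("upper.C", resp.upper.C),
        ):
            lines.append(f"{code}.{name} = {val!r}")
    return "\n".join(lines) + "\n"


def params_from_text(text: str) -> ResponseParams:
    """Parse the flat key-value format of :func:`params_to_text`.

    Unknown keys are errors (fail-fast); missing keys are errors too.
    """
    kv: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        kv[key.strip()] = val.strip()

    valid_keys = {"ear_rank", "regressor_mode"}
    for organ in OrganDim:
        for suffix in (
            "lower.A", "lower.B", "lower.C", "ear.D", "ear.E",
            "upper.A", "upper.B", "upper.C",
        ):
            valid_keys.add(f"{organ.value}.{suffix}")
    unknown = set(kv) - valid_keys
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    missing_keys = valid_keys - set(kv)
    if missing_keys:
        raise ValueError(f"missing parameter keys: {sorted(missing_keys)}")

    organs = {}
    for organ in OrganDim:
        c = organ.value
        organs[organ] = OrganResponse(
            lower=GroupParams(
                float(kv[f"{c}.lower.A"]),
                float(kv[f"{c}.lower.B"]),
                float(kv[f"{c}.lower.C"]),
            ),
            ear=EarParams(float(kv[f"{c}.ear.D"]), float(kv[f"{c}.ear.E"])),
            upper=GroupParams(
                float(kv[f"{c}.upper.A"]),
                float(kv[f"{c}.upper.B"]),
                float(kv[f"{c}.upper.C"]),
            ),
        )
    return ResponseParams(
        organs=organs,
        ear_rank=int(kv["ear_rank"]),
        regressor_mode=kv["regressor_mode"],
    )
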