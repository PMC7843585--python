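"""Simulation-observation agreement via normalized RMSE.

NRMSE = 100 x sqrt( mean((SIM_i - OBS_i)^2) ) / mean(OBS), in percent.
The root is over the mean-square term (RMSE semantics), then normalized by
the observed mean.  Quality bands: <=10 % excellent, 10-20 % good,
20-30 % fair, >30 % poor; exact band edges belong to the lower band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .density_response import MODELED_RANKS, OrganDim
from .canopy_geometry import BaseProfile, leaf_area, leaf_insertion_heights

log = logging.getLogger("maizecanopy")

QUALITY_BANDS = ((10.0, "excellent"), (20.0, "good"), (30.0, "fair"))


class EmptyComparisonError(ValueError):
    """No overlapping ranks between simulation and observation."""


def nrmse(sim: Sequence[float], obs: Sequence[float]) -> float:
    """Normalized root-mean-square error between two paired series, in %.

    Raises on length mismatch or a zero observed mean (degenerate
    normalization).  Invariant under joint positive rescaling of both
    series.
    """
    sim_a = np.asarray(sim, dtype=float)
    obs_a = np.asarray(obs, dtype=float)
    if sim_a.shape != obs_a.shape:
        raise ValueError(f"shape mismatch: sim {sim_a.shape} vs obs {obs_a.shape}")
    if sim_a.size == 0:
        raise ValueError("need at least one pair")
    mean_obs = obs_a.mean()
    if mean_obs == 0:
        raise ZeroDivisionError("observed mean is zero; NRMSE undefined")
    rmse = float(np.sqrt(np.mean((sim_a - obs_a) ** 2)))
    return 100.0 * rmse / mean_obs


def classify_nrmse(value: float) -> str:
    """Map an NRMSE percentage to its quality class."""
    if value < 0:
        raise ValueError("NRMSE cannot be negative")
    for edge, label in QUALITY_BANDS:
        if value <= edge:
            return label
    return "poor"


@dataclass(frozen=True)
class ValidationReport:
    """Per-(quantity, density) NRMSE with quality class.

    ``table`` has columns: quantity, density, nrmse, n, mean_observed,
    quality.  Quantities are the six organ codes plus derived LA (leaf
    area) and LIH (leaf insertion height) when derivable.
    """

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def pivot(self) -> pd.DataFrame:
        """Quantity rows x density columns of NRMSE values."""
        return self.table.pivot(index="quantity", columns="density", values="nrmse")


def _derived_series(
    profile_values: dict[str, dict[int, float]], shape_factor: float
) -> dict[str, dict[int, float]]:
    """LA and LIH per rank from LL/LW and IL rank series."""
    out: dict[str, dict[int, float]] = {}
    ll, lw, il = (
        profile_values.get("LL", {}),
        profile_values.get("LW", {}),
        profile_values.get("IL", {}),
    )
    la_ranks = sorted(set(ll) & set(lw))
    if la_ranks:
        out["LA"] = {r: leaf_area(ll[r], lw[r], shape_factor) for r in la_ranks}
    if il:
        # cumulative insertion height requires a contiguous run from rank 6
        ranks = sorted(il)
        if ranks and ranks[0] == MODELED_RANKS[0] and ranks == list(
            range(ranks[0], ranks[-1] + 1)
        ):
            total = 0.0
            lih = {}
            for r in ranks:
                total += il[r]
                lih[r] = total
            out["LIH"] = lih
    return out


def validate_profiles(
    simulated: BaseProfile,
    observed: pd.DataFrame,
    density: float | None = None,
    shape_factor: float = 0.75,
) -> ValidationReport:
    """NRMSE of a simulated profile against observed organ measurements.

    ``observed`` is a long-form measurement table (columns density,
    replicate, rank, organ, value).  Replicates are averaged per rank
    before pairing with the simulation.  LA and LIH are validated when
    LL/LW (respectively a contiguous IL series from rank 6) are present on
    both sides; otherwise they are skipped with a log note.
    """
    if density is None:
        density = simulated.density
    sub = observed[np.isclose(observed["density"].astype(float), density)]
    if sub.empty:
        raise EmptyComparisonError(
            f"no observations at density {density} plants/m^2"
        )
    obs_means = (
        sub.groupby(["organ", "rank"], sort=True)["value"].mean().reset_index()
    )

    obs_by_organ: dict[str, dict[int, float]] = {}
    for _, rec in obs_means.iterrows():
        obs_by_organ.setdefault(rec["organ"], {})[int(rec["rank"])] = float(
            rec["value"]
        )
    sim_by_organ: dict[str, dict[int, float]] = {
        o.value: {
            r: simulated.entries[(r, o)]
            for r in MODELED_RANKS
            if (r, o) in simulated.entries
        }
        for o in OrganDim
    }

    obs_all = dict(obs_by_organ)
    sim_all = dict(sim_by_organ)
    for side_src, side_dst in ((obs_by_organ, obs_all), (sim_by_organ, sim_all)):
        derived = _derived_series(side_src, shape_factor)
        for key in ("LA", "LIH"):
            if key in derived:
                side_dst[key] = derived[key]
            elif side_src is obs_by_organ:
                log.info("skipping %s validation: inputs incomplete", key)

    rows = []
    for quantity in [o.value for o in OrganDim] + ["LA", "LIH"]:
        sim_series = sim_all.get(quantity, {})
        obs_series = obs_all.get(quantity, {})
        ranks = sorted(set(sim_series) & set(obs_series))
        if not ranks:
            continue
        sim_v = [sim_series[r] for r in ranks]
        obs_v = [obs_series[r] for r in ranks]
        value = nrmse(sim_v, obs_v)
        rows.append(
            {
                "quantity": quantity,
                "density": density,
                "nrmse": value,
                "n": len(ranks),
                "mean_observed": float(np.mean(obs_v)),
                "quality": classify_nrmse(value),
            }
        )
    if not rows:
        raise EmptyComparisonError("no overlapping (organ, rank) pairs")
    return ValidationReport(pd.DataFrame(rows))
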