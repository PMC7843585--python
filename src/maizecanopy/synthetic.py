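"""Synthetic base profiles and field-trial observation tables.

The reference-density organ sizes of the studied hybrid exist only as
figure columns, so testing end-to-end requires a realistic stand-in: each
organ's size over phytomer ranks 6-18 follows a Gaussian-in-rank bump
(bell-shaped profiles are what maize rank series look like), and noisy
multi-density observation tables are sampled around the density-response
model's predictions with multiplicative Gaussian noise, mirroring the
trial's structure of 3 replicates x 5 densities {4.5, 6, 7.5, 9, 15}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .density_response import (
    MODELED_RANKS,
    REFERENCE_DENSITY,
    TRIAL_DENSITIES,
    DensityLevel,
    OrganDim,
    ResponseParams,
    apply_response,
    default_params,
)
from .canopy_geometry import BaseProfile

log = logging.getLogger("maizecanopy")

#: Per-organ (peak size cm, peak rank, width in ranks) of the synthetic
#: reference profile.  Peaks are plausible for a modern dent hybrid at low
#: density; widths set how quickly the bell decays away from the peak.
DEFAULT_ORGAN_SHAPES: dict[str, tuple[float, float, float]] = {
    "LL": (80.0, 12.0, 4.0),
    "LW": (10.0, 13.0, 5.0),
    "SL": (18.0, 10.0, 5.0),
    "SW": (3.0, 10.0, 6.0),
    "IL": (14.0, 14.0, 5.0),
    "ID": (2.2, 8.0, 8.0),
}


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic generator.

    ``organ_shapes`` maps organ code to (peak cm, peak rank, width ranks);
    ``noise_sd_percent`` is the standard deviation of the multiplicative
    observation noise in percent of the true size.
    """

    organ_shapes: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_SHAPES)
    )
    noise_sd_percent: float = 2.0
    replicates: int = 3
    densities: Sequence[float] = TRIAL_DENSITIES
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        for code, (peak, peak_rank, width) in self.organ_shapes.items():
            OrganDim(code)  # raises on unknown codes
            if peak <= 0:
                raise ValueError(f"{code}: peak size must be positive")
            if not MODELED_RANKS[0] <= peak_rank <= MODELED_RANKS[-1]:
                raise ValueError(f"{code}: peak rank must lie in 6-18")
            if width <= 0:
                raise ValueError(f"{code}: width must be positive")
        missing = {o.value for o in OrganDim} - set(self.organ_shapes)
        if missing:
            raise ValueError(f"organ_shapes missing organs: {sorted(missing)}")
        if self.noise_sd_percent < 0:
            raise ValueError("noise_sd_percent must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if any(d <= 0 for d in self.densities):
            raise ValueError("densities must be positive")


def generate_base_profile(config: SynthConfig | None = None) -> BaseProfile:
    """Deterministic bell-shaped reference profile at 4.5 plants m⁻².

    size(rank) = peak x exp(-(rank - peak_rank)^2 / (2 width^2)) per organ.
    """
    if config is None:
        config = SynthConfig()
    entries = {}
    for code, (peak, peak_rank, width) in config.organ_shapes.items():
        organ = OrganDim(code)
        for rank in MODELED_RANKS:
            entries[(rank, organ)] = peak * float(
                np.exp(-((rank - peak_rank) ** 2) / (2.0 * width**2))
            )
    return BaseProfile(density=REFERENCE_DENSITY, entries=entries)


def generate_observations(
    base: BaseProfile,
    params: ResponseParams | None = None,
    config: SynthConfig | None = None,
) -> pd.DataFrame:
    """Long-form noisy observation table across densities and replicates.

    Each record is the model prediction at its density times (1 + eps),
    eps ~ Normal(0, noise_sd_percent/100), truncated at zero (truncations
    are logged).  Noise streams are derived per density from the master
    seed, so adding a density leaves other densities' draws unchanged.
    Columns: label, density, replicate, rank, organ, value.
    """
    if params is None:
        params = default_params()
    if config is None:
        config = SynthConfig()
    sd = config.noise_sd_percent / 100.0
    streams = np.random.SeedSequence(config.seed).spawn(len(config.densities))
    rows = []
    truncated = 0
    for density, stream in zip(config.densities, streams):
        rng = np.random.default_rng(stream)
        predicted = apply_response(base, DensityLevel(density), params)
        for replicate in range(1, config.replicates + 1):
            for rank in MODELED_RANKS:
                for organ in OrganDim:
                    true = predicted.entries[(rank, organ)]
                    eps = rng.normal(0.0, sd) if sd > 0 else 0.0
                    value = true * (1.0 + eps)
                    if value < 0:
                        truncated += 1
                        value = 0.0
                    rows.append(
                        {
                            "label": config.label,
                            "density": float(density),
                            "replicate": replicate,
                            "rank": rank,
                            "organ": organ.value,
                            "value": value,
                        }
                    )
    if truncated:
        log.warning("%d synthetic values truncated at zero", truncated)
    return pd.DataFrame(
        rows, columns=["label", "density", "replicate", "rank", "organ", "value"]
    )
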