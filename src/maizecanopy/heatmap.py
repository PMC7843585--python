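"""Heatmaps of organ-size percent change across density steps.

Two framings are exposed: the successive-transition matrix (change of each
density level relative to the previous level: 4.5->6, 6->7.5, 7.5->9,
9->15 by default) used for the canopy-overview heatmap, and a
reference-change variant (every level relative to the reference density)
that matches the framing the regression model is fitted in.  Rendering
uses a diverging red->green scale with fixed limits of -16 to +10 % by
default; out-of-range values are clamped to the limits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .density_response import MODELED_RANKS, OrganDim
from .canopy_geometry import BaseProfile

log = logging.getLogger("maizecanopy")

#: Fixed color limits of the diverging scale, percent change.
DEFAULT_SCALE_LIMITS = (-16.0, 10.0)


@dataclass(frozen=True)
class ChangeMatrix:
    """Percent-change matrix for one organ: ranks x density transitions.

    Rows are phytomer ranks (top of the plant first by default); columns
    are labelled density transitions.  Cells where the denominator size is
    zero are NaN (flagged missing, not an error).
    """

    organ: OrganDim
    data: pd.DataFrame  # index: rank, columns: transition labels

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="rank")


def _change_frame(
    profiles: Sequence[BaseProfile],
    organ: OrganDim,
    pairs: Sequence[tuple[int, int]],
    labels: Sequence[str],
    top_rank_first: bool,
) -> pd.DataFrame:
    ranks = list(MODELED_RANKS)
    if top_rank_first:
        ranks = ranks[::-1]
    cols = {}
    for (i, j), label in zip(pairs, labels):
        col = []
        for rank in ranks:
            prev = profiles[i].entries[(rank, organ)]
            nxt = profiles[j].entries[(rank, organ)]
            if prev == 0:
                log.warning(
                    "zero %s size at rank %d in the %s denominator; "
                    "cell flagged missing",
                    organ.value,
                    rank,
                    label,
                )
                col.append(np.nan)
            else:
                col.append(100.0 * (nxt - prev) / prev)
        cols[label] = col
    return pd.DataFrame(cols, index=pd.Index(ranks, name="rank"))


def _check_profiles(profiles: Sequence[BaseProfile]) -> None:
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    densities = [p.density for p in profiles]
    if not all(b > a for a, b in zip(densities, densities[1:])):
        raise ValueError(f"densities must strictly increase, got {densities}")
    for p in profiles:
        p.require_complete()


def successive_change_matrix(
    profiles: Sequence[BaseProfile], top_rank_first: bool = True
) -> dict[OrganDim, ChangeMatrix]:
    """Per-organ change of each density level relative to the previous one.

    With the five trial densities this yields 13 x 4 matrices (transitions
    4.5->6, 6->7.5, 7.5->9, 9->15).
    """
    _check_profiles(profiles)
    pairs = [(i, i + 1) for i in range(len(profiles) - 1)]
    labels = [
        f"{profiles[i].density:g}→{profiles[j].density:g}" for i, j in pairs
    ]
    return {
        organ: ChangeMatrix(
            organ, _change_frame(profiles, organ, pairs, labels, top_rank_first)
        )
        for organ in OrganDim
    }


def reference_change_matrix(
    profiles: Sequence[BaseProfile], top_rank_first: bool = True
) -> dict[OrganDim, ChangeMatrix]:
    """Per-organ change of each elevated density relative to the first
    (reference) profile — the framing the response regressions use."""
    _check_profiles(profiles)
    pairs = [(0, j) for j in range(1, len(profiles))]
    labels = [
        f"{profiles[0].density:g}→{profiles[j].density:g}" for _, j in pairs
    ]
    return {
        organ: ChangeMatrix(
            organ, _change_frame(profiles, organ, pairs, labels, top_rank_first)
        )
        for organ in OrganDim
    }


_ORGAN_TITLES = {
    OrganDim.LL: "Lamina length",
    OrganDim.LW: "Lamina width",
    OrganDim.SL: "Sheath length",
    OrganDim.SW: "Sheath width",
    OrganDim.IL: "Internode length",
    OrganDim.ID: "Internode diameter",
}


def render_heatmap(
    matrices: Mapping[OrganDim, ChangeMatrix],
    path,
    base_profile: BaseProfile | None = None,
    limits: tuple[float, float] = DEFAULT_SCALE_LIMITS,
) -> "plt.Figure":
    """Render per-organ percent-change panels to an image file.

    One panel per organ, diverging red-to-green colormap with color limits
    fixed at ``limits`` (default -16 to +10 %); values beyond the limits
    render at the clamp color.  When ``base_profile`` is given, its
    absolute reference-density sizes are printed as a first numeric column
    next to the rank axis.
    """
    if not matrices:
        raise ValueError("no matrices to render")
    organs = [o for o in OrganDim if o in matrices]
    n = len(organs)
    ncols = min(3, n)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4.2 * ncols, 3.6 * nrows), squeeze=False
    )
    vmin, vmax = limits
    im = None
    for ax, organ in zip(axes.flat, organs):
        frame = matrices[organ].data
        values = np.clip(frame.to_numpy(dtype=float), vmin, vmax)
        im = ax.imshow(
            values, cmap="RdYlGn", vmin=vmin, vmax=vmax, aspect="auto"
        )
        ax.set_title(f"{_ORGAN_TITLES[organ]} ({organ.value})", fontsize=9)
        ax.set_xticks(range(frame.shape[1]))
        ax.set_xticklabels(frame.columns, fontsize=7, rotation=30)
        ax.set_yticks(range(frame.shape[0]))
        ylabels = [str(r) for r in frame.index]
        if base_profile is not None:
            ylabels = [
                f"{r}  {base_profile.entries[(r, organ)]:.1f}" for r in frame.index
            ]
        ax.set_yticklabels(ylabels, fontsize=7)
        ax.set_ylabel("phytomer rank (base size, cm)" if base_profile else "rank",
                      fontsize=8)
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    fig.colorbar(
        im, ax=axes, shrink=0.8, label="change (%)", orientation="horizontal",
        fraction=0.05,
    )
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return fig
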