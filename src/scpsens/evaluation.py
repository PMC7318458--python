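"""Gap analysis: how well a protected-area network captures priorities.

Three complementary statistics compare a priority rank raster with a
binary PA mask: the point-biserial correlation between rank and protected
status, the Jaccard overlap between the PA network and an equal-area set
of top-ranked cells, and Kendall's tau between rank bins and the fraction
of each bin that is protected. A fourth operation selects expansion sites:
the best unprotected cells needed to reach an area target (e.g. 17% of
the landscape) once existing PAs are locked into the solution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .prioritiser import PriorityRanking

logger = logging.getLogger(__name__)

__all__ = [
    "GapReport",
    "point_biserial",
    "jaccard_top_overlap",
    "protection_by_rank_bins",
    "expansion_sites",
    "summed_top_rankings",
    "gap_report",
]


def _rank_and_pa(rank: np.ndarray, pa_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rank = np.asarray(rank, dtype=np.float64)
    pa = np.asarray(pa_mask, dtype=bool)
    if rank.shape != pa.shape:
        raise ValueError("rank raster and PA mask shapes differ")
    m = np.isfinite(rank)
    return rank[m], pa[m]


def point_biserial(rank: np.ndarray, pa_mask: np.ndarray) -> float:
    """Pearson correlation between priority rank and the 0/1 PA indicator."""
    r, pa = _rank_and_pa(rank, pa_mask)
    if pa.all() or not pa.any():
        raise ValueError("PA indicator has zero variance (all or no cells protected)")
    return float(stats.pearsonr(r, pa.astype(np.float64)).statistic)


def jaccard_top_overlap(rank: np.ndarray, pa_mask: np.ndarray) -> float:
    """Jaccard similarity of the PA set and the equal-area top-rank set."""
    r, pa = _rank_and_pa(rank, pa_mask)
    n_pa = int(pa.sum())
    if n_pa == 0:
        raise ValueError("PA mask is empty")
    # the n_pa highest-ranked cells; ties broken by cell order for determinism
    top_idx = np.lexsort((np.arange(r.size), -r))[:n_pa]
    top = np.zeros(r.size, dtype=bool)
    top[top_idx] = True
    inter = (top & pa).sum()
    union = (top | pa).sum()
    return float(inter / union)


def protection_by_rank_bins(
    rank: np.ndarray, pa_mask: np.ndarray, bin_width: float = 0.01
) -> tuple[pd.DataFrame, float]:
    """Fraction protected per rank interval, and its Kendall trend.

    Ranks in (0, 1] are cut into equal-width intervals; for each the
    proportion of cells inside PAs is computed. Kendall's tau-b between
    bin midpoint and protected fraction summarises whether protection
    increases towards the high-priority end. Empty bins are dropped; a
    constant protected fraction leaves tau undefined (NaN).
    """
    if not 0 < bin_width <= 0.5:
        raise ValueError("bin_width must be in (0, 0.5]")
    r, pa = _rank_and_pa(rank, pa_mask)
    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # ranks are in (0,1]: right-closed intervals
    idx = np.clip(np.searchsorted(edges, r, side="left") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    protected = np.bincount(idx, weights=pa.astype(float), minlength=n_bins)
    keep = counts > 0
    mid = (edges[:-1] + edges[1:]) / 2.0
    frac = np.divide(protected, counts, out=np.zeros(n_bins), where=keep)
    bins = pd.DataFrame(
        {
            "bin_low": edges[:-1][keep],
            "bin_high": edges[1:][keep],
            "bin_mid": mid[keep],
            "n_cells": counts[keep],
            "fraction_protected": frac[keep],
        }
    )
    if bins["fraction_protected"].nunique() < 2:
        logger.info("protected fraction constant across bins; tau undefined")
        tau = float("nan")
    else:
        tau = float(
            stats.kendalltau(bins["bin_mid"], bins["fraction_protected"]).statistic
        )
    return bins, tau


def expansion_sites(
    ranking: PriorityRanking, pa_mask: np.ndarray, target_fraction: float = 0.17
) -> np.ndarray:
    """Unprotected cells of the top ``target_fraction`` of a PA-forced ranking.

    ``ranking`` must come from a run where PAs were forced to the highest
    priority, so the top set contains the whole network plus the best
    candidate cells to expand it to the area target. Returns a boolean
    raster of the expansion cells (top set minus PAs).
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0,1]")
    pa = np.asarray(pa_mask, dtype=bool)
    top = ranking.top_mask(target_fraction)
    n_valid = ranking.grid.n_valid
    if pa.sum() >= target_fraction * n_valid:
        logger.warning("PA network already meets the area target; nothing to add")
        return np.zeros_like(pa)
    return top & ~pa


def summed_top_rankings(
    ranks: list[np.ndarray], top_fraction: float = 0.17
) -> np.ndarray:
    """Cell-wise sum of rank rasters thresholded to their top fraction.

    Cells outside a raster's top set contribute 0; the result highlights
    cells that several surrogate-specific solutions agree on.
    """
    if not ranks:
        raise ValueError("need at least one rank raster")
    shape = ranks[0].shape
    out = np.zeros(shape, dtype=np.float64)
    for r in ranks:
        r = np.asarray(r, dtype=np.float64)
        if r.shape != shape:
            raise ValueError("rank rasters are not co-registered")
        thresholded = np.where(
            np.isfinite(r) & (r > (1.0 - top_fraction) + 1e-12), r, 0.0
        )
        out += thresholded
    return out


@dataclass
class GapReport:
    """Summary statistics of one gap analysis."""

    point_biserial_r: float
    jaccard: float
    kendall_tau: float
    bins: pd.DataFrame
    expansion_cells: np.ndarray | None = None

    def to_dict(self) -> dict[str, float]:
        return {
            "point_biserial_r": self.point_biserial_r,
            "jaccard": self.jaccard,
            "kendall_tau": self.kendall_tau,
        }


def gap_report(
    rank: np.ndarray,
    pa_mask: np.ndarray,
    bin_width: float = 0.01,
    forced_ranking: PriorityRanking | None = None,
    target_fraction: float = 0.17,
) -> GapReport:
    """Run the three PA-assessment statistics (and optionally expansion)."""
    bins, tau = protection_by_rank_bins(rank, pa_mask, bin_width)
    expansion = (
        expansion_sites(forced_ranking, pa_mask, target_fraction)
        if forced_ranking is not None
        else None
    )
    return GapReport(
        point_biserial_r=point_biserial(rank, pa_mask),
        jaccard=jaccard_top_overlap(rank, pa_mask),
        kendall_tau=tau,
        bins=bins,
        expansion_cells=expansion,
    )
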