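"""Recall-driven reactivation of encoding-labelled cells, tested vs chance.

Reactivation (co-positivity) is the fraction of encoding-labelled
(tdTomato+) cells whose centre falls inside a high-intensity area of the
recall cFos staining channel, thresholded at 0.6 on an intensity probability
map.  The chance level under independence is the recall-active fraction of
all neurons (cFos+ count over NeuN+ count) per region; significance is a
two-tailed one-sample t-test of per-subject percentages against that chance
level, with the mean required to exceed chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.base import BaseEstimator

from .detection import CellCentroid
from .volume import ImageVolume

DEFAULT_THRESHOLD = 0.6


@dataclass
class IntensityProbabilityMap:
    """cFos-channel foreground probability in [0, 1] with its threshold."""

    data: np.ndarray
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("probability map values must lie in [0, 1]")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")


def build_probability_map(
    cfos_volume: ImageVolume,
    smoothing_sigma: float = 2.0,
    threshold: float = DEFAULT_THRESHOLD,
    quantiles: tuple[float, float] = (1.0, 99.9),
    norm_range: tuple[float, float] | None = None,
) -> IntensityProbabilityMap:
    """Smooth and quantile-normalise the cFos channel to [0, 1].

    The default mapping sends the 1st percentile of the smoothed intensities
    to 0 and the 99.9th to 1 (clipped), which is monotone in intensity;
    ``norm_range`` supplies fixed normalisation bounds instead (e.g. to apply
    one volume's quantiles to another).  A constant volume maps to all zeros.
    """
    if smoothing_sigma > 0:
        sig = tuple(smoothing_sigma / v for v in cfos_volume.voxel_size)
        sm = ndimage.gaussian_filter(cfos_volume.data.astype(float), sigma=sig)
    else:
        sm = cfos_volume.data.astype(float)
    if norm_range is None:
        lo, hi = np.percentile(sm, quantiles)
    else:
        lo, hi = norm_range
    if hi <= lo:
        return IntensityProbabilityMap(np.zeros_like(sm), threshold)
    return IntensityProbabilityMap(np.clip((sm - lo) / (hi - lo), 0.0, 1.0), threshold)


def overlap_fraction(
    tdtomato_centroids: Sequence[CellCentroid] | Sequence[tuple[int, int, int]],
    pmap: IntensityProbabilityMap,
    threshold: float | None = None,
) -> tuple[int, float]:
    """Count centroids sitting on high-probability cFos voxels.

    Membership is the map value at the centre voxel >= threshold (no dilation
    radius).  Returns ``(n_overlap, reactivation_pct)``; an empty centroid
    list leaves the percentage undefined (NaN).
    """
    thr = pmap.threshold if threshold is None else threshold
    positions = [
        c.position if isinstance(c, CellCentroid) else tuple(int(v) for v in c)
        for c in tdtomato_centroids
    ]
    if not positions:
        return 0, float("nan")
    n_overlap = sum(1 for p in positions if pmap.data[p] >= thr)
    return n_overlap, 100.0 * n_overlap / len(positions)


def chance_level(n_cfos_recall: int, n_neun: int) -> float:
    """Chance reactivation percentage: recall-active fraction of all neurons."""
    if n_neun <= 0:
        raise ValueError("n_neun must be > 0")
    if n_cfos_recall > n_neun:
        raise ValueError(f"n_cfos_recall ({n_cfos_recall}) > n_neun ({n_neun})")
    if n_cfos_recall < 0:
        raise ValueError("n_cfos_recall must be >= 0")
    return 100.0 * n_cfos_recall / n_neun


def test_reactivation(
    per_subject_pcts: Sequence[float], chance_pct: float, alpha: float = 0.05
) -> tuple[float, float, bool, bool]:
    """Two-tailed one-sample t-test of subject percentages against chance.

    Returns ``(t_stat, p_value, significant, degenerate)``; significance
    additionally requires the mean to exceed chance.  Zero variance across
    subjects short-circuits: p = 1 (t = 0) when the common value equals
    chance, otherwise the result is flagged degenerate.
    """
    vals = np.asarray(per_subject_pcts, dtype=float)
    if len(vals) < 2:
        raise ValueError("need >= 2 subjects for the one-sample t-test")
    if np.ptp(vals) == 0:
        if vals[0] == chance_pct:
            return 0.0, 1.0, False, False
        return float("nan"), float("nan"), False, True
    res = stats.ttest_1samp(vals, popmean=chance_pct, alternative="two-sided")
    significant = bool(res.pvalue < alpha and vals.mean() > chance_pct)
    return float(res.statistic), float(res.pvalue), significant, False


def list_consistency(list_a: Iterable, list_b: Iterable) -> float:
    """Fraction of regions in A that also appear in B: |A & B| / |A|."""
    a, b = set(list_a), set(list_b)
    if not a:
        raise ValueError("list A must be non-empty")
    return len(a & b) / len(a)


class ReactivationAnalyzer(BaseEstimator):
    """Per-region reactivation statistics from a per-subject overlap table.

    ``fit`` expects tidy rows (region_id, subject_id, n_tdtomato, n_overlap,
    n_cfos_recall, n_neun), as produced by the synthetic generator or by
    region-wise aggregation of detections against a thresholded probability
    map.  Chance levels pool the cFos/NeuN counts across subjects per region.

    Attributes (after ``fit``)
    --------------------------
    results_ : ranked per-region table (reactivation_pct descending) with
        chance_pct, t_stat, p_value, significant and degenerate flags.
    significant_regions_ : set of region ids passing the test.
    n_regions_, n_significant_ : partition bookkeeping.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, table: pd.DataFrame) -> "ReactivationAnalyzer":
        rows = []
        for region, grp in table.groupby("region_id", sort=True):
            n_td = grp["n_tdtomato"].to_numpy(dtype=float)
            n_ov = grp["n_overlap"].to_numpy(dtype=float)
            valid = n_td > 0
            pcts = 100.0 * n_ov[valid] / n_td[valid]
            chance = chance_level(int(grp["n_cfos_recall"].sum()), int(grp["n_neun"].sum()))
            if len(pcts) < 2:
                rows.append((region, n_td.sum(), n_ov.sum(), np.nan, chance, np.nan, np.nan, False, True))
                continue
            t, p, sig, degen = test_reactivation(pcts, chance, alpha=self.alpha)
            rows.append((region, n_td.sum(), n_ov.sum(), float(pcts.mean()), chance, t, p, sig, degen))
        res = pd.DataFrame(
            rows,
            columns=[
                "region_id", "n_tdtomato", "n_overlap", "reactivation_pct",
                "chance_pct", "t_stat", "p_value", "significant", "degenerate",
            ],
        )
        res = res.sort_values(
            ["significant", "reactivation_pct"], ascending=[False, False], kind="mergesort"
        ).reset_index(drop=True)
        self.results_ = res
        self.significant_regions_ = set(res.loc[res["significant"], "region_id"])
        self.n_regions_ = int(len(res))
        self.n_significant_ = int(res["significant"].sum())
        return self
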