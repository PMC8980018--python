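"""Downstream cFos responses to engram-cell manipulations.

Given per-region, per-subject cFos+ densities (cells per mm^2) for a control
and a manipulation group (optogenetic/chemogenetic activation or inhibition,
or natural recall vs neutral context), this module computes the group-mean
ratio per region, an unpaired two-tailed t-test, a tri-level
increase/no_change/decrease call, heat-map export of signed significance
tiers, Pearson correlation between manipulation-driven and natural-recall
activation patterns, and the set of calls unique to the engram contrast
relative to a random-labelling control contrast.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

CALLS = ("increase", "decrease", "no_change")


def region_calls(counts: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-region ratio, p-value and tri-level call.

    ``counts`` is tidy with columns (region_id, subject_id, group, value),
    group in {control, manipulation}.  ratio = mean(manipulation) /
    mean(control); call requires p < alpha from an unpaired two-tailed
    t-test.  A zero control mean leaves the ratio undefined (flagged).
    """
    rows = []
    for region, grp in counts.groupby("region_id", sort=True):
        ctrl = grp.loc[grp["group"] == "control", "value"].to_numpy(dtype=float)
        manip = grp.loc[grp["group"] == "manipulation", "value"].to_numpy(dtype=float)
        if len(ctrl) < 2 or len(manip) < 2:
            raise ValueError(f"region {region!r}: need >= 2 subjects per group")
        undefined = ctrl.mean() == 0
        ratio = np.nan if undefined else manip.mean() / ctrl.mean()
        if np.ptp(np.concatenate([ctrl, manip])) == 0:
            rows.append((region, ratio, np.nan, np.nan, "no_change", undefined, True))
            continue
        res = stats.ttest_ind(manip, ctrl, equal_var=True)
        p = float(res.pvalue)
        if p < alpha and manip.mean() > ctrl.mean():
            call = "increase"
        elif p < alpha and manip.mean() < ctrl.mean():
            call = "decrease"
        else:
            call = "no_change"
        rows.append((region, ratio, float(res.statistic), p, call, undefined, False))
    return pd.DataFrame(
        rows,
        columns=["region_id", "ratio", "t_stat", "p_value", "call", "ratio_undefined", "degenerate"],
    )


def pattern_correlation(
    ratios_manipulation: Sequence[float] | Mapping, ratios_recall: Sequence[float] | Mapping
) -> tuple[float, float]:
    """Pearson r (and two-tailed p) between paired per-region ratios.

    Mappings are aligned on their shared keys; sequences must already be
    paired.  Requires >= 3 shared finite pairs and nonzero variance.
    """
    if isinstance(ratios_manipulation, Mapping) and isinstance(ratios_recall, Mapping):
        keys = sorted(set(ratios_manipulation) & set(ratios_recall))
        a = np.asarray([ratios_manipulation[k] for k in keys], dtype=float)
        b = np.asarray([ratios_recall[k] for k in keys], dtype=float)
    else:
        a = np.asarray(ratios_manipulation, dtype=float)
        b = np.asarray(ratios_recall, dtype=float)
        if len(a) != len(b):
            raise ValueError("paired ratio vectors must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError("need >= 3 shared regions with defined ratios")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a ratio vector; correlation undefined")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def significance_tier(p: float, ratio: float) -> int:
    """Signed heat-map tier: +/-1, 2, 3 for p < 0.05, 0.01, 0.001; else 0."""
    if not np.isfinite(p) or p >= 0.05 or not np.isfinite(ratio):
        return 0
    tier = 3 if p < 0.001 else 2 if p < 0.01 else 1
    return tier if ratio > 1 else -tier


def heatmap_table(calls_by_contrast: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Region x contrast table of ratios and signed significance tiers."""
    pieces = []
    for contrast, calls in calls_by_contrast.items():
        df = calls.set_index("region_id")
        pieces.append(
            pd.DataFrame(
                {
                    f"{contrast}_ratio": df["ratio"],
                    f"{contrast}_tier": [
                        significance_tier(p, r) for p, r in zip(df["p_value"], df["ratio"])
                    ],
                }
            )
        )
    return pd.concat(pieces, axis=1).reset_index()


def save_heatmap_png(table: pd.DataFrame, path: str | Path) -> None:
    """Render the signed-tier heat map (red = increase, blue = decrease)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tiers = table[[c for c in table.columns if c.endswith("_tier")]]
    fig, ax = plt.subplots(figsize=(1 + 0.6 * tiers.shape[1], 1 + 0.25 * len(table)))
    im = ax.imshow(tiers.to_numpy(dtype=float), cmap="bwr_r", vmin=-3, vmax=3, aspect="auto")
    ax.set_yticks(range(len(table)), table["region_id"].astype(str))
    ax.set_xticks(range(tiers.shape[1]), [c[: -len("_tier")] for c in tiers.columns], rotation=45, ha="right")
    fig.colorbar(im, ax=ax, label="signed significance tier")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def engram_specific_set(engram_calls: pd.DataFrame, random_control_calls: pd.DataFrame) -> set:
    """Regions with a directional call in the engram contrast that the
    random-labelling control contrast does not reproduce."""
    eng = engram_calls.set_index("region_id")["call"]
    rnd = random_control_calls.set_index("region_id")["call"]
    out = set()
    for region, call in eng.items():
        if call == "no_change":
            continue
        if region not in rnd.index or rnd[region] != call:
            out.add(region)
    return out


class ManipulationContrast(BaseEstimator):
    """Fit-shaped wrapper: per-region calls for one control-vs-manipulation
    contrast.

    Attributes (after ``fit``): ``calls_`` (region table), ``increased_`` and
    ``decreased_`` region sets.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, counts: pd.DataFrame) -> "ManipulationContrast":
        self.calls_ = region_calls(counts, alpha=self.alpha)
        self.increased_ = set(self.calls_.loc[self.calls_["call"] == "increase", "region_id"])
        self.decreased_ = set(self.calls_.loc[self.calls_["call"] == "decrease", "region_id"])
        return self
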