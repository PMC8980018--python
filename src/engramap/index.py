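"""Significance gating and the engram-index ranking statistic.

A region qualifies as a "significant brain region" when its activated-cell
counts in both the encoding (CFC) and recall (RE) cohorts are individually
significantly greater than home cage (one-way ANOVA followed by Tukey HSD
pairwise comparisons, subject as the replicate unit).  For those regions the
engram index

    index = log10( |mu_CFC - mu_HC| / |mu_CFC - mu_RE| )

ranks candidates: the numerator rewards a strong encoding response over home
cage, the denominator penalises encoding/recall mismatch — which demotes
regions that respond to the foot shocks at encoding but are not re-engaged by
recall.  A zero numerator or denominator leaves the index undefined; such
regions are flagged and listed after the ranked entries, never epsilon-padded.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests


def engram_index(mean_hc: float, mean_cfc: float, mean_re: float) -> float:
    """log10(|mu_CFC - mu_HC| / |mu_CFC - mu_RE|); NaN when undefined.

    Undefined when the denominator is zero (CFC and RE means equal) or the
    numerator is zero (no encoding response).  Negative or non-finite means
    raise.
    """
    means = (mean_hc, mean_cfc, mean_re)
    if any(not math.isfinite(m) or m < 0 for m in means):
        raise ValueError(f"means must be finite and >= 0, got {means}")
    num = abs(mean_cfc - mean_hc)
    den = abs(mean_cfc - mean_re)
    if den == 0 or num == 0:
        return float("nan")
    return math.log10(num / den)


def gate_significant_regions(
    table: pd.DataFrame, alpha: float = 0.05, bh: bool = False, log1p: bool = False
) -> pd.DataFrame:
    """Per-region ANOVA + Tukey gate over the three behavioural cohorts.

    Returns one row per region with cohort means, the omnibus ANOVA p, both
    Tukey pairwise p-values against home cage, and the ``significant`` flag
    (both CFC-HC and RE-HC pairwise-significant with positive differences).
    Regions with no within-region variance are reported non-significant with
    ``degenerate=True``.  ``bh`` applies Benjamini-Hochberg across regions to
    each pairwise family (opt-in; the default mirrors per-region testing
    without cross-region correction).  ``log1p`` runs the tests on
    log1p-transformed counts.
    """
    rows = []
    for region, grp in table.groupby("region_id", sort=True):
        samples = {}
        for cohort in ("HC", "CFC", "RE"):
            vals = grp.loc[grp["cohort"] == cohort, "count"].to_numpy(dtype=float)
            if len(vals) < 2:
                raise ValueError(f"region {region!r}: cohort {cohort} needs >= 2 subjects")
            samples[cohort] = np.log1p(vals) if log1p else vals
        hc, cfc, re = samples["HC"], samples["CFC"], samples["RE"]
        raw = grp.groupby("cohort")["count"].mean()
        mean_hc, mean_cfc, mean_re = raw["HC"], raw["CFC"], raw["RE"]
        allv = np.concatenate([hc, cfc, re])
        if np.ptp(allv) == 0 or (np.ptp(hc) == 0 and np.ptp(cfc) == 0 and np.ptp(re) == 0):
            rows.append((region, mean_hc, mean_cfc, mean_re, np.nan, np.nan, np.nan, False, True))
            continue
        anova_p = float(stats.f_oneway(hc, cfc, re).pvalue)
        tuk = stats.tukey_hsd(hc, cfc, re)
        p_cfc_hc = float(tuk.pvalue[0, 1])
        p_re_hc = float(tuk.pvalue[0, 2])
        rows.append((region, mean_hc, mean_cfc, mean_re, anova_p, p_cfc_hc, p_re_hc, False, False))
    out = pd.DataFrame(
        rows,
        columns=[
            "region_id", "mean_hc", "mean_cfc", "mean_re",
            "anova_p", "tukey_p_cfc_hc", "tukey_p_re_hc", "significant", "degenerate",
        ],
    )
    p_cfc = out["tukey_p_cfc_hc"].to_numpy(copy=True)
    p_re = out["tukey_p_re_hc"].to_numpy(copy=True)
    if bh:
        for arr in (p_cfc, p_re):
            ok = np.isfinite(arr)
            if ok.any():
                arr[ok] = multipletests(arr[ok], method="fdr_bh")[1]
        out["tukey_p_cfc_hc_bh"] = p_cfc
        out["tukey_p_re_hc_bh"] = p_re
    sig = (
        (p_cfc < alpha)
        & (p_re < alpha)
        & (out["mean_cfc"] > out["mean_hc"])
        & (out["mean_re"] > out["mean_hc"])
        & ~out["degenerate"]
    )
    out["significant"] = np.nan_to_num(sig, nan=False).astype(bool)
    return out


def compute_indices(gating: pd.DataFrame) -> pd.DataFrame:
    """Engram index for each gated (significant) region; others NaN."""
    out = gating.copy()
    vals = []
    for _, row in out.iterrows():
        if row["significant"]:
            vals.append(engram_index(row["mean_hc"], row["mean_cfc"], row["mean_re"]))
        else:
            vals.append(float("nan"))
    out["index"] = vals
    out["defined"] = out["significant"] & np.isfinite(out["index"])
    return out


def rank_regions(
    indexed: pd.DataFrame, acronyms: Mapping | None = None
) -> pd.DataFrame:
    """Rank significant regions by descending index.

    Ties break by acronym ascending (region_id when no acronym map is given);
    significant regions with an undefined index are listed after the ranked
    entries with rank NaN.
    """
    sig = indexed.loc[indexed["significant"]].copy()
    sig["acronym"] = [
        str(acronyms[r]) if acronyms is not None and r in acronyms else str(r)
        for r in sig["region_id"]
    ]
    defined = sig.loc[sig["defined"]].sort_values(
        ["index", "acronym"], ascending=[False, True], kind="mergesort"
    )
    defined["rank"] = np.arange(1, len(defined) + 1)
    undefined = sig.loc[~sig["defined"]].sort_values("acronym", kind="mergesort")
    undefined["rank"] = np.nan
    return pd.concat([defined, undefined], ignore_index=True)


class EngramIndexRanker(BaseEstimator):
    """Gate + index + rank in one fit-shaped analyzer.

    Parameters
    ----------
    alpha:
        Pairwise significance level for the Tukey gate (default 0.05).
    bh:
        Apply Benjamini-Hochberg across regions to each pairwise family.
    log1p:
        Run the gate on log1p counts (for heavy overdispersion).

    Attributes (after ``fit``)
    --------------------------
    gating_ : per-region gate outcomes with cohort means and p-values.
    results_ : ranked table of significant regions with engram indices.
    n_regions_, n_significant_ : partition bookkeeping
        (``n_significant_ + (gating_.significant == False).sum() ==
        n_regions_``).
    """

    def __init__(self, alpha: float = 0.05, bh: bool = False, log1p: bool = False):
        self.alpha = alpha
        self.bh = bh
        self.log1p = log1p

    def fit(self, table: pd.DataFrame, acronyms: Mapping | None = None) -> "EngramIndexRanker":
        self.gating_ = gate_significant_regions(table, alpha=self.alpha, bh=self.bh, log1p=self.log1p)
        indexed = compute_indices(self.gating_)
        self.results_ = rank_regions(indexed, acronyms=acronyms)
        self.n_regions_ = int(len(self.gating_))
        self.n_significant_ = int(self.gating_["significant"].sum())
        return self
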