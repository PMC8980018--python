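"""Atlas-region assignment of detected cells and per-region counting.

Registration is out of scope: the package consumes a pre-aligned integer
label volume (0 = outside brain) paired with a region ontology table.
Regions can be flagged excluded (medulla — atlas mismatch in cleared tissue;
fiber tracts — negligible activated-cell content) and are dropped from all
counts with the reason recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .detection import CellCentroid

EXCLUSION_REASONS = ("medulla", "fiber_tract", "none")


class RegionOntology:
    """Table of regions: id (> 0, unique), name, acronym, exclusion flag."""

    def __init__(self, table: pd.DataFrame):
        required = {"region_id", "name", "acronym", "excluded", "reason"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"ontology missing columns {sorted(missing)}")
        table = table.copy()
        table["region_id"] = table["region_id"].astype(int)
        if (table["region_id"] <= 0).any():
            raise ValueError("region_ids must be > 0 (0 means outside brain)")
        if table["region_id"].duplicated().any():
            raise ValueError("region_ids must be unique")
        bad = set(table["reason"]) - set(EXCLUSION_REASONS)
        if bad:
            raise ValueError(f"unknown exclusion reasons {sorted(bad)}")
        self.table = table.reset_index(drop=True)
        self._by_id = table.set_index("region_id")

    @property
    def region_ids(self) -> np.ndarray:
        return self.table["region_id"].to_numpy()

    @property
    def included_ids(self) -> np.ndarray:
        return self.table.loc[~self.table["excluded"], "region_id"].to_numpy()

    def __contains__(self, region_id: int) -> bool:
        return int(region_id) in self._by_id.index

    def is_excluded(self, region_id: int) -> bool:
        return bool(self._by_id.loc[int(region_id), "excluded"])

    def reason(self, region_id: int) -> str:
        return str(self._by_id.loc[int(region_id), "reason"])

    def acronym(self, region_id: int) -> str:
        return str(self._by_id.loc[int(region_id), "acronym"])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionOntology":
        return cls(pd.read_csv(path))


def synthetic_ontology(n_included: int = 247, n_fiber_tracts: int = 2, n_medulla: int = 1) -> RegionOntology:
    """A synthetic stand-in ontology: ``n_included`` analyzable regions plus
    excluded medulla/fiber-tract entries."""
    rows = []
    for i in range(1, n_included + 1):
        rows.append((i, f"Region {i:03d}", f"R{i:03d}", False, "none"))
    next_id = n_included + 1
    for j in range(n_medulla):
        rows.append((next_id, f"Medulla {j + 1}", f"MED{j + 1}", True, "medulla"))
        next_id += 1
    for j in range(n_fiber_tracts):
        rows.append((next_id, f"Fiber tract {j + 1}", f"FT{j + 1}", True, "fiber_tract"))
        next_id += 1
    return RegionOntology(
        pd.DataFrame(rows, columns=["region_id", "name", "acronym", "excluded", "reason"])
    )


@dataclass
class LabelVolume:
    """Integer region-id volume aligned to a paired image volume."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)


def nearest_seed_labels(
    shape: tuple[int, int, int],
    region_ids: Sequence[int],
    voxel_size: tuple[float, float, float] = (1.8, 1.8, 2.0),
    seed: int = 0,
    background_fraction: float = 0.0,
) -> LabelVolume:
    """Synthetic parcellation: each voxel takes the id of its nearest random
    seed point (a Voronoi partition); optionally carve a band of label 0."""
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(seed)
    ids = np.asarray(region_ids, dtype=int)
    pts = rng.uniform(0, 1, size=(len(ids), 3)) * np.asarray(shape)
    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1).reshape(-1, 3)
    _, nearest = cKDTree(pts).query(grid)
    data = ids[nearest].reshape(shape).astype(np.int32)
    if background_fraction > 0:
        cut = int(shape[0] * background_fraction)
        data[:cut] = 0
    return LabelVolume(data=data, voxel_size=voxel_size)


def assign_regions(
    centroids: Iterable[CellCentroid], labels: LabelVolume, ontology: RegionOntology
) -> pd.DataFrame:
    """Map each centroid to the region id at its voxel.

    Label 0 -> ``unassigned``; excluded regions -> ``excluded`` with the
    reason recorded; labels absent from the ontology raise.
    """
    rows = []
    for c in centroids:
        label = int(labels.data[c.position])
        if label == 0:
            rows.append((*c.position, 0, "unassigned", "none"))
            continue
        if label not in ontology:
            raise KeyError(f"label {label} at voxel {c.position} is absent from the ontology")
        if ontology.is_excluded(label):
            rows.append((*c.position, label, "excluded", ontology.reason(label)))
        else:
            rows.append((*c.position, label, "assigned", "none"))
    return pd.DataFrame(rows, columns=["x_vox", "y_vox", "z_vox", "region_id", "status", "reason"])


def count_per_region(
    assignments: pd.DataFrame, ontology: RegionOntology, subject_id: str, cohort: str
) -> pd.DataFrame:
    """One zero-filled row per non-excluded region; counts sum to the number
    of assigned, non-excluded centroids."""
    counted = assignments.loc[assignments["status"] == "assigned", "region_id"].value_counts().to_dict()
    rows = [
        (int(rid), subject_id, cohort, int(counted.get(rid, 0)))
        for rid in ontology.included_ids
    ]
    return pd.DataFrame(rows, columns=["region_id", "subject_id", "cohort", "count"])


def cohort_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per-region cohort mean counts as columns mean_hc/mean_cfc/mean_re."""
    wide = (
        table.groupby(["region_id", "cohort"])["count"].mean().unstack("cohort")
    )
    out = pd.DataFrame(index=wide.index)
    for cohort, col in (("HC", "mean_hc"), ("CFC", "mean_cfc"), ("RE", "mean_re")):
        out[col] = wide[cohort] if cohort in wide else np.nan
    return out.reset_index()


def normalize_to_homecage(table: pd.DataFrame) -> pd.DataFrame:
    """Fold-changes of CFC and RE cohort means over the home-cage mean.

    Regions with a zero home-cage mean are flagged ``undefined`` (folds NaN)
    rather than dropped.
    """
    means = cohort_means(table)
    undefined = means["mean_hc"] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        fold_cfc = np.where(undefined, np.nan, means["mean_cfc"] / means["mean_hc"])
        fold_re = np.where(undefined, np.nan, means["mean_re"] / means["mean_hc"])
    out = means.copy()
    out["fold_cfc"] = fold_cfc
    out["fold_re"] = fold_re
    out["undefined"] = undefined.to_numpy()
    return out
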