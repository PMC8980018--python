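"""Seeded generators for every input the mapping pipeline consumes.

Three families of ground-truthed synthetic data:

* image volumes — Gaussian cell bodies (isotropic in micrometres, hence
  anisotropic in voxels) on additive Gaussian background noise, with the
  exact blob centres returned as ground truth;
* region-structured activated-cell count tables for three behavioural
  cohorts (home cage HC, fear-conditioning CFC, recall RE) with class-typed
  regions: true engram regions elevated in both CFC and RE, shock-responsive
  distractors elevated in CFC only, recall-preferential regions, and null
  regions;
* per-subject Bernoulli/binomial reactivation tables (tdTomato-labelled
  cells re-expressing cFos at recall) with NeuN denominators for chance
  levels.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .detection import CellCentroid
from .volume import ImageVolume

COHORTS = ("HC", "CFC", "RE")
REGION_CLASSES = ("engram", "shock_only", "recall_preferential", "null")

#: default (CFC, RE) fold-changes over the home-cage baseline per region class
CLASS_FOLDS: dict[str, tuple[float, float]] = {
    "engram": (4.0, 3.5),
    "shock_only": (4.0, 1.0),
    "recall_preferential": (2.0, 4.0),
    "null": (1.0, 1.0),
}


class PackingError(RuntimeError):
    """Raised when cells cannot be placed at the requested separation."""


@dataclass
class VolumeSpec:
    """Parameters of one synthetic two-channel-style image volume.

    ``blob_sigma`` and ``min_separation`` are physical (um); ``margin`` keeps
    every centre at least half a (16, 16, 8) patch away from each face so that
    ground-truth cells are never border-rejected downstream.
    """

    shape: tuple[int, int, int] = (128, 128, 32)
    voxel_size: tuple[float, float, float] = (1.8, 1.8, 2.0)
    n_cells: int = 50
    blob_sigma: float = 3.0
    peak_intensity: float = 1000.0
    background_mean: float = 300.0
    background_sd: float = 100.0
    min_separation: float = 12.0
    margin: tuple[int, int, int] = (8, 8, 4)
    channel: str = "tdTomato"
    n_distractors: int = 0
    distractor_sigma: float = 1.0
    distractor_intensity: float = 3000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.shape):
            raise ValueError("shape must be strictly positive")
        if self.min_separation < 2 * self.blob_sigma:
            raise ValueError("min_separation must be >= 2 * blob_sigma")
        if self.peak_intensity <= self.background_mean:
            raise ValueError("peak_intensity must exceed background_mean")
        if self.n_cells < 0 or self.background_sd < 0 or self.blob_sigma <= 0:
            raise ValueError("invalid VolumeSpec")
        if self.n_distractors < 0 or self.distractor_sigma <= 0:
            raise ValueError("invalid distractor settings")
        self.shape = tuple(int(s) for s in self.shape)
        self.margin = tuple(int(m) for m in self.margin)


def _place_centres(spec: VolumeSpec, rng: np.random.Generator, n: int) -> list[tuple[int, int, int]]:
    lo = np.asarray(spec.margin)
    hi = np.asarray(spec.shape) - np.asarray(spec.margin)
    if (hi <= lo).any() and n > 0:
        raise PackingError(f"margin {spec.margin} leaves no interior in shape {spec.shape}")
    vs = np.asarray(spec.voxel_size)
    centres: list[np.ndarray] = []
    attempts = 0
    max_attempts = 10_000 * max(n, 1)
    while len(centres) < n:
        if attempts >= max_attempts:
            raise PackingError(
                f"could not place {n} objects at separation "
                f"{spec.min_separation} um in shape {spec.shape} "
                f"(placed {len(centres)} after {attempts} attempts)"
            )
        attempts += 1
        cand = rng.integers(lo, hi)
        cand_um = cand * vs
        if all(np.linalg.norm(cand_um - c * vs) >= spec.min_separation for c in centres):
            centres.append(cand)
    return [tuple(int(v) for v in c) for c in centres]


def _render_blobs(
    data: np.ndarray,
    centres: list[tuple[int, int, int]],
    sigma_um: float,
    amplitude: float,
    voxel_size: tuple[float, float, float],
) -> None:
    sig_vox = np.asarray([sigma_um / v for v in voxel_size])
    win = np.ceil(4 * sig_vox).astype(int)
    shape = np.asarray(data.shape)
    for c in centres:
        lo = np.maximum(np.asarray(c) - win, 0)
        hi = np.minimum(np.asarray(c) + win + 1, shape)
        grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
        r2 = sum(((g - ci) / s) ** 2 for g, ci, s in zip(grids, c, sig_vox))
        data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amplitude * np.exp(-0.5 * r2)


def generate_volume_with_distractors(
    spec: VolumeSpec,
) -> tuple[ImageVolume, list[CellCentroid], list[tuple[int, int, int]]]:
    """As :func:`generate_volume` but also return distractor-speckle centres.

    Distractors are bright sub-cellular speckles (``distractor_sigma`` um)
    that imitate staining noise; they share the cell separation constraint and
    are never part of the ground-truth cell list.
    """
    rng = np.random.default_rng(spec.seed)
    centres = _place_centres(spec, rng, spec.n_cells + spec.n_distractors)
    cell_centres = centres[: spec.n_cells]
    distractors = centres[spec.n_cells :]
    if spec.background_sd > 0:
        data = rng.normal(spec.background_mean, spec.background_sd, spec.shape)
    else:
        data = np.full(spec.shape, float(spec.background_mean))
    _render_blobs(data, cell_centres, spec.blob_sigma, spec.peak_intensity, spec.voxel_size)
    if distractors:
        _render_blobs(data, distractors, spec.distractor_sigma, spec.distractor_intensity, spec.voxel_size)
    data = np.clip(data, 0, None).astype(np.float32)
    vol = ImageVolume(data, spec.voxel_size, spec.channel)
    truth = [
        CellCentroid(position=c, position_um=vol.to_um(c), peak_intensity=spec.peak_intensity)
        for c in cell_centres
    ]
    return vol, truth, distractors


def generate_volume(spec: VolumeSpec) -> tuple[ImageVolume, list[CellCentroid]]:
    """Render Gaussian cell blobs plus background noise; return exact centres.

    Raises :class:`PackingError` when the requested objects cannot be placed
    at ``min_separation`` within the margins — never silently fewer cells.
    """
    vol, truth, _ = generate_volume_with_distractors(spec)
    return vol, truth


def sample_background_positions(
    spec: VolumeSpec,
    truth: list[CellCentroid],
    n: int,
    min_distance: float | None = None,
    seed: int = 1,
) -> list[tuple[int, int, int]]:
    """Sample in-margin positions away from every true cell (negatives)."""
    rng = np.random.default_rng(seed)
    min_distance = 2 * spec.blob_sigma if min_distance is None else min_distance
    vs = np.asarray(spec.voxel_size)
    truth_um = [np.asarray(c.position) * vs for c in truth]
    lo = np.asarray(spec.margin)
    hi = np.asarray(spec.shape) - np.asarray(spec.margin)
    out: list[tuple[int, int, int]] = []
    attempts = 0
    while len(out) < n:
        if attempts > 10_000 * max(n, 1):
            raise PackingError("could not sample enough background positions")
        attempts += 1
        cand = rng.integers(lo, hi)
        cand_um = cand * vs
        if all(np.linalg.norm(cand_um - t) >= min_distance for t in truth_um):
            out.append(tuple(int(v) for v in cand))
    return out


def generate_training_patches(
    base: VolumeSpec,
    seeds: tuple[int, ...] = (11, 12),
    patch_shape: tuple[int, int, int] = (16, 16, 8),
    n_background: int = 40,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Labelled patch sets for the accept/reject classifier.

    Positives are patches centred on true cells; negatives are patches at
    distractor speckles and at background positions away from any cell, drawn
    from one volume per seed.
    """
    from dataclasses import replace as _replace

    from .detection import extract_patches

    pos: list[np.ndarray] = []
    neg: list[np.ndarray] = []
    for seed in seeds:
        spec = _replace(base, seed=seed)
        vol, truth, distractors = generate_volume_with_distractors(spec)
        pairs, _ = extract_patches(vol, truth, patch_shape)
        pos.extend(p for _, p in pairs)
        neg_positions = list(distractors) + sample_background_positions(
            spec, truth, n_background, seed=seed + 1
        )
        neg_cents = [CellCentroid(position=p) for p in neg_positions]
        pairs, _ = extract_patches(vol, neg_cents, patch_shape)
        neg.extend(p for _, p in pairs)
    return pos, neg


# ---------------------------------------------------------------------------
# cohort count tables


@dataclass
class CohortCountSpec:
    """Region-structured cohort count model.

    ``dispersion`` is the NB2 overdispersion alpha: counts have mean m and
    variance m + alpha * m^2, so alpha = 0 is exactly Poisson.  Cohort sizes
    default to 7 home-cage, 10 CFC and 9 recall subjects.
    """

    region_classes: Mapping[str, str]
    n_hc: int = 7
    n_cfc: int = 10
    n_re: int = 9
    baseline_mean: float = 100.0
    dispersion: float = 0.1
    class_folds: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(CLASS_FOLDS))
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hc, self.n_cfc, self.n_re) < 2:
            raise ValueError("cohort sizes must be >= 2")
        if self.dispersion < 0 or not np.isfinite(self.dispersion):
            raise ValueError("dispersion must be finite and >= 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        for region, cls in self.region_classes.items():
            if cls not in self.class_folds:
                raise ValueError(f"region {region!r} has unknown class {cls!r}")
        for cls, folds in self.class_folds.items():
            arr = np.asarray(folds, dtype=float)
            if arr.shape != (2,) or not np.isfinite(arr).all() or (arr < 0).any():
                raise ValueError(f"fold-changes for {cls!r} must be two finite values >= 0")


def make_region_classes(
    n_engram: int = 15, n_shock: int = 15, n_recall: int = 15, n_null: int = 15
) -> dict[str, str]:
    """Name regions by class (ENG01..., SHK01..., RCL01..., NUL01...)."""
    out: dict[str, str] = {}
    for prefix, cls, n in (
        ("ENG", "engram", n_engram),
        ("SHK", "shock_only", n_shock),
        ("RCL", "recall_preferential", n_recall),
        ("NUL", "null", n_null),
    ):
        for i in range(n):
            out[f"{prefix}{i + 1:03d}"] = cls
    return out


def _draw_counts(rng: np.random.Generator, mean: float, alpha: float, size: int) -> np.ndarray:
    if alpha == 0:
        return rng.poisson(mean, size)
    k = 1.0 / alpha
    return rng.negative_binomial(k, k / (k + mean), size)


def generate_count_table(spec: CohortCountSpec) -> tuple[pd.DataFrame, dict[str, str]]:
    """Draw a tidy (region_id, subject_id, cohort, count) table plus truth."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for region in spec.region_classes:
        cls = spec.region_classes[region]
        f_cfc, f_re = spec.class_folds[cls]
        for cohort, n, fold in (("HC", spec.n_hc, 1.0), ("CFC", spec.n_cfc, f_cfc), ("RE", spec.n_re, f_re)):
            counts = _draw_counts(rng, spec.baseline_mean * fold, spec.dispersion, n)
            for i, c in enumerate(counts):
                rows.append((region, f"{cohort}{i + 1:02d}", cohort, int(c)))
    table = pd.DataFrame(rows, columns=["region_id", "subject_id", "cohort", "count"])
    return table, dict(spec.region_classes)


# ---------------------------------------------------------------------------
# reactivation tables


@dataclass
class ReactivationSpec:
    """Per-region reactivation model: for each region a tuple
    ``(n_tdtomato, overlap_p, n_cfos_recall, n_neun)``; overlap counts are
    Binomial(n_tdtomato, overlap_p) independently per subject."""

    regions: Mapping[str, tuple[int, float, int, int]]
    n_subjects: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for region, (n_td, p, n_cfos, n_neun) in self.regions.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"overlap_p for {region!r} outside [0, 1]: {p}")
            if n_cfos > n_neun:
                raise ValueError(f"{region!r}: n_cfos_recall ({n_cfos}) > n_neun ({n_neun})")
            if min(n_td, n_cfos, n_neun) < 0:
                raise ValueError(f"{region!r}: counts must be >= 0")


def generate_reactivation_dataset(spec: ReactivationSpec) -> pd.DataFrame:
    """Per-subject, per-region (n_tdtomato, n_overlap, n_cfos_recall, n_neun)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for region, (n_td, p, n_cfos, n_neun) in spec.regions.items():
        overlaps = rng.binomial(n_td, p, spec.n_subjects)
        for i, ov in enumerate(overlaps):
            rows.append((region, f"S{i + 1:02d}", int(n_td), int(ov), int(n_cfos), int(n_neun)))
    return pd.DataFrame(
        rows, columns=["region_id", "subject_id", "n_tdtomato", "n_overlap", "n_cfos_recall", "n_neun"]
    )
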