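"""Detection of activated (cFos/tdTomato-labelled) cells in 3D volumes.

The pipeline mirrors standard cleared-tissue cell mapping practice:

1. optional block-mean down-sampling in xy;
2. candidate proposal — Gaussian smoothing, strict local maxima above an
   intensity floor, physical minimum-separation merging, and a
   marker-controlled watershed over the inverted smoothed intensity (one
   candidate per basin, at its seed);
3. a curvature/intensity filter: a bright round cell has a negative-definite
   Hessian at its centre, scored by the cube root of the magnitude of the
   eigenvalue product ("blobness");
4. patch extraction (default 16 x 16 x 8 voxels) around each surviving
   candidate, min-max normalised;
5. a patch-level accept/reject classifier that removes false-positive
   candidates (speckle, edges, background).

Every proposed candidate ends in exactly one state: ``accepted``,
``rejected_filter``, ``rejected_border``, ``rejected_classifier``, or is left
``candidate`` if the pipeline is stopped early.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.segmentation import watershed
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .volume import ImageVolume

STATES = ("candidate", "accepted", "rejected_filter", "rejected_classifier", "rejected_border")


@dataclass
class CellCentroid:
    """A detected (or ground-truth) cell centre in voxel coordinates."""

    position: tuple[int, int, int]
    position_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    peak_intensity: float = float("nan")
    blobness: float = float("nan")
    prob: float = float("nan")
    state: str = "candidate"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")


@dataclass
class DetectionParams:
    """Tunable knobs of the detection pipeline.

    ``smoothing_sigma`` and ``min_peak_separation`` are physical (um);
    ``intensity_floor`` is a fraction of the smoothed-channel maximum;
    ``curvature_floor`` is a minimum blobness (0 = require only a
    negative-definite Hessian); ``patch_shape`` is in voxels.
    """

    smoothing_sigma: float = 2.0
    intensity_floor: float = 0.5
    curvature_floor: float = 0.0
    patch_shape: tuple[int, int, int] = (16, 16, 8)
    min_peak_separation: float = 8.0
    classifier_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.intensity_floor <= 1.0:
            raise ValueError("intensity_floor must be in [0, 1]")
        if self.curvature_floor < 0:
            raise ValueError("curvature_floor must be >= 0")
        if self.smoothing_sigma < 0 or self.min_peak_separation < 0:
            raise ValueError("sigma and separation must be >= 0")
        if len(self.patch_shape) != 3 or any(int(p) < 4 for p in self.patch_shape):
            raise ValueError("patch_shape entries must each be >= 4")
        self.patch_shape = tuple(int(p) for p in self.patch_shape)
        # classifier_threshold may exceed 1 to express "accept nothing"
        if self.classifier_threshold < 0:
            raise ValueError("classifier_threshold must be >= 0")


def downsample_xy(volume: ImageVolume, factor: int) -> ImageVolume:
    """Block-mean pool xy by ``factor``; z untouched, voxel size scaled."""
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return ImageVolume(volume.data.copy(), volume.voxel_size, volume.channel)
    nx, ny, nz = volume.shape
    if nx % factor or ny % factor:
        raise ValueError(
            f"xy extents ({nx}, {ny}) not divisible by {factor}; "
            f"crop to ({nx - nx % factor}, {ny - ny % factor}) first"
        )
    pooled = volume.data.reshape(nx // factor, factor, ny // factor, factor, nz).mean(axis=(1, 3))
    vx, vy, vz = volume.voxel_size
    return ImageVolume(pooled, (vx * factor, vy * factor, vz), volume.channel)


def _sigma_vox(sigma_um: float, voxel_size: Sequence[float]) -> tuple[float, ...]:
    return tuple(sigma_um / v for v in voxel_size)


def smooth(volume: ImageVolume, sigma_um: float) -> np.ndarray:
    """Gaussian-smooth with an isotropic-in-um sigma (anisotropic in voxels)."""
    if sigma_um == 0:
        return volume.data.astype(float)
    return ndimage.gaussian_filter(volume.data.astype(float), sigma=_sigma_vox(sigma_um, volume.voxel_size))


def _strict_local_maxima(sm: np.ndarray, floor: float) -> list[tuple[int, int, int]]:
    """Voxels >= all 26 neighbours and > floor; plateau components collapse to
    their lexicographically smallest voxel."""
    mask = (sm == ndimage.maximum_filter(sm, size=3, mode="constant", cval=-np.inf)) & (sm > floor)
    if not mask.any():
        return []
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    out = []
    idx = np.argwhere(mask)
    # argwhere is already lexicographic; first hit per component wins
    seen: dict[int, tuple[int, int, int]] = {}
    for pos in idx:
        lab = labels[tuple(pos)]
        if lab not in seen:
            seen[lab] = tuple(int(p) for p in pos)
    return sorted(seen.values())


def _enforce_separation(
    peaks: list[tuple[int, int, int]],
    sm: np.ndarray,
    voxel_size: Sequence[float],
    min_sep_um: float,
) -> list[tuple[int, int, int]]:
    """Greedy physical-distance merge: brighter peak wins, ties lexicographic."""
    if not peaks or min_sep_um <= 0:
        return peaks
    order = sorted(peaks, key=lambda p: (-sm[p], p))
    kept: list[tuple[int, int, int]] = []
    kept_um: list[np.ndarray] = []
    vs = np.asarray(voxel_size, dtype=float)
    for p in order:
        pu = np.asarray(p, dtype=float) * vs
        if all(np.linalg.norm(pu - q) >= min_sep_um for q in kept_um):
            kept.append(p)
            kept_um.append(pu)
    return sorted(kept)


def propose_candidates(volume: ImageVolume, params: DetectionParams) -> list[CellCentroid]:
    """Seed candidates at strict local maxima of the smoothed volume.

    Maxima below ``intensity_floor * max(smoothed)`` are discarded, peaks
    closer than ``min_peak_separation`` um are merged to the brighter one, and
    surviving peaks seed a watershed of the inverted smoothed intensity
    restricted to the above-floor mask (one candidate per basin, at its seed).
    """
    sm = smooth(volume, params.smoothing_sigma)
    floor = params.intensity_floor * float(sm.max()) if sm.size else 0.0
    peaks = _strict_local_maxima(sm, floor)
    peaks = _enforce_separation(peaks, sm, volume.voxel_size, params.min_peak_separation)
    if not peaks:
        return []
    markers = np.zeros(sm.shape, dtype=np.int32)
    for i, p in enumerate(peaks, start=1):
        markers[p] = i
    basins = watershed(-sm, markers=markers, mask=sm > floor)
    out = []
    for i, p in enumerate(peaks, start=1):
        if basins[p] != i:  # pragma: no cover - markers always own their basin
            continue
        out.append(
            CellCentroid(
                position=p,
                position_um=volume.to_um(p),
                peak_intensity=float(sm[p]),
                state="candidate",
            )
        )
    return out


def hessian_at(sm: np.ndarray, voxel_size: Sequence[float], position: Sequence[int]) -> np.ndarray:
    """Central-difference Hessian (um^-2 scaling) of ``sm`` at one voxel."""
    vs = np.asarray(voxel_size, dtype=float)
    p = np.asarray(position, dtype=int)
    H = np.zeros((3, 3))
    f0 = sm[tuple(p)]
    for i in range(3):
        ei = np.zeros(3, dtype=int)
        ei[i] = 1
        fp = sm[tuple(np.clip(p + ei, 0, np.array(sm.shape) - 1))]
        fm = sm[tuple(np.clip(p - ei, 0, np.array(sm.shape) - 1))]
        H[i, i] = (fp - 2 * f0 + fm) / vs[i] ** 2
        for j in range(i + 1, 3):
            ej = np.zeros(3, dtype=int)
            ej[j] = 1
            hi, lo = np.array(sm.shape) - 1, 0
            fpp = sm[tuple(np.clip(p + ei + ej, lo, hi))]
            fpm = sm[tuple(np.clip(p + ei - ej, lo, hi))]
            fmp = sm[tuple(np.clip(p - ei + ej, lo, hi))]
            fmm = sm[tuple(np.clip(p - ei - ej, lo, hi))]
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * vs[i] * vs[j])
    return H


def blobness_score(H: np.ndarray) -> float:
    """Cube root of |det H| when H is negative definite, else 0."""
    eig = np.linalg.eigvalsh(H)
    if (eig >= 0).any():
        return 0.0
    return float(np.cbrt(abs(np.prod(eig))))


def filter_curvature_intensity(
    volume: ImageVolume, candidates: Iterable[CellCentroid], params: DetectionParams
) -> list[CellCentroid]:
    """Score candidates by Hessian blobness; reject flat/ridge/dim ones.

    A candidate is kept when its blobness is positive (all principal
    curvatures negative) and >= ``curvature_floor``, and its peak intensity is
    above the intensity floor.
    """
    sm = smooth(volume, params.smoothing_sigma)
    floor = params.intensity_floor * float(sm.max()) if sm.size else 0.0
    out = []
    for c in candidates:
        b = blobness_score(hessian_at(sm, volume.voxel_size, c.position))
        passed = b > 0 and b >= params.curvature_floor and c.peak_intensity > floor
        out.append(replace(c, blobness=b, state="candidate" if passed else "rejected_filter"))
    return out


def extract_patches(
    volume: ImageVolume,
    centroids: Iterable[CellCentroid],
    patch_shape: tuple[int, int, int] = (16, 16, 8),
) -> tuple[list[tuple[CellCentroid, np.ndarray]], list[CellCentroid]]:
    """Crop min-max normalised patches centred on each candidate.

    Returns ``(pairs, rejected)`` where candidates closer than half a patch to
    any face are returned in ``rejected`` with state ``rejected_border``.
    Constant patches normalise to all zeros.
    """
    shape = np.asarray(volume.shape)
    ps = np.asarray(patch_shape, dtype=int)
    if (ps > shape).any():
        raise ValueError(f"patch_shape {tuple(ps)} exceeds volume shape {tuple(shape)}")
    pairs: list[tuple[CellCentroid, np.ndarray]] = []
    rejected: list[CellCentroid] = []
    for c in centroids:
        lo = np.asarray(c.position) - ps // 2
        hi = lo + ps
        if (lo < 0).any() or (hi > shape).any():
            rejected.append(replace(c, state="rejected_border"))
            continue
        patch = volume.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].astype(float)
        pmin, pmax = patch.min(), patch.max()
        patch = np.zeros_like(patch) if pmax == pmin else (patch - pmin) / (pmax - pmin)
        pairs.append((c, patch))
    return pairs, rejected


def patch_physical_extent(
    voxel_size: Sequence[float], patch_shape: Sequence[int]
) -> tuple[float, float, float]:
    """Physical patch coverage in um: elementwise voxel_size * patch_shape."""
    vs = tuple(float(v) for v in voxel_size)
    ps = tuple(int(p) for p in patch_shape)
    if any(v <= 0 for v in vs) or any(p <= 0 for p in ps):
        raise ValueError("voxel_size and patch_shape must be positive")
    return tuple(v * p for v, p in zip(vs, ps))  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# patch classification


def patch_features(patch: np.ndarray) -> np.ndarray:
    """Summary features of a normalised patch for the accept/reject model.

    Captures what distinguishes a centred bright cell from background: a hot
    centre relative to the border shell, radial Gaussian-template similarity,
    gradient structure and a centre curvature score.
    """
    p = np.asarray(patch, dtype=float)
    centre = tuple(s // 2 for s in p.shape)
    core = p[
        max(centre[0] - 2, 0) : centre[0] + 3,
        max(centre[1] - 2, 0) : centre[1] + 3,
        max(centre[2] - 1, 0) : centre[2] + 2,
    ]
    shell_mask = np.ones(p.shape, dtype=bool)
    shell_mask[1:-1, 1:-1, 1:-1] = False
    grads = np.gradient(p)
    gmag = np.sqrt(sum(g**2 for g in grads))
    # Gaussian template correlation (sigma = quarter patch per axis)
    axes = [np.arange(s) - c for s, c in zip(p.shape, centre)]
    sig = [max(s / 4.0, 1.0) for s in p.shape]
    tx, ty, tz = np.meshgrid(*[np.exp(-0.5 * (a / s) ** 2) for a, s in zip(axes, sig)], indexing="ij")
    template = tx * ty * tz
    tflat, pflat = template.ravel(), p.ravel()
    tstd, pstd = tflat.std(), pflat.std()
    corr = 0.0 if tstd == 0 or pstd == 0 else float(np.corrcoef(tflat, pflat)[0, 1])
    H = hessian_at(p, (1.0, 1.0, 1.0), centre)
    return np.array(
        [
            float(p[centre]),
            float(core.mean()),
            float(p.mean()),
            float(p.std()),
            float(core.mean() - p[shell_mask].mean()),
            corr,
            float(gmag.mean()),
            float(gmag.max()),
            blobness_score(H),
            float((p > 0.5).mean()),
        ]
    )


class PatchClassifier(ClassifierMixin, BaseEstimator):
    """Accept/reject classifier over candidate patches.

    A featurised logistic-regression model (intensity, gradient and curvature
    summaries of the normalised patch) behind the same interface a 3D CNN
    would use: ``fit(patches, y)`` / ``predict_proba(patches)``.  An internal
    held-out split reports generalisation accuracy in ``holdout_accuracy_``.
    """

    def __init__(self, C: float = 1.0, test_size: float = 0.25, random_state: int = 0):
        self.C = C
        self.test_size = test_size
        self.random_state = random_state

    @staticmethod
    def _featurize(patches: Sequence[np.ndarray]) -> np.ndarray:
        return np.vstack([patch_features(p) for p in patches])

    def fit(self, patches: Sequence[np.ndarray], y: Sequence[int]) -> "PatchClassifier":
        y = np.asarray(y, dtype=int)
        counts = np.bincount(y, minlength=2)
        if counts.min() < 50:
            raise ValueError(f"need >= 50 examples per class, got {counts.tolist()}")
        if counts.max() > 10 * counts.min():
            raise ValueError(f"class imbalance worse than 10:1 rejected, got {counts.tolist()}")
        X = self._featurize(patches)
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=self.test_size, random_state=self.random_state, stratify=y
        )
        self.model_ = make_pipeline(
            StandardScaler(), LogisticRegression(C=self.C, max_iter=2000, random_state=self.random_state)
        )
        self.model_.fit(Xtr, ytr)
        self.holdout_accuracy_ = float((self.model_.predict(Xte) == yte).mean())
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, patches: Sequence[np.ndarray]) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._featurize(patches))

    def predict(self, patches: Sequence[np.ndarray]) -> np.ndarray:
        return (self.predict_proba(patches)[:, 1] >= 0.5).astype(int)


def train_patch_classifier(
    positive_patches: Sequence[np.ndarray],
    negative_patches: Sequence[np.ndarray],
    seed: int = 0,
) -> PatchClassifier:
    """Fit a :class:`PatchClassifier` on labelled positive/negative patches."""
    patches = list(positive_patches) + list(negative_patches)
    y = [1] * len(positive_patches) + [0] * len(negative_patches)
    return PatchClassifier(random_state=seed).fit(patches, y)


def classify_candidates(
    classifier: PatchClassifier,
    patch_pairs: Sequence[tuple[CellCentroid, np.ndarray]],
    classifier_threshold: float = 0.5,
) -> list[CellCentroid]:
    """Final accept/reject: probability >= threshold keeps a candidate."""
    if not patch_pairs:
        return []
    probs = classifier.predict_proba([p for _, p in patch_pairs])[:, 1]
    out = []
    for (c, _), pr in zip(patch_pairs, probs):
        state = "accepted" if pr >= classifier_threshold else "rejected_classifier"
        out.append(replace(c, prob=float(pr), state=state))
    return out


def detect_cells(
    volume: ImageVolume,
    params: DetectionParams | None = None,
    classifier: PatchClassifier | None = None,
) -> list[CellCentroid]:
    """Run the full pipeline; returns every candidate with its final state.

    Without a classifier every in-border filtered candidate is accepted.
    """
    params = params or DetectionParams()
    candidates = propose_candidates(volume, params)
    filtered = filter_curvature_intensity(volume, candidates, params)
    passed = [c for c in filtered if c.state == "candidate"]
    dropped = [c for c in filtered if c.state != "candidate"]
    pairs, border = extract_patches(volume, passed, params.patch_shape)
    if classifier is None:
        final = [replace(c, state="accepted") for c, _ in pairs]
    else:
        final = classify_candidates(classifier, pairs, params.classifier_threshold)
    return final + border + dropped


def accepted(centroids: Iterable[CellCentroid]) -> list[CellCentroid]:
    return [c for c in centroids if c.state == "accepted"]


def match_detections(
    detected: Sequence[CellCentroid],
    truth: Sequence[CellCentroid],
    radius_um: float,
    voxel_size: Sequence[float],
) -> dict[str, float]:
    """Greedy one-to-one matching within a physical radius; returns P/R/F1."""
    vs = np.asarray(voxel_size, dtype=float)
    if not detected or not truth:
        tp = 0
    else:
        d = np.asarray([c.position for c in detected], dtype=float) * vs
        t = np.asarray([c.position for c in truth], dtype=float) * vs
        dist = np.linalg.norm(d[:, None, :] - t[None, :, :], axis=2)
        pairs = sorted(
            ((dist[i, j], i, j) for i in range(len(d)) for j in range(len(t)) if dist[i, j] <= radius_um)
        )
        used_d: set[int] = set()
        used_t: set[int] = set()
        tp = 0
        for _, i, j in pairs:
            if i in used_d or j in used_t:
                continue
            used_d.add(i)
            used_t.add(j)
            tp += 1
    fp = len(detected) - tp
    fn = len(truth) - tp
    precision = tp / len(detected) if detected else 0.0
    recall = tp / len(truth) if truth else 0.0
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return {"tp": tp, "fp": fp, "fn": fn, "precision": precision, "recall": recall, "f1": f1}


def detections_to_frame(centroids: Sequence[CellCentroid]) -> pd.DataFrame:
    """Tabulate detections for CSV export."""
    return pd.DataFrame(
        {
            "x_vox": [c.position[0] for c in centroids],
            "y_vox": [c.position[1] for c in centroids],
            "z_vox": [c.position[2] for c in centroids],
            "x_um": [c.position_um[0] for c in centroids],
            "y_um": [c.position_um[1] for c in centroids],
            "z_um": [c.position_um[2] for c in centroids],
            "peak_intensity": [c.peak_intensity for c in centroids],
            "blobness": [c.blobness for c in centroids],
            "prob": [c.prob for c in centroids],
            "state": [c.state for c in centroids],
        }
    )
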