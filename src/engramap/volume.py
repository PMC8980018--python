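"""3D image volumes with physical voxel metadata, plus TIFF/HDF5 round-trip.

Axis convention throughout the package: arrays are indexed ``data[x, y, z]``
with 0-based voxel indices, and physical coordinates are
``index * voxel_size`` (voxel-corner origin), in micrometres.  TIFF files are
written page-per-z in the usual (z, y, x) page layout and transposed on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import tifffile

CHANNELS = ("tdTomato", "cFos", "NeuN", "autofluorescence")


@dataclass
class ImageVolume:
    """A single-channel 3D intensity volume.

    Parameters
    ----------
    data:
        Non-negative, finite 3D array, axes (x, y, z).
    voxel_size:
        Physical voxel edge lengths in micrometres, (x, y, z).
    channel:
        One of ``tdTomato``, ``cFos``, ``NeuN``, ``autofluorescence``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel: str = "tdTomato"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim} axes")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be three positive values, got {self.voxel_size}")
        self.voxel_size = vs
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if not np.isfinite(self.data).all():
            raise ValueError("volume intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("volume intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def to_um(self, position: Sequence[float]) -> tuple[float, float, float]:
        """Convert a voxel index to physical micrometre coordinates."""
        return tuple(float(p) * v for p, v in zip(position, self.voxel_size))  # type: ignore[return-value]


def write_tiff(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF (one page per z plane)."""
    meta = {"voxel_size_um": list(volume.voxel_size), "channel": volume.channel, "axes_on_disk": "zyx"}
    pages = np.transpose(volume.data, (2, 1, 0))
    tifffile.imwrite(str(path), pages.astype(np.float32), description=json.dumps(meta))


def read_tiff(path: str | Path) -> ImageVolume:
    with tifffile.TiffFile(str(path)) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description or "{}"
    meta = json.loads(desc)
    data = np.transpose(pages, (2, 1, 0))
    return ImageVolume(data=data, voxel_size=tuple(meta["voxel_size_um"]), channel=meta.get("channel", "tdTomato"))


def write_hdf5(volume: ImageVolume, path: str | Path, dataset: str = "volume") -> None:
    with h5py.File(str(path), "w") as f:
        ds = f.create_dataset(dataset, data=volume.data.astype(np.float32))
        ds.attrs["voxel_size_um"] = np.asarray(volume.voxel_size, dtype=float)
        ds.attrs["channel"] = volume.channel
        ds.attrs["axes"] = "xyz"


def read_hdf5(path: str | Path, dataset: str = "volume") -> ImageVolume:
    with h5py.File(str(path), "r") as f:
        ds = f[dataset]
        data = ds[...]
        voxel = tuple(float(v) for v in ds.attrs["voxel_size_um"])
        channel = ds.attrs.get("channel", "tdTomato")
        if isinstance(channel, bytes):
            channel = channel.decode()
    return ImageVolume(data=data, voxel_size=voxel, channel=str(channel))
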