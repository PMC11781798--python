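"""Reading and writing image volumes, region-label maps, and measurement tables.

Volumes are multi-channel 3D stacks in (z, y, x) axis order with 0-based
voxel indices and voxel centers on the integer lattice.  Channels are
addressed by name everywhere downstream of the reader so that a channel
swap is impossible to commit silently.  Intensities are kept in the linear
arbitrary units of the file: the reader never rescales.

Physical calibration (voxel size in µm, anisotropy allowed) travels as
metadata on the :class:`Volume`; every physical-distance parameter in the
package (adjacency radii, spot sigmas) is converted to voxels through it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Volume",
    "RegionLabelMap",
    "GroupTable",
    "VolumeIOError",
    "read_volume",
    "write_volume",
    "read_label_map",
    "write_label_map",
    "read_group_table",
    "write_group_table",
]


class VolumeIOError(ValueError):
    """Raised for malformed image or table inputs."""


@dataclass
class Volume:
    """A named-channel 3D image stack with physical voxel size.

    Parameters
    ----------
    channels
        Mapping channel-name -> 3D array, all sharing one (nz, ny, nx)
        shape, finite and non-negative.
    voxel_size
        (dz, dy, dx) in µm, strictly positive; defaults to isotropic 1 µm
        when the source file carries no calibration.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not self.channels:
            raise VolumeIOError("a Volume needs at least one channel")
        self.channels = {
            str(k): np.asarray(v, dtype=np.float64) for k, v in self.channels.items()
        }
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise VolumeIOError(f"channels disagree on shape: {sorted(shapes)}")
        (shape,) = shapes
        if len(shape) != 3:
            raise VolumeIOError(f"channels must be 3D (z, y, x); got shape {shape}")
        for name, arr in self.channels.items():
            if not np.all(np.isfinite(arr)):
                raise VolumeIOError(f"channel {name!r} contains non-finite values")
            if np.any(arr < 0):
                raise VolumeIOError(f"channel {name!r} contains negative intensities")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise VolumeIOError(f"voxel_size must be 3 strictly positive µm values, got {self.voxel_size}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not present; available: {sorted(self.channels)}"
            ) from None


@dataclass
class RegionLabelMap:
    """Integer compartment labels over a volume; 0 is reserved background.

    ``names`` maps each nonzero label to a region name (e.g. "calyx",
    "peduncle", "alpha3").  Names may list labels that never occur in the
    field (a region is allowed to be empty), but every label present in
    the field must be named.
    """

    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise VolumeIOError(f"label field must be integer, got dtype {self.labels.dtype}")
        if self.labels.ndim != 3:
            raise VolumeIOError(f"label field must be 3D, got shape {self.labels.shape}")
        if self.labels.min() < 0:
            raise VolumeIOError("labels must be non-negative")
        self.names = {int(k): str(v) for k, v in self.names.items()}
        present = {int(v) for v in np.unique(self.labels)} - {0}
        unnamed = sorted(present - set(self.names))
        if unnamed:
            raise VolumeIOError(f"label(s) {unnamed} present in field but missing from names")

    def labels_for(self, region: str) -> list[int]:
        """All label ids mapping to ``region`` (usually exactly one)."""
        ids = [k for k, v in self.names.items() if v == region]
        if not ids:
            raise KeyError(f"region {region!r} unknown; known regions: {sorted(set(self.names.values()))}")
        return ids

    def region_mask(self, region: str) -> np.ndarray:
        return np.isin(self.labels, self.labels_for(region))


#: columns every measurement table must provide; the condition factor may be
#: called either "starvation_hours" or "condition".
REQUIRED_TABLE_COLUMNS = ("sample_id", "genotype", "region", "measurement")


@dataclass
class GroupTable:
    """Per-sample measurements with genotype x condition factors.

    One row per (sample, region) within each factor cell; each brain
    sample is one statistical unit, so duplicates within a cell are
    rejected.
    """

    data: pd.DataFrame
    condition_column: str = "starvation_hours"

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in REQUIRED_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise VolumeIOError(f"group table missing required column(s): {missing}")
        if self.condition_column not in df.columns:
            if "condition" in df.columns:
                self.condition_column = "condition"
            else:
                raise VolumeIOError(
                    f"group table missing condition column "
                    f"({self.condition_column!r} or 'condition')"
                )
        meas = pd.to_numeric(df["measurement"], errors="coerce")
        bad = df.index[~np.isfinite(meas)].tolist()
        if bad:
            raise VolumeIOError(f"non-numeric or non-finite measurement at row(s) {bad}")
        df["measurement"] = meas.astype(float)
        key = ["genotype", self.condition_column, "sample_id", "region"]
        dup = df[df.duplicated(subset=key, keep=False)]
        if len(dup):
            pairs = dup[["sample_id", "region"]].drop_duplicates().to_records(index=False).tolist()
            raise VolumeIOError(f"duplicate (sample_id, region) within a factor cell: {pairs}")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# volumes


def read_volume(
    path: str | Path,
    channel_map: Mapping[int, str],
    voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
) -> Volume:
    """Read a 3D or 4D (channel-first) TIFF/OME-TIFF into a :class:`Volume`.

    ``channel_map`` assigns names to channel indices; a plain 3D stack is
    treated as a single channel with index 0.  Intensities are cast to
    float64 without rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    data = np.asarray(tifffile.imread(path))
    if data.ndim == 3:
        planes = {0: data}
    elif data.ndim == 4:
        planes = {i: data[i] for i in range(data.shape[0])}
    else:
        raise VolumeIOError(f"{path}: expected a 3D or 4D stack, got shape {data.shape}")
    channels: dict[str, np.ndarray] = {}
    for idx, name in channel_map.items():
        if int(idx) not in planes:
            raise VolumeIOError(
                f"{path}: channel index {idx} out of range (file has {len(planes)} channel(s))"
            )
        channels[str(name)] = planes[int(idx)]
    return Volume(channels=channels, voxel_size=tuple(voxel_size))


def write_volume(
    path: str | Path,
    volume: Volume,
    channel_order: Sequence[str] | None = None,
) -> dict[int, str]:
    """Write a Volume as a (C, Z, Y, X) TIFF; returns the index->name map.

    Data are stored as float64 so that a write/read round trip reproduces
    every voxel exactly.
    """
    order = list(channel_order) if channel_order is not None else list(volume.channels)
    stack = np.stack([volume.channel(name) for name in order], axis=0)
    dz, dy, dx = volume.voxel_size
    tifffile.imwrite(
        Path(path),
        stack,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
        },
    )
    return {i: name for i, name in enumerate(order)}


# ---------------------------------------------------------------------------
# label maps


def read_label_map(
    path: str | Path,
    names: Mapping[int, str],
    reference: Volume | None = None,
) -> RegionLabelMap:
    """Read an integer-label TIFF; optionally check shape against a Volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label map file not found: {path}")
    data = np.asarray(tifffile.imread(path))
    if not np.issubdtype(data.dtype, np.integer):
        # tolerate float storage of exact integers, reject anything else
        rounded = np.round(data)
        if not np.array_equal(rounded, data):
            raise VolumeIOError(f"{path}: label map contains non-integer values")
        data = rounded.astype(np.int32)
    if reference is not None and data.shape != reference.shape:
        raise VolumeIOError(
            f"{path}: label shape {data.shape} does not match volume shape {reference.shape}"
        )
    return RegionLabelMap(labels=data, names=dict(names))


def write_label_map(path: str | Path, label_map: RegionLabelMap) -> None:
    tifffile.imwrite(Path(path), label_map.labels.astype(np.int32), photometric="minisblack")


# ---------------------------------------------------------------------------
# tables


def read_group_table(path: str | Path) -> GroupTable:
    """Read and validate a per-sample measurement CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"group table not found: {path}")
    return GroupTable(data=pd.read_csv(path))


def write_group_table(path: str | Path, table: GroupTable) -> None:
    table.data.to_csv(Path(path), index=False)
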