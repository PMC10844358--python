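"""Calibrated two-channel z-stack I/O, channel fusion, and report serialization.

A microtissue stack is imaged in two fluorescence channels — nuclei
(Hoechst) and F-actin (phalloidin) — as a series of optical sections taken
at a fixed axial step (5 µm by default).  This module owns the in-memory
containers for such stacks, reads them from multi-page TIFF / OME-TIFF,
fuses the two channels into the single intensity image the detection stages
consume, and writes the per-lumen / per-stack CSV reports and labeled-mask
TIFFs the pipeline produces.

Conventions
-----------
* arrays are indexed ``(z, y, x)``, 0-based, ascending z;
* the physical coordinate of voxel ``(z, y, x)`` is
  ``(z * z_step, y * pixel_size_xy, x * pixel_size_xy)`` in µm;
* all physical quantities are µm / µm² / µm³.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

CHANNEL_NUCLEI = "nuclei"
CHANNEL_ACTIN = "actin"
CHANNELS = (CHANNEL_NUCLEI, CHANNEL_ACTIN)


class StackReadError(ValueError):
    """Raised when a file cannot be interpreted as a two-channel z-stack."""


@dataclass(frozen=True)
class Calibration:
    """Physical voxel calibration.

    Parameters
    ----------
    pixel_size_xy:
        Lateral pixel size in µm per pixel (must be positive).  Typical
        high-content systems with a 20x water objective fall around
        0.6–1.5 µm/px after binning; this value must come from acquisition
        metadata.
    z_step:
        Axial distance between consecutive slices in µm (default 5.0).
    """

    pixel_size_xy: float
    z_step: float = 5.0

    def __post_init__(self) -> None:
        if not (self.pixel_size_xy > 0):
            raise ValueError(f"pixel_size_xy must be > 0, got {self.pixel_size_xy}")
        if not (self.z_step > 0):
            raise ValueError(f"z_step must be > 0, got {self.z_step}")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_xy ** 2

    def um_to_px(self, length_um: float) -> int:
        """Convert a physical length to a pixel count, rounding half up.

        A strictly positive length never rounds below 1 px so that a
        nominally non-zero structuring element is never the identity.
        """
        if length_um < 0:
            raise ValueError("length_um must be >= 0")
        if length_um == 0:
            return 0
        return max(1, int(np.floor(length_um / self.pixel_size_xy + 0.5)))

    def scaled(self, s: float) -> "Calibration":
        return Calibration(self.pixel_size_xy * s, self.z_step * s)


@dataclass
class ImageStack:
    """A calibrated two-channel 3D voxel grid.

    ``channels`` maps the channel name (``"nuclei"``, ``"actin"``) to a
    float array of shape ``(n_slices, height, width)``.
    """

    channels: dict[str, np.ndarray]
    calibration: Calibration
    stack_id: str = "stack"

    def __post_init__(self) -> None:
        if set(self.channels) != set(CHANNELS):
            raise StackReadError(
                f"channel count / names must be exactly {CHANNELS}, got {sorted(self.channels)}"
            )
        shapes = {name: np.asarray(a).shape for name, a in self.channels.items()}
        for name, a in self.channels.items():
            a = np.asarray(a, dtype=float)
            if a.ndim != 3 or a.shape[0] < 1:
                raise StackReadError(f"channel {name!r} must be a (z, y, x) array with >=1 slice")
            if not np.all(np.isfinite(a)) or np.any(a < 0):
                raise StackReadError(f"channel {name!r} contains non-finite or negative intensities")
            self.channels[name] = a
        if len({s for s in shapes.values()}) != 1:
            raise StackReadError(f"channel shapes differ: {shapes}")

    @property
    def nuclei(self) -> np.ndarray:
        return self.channels[CHANNEL_NUCLEI]

    @property
    def actin(self) -> np.ndarray:
        return self.channels[CHANNEL_ACTIN]

    @property
    def n_slices(self) -> int:
        return self.nuclei.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.nuclei.shape[1:]


@dataclass(frozen=True)
class FusedSlice:
    """A single z-slice after channel fusion; values lie in [0, 1]."""

    raster: np.ndarray
    z_index: int


def _minmax(a: np.ndarray) -> np.ndarray:
    """Min–max rescale to [0, 1]; a constant (zero-range) image maps to zeros.

    The all-zeros convention for degenerate channels lets blank slices flow
    through the pipeline instead of erroring.
    """
    a = np.asarray(a, dtype=float)
    lo = float(a.min())
    hi = float(a.max())
    if hi <= lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def fuse_channels(
    stack: ImageStack,
    z: int,
    mode: str = "max",
    weights: tuple[float, float] = (0.5, 0.5),
) -> FusedSlice:
    """Fuse the nuclei ("cells") and actin ("walls") channels of one slice.

    Each channel slice is min–max normalized to [0, 1] independently, then
    combined pixelwise: ``mode="max"`` (default) takes the maximum,
    ``mode="weighted-sum"`` takes ``w_n * nuclei + w_a * actin`` and
    re-normalizes the result to [0, 1].
    """
    if not (0 <= z < stack.n_slices):
        raise IndexError(f"z={z} out of range for stack with {stack.n_slices} slices")
    nuc = _minmax(stack.nuclei[z])
    act = _minmax(stack.actin[z])
    if mode == "max":
        fused = np.maximum(nuc, act)
    elif mode == "weighted-sum":
        fused = _minmax(weights[0] * nuc + weights[1] * act)
    else:
        raise ValueError(f"unknown fuse mode {mode!r}")
    return FusedSlice(raster=fused, z_index=z)


# ---------------------------------------------------------------------------
# TIFF reading / writing
# ---------------------------------------------------------------------------

def read_stack(
    path: str | Path,
    calibration: Calibration,
    channel_map: Mapping[str, int] | None = None,
    stack_id: str | None = None,
) -> ImageStack:
    """Read a two-channel z-stack from a multi-page TIFF or OME-TIFF.

    ``channel_map`` maps channel names to their index along the channel
    axis (default ``{"nuclei": 0, "actin": 1}``).  Accepted page layouts:

    * 4-D array ``(Z, C, Y, X)`` or ``(C, Z, Y, X)`` with C == 2
      (the axis of length 2 is taken as the channel axis);
    * 3-D array of ``2 * Z`` pages, channel-interleaved per z
      (page ``2 * z + c`` holds channel ``c`` of slice ``z``).

    File-level calibration metadata, if any, is overridden by the explicit
    ``calibration`` argument.
    """
    path = Path(path)
    channel_map = dict(channel_map or {CHANNEL_NUCLEI: 0, CHANNEL_ACTIN: 1})
    if set(channel_map) != set(CHANNELS):
        raise StackReadError(f"channel_map must name exactly {CHANNELS}")
    try:
        with tifffile.TiffFile(path) as tf:
            pages = [p.shape for p in tf.pages]
            if len(set(pages)) > 1:
                bad = next(i for i, s in enumerate(pages) if s != pages[0])
                raise StackReadError(
                    f"{path.name}: ragged slice shapes (page {bad} is {pages[bad]}, "
                    f"page 0 is {pages[0]})"
                )
            arr = tf.asarray()
    except StackReadError:
        raise
    except Exception as exc:  # pragma: no cover - passthrough of tifffile errors
        raise StackReadError(f"unreadable TIFF {path}: {exc}") from exc

    if arr.ndim == 4:
        if arr.shape[1] == 2:
            zcyx = arr
        elif arr.shape[0] == 2:
            zcyx = np.moveaxis(arr, 0, 1)
        else:
            raise StackReadError(
                f"{path.name}: channel count != 2 (4-D shape {arr.shape})"
            )
    elif arr.ndim == 3:
        n_pages = arr.shape[0]
        if n_pages % 2 != 0:
            raise StackReadError(
                f"{path.name}: channel count != 2 ({n_pages} pages cannot interleave 2 channels)"
            )
        zcyx = arr.reshape(n_pages // 2, 2, *arr.shape[1:])
    elif arr.ndim == 2:
        raise StackReadError(f"{path.name}: channel count != 2 (single page)")
    else:
        raise StackReadError(f"{path.name}: unsupported array shape {arr.shape}")

    channels = {
        name: np.asarray(zcyx[:, idx], dtype=float)
        for name, idx in channel_map.items()
    }
    default_id = path.stem
    if default_id.endswith(".ome"):
        default_id = default_id[: -len(".ome")]
    return ImageStack(
        channels=channels,
        calibration=calibration,
        stack_id=stack_id or default_id,
    )


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as OME-TIFF with ZCYX axes and physical pixel sizes."""
    path = Path(path)
    zcyx = np.stack([stack.nuclei, stack.actin], axis=1).astype(np.float32)
    tifffile.imwrite(
        path,
        zcyx,
        ome=True,
        metadata={
            "axes": "ZCYX",
            "PhysicalSizeX": stack.calibration.pixel_size_xy,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.calibration.pixel_size_xy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.calibration.z_step,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": [CHANNEL_NUCLEI, CHANNEL_ACTIN]},
        },
    )


def write_label_masks(labels: np.ndarray, path: str | Path) -> None:
    """Write per-slice lumen label masks as a 16-bit multi-page TIFF."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored as uint16")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_label_masks(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(np.uint16)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

LUMEN_COLUMNS = [
    "stack_id", "lumen_id", "n_slices", "z_min", "z_max",
    "volume_um3", "surface_area_um2",
]
SUMMARY_COLUMNS = ["stack_id", "lumen_count", "total_volume_um3"]


def summary_path_for(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + "_summary" + path.suffix)


def write_report(report, path: str | Path) -> None:
    """Write a MicrotissueReport as two RFC-4180 CSV files.

    ``path`` receives one row per 3D lumen; a sibling file with the
    ``_summary`` suffix receives the per-stack summary row (lumen count and
    total luminal volume in µm³).
    """
    path = Path(path)
    rows = [
        {
            "stack_id": report.stack_id,
            "lumen_id": lum.group.group_id,
            "n_slices": len(lum.group.members),
            "z_min": lum.group.z_min,
            "z_max": lum.group.z_max,
            "volume_um3": lum.volume_um3,
            "surface_area_um2": lum.surface_area_um2,
        }
        for lum in report.lumens
    ]
    pd.DataFrame(rows, columns=LUMEN_COLUMNS).to_csv(path, index=False, lineterminator="\r\n")
    summary = pd.DataFrame(
        [{
            "stack_id": report.stack_id,
            "lumen_count": report.lumen_count,
            "total_volume_um3": report.total_volume_um3,
        }],
        columns=SUMMARY_COLUMNS,
    )
    summary.to_csv(summary_path_for(path), index=False, lineterminator="\r\n")


def read_report(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back the per-lumen and summary CSVs written by :func:`write_report`."""
    path = Path(path)
    return pd.read_csv(path), pd.read_csv(summary_path_for(path))


# ---------------------------------------------------------------------------
# Configuration files
# ---------------------------------------------------------------------------

def load_config_file(path: str | Path) -> dict:
    """Load a YAML (or plain ``key: value``) configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data


def dump_config_file(config: Mapping, path: str | Path) -> None:
    def _plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: _plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(_plain(dict(config)), fh, sort_keys=True)
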