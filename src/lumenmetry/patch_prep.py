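"""Phase-II preparation: cut standardized patches around candidate voids.

Each candidate void is turned into a fixed-size intensity patch cut from
the fused slice, so that a classifier can judge whether the void is a true
lumen (dark core enclosed by a bright actin wall) or a false one.  The
candidate's bounding box is dilated by a physical margin so the patch
includes the surrounding wall, the window is intensity-remapped to [0, 1],
and resampled to ``side x side`` pixels with aspect preserved by
zero-padding the shorter axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

from .detect2d import CandidateLumen2D
from .image_io import Calibration, FusedSlice

DEFAULT_MARGIN_UM = 5.0
DEFAULT_SIDE = 64


@dataclass(frozen=True)
class LumenPatch:
    """A standardized classifier input.

    ``pixels`` is ``side x side`` with values in [0, 1];
    ``scale_factor`` is the ratio of patch side to the (padded, square)
    source window side; ``source_bbox`` is the margin-expanded, clipped
    pixel box ``(y0, x0, y1, x1)`` the window was cut from.
    """

    candidate_id: str
    pixels: np.ndarray = field(repr=False)
    scale_factor: float
    source_bbox: tuple[int, int, int, int]

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


def _rescale01(window: np.ndarray) -> np.ndarray:
    lo, hi = float(window.min()), float(window.max())
    if hi <= lo:  # constant window: degenerate remap convention
        return np.zeros_like(window, dtype=float)
    return (window - lo) / (hi - lo)


def prepare_patch(
    candidate: CandidateLumen2D,
    fused: FusedSlice,
    calibration: Calibration,
    margin_um: float = DEFAULT_MARGIN_UM,
    side: int = DEFAULT_SIDE,
) -> LumenPatch:
    """Dilate, remap and cut one candidate from the fused image.

    The bounding box grows by ``margin_um`` on all four sides (clipped to
    the image), the window is min–max remapped to [0, 1] (a constant
    window maps to zeros), symmetrically zero-padded to a square, and
    resampled to ``side x side`` by bilinear interpolation.
    """
    if candidate.z_index != fused.z_index:
        raise ValueError(
            f"candidate z={candidate.z_index} does not match fused slice z={fused.z_index}"
        )
    y0, x0, y1, x1 = candidate.bbox
    if y1 <= y0 or x1 <= x0:
        raise ValueError(f"degenerate bbox {candidate.bbox} for {candidate.candidate_id}")
    h_img, w_img = fused.raster.shape
    m = calibration.um_to_px(margin_um) if margin_um > 0 else 0
    y0e, x0e = max(0, y0 - m), max(0, x0 - m)
    y1e, x1e = min(h_img, y1 + m), min(w_img, x1 + m)
    window = _rescale01(np.asarray(fused.raster[y0e:y1e, x0e:x1e], dtype=float))

    h, w = window.shape
    size = max(h, w)
    pad_y, pad_x = size - h, size - w
    window = np.pad(
        window,
        ((pad_y // 2, pad_y - pad_y // 2), (pad_x // 2, pad_x - pad_x // 2)),
        mode="constant",
    )
    pixels = resize(
        window,
        (side, side),
        order=1,
        mode="constant",
        anti_aliasing=size > side,
        preserve_range=True,
    )
    return LumenPatch(
        candidate_id=candidate.candidate_id,
        pixels=np.clip(pixels, 0.0, 1.0),
        scale_factor=side / size,
        source_bbox=(y0e, x0e, y1e, x1e),
    )


# ---------------------------------------------------------------------------
# Patch archives (for external labeling tools)
# ---------------------------------------------------------------------------

def export_patch_archive(patches: list[LumenPatch], directory: str | Path) -> Path:
    """Write one 8-bit PNG per patch plus ``index.csv``.

    The index records candidate_id, filename, scale_factor and source
    bbox so external labeling tools can produce a labels CSV
    (``candidate_id,label``) for training.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for patch in patches:
        fname = f"{patch.candidate_id}.png"
        iio.imwrite(
            directory / fname,
            np.round(patch.pixels * 255).astype(np.uint8),
        )
        rows.append(
            {
                "candidate_id": patch.candidate_id,
                "file": fname,
                "scale_factor": patch.scale_factor,
                "bbox": "/".join(map(str, patch.source_bbox)),
            }
        )
    index = directory / "index.csv"
    pd.DataFrame(rows, columns=["candidate_id", "file", "scale_factor", "bbox"]).to_csv(
        index, index=False
    )
    return index


def load_patch_archive(directory: str | Path) -> list[LumenPatch]:
    """Read patches back from an archive written by :func:`export_patch_archive`."""
    directory = Path(directory)
    index = pd.read_csv(directory / "index.csv")
    patches = []
    for row in index.itertuples():
        pixels = iio.imread(directory / row.file).astype(float) / 255.0
        y0, x0, y1, x1 = (int(v) for v in row.bbox.split("/"))
        patches.append(
            LumenPatch(
                candidate_id=row.candidate_id,
                pixels=pixels,
                scale_factor=float(row.scale_factor),
                source_bbox=(y0, x0, y1, x1),
            )
        )
    return patches
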