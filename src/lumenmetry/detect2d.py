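"""Phase-I lumen detection on single z-slices.

A lumen appears in an optical section as a void: a dark region with the
same intensity class as the background, enclosed by the bright cellular
signal.  Imperfect staining and imaging leave gaps in the enclosing wall,
so a void is often connected to the outside background and would be missed
by naive connected-component analysis.  The pipeline therefore:

1. binarizes the fused slice (between-class-variance threshold after light
   Gaussian smoothing);
2. applies morphological closing with a disk, repeatedly, with a schedule
   of growing radii (6 µm start, 5 µm increments, 8 iterations by
   default) so that progressively wider wall gaps get sealed;
3. after each closing, labels the connected components of the *background*
   phase, discards the single largest one (the true outside background),
   and keeps the rest as candidate voids;
4. superimposes the candidates of all iterations, keeping one copy of each
   physical void — its largest detected form, since larger disks shrink
   the same void in place.

The output is a set of :class:`CandidateLumen2D` per slice, subject to
true/false classification downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk

from .image_io import Calibration, FusedSlice

#: complementary connectivity pairing: voids (background phase) are
#: 4-connected, cellular foreground is 8-connected, which avoids the
#: topological paradox of a 4-connected curve failing to separate the plane.
VOID_CONNECTIVITY = 1
FOREGROUND_CONNECTIVITY = 2


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of the phase-I pipeline.

    Attributes
    ----------
    r0:
        Initial closing-disk radius in µm (default 6).  Kept deliberately
        small in the first iteration so that small lumens are not closed
        over entirely and lost.
    dr:
        Radius increment per iteration in µm (default 5).
    n_iter:
        Number of closing iterations (default 8).
    min_area_um2:
        Minimum candidate area in µm² (default 25); suppresses noise specks.
    border_filter:
        If true, drop void components touching the slice border.  Off by
        default: background rejection already removes the one largest
        background component and nothing else.
    binarize_method:
        ``"otsu"`` (between-class-variance maximization, default) or
        ``"fixed"`` (compare against ``fixed_threshold``).
    fixed_threshold:
        Threshold in [0, 1] used when ``binarize_method == "fixed"``.
    smoothing_sigma:
        Gaussian pre-smoothing sigma in pixels (default 1.0; 0 disables).
    radius_is_diameter:
        Interpret the schedule values as disk diameters instead of radii.
    """

    r0: float = 6.0
    dr: float = 5.0
    n_iter: int = 8
    min_area_um2: float = 25.0
    border_filter: bool = False
    binarize_method: str = "otsu"
    fixed_threshold: float = 0.5
    smoothing_sigma: float = 1.0
    radius_is_diameter: bool = False

    def __post_init__(self) -> None:
        if not (self.r0 > 0):
            raise ValueError("r0 must be > 0")
        if self.dr < 0:
            raise ValueError("dr must be >= 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.min_area_um2 < 0:
            raise ValueError("min_area_um2 must be >= 0")
        if self.binarize_method not in ("otsu", "fixed"):
            raise ValueError("binarize_method must be 'otsu' or 'fixed'")


@dataclass(frozen=True)
class BinarySlice:
    """Boolean raster of one z-slice; True marks cellular foreground."""

    mask: np.ndarray
    z_index: int


@dataclass(frozen=True)
class CandidateLumen2D:
    """One connected void component on one z-slice.

    ``mask`` is a full-frame boolean raster containing a single
    4-connected component; ``bbox`` is the tight half-open pixel box
    ``(y0, x0, y1, x1)``; ``first_iter`` records the closing iteration
    (1-based) at which this, the component's largest detected form, was
    found.
    """

    z_index: int
    mask: np.ndarray = field(repr=False)
    area_um2: float
    bbox: tuple[int, int, int, int]
    first_iter: int
    candidate_id: str

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def iteration_radii(config: DetectionConfig) -> list[float]:
    """Disk-size schedule in µm: ``[r0, r0+dr, ..., r0+(n_iter-1)*dr]``."""
    return [config.r0 + i * config.dr for i in range(config.n_iter)]


def binarize_slice(fused: FusedSlice, config: DetectionConfig = DetectionConfig()) -> BinarySlice:
    """Convert a fused slice to a black-and-white image.

    Foreground = pixels strictly above an automatically chosen threshold
    that maximizes between-class variance (Otsu), computed after Gaussian
    smoothing with ``config.smoothing_sigma``.  Constant images yield
    all-background by convention.
    """
    img = np.asarray(fused.raster, dtype=float)
    if config.smoothing_sigma > 0:
        img = gaussian(img, sigma=config.smoothing_sigma, preserve_range=True)
    if config.binarize_method == "fixed":
        thresh = config.fixed_threshold
    else:
        if np.ptp(img) == 0:
            return BinarySlice(mask=np.zeros(img.shape, dtype=bool), z_index=fused.z_index)
        thresh = threshold_otsu(img)
    return BinarySlice(mask=img > thresh, z_index=fused.z_index)


def disk_radius_px(radius_um: float, config: DetectionConfig, calibration: Calibration) -> int:
    """Scheduled disk size in pixels (radius semantics unless configured)."""
    if config.radius_is_diameter:
        radius_um = radius_um / 2.0
    return calibration.um_to_px(radius_um)


def close_mask(
    binary: BinarySlice,
    radius_um: float,
    calibration: Calibration,
    config: DetectionConfig = DetectionConfig(),
) -> BinarySlice:
    """Morphological closing (dilation then erosion) with a disk element.

    The disk contains the pixel offsets ``(dy, dx)`` with
    ``dy² + dx² <= r²`` where ``r = round(radius_um / pixel_size_xy)``
    (half-up, minimum 1 px for any positive physical radius).  The image is
    treated as embedded in an infinite zero background: the mask is padded
    by ``r`` before dilation so that closing is exactly the unbounded
    operation restricted to the frame.  Closing is extensive
    (result ⊇ input) and idempotent.
    """
    if radius_um < 0:
        raise ValueError("radius_um must be >= 0")
    r = disk_radius_px(radius_um, config, calibration) if radius_um > 0 else 0
    if r == 0:
        return BinarySlice(mask=binary.mask.copy(), z_index=binary.z_index)
    fp = disk(r).astype(bool)
    padded = np.pad(binary.mask, r, mode="constant", constant_values=False)
    dil = ndi.binary_dilation(padded, structure=fp)
    ero = ndi.binary_erosion(dil, structure=fp, border_value=0)
    return BinarySlice(mask=ero[r:-r, r:-r], z_index=binary.z_index)


def extract_voids(
    closed: BinarySlice,
    config: DetectionConfig,
    calibration: Calibration,
    iteration: int = 1,
) -> list[CandidateLumen2D]:
    """Connected void components of a closed slice, minus the background.

    Labels the 4-connected components of the background (non-foreground)
    phase, removes the single largest component — which represents the
    outside background; area ties break to the smallest label, hence
    deterministically — then drops components below ``min_area_um2`` and,
    if ``border_filter`` is set, components touching the slice border.
    """
    voids = ~closed.mask
    labels = cc_label(voids, connectivity=VOID_CONNECTIVITY)
    n = labels.max()
    if n == 0:
        return []
    areas_px = np.bincount(labels.ravel())[1:]  # label i -> areas_px[i-1]
    background_label = int(np.argmax(areas_px)) + 1  # first max = smallest label
    out: list[CandidateLumen2D] = []
    for prop in regionprops(labels):
        lab = prop.label
        if lab == background_label:
            continue
        area_um2 = prop.area * calibration.pixel_area_um2
        if area_um2 < config.min_area_um2:
            continue
        y0, x0, y1, x1 = prop.bbox
        if config.border_filter:
            h, w = labels.shape
            if y0 == 0 or x0 == 0 or y1 == h or x1 == w:
                continue
        out.append(
            CandidateLumen2D(
                z_index=closed.z_index,
                mask=labels == lab,
                area_um2=float(area_um2),
                bbox=(y0, x0, y1, x1),
                first_iter=iteration,
                candidate_id=f"z{closed.z_index:03d}-i{iteration}-c{lab}",
            )
        )
    return out


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _bbox_intersects(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> bool:
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]


def superimpose(candidates_by_iter: list[list[CandidateLumen2D]]) -> list[CandidateLumen2D]:
    """Merge candidates found at different closing iterations of one slice.

    Candidates whose masks share at least one pixel are detections of the
    same physical void (transitive closure over pairwise overlap).  Each
    equivalence class is represented once by its maximum-area member; area
    ties break to the earliest iteration, then to the lexicographically
    smallest candidate id.  Every returned mask is one of the input masks
    verbatim.
    """
    flat = [c for group in candidates_by_iter for c in group]
    if not flat:
        return []
    uf = _UnionFind(len(flat))
    for i, j in itertools.combinations(range(len(flat)), 2):
        a, b = flat[i], flat[j]
        if _bbox_intersects(a.bbox, b.bbox) and np.any(a.mask & b.mask):
            uf.union(i, j)
    classes: dict[int, list[CandidateLumen2D]] = {}
    for i, c in enumerate(flat):
        classes.setdefault(uf.find(i), []).append(c)
    reps = [
        min(members, key=lambda c: (-c.n_pixels, c.first_iter, c.candidate_id))
        for members in classes.values()
    ]
    reps.sort(key=lambda c: (c.bbox, c.candidate_id))
    return reps


def detect_slice(
    fused: FusedSlice,
    config: DetectionConfig,
    calibration: Calibration,
) -> list[CandidateLumen2D]:
    """Full phase-I pipeline for one slice.

    Binarize, then for every radius in the schedule: close and extract
    voids; finally superimpose all iterations.  Candidate ids are unique
    within the slice.
    """
    binary = binarize_slice(fused, config)
    per_iter: list[list[CandidateLumen2D]] = []
    for it, radius in enumerate(iteration_radii(config), start=1):
        closed = close_mask(binary, radius, calibration, config)
        per_iter.append(extract_voids(closed, config, calibration, iteration=it))
    return superimpose(per_iter)
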