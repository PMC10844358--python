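"""Synthetic two-channel spheroid z-stacks with full ground truth.

The generator emulates what the pipeline sees in cleared, Hoechst +
phalloidin stained microtissue stacks: a bright roughly spherical cell
mass (actin rendered as a continuous bright region, nuclei as speckled
dots) on a dark background, containing dark ellipsoidal voids.  Three void
archetypes are rendered:

``lumen``
    A true lumen: fully rimmed by bright cell signal, optionally with a
    boundary gap — a dark corridor of specified width connecting the void
    to the outside background, emulating imperfect staining/imaging.  Only
    a closing disk wide enough to seal the corridor encloses such a void.
``dimhole``
    A rimless texture hole: an in-shell void whose surrounding actin is
    locally dimmed, so it binarizes as an enlarged enclosed void without a
    genuine bright rim — a false lumen.
``pocket``
    A shell-exterior background pocket: a dim debris ring outside the
    spheroid enclosing plain background — a false lumen.

Every void carries an analytic ellipsoid volume (4/3 π a b c) and a
true/false label, so detection, classification and volumetry are all
verifiable without any external data.  Output is bit-identical for
identical specs (all randomness flows from the spec seed through
``numpy.random.default_rng``; per-slice streams are spawned in fixed
order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from .classify import FALSE_LUMEN, TRUE_LUMEN, LabeledPatch, ORACLE_OVERLAP_FRACTION
from .detect2d import DetectionConfig, detect_slice
from .image_io import Calibration, ImageStack, fuse_channels
from .patch_prep import prepare_patch

# rendering intensity levels (arbitrary fluorescence units, pre-noise)
BACKGROUND_LEVEL = 0.03
ACTIN_LEVEL = 0.85
ACTIN_TEXTURE = 0.05
NUCLEUS_LEVEL = 0.92
NUCLEI_BACKGROUND = 0.03
DIM_RIM_LEVEL = 0.35
POCKET_RING_LEVEL = 0.55
POCKET_RING_NUCLEI = 0.25

#: minimum cell-wall thickness between a true void and the spheroid surface
RIM_MARGIN_UM = 12.0


@dataclass(frozen=True)
class VoidSpec:
    """One ellipsoidal void.

    ``center_um`` is the physical (z, y, x) center; ``radii_um`` the
    (rz, ry, rx) semi-axes.  ``gap_width_um`` > 0 carves a boundary gap of
    that width from the void toward +x (true lumens only).
    """

    center_um: tuple[float, float, float]
    radii_um: tuple[float, float, float]
    is_true_lumen: bool = True
    kind: str = "lumen"  # "lumen" | "dimhole" | "pocket"
    gap_width_um: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("lumen", "dimhole", "pocket"):
            raise ValueError(f"unknown void kind {self.kind!r}")
        if self.is_true_lumen and self.kind != "lumen":
            raise ValueError("only kind='lumen' voids can be true lumens")
        if min(self.radii_um) <= 0:
            raise ValueError("void radii must be positive")

    @property
    def analytic_volume_um3(self) -> float:
        rz, ry, rx = self.radii_um
        return 4.0 / 3.0 * np.pi * rz * ry * rx


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic stack (the generator's input)."""

    seed: int
    image_size: tuple[int, int] = (176, 176)
    n_slices: int = 36
    calibration: Calibration = field(default_factory=lambda: Calibration(2.0, 5.0))
    spheroid_radius_um: float = 80.0
    spheroid_center_um: tuple[float, float, float] | None = None
    lumens: tuple[VoidSpec, ...] = ()
    noise_sigma: float = 0.05
    nuclei_density_per_um2: float = 0.004
    stack_id: str = "synthetic"

    @property
    def center(self) -> np.ndarray:
        if self.spheroid_center_um is not None:
            return np.asarray(self.spheroid_center_um, dtype=float)
        h, w = self.image_size
        return np.array(
            [
                (self.n_slices - 1) / 2.0 * self.calibration.z_step,
                (h - 1) / 2.0 * self.calibration.pixel_size_xy,
                (w - 1) / 2.0 * self.calibration.pixel_size_xy,
            ]
        )

    def validate(self) -> None:
        c = self.center
        R = self.spheroid_radius_um
        for i, v in enumerate(self.lumens):
            d = float(np.linalg.norm(np.asarray(v.center_um) - c))
            if v.kind == "pocket":
                if d < R + max(v.radii_um):
                    raise ValueError(f"pocket {i} overlaps the spheroid shell")
            else:
                if d + max(v.radii_um) > R - 2.0:
                    raise ValueError(f"lumen {i} outside the spheroid")


@dataclass
class SyntheticGroundTruth:
    """Generator-side truth for a rendered stack."""

    void_masks: np.ndarray = field(repr=False)  # (Z, H, W) int16, 0 = none
    cell_masks: np.ndarray = field(repr=False)  # (Z, H, W) bool
    labels: dict[int, bool]  # void id (1-based) -> is_true_lumen
    analytic_volumes_um3: dict[int, float]
    kinds: dict[int, str]

    @property
    def expected_lumen_count(self) -> int:
        return sum(1 for t in self.labels.values() if t)

    @property
    def expected_total_volume_um3(self) -> float:
        return float(
            sum(v for i, v in self.analytic_volumes_um3.items() if self.labels[i])
        )

    @property
    def true_masks(self) -> np.ndarray:
        true_ids = [i for i, t in self.labels.items() if t]
        return np.isin(self.void_masks, true_ids)


def _ellipse_mask(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float,
                  ry: float, rx: float) -> np.ndarray:
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate(spec: SyntheticSpec) -> tuple[ImageStack, SyntheticGroundTruth]:
    """Render a stack and its ground truth.  Deterministic given the spec."""
    spec.validate()
    ps = spec.calibration.pixel_size_xy
    zs = spec.calibration.z_step
    h, w = spec.image_size
    cz, cy, cx = spec.center
    R = spec.spheroid_radius_um

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    yy *= ps
    xx *= ps

    actin = np.full((spec.n_slices, h, w), BACKGROUND_LEVEL)
    nuclei = np.full((spec.n_slices, h, w), NUCLEI_BACKGROUND)
    void_masks = np.zeros((spec.n_slices, h, w), dtype=np.int16)
    cell_masks = np.zeros((spec.n_slices, h, w), dtype=bool)

    root = np.random.default_rng(spec.seed)
    slice_rngs = root.spawn(spec.n_slices)
    noise_rng = root.spawn(1)[0]

    for z in range(spec.n_slices):
        zp = z * zs
        rng = slice_rngs[z]
        # spheroid cross-section
        dz2 = (zp - cz) ** 2
        cell = np.zeros((h, w), dtype=bool)
        if dz2 < R ** 2:
            rsl = float(np.sqrt(R ** 2 - dz2))
            cell = _ellipse_mask(yy, xx, cy, cx, rsl, rsl)

        dim = np.zeros((h, w), dtype=bool)
        ring = np.zeros((h, w), dtype=bool)

        for vid, v in enumerate(spec.lumens, start=1):
            vz, vy, vx = v.center_um
            rz, ry, rx = v.radii_um
            s = 1.0 - ((zp - vz) / rz) ** 2
            if v.kind == "pocket":
                # spherical-shell debris ring with enclosed background
                ro = max(v.radii_um)
                t = 6.0
                out2 = ro ** 2 - (zp - vz) ** 2
                in2 = (ro - t) ** 2 - (zp - vz) ** 2
                if out2 > 0:
                    d2 = (yy - vy) ** 2 + (xx - vx) ** 2
                    outer = d2 <= out2
                    inner = d2 <= in2 if in2 > 0 else np.zeros_like(outer)
                    ring |= outer & ~inner
                    if in2 > 0:
                        void_masks[z][inner] = vid
                continue
            if s <= 0:
                continue
            ell = _ellipse_mask(yy, xx, vy, vx, ry * np.sqrt(s), rx * np.sqrt(s))
            void_masks[z][ell & cell] = vid
            cell &= ~ell
            if v.kind == "dimhole":
                halo = _ellipse_mask(
                    yy, xx, vy, vx, ry * np.sqrt(s) + 6.0, rx * np.sqrt(s) + 6.0
                )
                dim |= halo & cell
            elif v.gap_width_um > 0:
                corridor = (np.abs(yy - vy) <= v.gap_width_um / 2.0) & (xx >= vx)
                cell &= ~corridor

        cell_masks[z] = cell
        # actin: continuous bright wall texture over the cell mass
        tex = rng.uniform(-ACTIN_TEXTURE, ACTIN_TEXTURE, size=(h, w))
        a = actin[z]
        a[cell] = ACTIN_LEVEL + tex[cell]
        a[dim] = DIM_RIM_LEVEL
        a[ring & ~cell] = POCKET_RING_LEVEL
        # nuclei: speckled dots inside the cell mass
        n_cells_px = int(cell.sum())
        if n_cells_px:
            area_um2 = n_cells_px * ps * ps
            n_dots = max(1, int(area_um2 * spec.nuclei_density_per_um2))
            flat = np.flatnonzero(cell)
            centers = flat[rng.integers(0, len(flat), size=n_dots)]
            dots = np.zeros((h, w), dtype=bool)
            dots.ravel()[centers] = True
            dots = ndi.binary_dilation(dots, structure=disk(2).astype(bool)) & cell
            nuclei[z][dots] = NUCLEUS_LEVEL
        nuclei[z][ring & ~cell] = POCKET_RING_NUCLEI

    if spec.noise_sigma > 0:
        actin = actin + noise_rng.normal(0.0, spec.noise_sigma, size=actin.shape)
        nuclei = nuclei + noise_rng.normal(0.0, spec.noise_sigma, size=nuclei.shape)
    actin = np.clip(actin, 0.0, None)
    nuclei = np.clip(nuclei, 0.0, None)

    stack = ImageStack(
        channels={"nuclei": nuclei, "actin": actin},
        calibration=spec.calibration,
        stack_id=spec.stack_id,
    )
    truth = SyntheticGroundTruth(
        void_masks=void_masks,
        cell_masks=cell_masks,
        labels={i: v.is_true_lumen for i, v in enumerate(spec.lumens, start=1)},
        analytic_volumes_um3={
            i: v.analytic_volume_um3 for i, v in enumerate(spec.lumens, start=1)
        },
        kinds={i: v.kind for i, v in enumerate(spec.lumens, start=1)},
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Randomized specs (the default study conditions)
# ---------------------------------------------------------------------------

def random_spec(
    seed: int,
    n_true: tuple[int, int] = (1, 4),
    n_decoy: tuple[int, int] = (0, 2),
    radius_range_um: tuple[float, float] = (10.0, 30.0),
    gap_probability: float = 0.5,
    gap_range_um: tuple[float, float] = (5.0, 10.0),
    stack_id: str | None = None,
) -> SyntheticSpec:
    """Draw a random stack spec: 1–4 true ellipsoidal lumens of 10–30 µm
    semi-axes, 0–2 decoys, optionally one boundary gap of 5–10 µm.

    Placement is rejection-sampled so voids stay inside the spheroid with
    a ``RIM_MARGIN_UM`` wall, never touch one another, and no other void
    crosses a gap corridor.
    """
    rng = np.random.default_rng(seed)
    base = SyntheticSpec(seed=seed, stack_id=stack_id or f"synthetic-{seed}")
    c = base.center
    R = base.spheroid_radius_um
    h, w = base.image_size
    ps, zs = base.calibration.pixel_size_xy, base.calibration.z_step
    zmax = (base.n_slices - 1) * zs

    voids: list[VoidSpec] = []

    def _separated(center, radius) -> bool:
        for v in voids:
            if v.kind == "pocket":
                continue
            d = float(np.linalg.norm(np.asarray(v.center_um) - center))
            if d < max(v.radii_um) + radius + 14.0:
                return False
        return True

    k_true = int(rng.integers(n_true[0], n_true[1] + 1))
    for _ in range(k_true):
        for _attempt in range(200):
            r_base = rng.uniform(*radius_range_um)
            radii = np.clip(
                r_base * rng.uniform(0.85, 1.15, size=3), *radius_range_um
            )
            rmax = float(radii.max())
            budget = R - RIM_MARGIN_UM - rmax
            if budget <= 0:
                continue
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            center = c + u * rng.uniform(0, budget)
            if _separated(center, rmax):
                voids.append(
                    VoidSpec(tuple(center), tuple(radii), is_true_lumen=True)
                )
                break
        else:  # pragma: no cover - generous attempt budget
            break

    k_decoy = int(rng.integers(n_decoy[0], n_decoy[1] + 1))
    for _ in range(k_decoy):
        kind = str(rng.choice(["pocket", "dimhole"]))
        if kind == "dimhole":
            for _attempt in range(200):
                r = float(rng.uniform(8.0, 14.0))
                budget = R - RIM_MARGIN_UM - r - 8.0  # keep clear of the dim halo
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                center = c + u * rng.uniform(0, max(budget, 0))
                if budget > 0 and _separated(center, r + 8.0):
                    voids.append(
                        VoidSpec(tuple(center), (r, r, r), is_true_lumen=False, kind=kind)
                    )
                    break
        else:
            for _attempt in range(200):
                ro = float(rng.uniform(14.0, 18.0))
                ang = rng.uniform(0, 2 * np.pi)
                d_lo = R + ro + 8.0
                # stay inside the lateral field of view
                dy, dx = np.sin(ang), np.cos(ang)
                lim_y = ((h - 1) * ps / 2 - ro - 6.0) / abs(dy) if dy else np.inf
                lim_x = ((w - 1) * ps / 2 - ro - 6.0) / abs(dx) if dx else np.inf
                d_hi = min(lim_y, lim_x)
                if d_hi <= d_lo:
                    continue
                d = rng.uniform(d_lo, d_hi)
                zc = rng.uniform(ro + 2.5, zmax - ro - 2.5)
                center = np.array([zc, c[1] + dy * d, c[2] + dx * d])
                voids.append(
                    VoidSpec(tuple(center), (ro, ro, ro), is_true_lumen=False, kind=kind)
                )
                break

    # at most one boundary gap, on a true lumen whose +x corridor is clear
    if voids and rng.uniform() < gap_probability:
        true_idx = [i for i, v in enumerate(voids) if v.is_true_lumen]
        true_idx = [true_idx[k] for k in rng.permutation(len(true_idx))]
        for i in true_idx:
            g = float(rng.uniform(*gap_range_um))
            vz, vy, vx = voids[i].center_um
            clear = True
            for j, o in enumerate(voids):
                if j == i or o.kind == "pocket":
                    continue
                oz, oy, ox = o.center_um
                rv = max(o.radii_um) + 4.0
                if abs(oy - vy) < g / 2.0 + 6.0 + rv and ox + rv > vx:
                    clear = False
                    break
            if clear:
                voids[i] = replace(voids[i], gap_width_um=g)
                break

    return replace(base, lumens=tuple(voids))


# ---------------------------------------------------------------------------
# Labeled training patches
# ---------------------------------------------------------------------------

def make_patch_training_set(
    specs: list[SyntheticSpec],
    n: int,
    seed: int,
    config: DetectionConfig | None = None,
    margin_um: float = 5.0,
    side: int = 64,
) -> list[LabeledPatch]:
    """Build a balanced labeled patch set from generated stacks.

    Phase-I detection runs on every generated stack; each candidate is
    labeled true when at least half of its pixels fall inside a
    ground-truth true void, false otherwise, then ``n/2`` patches of each
    label are drawn (seeded).  If balance cannot be reached the maximal
    balanced subset is returned with a warning.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    config = config or DetectionConfig()
    pos: list[LabeledPatch] = []
    neg: list[LabeledPatch] = []
    for spec in specs:
        stack, truth = generate(spec)
        true_masks = truth.true_masks
        for z in range(stack.n_slices):
            fused = fuse_channels(stack, z)
            for cand in detect_slice(fused, config, stack.calibration):
                frac = float((cand.mask & true_masks[z]).sum()) / max(1, cand.n_pixels)
                label = TRUE_LUMEN if frac >= ORACLE_OVERLAP_FRACTION else FALSE_LUMEN
                patch = prepare_patch(cand, fused, stack.calibration, margin_um, side)
                (pos if label == TRUE_LUMEN else neg).append(LabeledPatch(patch, label))
    rng = np.random.default_rng(seed)
    pos = [pos[i] for i in rng.permutation(len(pos))]
    neg = [neg[i] for i in rng.permutation(len(neg))]
    half = n // 2
    k = min(half, len(pos), len(neg))
    if k < half:
        warnings.warn(
            f"could not reach {half}/{half} balance; returning {k}/{k} patches",
            stacklevel=2,
        )
    out = pos[:k] + neg[:k]
    return [out[i] for i in rng.permutation(len(out))]
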