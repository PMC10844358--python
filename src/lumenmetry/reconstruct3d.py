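"""Grouping of accepted 2D lumens into 3D lumens and alpha-shape volumetry.

Accepted 2D lumens are grouped across slices by vertical bounding-box
overlap; a run of slices with no member ("gap") wider than ``max_gap``
splits a group, because such a stack most probably holds several
vertically stacked lumens.  Each group's boundary pixels become a physical
point cloud and an alpha shape — a circumradius-filtered Delaunay complex —
provides the enclosing surface whose volume (µm³) and surface area (µm²)
are reported.

Each optical section represents a slab of thickness ``z_step``; boundary
points are placed at every member's section plane, and the terminal
sections are repeated half a slab outward (``z ∓ z_step/2``), so the
reconstructed solid interpolates linearly between sections and caps the
ends with half-slab extrusions — consistent with the extrusion convention
used for single-slice lumens (``volume = area * z_step``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import Delaunay, QhullError

from .detect2d import CandidateLumen2D, _UnionFind, _bbox_intersects
from .image_io import Calibration

logger = logging.getLogger(__name__)

MAX_CLOUD_POINTS = 20_000


@dataclass(frozen=True)
class LumenGroup:
    """Accepted 2D lumens forming one 3D lumen; members sorted by z."""

    members: tuple[CandidateLumen2D, ...]
    group_id: str

    @property
    def z_levels(self) -> list[int]:
        return sorted({m.z_index for m in self.members})

    @property
    def z_min(self) -> int:
        return self.members[0].z_index

    @property
    def z_max(self) -> int:
        return self.members[-1].z_index


@dataclass
class Lumen3D:
    """A reconstructed lumen with its measured volume and surface area."""

    group: LumenGroup
    point_cloud: np.ndarray = field(repr=False)  # (n, 3) physical (z, y, x) µm
    volume_um3: float
    surface_area_um2: float
    method: str  # "alpha" or "extrusion"
    alpha_um: float | None = None
    mesh: object | None = field(default=None, repr=False)  # trimesh.Trimesh


@dataclass
class MicrotissueReport:
    """Per-stack summary: every identified lumen plus the headline totals."""

    stack_id: str
    lumens: list[Lumen3D]

    @property
    def lumen_count(self) -> int:
        return len(self.lumens)

    @property
    def total_volume_um3(self) -> float:
        return float(sum(l.volume_um3 for l in self.lumens))


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def group_lumens(
    accepted: list[CandidateLumen2D],
    max_gap: int = 0,
    mask_overlap: bool = False,
) -> list[LumenGroup]:
    """Partition accepted 2D lumens into 3D groups.

    Two lumens on different slices are linked when their xy bounding boxes
    intersect (or their masks, with ``mask_overlap=True``) and their
    z-distance is at most ``max_gap + 1``.  Connected components of this
    graph are provisional groups; each is then split at z-gaps wider than
    ``max_gap`` (a gap is a run of z-levels between members with no
    member).  Group ids are assigned deterministically in (z_min, bbox)
    order.  Every accepted lumen ends up in exactly one group.
    """
    nodes = sorted(accepted, key=lambda c: (c.z_index, c.bbox, c.candidate_id))
    if not nodes:
        return []
    uf = _UnionFind(len(nodes))
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            a, b = nodes[i], nodes[j]
            dz = abs(a.z_index - b.z_index)
            if dz == 0 or dz > max_gap + 1:
                continue
            if not _bbox_intersects(a.bbox, b.bbox):
                continue
            if mask_overlap and not np.any(a.mask & b.mask):
                continue
            uf.union(i, j)

    components: dict[int, list[CandidateLumen2D]] = {}
    for i, c in enumerate(nodes):
        components.setdefault(uf.find(i), []).append(c)

    raw_groups: list[list[CandidateLumen2D]] = []
    for members in components.values():
        members.sort(key=lambda c: (c.z_index, c.bbox, c.candidate_id))
        # split at z-gaps wider than max_gap
        current = [members[0]]
        for m in members[1:]:
            if m.z_index - current[-1].z_index > max_gap + 1:
                raw_groups.append(current)
                current = [m]
            else:
                current.append(m)
        raw_groups.append(current)

    raw_groups.sort(key=lambda g: (g[0].z_index, g[0].bbox, g[0].candidate_id))
    return [
        LumenGroup(members=tuple(g), group_id=f"g{i:03d}")
        for i, g in enumerate(raw_groups)
    ]


# ---------------------------------------------------------------------------
# Point clouds
# ---------------------------------------------------------------------------

_CROSS = ndi.generate_binary_structure(2, 1)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """(y, x) indices of mask pixels with a 4-neighbor outside the mask."""
    inner = ndi.binary_erosion(mask, structure=_CROSS, border_value=0)
    return np.argwhere(mask & ~inner)


def build_point_cloud(
    group: LumenGroup,
    calibration: Calibration,
    max_points: int = MAX_CLOUD_POINTS,
    seed: int = 0,
) -> np.ndarray:
    """Physical (z, y, x) µm point cloud of a group's boundary rings.

    A pixel classified as void stands for its whole ``pixel_size_xy``
    square, so each member contributes the midpoints of its *exposed*
    pixel edges — the polygonal boundary of the union of void-pixel
    squares, whose enclosed area equals the pixel-count area — at its
    section plane ``z * z_step``.  The first and last members additionally
    repeat their rings half a slab out (``z ∓ z_step/2``): the
    reconstructed solid then interpolates linearly between section planes
    and extrudes the terminal sections over their half-slabs, which keeps
    the single-slice extrusion convention as the one-member limit.
    Duplicate points are removed; clouds larger than ``max_points`` are
    uniformly subsampled with a fixed seed.
    """
    if not group.members:
        raise ValueError("group has no members")
    ps, zs = calibration.pixel_size_xy, calibration.z_step
    z_lo = group.members[0].z_index
    z_hi = group.members[-1].z_index
    pts = []
    for m in group.members:
        mask = m.mask
        edge_pts = []
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            # neighbor in direction (dy, dx); out-of-frame neighbors are outside
            neighbor = np.roll(mask, (-dy, -dx), axis=(0, 1))
            if dy > 0:
                neighbor[-1, :] = False
            elif dy < 0:
                neighbor[0, :] = False
            if dx > 0:
                neighbor[:, -1] = False
            elif dx < 0:
                neighbor[:, 0] = False
            exposed = np.argwhere(mask & ~neighbor).astype(float)
            exposed[:, 0] += 0.5 * dy
            exposed[:, 1] += 0.5 * dx
            edge_pts.append(exposed)
        yx = np.concatenate(edge_pts, axis=0) * ps
        zc = m.z_index * zs
        planes = [zc]
        if m.z_index == z_lo:
            planes.append(zc - zs / 2.0)
        if m.z_index == z_hi:
            planes.append(zc + zs / 2.0)
        for zp in planes:
            pts.append(np.column_stack([np.full(len(yx), zp), yx]))
    cloud = np.unique(np.concatenate(pts, axis=0), axis=0)
    if len(cloud) > max_points:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(cloud), size=max_points, replace=False))
        cloud = cloud[idx]
    return cloud


# ---------------------------------------------------------------------------
# Alpha complex
# ---------------------------------------------------------------------------

def _tetrahedra_geometry(points: np.ndarray, simplices: np.ndarray):
    """Per-tetrahedron circumradius and volume (degenerate tets -> inf, 0)."""
    a, b, c, d = (points[simplices[:, i]] for i in range(4))
    ab, ac, ad = b - a, c - a, d - a
    det = np.einsum("ij,ij->i", ab, np.cross(ac, ad))
    vol = np.abs(det) / 6.0
    # circumcenter relative to a solves 2 M x = |row|^2 rowwise
    M = np.stack([ab, ac, ad], axis=1)  # (n, 3, 3)
    rhs = np.stack(
        [np.einsum("ij,ij->i", v, v) for v in (ab, ac, ad)], axis=1
    )
    radii = np.full(len(simplices), np.inf)
    good = np.abs(det) > 1e-12
    if good.any():
        x = np.linalg.solve(2.0 * M[good], rhs[good][..., None])[..., 0]
        radii[good] = np.linalg.norm(x, axis=1)
    return radii, vol


def _outside_tets(neighbors: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Non-kept tetrahedra face-reachable from the convex-hull exterior.

    Non-kept tets form the "empty space" of the alpha complex; those
    connected to a hull facet (neighbor index -1) through other non-kept
    tets are outside the shape.  Non-kept tets *not* reachable are
    cavities enclosed by the alpha surface.
    """
    outside = np.zeros(len(neighbors), dtype=bool)
    stack = [
        i for i in np.flatnonzero(~keep) if -1 in neighbors[i]
    ]
    outside[stack] = True
    while stack:
        i = stack.pop()
        for nb in neighbors[i]:
            if nb != -1 and not keep[nb] and not outside[nb]:
                outside[nb] = True
                stack.append(nb)
    return outside


def _connected_one_region(simplices: np.ndarray, keep: np.ndarray, n_points: int) -> bool:
    """True when kept tets cover all points and form one face-connected region."""
    kept_idx = np.flatnonzero(keep)
    if len(kept_idx) == 0:
        return False
    kept = simplices[kept_idx]
    if len(np.unique(kept)) != n_points:
        return False
    uf = _UnionFind(len(kept_idx))
    face_owner: dict[tuple[int, int, int], int] = {}
    for ti, tet in enumerate(kept):
        for f in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
            key = tuple(sorted((tet[f[0]], tet[f[1]], tet[f[2]])))
            if key in face_owner:
                uf.union(face_owner[key], ti)
            else:
                face_owner[key] = ti
    root = uf.find(0)
    return all(uf.find(i) == root for i in range(len(kept_idx)))


class AlphaShape3D:
    """3D alpha shape of a point set.

    The alpha complex keeps the Delaunay tetrahedra whose circumradius is
    at most ``alpha`` (in the same units as the points).  ``alpha="auto"``
    selects the smallest circumradius threshold for which the kept
    tetrahedra cover every point and form a single face-connected region —
    the usual "one enclosing region" default.

    For boundary-sampled solids the kept tets form a crust around an
    internal cavity; the reported volume is the *enclosed* volume: kept
    tets plus any cavity tets unreachable from the hull exterior through
    non-kept tets.  The surface is the triangle set separating that
    enclosed region from the outside.
    """

    def __init__(self, points: np.ndarray, alpha: float | str = "auto") -> None:
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3 or len(points) < 4:
            raise ValueError("need at least 4 points in 3D")
        try:
            tri = Delaunay(points)
        except QhullError:
            tri = Delaunay(points, qhull_options="QJ Qbb Qz")
        self.points = points
        self._simplices = tri.simplices
        self._neighbors = tri.neighbors
        self._radii, self._vols = _tetrahedra_geometry(points, tri.simplices)
        self._centroid_tet = int(
            Delaunay.find_simplex(tri, points.mean(axis=0)[None, :])[0]
        )
        if alpha == "auto":
            self.alpha = self._auto_alpha()
        else:
            self.alpha = float(alpha)
        self._keep = self._radii <= self.alpha
        self._region = ~_outside_tets(self._neighbors, self._keep)

    def _acceptable(self, alpha: float) -> bool:
        """One all-point-covering connected region whose interior is sealed.

        A crust that covers every point can still leak: surface holes let
        the flood fill drain the cavity.  Requiring the enclosed region to
        contain the cloud centroid rejects leaky crusts — for a
        boundary-sampled void the cavity empties or fills as a whole.
        """
        keep = self._radii <= alpha
        if not _connected_one_region(self._simplices, keep, len(self.points)):
            return False
        if self._centroid_tet >= 0:
            region = ~_outside_tets(self._neighbors, keep)
            if not region[self._centroid_tet]:
                return False
        return True

    def _auto_alpha(self) -> float:
        candidates = np.unique(self._radii[np.isfinite(self._radii)])
        if len(candidates) == 0:
            raise ValueError("all tetrahedra degenerate")
        lo, hi = 0, len(candidates) - 1
        if not self._acceptable(candidates[hi]):
            # no threshold is acceptable; keep every finite tetrahedron
            return float(candidates[hi])
        while lo < hi:
            mid = (lo + hi) // 2
            if self._acceptable(candidates[mid]):
                hi = mid
            else:
                lo = mid + 1
        return float(candidates[lo])

    @property
    def volume(self) -> float:
        return float(self._vols[self._region].sum())

    def boundary_faces(self) -> np.ndarray:
        """Triangles separating the enclosed region from the outside.

        Local face ``f`` of a tetrahedron is the one opposite its ``f``-th
        vertex, matching the scipy Delaunay ``neighbors`` convention.
        """
        faces = []
        region = self._region
        for i in np.flatnonzero(region):
            for f in range(4):
                nb = self._neighbors[i, f]
                if nb == -1 or not region[nb]:
                    faces.append(np.delete(self._simplices[i], f))
        if not faces:
            return np.empty((0, 3), dtype=int)
        return np.sort(np.asarray(faces), axis=1)

    @property
    def surface_area(self) -> float:
        faces = self.boundary_faces()
        if len(faces) == 0:
            return 0.0
        p = self.points
        cross = np.cross(p[faces[:, 1]] - p[faces[:, 0]], p[faces[:, 2]] - p[faces[:, 0]])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())


# ---------------------------------------------------------------------------
# Reconstruction and summary
# ---------------------------------------------------------------------------

def _extrusion_measures(group: LumenGroup, calibration: Calibration) -> tuple[float, float]:
    """Extrusion convention: each member is a z_step-thick prism.

    ``volume = sum area * z_step``; ``surface = sum (2 * area +
    perimeter * z_step)`` — exact for a single-slice group, an upper bound
    for the degenerate multi-slice fallback (internal prism faces are not
    subtracted).
    """
    ps, zs = calibration.pixel_size_xy, calibration.z_step
    volume = 0.0
    surface = 0.0
    for m in group.members:
        area = m.n_pixels * ps * ps
        perimeter = len(boundary_pixels(m.mask)) * ps
        volume += area * zs
        surface += 2.0 * area + perimeter * zs
    return volume, surface


def reconstruct(
    group: LumenGroup,
    calibration: Calibration,
    alpha: float | str = "auto",
    seed: int = 0,
    build_mesh: bool = False,
) -> Lumen3D:
    """Reconstruct one 3D lumen and measure its volume and surface area.

    Groups spanning at least two distinct z-levels are reconstructed with
    an alpha shape of the slab-face boundary cloud (``alpha="auto"``
    selects the smallest alpha yielding one connected enclosing region; a
    fixed alpha is interpreted in µm).  Single-slice groups use the
    extrusion convention: ``volume = area * z_step`` and
    ``surface = 2 * area + perimeter * z_step``.  Degenerate multi-slice
    clouds fall back to extrusion with a logged warning.
    """
    cloud = build_point_cloud(group, calibration, seed=seed)
    if len(group.z_levels) < 2:
        volume, surface = _extrusion_measures(group, calibration)
        return Lumen3D(group, cloud, volume, surface, method="extrusion")
    try:
        shape = AlphaShape3D(cloud, alpha=alpha)
    except (ValueError, QhullError) as exc:
        logger.warning(
            "group %s: alpha shape failed (%s); falling back to extrusion",
            group.group_id, exc,
        )
        volume, surface = _extrusion_measures(group, calibration)
        return Lumen3D(group, cloud, volume, surface, method="extrusion")
    mesh = None
    if build_mesh:
        import trimesh

        mesh = trimesh.Trimesh(
            vertices=shape.points[:, ::-1],  # (x, y, z) for viewers
            faces=shape.boundary_faces(),
            process=False,
        )
    return Lumen3D(
        group,
        cloud,
        shape.volume,
        shape.surface_area,
        method="alpha",
        alpha_um=shape.alpha,
        mesh=mesh,
    )


def export_mesh(lumen: Lumen3D, path) -> None:
    """Export a lumen surface as PLY or OBJ (by file suffix)."""
    if lumen.mesh is None:
        raise ValueError("lumen has no mesh; reconstruct with build_mesh=True")
    lumen.mesh.export(path)


def summarize(stack_id: str, lumens: list[Lumen3D]) -> MicrotissueReport:
    """Per-stack report: lumen count and total luminal volume.

    An empty list is a valid result — microtissues with no detected lumen
    are a biologically meaningful outcome.
    """
    return MicrotissueReport(stack_id=stack_id, lumens=list(lumens))
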