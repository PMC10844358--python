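"""Shared fixtures: calibrations, small synthetic stacks, training patches."""

from __future__ import annotations

import numpy as np
import pytest

from lumenmetry import (
    Calibration,
    CandidateLumen2D,
    FusedSlice,
    SyntheticSpec,
    VoidSpec,
    generate,
    group_lumens,
    make_patch_training_set,
    random_spec,
)


@pytest.fixture(scope="session")
def cal2() -> Calibration:
    """2 µm/px, 5 µm z-step — the default synthetic imaging geometry."""
    return Calibration(pixel_size_xy=2.0, z_step=5.0)


@pytest.fixture(scope="session")
def cal1() -> Calibration:
    """1 µm/px, 2 µm z-step — fine geometry for digitized-shape tests."""
    return Calibration(pixel_size_xy=1.0, z_step=2.0)


def make_candidate(mask: np.ndarray, z: int = 0, first_iter: int = 1,
                   label: int = 1, pixel_size: float = 1.0) -> CandidateLumen2D:
    ys, xs = np.where(mask)
    return CandidateLumen2D(
        z_index=z,
        mask=mask,
        area_um2=float(mask.sum()) * pixel_size ** 2,
        bbox=(int(ys.min()), int(xs.min()), int(ys.max()) + 1, int(xs.max()) + 1),
        first_iter=first_iter,
        candidate_id=f"z{z:03d}-i{first_iter}-c{label}",
    )


def annulus_slice(size: int = 64, center: tuple[float, float] = (32.0, 32.0),
                  r_inner: float = 10.0, r_outer: float = 16.0,
                  gap_px: float = 0.0) -> FusedSlice:
    """Bright ring with a dark interior void, optionally with a boundary gap
    of ``gap_px`` width opening toward +x."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy, cx = center
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    ring = (d2 >= r_inner ** 2) & (d2 <= r_outer ** 2)
    if gap_px > 0:
        ring &= ~((np.abs(yy - cy) <= gap_px / 2.0) & (xx >= cx))
    return FusedSlice(raster=ring.astype(float), z_index=0)


def digitized_ball_candidates(radius_um: float, calibration: Calibration,
                              size: int = 60) -> list[CandidateLumen2D]:
    """Per-slice cross-section masks of a ball, as accepted candidates."""
    zs = calibration.z_step
    ps = calibration.pixel_size_xy
    c_px = size / 2.0
    cz = radius_um + 2 * zs
    yy, xx = np.mgrid[0:size, 0:size].astype(float) * ps
    members = []
    n_slices = int(np.ceil(2 * (radius_um + 2 * zs) / zs))
    for z in range(n_slices):
        s = radius_um ** 2 - (z * zs - cz) ** 2
        if s <= 0:
            continue
        m = (yy - c_px * ps) ** 2 + (xx - c_px * ps) ** 2 <= s
        if not m.any():
            continue
        members.append(make_candidate(m, z=z, pixel_size=ps))
    return members


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A compact two-lumen, one-decoy stack for fast pipeline tests."""
    return SyntheticSpec(
        seed=5,
        image_size=(112, 112),
        n_slices=16,
        calibration=Calibration(2.0, 5.0),
        spheroid_radius_um=40.0,
        lumens=(
            VoidSpec((32.5, 97.0, 97.0), (13.0, 12.0, 12.0)),
            VoidSpec((45.0, 127.0, 127.0), (12.0, 12.0, 12.0)),
            VoidSpec((37.5, 196.0, 111.0), (12.0, 12.0, 12.0),
                     is_true_lumen=False, kind="pocket"),
        ),
        stack_id="small",
    )


@pytest.fixture(scope="session")
def small_stack(small_spec):
    return generate(small_spec)


@pytest.fixture(scope="session")
def training_patches():
    """Balanced n=200 labeled patch set from eight randomized stacks."""
    specs = [random_spec(100 + i) for i in range(8)]
    return make_patch_training_set(specs, 200, seed=7)


@pytest.fixture(scope="session")
def geometry_recovery_runs():
    """Twenty randomized stacks analyzed end-to-end with the oracle classifier.

    Session-scoped because this is the most expensive computation in the
    suite; several tests assert different properties of the same runs.
    """
    from lumenmetry import OracleClassifier, RunConfig, analyze_stack

    results = []
    for seed in range(1, 21):
        spec = random_spec(seed)
        stack, truth = generate(spec)
        clf = OracleClassifier(truth.true_masks)
        config = RunConfig(calibration=spec.calibration, seed=seed)
        report = analyze_stack(stack, config, clf)
        results.append((spec, truth, report))
    return results
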