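"""Brute-force reference implementations used as independent test oracles.

Deliberately naive: shift-based morphology and BFS flood fill, written
without scipy/skimage morphology so they share no code path with the
package implementation.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def disk_offsets(r: int) -> list[tuple[int, int]]:
    return [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dy * dy + dx * dx <= r * r
    ]


def brute_close(mask: np.ndarray, r: int) -> np.ndarray:
    """Dilation then erosion with a radius-r disk over an infinite zero plane."""
    if r == 0:
        return mask.copy()
    offs = disk_offsets(r)
    h, w = mask.shape
    pad = 2 * r
    big = np.zeros((h + 2 * pad, w + 2 * pad), dtype=bool)
    big[pad : pad + h, pad : pad + w] = mask
    dil = np.zeros_like(big)
    for dy, dx in offs:
        dil |= np.roll(big, (dy, dx), axis=(0, 1))
    ero = np.ones_like(big)
    for dy, dx in offs:
        ero &= np.roll(dil, (dy, dx), axis=(0, 1))
    return ero[pad : pad + h, pad : pad + w]


def flood_components(mask: np.ndarray) -> list[frozenset[tuple[int, int]]]:
    """4-connected components of True pixels, in raster-scan discovery order."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for y0 in range(h):
        for x0 in range(w):
            if not mask[y0, x0] or seen[y0, x0]:
                continue
            comp = []
            q = deque([(y0, x0)])
            seen[y0, x0] = True
            while q:
                y, x = q.popleft()
                comp.append((y, x))
                for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        q.append((ny, nx))
            comps.append(frozenset(comp))
    return comps


def oracle_void_components(
    closed_foreground: np.ndarray, min_area_px: float
) -> list[frozenset[tuple[int, int]]]:
    """Void components after largest-background removal and the area filter.

    Ties for largest break to the earliest raster-scan component, which is
    the component with the smallest label under raster-scan labeling.
    """
    comps = flood_components(~closed_foreground)
    if not comps:
        return []
    largest = max(range(len(comps)), key=lambda i: (len(comps[i]), -i))
    return [
        c
        for i, c in enumerate(comps)
        if i != largest and len(c) >= min_area_px
    ]


def exhaustive_otsu_classify(img: np.ndarray) -> np.ndarray:
    """Foreground by the threshold maximizing between-class variance,
    found by exhaustive search over midpoints of adjacent distinct values."""
    vals = np.unique(img)
    if len(vals) < 2:
        return np.zeros(img.shape, dtype=bool)
    best_t, best_v = None, -1.0
    flat = img.ravel()
    for t in (vals[:-1] + vals[1:]) / 2.0:
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0 = len(lo) / len(flat)
        w1 = 1.0 - w0
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return img > best_t


def random_blob_mask(rng: np.random.Generator, shape=(64, 64), p: float = 0.45,
                     smooth: int = 2) -> np.ndarray:
    """Random connected-ish binary mask via box-smoothed noise thresholding."""
    noise = rng.random(shape)
    k = 2 * smooth + 1
    csum = np.cumsum(np.cumsum(np.pad(noise, (smooth + 1, smooth)), axis=0), axis=1)
    box = (
        csum[k:, k:] - csum[:-k, k:] - csum[k:, :-k] + csum[:-k, :-k]
    ) / (k * k)
    return box > np.quantile(box, 1 - p)
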