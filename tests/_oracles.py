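"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — direct enumeration, flood fill,
pairwise scans — and shares no code with the package internals it checks.
"""

from __future__ import annotations

from collections import deque

import numpy as np

_N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_N8 = _N4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def flood_fill_label(mask: np.ndarray, connectivity: int) -> list[set]:
    """Connected components of a boolean mask via BFS flood fill.

    Returns a list of pixel-coordinate sets, one per component, in raster
    order of each component's first pixel.
    """
    nbrs = _N4 if connectivity == 4 else _N8
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                q = deque([(r, c)])
                seen[r, c] = True
                while q:
                    y, x = q.popleft()
                    comp.add((y, x))
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] \
                                and not seen[ny, nx]:
                            seen[ny, nx] = True
                            q.append((ny, nx))
                comps.append(comp)
    return comps


def brute_feret(coords: np.ndarray) -> float:
    """Max pairwise distance over ALL pixel-corner points (no hull)."""
    pts = set()
    for r, c in np.asarray(coords):
        for dr in (0, 1):
            for dc in (0, 1):
                pts.add((r + dr, c + dc))
    pts = np.array(sorted(pts), dtype=float)
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def mann_whitney_auc(pos, neg) -> float:
    """AUC as the Mann-Whitney pair probability, ties counted 1/2."""
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def brute_opening_ball(arr: np.ndarray, radius: float) -> np.ndarray:
    """Grayscale opening with a ball-top structuring element.

    Direct min/max over explicit footprint offsets with symmetric boundary
    padding (matching scipy.ndimage's 'reflect' convention).
    """
    arr = np.asarray(arr, dtype=float)
    r = int(np.ceil(radius))
    offs = []
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            d2 = dy * dy + dx * dx
            if d2 <= radius * radius:
                offs.append((dy, dx, np.sqrt(radius * radius - d2)))
    h, w = arr.shape
    pad = np.pad(arr, r, mode="symmetric")
    ero = np.full((h, w), np.inf)
    for dy, dx, b in offs:
        ero = np.minimum(ero, pad[r + dy:r + dy + h, r + dx:r + dx + w] - b)
    pade = np.pad(ero, r, mode="symmetric")
    dil = np.full((h, w), -np.inf)
    for dy, dx, b in offs:
        dil = np.maximum(dil, pade[r + dy:r + dy + h, r + dx:r + dx + w] + b)
    return dil


def brute_opening_ball_full(arr: np.ndarray, radius: float) -> np.ndarray:
    """Exact ball opening when the ball footprint covers the whole image.

    Mirror-padding is immaterial in that regime: every reflected copy of a
    pixel lies at least as far away as the original, so it can never win
    the erosion minimum or the dilation maximum.
    """
    arr = np.asarray(arr, dtype=float)
    h, w = arr.shape
    assert radius ** 2 >= (h - 1) ** 2 + (w - 1) ** 2, "footprint must cover image"
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.stack([ys.ravel(), xs.ravel()], axis=1).astype(float)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    b = np.sqrt(radius * radius - d2)
    flat = arr.ravel()
    ero = (flat[None, :] - b).min(axis=1)
    return (ero[None, :] + b).max(axis=1).reshape(h, w)


def otsu_between_class_variance(arr: np.ndarray, threshold: float,
                                nbins: int = 256) -> float:
    """Between-class variance of the split at ``threshold`` (bin-based)."""
    arr = np.asarray(arr, dtype=float).ravel()
    counts, edges = np.histogram(arr, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    lower = centers <= threshold
    w0 = counts[lower].sum()
    w1 = counts[~lower].sum()
    if w0 == 0 or w1 == 0:
        return 0.0
    mu0 = (counts[lower] * centers[lower]).sum() / w0
    mu1 = (counts[~lower] * centers[~lower]).sum() / w1
    return float(w0 * w1 * (mu0 - mu1) ** 2)


def brute_otsu(arr: np.ndarray, nbins: int = 256) -> float:
    """Between-class-variance maximization over histogram bin centers."""
    arr = np.asarray(arr, dtype=float).ravel()
    _, edges = np.histogram(arr, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return float(max(centers[:-1],
                     key=lambda t: otsu_between_class_variance(arr, t, nbins)))
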