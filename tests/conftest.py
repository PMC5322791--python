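"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

import thallometry as tm

STRUCT8 = np.ones((3, 3), dtype=int)


# ---------------------------------------------------------------------------
# random blob shapes (thinning / distance-map batteries)
# ---------------------------------------------------------------------------

def random_blobs(seed: int, size: int = 64) -> np.ndarray:
    """Seeded random blob image: discs and rectangles, sometimes a hole."""
    rng = np.random.default_rng(seed)
    mask = np.zeros((size, size), dtype=bool)
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(rng.integers(3, 9)):
        r = rng.integers(4, 11)
        cy, cx = rng.integers(r, size - r, 2)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    for _ in range(rng.integers(2, 5)):
        h, w = rng.integers(4, 20, 2)
        y0 = rng.integers(0, size - h)
        x0 = rng.integers(0, size - w)
        mask[y0:y0 + h, x0:x0 + w] = True
    if rng.random() < 0.4:
        r = rng.integers(2, 5)
        cy, cx = rng.integers(r + 8, size - r - 8, 2)
        hole = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        if (mask & hole).sum() == hole.sum():
            mask &= ~hole
    return mask


def zhang_suen_reference(mask: np.ndarray) -> np.ndarray:
    """Naive per-pixel transcription of the two deletion subiterations.

    Independent of the vectorized implementation: explicit Python loops
    over the eight neighbours P2..P9 in clockwise order from north.
    """
    img = np.pad(np.asarray(mask, dtype=np.uint8), 1)

    def neighbours(i, j):
        return [img[i - 1, j], img[i - 1, j + 1], img[i, j + 1],
                img[i + 1, j + 1], img[i + 1, j], img[i + 1, j - 1],
                img[i, j - 1], img[i - 1, j - 1]]

    changed = True
    while changed:
        changed = False
        for step in (0, 1):
            deletions = []
            for i in range(1, img.shape[0] - 1):
                for j in range(1, img.shape[1] - 1):
                    if img[i, j] != 1:
                        continue
                    P = neighbours(i, j)
                    B = sum(P)
                    if not 2 <= B <= 6:
                        continue
                    seq = P + [P[0]]
                    A = sum(1 for a, b in zip(seq, seq[1:])
                            if a == 0 and b == 1)
                    if A != 1:
                        continue
                    P2, _, P4, _, P6, _, P8, _ = P
                    if step == 0:
                        if P2 * P4 * P6 == 0 and P4 * P6 * P8 == 0:
                            deletions.append((i, j))
                    else:
                        if P2 * P4 * P8 == 0 and P2 * P6 * P8 == 0:
                            deletions.append((i, j))
            for i, j in deletions:
                img[i, j] = 0
                changed = True
    return img[1:-1, 1:-1].astype(bool)


def count_components(mask: np.ndarray) -> int:
    return ndimage.label(mask, structure=STRUCT8)[1]


def count_holes(mask: np.ndarray) -> int:
    """4-connected background components minus the outside."""
    inv = np.pad(~np.asarray(mask, bool), 1, constant_values=True)
    return ndimage.label(inv)[1] - 1


def brute_force_edt(mask: np.ndarray) -> np.ndarray:
    """O(N^2) exhaustive distance-to-background, border as background."""
    from scipy.spatial.distance import cdist

    padded = np.pad(np.asarray(mask, bool), 1)
    fg = np.argwhere(padded)
    bg = np.argwhere(~padded)
    out = np.zeros(padded.shape)
    if len(fg) and len(bg):
        out[tuple(fg.T)] = cdist(fg, bg).min(axis=1)
    return out[1:-1, 1:-1]


# ---------------------------------------------------------------------------
# hand-built skeleton fixtures
# ---------------------------------------------------------------------------

def line_mask(length: int = 20, size: int = 30) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    mask[size // 2, 5:5 + length] = True
    return mask


def y_skeleton() -> np.ndarray:
    """Y: trunk down from the junction at (7,7), two diagonal arms up."""
    mask = np.zeros((16, 16), dtype=bool)
    for r in range(7, 13):
        mask[r, 7] = True          # junction (7,7), trunk to (12,7)
    for k in range(1, 6):
        mask[7 - k, 7 - k] = True  # arm to upper-left
        mask[7 - k, 7 + k] = True  # arm to upper-right
    return mask


def cross_skeleton() -> np.ndarray:
    mask = np.zeros((11, 11), dtype=bool)
    mask[5, 2:9] = True
    mask[2:9, 5] = True
    return mask


def comb_skeleton() -> np.ndarray:
    """Horizontal spine with three upward teeth of lengths 2, 3 and 9.

    The spine stubs left and right of the outermost teeth are >= 5 px so
    that pruning at threshold 5 removes only the short teeth.
    """
    mask = np.zeros((14, 32), dtype=bool)
    mask[11, 1:30] = True
    mask[9:11, 7] = True    # 2-px tooth
    mask[8:11, 15] = True   # 3-px tooth
    mask[2:11, 23] = True   # 9-px tooth
    return mask


def ring_mask(size: int = 61, r_out: int = 25, r_in: int = 15) -> np.ndarray:
    c = size // 2
    yy, xx = np.ogrid[-c:size - c, -c:size - c]
    r2 = yy * yy + xx * xx
    return (r2 <= r_out ** 2) & (r2 >= r_in ** 2)


def theta_mask() -> np.ndarray:
    """Ring plus a horizontal chord: two independent loops."""
    size = 61
    c = size // 2
    yy, xx = np.ogrid[-c:size - c, -c:size - c]
    r2 = yy * yy + xx * xx
    ring = (r2 <= 25 ** 2) & (r2 >= 15 ** 2)
    chord = (r2 <= 25 ** 2) & (np.abs(yy) <= 2)
    return ring | chord


# ---------------------------------------------------------------------------
# pipeline helpers
# ---------------------------------------------------------------------------

def run_pipeline(binary, prune=None):
    """binary -> (skeleton, graphs with DFS orientation, distance map)."""
    if isinstance(binary, np.ndarray):
        binary = tm.BinaryImage(binary)
    dm = tm.distance_map(binary)
    skel = tm.classify_features(tm.thin_zhang_suen(binary))
    if prune is not None:
        skel = tm.prune_spurs(skel, min_length=prune)
    graphs = tm.build_graphs(skel)
    for g in graphs:
        tm.traverse_dfs(g)
    return skel, graphs, dm


def measure_thallus(spec):
    """Generate a thallus and run the full measurement pipeline."""
    binary, truth = tm.generate_thallus(spec)
    skel, graphs, dm = run_pipeline(binary)
    ms = tm.merge_measurements(
        [tm.measure(binary, g, dm=dm) for g in graphs])
    return binary, truth, skel, graphs, ms


@pytest.fixture(scope="session")
def riccardia_table():
    """Simulated four-group table at the published summary statistics."""
    return tm.generate_group_tables(seed=1)
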