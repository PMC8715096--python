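"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from nibstarget.core import BinaryMask, VolumeGrid


@pytest.fixture
def grid12() -> VolumeGrid:
    """Small 12^3 isotropic 3 mm grid centered on the origin."""
    return VolumeGrid.isotropic((12, 12, 12), 3.0)


@pytest.fixture
def default_grid() -> VolumeGrid:
    return VolumeGrid.default()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251)


# --------------------------------------------------------------------------
# independent oracles (kept deliberately naive)

def flood_fill_clusters(mask: np.ndarray, connectivity: int) -> list[set[tuple[int, int, int]]]:
    """Breadth-first flood fill, the reference for connected-component labeling.

    connectivity 6: face neighbors; 18: face+edge; 26: face+edge+corner.
    """
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            i, j, k = queue.popleft()
            comp.add((i, j, k))
            for di, dj, dk in offsets:
                n = (i + di, j + dj, k + dk)
                if all(0 <= n[a] < mask.shape[a] for a in range(3)) and mask[n] and not seen[n]:
                    seen[n] = True
                    queue.append(n)
        comps.append(comp)
    return comps


def brute_force_sphere_count(radius_mm: float, voxel_mm: float, reach: int = 10) -> int:
    """Count lattice offsets with ||voxel_mm * (i,j,k)|| <= radius (inclusive)."""
    count = 0
    for i in range(-reach, reach + 1):
        for j in range(-reach, reach + 1):
            for k in range(-reach, reach + 1):
                if voxel_mm * np.sqrt(i * i + j * j + k * k) <= radius_mm:
                    count += 1
    return count


def random_blob_mask(grid: VolumeGrid, rng: np.random.Generator, p: float = 0.3) -> BinaryMask:
    return BinaryMask(grid, rng.random(grid.shape) < p)
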