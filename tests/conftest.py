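"""Shared fixtures and brute-force oracles.

The oracles deliberately use naive exhaustive algorithms (boundary scans,
BFS flood fill, union-find) so they are independent of the scipy-based
implementations they validate.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from sxtcell import generate_cell_phantom, preset_params, segment_cell


def quick_params(**overrides):
    """Small, fast phantom (96³, ~1.2-μm cell) for unit tests."""
    defaults = dict(
        grid_shape=(96, 96, 96),
        cell_radius_nm=1200.0,
        nucleus_radius_nm=550.0,
        nucleus_offset_nm=100.0,
        n_vesicles=40,
        vesicle_diameter_mean_nm=180.0,
        vesicle_diameter_sd_nm=25.0,
        n_mitochondria=4,
        mito_length_mean_nm=800.0,
        mito_length_sd_nm=80.0,
        mito_length_clip_nm=(650.0, 1000.0),
        mito_radius_nm=120.0,
        n_lipid_droplets=2,
        droplet_diameter_mean_nm=280.0,
        droplet_diameter_sd_nm=25.0,
        seed=11,
    )
    defaults.update(overrides)
    name = defaults.pop("preset", "unstimulated")
    return preset_params(name, **defaults)


@pytest.fixture(scope="session")
def small_cell():
    """One quick docked-mode phantom, generated once per session."""
    params = quick_params()
    volume, gt = generate_cell_phantom(params)
    return params, volume, gt


@pytest.fixture(scope="session")
def small_segmented(small_cell):
    params, volume, gt = small_cell
    label_map, table = segment_cell(
        volume, gt.label_map.cell_mask(), gt.label_map.mask("nucleus")
    )
    return params, volume, gt, label_map, table


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def brute_force_edt(mask: np.ndarray) -> np.ndarray:
    """Per-voxel distance (in voxels) to the nearest outside voxel, by scan."""
    inside = np.argwhere(mask)
    outside = np.argwhere(~mask)
    out = np.zeros(mask.shape, dtype=float)
    for p in inside:
        out[tuple(p)] = np.sqrt(((outside - p) ** 2).sum(axis=1).min())
    return out


def bfs_flood_fill(mask: np.ndarray, seed: tuple[int, int, int]) -> np.ndarray:
    """26-connected flood fill from a seed within a binary mask."""
    assert mask[seed]
    visited = np.zeros_like(mask, dtype=bool)
    queue = deque([seed])
    visited[seed] = True
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    shape = mask.shape
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offsets:
            q = (z + dz, y + dy, x + dx)
            if all(0 <= q[i] < shape[i] for i in range(3)):
                if mask[q] and not visited[q]:
                    visited[q] = True
                    queue.append(q)
    return visited


def union_find_components(mask: np.ndarray, connectivity: int = 26) -> int:
    """Number of connected components by union-find."""
    idx = {tuple(p): i for i, p in enumerate(map(tuple, np.argwhere(mask)))}
    parent = list(range(len(idx)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    if connectivity == 26:
        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    else:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for p, i in idx.items():
        for off in offsets:
            q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
            if q in idx:
                union(i, idx[q])
    return len({find(i) for i in idx.values()})


def lattice_sphere_count(center, radius, shape) -> int:
    """Voxel centers within ``radius`` of ``center`` (both in voxel units)."""
    count = 0
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                p = np.array([z + 0.5, y + 0.5, x + 0.5])
                if np.linalg.norm(p - center) <= radius:
                    count += 1
    return count
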