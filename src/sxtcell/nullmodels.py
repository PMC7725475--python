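"""Constrained random vesicle placements (null models).

Three placement classes test whether an observed vesicle arrangement could
have arisen by chance inside the same cell geometry:

* class 1 — uniform over the cytoplasm restricted to PM distance ≤ T,
* class 2 — uniform over the entire cytoplasmic volume,
* class 3 — uniform over the cytoplasm restricted to PM distance > T,

with T = 20% of the cell's maximum possible PM distance (D_C).  The
cytoplasm excludes the nucleus and the mitochondria.  Points carry an
excluded volume: voxel centers at least ``min_separation`` voxels apart
(default 4).  Each ensemble holds 50 replicates, each with exactly as many
points as vesicles were observed, and converts every replicate into a
distance distribution binned on the same edges as the observed one.

Ties at exactly T go to class 1 (the boundary voxel set is measure-small;
class 3 uses the strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import PlacementError
from .spatial import DistanceDistribution, distribution_from_normalized

PLACEMENT_CLASSES = (1, 2, 3)


@dataclass
class NullModelEnsemble:
    """Replicate random point sets for one cell and one placement class."""

    cell_id: str
    placement_class: int
    threshold_nm: float
    min_separation_voxels: float
    n_points: int
    n_replicates: int
    seed: int
    replicates: list[np.ndarray] = field(default_factory=list)  # (n, 3) voxel indices


def allowed_mask(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    mito_mask: np.ndarray | None,
    placement_class: int,
    distance_field: np.ndarray,
    threshold_nm: float,
) -> np.ndarray:
    """Voxels a random point of the given class may occupy."""
    if placement_class not in PLACEMENT_CLASSES:
        raise ValueError(f"placement class must be in {PLACEMENT_CLASSES}")
    cytoplasm = np.asarray(cell_mask, dtype=bool) & ~np.asarray(nucleus_mask, dtype=bool)
    if mito_mask is not None:
        cytoplasm = cytoplasm & ~np.asarray(mito_mask, dtype=bool)
    if placement_class == 1:
        out = cytoplasm & (distance_field <= threshold_nm)
    elif placement_class == 2:
        out = cytoplasm
    else:
        out = cytoplasm & (distance_field > threshold_nm)
    if not out.any():
        raise ValueError(f"class-{placement_class} allowed volume is empty")
    return out


def sample_placement(
    allowed: np.ndarray,
    n: int,
    min_sep_voxels: float = 4.0,
    seed: int = 0,
    max_attempts: int | None = None,
) -> np.ndarray:
    """``n`` voxel positions uniform over ``allowed`` with pairwise exclusion.

    Rejection sampling over the allowed voxel list; separation is Euclidean
    between voxel centers, in voxel units.  Returns an ``(n, 3)`` integer
    index array; raises :class:`PlacementError` (reporting the achieved
    count) when ``max_attempts`` (default ``100·n``) is exhausted.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    idx = np.argwhere(np.asarray(allowed, dtype=bool))
    if idx.shape[0] == 0 and n > 0:
        raise ValueError("allowed mask is empty")
    rng = np.random.default_rng(seed)
    max_attempts = max_attempts if max_attempts is not None else max(100 * n, 100)
    placed = np.empty((n, 3), dtype=int)
    count = 0
    attempts = 0
    while count < n:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placement infeasible: {count}/{n} points placed with "
                f"min separation {min_sep_voxels} voxels after {attempts} attempts"
            )
        attempts += 1
        cand = idx[rng.integers(idx.shape[0])]
        if count and min_sep_voxels > 0:
            d2 = np.sum((placed[:count] - cand) ** 2, axis=1)
            if d2.min() < min_sep_voxels**2:
                continue
        placed[count] = cand
        count += 1
    return placed


def build_ensemble(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    mito_mask: np.ndarray | None,
    distance_field: np.ndarray,
    placement_class: int,
    n_points: int,
    n_replicates: int = 50,
    seed: int = 0,
    n_bins: int = 20,
    min_sep_voxels: float = 4.0,
    cell_id: str = "",
    threshold_fraction: float = 0.2,
) -> tuple[NullModelEnsemble, list[DistanceDistribution]]:
    """Replicate ensemble plus per-replicate distance distributions.

    ``n_points`` is the observed vesicle count of the cell.  The threshold
    T is ``threshold_fraction × max(distance_field)``; distributions are
    binned over normalized distance with ``n_bins`` shared edges.
    """
    d_c = float(distance_field.max())
    threshold_nm = threshold_fraction * d_c
    mask = allowed_mask(
        cell_mask, nucleus_mask, mito_mask, placement_class, distance_field, threshold_nm
    )
    master = np.random.SeedSequence(seed)
    child_seeds = master.generate_state(n_replicates)
    ensemble = NullModelEnsemble(
        cell_id=cell_id,
        placement_class=placement_class,
        threshold_nm=threshold_nm,
        min_separation_voxels=min_sep_voxels,
        n_points=n_points,
        n_replicates=n_replicates,
        seed=seed,
    )
    distributions = []
    for rep_seed in child_seeds:
        pts = sample_placement(mask, n_points, min_sep_voxels, seed=int(rep_seed))
        ensemble.replicates.append(pts)
        d_obs = distance_field[pts[:, 0], pts[:, 1], pts[:, 2]]
        distributions.append(
            distribution_from_normalized(d_obs / d_c, n_bins=n_bins, d_c_nm=d_c)
        )
    return ensemble, distributions
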