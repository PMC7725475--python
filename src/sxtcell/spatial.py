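"""Distance-transform analytics for vesicle topology.

The plasma-membrane (PM) distance of every in-cell voxel comes from a
Euclidean distance transform of the cell mask (center-to-center, in nm).
Per-cell distances are made comparable across cells of different size and
shape by normalizing with D_C, the maximum possible PM distance of that
cell: d = d_obs / D_C ∈ [0, 1].  Binned normalized distances divided by the
vesicle count give the probability distribution that is later compared to
null models via the Bhattacharyya distance.

Mitochondria–vesicle proximity uses the nearest mitochondrial voxel per
vesicle center, summarized as fractions per 175-nm shell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class DistanceDistribution:
    """Binned probability distribution over normalized PM distance d ∈ [0,1]."""

    bin_edges: np.ndarray
    probabilities: np.ndarray
    n_points: int
    d_c_nm: float

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.bin_edges.ndim != 1 or len(self.bin_edges) != len(self.probabilities) + 1:
            raise ValueError("bin_edges must have len(probabilities)+1 entries")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")
        if self.n_points > 0 and abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    def same_edges(self, other: "DistanceDistribution", atol: float = 1e-12) -> bool:
        return self.bin_edges.shape == other.bin_edges.shape and np.allclose(
            self.bin_edges, other.bin_edges, atol=atol
        )


def distance_field_from_pm(cell_mask: np.ndarray, voxel_edge_nm: float) -> np.ndarray:
    """Euclidean distance (nm) of each in-cell voxel to the nearest outside voxel."""
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("cell mask is empty")
    if cell_mask.all():
        raise ValueError("cell mask covers the whole grid; no PM to measure from")
    return ndimage.distance_transform_edt(cell_mask) * voxel_edge_nm


def _sample_field(field: np.ndarray, centers_nm: np.ndarray, voxel_edge_nm: float) -> np.ndarray:
    centers_nm = np.atleast_2d(np.asarray(centers_nm, dtype=float))
    idx = np.floor(centers_nm / voxel_edge_nm).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.array(field.shape)[None, :]):
        bad = np.where((idx < 0).any(axis=1) | (idx >= np.array(field.shape)).any(axis=1))[0]
        raise ValueError(f"centers {bad.tolist()} fall outside the grid")
    return field[idx[:, 0], idx[:, 1], idx[:, 2]]


def pm_distance_distribution(
    vesicle_centers_nm: np.ndarray,
    distance_field: np.ndarray,
    voxel_edge_nm: float,
    d_c_nm: float | None = None,
    n_bins: int = 20,
) -> DistanceDistribution:
    """Normalized PM-distance distribution of vesicle centers.

    Each center's observed distance is the distance-field value of its
    containing voxel; a center in a zero-distance voxel (outside the cell)
    raises, naming the offending vesicle indices.
    """
    d_obs = _sample_field(distance_field, vesicle_centers_nm, voxel_edge_nm)
    if np.any(d_obs <= 0):
        bad = np.where(d_obs <= 0)[0]
        raise ValueError(f"vesicle centers {bad.tolist()} lie outside the cell")
    if d_c_nm is None:
        d_c_nm = float(distance_field.max())
    d = d_obs / d_c_nm
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    return DistanceDistribution(edges, counts / len(d), len(d), d_c_nm)


def distribution_from_normalized(
    d: np.ndarray, n_bins: int = 20, d_c_nm: float = float("nan")
) -> DistanceDistribution:
    """Distribution directly from normalized distances in [0, 1]."""
    d = np.asarray(d, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    return DistanceDistribution(edges, counts / max(len(d), 1), len(d), d_c_nm)


def mito_vesicle_distances(
    vesicle_centers_nm: np.ndarray,
    mito_mask: np.ndarray,
    voxel_edge_nm: float,
    cell_volume_um3: float | None = None,
    normalize_by_cell_size: bool = False,
) -> np.ndarray:
    """Distance (nm) of each vesicle center to the nearest mitochondrial voxel.

    With ``normalize_by_cell_size`` the distances are divided by the cube
    root of the cell volume (in μm), yielding a dimensionless proximity
    measure that discounts cell size; raw nm distances are the default.
    """
    mito_mask = np.asarray(mito_mask, dtype=bool)
    if not mito_mask.any():
        raise ValueError("mitochondria mask is empty")
    field = ndimage.distance_transform_edt(~mito_mask) * voxel_edge_nm
    d = _sample_field(field, vesicle_centers_nm, voxel_edge_nm)
    if normalize_by_cell_size:
        if not cell_volume_um3 or cell_volume_um3 <= 0:
            raise ValueError("cell volume required for size normalization")
        d = d / (cell_volume_um3 ** (1.0 / 3.0) * 1000.0)
    return d


def shell_fractions(
    distances_nm: np.ndarray, increment_nm: float = 175.0, n_shells: int = 3
) -> np.ndarray:
    """Fraction of distances per concentric shell of width ``increment_nm``.

    Shells are ``[0, w], (w, 2w], ..., ((n-1)·w, ∞)``; the last shell is
    open-ended, so fractions always sum to 1.
    """
    if increment_nm <= 0:
        raise ValueError("shell increment must be positive")
    if n_shells < 2:
        raise ValueError("need at least two shells")
    distances_nm = np.asarray(distances_nm, dtype=float)
    if np.any(distances_nm < 0):
        raise ValueError("distances must be non-negative")
    # shells closed on the right: [0, w], (w, 2w], ..., ((n-1)w, inf)
    idx = np.clip(np.ceil(distances_nm / increment_nm).astype(int) - 1, 0, n_shells - 1)
    counts = np.bincount(idx, minlength=n_shells)
    return counts / max(len(distances_nm), 1)
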