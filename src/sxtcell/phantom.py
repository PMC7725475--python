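"""Synthetic SXT cell phantoms with ground truth.

Generates LAC volumes that emulate soft x-ray tomograms of insulin-secreting
β cells: a roughly spherical ~7-μm cell inside a glass-capillary shell, with
a nucleus, elongated mitochondria, a few high-LAC lipid droplets, and a
population of insulin vesicles whose diameters, LAC values and spatial
arrangement (docked at the plasma membrane, clustered in the interior, in
chains, or diffuse) follow per-condition presets.  Every generated object is
recorded in a ground-truth table and an object-id map, so the downstream
segmentation and spatial statistics can be validated exactly.

Lipid droplets are rendered with a dense core (default 0.70 μm⁻¹ over the
inner 30% of the radius) and a shell value solved from the rasterized voxel
counts so that the object's voxel-mean LAC equals the drawn per-object mean;
this makes the droplets satisfy the max-LAC classification rule while
keeping the printed mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import (
    CAPILLARY,
    CYTOSOL,
    INSULIN_VESICLE,
    LIPID_DROPLET,
    MITOCHONDRIA,
    NUCLEUS,
    DEFAULT_LEGEND,
    LabelMap,
    TomogramVolume,
)

PLACEMENT_MODES = ("docked", "clustered", "chains", "diffuse")


class PlacementError(RuntimeError):
    """Requested object count could not be placed in the available volume."""


@dataclass
class PhantomParams:
    """Full parameterization of one synthetic cell.

    Lengths in nm, LAC values in μm⁻¹.  Defaults correspond to the
    unstimulated condition; see :mod:`sxtcell.presets` for the others.
    """

    voxel_edge_nm: float = 35.0
    grid_shape: tuple[int, int, int] = (256, 256, 256)
    cell_radius_nm: float = 3600.0
    nucleus_radius_nm: float = 1700.0
    nucleus_offset_nm: float = 350.0
    deform_amplitude_nm: float = 0.0

    n_mitochondria: int = 40
    mito_lac_mean: float = 0.34
    mito_lac_sd: float = 0.02
    mito_lac_clip: tuple[float, float] = (0.305, 0.395)
    mito_length_mean_nm: float = 1500.0
    mito_length_sd_nm: float = 300.0
    mito_length_clip_nm: tuple[float, float] = (900.0, 2500.0)
    mito_radius_nm: float = 150.0

    n_lipid_droplets: int = 10
    droplet_diameter_mean_nm: float = 319.0
    droplet_diameter_sd_nm: float = 45.0
    droplet_lac_mean: float = 0.59
    droplet_lac_sd: float = 0.01
    droplet_core_lac: float = 0.70
    droplet_core_radius_fraction: float = 0.3

    n_vesicles: int = 319
    vesicle_diameter_mean_nm: float = 243.0
    vesicle_diameter_sd_nm: float = 39.0
    vesicle_lac_mean: float = 0.39
    vesicle_lac_sd: float = 0.02
    vesicle_lac_clip: tuple[float, float] = (0.355, 0.665)

    placement_mode: str = "docked"
    band_fraction: float = 0.2
    n_clusters: int = 4
    cluster_sigma_nm: float = 800.0
    cluster_interior_fraction: float = 0.5
    chain_spacing_factor: float = 1.2

    cytosol_lac: float = 0.20
    nucleus_lac: float = 0.26
    capillary_lac: float = 0.30
    background_lac: float = 0.10
    noise_sd: float = 0.01

    min_gap_nm: float = 70.0  # clearance between object surfaces (2 voxels)
    max_attempts_factor: int = 300
    seed: int = 0

    def validate(self) -> None:
        if self.placement_mode not in PLACEMENT_MODES:
            raise ValueError(f"unknown placement mode {self.placement_mode!r}")
        lengths = (
            self.voxel_edge_nm, self.cell_radius_nm, self.nucleus_radius_nm,
            self.mito_radius_nm, self.vesicle_diameter_mean_nm,
            self.droplet_diameter_mean_nm,
        )
        if any(x <= 0 for x in lengths):
            raise ValueError("all characteristic lengths must be positive")
        if min(self.n_mitochondria, self.n_lipid_droplets, self.n_vesicles) < 0:
            raise ValueError("object counts must be >= 0")
        if self.nucleus_radius_nm + self.nucleus_offset_nm >= self.cell_radius_nm:
            raise ValueError("nucleus does not fit inside the cell")
        edge = self.voxel_edge_nm
        half_extent = min(self.grid_shape) * edge / 2.0
        cap_outer = half_extent - 2 * edge
        cap_inner = cap_outer - 3 * edge
        if self.cell_radius_nm + 3 * self.deform_amplitude_nm + 2 * edge >= cap_inner:
            raise ValueError("grid too small for the cell plus a capillary shell")
        lo, hi = self.vesicle_lac_clip
        if not (lo < hi):
            raise ValueError("vesicle LAC clip window is empty")

    @property
    def capillary_radii_nm(self) -> tuple[float, float]:
        """(inner, outer) radius of the capillary wall in nm."""
        edge = self.voxel_edge_nm
        outer = min(self.grid_shape[1:]) * edge / 2.0 - 2 * edge
        return outer - 3 * edge, outer


@dataclass
class GroundTruth:
    """Generator-side truth: object table, label map and per-object id map."""

    table: pd.DataFrame
    label_map: LabelMap
    object_ids: np.ndarray  # uint16, 0 = no object

    @property
    def labels(self) -> np.ndarray:
        return self.label_map.labels


# ---------------------------------------------------------------------------
# Rasterization primitives
# ---------------------------------------------------------------------------

def _patch(grid_shape, center_nm, radius_nm, edge):
    """Index slab covering a sphere; None if fully outside the grid."""
    lo = np.floor((np.asarray(center_nm) - radius_nm) / edge).astype(int) - 1
    hi = np.ceil((np.asarray(center_nm) + radius_nm) / edge).astype(int) + 1
    lo_c = np.maximum(lo, 0)
    hi_c = np.minimum(hi, grid_shape)
    if np.any(lo_c >= hi_c):
        return None
    return tuple(slice(a, b) for a, b in zip(lo_c, hi_c))


def _voxel_centers(slices, edge):
    axes = [np.arange(s.start, s.stop) * edge + edge / 2.0 for s in slices]
    return np.meshgrid(*axes, indexing="ij")


def rasterize_sphere(
    values: np.ndarray,
    center_nm,
    diameter_nm: float,
    lac_value: float,
    voxel_edge_nm: float,
    clip: bool = True,
    out_mask: np.ndarray | None = None,
) -> int:
    """Set all voxels whose centers fall within the sphere to ``lac_value``.

    A sphere smaller than one voxel still claims its containing voxel.
    Returns the number of voxels written.  With ``clip=False`` a sphere
    extending past the grid raises instead of being silently clipped; a
    sphere entirely outside the grid always raises.
    """
    if diameter_nm <= 0:
        raise ValueError("diameter must be positive")
    edge = voxel_edge_nm
    center_nm = np.asarray(center_nm, dtype=float)
    r = diameter_nm / 2.0
    if np.any(center_nm + r < 0) or np.any(center_nm - r > np.array(values.shape) * edge):
        raise ValueError("sphere lies entirely outside the grid")
    if not clip:
        if np.any(center_nm - r < 0) or np.any(center_nm + r > np.array(values.shape) * edge):
            raise ValueError("sphere extends outside the grid and clip=False")
    slices = _patch(values.shape, center_nm, r, edge)
    if slices is None:
        raise ValueError("sphere lies entirely outside the grid")
    zz, yy, xx = _voxel_centers(slices, edge)
    inside = (
        (zz - center_nm[0]) ** 2 + (yy - center_nm[1]) ** 2 + (xx - center_nm[2]) ** 2
    ) <= r**2
    if not inside.any():
        # sub-voxel sphere: claim the containing voxel
        idx = np.clip(np.floor(center_nm / edge).astype(int), 0, np.array(values.shape) - 1)
        values[tuple(idx)] = lac_value
        if out_mask is not None:
            out_mask[tuple(idx)] = True
        return 1
    values[slices][inside] = lac_value
    if out_mask is not None:
        out_mask[slices][inside] = True
    return int(inside.sum())


def rasterize_capsule(
    values: np.ndarray,
    a_nm,
    b_nm,
    radius_nm: float,
    lac_value: float,
    voxel_edge_nm: float,
    out_mask: np.ndarray | None = None,
) -> int:
    """Rasterize a capsule (cylinder with hemispherical caps) from a to b."""
    edge = voxel_edge_nm
    a = np.asarray(a_nm, dtype=float)
    b = np.asarray(b_nm, dtype=float)
    lo = np.minimum(a, b) - radius_nm
    hi = np.maximum(a, b) + radius_nm
    center = (lo + hi) / 2.0
    slices = _patch(values.shape, center, float(np.max(hi - lo)) / 2.0, edge)
    if slices is None:
        raise ValueError("capsule lies entirely outside the grid")
    zz, yy, xx = _voxel_centers(slices, edge)
    pts = np.stack([zz, yy, xx], axis=-1)
    ab = b - a
    denom = float(ab @ ab)
    t = ((pts - a) @ ab) / denom if denom > 0 else np.zeros(pts.shape[:-1])
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[..., None] * ab
    inside = np.sum((pts - closest) ** 2, axis=-1) <= radius_nm**2
    values[slices][inside] = lac_value
    if out_mask is not None:
        out_mask[slices][inside] = True
    return int(inside.sum())


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _unit_vector(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)

def _point_segment_dist(p, a, b) -> float:
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))

def _segment_segment_dist(a0, a1, b0, b1) -> float:
    # standard closest-approach of two segments
    d1, d2, r = a1 - a0, b1 - b0, a0 - b0
    a, e, f = float(d1 @ d1), float(d2 @ d2), float(d2 @ r)
    if a <= 1e-12 and e <= 1e-12:
        return float(np.linalg.norm(r))
    if a <= 1e-12:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = float(d1 @ r)
        if e <= 1e-12:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = float(d1 @ d2)
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    return float(np.linalg.norm((a0 + s * d1) - (b0 + t * d2)))


class _Obstacles:
    """Placed spheres and capsules, queried for clearance."""

    def __init__(self) -> None:
        self.sphere_centers: list[np.ndarray] = []
        self.sphere_radii: list[float] = []
        self.capsules: list[tuple[np.ndarray, np.ndarray, float]] = []

    def clear_of_point(self, p: np.ndarray, radius: float, gap: float) -> bool:
        if self.sphere_centers:
            centers = np.asarray(self.sphere_centers)
            radii = np.asarray(self.sphere_radii)
            d = np.linalg.norm(centers - p, axis=1)
            if np.any(d < radii + radius + gap):
                return False
        for a, b, r in self.capsules:
            if _point_segment_dist(p, a, b) < r + radius + gap:
                return False
        return True

    def clear_of_segment(self, a: np.ndarray, b: np.ndarray, radius: float, gap: float) -> bool:
        for c, r in zip(self.sphere_centers, self.sphere_radii):
            if _point_segment_dist(c, a, b) < r + radius + gap:
                return False
        for a2, b2, r2 in self.capsules:
            if _segment_segment_dist(a, b, a2, b2) < radius + r2 + gap:
                return False
        return True


# ---------------------------------------------------------------------------
# Point placement
# ---------------------------------------------------------------------------

def _df_at(df: np.ndarray, p_nm: np.ndarray, edge: float) -> float:
    idx = np.clip(np.floor(p_nm / edge).astype(int), 0, np.array(df.shape) - 1)
    return float(df[tuple(idx)])


def _sample_from_voxels(rng, idx: np.ndarray, edge: float) -> np.ndarray:
    """Uniform point: random allowed voxel plus uniform jitter inside it."""
    k = rng.integers(idx.shape[0])
    return (idx[k] + rng.uniform(0.0, 1.0, size=3)) * edge


def place_points(
    mode: str,
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    n: int,
    min_sep_nm: float,
    band_fraction: float = 0.2,
    seed: int = 0,
    voxel_edge_nm: float = 35.0,
    n_clusters: int = 4,
    cluster_sigma_nm: float = 800.0,
    cluster_interior_fraction: float = 0.5,
    chain_spacing_nm: float | None = None,
    max_attempts: int | None = None,
) -> np.ndarray:
    """Place ``n`` points inside the cell, outside the nucleus, per ``mode``.

    Modes mirror the observed vesicle arrangements: ``docked`` confines all
    points to within ``band_fraction`` of the maximum PM distance;
    ``clustered`` mixes a docked fraction with points drawn around
    ``n_clusters`` interior seeds; ``chains`` lays down collinear runs;
    ``diffuse`` is uniform over the cytoplasm.  Pairwise separation is at
    least ``min_sep_nm``.  Returns an ``(n, 3)`` array of nm coordinates.
    """
    if mode not in PLACEMENT_MODES:
        raise ValueError(f"unknown placement mode {mode!r}")
    if n < 0:
        raise ValueError("n must be >= 0")
    if not cell_mask.any() or not nucleus_mask.any():
        raise ValueError("cell and nucleus masks must be nonempty")
    rng = np.random.default_rng(seed)
    edge = voxel_edge_nm
    df = ndimage.distance_transform_edt(cell_mask) * edge
    d_c = float(df.max())
    band_nm = band_fraction * d_c
    allowed = cell_mask & ~nucleus_mask

    def valid(p, placed):
        idx = np.floor(p / edge).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(allowed.shape)):
            return False
        if not allowed[tuple(idx)]:
            return False
        if placed and min_sep_nm > 0:
            if np.min(np.linalg.norm(np.asarray(placed) - p, axis=1)) < min_sep_nm:
                return False
        return True

    docked_idx = np.argwhere(allowed & (df <= band_nm) & (df > 0))
    interior_idx = np.argwhere(allowed & (df > band_nm))
    any_idx = np.argwhere(allowed)
    max_attempts = max_attempts or max(1000, 300 * n)
    placed: list[np.ndarray] = []

    if mode == "clustered":
        if interior_idx.shape[0] == 0:
            raise PlacementError("clustered mode: no interior volume beyond the band")
        seeds = [
            _sample_from_voxels(rng, interior_idx, edge) for _ in range(max(1, n_clusters))
        ]
        n_cluster_pts = round(n * cluster_interior_fraction)
        targets = ["docked"] * (n - n_cluster_pts) + ["cluster"] * n_cluster_pts
    elif mode == "chains":
        spacing = chain_spacing_nm or 1.2 * max(min_sep_nm, 4 * edge)
        targets = []
    else:
        targets = [mode] * n

    attempts = 0
    if mode == "chains":
        while len(placed) < n and attempts < max_attempts:
            attempts += 1
            run_len = min(int(rng.integers(4, 9)), n - len(placed))
            start = _sample_from_voxels(rng, any_idx, edge)
            direction = _unit_vector(rng)
            run = [start + j * spacing * direction for j in range(run_len)]
            trial = list(placed)
            ok = True
            for p in run:
                if not valid(p, trial):
                    ok = False
                    break
                trial.append(p)
            if ok:
                placed = trial
    else:
        for target in targets:
            placed_one = False
            while attempts < max_attempts:
                attempts += 1
                if target == "docked":
                    if docked_idx.shape[0] == 0:
                        raise PlacementError("docked mode: empty PM band")
                    p = _sample_from_voxels(rng, docked_idx, edge)
                elif target == "cluster":
                    seed_pt = seeds[int(rng.integers(len(seeds)))]
                    p = seed_pt + rng.normal(0.0, cluster_sigma_nm, size=3)
                else:  # diffuse
                    p = _sample_from_voxels(rng, any_idx, edge)
                if target == "docked" and _df_at(df, p, edge) > band_nm:
                    continue
                if valid(p, placed):
                    placed.append(p)
                    placed_one = True
                    break
            if not placed_one:
                break

    if len(placed) < n:
        raise PlacementError(
            f"{mode} placement infeasible: placed {len(placed)}/{n} points "
            f"with min_sep {min_sep_nm} nm after {attempts} attempts"
        )
    return np.asarray(placed).reshape(n, 3)


# ---------------------------------------------------------------------------
# Whole-cell generation
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Simple rejection-sampled truncated normal (narrow truncation only)."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    guard = 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
        guard += 1
        if guard > 1000:
            out = np.clip(out, lo, hi)
            break
    return out


def _cell_mask(params: PhantomParams, rng) -> tuple[np.ndarray, np.ndarray]:
    """Boolean cell mask and its center (nm); optional smooth deformation."""
    shape = params.grid_shape
    edge = params.voxel_edge_nm
    center = np.array(shape) * edge / 2.0
    zz = (np.arange(shape[0]) + 0.5) * edge - center[0]
    yy = (np.arange(shape[1]) + 0.5) * edge - center[1]
    xx = (np.arange(shape[2]) + 0.5) * edge - center[2]
    r = np.sqrt(
        zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    ).astype(np.float32)
    radius = params.cell_radius_nm
    if params.deform_amplitude_nm > 0:
        coarse = rng.standard_normal((4, 4, 4))
        smooth = ndimage.zoom(coarse, [s / 4 for s in shape], order=3)
        smooth = smooth / max(np.abs(smooth).max(), 1e-9)
        mask = r <= radius + params.deform_amplitude_nm * smooth.astype(np.float32)
    else:
        mask = r <= radius
    return mask, center


def generate_cell_phantom(params: PhantomParams) -> tuple[TomogramVolume, GroundTruth]:
    """Generate one synthetic cell: LAC volume plus ground truth.

    Deterministic for a given ``params`` (including ``seed``).  Raises
    :class:`PlacementError` if a requested object count cannot be placed.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    edge = params.voxel_edge_nm
    shape = params.grid_shape
    gap = params.min_gap_nm

    values = np.full(shape, params.background_lac, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.uint16)
    object_ids = np.zeros(shape, dtype=np.uint16)

    # --- compartments -----------------------------------------------------
    cytosol_lac = float(np.clip(rng.normal(params.cytosol_lac, 0.01), 0.14, 0.24))
    nucleus_lac = float(np.clip(rng.normal(params.nucleus_lac, 0.02), 0.20, 0.32))
    capillary_lac = float(max(rng.normal(params.capillary_lac, 0.005), 0.05))

    cell, center = _cell_mask(params, rng)
    cap_inner, cap_outer = params.capillary_radii_nm
    yy = (np.arange(shape[1]) + 0.5) * edge - center[1]
    xx = (np.arange(shape[2]) + 0.5) * edge - center[2]
    rho = np.sqrt(yy[:, None] ** 2 + xx[None, :] ** 2)
    cap_wall = ((rho >= cap_inner) & (rho <= cap_outer))[None, :, :] & ~cell
    values[cap_wall] = capillary_lac
    labels[cap_wall] = CAPILLARY

    values[cell] = cytosol_lac
    labels[cell] = CYTOSOL

    nuc_center = center + _unit_vector(rng) * params.nucleus_offset_nm
    rasterize_sphere(values, nuc_center, 2 * params.nucleus_radius_nm, nucleus_lac, edge)
    nuc_mask = np.zeros(shape, dtype=bool)
    lab_f = np.zeros(shape, dtype=np.float32)  # scratch for label rasterization
    rasterize_sphere(lab_f, nuc_center, 2 * params.nucleus_radius_nm, 1.0, edge, out_mask=nuc_mask)
    labels[nuc_mask] = NUCLEUS

    df = ndimage.distance_transform_edt(cell) * edge  # PM distance field, nm
    d_c = float(df.max())
    nuc_r = params.nucleus_radius_nm

    obstacles = _Obstacles()
    records: list[dict] = []
    next_id = 1

    def record(cls, center_nm, diameter_nm, lac, length_nm=0.0):
        nonlocal next_id
        records.append(
            dict(
                object_id=next_id,
                **{"class": cls},
                cz_nm=float(center_nm[0]),
                cy_nm=float(center_nm[1]),
                cx_nm=float(center_nm[2]),
                diameter_nm=float(diameter_nm),
                lac=float(lac),
                length_nm=float(length_nm),
            )
        )
        next_id += 1
        return next_id - 1

    # --- mitochondria (capsules) -----------------------------------------
    mito_r = params.mito_radius_nm
    n_mito = params.n_mitochondria
    if n_mito > 0:
        lengths = _truncated_normal(
            rng, params.mito_length_mean_nm, params.mito_length_sd_nm,
            *params.mito_length_clip_nm, size=n_mito,
        )
        lacs = _truncated_normal(
            rng, params.mito_lac_mean, params.mito_lac_sd, *params.mito_lac_clip, size=n_mito
        )
        attempts, placed = 0, 0
        max_attempts = params.max_attempts_factor * n_mito
        while placed < n_mito:
            if attempts >= max_attempts:
                raise PlacementError(
                    f"mitochondria: placed {placed}/{n_mito} after {attempts} attempts"
                )
            attempts += 1
            length = lengths[placed]
            half = length / 2.0 - mito_r
            c = center + _unit_vector(rng) * rng.uniform(0, params.cell_radius_nm) ** 1.0
            u = _unit_vector(rng)
            a, b = c - u * half, c + u * half
            # clearance from PM along the core segment
            probes = [a, (a + c) / 2, c, (b + c) / 2, b]
            if any(_df_at(df, p, edge) < mito_r + gap for p in probes):
                continue
            if _point_segment_dist(nuc_center, a, b) < nuc_r + mito_r + gap:
                continue
            if not obstacles.clear_of_segment(a, b, mito_r, gap):
                continue
            lac = float(lacs[placed])
            oid = record(
                "mitochondria", c,
                2 * ((length * mito_r**2 * 3 / 4) ** (1 / 3)),  # equivalent-sphere diameter
                lac, length_nm=length,
            )
            m = np.zeros(shape, dtype=bool)
            rasterize_capsule(values, a, b, mito_r, lac, edge, out_mask=m)
            labels[m] = MITOCHONDRIA
            object_ids[m] = oid
            obstacles.capsules.append((a, b, mito_r))
            placed += 1

    # --- lipid droplets (dense-core spheres) ------------------------------
    n_drop = params.n_lipid_droplets
    if n_drop > 0:
        diams = _truncated_normal(
            rng, params.droplet_diameter_mean_nm, params.droplet_diameter_sd_nm,
            max(3 * edge, params.droplet_diameter_mean_nm - 3 * params.droplet_diameter_sd_nm),
            params.droplet_diameter_mean_nm + 3 * params.droplet_diameter_sd_nm,
            size=n_drop,
        )
        lacs = _truncated_normal(
            rng, params.droplet_lac_mean, params.droplet_lac_sd,
            params.droplet_lac_mean - 3 * params.droplet_lac_sd,
            min(params.droplet_lac_mean + 3 * params.droplet_lac_sd,
                params.droplet_core_lac - 0.02),
            size=n_drop,
        )
        attempts, placed = 0, 0
        max_attempts = params.max_attempts_factor * n_drop
        while placed < n_drop:
            if attempts >= max_attempts:
                raise PlacementError(
                    f"lipid_droplet: placed {placed}/{n_drop} after {attempts} attempts"
                )
            attempts += 1
            r = diams[placed] / 2.0
            p = center + _unit_vector(rng) * rng.uniform(0, params.cell_radius_nm)
            if _df_at(df, p, edge) < r + gap:
                continue
            if np.linalg.norm(p - nuc_center) < nuc_r + r + gap:
                continue
            if not obstacles.clear_of_point(p, r, gap):
                continue
            mean_lac = float(lacs[placed])
            oid = record("lipid_droplet", p, diams[placed], mean_lac)
            m = np.zeros(shape, dtype=bool)
            n_total = rasterize_sphere(values, p, diams[placed], mean_lac, edge, out_mask=m)
            core_m = np.zeros(shape, dtype=bool)
            n_core = rasterize_sphere(
                lab_f, p, diams[placed] * params.droplet_core_radius_fraction,
                1.0, edge, out_mask=core_m,
            )
            # solve shell LAC from rasterized counts so voxel mean == drawn mean
            if n_core < n_total:
                shell_lac = (mean_lac * n_total - params.droplet_core_lac * n_core) / (
                    n_total - n_core
                )
                values[m] = shell_lac
            values[core_m] = params.droplet_core_lac
            labels[m] = LIPID_DROPLET
            object_ids[m] = oid
            obstacles.sphere_centers.append(p)
            obstacles.sphere_radii.append(float(r))
            placed += 1

    # --- insulin vesicles --------------------------------------------------
    n_ves = params.n_vesicles
    if n_ves > 0:
        diams = _truncated_normal(
            rng, params.vesicle_diameter_mean_nm, params.vesicle_diameter_sd_nm,
            max(100.0, params.vesicle_diameter_mean_nm - 3 * params.vesicle_diameter_sd_nm),
            params.vesicle_diameter_mean_nm + 3 * params.vesicle_diameter_sd_nm,
            size=n_ves,
        )
        lacs = _truncated_normal(
            rng, params.vesicle_lac_mean, params.vesicle_lac_sd,
            *params.vesicle_lac_clip, size=n_ves,
        )
        centers = _place_vesicles(params, rng, df, d_c, nuc_center, obstacles, diams)
        for k in range(n_ves):
            oid = record("insulin_vesicle", centers[k], diams[k], float(lacs[k]))
            m = np.zeros(shape, dtype=bool)
            rasterize_sphere(values, centers[k], diams[k], float(lacs[k]), edge, out_mask=m)
            labels[m] = INSULIN_VESICLE
            object_ids[m] = oid

    # --- noise -------------------------------------------------------------
    if params.noise_sd > 0:
        values += rng.normal(0.0, params.noise_sd, size=shape).astype(np.float32)

    table = pd.DataFrame(
        records,
        columns=["object_id", "class", "cz_nm", "cy_nm", "cx_nm",
                 "diameter_nm", "lac", "length_nm"],
    )
    volume = TomogramVolume(values, edge, name=f"phantom_{params.seed}")
    gt = GroundTruth(table, LabelMap(labels, dict(DEFAULT_LEGEND), edge), object_ids)
    return volume, gt


def _place_vesicles(params, rng, df, d_c, nuc_center, obstacles, diams) -> np.ndarray:
    """Mode-dependent vesicle centers with per-object radii and clearances."""
    edge = params.voxel_edge_nm
    gap = params.min_gap_nm
    nuc_r = params.nucleus_radius_nm
    band_nm = params.band_fraction * d_c
    mode = params.placement_mode
    n = len(diams)
    radii = np.asarray(diams) / 2.0

    shallow_idx = np.argwhere((df > 0) & (df <= band_nm))
    interior_idx = np.argwhere(df > band_nm)
    any_idx = np.argwhere(df > 0)

    if mode == "clustered":
        if interior_idx.shape[0] == 0:
            raise PlacementError("clustered: no interior volume beyond the band")
        seeds = [
            _sample_from_voxels(rng, interior_idx, edge)
            for _ in range(max(1, params.n_clusters))
        ]
        n_cluster = round(n * params.cluster_interior_fraction)
        targets = ["docked"] * (n - n_cluster) + ["cluster"] * n_cluster
    elif mode == "chains":
        targets = []
    else:
        targets = [mode] * n

    placed_pts: list[np.ndarray] = []
    placed_r: list[float] = []

    def valid(p, r):
        if _df_at(df, p, edge) < r + gap:
            return False
        if np.linalg.norm(p - nuc_center) < nuc_r + r + gap:
            return False
        if placed_pts:
            d = np.linalg.norm(np.asarray(placed_pts) - p, axis=1)
            if np.any(d < np.asarray(placed_r) + r + gap):
                return False
        return obstacles.clear_of_point(p, r, gap)

    attempts = 0
    max_attempts = params.max_attempts_factor * max(n, 1)

    if mode == "chains":
        spacing = params.chain_spacing_factor * params.vesicle_diameter_mean_nm
        while len(placed_pts) < n and attempts < max_attempts:
            attempts += 1
            run_len = min(int(rng.integers(4, 9)), n - len(placed_pts))
            start = _sample_from_voxels(rng, any_idx, edge)
            u = _unit_vector(rng)
            idx0 = len(placed_pts)
            run_pts = [start + j * spacing * u for j in range(run_len)]
            ok = True
            for j, p in enumerate(run_pts):
                if not valid(p, radii[idx0 + j]):
                    ok = False
                    break
                placed_pts.append(p)
                placed_r.append(float(radii[idx0 + j]))
            if not ok:
                del placed_pts[idx0:]
                del placed_r[idx0:]
    else:
        for k, target in enumerate(targets):
            r = float(radii[k])
            ok = False
            while attempts < max_attempts:
                attempts += 1
                if target == "docked":
                    if shallow_idx.shape[0] == 0:
                        raise PlacementError("docked: empty PM band")
                    p = _sample_from_voxels(rng, shallow_idx, edge)
                    if _df_at(df, p, edge) > band_nm:
                        continue
                elif target == "cluster":
                    seed_pt = seeds[int(rng.integers(len(seeds)))]
                    p = seed_pt + rng.normal(0.0, params.cluster_sigma_nm, size=3)
                else:
                    p = _sample_from_voxels(rng, any_idx, edge)
                if valid(p, r):
                    placed_pts.append(p)
                    placed_r.append(r)
                    ok = True
                    break
            if not ok:
                break

    if len(placed_pts) < n:
        raise PlacementError(
            f"insulin_vesicle ({mode}): placed {len(placed_pts)}/{n} "
            f"after {attempts} attempts"
        )
    return np.asarray(placed_pts)
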