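"""Per-object and per-cell morphometry.

Object metrics are computed from a labeled component array aligned with an
LAC volume: voxel count and physical volume, centroid (voxel-center mean,
nm), equivalent-sphere diameter ``(6V/π)^{1/3}``, principal-axis ratio from
the voxel-coordinate covariance (regularized by the 1/12 per-axis variance
of a single voxel, so single voxels are spherical and 1-voxel-thick rods
still register as elongated), and mean/max LAC over the object's voxels.

Cell summaries aggregate one segmented cell: compartment volumes, the
mitochondria/cytosol volume ratio, the vesicle count normalized to a
reference cell volume (``count × reference / cell volume``) and mean LAC
per compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

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
    LabelMap,
    TomogramVolume,
    check_aligned,
)


def equivalent_diameter_nm(voxel_count: int, voxel_edge_nm: float) -> float:
    """Diameter of the sphere with the same volume as ``voxel_count`` voxels."""
    volume_nm3 = voxel_count * voxel_edge_nm**3
    return float((6.0 * volume_nm3 / np.pi) ** (1.0 / 3.0))


def _axis_ratio(coords: np.ndarray) -> float:
    """√(λ_max/λ_min) of the voxel-coordinate covariance, 1/12-regularized."""
    if coords.shape[0] == 1:
        return 1.0
    cov = np.cov(coords.T, bias=True) + np.eye(3) / 12.0
    eig = np.linalg.eigvalsh(cov)
    return float(np.sqrt(eig[-1] / eig[0]))


def object_metrics(labeled: np.ndarray, volume: TomogramVolume) -> pd.DataFrame:
    """One record per labeled object (ids 1..N; 0 is background).

    Empty ids are skipped.  Mean LAC is the arithmetic mean over the
    object's voxels; the centroid is the mean voxel-center position in nm.
    """
    labeled = np.asarray(labeled)
    if labeled.shape != volume.shape:
        raise ValueError("labeled array and volume shapes differ")
    edge = volume.voxel_edge_nm
    slices = ndimage.find_objects(labeled)
    records = []
    for oid, slc in enumerate(slices, start=1):
        if slc is None:
            continue
        patch = labeled[slc] == oid
        count = int(patch.sum())
        if count == 0:
            continue
        coords = np.argwhere(patch).astype(float)
        coords += np.array([s.start for s in slc], dtype=float)
        centroid = (coords.mean(axis=0) + 0.5) * edge
        lacs = volume.values[slc][patch]
        records.append(
            dict(
                object_id=oid,
                cz_nm=centroid[0],
                cy_nm=centroid[1],
                cx_nm=centroid[2],
                voxel_volume=count,
                volume_um3=count * volume.voxel_volume_um3,
                equivalent_diameter_nm=equivalent_diameter_nm(count, edge),
                axis_ratio=_axis_ratio(coords),
                mean_lac=float(lacs.mean()),
                max_lac=float(lacs.max()),
            )
        )
    columns = [
        "object_id", "cz_nm", "cy_nm", "cx_nm", "voxel_volume", "volume_um3",
        "equivalent_diameter_nm", "axis_ratio", "mean_lac", "max_lac",
    ]
    return pd.DataFrame(records, columns=columns)


@dataclass
class CellSummary:
    """Per-cell aggregate quantities (volumes in μm³, LAC in μm⁻¹)."""

    cell_id: str
    cell_volume_um3: float
    nucleus_volume_um3: float
    cytosol_volume_um3: float
    mitochondria_volume_um3: float
    vesicle_count: int
    vesicle_count_normalized: float
    mito_cytosol_ratio: float
    mean_vesicle_lac: float
    mean_vesicle_diameter_nm: float
    mean_nucleus_lac: float
    mean_cytosol_lac: float
    mean_mitochondria_lac: float
    mean_droplet_lac: float
    mean_droplet_diameter_nm: float
    droplet_count: int
    mitochondria_count: int
    capillary_mean_lac: float

    def as_dict(self) -> dict:
        return asdict(self)


def _compartment_mean(volume, labels, label) -> float:
    mask = labels == label
    return float(volume.values[mask].mean()) if mask.any() else float("nan")


def cell_summary(
    label_map: LabelMap,
    volume: TomogramVolume,
    table: pd.DataFrame,
    reference_volume_um3: float | None = None,
    cell_id: str = "",
) -> CellSummary:
    """Aggregate a segmented cell into a :class:`CellSummary`.

    ``reference_volume_um3`` is the cohort reference for count
    normalization; defaults to this cell's own volume (normalized count ==
    raw count).  Raises if the cytosol is empty.
    """
    check_aligned(volume, label_map)
    labels = label_map.labels
    vox = volume.voxel_volume_um3
    counts = {
        lab: int((labels == lab).sum())
        for lab in (CYTOSOL, NUCLEUS, MITOCHONDRIA, LIPID_DROPLET, INSULIN_VESICLE)
    }
    cell_volume = vox * sum(counts.values())
    cytosol_volume = vox * counts[CYTOSOL]
    if counts[CYTOSOL] == 0:
        raise ValueError("cell has zero cytosol volume")
    if reference_volume_um3 is None:
        reference_volume_um3 = cell_volume

    by_class = {cls: sub for cls, sub in table.groupby("class")} if len(table) else {}
    vesicles = by_class.get("insulin_vesicle", table.iloc[0:0])
    droplets = by_class.get("lipid_droplet", table.iloc[0:0])
    mitos = by_class.get("mitochondria", table.iloc[0:0])

    n_ves = len(vesicles)
    cap_mask = labels == CAPILLARY
    return CellSummary(
        cell_id=cell_id or volume.name,
        cell_volume_um3=cell_volume,
        nucleus_volume_um3=vox * counts[NUCLEUS],
        cytosol_volume_um3=cytosol_volume,
        mitochondria_volume_um3=vox * counts[MITOCHONDRIA],
        vesicle_count=n_ves,
        vesicle_count_normalized=n_ves * reference_volume_um3 / cell_volume,
        mito_cytosol_ratio=vox * counts[MITOCHONDRIA] / cytosol_volume,
        mean_vesicle_lac=float(vesicles["mean_lac"].mean()) if n_ves else float("nan"),
        mean_vesicle_diameter_nm=(
            float(vesicles["equivalent_diameter_nm"].mean()) if n_ves else float("nan")
        ),
        mean_nucleus_lac=_compartment_mean(volume, labels, NUCLEUS),
        mean_cytosol_lac=_compartment_mean(volume, labels, CYTOSOL),
        mean_mitochondria_lac=float(mitos["mean_lac"].mean()) if len(mitos) else float("nan"),
        mean_droplet_lac=float(droplets["mean_lac"].mean()) if len(droplets) else float("nan"),
        mean_droplet_diameter_nm=(
            float(droplets["equivalent_diameter_nm"].mean()) if len(droplets) else float("nan")
        ),
        droplet_count=len(droplets),
        mitochondria_count=len(mitos),
        capillary_mean_lac=float(volume.values[cap_mask].mean()) if cap_mask.any() else float("nan"),
    )
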