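"""Core in-memory containers for SXT volumes and compartment label maps.

A tomogram is a 3D grid of linear absorption coefficient (LAC) values in
μm⁻¹ together with an isotropic voxel edge length in nm.  A label map is an
aligned integer grid assigning each voxel to exactly one compartment class.

Conventions
-----------
* Voxel indices are 0-based and arrays are indexed ``(z, y, x)`` in C order.
* Physical coordinates are voxel-*center* positions in nm: the center of
  voxel ``i`` along an axis sits at ``(i + 0.5) * voxel_edge_nm``.
* All distances are reported in nm; all LAC values in μm⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Compartment labels shared by the phantom generator and the segmenter.
BACKGROUND = 0
CAPILLARY = 1
CYTOSOL = 2
NUCLEUS = 3
MITOCHONDRIA = 4
LIPID_DROPLET = 5
INSULIN_VESICLE = 6

DEFAULT_LEGEND: dict[int, str] = {
    BACKGROUND: "background",
    CAPILLARY: "capillary",
    CYTOSOL: "cytosol",
    NUCLEUS: "nucleus",
    MITOCHONDRIA: "mitochondria",
    LIPID_DROPLET: "lipid_droplet",
    INSULIN_VESICLE: "insulin_vesicle",
}

#: Organelle classes enumerated as distinct objects (not bulk compartments).
ORGANELLE_CLASSES = ("mitochondria", "lipid_droplet", "insulin_vesicle")


class VolumeFormatError(ValueError):
    """Raised for unreadable, degenerate or metadata-less volume files."""


@dataclass
class TomogramVolume:
    """3D LAC volume (μm⁻¹) with an isotropic voxel size.

    Parameters
    ----------
    values : ndarray, 3D, floating point
        Per-voxel LAC in μm⁻¹.
    voxel_edge_nm : float
        Isotropic voxel edge length in nm (> 0).
    name : str
        Identifier; by convention ``<capillary>_<cell>`` (first number is
        the capillary, the number after the hyphen the cell position).
    """

    values: np.ndarray
    voxel_edge_nm: float
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise VolumeFormatError(
                f"volume must be 3D with all dims >= 2, got shape {self.values.shape}"
            )
        if not np.issubdtype(self.values.dtype, np.floating):
            self.values = self.values.astype(np.float32)
        if not np.all(np.isfinite(self.values)):
            raise VolumeFormatError("volume contains non-finite LAC values")
        if not (self.voxel_edge_nm > 0):
            raise VolumeFormatError(f"voxel_edge_nm must be > 0, got {self.voxel_edge_nm}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def voxel_volume_um3(self) -> float:
        """Volume of one voxel in μm³."""
        return (self.voxel_edge_nm * 1e-3) ** 3


@dataclass
class LabelMap:
    """Integer compartment assignment aligned to a :class:`TomogramVolume`."""

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))
    voxel_edge_nm: float = 35.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise VolumeFormatError(f"label map must be 3D, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise VolumeFormatError("label map must be integer typed")
        if self.labels.min() < 0:
            raise VolumeFormatError("label map contains negative labels")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise VolumeFormatError(f"labels {sorted(missing)} missing from legend")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def mask(self, class_name: str) -> np.ndarray:
        """Boolean mask of all voxels carrying ``class_name``."""
        ids = [k for k, v in self.legend.items() if v == class_name]
        if not ids:
            raise KeyError(f"class {class_name!r} not in legend")
        return np.isin(self.labels, ids)

    def cell_mask(self) -> np.ndarray:
        """All voxels inside the cell (everything but background/capillary)."""
        return ~np.isin(self.labels, [BACKGROUND, CAPILLARY])


def check_aligned(volume: TomogramVolume, labels: LabelMap) -> None:
    if volume.shape != labels.shape:
        raise VolumeFormatError(
            f"shape mismatch: volume {volume.shape} vs label map {labels.shape}"
        )
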