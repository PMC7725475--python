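"""Rule-based organelle segmentation of LAC volumes.

Deterministic re-expression of the interactive "magic wand" workflow used
on β-cell tomograms: voxels inside the cell whose LAC exceeds a candidate
threshold are grouped into 26-connected components, each component is
measured, and classified by LAC window, size and shape:

* spherical with max LAC ≥ 0.68 μm⁻¹            → lipid droplet
* spherical, mean LAC in [0.35, 0.67] μm⁻¹ and
  equivalent diameter ≥ 90 nm                    → insulin vesicle
* elongated with mean LAC in the mitochondria
  window (default [0.30, 0.40] μm⁻¹)             → mitochondrion
* anything else                                  → rejected, with a reason

"Spherical" and "elongated" are operationalized through the principal-axis
ratio √(λ_max/λ_min) of the voxel-coordinate covariance (≤ 2 spherical,
≥ 3 elongated; the gap band is rejected as ambiguous).  Per-cell LAC values
can be rescaled against the glass-capillary reference to absorb small
systematic offsets between tomograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import morphometry
from .volumes import (
    CYTOSOL,
    INSULIN_VESICLE,
    LIPID_DROPLET,
    MITOCHONDRIA,
    NUCLEUS,
    DEFAULT_LEGEND,
    LabelMap,
    TomogramVolume,
)

_CLASS_TO_LABEL = {
    "mitochondria": MITOCHONDRIA,
    "lipid_droplet": LIPID_DROPLET,
    "insulin_vesicle": INSULIN_VESICLE,
}

_REQUIRED_METRICS = ("mean_lac", "max_lac", "equivalent_diameter_nm", "axis_ratio")


@dataclass
class ClassificationRules:
    """Thresholds for object classification; LAC in μm⁻¹, lengths in nm."""

    droplet_max_lac_min: float = 0.68
    vesicle_lac_window: tuple[float, float] = (0.35, 0.67)
    vesicle_min_diameter_nm: float = 90.0
    mito_lac_window: tuple[float, float] = (0.30, 0.40)
    sphericity_axis_ratio_max: float = 2.0
    elongation_axis_ratio_min: float = 3.0
    #: LAC floor for candidate voxels; None derives it from the windows.
    candidate_lac_min: float | None = None

    def __post_init__(self) -> None:
        for window in (self.vesicle_lac_window, self.mito_lac_window):
            if not window[0] < window[1]:
                raise ValueError(f"LAC window {window} not ordered")
        if min(self.droplet_max_lac_min, self.vesicle_min_diameter_nm) <= 0:
            raise ValueError("thresholds must be positive")

    @property
    def effective_candidate_lac_min(self) -> float:
        if self.candidate_lac_min is not None:
            return self.candidate_lac_min
        return min(self.mito_lac_window[0], self.vesicle_lac_window[0]) - 0.02


def region_grow(volume: TomogramVolume, seed_voxel, lac_window) -> np.ndarray:
    """Maximal 26-connected region through ``seed_voxel`` within an LAC window.

    Mirrors the interactive wand: all voxels reachable from the seed whose
    LAC lies in ``lac_window`` (inclusive).  The seed itself must qualify.
    """
    lo, hi = lac_window
    seed_voxel = tuple(int(i) for i in seed_voxel)
    seed_lac = float(volume.values[seed_voxel])
    if not (lo <= seed_lac <= hi):
        raise ValueError(
            f"seed voxel LAC {seed_lac:.4f} outside window [{lo}, {hi}]"
        )
    window_mask = (volume.values >= lo) & (volume.values <= hi)
    labeled, _ = ndimage.label(window_mask, structure=np.ones((3, 3, 3), dtype=bool))
    return labeled == labeled[seed_voxel]


def label_components(mask: np.ndarray, connectivity: int = 26) -> tuple[np.ndarray, int]:
    """Connected-component labeling of a binary mask; returns (labels, count)."""
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    labeled, n = ndimage.label(np.asarray(mask, dtype=bool), structure=structure)
    return labeled, int(n)


def classify_object(metrics, rules: ClassificationRules) -> tuple[str, str]:
    """Classify one measured object.

    Returns ``(class, reason)``; class is one of ``lipid_droplet``,
    ``insulin_vesicle``, ``mitochondria`` or ``rejected``.  Precedence:
    droplet before vesicle (a bright spherical object is a droplet even if
    its mean LAC falls in the vesicle window), then mitochondrion.
    """
    missing = [k for k in _REQUIRED_METRICS if k not in metrics or metrics[k] is None]
    if missing:
        raise ValueError(f"metrics record incomplete: missing {missing}")
    spherical = metrics["axis_ratio"] <= rules.sphericity_axis_ratio_max
    elongated = metrics["axis_ratio"] >= rules.elongation_axis_ratio_min
    v_lo, v_hi = rules.vesicle_lac_window
    m_lo, m_hi = rules.mito_lac_window
    if spherical and metrics["max_lac"] >= rules.droplet_max_lac_min:
        return "lipid_droplet", ""
    if spherical and v_lo <= metrics["mean_lac"] <= v_hi:
        if metrics["equivalent_diameter_nm"] >= rules.vesicle_min_diameter_nm:
            return "insulin_vesicle", ""
        return "rejected", "microvesicle"
    if elongated and m_lo <= metrics["mean_lac"] <= m_hi:
        return "mitochondria", ""
    if not spherical and not elongated:
        return "rejected", "ambiguous_shape"
    return "rejected", "lac_outside_windows"


def normalize_lac(
    table: pd.DataFrame,
    capillary_mean_lac: float,
    reference_capillary_lac: float,
    columns: tuple[str, ...] = ("mean_lac", "max_lac"),
) -> pd.DataFrame:
    """Rescale per-object LAC against the glass-capillary reference.

    Adds ``<col>_norm = <col> * reference / capillary`` for each LAC column,
    keeping the raw values alongside.  Idempotent on the normalized columns.
    """
    if capillary_mean_lac <= 0:
        raise ValueError(f"capillary LAC must be > 0, got {capillary_mean_lac}")
    if reference_capillary_lac <= 0:
        raise ValueError("reference capillary LAC must be > 0")
    out = table.copy()
    scale = reference_capillary_lac / capillary_mean_lac
    for col in columns:
        if col in out.columns:
            out[f"{col}_norm"] = out[col] * scale
    return out


def segment_cell(
    volume: TomogramVolume,
    pm_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    rules: ClassificationRules | None = None,
) -> tuple[LabelMap, pd.DataFrame]:
    """Segment one cell into compartments and classified organelles.

    ``pm_mask`` is everything inside the plasma membrane; ``nucleus_mask``
    the nucleus (must lie inside ``pm_mask``).  Every in-cell voxel ends up
    with exactly one label (cytosol by default); rejected candidate
    components fall back to cytosol.  Returns the label map and the
    organelle table (accepted objects only, with metrics and class).
    """
    rules = rules or ClassificationRules()
    pm_mask = np.asarray(pm_mask, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if pm_mask.shape != volume.shape or nucleus_mask.shape != volume.shape:
        raise ValueError("masks must match the volume shape")
    if np.any(nucleus_mask & ~pm_mask):
        raise ValueError("nucleus mask extends outside the plasma membrane mask")

    cytoplasm = pm_mask & ~nucleus_mask
    candidates = cytoplasm & (volume.values >= rules.effective_candidate_lac_min)
    labeled, n = label_components(candidates, connectivity=26)

    table = morphometry.object_metrics(labeled, volume)
    classes, reasons = [], []
    for _, row in table.iterrows():
        cls, reason = classify_object(row, rules)
        classes.append(cls)
        reasons.append(reason)
    table = table.assign(**{"class": classes, "reject_reason": reasons})

    labels = np.zeros(volume.shape, dtype=np.uint16)
    labels[pm_mask] = CYTOSOL
    labels[nucleus_mask] = NUCLEUS
    # component id -> compartment label lookup (rejected components stay cytosol)
    lut = np.full(n + 1, CYTOSOL, dtype=np.uint16)
    for oid, cls in zip(table["object_id"], table["class"]):
        if cls in _CLASS_TO_LABEL:
            lut[int(oid)] = _CLASS_TO_LABEL[cls]
    labels[candidates] = lut[labeled[candidates]]

    accepted = table[table["class"] != "rejected"].drop(columns=["reject_reason"])
    accepted = accepted.reset_index(drop=True)
    label_map = LabelMap(labels, dict(DEFAULT_LEGEND), volume.voxel_edge_nm)
    return label_map, accepted
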