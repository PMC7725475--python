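"""Bhattacharyya distance between distance distributions.

For two discrete probability distributions p, q on shared bins the
Bhattacharyya coefficient is BC = Σ_i √(p_i q_i) and the distance
BD = −ln BC.  BD is symmetric, zero iff p = q, and +∞ when the supports
are disjoint (BC = 0); an optional additive smoothing flag yields finite
values for plotting.  Observed vesicle distributions are scored against
each null-model class, giving one BD per replicate (50 per class per cell).
A low BD against a class means the observed arrangement is similar to that
class of random placements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nullmodels import NullModelEnsemble
from .spatial import DistanceDistribution


@dataclass
class DivergenceRecord:
    """BD values of one cell against one null-model class."""

    cell_id: str
    placement_class: int
    bd_values: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.bd_values))

    @property
    def sd(self) -> float:
        return float(np.std(self.bd_values, ddof=1)) if len(self.bd_values) > 1 else 0.0


def bhattacharyya_distance(
    p: DistanceDistribution,
    q: DistanceDistribution,
    smoothing: float = 0.0,
) -> float:
    """BD = −ln Σ √(p_i q_i); +inf when supports are disjoint.

    Requires identical bin edges and normalized inputs.  ``smoothing`` adds
    a constant to every bin (renormalizing) before the comparison.
    """
    if not p.same_edges(q):
        raise ValueError("distributions must share identical bin edges")
    pv, qv = p.probabilities, q.probabilities
    for v in (pv, qv):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("distributions must be normalized")
    if smoothing > 0:
        pv = (pv + smoothing) / (pv + smoothing).sum()
        qv = (qv + smoothing) / (qv + smoothing).sum()
    bc = float(np.sqrt(pv * qv).sum())
    if bc <= 0.0:
        return float("inf")
    return float(-np.log(min(bc, 1.0)))


def observed_vs_null(
    observed: DistanceDistribution,
    ensembles: dict[int, tuple[NullModelEnsemble, list[DistanceDistribution]]],
    smoothing: float = 0.0,
) -> tuple[list[DivergenceRecord], pd.DataFrame]:
    """Score an observed distribution against null ensembles per class.

    Returns per-class :class:`DivergenceRecord` objects plus a scatter-ready
    long table (cell_id, placement_class, replicate, bd).
    """
    records = []
    rows = []
    for cls in sorted(ensembles):
        ensemble, dists = ensembles[cls]
        bds = np.array(
            [bhattacharyya_distance(observed, d, smoothing=smoothing) for d in dists]
        )
        records.append(DivergenceRecord(ensemble.cell_id, cls, bds))
        rows.extend(
            dict(cell_id=ensemble.cell_id, placement_class=cls, replicate=i, bd=bd)
            for i, bd in enumerate(bds)
        )
    return records, pd.DataFrame(rows, columns=["cell_id", "placement_class", "replicate", "bd"])
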