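"""Resection-relative ROI classification: overlapping, adjacent, or far.

A region with at least 10% of its vertices inside the resection is treated
as overlapping and excluded from connectivity statistics (its parcellation
and its signals are unreliable after surgery).  Untouched regions in the
resection hemisphere within 10 mm (minimum vertex-to-vertex Euclidean
distance) of the resected cortex are "adjacent"; every other untouched
region, including contralateral ones at any distance, is "far".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .synth import CorticalGeometry, ResectionMask

OVERLAP_EXCLUDED = "overlap-excluded"
ADJACENT = "adjacent"
FAR = "far"


@dataclass(frozen=True)
class ClassificationConfig:
    overlap_fraction_threshold: float = 0.10
    adjacency_distance_mm: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.overlap_fraction_threshold < 1:
            raise ValueError("overlap threshold must be in (0, 1)")
        if self.adjacency_distance_mm <= 0:
            raise ValueError("adjacency distance must be positive")


@dataclass
class ROILabeling:
    """Per-ROI class, resected fraction and distance to the resection."""

    roi_names: list[str]
    labels: list[str]
    fractions: np.ndarray
    distances_mm: np.ndarray
    resection_hemisphere: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"class": self.labels, "resected_fraction": self.fractions,
             "distance_mm": self.distances_mm},
            index=self.roi_names,
        )

    def rois_in_class(self, label: str) -> list[str]:
        return [n for n, c in zip(self.roi_names, self.labels) if c == label]


def _check_mask(geom: CorticalGeometry, mask: ResectionMask) -> None:
    if len(mask.resected) != geom.n_vertices:
        raise ValueError("mask vertex count does not match geometry")


def resected_fraction(geom: CorticalGeometry, mask: ResectionMask) -> np.ndarray:
    """Fraction of each ROI's vertices inside the resection."""
    _check_mask(geom, mask)
    counts = np.bincount(geom.vertex_roi, minlength=geom.n_rois)
    hits = np.bincount(geom.vertex_roi, weights=mask.resected.astype(float),
                       minlength=geom.n_rois)
    return hits / counts


def roi_distance_to_resection(geom: CorticalGeometry,
                              mask: ResectionMask) -> np.ndarray:
    """Minimum Euclidean distance (mm) from each ROI's vertices to the resection."""
    _check_mask(geom, mask)
    if not mask.resected.any():
        raise ValueError("resection mask is empty")
    resected_coords = geom.vertex_coords[mask.resected]
    d = cdist(geom.vertex_coords, resected_coords).min(axis=1)
    out = np.empty(geom.n_rois)
    for roi in range(geom.n_rois):
        out[roi] = d[geom.vertex_roi == roi].min()
    return out


def resection_hemisphere(geom: CorticalGeometry, mask: ResectionMask) -> str:
    """Hemisphere of the resection; a bilateral mask is rejected.

    The pipeline models unilateral focal resections only, so resected
    vertices in both hemispheres are an error rather than a majority vote.
    """
    _check_mask(geom, mask)
    hemis = {geom.roi_hemisphere[geom.vertex_roi[v]]
             for v in np.flatnonzero(mask.resected)}
    if len(hemis) != 1:
        raise ValueError(f"resection spans hemispheres {sorted(hemis)}; "
                         "only unilateral focal resections are supported")
    return hemis.pop()


def classify_rois(geom: CorticalGeometry, mask: ResectionMask,
                  cfg: ClassificationConfig = ClassificationConfig()) -> ROILabeling:
    """Label every ROI as overlap-excluded, adjacent, or far.

    Overlap uses ``fraction >= threshold`` (a region with exactly 10% of its
    vertices resected is excluded); adjacency requires both the resection
    hemisphere and ``distance <= adjacency_distance_mm``.
    """
    fractions = resected_fraction(geom, mask)
    distances = roi_distance_to_resection(geom, mask)
    hemi = resection_hemisphere(geom, mask)
    labels = []
    for roi in range(geom.n_rois):
        if fractions[roi] >= cfg.overlap_fraction_threshold:
            labels.append(OVERLAP_EXCLUDED)
        elif (geom.roi_hemisphere[roi] == hemi
              and distances[roi] <= cfg.adjacency_distance_mm):
            labels.append(ADJACENT)
        else:
            labels.append(FAR)
    return ROILabeling(roi_names=list(geom.roi_names), labels=labels,
                       fractions=fractions, distances_mm=distances,
                       resection_hemisphere=hemi)
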