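"""LCMV beamformer source reconstruction and ROI time-series extraction.

A linearly constrained minimum variance (LCMV) spatial filter is built for
every cortical vertex from the sensor data covariance (pooled over epochs)
and a scalar leadfield column, with identity noise covariance and diagonal
loading for the near-singular covariances typical of 19-64-channel EEG.
Vertex time series are averaged within each atlas region to give one source
time series per ROI per epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocess import EpochSet

logger = logging.getLogger(__name__)


@dataclass
class SourceEpochs:
    """Per-epoch ROI-level source time series.

    ``data`` has shape ``(n_epochs, n_rois, n_samples)``.
    """

    data: np.ndarray
    fs: float
    roi_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("source data must be (epochs, rois, samples)")
        if self.data.shape[1] != len(self.roi_names):
            raise ValueError("one name per ROI required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("source samples must be finite")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class BeamformerModel:
    """Vertex-wise LCMV spatial filters with their covariance model."""

    weights: np.ndarray           # (n_vertices, n_sensors)
    data_cov: np.ndarray          # (n_sensors, n_sensors)
    reg_lambda: float
    noise_cov: str = field(default="identity", init=False)  # fixed by design

    @property
    def n_vertices(self) -> int:
        return self.weights.shape[0]


def compute_data_covariance(ep: EpochSet) -> np.ndarray:
    """Sensor covariance pooled over epochs after per-epoch mean removal."""
    if ep.n_epochs < 2:
        raise ValueError("need at least 2 epochs for a data covariance")
    centered = ep.data - ep.data.mean(axis=-1, keepdims=True)
    x = np.concatenate(list(centered), axis=-1)  # (sensors, epochs*samples)
    cov = x @ x.T / x.shape[-1]
    cov = 0.5 * (cov + cov.T)
    rank = np.linalg.matrix_rank(cov)
    if rank < cov.shape[0]:
        logger.warning("data covariance rank-deficient (%d/%d); regularization "
                       "will handle it", rank, cov.shape[0])
    return cov


def lcmv_weights(gain: np.ndarray, data_cov: np.ndarray,
                 reg_lambda: float = 0.05) -> BeamformerModel:
    """Unit-gain LCMV filter per vertex: ``w = C_r^-1 l / (l^T C_r^-1 l)``.

    ``C_r = C + reg_lambda * mean(diag(C)) * I`` is the diagonally loaded
    data covariance.  The unit-gain constraint ``w^T l = 1`` is verified for
    every vertex.
    """
    gain = np.asarray(gain, dtype=float)
    data_cov = np.asarray(data_cov, dtype=float)
    n_sensors = gain.shape[0]
    if data_cov.shape != (n_sensors, n_sensors):
        raise ValueError("covariance dimension must equal sensor count")
    c_r = data_cov + reg_lambda * float(np.mean(np.diag(data_cov))) * np.eye(n_sensors)
    try:
        cinv_l = np.linalg.solve(c_r, gain)  # (sensors, vertices)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "regularized covariance is singular; increase reg_lambda"
        ) from err
    denom = np.einsum("sv,sv->v", gain, cinv_l)
    if np.any(denom <= 0) or not np.all(np.isfinite(denom)):
        raise np.linalg.LinAlgError("degenerate leadfield column (l^T C^-1 l <= 0)")
    weights = (cinv_l / denom).T  # (vertices, sensors)
    unit_gain = np.einsum("vs,sv->v", weights, gain)
    if not np.allclose(unit_gain, 1.0, atol=1e-6):
        raise AssertionError("unit-gain constraint violated beyond 1e-6")
    return BeamformerModel(weights=weights, data_cov=data_cov, reg_lambda=reg_lambda)


def reconstruct_roi_timeseries(ep: EpochSet, model: BeamformerModel,
                               geometry) -> SourceEpochs:
    """Beamform sensor epochs to vertices and average within each ROI.

    The ROI series is the arithmetic mean of its vertex series, matching the
    mean-activation definition of regional source activity.
    """
    if model.weights.shape[1] != ep.n_sensors:
        raise ValueError("beamformer sensor count does not match epochs")
    if model.n_vertices != geometry.n_vertices:
        raise ValueError("beamformer vertex count does not match geometry")
    # ROI-mean of vertex filters collapses to one spatial filter per ROI
    n_rois = geometry.n_rois
    membership = np.zeros((n_rois, model.n_vertices))
    membership[geometry.vertex_roi, np.arange(model.n_vertices)] = 1.0
    membership /= membership.sum(axis=1, keepdims=True)
    roi_filters = membership @ model.weights  # (rois, sensors)
    data = np.einsum("rs,est->ert", roi_filters, ep.data)
    return SourceEpochs(data=data, fs=ep.fs, roi_names=list(geometry.roi_names))
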