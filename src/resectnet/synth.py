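"""Synthetic cortical geometry, planted source networks, leadfields and scalp EEG.

Every downstream stage of the pipeline (filtering, beamforming, envelope
connectivity, tree centrality, resection-relative statistics) is testable
against data with known ground truth generated here:

* a spherical cortex parcellated into contiguous ROI patches, with a
  contiguous resection mask targeting chosen ROIs;
* band-limited sources whose slow power envelopes carry a planted pairwise
  correlation structure, optionally with one high-coupling hub region;
* a smooth synthetic leadfield projecting vertex activity to scalp sensors,
  with additive white sensor noise at a requested SNR and optional
  spike-like transients recorded in the annotations.

The envelope model: correlated Gaussian processes (Cholesky factor of the
target correlation matrix) are low-pass filtered at 1 Hz, standardized,
winsorized at +/-2.5 SD, and exponentiated into strictly positive log-normal
envelopes.  The Gaussian correlations are pre-warped through the (clip-
corrected) log-normal moment map so the envelopes themselves carry the
requested correlation.  Each ROI signal is envelope x independent band-passed
unit-variance carrier noise, and bands are summed into one broadband trace
per ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .connectivity import BandDefinition
from .preprocess import Annotations, EEGRecording
from .sourceimg import SourceEpochs

#: Head radius (mm) of the spherical stand-in cortex.
CORTEX_RADIUS_MM = 80.0
#: Scalp radius (mm) where synthetic sensors sit.
SCALP_RADIUS_MM = 95.0
#: Log-normal modulation depth of the power envelopes (SD of log-envelope).
ENVELOPE_LOG_SD = 1.0
#: Winsorization bound (in SD) on the log-envelope before exponentiation.
#: Unbounded exponentiated Gaussians have sub-exponential tails that make
#: sample envelope correlations wildly unstable at minutes-long records; the
#: clip bounds single-excursion influence while keeping the modulation deep.
ENVELOPE_CLIP_SD = 2.5
#: Low-pass cutoff (Hz) defining "slow" envelope dynamics.
ENVELOPE_CUTOFF_HZ = 1.0

#: Bands used by default for planted networks.  The 256 Hz default sampling
#: rate supports band edges up to 64 Hz at the required 4x margin, so the
#: defaults are the three mid-frequency bands most relevant downstream.
DEFAULT_SOURCE_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 5.0, 7.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 13.0, 29.0),
)


@dataclass
class CorticalGeometry:
    """A parcellated source space: vertex positions, ROI labels, hemispheres."""

    vertex_coords: np.ndarray      # (n_vertices, 3) in mm
    vertex_roi: np.ndarray         # (n_vertices,) ROI index per vertex
    roi_names: list[str]
    roi_hemisphere: list[str]      # 'left' | 'right' per ROI

    def __post_init__(self) -> None:
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=float)
        self.vertex_roi = np.asarray(self.vertex_roi, dtype=int)
        n_rois = len(self.roi_names)
        if self.vertex_coords.ndim != 2 or self.vertex_coords.shape[1] != 3:
            raise ValueError("vertex coordinates must be (n_vertices, 3)")
        if len(self.vertex_roi) != len(self.vertex_coords):
            raise ValueError("one ROI index per vertex required")
        if self.vertex_roi.min(initial=0) < 0 or self.vertex_roi.max(initial=-1) >= n_rois:
            raise ValueError("vertex ROI index out of range")
        if len(self.roi_hemisphere) != n_rois:
            raise ValueError("one hemisphere per ROI required")
        if set(np.unique(self.vertex_roi)) != set(range(n_rois)):
            raise ValueError("every ROI must own at least one vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_coords)

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    def roi_vertices(self, roi: int) -> np.ndarray:
        return np.flatnonzero(self.vertex_roi == roi)


@dataclass
class ResectionMask:
    """Per-vertex boolean flag marking surgically removed cortex."""

    resected: np.ndarray

    def __post_init__(self) -> None:
        self.resected = np.asarray(self.resected, dtype=bool)

    @property
    def n_resected(self) -> int:
        return int(self.resected.sum())


@dataclass
class Leadfield:
    """Sensor x vertex forward gain matrix with sensor labels."""

    gain: np.ndarray
    sensor_labels: list[str]
    sensor_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("leadfield entries must be finite")
        if np.any(np.all(self.gain == 0, axis=0)):
            raise ValueError("leadfield has an all-zero column (unseen vertex)")
        if len(self.sensor_labels) != self.gain.shape[0]:
            raise ValueError("one label per sensor required")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.gain.shape[1]


@dataclass
class NetworkSpec:
    """Parameters of a planted envelope-correlation network."""

    n_rois: int = 68
    base_coupling: float = 0.1
    hub_roi: int | None = None
    hub_coupling: float = 0.6
    bands: tuple[BandDefinition, ...] = DEFAULT_SOURCE_BANDS
    fs: float = 256.0
    epoch_len_s: float = 2.0
    n_epochs: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 2:
            raise ValueError("need at least 2 ROIs")
        if not 0 <= self.base_coupling < 1:
            raise ValueError("base_coupling must be in [0, 1)")
        if self.hub_roi is not None:
            if not 0 <= self.hub_roi < self.n_rois:
                raise ValueError("hub_roi out of range")
            if not self.base_coupling < self.hub_coupling < 1:
                raise ValueError("need base_coupling < hub_coupling < 1")
        top = max(b.high for b in self.bands)
        if self.fs < 4 * top:
            raise ValueError(f"fs={self.fs} below 4x highest band edge ({top} Hz)")
        if self.n_epochs < 1 or self.epoch_len_s <= 0:
            raise ValueError("invalid epoch configuration")

    @property
    def n_samples(self) -> int:
        return int(round(self.n_epochs * self.epoch_len_s * self.fs))


@dataclass
class SimulatedSources(SourceEpochs):
    """Source epochs plus the planted ground truth used by test oracles."""

    band_envelopes: dict[str, np.ndarray] = field(default_factory=dict)
    spec: NetworkSpec | None = None

    def continuous(self) -> np.ndarray:
        """Concatenate epochs back into ``(n_rois, total_samples)``."""
        return np.moveaxis(self.data, 0, 1).reshape(self.n_rois, -1)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly-even unit vectors (golden-angle spiral)."""
    i = np.arange(n)
    z = 1 - 2 * (i + 0.5) / n
    r = np.sqrt(1 - z**2)
    phi = i * np.pi * (3 - np.sqrt(5))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_geometry(n_rois: int = 68, vertices_per_roi: int = 20,
                  seed: int = 0) -> CorticalGeometry:
    """Spherical cortex of contiguous ROI patches at radius 80 mm.

    ROI centres are spread evenly over the sphere; each patch is the centre
    plus tangential Gaussian jitter, re-projected to the sphere.  ROIs whose
    centre has x < 0 are labelled left-hemisphere, the rest right.
    """
    if n_rois < 2 or vertices_per_roi < 1:
        raise ValueError("need n_rois >= 2 and vertices_per_roi >= 1")
    rng = np.random.default_rng(seed)
    centers = _fibonacci_sphere(n_rois)
    patch_sd = CORTEX_RADIUS_MM * np.sqrt(4.0 / n_rois) * 0.35
    coords = np.empty((n_rois * vertices_per_roi, 3))
    vertex_roi = np.repeat(np.arange(n_rois), vertices_per_roi)
    for k, c in enumerate(centers):
        pts = c * CORTEX_RADIUS_MM + rng.normal(0.0, patch_sd, size=(vertices_per_roi, 3))
        pts *= CORTEX_RADIUS_MM / np.linalg.norm(pts, axis=1, keepdims=True)
        coords[k * vertices_per_roi:(k + 1) * vertices_per_roi] = pts
    hemis = ["left" if c[0] < 0 else "right" for c in centers]
    names = [f"{'L' if h == 'left' else 'R'}.roi{k:02d}" for k, h in enumerate(hemis)]
    return CorticalGeometry(coords, vertex_roi, names, hemis)


def make_resection(geometry: CorticalGeometry, target_rois: list[int],
                   partial_fraction: float | list[float] = 1.0) -> ResectionMask:
    """Resect the requested fraction of each target ROI, nearest-centroid first.

    For a fraction f > 0 on an m-vertex ROI, ``max(1, floor(f*m))`` vertices
    closest to the ROI centroid are marked resected.  An all-empty result is
    rejected: a surgical case has a non-empty resection.
    """
    fractions = (np.full(len(target_rois), partial_fraction, dtype=float)
                 if np.isscalar(partial_fraction)
                 else np.asarray(partial_fraction, dtype=float))
    if len(fractions) != len(target_rois):
        raise ValueError("one fraction per target ROI required")
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("fractions must be in [0, 1]")
    resected = np.zeros(geometry.n_vertices, dtype=bool)
    for roi, frac in zip(target_rois, fractions):
        if not 0 <= roi < geometry.n_rois:
            raise ValueError(f"unknown ROI index {roi}")
        if frac == 0:
            continue
        verts = geometry.roi_vertices(roi)
        k = max(1, int(np.floor(frac * len(verts))))
        centroid = geometry.vertex_coords[verts].mean(axis=0)
        d = np.linalg.norm(geometry.vertex_coords[verts] - centroid, axis=1)
        resected[verts[np.argsort(d, kind="stable")[:k]]] = True
    if not resected.any():
        raise ValueError("resection mask is empty; surgical cases resect >= 1 vertex")
    return ResectionMask(resected)


def planted_correlation(n_rois: int, base: float, hub_roi: int | None,
                        hub: float) -> np.ndarray:
    """Target envelope-correlation matrix: base off-diagonal, hub rows boosted.

    The matrix is made positive semidefinite by eigenvalue clipping (then
    re-scaled to unit diagonal) in the rare configurations where the raw
    construction is indefinite.
    """
    c = np.full((n_rois, n_rois), base)
    if hub_roi is not None:
        c[hub_roi, :] = hub
        c[:, hub_roi] = hub
    np.fill_diagonal(c, 1.0)
    return planted_correlation_repair(c)


def _clipped_exp_corr_map(sigma: float, clip: float,
                          n_nodes: int = 48) -> tuple[np.ndarray, np.ndarray]:
    """Tabulate rho_gauss -> corr(exp(sigma*clip(X)), exp(sigma*clip(Y))).

    Gauss-Hermite quadrature over the bivariate normal; the map is strictly
    increasing, so its inverse (used by the warp) is a 1-D interpolation.
    """
    x, wq = np.polynomial.hermite_e.hermegauss(n_nodes)
    wq = wq / wq.sum()
    f = np.exp(sigma * np.clip(x, -clip, clip))
    m1 = float(wq @ f)
    var = float(wq @ f**2) - m1**2
    rhos = np.linspace(0.0, 0.999, 60)
    out = np.empty_like(rhos)
    for k, r in enumerate(rhos):
        # Y | X=x ~ N(r x, 1 - r^2); integrate E[f(X) f(Y)] on the tensor grid
        y = r * x[:, None] + np.sqrt(1 - r**2) * x[None, :]
        fy = np.exp(sigma * np.clip(y, -clip, clip))
        e_xy = float(wq @ ((fy * wq[None, :]).sum(axis=1) * f))
        out[k] = (e_xy - m1**2) / var
    return rhos, out


def _envelope_warp(c: np.ndarray, sigma: float = ENVELOPE_LOG_SD,
                   clip: float = ENVELOPE_CLIP_SD) -> np.ndarray:
    """Gaussian correlations whose winsorized exponentials carry ``c``.

    Without the winsorization this is the closed-form log-normal moment map
    ``rho_g = log(1 + c (e^{s^2}-1)) / s^2``; the clip perturbs it slightly,
    so the map is tabulated by quadrature and inverted numerically.
    """
    rhos, corr = _clipped_exp_corr_map(sigma, clip)
    rho = np.interp(c, corr, rhos)
    np.fill_diagonal(rho, 1.0)
    return rho


def envelope_correlation_of(rho_gauss: float, sigma: float = ENVELOPE_LOG_SD,
                            clip: float = ENVELOPE_CLIP_SD) -> float:
    """Forward map: Gaussian correlation -> envelope correlation."""
    rhos, corr = _clipped_exp_corr_map(sigma, clip)
    return float(np.interp(rho_gauss, rhos, corr))


def _correlated_envelopes(c_env: np.ndarray, n_samples: int, fs: float,
                          rng: np.random.Generator,
                          sigma: float = ENVELOPE_LOG_SD) -> np.ndarray:
    """Positive slow envelopes with pairwise correlation ``c_env``."""
    rho = planted_correlation_repair(_envelope_warp(c_env, sigma))
    chol = np.linalg.cholesky(rho + 1e-10 * np.eye(len(rho)))
    white = rng.standard_normal((len(rho), n_samples))
    z = chol @ white
    sos = signal.butter(4, ENVELOPE_CUTOFF_HZ, fs=fs, output="sos")
    z = signal.sosfiltfilt(sos, z, axis=-1)
    z = (z - z.mean(-1, keepdims=True)) / z.std(-1, keepdims=True)
    env = np.exp(sigma * np.clip(z, -ENVELOPE_CLIP_SD, ENVELOPE_CLIP_SD))
    return env / env.mean(-1, keepdims=True)


def planted_correlation_repair(c: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and restore the unit diagonal."""
    vals = np.linalg.eigvalsh(c)
    if vals[0] >= 0:
        return c
    w, v = np.linalg.eigh(c)
    out = (v * np.clip(w, 1e-10, None)) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    assert np.linalg.eigvalsh(out)[0] >= -1e-12, "PSD repair failed"
    return out


def _bandpassed_noise(n_rois: int, n_samples: int, band: BandDefinition,
                      fs: float, rng: np.random.Generator) -> np.ndarray:
    """Independent unit-variance carriers band-passed to ``band``."""
    x = rng.standard_normal((n_rois, n_samples))
    sos = signal.butter(4, [band.low, band.high], btype="bandpass", fs=fs,
                        output="sos")
    x = signal.sosfiltfilt(sos, x, axis=-1)
    return x / x.std(-1, keepdims=True)


def simulate_sources(spec: NetworkSpec) -> SimulatedSources:
    """Planted-network ROI sources: envelope x carrier per band, bands summed.

    Deterministic for a fixed ``spec.seed``.  The per-band planted envelopes
    are retained on the returned object so tests can use the direct Pearson
    correlation of the true envelopes as an oracle for downstream AEC.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    c_env = planted_correlation(spec.n_rois, spec.base_coupling,
                                spec.hub_roi, spec.hub_coupling)
    broadband = np.zeros((spec.n_rois, n))
    band_envelopes: dict[str, np.ndarray] = {}
    for band in spec.bands:
        env = _correlated_envelopes(c_env, n, spec.fs, rng)
        carrier = _bandpassed_noise(spec.n_rois, n, band, spec.fs, rng)
        broadband += env * carrier
        band_envelopes[band.name] = env
    per_epoch = int(round(spec.epoch_len_s * spec.fs))
    data = np.moveaxis(broadband.reshape(spec.n_rois, spec.n_epochs, per_epoch), 1, 0)
    names = [f"roi{k:02d}" for k in range(spec.n_rois)]
    return SimulatedSources(data=data, fs=spec.fs, roi_names=names,
                            band_envelopes=band_envelopes, spec=spec)


def make_leadfield(geometry: CorticalGeometry, n_sensors: int = 64,
                   seed: int = 0, sensitivity_mm: float = 20.0,
                   noise_scale: float = 0.02) -> Leadfield:
    """Smooth synthetic forward gain: Gaussian sensitivity bumps over vertices.

    Sensors sit on an even spiral over the whole scalp sphere — the stand-in
    cortex is a full sphere, so full coverage is the geometrically consistent
    phantom montage.  Sensor s sees vertex v with gain
    exp(-d(s,v)^2 / (2 * sensitivity_mm^2)), plus a small random component
    that keeps the matrix conditioning finite.  The condition number
    (largest/smallest singular value) is checked to be below 1e6.
    """
    rng = np.random.default_rng(seed)
    sensors = _fibonacci_sphere(n_sensors) * SCALP_RADIUS_MM
    d2 = ((sensors[:, None, :] - geometry.vertex_coords[None, :, :])**2).sum(-1)
    gain = np.exp(-d2 / (2 * sensitivity_mm**2))
    gain *= (1.0 + 0.05 * rng.standard_normal((n_sensors, 1)))
    gain += noise_scale * float(np.median(gain)) * rng.standard_normal(gain.shape)
    sv = np.linalg.svd(gain, compute_uv=False)
    cond = sv[0] / sv[-1]
    if cond > 1e6:
        raise ValueError(f"leadfield condition number {cond:.2e} exceeds 1e6")
    labels = [f"E{k:03d}" for k in range(n_sensors)]
    return Leadfield(gain=gain, sensor_labels=labels, sensor_coords=sensors)


def _spike_waveform(fs: float, duration_s: float = 0.2) -> np.ndarray:
    """Biphasic transient: one windowed sine cycle (sharp up, rebound down)."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / n
    return np.sin(2 * np.pi * t) * np.hanning(n)


def simulate_scalp_eeg(sources: SimulatedSources, geometry: CorticalGeometry,
                       leadfield: Leadfield, snr_db: float | None = 10.0,
                       spike_times_s: list[float] | None = None,
                       seed: int = 0) -> EEGRecording:
    """Project ROI sources through the leadfield and add sensor noise.

    Every vertex emits its ROI's source signal; sensor traces are the gain
    matrix applied to the vertex signals plus white noise scaled so that the
    mean sensor signal power over noise power equals ``snr_db`` (no noise for
    ``snr_db=None``).  Optional 200 ms biphasic spike transients are added at
    ``spike_times_s`` with a fixed random scalp topography and recorded in the
    annotations.
    """
    if leadfield.n_vertices != geometry.n_vertices:
        raise ValueError("leadfield column count must equal vertex count")
    if sources.n_rois != geometry.n_rois:
        raise ValueError("source ROI count must match geometry")
    rng = np.random.default_rng(seed)
    src = sources.continuous()
    membership = np.zeros((geometry.n_vertices, geometry.n_rois))
    membership[np.arange(geometry.n_vertices), geometry.vertex_roi] = 1.0
    roi_gain = leadfield.gain @ membership  # (sensors, rois)
    data = roi_gain @ src
    if snr_db is not None and np.isfinite(snr_db):
        sig_power = float(np.mean(data**2))
        noise_sd = np.sqrt(sig_power / 10 ** (snr_db / 10))
        data = data + noise_sd * rng.standard_normal(data.shape)
    spikes = [float(t) for t in (spike_times_s or [])]
    if spikes:
        wave = _spike_waveform(sources.fs)
        topo = rng.standard_normal(leadfield.n_sensors)
        topo *= 5.0 * float(np.sqrt(np.mean(data**2))) / np.abs(topo).max()
        for t in spikes:
            i0 = int(round(t * sources.fs)) - len(wave) // 2
            lo, hi = max(i0, 0), min(i0 + len(wave), data.shape[1])
            if hi <= lo:
                raise ValueError(f"spike time {t} s outside the recording")
            data[:, lo:hi] += np.outer(topo, wave[lo - i0:hi - i0])
    return EEGRecording(data=data, fs=sources.fs,
                        sensor_labels=list(leadfield.sensor_labels),
                        annotations=Annotations(spikes_s=spikes))
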