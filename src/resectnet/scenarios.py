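"""End-to-end synthetic cohorts: virtual surgery on planted-hub networks.

A "case" is one synthetic patient: a parcellated spherical cortex with a
planted epileptogenic hub (one region whose envelope coupling to every other
region is elevated), projected to scalp sensors through a synthetic
leadfield with additive noise, then pushed through the full analysis chain
(filtering, epoching, LCMV beamforming, orthogonalized AEC, MST global
centrality, resection-relative ROI classification).

Two cohort types mirror the clinical contrast of interest:

* successful surgery — the resection removes the hub; post-surgical sources
  are simulated without the hub coupling and with the resected tissue silent;
* failed surgery — the resection removes an unrelated region while the hub
  keeps driving the network.

A cheap source-free null cohort (no hub, identically distributed pre/post
connectivity) supports calibration checks of the statistical battery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .anatomy import classify_rois
from .connectivity import BandDefinition, connectivity_matrices, relative_power
from .netmetrics import CentralityTable, centrality_from_matrices
from .preprocess import apply_bandpass, apply_notch, exclude_contaminated, segment_epochs
from .sourceimg import compute_data_covariance, lcmv_weights, reconstruct_roi_timeseries
from .stats import REPEATED_SURGERY, SEIZURE_FREE, SurgeryCase, compare_pre_post
from .synth import (DEFAULT_SOURCE_BANDS, CorticalGeometry, Leadfield, NetworkSpec,
                    make_geometry, make_leadfield, make_resection, simulate_sources,
                    simulate_scalp_eeg)


@dataclass(frozen=True)
class CaseConfig:
    """Study conditions for one synthetic case."""

    n_rois: int = 68
    vertices_per_roi: int = 8
    n_sensors: int = 64
    bands: tuple[BandDefinition, ...] = DEFAULT_SOURCE_BANDS
    n_epochs: int = 60
    epoch_len_s: float = 2.0
    fs: float = 256.0
    snr_db: float = 10.0
    base_coupling: float = 0.1
    hub_coupling: float = 0.6
    reg_lambda: float = 0.05
    resect_fraction: float = 1.0


def analyze_recording(rec, geometry: CorticalGeometry, leadfield: Leadfield,
                      bands: tuple[BandDefinition, ...],
                      epoch_len_s: float = 2.0, reg_lambda: float = 0.05,
                      notch_hz: float = 60.0, band_lo: float = 1.0,
                      band_hi: float = 70.0,
                      with_power: bool = False):
    """Sensor EEG -> per-band global-centrality tables (the core pipeline).

    Returns ``(tables, power)`` where ``tables`` maps band name to
    :class:`CentralityTable` and ``power`` is the per-ROI relative band-power
    DataFrame (or None when not requested).
    """
    rec = apply_notch(rec, notch_hz)
    rec = apply_bandpass(rec, band_lo, min(band_hi, 0.45 * rec.fs))
    ep = segment_epochs(rec, epoch_len_s)
    ep = exclude_contaminated(ep, rec.annotations)
    cov = compute_data_covariance(ep)
    model = lcmv_weights(leadfield.gain, cov, reg_lambda)
    src = reconstruct_roi_timeseries(ep, model, geometry)
    mats = connectivity_matrices(src, bands)
    tables: dict[str, CentralityTable] = {}
    for band in bands:
        per_band = [m.values for m in mats if m.band.name == band.name]
        tables[band.name] = centrality_from_matrices(per_band, geometry.roi_names)
    power = relative_power(src, bands) if with_power else None
    return tables, power


def simulate_case(case_id: str, hub_resected: bool, seed: int,
                  config: CaseConfig = CaseConfig(),
                  with_power: bool = False) -> SurgeryCase:
    """One synthetic patient with pre- and post-surgical EEG analyses.

    The hub region and the resection target are drawn from ``seed``; with
    ``hub_resected`` the resection covers the hub and the post-surgical
    network has no hub, otherwise a same-hemisphere non-hub region is
    resected and the hub remains active.  Resected tissue is silenced in the
    post-surgical simulation.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=8)
    geometry = make_geometry(config.n_rois, config.vertices_per_roi, seed=int(sub[0]))
    leadfield = make_leadfield(geometry, config.n_sensors, seed=int(sub[1]))

    hub = int(rng.integers(config.n_rois))
    if hub_resected:
        target = hub
    else:
        same_hemi = [r for r in range(config.n_rois)
                     if r != hub
                     and geometry.roi_hemisphere[r] == geometry.roi_hemisphere[hub]]
        target = int(same_hemi[rng.integers(len(same_hemi))])
    mask = make_resection(geometry, [target], config.resect_fraction)

    spec_pre = NetworkSpec(n_rois=config.n_rois, base_coupling=config.base_coupling,
                           hub_roi=hub, hub_coupling=config.hub_coupling,
                           bands=config.bands, fs=config.fs,
                           epoch_len_s=config.epoch_len_s,
                           n_epochs=config.n_epochs, seed=int(sub[2]))
    spec_post = dc_replace(spec_pre, hub_roi=None if hub_resected else hub,
                           seed=int(sub[3]))

    centrality: dict[str, dict[str, CentralityTable]] = {}
    power: dict = {}
    for tp, spec, eeg_seed in (("pre", spec_pre, int(sub[4])),
                               ("post", spec_post, int(sub[5]))):
        sources = simulate_sources(spec)
        if tp == "post":
            sources.data[:, target, :] = 0.0  # resected tissue is silent
        rec = simulate_scalp_eeg(sources, geometry, leadfield,
                                 snr_db=config.snr_db, seed=eeg_seed)
        tables, pw = analyze_recording(rec, geometry, leadfield, config.bands,
                                       config.epoch_len_s, config.reg_lambda,
                                       with_power=with_power)
        centrality[tp] = tables
        if with_power:
            power[tp] = pw

    labeling = classify_rois(geometry, mask)
    return SurgeryCase(
        case_id=case_id,
        group=SEIZURE_FREE if hub_resected else REPEATED_SURGERY,
        outcomes={1: "good" if hub_resected else "poor"},
        centrality=centrality,
        labeling={1: labeling},
        metadata={"hub_roi": hub, "resected_roi": target,
                  "age_years": None, "interval_years": None, "n_aed": {}},
        relative_power=power,
    )


def simulate_cohort(n_cases: int, hub_resected: bool, seed: int,
                    config: CaseConfig = CaseConfig()) -> list[SurgeryCase]:
    """Independent synthetic cases of one surgery-outcome type."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_cases)
    prefix = "sf" if hub_resected else "rs"
    return [simulate_case(f"{prefix}{k:02d}", hub_resected, int(s), config)
            for k, s in enumerate(seeds)]


# --- source-free null cohort for calibration --------------------------------

def _random_aec(n_rois: int, rng: np.random.Generator) -> np.ndarray:
    """A connectivity-matrix-shaped draw with no planted structure."""
    m = rng.uniform(0.05, 0.95, size=(n_rois, n_rois))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return m


def null_cohort(n_cases: int, seed: int, n_rois: int = 16,
                vertices_per_roi: int = 4, n_epochs: int = 20) -> list[SurgeryCase]:
    """Cases whose pre and post connectivity are identically distributed.

    Centrality tables are computed from independent structureless AEC draws
    at both time points, with a real (small) geometry and resection so that
    region classes are populated; only band 'theta' is instantiated since the
    null is band-agnostic.
    """
    rng = np.random.default_rng(seed)
    cases = []
    for k in range(n_cases):
        geometry = make_geometry(n_rois, vertices_per_roi,
                                 seed=int(rng.integers(2**31 - 1)))
        target = int(rng.integers(n_rois))
        mask = make_resection(geometry, [target], 1.0)
        centrality = {}
        for tp in ("pre", "post"):
            mats = [_random_aec(n_rois, rng) for _ in range(n_epochs)]
            centrality[tp] = {"theta": centrality_from_matrices(mats,
                                                                geometry.roi_names)}
        cases.append(SurgeryCase(
            case_id=f"null{k:02d}", group=SEIZURE_FREE, outcomes={1: "good"},
            centrality=centrality, labeling={1: classify_rois(geometry, mask)},
        ))
    return cases


def null_rejection_rate(n_replicates: int = 200, n_cases: int = 6,
                        alpha: float = 0.05, seed: int = 0) -> float:
    """Fraction of null cohorts where the far-region pre/post test rejects."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        cases = null_cohort(n_cases, seed=int(rng.integers(2**31 - 1)))
        res = compare_pre_post(cases, "theta", "far", "first-successful", alpha)
        rejections += res.p_value < alpha
    return rejections / n_replicates
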