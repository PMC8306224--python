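"""Readers and writers for the pipeline's on-disk formats.

Plain-text formats throughout: geometry, masks and annotations as JSON;
leadfields, EEG and result tables as TSV.  Epoch and source tensors are
stored as little-endian NPY with a JSON sidecar describing shape, sampling
rate and labels.  EDF recordings are read through MNE when it is installed;
writing always goes to TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Annotations, EEGRecording, EpochSet
from .sourceimg import SourceEpochs
from .synth import CorticalGeometry, Leadfield, ResectionMask


# --- geometry / mask / annotations (JSON) -----------------------------------

def write_geometry(geom: CorticalGeometry, path: str | Path) -> None:
    payload = {
        "vertices": geom.vertex_coords.tolist(),
        "vertex_roi": geom.vertex_roi.tolist(),
        "roi_names": list(geom.roi_names),
        "roi_hemisphere": list(geom.roi_hemisphere),
    }
    Path(path).write_text(json.dumps(payload))


def read_geometry(path: str | Path) -> CorticalGeometry:
    d = json.loads(Path(path).read_text())
    return CorticalGeometry(np.asarray(d["vertices"]), np.asarray(d["vertex_roi"]),
                            d["roi_names"], d["roi_hemisphere"])


def write_mask(mask: ResectionMask, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"resected": mask.resected.astype(int).tolist()}))


def read_mask(path: str | Path) -> ResectionMask:
    return ResectionMask(np.asarray(json.loads(Path(path).read_text())["resected"]))


def write_annotations(ann: Annotations, path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {"spikes_s": ann.spikes_s, "artifacts_s": [list(x) for x in ann.artifacts_s]}
    ))


def read_annotations(path: str | Path) -> Annotations:
    d = json.loads(Path(path).read_text())
    return Annotations(spikes_s=d.get("spikes_s", []),
                       artifacts_s=[tuple(x) for x in d.get("artifacts_s", [])])


# --- leadfield and EEG (TSV) ------------------------------------------------

def write_leadfield(lf: Leadfield, path: str | Path) -> None:
    """Sensors x vertices TSV with sensor labels as the index column."""
    pd.DataFrame(lf.gain, index=lf.sensor_labels).to_csv(path, sep="\t", header=False)


def read_leadfield(path: str | Path) -> Leadfield:
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    return Leadfield(gain=df.to_numpy(dtype=float),
                     sensor_labels=[str(i) for i in df.index])


def write_eeg_tsv(rec: EEGRecording, path: str | Path) -> None:
    """Samples x sensors TSV; the sampling rate goes in a ``.meta.json`` sidecar."""
    path = Path(path)
    pd.DataFrame(rec.data.T, columns=rec.sensor_labels).to_csv(
        path, sep="\t", index=False, float_format="%.6f")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps({"fs": rec.fs}))


def read_eeg_tsv(path: str | Path, fs: float | None = None,
                 annotations: Annotations | None = None) -> EEGRecording:
    path = Path(path)
    if fs is None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        if not sidecar.exists():
            raise ValueError("sampling rate required (no sidecar found)")
        fs = float(json.loads(sidecar.read_text())["fs"])
    df = pd.read_csv(path, sep="\t")
    return EEGRecording(df.to_numpy(dtype=float).T, fs, [str(c) for c in df.columns],
                        annotations or Annotations())


def read_eeg_edf(path: str | Path,
                 annotations: Annotations | None = None) -> EEGRecording:
    """Read an EDF recording through MNE (optional dependency)."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecording(raw.get_data() * 1e6, raw.info["sfreq"], raw.ch_names,
                        annotations or Annotations())


def read_eeg(path: str | Path, **kwargs) -> EEGRecording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_eeg_edf(path, **kwargs)
    return read_eeg_tsv(path, **kwargs)


# --- epoch / source tensors (NPY + sidecar) ---------------------------------

def write_epochs(ep: EpochSet, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "epochs.npy", ep.data.astype("<f8"))
    (directory / "epochs.json").write_text(json.dumps({
        "fs": ep.fs, "epoch_len_s": ep.epoch_len_s,
        "epoch_start_times_s": ep.epoch_start_times_s.tolist(),
        "sensor_labels": ep.sensor_labels,
    }))


def read_epochs(directory: str | Path) -> EpochSet:
    directory = Path(directory)
    meta = json.loads((directory / "epochs.json").read_text())
    return EpochSet(np.load(directory / "epochs.npy"), meta["fs"],
                    meta["epoch_len_s"], np.asarray(meta["epoch_start_times_s"]),
                    meta["sensor_labels"])


def write_sources(src: SourceEpochs, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "sources.npy", src.data.astype("<f8"))
    (directory / "sources.json").write_text(json.dumps(
        {"fs": src.fs, "roi_names": src.roi_names}))


def read_sources(directory: str | Path) -> SourceEpochs:
    directory = Path(directory)
    meta = json.loads((directory / "sources.json").read_text())
    return SourceEpochs(np.load(directory / "sources.npy"), meta["fs"],
                        meta["roi_names"])
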