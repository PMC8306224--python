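# resectnet

Source-level functional-network analysis of scalp EEG around pediatric
epilepsy surgery, with a synthetic-data generator that plants known network
structure so the entire pipeline is testable without clinical data.

## The problem

After a focal resection for drug-resistant epilepsy, does the rest of the
brain's functional network reorganize — and does that reorganization track
surgical success? The pipeline answers this at the level of cortical
regions: reconstruct region time series from the scalp, estimate a
functional network per frequency band, summarize each region's importance
with a single centrality number, classify regions by their spatial relation
to the resection, and test pre- vs post-surgical changes.

## The method

For interictal sleep EEG (19–64 channels), per patient and time point:

1. **Preprocess** — 60 Hz zero-phase IIR notch, 1–70 Hz zero-delay
   Kaiser-window FIR band-pass, 2 s epochs, exclusion of every epoch within
   ±1 s of an annotated spike or inside an artifact interval.
2. **Source imaging** — scalar LCMV beamformer per cortical vertex,
   `w = C_r⁻¹ l / (lᵀ C_r⁻¹ l)` with diagonally loaded data covariance
   `C_r = C + λ·mean(diag C)·I` and identity noise covariance; region time
   series are the mean over the region's vertices.
3. **Connectivity** — orthogonalized amplitude-envelope correlation (AEC)
   per 2 s epoch in δ, θ, α, β, γ: band-pass + Hilbert envelopes, pairwise
   zero-lag orthogonalization to suppress spatial leakage, symmetrized
   absolute correlation in [0, 1]; plus relative band power (Welch).
4. **Networks** — per epoch, a complete graph with edge cost = 1/AEC is
   reduced to its minimum spanning tree; betweenness, closeness and
   eigenvector centrality are computed on the tree, epoch-averaged,
   max-normalized (most central region = 1), and averaged into a composite
   **global centrality** per region, band and time point.
5. **Anatomy** — regions with ≥ 10 % of vertices resected are excluded;
   untouched regions ≤ 10 mm from the resection in its hemisphere are
   *adjacent*, the rest *far*.
6. **Statistics** — Wilcoxon signed-rank on pooled per-region (pre, post)
   global-centrality pairs per band / region class / surgery type, plus
   rank-sum group comparisons and Spearman covariate checks (age, interval,
   drug load, relative-power change).

The `synth` module generates spherical parcellated cortices, contiguous
resections, leadfields, and band-limited sources whose slow log-normal
envelopes carry a planted correlation structure — including a removable
high-coupling hub region — so every stage above has ground truth. See
`docs/methods.md` for models, parameters, design choices and limitations.

## Worked example

Simulate a 16-region network with a planted hub, project it to 32 sensors
at 10 dB SNR, and run the full chain back to centralities:

```python
from resectnet import (NetworkSpec, simulate_sources, make_geometry,
                      make_leadfield, simulate_scalp_eeg, apply_notch,
                      apply_bandpass, segment_epochs, exclude_contaminated,
                      compute_data_covariance, lcmv_weights,
                      reconstruct_roi_timeseries, connectivity_matrices,
                      centrality_from_matrices)
from resectnet.connectivity import BandDefinition

beta = BandDefinition("beta", 13.0, 29.0)
geom = make_geometry(n_rois=16, vertices_per_roi=8, seed=0)
lf = make_leadfield(geom, n_sensors=32, seed=0)
spec = NetworkSpec(n_rois=16, base_coupling=0.1, hub_roi=4,
                   hub_coupling=0.6, bands=(beta,), n_epochs=30, seed=0)
src = simulate_sources(spec)
rec = simulate_scalp_eeg(src, geom, lf, snr_db=10.0, seed=1)

rec = apply_bandpass(apply_notch(rec, 60.0), 1.0, 70.0)
epochs = exclude_contaminated(segment_epochs(rec, 2.0), rec.annotations)
model = lcmv_weights(lf.gain, compute_data_covariance(epochs), reg_lambda=0.05)
sources = reconstruct_roi_timeseries(epochs, model, geom)

mats = [m.values for m in connectivity_matrices(sources, (beta,))]
table = centrality_from_matrices(mats, geom.roi_names)
print(table.to_frame().sort_values("global", ascending=False).head(4).round(3))
```

```
         betweenness  closeness  eigenvector  global
L.roi04        1.000      1.000        1.000   1.000
R.roi00        0.754      0.935        0.907   0.865
L.roi01        0.859      0.932        0.790   0.860
L.roi14        0.653      0.902        0.893   0.816
```

The planted hub (region 4) comes out as the most central region on all
three measures — global centrality 1.0 after per-patient max-normalization
— despite the signal having passed through sensor noise and the ill-posed
inverse problem. `scenarios.simulate_cohort` wraps this into whole
virtual-surgery cohorts (hub resected vs hub retained) whose pooled
pre/post comparison reproduces the qualitative clinical signature: far-region
centrality rises after hub removal and not otherwise.

A command-line interface mirrors the stages
(`resectnet simulate | preprocess | localize | connect | graph | classify`);
each subcommand reads and writes plain JSON/TSV formats.

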