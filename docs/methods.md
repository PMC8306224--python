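# Methods

This note documents the models, estimators and numerical choices behind
`resectnet`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## Scientific setting

Children with drug-resistant epilepsy may undergo focal resective surgery.
The package implements a network-level analysis of interictal scalp EEG
around such surgery: cortical source activity is reconstructed from the
sensors, a functional network between cortical regions is estimated from
band-limited amplitude envelopes, each region's importance is summarized by
a composite centrality on the network's minimum spanning tree, regions are
classified by their spatial relation to the resection, and pre- vs
post-surgical centrality is compared per frequency band and region class.
The guiding hypothesis is that removing an epileptogenic hub lets the
remaining, untouched cortex reorganize: its relative centrality rises after
a successful surgery and does not after a failed one.

## Synthetic data model

No clinical recordings ship with the package; a generator plants known
structure so every claim the tests make is checkable against ground truth.

**Geometry.** The cortex is a sphere of radius 80 mm parcellated into
`n_rois` contiguous patches (default 68, the granularity of a standard
whole-brain gyral atlas): patch centres sit on a golden-angle spiral, each
patch is its centre plus tangential Gaussian jitter re-projected onto the
sphere. ROIs with centre x < 0 are "left" hemisphere. A resection is the
`fraction` of a target ROI's vertices nearest its centroid, so it is
contiguous and unilateral. The sphere preserves what the downstream rules
need — Euclidean distances and hemisphere membership — and nothing else;
gyral folding, vertex density gradients and post-surgical deformation are
not modelled.

**Sources.** For each band, each ROI emits `envelope x carrier`:

* *Carriers* are independent unit-variance Gaussian noises band-passed to
  the band (4th-order Butterworth, zero-phase). They carry no coupling.
* *Envelopes* carry all planted coupling. Correlated Gaussians (Cholesky
  factor of the target correlation matrix) are low-pass filtered at 1 Hz,
  standardized, winsorized at ±2.5 SD, exponentiated with log-SD 1.0 and
  mean-normalized, giving strictly positive, slowly varying, strongly
  modulated envelopes. The Gaussian correlations are pre-warped through a
  quadrature-tabulated moment map so the envelopes themselves carry the
  requested correlation. The winsorization exists because unbounded
  log-normal envelopes have sub-exponential tails: a single multi-second
  excursion can dominate a whole recording's sample correlation, making the
  planted coupling practically unrecoverable at realistic record lengths
  (empirical SD of the 4-minute sample correlation ≈ 0.27 unclipped
  vs ≈ 0.04 clipped).

The planted correlation matrix is `base_coupling` everywhere with one
optional hub row/column at `hub_coupling`. This matrix is not positive
semidefinite for strong hubs (at 68 ROIs with base 0.1 the feasible hub
ceiling is ≈ 0.34); it is repaired by eigenvalue clipping and re-scaling to
unit diagonal, and **the repaired matrix is the ground truth**: oracles use
the realized planted envelopes, never the nominal numbers.

**Forward model.** Sensors (default 64) sit on an even spiral over a
95 mm scalp sphere; sensor-to-vertex gain is a Gaussian bump of scale
20 mm plus a 2% random component that bounds the condition number (checked
< 1e6). Because the stand-in cortex is a full sphere, full-scalp coverage
is the geometrically consistent phantom montage; a cap-only montage would
leave half the source space unobservable, which is a property of the
phantom, not of the method. White sensor noise is scaled to a requested
SNR (default 10 dB); optional 200 ms biphasic spike transients with a fixed
random topography are added and logged in the annotations. Volume
conduction physics (BEM), electrode drift and physiological artifacts are
not modelled, so passing tests validate the analysis chain, not robustness
to un-modelled clinical noise.

## Preprocessing

Second-order IIR notch (Q = 30) applied forward-backward (zero phase), then
a 1–70 Hz band-pass built as a high-pass/low-pass cascade of even-order
Kaiser-window FIRs (40 dB design, 1 Hz transition at the low edge, 5 Hz at
the high edge) applied with exact group-delay compensation. Filtering
precedes epoching so no per-epoch edge transients arise. The record is cut
into non-overlapping 2 s epochs from t = 0; any epoch intersecting
[spike − 1 s, spike + 1 s] for any annotated spike, or any artifact
interval, is dropped whole.

## Source reconstruction

Scalar LCMV beamformer with identity noise covariance: per vertex,
`w = C_r^-1 l / (l^T C_r^-1 l)` with `C_r = C + λ·mean(diag C)·I`,
λ = 0.05 by default (exposed; diagonal loading is unavoidable when
inverting an EEG-rank covariance). The data covariance pools all epochs
after per-epoch mean removal. The unit-gain constraint `w^T l = 1` is
asserted to 1e-6 for every vertex. ROI time series are the plain arithmetic
mean of the ROI's vertex series (the "mean activation" convention; no
sign-flipping or rectification).

## Connectivity

Per epoch and band: zero-phase FIR band-pass (Kaiser, transition
clip(0.25·low, 0.5, 2) Hz) and Hilbert transform, computed with reflection
padding of one epoch length to keep edge bias out of 2 s windows. The
orthogonalized amplitude-envelope correlation of ROIs i, j is the mean of
the two directed values: project j's analytic signal on the instantaneous
phase of i, take the magnitude of the orthogonal remainder as j's
leakage-corrected envelope, Pearson-correlate with |i|'s envelope, take the
absolute value; swap roles and average. Identical inputs give exactly 0;
values lie in [0, 1].

Envelope magnitudes are smoothed (centred moving average) before
correlating. The carrier contributes envelope fluctuations at the inverse
bandwidth that are independent between ROIs and only dilute the planted
sub-1-Hz envelope correlation; averaging removes them. The window is 0.5 s
on long records, capped at 1/32 of the series so that short (2 s) epochs
retain ≈ 32 independent envelope samples — below that, lost degrees of
freedom cost more than residual carrier noise. One structural limitation is
worth stating: for narrow bands (theta is 2 Hz wide) the carrier-envelope
spectrum overlaps the sub-1-Hz band of the planted envelopes, so no
smoothing can remove all of it; amplitude-coupling estimates in narrow
bands are intrinsically noisier and more attenuated than in wide bands, and
the quantitative recovery check is therefore run in the beta band.

Relative power: Welch PSD (1 s Hann segments, 50% overlap), band power
integrated over each band and normalized by total 1–70 Hz power, averaged
over epochs.

## Networks and centrality

Each AEC matrix becomes a complete graph with edge cost 1/AEC (floored at
1e-12) and edge weight AEC, reduced to its minimum spanning tree by Kruskal
with deterministic tie-breaking (cost, then smaller node, then larger
node). On the tree: raw betweenness (pair counts; the downstream
max-normalization makes constant factors immaterial), closeness
`(n-1)/Σ d` on cost-weighted path distances, and eigenvector centrality on
the AEC-weighted adjacency (weights, not costs — eigenvector centrality on
costs would invert "quality"). Eigenvector centrality uses shifted power
iteration (trees are bipartite, so the unshifted iteration oscillates
between ±λ pairs); when near-degenerate leading eigenvalues stall the
iteration below tolerance 1e-10 it finishes with an exact dense symmetric
eigendecomposition rather than erroring mid-pipeline.

Per band and time point, each measure is averaged over epochs, divided by
its maximum over ROIs (the most central region scores exactly 1), and the
three normalized measures are averaged into the composite *global
centrality*. A measure that is identically zero (betweenness on a 2-node
tree) is dropped from the composite with a warning.

## Resection-relative classification

A region with ≥ 10% of its vertices resected is *overlap-excluded* (its
post-operative parcellation and signal are unreliable); among untouched
regions, those in the resection hemisphere within 10 mm (minimum
vertex-to-vertex Euclidean distance) are *adjacent*, all others *far*.
The boundary case of exactly 10% is excluded, honouring the strict "< 10%
untouched" reading. Resections spanning both hemispheres are rejected: the
pipeline models unilateral focal surgery only.

## Statistics

Paired pre/post comparisons use the Wilcoxon signed-rank test on per-ROI
(pre, post) global-centrality pairs pooled across the cases of one surgery
type, restricted to one region class and band. Zero differences are
dropped; ≤ 25 non-zero pairs use an exact null computed by dynamic
programming over sign patterns (midrank ties doubled to stay integral),
more pairs use the normal approximation with continuity and tie
corrections. Group comparisons use the rank-sum test (exact for combined
n ≤ 20 without ties), covariate checks use Spearman correlation (full
permutation null for n ≤ 8, t-approximation above). α = 0.05, two-sided,
uncorrected by default; Holm adjustment is available behind a flag.

**Calibration caveat.** Pooling ROI-level pairs across patients treats
within-patient regions as independent units, but they are not: all regions
in one table share the epoch sample, the tree, and above all the same noisy
max-normalization divisor, which couples their pre/post differences
positively. Under a structureless null (no hub, identically distributed pre
and post connectivity) the pooled signed-rank test therefore rejects at
≈ 0.11–0.16 rather than the nominal 0.05, independent of epoch count (the
shared-divisor noise and the per-ROI noise scale together). Per-patient
averaging would restore calibration but collapses a 6-case cohort to 6
pairs and with it essentially all power. The pooled design is kept because
it is the region-level design the analysis is built around, and the
miscalibration is reported, not hidden: pooled p-values should be read as
descriptive strength-of-evidence, not exact error rates. The null
calibration experiment in `scripts/acceptance.py` computes this rejection
rate from scratch so the number stays visible.

## Virtual-surgery cohorts

A synthetic "patient" is a geometry + leadfield + planted-hub network
(base coupling 0.1, hub 0.6 before PSD repair; theta/alpha/beta bands;
60 2-s epochs per time point at 256 Hz; SNR 10 dB; 8 vertices per ROI and
64 sensors keep a case under a minute on one core). Pre-surgical sources
include the hub; the *successful* scenario resects the hub ROI and
simulates post-surgical sources without hub coupling, the *failed* scenario
resects a same-hemisphere non-hub ROI and keeps the hub; resected tissue is
silenced. Each time point runs the full chain (notch, band-pass, epoching,
beamforming, AEC, MST centralities, classification). With 6 cases per
scenario the far-region pre/post comparison shows the expected signature:
significant centrality increase in all three bands after hub removal, and
no increase (beta: a decrease) when the hub is retained.

The default sampling rate (256 Hz), epoch length (2 s) and epoch count
(60, i.e. 4 min minus exclusions) match routine clinical interictal
recordings; `NetworkSpec` defaults to the three mid-frequency bands because
256 Hz cannot support the gamma band edge at the generator's required 4x
oversampling margin (the connectivity module's default band set remains the
full five).

## Known limitations

* The synthetic leadfield is a smooth Gaussian-bump phantom, not a BEM head
  model; inverse-crime recovery numbers (same gain for forward and inverse)
  are upper bounds on real-data performance.
* Narrow-band (delta/theta) AEC is structurally attenuated and noisy at 2 s
  epochs; see the connectivity section.
* The pooled signed-rank battery is anticonservative under within-patient
  dependence; see the statistics section.
* Envelope correlation is estimated on raw (not log) envelopes; heavy
  envelope tails are controlled in the generator, not the estimator.
* Repeated-surgery (three-time-point) bookkeeping is implemented in the
  case containers and statistics, but the bundled scenarios exercise single
  surgeries only.
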