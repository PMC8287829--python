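# Methods

`fibroegm` builds a fully synthetic replica of a hybrid electrogram study:
tissue-scale simulations of fibrotic atrial patches produce catheter
electrograms, a generalized autoregressive noise model emulates the clinical
noise floor, and decision trees trained on seven signal features
characterize the substrate (fibrotic vs. non-fibrotic, collagen density
class, transmural depth class).  This note documents the model, its
assumptions, the tunable parameters, and the limits of what the synthetic
experiments can show.

## Tissue and fibrosis model

The tissue is a regular voxel grid (default study patch 15 x 15 x 2 mm at
0.25 mm; a 30 x 30 x 2 mm patch at 0.2 mm is available through
`StudyConfig`).  Fibers run along +x; z = 0 is the endocardium, where the
catheter sits.  Interstitial fibrosis is textured by laying straight
collagen fibers (lengths ~ N(0.6, 0.2) mm, uniformly random positions)
along the fiber axis inside a circular region (default radius 6.5 mm,
centered) down to the transmural depth, until the collagen volume fraction
is within +-0.02 of the requested density.  Collagen elements get an
extracellular conductivity of 1e-6 S/m (and no intracellular pathway), so
they act as diffusion barriers; surviving myocytes inside the fibrotic
volume have longitudinal conductivity scaled by 0.47 and transverse by 2.5
(gap-junction remodeling under persistent AF).

Baseline conductivities (S/m): sigma_i = 0.17 / 0.08 and sigma_e = 0.62 /
0.30 (longitudinal / transverse).  These give a mild bulk anisotropy with a
conduction-velocity ratio of ~1.45:1.  We deliberately avoid the stronger
ventricular-style anisotropy (CV ratio >2.5): with strong anisotropy,
transverse-paced control electrograms show multi-fold longer activity and
~20x smaller bipolar amplitude than longitudinal ones, which would make
the non-fibrotic class far more heterogeneous than healthy atrial
electrogram statistics support.  Mild atrial bulk anisotropy is a standard
modeling choice and keeps the control class physically coherent.

## Membrane kinetics

A two-variable Mitchell-Schaeffer-type model (normalized voltage u, recovery
gate h) stands in for biophysically detailed atrial ionic models.  Two
variants are shipped: control (tau_in 0.3, tau_out 6, tau_open 120,
tau_close 100 ms; APD ~200 ms) and AF-remodeled (tau_out 5.2, tau_close 72;
APD ~140 ms), mapped to millivolts by Vm = -80 + 100 u.  The study pipeline
uses the AF-remodeled variant throughout, matching a persistent-AF cohort.
The classifier consumes wavefront-level morphology and complexity, which
the reduced model reproduces; single-cell behavior beyond APD and
restitution-free pacing at 600 ms BCL is out of scope.  Cells are pre-paced
to their limit cycle (tolerance 1e-4 between beats) before tissue runs.

## Propagation and electrograms

Excitation propagates by a monodomain reduction of the bidomain equations:
the effective conductivity per direction is the harmonic mean of the
intracellular and extracellular tensors (equal-anisotropy assumption).  The
solver is finite-volume explicit Euler with no-flux boundaries (numba
kernels); face conductances are harmonic means of the adjacent elements, so
collagen faces carry ~zero flux.  Default dt = 0.05 ms (0.1 ms is stable
for the study conditions and used where runtime matters); the explicit
stability bound is checked before every run and |Vm| is monitored during
integration.  A 1-D strand calibration adjusts a global conductivity scale
by the CV ~ sqrt(scale) law until the plane-wave velocity matches the
target (30 or 40 cm/s) within 2 %.

Extracellular potentials use the infinite-homogeneous-medium Green's
function applied to the intracellular source density:

    phi_e(r) = k / (4 pi sigma_b) * sum_j [-div(sigma_i grad Vm)]_j V_j <1/|r - r_j|>

with distances averaged over seven points on the 0.5 mm electrode
footprint and a near-contact guard of half an element.  This preserves the
source physics of the electrogram while dropping the bath-loading and
metallic-electrode boundary effects of a full bidomain solve; absolute
amplitudes are therefore calibrated once through the constant k so that the
mean control contact bipolar peak-to-peak amplitude is ~2.25 mV, and k is
never changed across conditions (relative effects carry the information).

The HD-grid catheter (4 x 4 electrodes, 3 mm spacing, 12 spline bipoles) is
rotated 30 degrees in-plane by default: catheter orientation relative to the
paced wavefront is arbitrary in practice, and the unrotated grid puts every
bipole axis exactly parallel to one pacing direction, a measure-zero
degeneracy in which the bipolar signal cancels identically.  The 20-pole
circular (lasso-style) catheter with alternating 2/6 mm arc spacing is
implemented at its true size (80 mm circumference) and therefore only fits
the full-size patch.

## Noise model

Baseline (activity-blanked) stretches of unipolar electrograms are fitted
as AR(p) processes: per-segment order by BIC, global order by the AIC
summed over segments, per-segment coefficients re-fitted at the global
order and averaged; a non-stationary average is stabilized by shrinking
characteristic roots to radius 0.99 (flagged).  All candidate orders are
scored on a common estimation sample (hold_back = max order), otherwise
information criteria are not comparable across orders.  The repository
ships a stable AR(4) as the synthetic stand-in for clinical noise; the
pipeline adds it to control electrograms, re-detects and blanks activity,
and re-derives the global model from the surviving 13 baseline segments,
exercising the full clinical workflow.

Noise is injected into the raw unipolar traces at a fixed absolute level:
`snr_db` (default 20 dB) is defined against the mean active-window power of
the run's control unipolar electrograms, not per trace.  A clinical noise
floor does not scale with the local signal; per-trace SNR scaling was tried
and rejected because it drowns low-amplitude (transverse-wavefront) control
bipoles in proportionally huge noise while leaving every trace's SNR
constant — destroying exactly the amplitude information the voltage-map
comparison is about.

## Signal processing and activity detection

Unipolar traces: 2nd-order Butterworth band-pass 0.05-900 Hz, zero phase.
The 0.05 Hz pole has a ~3 s time constant (longer than the 2.5 s trace), so
the band is applied as demean -> high-pass with Gustafsson initial
conditions -> zero-phase SOS low-pass; naive reflect-padded filtfilt
produces large transients (measured: mid-band tone gain 1.52 instead of
1.0).  Bipolar traces: electrode-pair difference, 2nd-order Butterworth
30-300 Hz zero phase.  Zero-phase filtering doubles the effective order but
keeps activity timing unbiased.

Activity detection works in Hilbert space: the analytic signal is centered
on its time mean (estimated away from 50 ms edge zones), the sample-wise
radius is thresholded at mean + 1 SD, gaps < 10 ms are merged, and segments
< 5 ms discarded.  Detection is invariant to amplitude scaling by
construction.

## Features

Per activity segment: duration (ms), peak-to-peak amplitude (mV), sample
entropy (m = 2, r = 0.2 SD, Richman-Moorman counting: both template lengths
over the first N-m windows, so a constant signal scores exactly 0), Shannon
entropy (64 equal-width amplitude bins over the segment's range, bits),
normalized spectral entropy (Welch, 256-sample Hann segments, 50 % overlap,
natural log normalized by ln K), and LZ76 complexity of the
median-binarized signal (innovation counting — a constant sequence has one
phrase — normalized by c log2(n)/n).  Segments shorter than 64 samples are
evaluated on a 100 ms window centered on the segment.  Per-trace features
are arithmetic means across segments; the Higuchi fractal dimension
(k_max = 16) is computed once on the whole 2.5 s trace.  Time-reversal
invariance is exact for the histogram entropy and holds to within boundary
effects for the windowed estimators.

The study's printed absolute values for Shannon entropy and fractal
dimension under noise cannot be reconciled with standard definitions
(their binning/method is not stated); no numeric parity is attempted for
those two features.

## Dataset and classifiers

The default study dataset: control patches at 30 and 40 cm/s paced from
three sites (left edge, bottom edge, top-right corner); fibrotic patches at
densities 10/20/40/60 % crossed with transmural depths 0.5/1/2 mm, three
texture seeds each (pacing site and CV rotate across seeds); thirty
control-substitute runs (control tissue with CV jittered in 28-42 cm/s,
SNR 15-25 dB, electrode height 0-0.5 mm) standing in for clinically
recorded non-fibrotic signals, bringing the dataset to roughly half
non-fibrotic as in a hybrid clinical/simulated corpus; substitute rows keep
only bipoles with p2p > 0.5 mV, emulating the expert high-voltage
annotation of clinical non-fibrotic signals; 20 dB AR noise on every
trace.  Each usable bipole contributes one row: seven features plus
labels and provenance.

Each hold-out realization draws a stratified 70/15/15 split
(largest-remainder apportionment so the global sizes are exact; at least
one sample per class in validation and test), runs greedy forward feature
selection (candidates with |Pearson r| > 0.6 against any selected feature
are dropped each round; ties break by the canonical feature order; stop
when validation accuracy no longer improves), trains a Gini decision tree
(no depth cap, min leaf 3, fixed random state), and scores the test set.
Reported metrics are means +- standard errors over realizations; the
binary task uses fibrotic as the positive class, multiclass sensitivity
and specificity are macro-averaged one-vs-rest.

## Height sweeps and maps

Propagation does not depend on electrode height, so sweeps re-derive
electrograms from one stored transmembrane field per condition with the
lead field recomputed at each height, then score a contact-trained tree.
Synthetic substrate maps are planar point grids with circular fibrotic
patches of known truth; each point draws a bipolar trace from a simulated
library for its local condition.  Dice indices are reported truth-vs-low-
voltage (0.5 mV cutoff, ties labeled high) and truth-vs-prediction; the
original clinical voltage-vs-prediction comparison requires recordings
that do not exist here and is not attempted.

## What the synthetic data do and do not show

The generator reproduces: wavefront-direction and CV variability,
texture-dependent slowing and fractionation, amplitude reduction over
fibrosis, transmural-depth effects on near-field amplitude, a clinical-like
noise floor, and electrode-height degradation.  It does not reproduce:
atrial anatomy and wall-thickness heterogeneity, bath loading and metallic
electrode effects on morphology (absolute slopes and amplitudes are
calibrated, not emergent), far-field ventricular activity, catheter contact
variability beyond a height offset, or biophysically detailed ionic
heterogeneity.  Passing tests therefore demonstrate internal consistency of
the method chain and recovery of designed effects at desk scale — not
clinical validity.

## Numerical choices and degenerate inputs

Explicit stability is pre-checked (dt * max nodal diffusion rate <= 1) and
|u| monitored during integration.  Activation times use the
maximum-upstroke-slope sample refined by quadratic interpolation; probes
must activate exactly once.  Constant traces yield zero Shannon entropy,
sample entropy 0, empty activity lists, and NaN sentinels for spectral
entropy and fractal dimension (NaN features are tolerated by the trees).
Dice of two empty sets is defined as 1.  A peak-to-peak value exactly at
the 0.5 mV cutoff is labeled high voltage (strict < rule).

## Problem sizes used by the shipped tests and acceptance run

Unit tests run a 10 x 10 x 1 mm patch at 0.25 mm with 1.3 s traces; the
acceptance pipeline runs the default 15 x 15 x 2 mm study patch with 2.5 s
traces and 100 hold-out realizations per task.  These sizes are the
package's desk-scale defaults; the full-size patch and denser seed counts
are available through `StudyConfig`.
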