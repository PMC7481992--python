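# Methods

This note documents the models, conventions and numerical choices behind
`hemiconn`, in the order the pipeline runs.

## Node schemes

Every stage operates on a `NodeScheme`: an ordered node list with hemisphere
(L/R), area (frontal, central, temporal, parietal, occipital, or none) and a
homologue pairing that is a hemisphere-swapping involution with matched
areas.  The default EEG scheme has 15 channels per hemisphere, 3 per area,
with abstract labels (`FL1`…`OR3`) and conventional 10-20-style names
available as display aliases only — published channel listings for this kind
of montage mix odd/even labels inconsistently, and the analysis depends
exclusively on hemisphere/area structure, so homologues are paired
positionally within each area.  The default MRI scheme holds 42 parcels per
hemisphere: the 33 Desikan–Killiany cortical parcels that map cleanly onto
the five lobar areas, plus insula and eight subcortical structures which
carry no area label and enter only whole-hemisphere metrics.  No electrode
coordinates or atlas images are handled; parcel time series arrive
pre-extracted.

## EEG conditioning and spectral decomposition

Raw EEG is resampled to 500 Hz (polyphase), linearly detrended per channel,
and band-limited to 0.5–45 Hz with a 4th-order zero-phase Butterworth
filter.  Ocular artifacts are removed by per-channel ordinary least squares
on the EOG channels (with intercept); constant EOG channels are dropped with
a warning.  Zero-padding to the next power of two happens inside the PSD
estimator (`nfft`), not on the time series, so EEG and EOG stay
sample-aligned for the regression.

The PSD is a DPSS multitaper estimate with time–bandwidth product NW = 4 and
7 tapers, eigenvalue-weighted.  At five minutes of signal this gives a
half-bandwidth of ≈ 0.013 Hz — the ±1 Hz-scale spectral smoothing such
pipelines describe is here absorbed into the multitaper bandwidth rather
than applied as a separate smoothing pass, to avoid double smoothing.  Both
choices are configurable (`multitaper_nw`, `multitaper_tapers`).

Band definitions default to contiguous half-open intervals delta [1, 4),
theta [4, 8), alpha [8, 13), beta [13, 30) Hz.  Published band tables often
overlap or leave gaps (alpha 8–14 next to beta 13–30; delta 1–3 next to
theta 4–8); overlapping bands double-count power, so the contiguous
resolution is used and is configurable.  No gamma band: none of the
downstream statistics use it.  Relative power divides the band integral by
the 0.5–45 Hz total, giving values in [0, 1] that sum to ≤ 1 across the four
bands; relative (not absolute) power feeds the asymmetry index because it is
the only choice that keeps the index inside its printed ±100 range.
Absolute power is still emitted in the band-power tables.

## Connectomes, degree, and the asymmetry index

Connectomes are plain Pearson correlation matrices (diagonal 1, symmetric);
no Fisher transform, partial correlation or thresholding in the main path.
The contralateral degree of a node is the signed sum of its correlations
with all opposite-hemisphere nodes; an absolute-edge variant exists behind
`abs_edges` for sensitivity analysis, since summing |r| versus r per node is
a genuinely open convention.  Area-level degree restricts the *source* nodes
to one area while targets remain all contralateral nodes (the definition
names no target restriction).

The asymmetry index AI(X) = 100·(|X(R)|−|X(L)|)/N is computed on per-node
*mean* contralateral correlation (degree / number of contralateral nodes).
Two consequences of the formula are worth stating plainly:

* With raw degree sums, AI's range is ±100·N_contra, not the ±100 usually
  printed next to the formula; normalizing each node's degree to [−1, 1]
  restores the bound at every level and is the reading implemented here.
* At whole-hemisphere level the signed sums over the two hemispheres are
  *identical* — every interhemispheric edge contributes once to each — so
  whole-hemisphere FC AI is exactly 0 by construction.  The informative
  connectome asymmetry is the area-level AI.  (Both facts are covered by
  tests.)

Power AI uses the area-mean relative power directly with N = 1 (the quantity
is already an area average in [0, 1]); the whole-brain AI of a band is the
unweighted mean of the five area AIs, which equals the channel-level mean
because all areas hold equally many channels.

## Synthetic cohorts

The generator is a stand-in for a real cohort and defines the conditions the
statistical guarantees are demonstrated under.  Per subject `i`, a latent
asymmetry `a_i ~ N(0, 1)` drives the EEG, and `r·a_i + √(1−r²)·b_i` (with
independent `b_i`) drives the fMRI, so the induced asymmetries correlate at
the configured `cross_modal_r` in the population.  Subject `i` is generated
from the dedicated RNG substream `(seed, i)`, making every subject
reproducible independently of cohort size.

**EEG** channels are sums of band-limited Gaussian noise (disjoint rFFT
bands shaped by per-band amplitudes), a within-area shared component (mixing
0.5, giving realistic channel correlations and homotopic coupling), `1/f`
background noise (slope 1, scale 0.4), and a <4 Hz ocular source mixed into
frontal channels at fixed gains (0.4 / 0.25) to exercise the EOG regression.
Default band amplitudes (delta 1.0, theta 0.8, alpha 1.2, beta 0.5) give an
alpha-dominant resting spectrum.  Band amplitude on right/left channels
scales as `1 ± gain·a/2`; the default gain injects rightward alpha-power
asymmetry (0.3) in every area.

**fMRI** parcels load on a global factor, an area factor, a homologue-pair
factor and i.i.d. noise (loadings 0.6 / 0.5 / 0.3, noise SD 0.6).  The
global loading of *area-labeled* parcels is modulated by `1 ± gain·a/2`
per hemisphere (default gain 0.8) while the nine unlabeled parcels per
hemisphere stay symmetric.  The symmetry break matters: a hemisphere-signed
multiplicative modulation of *every* node cancels to first order in
cross-hemisphere correlations, because each interhemispheric edge joins one
up- and one down-weighted node; leaving the subcortical block unmodulated
(and the nonlinearity of variance normalization) is what shifts right versus
left contralateral degree.  This was verified analytically and by
simulation, and the default gains were fixed from that signal-to-noise
analysis.

What the generator does **not** emulate: volume conduction and electrode
reference effects, hemodynamic convolution, physiological noise spectra,
motion artifacts, or spatially graded connectivity.  Passing tests therefore
demonstrate the correctness and calibration of the *pipeline*, not
properties of any real cohort.

## Randomized-network null

Correlation connectomes are fully dense, where classical Maslov–Sneppen
double-edge swaps cannot change anything (every proposed edge already
exists).  The default null therefore permutes edge weights over the fixed
dense topology via repeated random transpositions of edge slots
(`swaps_per_edge` × edge count, default 100 for standalone use, 10 inside
ensembles) — exactly preserving node degrees, the off-diagonal weight
multiset and the total weight, which is the state weighted degree-preserving
randomization converges to on a dense graph.  A `sparsify` mode (proportional
threshold, default top 20 % |r|, then weight-carrying double-edge swaps
rejecting self-loops and duplicates) covers the classical binary-topology
variant.  Null ensembles rewire every subject's two connectomes with
independent substreams, recompute AI profiles and cross-modal correlations,
and report two-sided empirical p-values with the (k+1)/(n+1) correction
(never exactly 0 at finite ensembles).  Band power has no network, so the
power-EEG side stays fixed in the null correlations.

## Cohort statistics

Per (area, band) cell the FC-fMRI area AI is paired with the power-EEG AI of
the matching area (band varies on the EEG side only; FC-EEG pairing is
optional).  Shapiro–Wilk tests normality per variable; Pearson r carries the
two-sided t-based p; one-component PLS R² is tested by response permutation
(default 1000, `(k+1)/(n+1)`).  "PLS with principal-component regression" is
ambiguous between two methods; with a univariate predictor one-component
PLS reduces to simple least squares, so R² = r² exactly — implemented
closed-form and cross-checked against scikit-learn's NIPALS implementation
in the tests.  Raw p-values are reported as published practice does, with
Benjamini–Hochberg q-values in an extra column per group for transparency.
Group comparisons per cell use one-way ANOVA with Tukey HSD adjusted
pairwise p-values; zero within-group variance is reported as degenerate
rather than an error.

The composite cross-modal estimator (`recover_cross_modal_r`) correlates
each subject's FC-fMRI AI averaged over the five areas with the whole-brain
power AI of the coupled band; averaging pools the areas' estimation noise
and is the natural estimator of the latent coupling.

## Problem sizes and determinism

Full-length defaults are 300 s EEG at 500 Hz and 248 fMRI volumes at
TR 1.45 s.  The statistical demonstrations use deliberately scaled
recordings chosen once from the signal-to-noise analysis: 20 s EEG / 120
volumes for 200-subject coupling-recovery cohorts (each modality still
recovers its own latent at r > 0.99, so the cross-modal estimate is
attenuation-free), and 5 s EEG / 60 volumes for the 200-cohort type-I-error
calibration, where only p-value uniformity matters.  All randomness flows
from a single seed through named `(seed, purpose, index)` substreams; result
CSVs contain no timestamps, so identical configurations reproduce
byte-identical outputs.

## Known limitations

* Whole-hemisphere FC AI is structurally zero (see above); it is reported
  for completeness but carries no information.
* The per-area N convention for power AI (N = 1 on area means) is one of
  several defensible readings; a per-channel-sum variant would rescale but
  not reorder subjects, leaving cross-subject correlations unchanged.
* The dense-mode null destroys all spatial structure of the weights, not
  only hemispheric structure; it is a chance baseline, not a spatially
  constrained null.
* Empirical p-values and permutation p-values are resolution-limited by the
  ensemble/permutation counts.
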