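# Methods

`oscinet` implements a resting-state EEG source-space network analysis of
the kind used to characterize large-scale cortical network disruption after
stroke (e.g. in hemispatial neglect): band-limited amplitude-envelope
connectivity with leakage correction, absolute/relative spectral power,
network-based permutation statistics for group contrasts and brain-behavior
regressions, and a conjunction test isolating behavior-specific network
components.  Because clinical EEG cohorts of this kind are rarely public,
the package ships a synthetic cohort generator whose planted structure the
analysis must recover; the test suite and `scripts/acceptance.py` exercise
the full chain against that ground truth.

## Signal model and preprocessing

Input is a channels × samples matrix at sampling rate `fs` (250 Hz default),
either sensor-level (e.g. a 19-channel 10-20 montage) or already ROI-level.
The cleaning chain is: zero-phase broadband band-pass (0.5-40 Hz default) →
segmentation into consecutive non-overlapping 1-s epochs → single-pass
amplitude-based rejection → Hann tapering of surviving epochs and
concatenation → per-band narrow-band filtering into delta (1-4), theta
(4-8), alpha (8-12), beta (13-30) and gamma (30-45 Hz).

Numerical choices:

* **Filters** are Butterworth band-passes of order 8, applied
  forward-backward (`sosfiltfilt`, 16 poles effective, zero phase).  Zero
  phase is required because envelope timing feeds the connectivity
  estimates.  The order is chosen so the 0.5-40 Hz filter suppresses a
  50 Hz tone below 5% RMS; a 4th-order design leaves ~9% steady-state at
  50 Hz.  Edge effects are handled with reflection padding of at least 1 s,
  extended to ~3 cycles of the high-pass corner (6 s at 0.5 Hz) so the
  slow pole's ringing decays inside the discarded padding.  The extension
  type is matched to the corner: sub-hertz high-pass corners ring on the
  mean step an odd (point-symmetric) extension introduces, so they get
  mirror (even) padding, while narrow bands ring on the slope
  discontinuity of a mirror extension and get the standard odd extension.
  Both effects were measured, not assumed; the mismatch injects localized
  in-band transients large enough to corrupt envelope statistics.
* **Epoch rejection metric**: per-epoch log variance per channel, averaged
  over channels (a FASTER-style variance criterion, robust to per-channel
  scale).  Epochs deviating from the across-epoch mean by more than
  `z_thresh` (default 1.5) standard deviations are dropped.  Mean and SD
  are computed once over all epochs — one threshold application, never
  iterated, so the rejected set does not depend on processing order.
  Degenerate case: if the metric spread is numerically zero (identical
  epochs), all epochs are kept with a warning.
* **Hann concatenation** multiplies each kept 1-s epoch by a symmetric Hann
  window before concatenation, forcing zeros at every epoch boundary so the
  stitched record has no discontinuities.  The taper also colors the
  envelope at the 1 Hz epoch rate; this is shared by all subjects and does
  not bias group contrasts.
* Gamma is 30-45 Hz by default.  With a 40 Hz acquisition low-pass the top
  third of that band is empty; users of such recordings can pass a custom
  30-40 Hz `BandSpec` anywhere a band is accepted.  The five bands leave a
  12-13 Hz gap between alpha and beta and therefore never tile the
  broadband range.

## Source estimation

`compute_inverse_kernel` builds a standardized minimum-norm (sLORETA-style)
inverse for a supplied fixed-orientation lead field `L` (sensors × sources):
minimum-norm kernel `K = Lᵀ(LLᵀ + αI)⁻¹`, standardized per source by
`sqrt(diag(KL))`.  This standardization makes estimates invariant to global
lead-field rescaling and gives *zero localization error* for noiseless
single-dipole data as α → 0 — the property the acceptance checks verify
exhaustively on a 19-sensor / 60-source toy model.  Defaults: Tikhonov
`α = 0.05·trace(LLᵀ)/n_sensors` (an SNR-agnostic heuristic; `α = 0` uses a
pseudoinverse and requires full row rank).  Common-average referencing of
data and lead-field rows is available (`car=True`) and is applied by the
pipeline, mirroring average-referenced EEG practice; the resulting Gram
rank deficiency is handled by the pseudoinverse path.  Source traces are
arithmetically averaged within parcellation regions (the packaged
68-region Desikan-Killiany list by default).  Averaging signed traces can
cancel opposite-polarity sources within a region — a real hazard of
sign-ambiguous estimates, surfaced in tests rather than hidden.

## Envelope connectivity

Volume conduction and inverse blur mix signals instantaneously, so any
zero-lag dependence between reconstructed signals is suspect.  For each
ordered pair the package removes the zero-lag shared component on analytic
signals: with centered analytic signals X, Y,

    Y⊥ = Y − (⟨Y,X⟩/⟨X,X⟩) X,      ⟨a,b⟩ = Σ a·conj(b)

This *static* projection guarantees corr(Re Y⊥, x) = 0 at machine
precision — the defining contract — whereas the per-sample
(instantaneous-phase) variant found in the literature only removes leakage
approximately at finite sample size.  Envelopes are Hilbert moduli; the
pairwise amplitude-envelope correlation (AEC) is the bidirectional average

    r = ½[ corr(env x, env y⊥x) + corr(env y, env x⊥y) ]

A channel paired with itself orthogonalizes to zero, yielding r = 0 (with
a warning about the constant envelope): naive envelope self-correlation is
1, corrected self-connectivity is 0, which is the leakage-removal property
in its purest form.  Optional envelope smoothing and decimation to a
configurable envelope rate is available but off by default.  The per-band
68×68 matrices are symmetric with zero diagonal.  Group effects are
reported per edge as the signed difference in mean correlation d
(patients − controls) plus the pooled-variance two-sample t; |d| serves as
the standardized effect size for correlations.

## Spectral power

Welch PSD with Hann-tapered 4-s segments and 50% overlap, density scaling
(the PSD integrates to the signal variance).  Absolute band power is the
mean PSD over half-open in-band bins [f_lo, f_hi); relative band power is
the in-band PSD integral as a fraction of the broadband [1, 45) Hz
integral, so a flat spectrum has relative alpha ≈ 4/44 and the five bands
sum to at most 1.  Group comparisons are per-ROI two-tailed t tests on
log10 absolute power by default (variance stabilization; configurable to
raw or relative values) with Benjamini-Hochberg FDR across ROIs.

## Network-based statistic

Edge-wise inference over N(N−1)/2 edges uses the NBS: edge statistics are
thresholded at a primary threshold, connected components of surviving edges
are identified, and each observed component's edge count is referred to the
permutation null of the *maximal* component size.  Only components, never
individual edges, are declared significant; per-edge statistics are
reported descriptively.

* Designs: two-group (pooled-variance t; group labels permuted) and simple
  regression of edge strength on a covariate (standardized beta = Pearson
  r, t = r·sqrt((n−2)/(1−r²)); covariate permuted).  Permutation is at the
  subject level, which preserves the within-subject edge covariance the
  null must respect.  |t| at perfect correlation is capped at 1e6 with a
  warning.
* p = (1 + #{null ≥ observed}) / (nperm + 1); never zero; nperm defaults
  to 5000 (minimum 100 enforced).
* The primary threshold defaults to the two-sided t quantile at
  uncorrected p = 0.01 for the design's degrees of freedom.  No primary
  threshold is canonical, and sensitivity to it is real: with 435 edges at
  p = 0.01 the null itself produces ~4.3 suprathreshold edges per
  permutation, so maximal null components regularly reach 3 edges and a
  small genuine 3-edge component cannot be family-wise significant at any
  effect size.  Analyses that must resolve few-edge components (such as
  the behavioral-regression recovery study below) therefore use a stricter
  primary threshold (p = 0.001); the threshold is config-exposed and
  recorded in every output.
* Regressions against behavior use the patient subsample only.
* The conjunction over several NBS results returns the edges belonging to
  a significant (p ≤ α) component in *every* result — valid under the
  global null (logical AND) precisely because each contributing test is
  individually significant.  An empty set is a legitimate outcome.

## Synthetic cohort generator

The generator's job is to produce data whose ground truth the analysis
must recover, with the statistical features that matter for envelope
connectivity:

* **Band signals with planted coupling.**  Each node's narrow-band signal
  is `envelope × carrier`: the carrier is independent unit-variance
  band-limited Gaussian noise; the envelope is `exp(σg/2)` (log-normal,
  σ = 1) of slow correlated Gaussian modulators, band-limited below
  min(f_lo/2, 2) Hz so envelopes are slow relative to the band.  All
  synthesis filtering is done by exact frequency-domain spectral shaping
  (Butterworth magnitude responses on the rfft grid): time-domain IIR
  filtering at sub-hertz cutoffs rings at the record edges, and the
  exponential envelope transform turns any such excursion into an
  explosion, so spectral shaping — exact for stationary Gaussian noise —
  is the only safe construction.  Planting a
  modulator correlation ρ yields a realized AEC that increases
  monotonically with ρ but is attenuated (empirically ≈ 0.35 at ρ = 0.8,
  ≈ 0.12 at ρ = 0.3 for 180-s alpha signals); the mapping is documented by
  measurement, never assumed to be the identity.  User coupling matrices
  are repaired to the PSD cone by eigenvalue clipping with diagonal
  re-normalization (logged); matrices losing more than half their trace to
  clipping are rejected.  Effective per-edge correlations are clamped to
  [0, 0.95] (logged when clamping occurs).
* **Cohorts.**  Defaults mirror a realistic clinical study: 15 patients vs
  27 controls, 68 ROIs, 3-min records at 250 Hz.  Per subject and band the
  effective edge correlation is base + group_delta·[patient] +
  behavior_slope·severity; severities are uniform(0,1) for patients, 0 for
  controls.  Band signals are summed into one broadband trace per node
  plus 1/f-amplitude background noise at 10 dB SNR (configurable).
* **Behavior.**  The cancellation sheet has 35 targets (15 left / 15 right
  / 5 central).  Omissions are binomial with miss probabilities
  p_left = 0.05 + 0.9·severity and p_right = 0.05 + 0.25·severity
  (central column follows p_right), so severe subjects miss left-side
  targets preferentially — spanning near-zero to near-total left omissions
  across the severity range.  Line-bisection deviation is
  40·severity + N(0, 5) percent (rightward positive).  Clinical flags:
  left-minus-right omissions ≥ 4 of 15, and bisection deviation > 11%.
* **Toy forward model.**  Sensors on a ring; each ROI is a contiguous
  patch of sources jittered (SD 0.05) around a center on a 0.85-radius
  ring, with spatial Gaussian gain profiles (width 0.2) and a shared
  orientation sign per patch.  Contiguity matters: spatially incoherent
  "regions" are unresolvable by any inverse.  Full row rank is verified
  (rank-deficient draws are redrawn with an incremented seed, logged).
  Sensor projection adds white noise rescaled so realized noise power
  matches the requested SNR exactly.
* **Connectivity-level cohorts** (`make_connectivity_cohort`) draw
  per-subject adjacency matrices directly — base AEC 0.2 plus Gaussian
  between-subject edge noise (SD 0.15, a realistic spread of resting
  envelope correlations) plus planted group or covariate effects.  This is
  the right granularity for permutation-test calibration studies, which
  only consume the matrices; time-series generation adds hours of compute
  and no information to those questions.

What the generator does *not* emulate: lesion anatomy, ocular or muscle
artifacts, hemianopia, nonstationarity across the recording, 1/f slope
differences between groups, or volume-conduction structure beyond the toy
lead field.  Tests passing on synthetic cohorts therefore validate the
*statistical machinery* — leakage removal, error control, power,
recovery — not robustness to every pathology of clinical EEG.

## Validation studies and problem sizes

The repeated-cohort studies run by the test suite and the acceptance
script use: 200 replicate null cohorts (20 vs 20 subjects, 30 nodes,
nperm = 1000) for family-wise error calibration; 100 replicates for
detection power of a planted 5-edge component (group AEC difference 0.3)
and for the 3-edge behavioral regression recovery (slope 0.4, edge noise
SD 0.08, n = 30 patients, primary threshold p = 0.001 as motivated above).
Unit tests run reduced-seed versions of the same Monte-Carlo checks; the
full-size runs live in the acceptance suite.

## Reproducibility

Every stochastic operation takes an explicit integer seed
(`numpy.random.default_rng`); identical configuration and seed give
bit-identical cohorts, permutation nulls, and serialized results.  The
pipeline spawns per-stage seeds from one master seed via `SeedSequence`,
and writes its configuration hash into every artifact.

## File formats

Time-series TSV: optional `# fs=<Hz> kind=<sensor|source|roi>` comment
line, then one row per channel — label, tab, samples printed with `%.17g`
(lossless for IEEE doubles), `.` decimal, no quoting.  Connectivity and
power tables are TSVs with labeled header row and index column.  Cohort
manifests are JSON (subject id, group, severity, behavior scores, file,
fs, generator seed).  EDF recordings are read through MNE (channel order
preserved); export is TSV.

## Known limitations

* ICA-based artifact removal is out of scope; real sensor data should be
  pre-cleaned before entering the pipeline.
* ROI averaging of signed source traces can cancel within-region sources
  of opposite polarity; orientation handling beyond the dominant-sign
  convention of the toy model (e.g. free-orientation SVD collapse) is left
  to the caller's lead field.
* The envelope generator plants nonnegative modulator correlations only;
  anti-correlated envelope structure is not modeled.
* Regression designs are simple (one covariate); no nuisance covariates or
  multiple regression.
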