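# Methods

## Detection model

Both recording modalities are treated as a uniformly sampled signal
containing transient waveforms on a slowly drifting baseline plus
additive noise. The detector never assumes a waveform shape or rate —
hence *frequency-independent*:

- **Running median.** Centered sliding-window median; windows shrink at
  the recording edges (truncated, never padded). Defaults: 5 s for
  calcium at ~1 frame/s, 50 ms for 2 kHz current traces. The median is
  not the baseline itself; it only decides which local extrema count as
  baseline samples.
- **Reference line.** Local extrema of the raw signal strictly on the
  baseline side of the running median (minima below it for fluorescence,
  maxima above it for inward-current recordings) become knots of a
  piecewise-linear reference. Plateaus of equal samples contribute their
  first sample; both endpoints are clamped to `min(y, median)` (resp.
  `max`). A trace entirely on the wrong side of its median degenerates to
  a flat reference at the global extremum, with a warning.
- **Events.** Maximal runs of positive signed residual
  `polarity · (y − reference)` are candidate waveforms, extended to the
  bounding zero-level samples so the integral runs down to the
  reference. A run is kept when its retained peak deviation under
  Ramer–Douglas–Peucker simplification exceeds ε; because the RDP chord
  of an interior run joins two zero-level samples, that retained peak
  deviation equals the maximum residual, and the implementation uses the
  maximum-residual form directly — it is exactly scale-equivariant and
  well defined for runs truncated at the recording boundary (those are
  kept but flagged `boundary_truncated` and excluded from
  duration/rise-time summaries, whose temporal extent is censored).
- **Metrics** are measured on the raw residual (never the simplified
  polyline): amplitude = max |residual|, area by the trapezoid rule
  (charge transfer *Q*, reported in pA·ms, for currents), duration,
  rise time (peak minus event start), and peak offset (peak minus event
  midpoint; negative = early peak). RDP itself is retained as a public
  primitive (`rdp_simplify`, first-index tie-break) and is
  oracle-checked against a naive recursive implementation.

### Detection tolerance ε

ε defaults to a multiple of a robust noise scale,
`1.4826 · median(|r − median r|)` of the reference-subtracted trace.
The multiplier is modality-dependent by an extreme-value argument: a
300-frame calcium trace contains a few hundred noise samples whose
expected maximum is ≈3σ, so 2σ plus the downstream 10%-of-max amplitude
cutoff suffices; a 180 s, 2 kHz current trace contains ~3.6×10⁵ noise
samples with expected maximum ≈5σ, so the current-modality default is
6σ. Both multipliers are configuration (`epsilon_multiplier`,
`epsilon_multiplier_current`).

The MAD estimator assumes transients occupy a minority of samples; on
traces where event footprints cover most of the recording it inflates
and the detector loses small events. The synthetic study conditions
(below) keep occupancy within the estimator's breakdown point, as real
spontaneous-fluctuation rates do.

## Calcium aggregation

Per-neuron means of each event metric control for differing recording
lengths. The noise cutoff removes events below 10% of the neuron's
largest fluctuation (inclusive boundary). Silent classification uses the
**no-cutoff** mean amplitude — a silent cell's noise fluctuations would
otherwise self-normalize — against an absolute threshold, default 5 AU,
chosen between the reported group scales of silent (~1.7 AU) and active
(~25–54 AU) neurons; it is explicit configuration, not a derived
quantity. A cell with no detected events is silent. Normalized-amplitude
histograms divide each neuron's amplitudes by its own maximum before
pooling, so the top bin always contains every neuron's largest event;
relative frequencies sum to 100%.

Fold-change grouping of paired drug recordings uses
`(post − pre)/pre` of the per-neuron mean; exactly zero counts as
"decrease" (non-increase), and a zero or undefined pre-mean excludes the
cell with a warning.

## Synchrony

Correlations are computed on the FIBSI-processed residual traces (not
raw fluorescence, not binarized event trains), each min–max normalized
to [0, 1]; a constant residual maps to zeros and correlates as 0 with a
flag rather than erroring, keeping culture matrices complete. Per-cell
mean correlation is averaged on the Fisher-Z scale with |r| clipped at
1−10⁻⁷ before `arctanh`. Mean r is only ever computed within one
co-recorded culture; condition comparisons pool per-cell means across
cultures and use a Mann–Whitney test. The synchronous-wave criterion —
a 2 s bin in which ≥50% of co-recorded cells have an event peak,
consecutive qualifying bins merged — is a package convention (no
published definition exists) and is labeled as such in outputs.

## sEPSC chain

Inward currents are detected on a low-pass-filtered copy: zero-phase
(forward–backward) 4-pole **Bessel** at 200 Hz. The Bessel family is the
electrophysiology standard because its near-linear phase adds almost no
ringing; a zero-phase Butterworth was rejected because its acausal
pre-ringing lobe ahead of each sharp sEPSC onset is itself detectable as
a spurious event that then competes for the true event's raw peak.
Amplitudes are re-measured on the unfiltered trace as the extreme raw
residual within ±5 ms of the filtered peak, against the
filtered-trace reference (the raw samples carry the true peak heights;
the filtered trace gives the cleaner baseline). Matching is one-to-one
and greedy in time order: when two filtered events claim the same raw
extremum, the earlier wins and the later keeps its filtered amplitude
with `matched=False`. Interevent intervals are peak-to-peak; the first
event of a recording has no IEI and is excluded from clustering.

Clustering is PAM (BUILD seeding + best-improvement SWAP) under L1
distance on unstandardized [IEI ms, amplitude pA, *Q* pA·ms], per neuron
and per neuron only. PAM is a local search: every returned model is a
single-swap local optimum, verified against exhaustive search on small
problems and against the reference R implementation (`cluster::pam`,
default settings, manhattan) in the tests. k is selected over 2–6 by
average silhouette width (manhattan). Labels: the largest-amplitude
medoid is "large", demoted to "medium" when its amplitude is under twice
the smallest medoid amplitude; with five clusters the second-largest
becomes "medium"; remaining clusters are "small" ordered by medoid IEI
(short/mid/long).

## Statistics

Fisher's exact test (two-sided by the point-probability rule),
Mann–Whitney, Wilcoxon signed rank (all-zero differences → p = 1,
flagged), and paired t delegate to scipy. Welch's ANOVA, the
Brown–Forsythe ANOVA on means (Satterthwaite denominator df),
Games–Howell (Welch–Satterthwaite df, studentized-range adjustment) and
Dunn's rank test (tie-corrected z, Bonferroni over pairs — the
conventional choice where the correction is unnamed) are implemented
from their closed forms and cross-checked against pingouin where it
offers the same test. The two-way repeated-measures (mixed) ANOVA is
fit with pingouin; Sidak-adjusted planned contrasts (pre vs post within
each between-group level, `1 − (1−p)^m`) are computed in-package.
Zero-variance groups are flagged and continued with an ε guard. The
D'Agostino–Pearson normality check is advisory only and never switches
tests. Two-group degeneracies are exact: Welch ANOVA reduces to the
Welch t-test and Kruskal–Wallis to the (asymptotic, uncorrected)
Mann–Whitney test.

## Synthetic study conditions

The generators define the conditions every benchmark runs under; no
quantitative generative model is published, so all distributional
choices are stand-ins, surfaced as configuration:

- **Calcium network** (`CalciumNetworkParams`): 20 cells (benchmarks
  scale to 100), 300 s at 1 frame/s (imaging cadence ~0.8–1.1 s/frame),
  Poisson transients at 0.02 Hz (1.2/min — sparse enough that the MAD
  noise estimator stays valid), difference-of-exponentials kinetics
  (rise 1.5 s, decay 6 s), lognormal amplitudes mean 50 AU / sd 15 AU
  against 0.5 AU Gaussian noise (silent cells then fluctuate at the
  ~1–2 AU scale reported for the silent subpopulation), a one-cycle
  sinusoidal drift of amplitude 2× noise with random phase, 20% silent
  cells (drift + noise only), and network waves at 0.02 Hz joined
  per-cell per-wave with probability `coupling_p` (default 0.6).
  Participation is implemented as `uniform < coupling_p` on a dedicated
  stream, so lowering the coupling probability (the octanol effect,
  factor 0.25) strictly nests each cell's wave set — the
  ≥90%-of-cells decrease is structural, not statistical. One global seed
  drives named per-cell substreams; adding cells never perturbs
  existing ones.
- **sEPSC recording** (`EpscParams`): 180 s at 2 kHz, bi-exponential
  kernels with τ_rise 1 ms / τ_decay 7.5 ms, 2 pA noise, inward
  polarity, and an equal-weight three-component mixture
  (amp 15/15/80 pA, IEI 20/2000/200 ms, both with sd = 20% of mean;
  IEIs truncated normal rather than exponential so the planted
  components stay separated in the IEI dimension). The kinetics sit at a
  deliberate optimum: the charge/amplitude ratio (≈10 ms, which sets the
  *Q* feature scale and hence the small-vs-large cluster separation
  under unstandardized L1) grows with τ_decay, but an isolated 80 pA
  event must stay under half of the 50 ms median window or the traced
  baseline dips into the event and corrupts amplitudes. τ_decay beyond
  ~8 ms measurably distorts large events; below ~5 ms the three-cluster
  structure stops being the silhouette optimum even on ground-truth
  features.

**What the generator does not emulate:** indicator photobleaching and
dye saturation, motion artifacts, spatially structured (correlated)
noise, bursty non-Poisson firing, synaptic summation statistics beyond
component mixing, and access-resistance drift in voltage clamp. Passing
benchmarks therefore demonstrate the pipeline's correctness under its
stated assumptions, not robustness to every pathology of real
recordings.

## Benchmark conventions

Ground-truth scoring counts a planted event as recovered when a detected
event's span (±2 frames) covers its onset, and a detection as true when
it covers at least one planted event: Poisson-timed transients with ~6 s
decay frequently summate, and the detector — by design — reports a
summated waveform as a single event. The detection benchmark uses an
all-active field (SNR is defined by event amplitude over noise; silent
cells carry no events) with recall/precision averaged over 20 seeds;
silent-cell handling is scored separately by the end-to-end
silent-fraction recovery on 100-cell fields. Problem sizes throughout
(20-seed detection, 10-seed clustering and synchrony grids, 1000-rep
type-I calibration, exhaustive Fisher sweep to table total 30) were
chosen so the whole suite completes in minutes on one CPU while keeping
Monte-Carlo error well inside the asserted bands.

## Known limitations

- The reference line degrades when waveforms occupy most of the median
  window (dense summation, very slow kinetics); amplitudes are then
  underestimated. This is intrinsic to the traced-baseline idea, not a
  bug, and bounds the usable kinetics/rate regime documented above.
- The silent threshold (5 AU) is meaningful only on the generator's
  amplitude scale; real recordings need it re-set against their own
  units.
- PAM local optima: on adversarial configurations the SWAP optimum can
  differ from the global k-medoids optimum (observed on ~1 in 10 random
  12-point 1-D problems); this matches the behavior of the reference
  implementation.
- IEI features inherit detection errors: a missed or merged event sums
  two intervals. At benchmark detection rates (>99%) this affects well
  under 1% of events.
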