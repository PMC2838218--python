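# Methods

This note documents the models and procedures `measpike` implements, the
defaults it ships with, and the choices made where the design was genuinely
open. Amplitudes are microvolts, times seconds, indices 0-based except the
1-based percentile index.

## Signal model and preprocessing

A recording is a single-channel voltage trace sampled at `fs` (default
25 kHz). Channels of a multi-channel file are processed independently.
All stages operate on a band-pass filtered trace: 2nd-order Butterworth,
150–2500 Hz, applied as second-order sections.

Two phase conventions are supported. `bandpass_filter` is causal by
default, matching a streaming/hardware datapath. The offline pipeline
(`run_pipeline`, `measpike detect/run`) defaults to zero-phase filtering
(forward-backward application). The reason is concrete: a causal 150 Hz
high-pass leaves a one-sided undershoot after every wide positive
waveform; for the ~1.4 ms complex class this undershoot crosses the
negative detection threshold about 2 ms after the apex — outside any
±1 ms validation window — and those crossings accumulate into a spurious
"undershoot" cluster. The zero-phase ripple is symmetric, half as deep,
and falls inside the validation window, so it is suppressed where it
belongs. Offline analysis pays no causality cost for this.

The data stream is split into contiguous, non-overlapping 10 ms windows
(250 samples at 25 kHz); a trailing partial window is dropped.

**Percentile convention.** Wherever a percentile appears (25th of RMS
values, 2nd/30th of voltages, 40th of extrema), the k-th percentile of n
sorted values is the element at the 1-based index `trunc(0.5 + n·k/100)`,
clamped to `[1, n]`. For (n, k) = (100, 25) this selects the 25th element.
Truncation mirrors what an integer shift-and-compare datapath computes and
keeps every estimator consistent with the same rule.

## Noise-level estimators

All five estimators consume windows and expose current positive/negative
thresholds (`valid = False` until initialized). Thresholds are a multiple
of the noise estimate: ×4 for the RMS/percentile family, ×2 for the
extrema family (whose 40th-percentile extrema statistics are intrinsically
larger than an RMS).

* **BandFlt** — collect 300 window RMS values once; the estimate is their
  25th percentile; thresholds are symmetric and never move. The low
  quantile deliberately under-reads the noise so that spike-contaminated
  windows cannot inflate the threshold.
* **Limada** — per window, compute the 2nd and 30th voltage percentiles
  (V.02, V.30; both negative for zero-mean noise). The window is *clean*
  iff `V.02/V.30 < 5` (no spike stretches the extreme tail) and
  `|V.30| > eps` (not blanked; default `eps = 1e-3 µV`, far below any ADC
  step — the test only needs to reject zeroed data). The estimate
  initializes as the mean of |V.02| over the first 100 clean windows (an
  unbiased, smooth start; the original formulation leaves the seed value
  open) and then updates on clean windows only:
  `est(k) = 0.99·est(k−1) + 0.01·|V.02|`. Because only *negative* spikes
  disturb the low tail, the clean test is blind to positive spikes; in
  practice |V.02| of such windows is still a noise-tail statistic, so the
  estimate stays put. Note the estimate targets ≈2σ of the noise, so ×4
  yields a conservative ≈8σ threshold — few false positives, the behavior
  its selection criteria reward.
* **AdaFlt** — initialize from the extrema of the first 128 windows: the
  estimate pair is the 40th percentile of the maxima (M.4) and of the
  minima (m.4, negative). Afterwards it retains the extrema of one window
  in ten and, each time 128 retained windows accumulate (1280 raw), blends
  `est_p(k) = 0.9·est_p(k−1) + 0.1·M.4` and symmetrically for m.4.
  Positive and negative thresholds are independent.
* **AdaFlt 128** — identical but undecimated: refreshes every 128 raw
  windows, an order of magnitude faster to track steps, and accordingly
  more sensitive to noise fluctuations.
* **AdaBandFlt** — adaptive BandFlt: the 25th percentile of each batch of
  100 window RMS values (N.25) feeds `est(k) = 0.8·est(k−1) + 0.2·N.25`,
  initialized by the first batch. The multiplier is 4, inherited from
  BandFlt (its non-adaptive parent); it is configurable.

Each update rule is an exponential smoother: after m refreshes of a
constant input c the estimate is `c + (init − c)·λ^m` with λ ∈
{0.99, 0.9, 0.8}. The tests assert this closed form to 1e-12.

**Pre-initialization samples.** The thresholds emitted before an
estimator initializes are invalid. For offline analysis the pipeline
back-fills them with the first valid pair (`pre_init="backfill"`),
applying the threshold retroactively from t = 0, so events in the first
1–3 s are not structurally lost; `pre_init="skip"` reproduces the strict
streaming behavior where that data cannot be scanned.

## Detection and validation

Scanning the filtered trace against the per-sample thresholds (zero-order
hold between refreshes), each maximal run of samples above the positive
threshold (below the negative one) yields one candidate at its extremum,
earliest sample on ties.

Validation suppresses double detections of unitary events in a ±1 ms
window around each candidate:

(a) the candidate's |amplitude| must be the largest absolute value the
    *trace* attains in the window, either polarity (exact ties go to the
    earlier sample);
(b) 50% of its amplitude must exceed every other same-polarity
    *candidate* in the window.

The asymmetry is deliberate. Rule (a) runs against the trace so that
secondary features of a large spike — an opposite-polarity lobe, a ripple
dip — can never become events of their own even when the spike's detected
peak sits outside their window. Rule (b) runs against detected candidates
only: measured against every noise wiggle, a genuine spike would be vetoed
by its own flanks. Under the literal rule, two comparable same-polarity
peaks within 1 ms reject each other (50% of either does not beat the
other); `keep_larger=True` optionally retains the winner of rule (a).
Candidates whose window leaves the trace are dropped and counted.
Validation depends only on the trace and the candidate set, so it is
order-independent and idempotent.

Validated waveforms are cut with a 2 ms symmetric window — c = 50 samples
at 25 kHz — with the tallest peak at column `floor(c/2) = 25`; events too
close to the boundary are dropped and counted.

## Classification

Waveforms are mean-centered and projected on the first two principal
components (eigen-decomposition of the waveform covariance; each
component's largest-magnitude loading is made positive so runs are
reproducible). The first two components carry the bulk of the
between-class variance for triangular/biphasic shapes; clustering operates
entirely in this 2-D score space.

The merge tree is agglomerative with centroid linkage and Euclidean
distance. Cut levels are examined from `min(max_clusters, N)` (default
max 7 — a plausible number of cell bodies per electrode plus a noise
source or two) downward, and the first partition satisfying the
separation criterion is returned, favoring resolution; the fallback is a
single cluster. The criterion demands pairwise disjoint bounding spheres:
for every pair, `D_i + D_j < ||Cm_i − Cm_j||`, with `Cm_i` the PC-space
centroid and `D_i` the cluster *radius* (max member–centroid distance).
Dispersion and comparison are configurable (`dispersion="rms"`,
`separation="one_sided"`); the defaults were chosen because the one-sided
form happily splits the cloud of validated noise detections into two
tight, well-separated polarity subgroups, whereas the spheres form keeps
them as the single mixed cluster that manual inspection identifies — two
polarity groups projecting around zero. A side effect of maximum-
resolution cuts with radius dispersion is that a diffuse cloud may shed
its most extreme member as a single-element cluster; singletons
participate in clustering untouched and are only rejected afterwards.

After the cut, clusters smaller than `min_cluster_size = 10` are rejected
(no re-merging — late rearrangements are more often wrong than right),
and any accepted cluster whose mean waveform is below
`noise_pp_uv = 30 µV` peak-to-peak is flagged `is_noise`: it is the
collection of false-positive detections, kept but reported separately so
it can be discarded wholesale. Signal reconstruction places each accepted
(optionally non-noise) event's cluster-mean waveform at its aligned
position on a zero baseline.

## Synthetic recordings

The generator emulates a 60 s single-channel MEA recording at 25 kHz with
600 events and exactly 5 dB SNR — the regime the detection and sorting
defaults are designed for.

* **Classes.** Five templates: A = +80 µV and B = −80 µV symmetric
  triangles, C = +45 µV triangle (all 20 samples, apex at the center
  sample); D = two same-polarity triangles (70 and 45.5 µV) shifted
  0.4 ms; E = the biphasic analogue (+70 then −45.5 µV). The complexes'
  second lobe is scaled to 0.65 of the first: two *equal* triangles
  shifted by their half-width sum to an exactly flat plateau (the
  opposing unit-slope ramps cancel), which leaves no well-defined tallest
  peak for time-stamping, and an equal-lobed biphasic wave makes the
  "highest peak" a coin flip on noise that splits one class into two
  alignment variants. The 0.65 scale keeps every event's tallest peak
  unique and stable. Classes are drawn uniformly by default
  (`class_mix` configurable).
* **Placement.** Peak positions are uniform with rejection to enforce a
  5 ms minimum separation (no inter-spike-interval model is claimed), and
  a margin keeps full templates inside the trace. An overlapped complex
  is a single event with one ground-truth row.
* **Noise.** White Gaussian noise, band-pass filtered (2nd-order
  Butterworth, 150–2500 Hz), normalized to unit RMS, then scaled so
  `20·log10(RMS_clean/RMS_noise)` over the full record equals the target
  SNR exactly — the 5 dB figure is reproduced by construction, not
  estimated. The amplitude unit is microvolts throughout.
* **Determinism.** One seed drives event placement, class assignment and
  the noise stream (the noise generator is re-seeded by a fixed integer
  mix of the config seed); identical configs give bit-identical traces
  and tables.

What the generator does *not* emulate: biophysical spike shapes and their
within-unit variability, electrode drift and nonstationary noise floors,
bursting statistics, overlaps closer than 5 ms, and multi-electrode
correlation. Passing tests on this material therefore demonstrate the
pipeline's mechanics — thresholds track the floor, validation suppresses
double detections, classes separable in two PCs are recovered — not
performance on real tissue, where waveform variability and drift dominate.

## Evaluation

Detections are matched to ground truth one-to-one by a greedy
nearest-first pairing within ±1 ms (the validation window mirrored; the
matching rule itself is a toolkit convention). Matched detections are TP,
unmatched detections FP, unmatched truths FN. True negatives need an
enumerable population of "noise peaks that could have been detected":
here, strict local extrema of the filtered trace outside ±1 ms of every
true event, with no detection within ±1 ms. TN is therefore defined only
for simulated or annotated data, and its absolute size depends on that
reconstruction; Se and PPV are the robust figures. Ratios with zero
denominators are reported as undefined with a reason rather than silently
NaN. Screening runs on unvalidated detections by default (the estimators
are compared upstream of validation), switchable.

The initialization-cost comparison uses worst-case operation counts for
F channels and N-sample windows: `100·F·N²` for the clean-window
estimator (percentiles of each window, quadratic worst-case sort) versus
`100²·F` for the adaptive-RMS estimator (one sort of 100 RMS values).
They cross at `N = sqrt(100) = 10` samples independently of F — and 10
samples per 10 ms window is far below any realistic sampling rate, which
is the argument for the adaptive-RMS design.

## Numerical choices and degenerate inputs

Ties in excursion extrema, validation rule (a), and cluster labels break
toward the earlier index; partitions are deterministic functions of the
scores. Thresholds with a non-positive multiplier, bands touching Nyquist,
empty windows/vectors, negative noise estimates, zero-power signals in
SNR computations, infeasible event packings, and all-zero confusion
tables raise errors rather than degrade. The extrema-family negative
estimate is clamped at 0 if a pathological input drives it positive.
Waveform extraction requires at least 2 waveforms for PCA; a single
observation yields a trivial tree.

## Problem sizes in the test suite

The unit tests run on windows and short constructed traces; end-to-end
tests and the acceptance script use the full reference conditions (60 s,
1.5 M samples, 600 events), which one pipeline pass processes in a few
seconds. Stochastic end-to-end quantities (false-negative counts, cluster
counts) are reported as medians over three independent noise realizations.

## Known limitations

* The clean-window test only reacts to negative-going spikes; a channel
  with exclusively positive units relies on the V.02 tail statistic alone.
* The 50% validation rule rejects *both* of two comparable same-polarity
  peaks within 1 ms (the `keep_larger` flag trades this strictness for
  recall).
* Two principal components bound what the classifier can separate; more
  than ~6 distinct shapes plus noise will alias in the score plane.
* Centroid linkage can produce inversions; cuts are by cluster count, not
  height, which tolerates them but makes the chosen level data-dependent.
* TN (hence Sp and NPV) is a documented reconstruction, meaningful only
  relative to this package's definition of candidate noise peaks.
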