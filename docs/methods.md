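# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the `hrvemotion` pipeline. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and preprocessing

The input is a uniformly sampled single-lead ECG (`ECGRecord`: float64
samples, rate `fs` in Hz; sample `i` is time `i/fs` s). Denoising uses a
discrete wavelet transform with symmetric signal extension, default sym8
at 5 levels. The noise scale is estimated from the finest detail
coefficients as δ = mean|w| / 0.6745 (the Gaussian third-quartile
constant, robust to the sparse large QRS coefficients), and one global
threshold is applied to every detail level; approximation coefficients
pass through untouched.

Two threshold conventions are implemented and never mixed:

* `universal` (default): θ = δ·√(2·ln H), the standard universal
  threshold for a length-H signal;
* `as_printed`: θ = δ·2·ln H. This grows like ln H rather than √ln H and
  over-thresholds long records by an order of magnitude (for H = 30 720,
  2·ln H ≈ 20.7 versus √(2 ln H) ≈ 4.5), visibly flattening R-peaks; it
  is retained as an explicit mode for comparison.

Shrinkage is the semi-soft compromise rule γ = sign(w)·(|w| − θ/2) for
|w| ≥ θ, zero below — halfway between hard thresholding (noisy spikes
survive) and soft thresholding (large coefficients biased by the full θ).
A `literal` variant γ = sign(w)·|w − θ/2| is available behind a flag; note
it *amplifies* negative coefficients (w = −2, θ = 1 → −2.5) and is not
recommended. Shrinkage under the default never increases coefficient
magnitude, and the whole path is positively homogeneous: scaling the
input by c > 0 scales δ, θ and the output by c.

## R-peak detection

The QRS template is sin(t) at n equally spaced points on [1.5π, 3.5π]
inclusive (default n = 15, ≈ 58 ms at 256 Hz): a symmetric R crest with
two negative flanks. The similarity trace is sliding cross-correlation
with both window and template mean-removed and unit-normalized, so scores
live in [−1, 1] and the detection threshold (default 0.3) is independent
of signal amplitude; zero-variance windows score 0, and the trace is
aligned so index i scores the window centered at i.

Candidate QRS groups are maximal runs of similarity > threshold. Each
surviving run yields one peak at its median index (lower median for
even-length runs — deterministic). Conformity filtering drops runs that

1. are shorter than 2 or longer than 2× the template length,
2. contain no sample reaching 0.4× the record's 98th-percentile absolute
   amplitude, or
3. fall within a 0.25 s refractory window of a larger-amplitude candidate
   (applied when the sampling rate is known). T waves correlate strongly
   with the template's central hump (normalized similarity ≈ 0.95 on
   synthetic morphology) and can clear the amplitude floor, but always
   lie inside the refractory window of their own QRS; the suppression is
   the standard remedy and all three criteria are configurable.

RR intervals are successive peak-time differences. An interval outside
the plausibility bounds (default 0.3–2.0 s, i.e. 30–200 bpm) removes the
beat that produced it, scanning left to right, so the surviving series
always satisfies `len(intervals) == n_beats − 1` with every interval in
bounds.

## Band decomposition

The RR series is a function of beat number; to make band edges in Hz
meaningful it is interpolated with a cubic spline against beat time onto
a uniform grid (default 4 Hz, comfortably above twice the 0.4 Hz upper
edge) and mean-centered. A full wavelet-packet tree (default db10) is
built; terminal nodes in natural frequency order tile [0, fs/2] into
2^L equal bins, and each of LF 0–0.15, HF1 0.15–0.25, HF2 0.25–0.35 and
HF3 0.35–0.4 Hz is reconstructed from exactly the nodes whose bin centers
fall inside it (a node straddling an edge goes to the band holding its
center). Content above 0.4 Hz is reconstructed separately as a residual,
so the five parts sum to the input to machine precision.

The default depth is the smallest L with node bandwidth ≤ 0.05 Hz — L = 6
at 4 Hz (0.03125 Hz bins), which resolves every band edge to within one
node. Deeper trees (e.g. L = 12, which needs ≥ 4096 samples ≈ 17 min of
recording at 4 Hz) are honored when the series is long enough and reduced
with a warning otherwise. A `beat_domain` flag skips resampling and
decomposes the raw per-beat series, in which case edges are read in
cycles/beat. With db10 at L = 6, single tones at 0.08/0.20/0.30/0.38 Hz
place ≥ 90 % of their four-band energy in LF/HF1/HF2/HF3 respectively
(filter leakage goes almost entirely to neighboring nodes of the same
band; the figure is computed by the acceptance script).

## Amplitude level quantization

Extrema are points where the first difference changes sign; plateaus
contribute one extremum at the (lower) plateau midpoint, and consecutive
same-type extrema are merged keeping the larger magnitude, so crests and
troughs strictly alternate. Quantization is by r = |amplitude| / Amax
with Amax the per-band, per-recording maximum: A [0.8, 1], B [0.6, 0.8),
C [0.4, 0.6), D [0.2, 0.4), E [0.1, 0.2), F [0, 0.1). Bins are half-open
with the A bin closed at 1 and r = 0 assigned F, making the map total;
it is monotone in magnitude and invariant to positive rescaling of the
band signal. Polarity (crest vs trough) is not encoded by default; an
optional mode appends +/−.

Sliding windows of lengths {2, 3, 4, 5} with stride 1 produce the
subsequence bag; the total window count is LE = Σ_L max(0, N − L + 1).

## Rule mining

A transaction is the set of *distinct* windows from one recording's one
band — the only granularity under which support is a fraction of
recordings. Mining is per emotion:

* **Frequent itemsets** via FP-growth (implemented here; the environment
  provides no frequent-pattern library), exact against brute-force
  enumeration. The pipeline default caps itemset size at 2: recordings of
  the same emotion share many windows, and unbounded enumeration over
  nearly-always-co-occurring items grows exponentially while contributing
  nothing to single-window matching. The cap is a config key; the
  mining-oracle tests run uncapped.
* **Association rules** X→Y for disjoint X, Y with X∪Y frequent, kept at
  reliability (confidence) sup(X∪Y)/sup(X) ≥ 0.60; the reliability is
  the rule's strength.
* **Potential rules**: for same-length windows at consecutive start
  positions (P, Q), the correlation is their joint support (a `lift`
  mode divides by sup(P)·sup(Q), clipped to 1). If it reaches 0.30 and an
  association rule with antecedent {P} exists, a rule on {P, Q} is
  emitted with strength = strength(P-rule) × correlation, clipped to
  (0, 1].

Thresholds (min support 0.10, min reliability 0.60, correlation 0.30) are
config keys reported in output metadata; they were fixed as round,
conventional values for across-recording pattern mining. Rules from all
emotions are merged by (pattern, antecedent, consequent, origin); label
sets are unioned, strengths kept per emotion with the maximum as the
merged strength, and any pattern labeled with *every* emotion is removed
as universal — it cannot discriminate.

## Feature matching and classification

A rule exposes the window tuples of its full pattern itemset (X∪Y for
implications). A window occurrence matches a rule iff it equals one of
those tuples; this is the only total reading of per-window equality that
covers multi-item rules. Per band: MA counts matching occurrences (a
window matching several rules counts once), TC sums every matched rule's
strength per occurrence (so TC can exceed MA when patterns overlap
across rules), FR = MA/LE, and PR = (distinct matched patterns of
length ≥ 2)/MA. PR uses distinct patterns deliberately: with the default
window lengths {2..5} an occurrence count would make PR identically 1;
a `length_sum` mode implements the alternative Σ(MNl_i − MNl_1)/MA
definition. All 0/0 cases yield 0. Matching is against the single merged
standard rule set, which fixes the feature count at 4 bands × 4
statistics = 16.

Features are z-scored with training-set statistics only, then fit by
multinomial logistic regression (L2, C = 1.0, lbfgs, tol 1e−6, ≤ 1000
iterations — deterministic for a fixed split). Splits are stratified;
rule mining runs on the training recordings only, so no label information
reaches the test features. Metrics are macro-averaged (F1, recall,
specificity from the confusion matrix, one-vs-rest AUC), and the
confusion matrix is row-normalized over true classes; averaging and
normalization are switchable.

## Emotion map

The 17 emotion categories are placed on [−1, 1]² valence × arousal. The
shipped coordinates are a synthetic approximate circumplex placement for
testing (`emotions.default_map`); studies should supply their own CSV.
Ratings on other scales (e.g. DREAMER's 1–5) are affinely rescaled.
Quantization is nearest-neighbor in Euclidean distance with alphabetical
tie-break. In the shipped map, gratitude and confidence sit ≈ 0.22 apart
— below the 0.25 confusability threshold the diagnostic flags — which is
exactly where nearest-neighbor label noise, and hence classifier
confusion, concentrates.

## Synthetic data: what it emulates, what it does not

`synth_ecg` draws beat times from an iterated-interval model,
RR(t) = mean + Σ_b a_b·sin(2π f_b t + φ_b) + jitter, stamps each beat
with the half-sine QRS template plus Gaussian P (amp 0.15, −180 ms) and
T (amp 0.30, +220 ms) bumps, and adds white noise at a specified SNR
(signal-power ratio in dB). Defaults: 120 s at 256 Hz, 70 bpm, 3 ms RR
jitter, 20 dB SNR. It emulates band-limited autonomic RR modulation with
exact peak ground truth and realistic-enough morphology to make template
detection non-trivial (T waves score ≈ 0.95 similarity). It does not
emulate baseline wander, electrode artifacts, ectopy, respiration-coupled
amplitude modulation, or inter-subject morphology variation — so passing
tests demonstrate the pipeline's correctness and internal consistency,
not field performance on ambulatory recordings.

`synth_labeled_dataset` gives each emotion a distinct dominant RR
modulation band (50 ms amplitude at the band-center frequency, 12 ms in
the other bands, cycling LF→HF1→HF2→HF3 across classes). The driven
band's extrema concentrate near Amax (A/B symbols), while noise-driven
bands spread across the alphabet, so the per-class symbol statistics are
separable by design. Class separation therefore shows end-to-end
parameter recovery under a known effect, not that real emotions induce
effects of this size. The 4-class study condition (200 recordings of
120 s) was chosen to exercise mining with ~40 training recordings per
class while keeping the full experiment under a minute of processing.

`synth_level_corpus` plants known symbol tuples into i.i.d.-uniform
background sequences at a given per-recording rate (replacing symbols,
preserving lengths), returning the ground-truth rule list.

All generators are deterministic given a seed.

## Degenerate inputs and tie-breaks

* Empty extrema (constant/monotone band) → empty level sequence → empty
  bag; a degenerate recording contributes a sentinel window so its mining
  transaction stays non-empty.
* Even-length similarity runs take the lower median; equidistant emotion
  coordinates take the alphabetically first name; duplicate merged rules
  keep the maximum strength.
* Support thresholds compare counts against ceil(min_support·n) with a
  1e−9 slack so exact boundary products are kept.

## Known limitations

* The detector is template-based; morphologies far from a dominant
  upright R (e.g. some leads, paced rhythms) need a different template.
* The RR plausibility filter drops beats greedily; after a long artifact
  gap it may discard a genuine beat whose interval exceeds 2 s.
* Band edges assume the 4 Hz resampled domain; the `beat_domain` mode
  changes their meaning to cycles/beat.
* Rule mining assumes enough recordings per emotion for support to be
  meaningful; with very few recordings the universal-rule filter can
  remove nearly everything.
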