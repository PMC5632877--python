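# Methods

## The marker

The Brain Engagement Index (BEI) is a template-matching statistic on raw
single-channel EEG. The premise: during attentive engagement, frontal EEG
contains transient deflections whose averaged (ERP) shape is known; scanning
the ongoing delta-band signal for 1500 ms stretches close to that shape, and
balancing their count against the count of dissimilar stretches, yields a
scalar that tracks attention recruitment in near real time — without stimulus
markers, multielectrode montages, or minutes of averaging.

Processing, per emission (every 10 s, covering the trailing 60 s):

1. **Segmentation.** The minute is divided into six 10 s segments on a fixed
   grid anchored at recording start. Segment results are computed once and
   shared by the overlapping minutes, so consecutive emissions share 50 s of
   analyzed signal.
2. **Delta filtering.** Each segment is bandpassed to 1–4 Hz with a 4th-order
   Butterworth applied forward–backward (zero phase, so template alignment
   survives filtering). Filters run in second-order sections; the
   transfer-function form of a 1–4 Hz band at 512 Hz is numerically
   ill-conditioned and was observed to amplify input round-off ~10^6-fold.
   Each segment is filtered with up to 2 s of true adjacent signal as context
   on each side (reflect-padded where the recording ends), which keeps
   filter transients out of the segment and makes chunked-streaming output
   bit-identical to batch output.
3. **Normalization.** The filtered segment is min–max mapped onto [−1, +1]
   (most negative deflection → −1, most positive → +1). The template receives
   the same filtering and normalization when loaded.
4. **Scanning.** A 1500 ms window slides with one-sample stride (the finest
   reading of "moving window"; the deduplication rule bounds the cost). Per
   window, the mean absolute distance to the template decides match
   (*d* < 0.5) versus no-match. The distance to the polarity-inverted
   template is also computed; under the default configuration it does not
   affect classification (the match rule is defined solely by the template
   distance), but `opposite_mode="opposite_counts_as_nomatch"` restricts
   no-matches to windows that actually resemble the inverted template.
   Under [−1, +1] normalization the polarity-inverted waveform is the
   meaningful "opposite"; a literal `1 − template` would leave the
   normalized range.
5. **Deduplication.** Greedy left-to-right: per class, the end of the last
   counted event is remembered and a new event is counted only if its window
   starts at or after that end. The same rule, implemented by explicit
   interval bookkeeping, serves as the brute-force oracle in the tests.
6. **Segment BEI.** `matches / no-matches`, clamped to at most 1; zero
   matches give 0, matches with zero no-matches give 1; a segment with no
   countable events at all is invalid.
7. **Emission.** Median of the valid segment BEIs; fewer than three valid
   segments leave the minute without a value. Gaps are explicit (NaN in the
   trace) and never interpolated. Emissions are stamped with the end of
   their 60 s window.

## Noise rejection

A 1500 ms window is rejected when the SD/mean ratio of its **delta-activity
amplitude** exceeds 1. Activity is measured as the magnitude of the analytic
(Hilbert) signal of the filtered segment — i.e. the band amplitude envelope.
This reading matters: applied to the signed filtered samples the same ratio
is ≈1.25 for perfectly clean Gaussian band noise and ≈1.11 for a pure
oscillation, so a signed-sample reading would reject everything and no valid
minute could ever be produced. On the envelope, clean band-limited EEG sits
near 0.4–0.6 and a blink-scale transient pushes the ratio well above 1.
`scan_segment` computes one envelope per segment (one FFT, no per-window
Hilbert edge artifacts); the standalone `noise_ratio` computes the envelope
of the window it is given. A window of exactly zero amplitude is noisy by
convention; a constant (zero-range) segment is invalid as degenerate rather
than an error, so one flat-lined stretch cannot abort a session.

Rejected windows count toward the segment's rejection tally only when
non-overlapping with the previously rejected window; more than one such
window discards the segment. One large blink typically produces noisy
windows spanning more than one window length and therefore invalidates its
segment on its own; smaller transients cost a single tolerated rejection.

## Session metrics and the feedback ladder

`session_bei` pools all non-missing BEI values of a patient's two sessions,
computes the pooled mean and sample SD (n−1; population SD available), and
grades each session by the fraction of its values strictly above
mean + 1 SD. Equal fractions are reported as a tie, never broken arbitrarily.

The advisory ladder judges engagement relative to the individual patient:
the baseline is the running mean of all non-missing values so far in the
session. A drop episode opens when the current value falls strictly below
(1 − 0.10) × baseline, accumulates 10 s per in-drop value, and closes on
recovery. Missing values neither extend nor reset an episode. The first
advisory (encourage) fires once the drop has persisted 30 s; the
difficulty-change stage (intensify when the exercise looks too easy, reduce
when too hard — a caller-supplied hint, since performance grading is outside
the EEG) follows after a further 30 s, and rest/passive after another 30 s.
The between-stage interval is not specified by the protocol; 30 s (the same
as the trigger window) is the default and is configurable. Each stage fires
at most once per episode, in order.

## Paired-session statistics

Two blinded raters score each session's temporary functional change on the
integer Likert scale [−3, +3]; the session score is their mean, and a patient
is excluded when any session shows a rater disagreement above 1 point.

`wilcoxon_paired` tests whether higher-engagement sessions score higher:
differences higher − lower, zeros dropped (classic convention; the protocol
does not specify Pratt handling), midranks for tied magnitudes. With fewer
than 10 nonzero pairs the p-value comes from exact enumeration of all 2^n
sign assignments; otherwise from the normal approximation with tie-corrected
variance. The default alternative is one-sided (the reported statistic pair
in this literature is consistent with a one-sided test); two-sided is an
option. Z follows the SPSS sign convention — computed from the rank sum
counting against the alternative — so a positive effect yields a negative Z.

The order-effect comparison is a Pearson 2×2 chi-square without continuity
correction by default (Yates optional); a zero margin is reported as
undefined. The categorical effect size between two proportions defaults to
the probit difference d = Φ⁻¹(p₁) − Φ⁻¹(p₂), with Cohen's h as an
alternative; boundary proportions take a 1/(2n) continuity adjustment when
the count is supplied. `cumulative_threshold_curve` gives the fraction of
session scores at or above each Likert threshold.

## Synthetic data: what it emulates, and what it does not

The generators stand in for clinical recordings that are not available.

- **Background**: Gaussian 1/f noise (power ∝ 1/f, the classic EEG-like
  slope), band-limited to 0.5–40 Hz, RMS 10 µV — plausible for a dry frontal
  electrode. It has no alpha peak, no spectral nonstationarity, and no
  physiological autocorrelation structure beyond its spectrum.
- **Engagement events**: instances of the matching template itself, embedded
  at Poisson times (non-overlapping, drawn uniformly over all feasible
  configurations), scaled to 3× the background RMS — the high-SNR deflection
  an averaged-ERP component represents. Real attention-related activity is
  not literal template copies; tests on this generator therefore show that
  the matcher recovers what it is defined to find, not that the marker
  captures attention in real EEG.
- **Artifacts**: biphasic half-second transients at Poisson times, 150 µV
  peak — the blink scale at Fpz. Real artifact palettes (saccades, EMG,
  electrode pops, cable sway) are broader.
- **Ratings**: per patient, two latent session-engagement levels uniform on
  [0.2, 0.8]; a session's expected Likert change is
  `engagement_link × (latent − 0.5)` (default link 5, i.e. the full latent
  spread maps to ±1.5 points; link 0 is the exact null used for type-I
  calibration), plus independent N(0, 0.7) noise per rater, rounded and
  clipped to the integer scale.

All generators are bit-reproducible given (spec, seed).

The packaged default template is a synthetic surrogate: five cycles of a
10/3 Hz sinusoid (mid delta band), delta-filtered and normalized like any
loaded template, shipped as `data/synthetic_erp_template_512hz.csv` (raw
burst; loading applies the filter). Sustained in-band amplitude is the one
property the surrogate must have: a waveform that idles near zero for most
of its 1500 ms lies within distance 0.5 of almost every normalized window,
and the fixed threshold stops discriminating. The original averaged-ERP
template is proprietary and was not reconstructed from figures.

## Numerical choices and degenerate inputs

- Zero-phase filtering via `sosfiltfilt`; templates are filtered with 2 s of
  zero padding (a template is a transient in silence, so zero context is the
  physical continuation; the resulting edge taper is the true delta content
  of a finite burst).
- Re-loading an already-filtered, normalized template is only approximately
  idempotent: each pass re-attenuates the burst's spectral content near the
  band edges. Observed deviation ≲0.13 peak, ≲0.05 RMS; the tests bound it
  at 0.15 / 0.06.
- Template resampling is polyphase (linear-phase), preserving shape without
  phase distortion.
- CSV recording timebases must be uniform within 1% of the median step; the
  rate is the reciprocal of the median step. EDF reading goes through `mne`;
  16-bit EDF quantization means bit-exact round-trips are not promised.
- A filtered segment whose range is below 10⁻⁸ of the raw range is declared
  degenerate (filter round-off would otherwise be normalized into garbage).
- Streaming mode buffers 2 s of look-ahead per segment so a segment's filter
  context is identical to batch; any chunking yields a bitwise-identical
  trace.
- Engine cadence must equal the segment length (10 s = 10 s, as in the
  protocol); the configuration validates this rather than supporting
  sub-segment emission grids.

## Problem sizes used in the checks

The distributional checks run at sizes chosen to make their statistics
stable: monotonicity uses twenty 3-minute recordings at 512 Hz with
embedding rates 0–5 per 10 s; session-grade recovery uses fifty pairs of
5-minute sessions at 256 Hz with rates 1 vs 4; the scan-versus-enumeration
equivalence uses one hundred 10 s segments at 64 Hz (the reference
enumerates every window position in Python); type-I calibration uses 500
null cohorts of 18 patients. Engine behavior is rate-agnostic: the sampling
rate changes only how many windows a segment contains.

## Known limitations

- The BEI's validity as an attention marker in real EEG is an empirical
  claim of the underlying clinical literature; this package reproduces the
  computation and its testable mechanics, not that claim.
- The noise gate's envelope reading and the 30 s escalation interval are
  interpretations where the protocol text underdetermines the algorithm;
  both are documented above and configurable where meaningful.
- Live acquisition hardware is out of scope; "live" operation is chunked
  streaming of recorded samples with a 2 s look-ahead.
- No multichannel support, no spectral band-power features, no
  alertness/arousal markers.
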