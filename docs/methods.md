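# Methods

This note documents the models and procedures implemented in `hsfibi`, the
assumptions behind them, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and pipeline

A cardiac vibration signal (CVS) is modelled as a quasi-periodic train of
beat-locked waveshapes plus broadband and structured noise.  Two physical
components matter for beat timing:

* a **low-frequency body-motion wave** (~1–6 Hz, aortic ejection and torso
  recoil): large, but broad-peaked and variable in its timing relative to
  the electrical beat;
* a **high-frequency valve burst** (~15–25 Hz, heart-valve closure): small,
  but sharp and tightly locked to the beat.

The pipeline's premise is that beat timing should be read from the
highest-frequency band that still has verifiable periodic content, and that
every decision (band choice, channel admission, per-beat source selection,
template refresh) should be driven by explicit signal-quality indices rather
than fixed per-sensor tuning.

### Filter bank and band weighting

All filters are third-order Butterworth applied forward-backward
(`sosfiltfilt`), so the cascade has zero phase and symmetric pulses keep
their peak sample exactly — a precondition for reading beat times off peaks.
Candidate bands are `[f_L, 40] Hz` with `f_L ∈ {1, 3, 5, 7}` Hz; the band
weight `β = 1 + K (f_L − 1)` with `K = 0.05` gives the 7 Hz band a 30 %
premium when per-beat quality scores are compared across channels.  The
printed form of the weighting rule is ambiguous between `β = K·f_L` and
`β = 1 + K(f_L − 1)`; the latter is implemented, since with `K = 0.05` the
former would cap `β ≤ 0.35` and no beat could ever clear the quality
threshold `θ = 0.75`.  When a configured high cutoff reaches the Nyquist
frequency the cutoff is clamped to `0.45 · sr` with a warning.

Forward-backward IIR filtering has edge transients; the first and last
0.5 s of a filtered signal are excluded from peak detection, and the
time-reversal symmetry property is exact only away from the edges.

### Harmonic-summation heart rate and its SQI

Per 8 s window (1 s step) the signal is z-scored, squared, and band-passed
to 1–10 Hz.  Squaring demodulates the beat-locked energy to the heart-rate
fundamental and low-order harmonics regardless of the carrier band; the
1–10 Hz band keeps roughly the first seven harmonics of a resting heart
rate.  The Hamming-windowed FFT (zero-padded 8×, so the grid spacing
`1/64 Hz` is independent of the sampling rate) is scored with the sparse
peak/valley kernel over a candidate grid of 0.005 Hz (0.3 bpm) steps
spanning 42–180 bpm; off-grid harmonic positions are read by linear
interpolation, and any multiplier whose `(i+½) f′` exceeds the spectrum top
is dropped for that candidate.

Two deliberate consequences of this parameterisation:

* For fundamentals just above the 1 Hz cutoff (60–75 bpm), the *raw*
  spectral peak of the squared signal often sits on the second harmonic
  (the filter skirt attenuates the fundamental).  The kernel stage exists
  to undo exactly this bias, and the tests assert the estimate, not the raw
  peak.
* Below 60 bpm the attenuated fundamental makes third-harmonic errors
  possible; the harmonic-robustness studies therefore draw heart rates from
  60–100 bpm, the range the 1–10 Hz band is designed around.  Lowering the
  band's low cutoff would extend the range at the cost of respiratory
  leakage.

**SQI normalisation.**  The quality index is the height of the HarSum
maximum, which is only meaningful against fixed thresholds if the spectrum
scale is pinned down.  The amplitude spectrum is normalised to unit L2 norm
over the analysis band `[0.5, 7 · f_max] Hz` and divided by the spectral
window's peak-to-norm gain, making the peak reading of a fully periodic
in-band signal a fixed constant (~0.74) independent of sampling rate and
window length.  `SQI_HarSum` is then a bounded concentration index.  Under
this calibration, on synthetic data, clean channels score ≈ 0.5–0.65,
windows with 20× noise artifacts ≈ 0.2, and white noise has its 95th
percentile just below `Q2 = 0.26` — consistent with the published thresholds
`Q1 = 0.52`, `Q2 = 0.26`.  A simple unit-*sum* normalisation was rejected:
on a padded grid it makes a pure tone's peak bin read ~0.07, putting both
thresholds out of reach.  If the normalisation is changed, re-derive
thresholds by running `estimate_window_hr` over clean renders and seeded
noise windows and placing `Q1`/`Q2` between the two populations.

### Band selection and channel admission

Per channel, rule 1 keeps the *highest* `f_L` whose SQI exceeds `Q1`
(prefer valve content whenever its quality is verified); rule 2 falls back
to the best SQI above `Q2` (ties toward the higher band); rule 3 discards
the channel.  The published clause-2 inequality (`Q1 < SQI < Q2`) is empty
as printed and is implemented as `Q2 < SQI ≤ Q1`, matching the surrounding
prose.  Selection is re-evaluated at template-update events, not every
window; the sliding HR/SQI analysis itself runs on every window.

### Template groups

From the first admissible 8 s window, segments of one mean beat period
`L = round(60/HR · sr)` (round-half-to-even) are cut around every strict
local maximum (plateaus count once, at their first sample).  Segments are
clustered sequentially: a segment joins the cluster maximising its *minimum*
correlation to all members, or opens a new cluster below `θ = 0.75`, so
clusters are internally coherent at level θ by construction.

Cluster ranking follows the "highest average centre point value" reading —
the mean centre-sample amplitude — rather than the mean member ℓ2 norm
(available as `cluster_rank="l2"`).  The two readings coincide for
peak-centred segments on clean signals, but on realistic noisy renders every
period-length window holds nearly the same energy, so ℓ2 ranking degenerates
to noise (measured template-to-truth correlation ≈ 0), while the
centre-amplitude rule directly rewards clusters anchored on true beat peaks
(correlation ≈ 0.99).  The representative (`T1`) is the member with the
highest within-cluster correlation sum; members are never averaged, so
morphology stays sharp.  A second template is extracted when the primary
cluster shows a gap > 1.5 L between consecutive member positions — the
signature of respiration-alternating morphology — from the best competing
cluster occupying those gaps.  Two templates are the maximum (respiration
has two phases).  Ties everywhere break toward the earliest cluster/member,
for determinism.

One known ambiguity: segments centred on adjacent burst-carrier peaks of
the *same* beat can correlate above θ, so a template may sit one carrier
period (~45 ms) off the beat centre.  The offset is constant per template
and cancels in interval estimation; morphology comparisons in the
experiments therefore align within ±60 ms before correlating.

### Beat tracking

Correlation is evaluated only at local maxima of the band-filtered signal
(cost: peaks × templates, never per-sample).  The first beat is the
best-matching peak in the first 2 s; each next beat is the best-matching
peak in `[(1−v)L, (1+v)L]` after the previous one (`v = 0.3`, ties toward
the earlier position).  Template choice is gated by which templates were
trustworthy (`ccf > θ`) at the previous beat; when none was, both compete
(cold-start rule — the published rule has no else-branch).  Per-beat quality
is `SQI_beat = β · max(ccf₁, ccf₂)`, capped at β.

Missed beats (no peak in the search window) advance the anchor by one
expected period and open a gap; no IBI is emitted across gaps.  Template
updates fire on five consecutive beats with `SQI_beat < θ`, on three
consecutive misses, or when the harmonic-summation SQI of every channel has
collapsed in the surrounding window.  An update re-selects the band and
rebuilds templates on the first window starting at or after the trigger —
not the trailing window, which is dominated by the very data that caused
the trigger and would make detection crawl through an artifact emitting bad
beats.  If no window is admissible (e.g. during an artifact epoch), the
channel stays silent until one is.

### Fusion

Per-channel beat sequences are aligned greedily into slots within 150 ms
(< (1−v)·L for heart rates up to ~140 bpm, so adjacent beats cannot merge);
each channel contributes at most one beat per slot.  Within a slot, channels
whose previous-slot beat cleared θ compete by current `SQI_beat`; a channel
resuming after its own gap competes if its current beat clears θ.  A slot
with no trustworthy beat at all is *rejected* when it is sandwiched between
trusted beats — such slots are almost always noise detections from a
corrupted channel, and emitting them would corrupt two otherwise-clean
intervals — but during a sustained outage (previous slot also untrusted)
the best available beat is emitted and flagged low-confidence, so output
degrades gracefully rather than stopping.  Fused IBIs are differences of
consecutive *fused* beat times, so a source-channel switch cannot
double-count fixed inter-sensor lags; constant lags also cancel in the
interval-level evaluation metrics.

## Evaluation metrics

Windowed HR error uses the reference rate `60 / mean(reference IBI)` per
8 s window; coverage is the analysed fraction of all windows.  For IBIs,
estimated beats match their nearest reference beat within half the local
reference interval (duplicates resolved to the nearest), and interval pairs
require endpoints matched to consecutive reference beats.  A pair is
correct when `|RR − JJ| ≤ 30 ms` (inclusive).  Precision divides by paired
estimates; the detection rate divides by *all* reference intervals,
including those in spans the estimator discarded — reference beats have one
interval fewer than beats, and that count is the denominator.  Bland–Altman
limits are `bias ± 1.96 · sd` (sample sd) of the paired differences.

## The synthetic-data generator

`hsfibi.simulate` is the package's study-condition definition, not a
physiological forward model.  It emulates:

* beat times with respiratory sinus arrhythmia (sinusoidal IBI modulation,
  default ±40 ms at 0.25 Hz), white IBI jitter (5 ms), and a ±30 %
  consecutive-interval clip matching the tracker's search window;
* per-archetype waveshapes = Gaussian-windowed low-frequency lobe +
  Gaussian-windowed high-frequency burst.  Piezo and EMFi carry strong
  bursts (valve-proximal sensors); radar and load cell are
  low-frequency-dominated.  The burst is locked to the true beat time while
  the low-frequency lobe wobbles by N(0, 6 ms) per beat — the mechanism
  that makes low-band timing worse and gives optimal band selection
  something to win;
* respiration-locked morphology alternation (two variants per archetype)
  with ±20 % amplitude modulation, exercising the two-template path;
* white noise at a per-channel SNR (default 15 dB against the clean beat
  train), a 50 Hz powerline sine, a 0.3 Hz baseline-wander sine, and
  channel-specific artifact epochs that multiply the noise.

It does **not** emulate: real sensor transfer functions, motion artifacts
with structure (noise is white within epochs), postural changes, arrhythmia
or ectopic beats, or inter-sensor lag (channels are perfectly synchronous).
Passing tests therefore demonstrate the pipeline's mechanics — quality
gating, band selection, template adaptation, fusion arithmetic — under
controlled violations, not clinical performance on real recordings.
Waveshape constants are package choices (documented in
`simulate.ARCHETYPES`) since real morphologies are known only pictorially.

## Study conditions and problem sizes

The verification suite and the results-reproduction script share drivers in
`hsfibi.experiments`: 120 s three-channel recordings at 250 Hz (~143 beats)
for recovery, fusion (disjoint 20 s artifact epochs, gain 20×) and
band-selection studies; 60 s single-channel recordings at 1000 Hz for the
sampling-rate study; 200 independent 8 s windows for harmonic robustness
(second harmonic 1.5–3× the fundamental, 10 dB SNR).  These sizes give
stable rates while keeping a full reproduction run around a minute on one
CPU.  The morphology study (template counts and shape capture) uses 30 dB
renders: it verifies the extraction logic, with noise robustness covered by
the end-to-end studies.

## Numerical choices and degenerate inputs

* Quadratic (order-2) splines for resampling; they reproduce polynomials up
  to degree 2 exactly and keep local extrema sharp.  Accuracy is ~1 % RMS
  for content below ~0.15× the lower sampling rate and degrades steeply
  toward Nyquist — plain decimation to 100 Hz followed by spline
  restoration is the supported low-rate path, and plain 100 Hz processing
  quantises beat times to 10 ms.
* Decimation is deliberately plain (no anti-alias stage); aliased
  out-of-band noise is expected behaviour in the sampling-rate study.
* Filters are designed as second-order sections and cached per
  (rate, band, order); stable for all configured bands at `sr ≥ 50 Hz`.
* Zero-variance windows are flagged unusable (SQI 0); zero-variance
  segments correlate 0 with everything; constant recordings yield an empty
  series with 0 % coverage rather than an error.
* All randomness flows through one seeded generator per scenario
  (spawned sub-streams per channel); identical scenarios are
  bit-reproducible.

## Known limitations

* Absolute SQI thresholds are calibrated on this package's normalisation;
  transfer to other front-ends may need the re-derivation procedure above.
* Beat times are sample-resolution (no sub-sample refinement); at low
  sampling rates use spline restoration.
* The tracker assumes quasi-periodicity within ±30 % beat-to-beat;
  arrhythmic rhythms violate the search-window assumption.
* Fusion assumes channel synchronisation well within the 150 ms alignment
  tolerance; fixed inter-sensor lags are tolerated (interval metrics cancel
  them) but are not estimated or corrected.
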