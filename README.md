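# hsfibi — beat-to-beat intervals from unobtrusive cardiac vibration sensors

`hsfibi` extracts the inter-beat interval (IBI) series — the beat-level
analogue of heart rate, and the raw material of heart-rate-variability
analysis — from multichannel **cardiac vibration signals**: bed-sensor
ballistocardiograms (piezoelectric ceramic, EMFi film, load cells) and
radar Doppler cardiograms.  It is aimed at researchers in unobtrusive
vital-sign monitoring who have time-synchronised waveforms from one or more
such sensors and want ECG-grade beat timing without electrodes.

Unlike ECG R-peaks, vibration waveforms have no fixed fiducial morphology:
waveshape varies across sensors, subjects, and even breathing phase, and any
single channel degrades whenever the subject moves.  The pipeline therefore
leans entirely on quasi-periodicity and signal-quality indices (SQIs):

1. **Zero-phase filter bank / optimal band selection.**  Each channel is
   band-passed into candidate bands `[f_L, 40] Hz`, `f_L ∈ {1, 3, 5, 7}`,
   with forward-backward Butterworth filters (no peak displacement).  Bands
   with a higher low cutoff isolate heart-valve vibrations — sharper and less
   variable than body recoil — and carry a weight `β = 1 + K (f_L − 1)`.
2. **Harmonic-summation heart rate (HarSum-HR).**  Per 8 s window the signal
   is z-scored, squared and band-passed to 1–10 Hz; the amplitude spectrum
   `X(f)` is scored against a sparse kernel with peaks `+1/i` at `i·f′` and
   valleys `−1/(2i)` at `(i ± ½)·f′`, `i ∈ {1, 2, 3, 5, 7}`:

   `HS(f′) = Σᵢ X(i f′)/i − [X((i−½) f′) + X((i+½) f′)]/(2i)`

   The argmax gives the mean heart rate; its height is `SQI_HarSum`, which
   drives band selection (thresholds `Q1 = 0.52`, `Q2 = 0.26`) and channel
   admission.
3. **Template groups via sequential clustering.**  Beat-length segments
   around signal peaks are clustered (BSAS, minimum-correlation admission at
   `θ = 0.75`); the best cluster's most central member becomes template `T1`,
   and a respiration-alternating morphology earns a second template `T2`.
4. **Peak-restricted template matching.**  Beats are tracked through the
   recording by Pearson-correlating templates only at signal peaks, searching
   `[(1−v)L, (1+v)L]` after each beat (`v = 0.3`).  Each beat carries
   `SQI_beat = β · max(ccf₁, ccf₂)`; sustained low quality triggers a
   template refresh.
5. **Beat-level fusion.**  Beats from all admitted channels are aligned and,
   per beat, the channel with the highest `SQI_beat` (gated on its previous
   beat's quality) supplies the fused interval.

A seeded synthetic-recording generator (`hsfibi.simulate`) emulates the
sensor archetypes, respiratory IBI modulation, morphology alternation, and
noise/artifact regimes, so the whole pipeline is testable without any data
download, and `hsfibi.metrics` implements the evaluation suite (MAE/MRAE/SDAE
for HR and IBI, coverage, precision and detection rate under the 30 ms rule,
Bland–Altman limits of agreement).

## Worked example

```python
from hsfibi import HsfIbi, Scenario, generate_recording

scn = Scenario(seed=1)                      # 3 channels, 72 bpm, 15 dB SNR
recording, truth, _ = generate_recording(scn)
results = HsfIbi(recording).fit()
print(results.summary())
ibi = results.evaluate_ibi(truth)
print(f"IBI vs truth: MAE {ibi.mae_ms:.2f} ms, Prec {ibi.prec_pct:.1f} %, "
      f"Det {ibi.det_pct:.1f} %")
hr = results.evaluate_hr(truth)
print(f"HR  vs truth: MAE {hr.mae_bpm:.2f} bpm, coverage {hr.cov_pct:.1f} %")
```

prints

```text
HSF-IBI fit summary
==============================================
channels:           piezo0, radar_lowfreq1, emfi2
duration:           120.0 s at 250 Hz
fused beats:        143
window coverage:    100.0 %
mean IBI:           832.5 ms (HR 72.1 bpm)
IBI range:          784-880 ms
per-channel band decisions (first epoch):
  piezo0           fL=7 Hz  rule 1  SQI 0.560  beats 143
  radar_lowfreq1   fL=1 Hz  rule 1  SQI 0.592  beats 142
  emfi2            fL=7 Hz  rule 1  SQI 0.572  beats 143
IBI vs truth: MAE 1.41 ms, Prec 100.0 %, Det 100.0 %
HR  vs truth: MAE 0.35 bpm, coverage 100.0 %
```

Reading the output: the burst-bearing piezo and EMFi channels passed the
strict quality threshold in their 7–40 Hz band (rule 1) and were up-weighted
(β = 1.3); the radar channel only carries low-frequency chest-wall motion
and was kept at 1–40 Hz.  All 143 ground-truth beats were recovered, with a
mean absolute interval error of 1.4 ms at a 4 ms sample period.

The same flow is available from a shell:

```bash
hsfibi simulate --out-dir demo --seed 1
hsfibi estimate demo/recording.csv --output demo/ibi.csv --manifest demo/run.json
hsfibi evaluate --est demo/ibi.csv --ref demo/beats.csv
```

`estimate --scenario-mode` switches between single-channel (`sc`),
multi-channel (`mc`/`hs`) and fixed-band (`hs-nobs`, low cutoff pinned to
3 Hz) operation.

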