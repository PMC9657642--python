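# Methods

## The detection model

`seizefeat` implements a classifier-free seizure detector for multichannel
scalp EEG. The premise: an electrographic seizure is a sustained, rhythmic,
high-amplitude discharge whose energy concentrates in the low delta band
(roughly 1–4 Hz). Instead of training a classifier on features, the
pipeline treats the EEG like a noisy transmission channel and tunes a fixed
receiver to the seizure band. All channels are collapsed into one *feature
signal* — a normalized RMS envelope — in which a seizure shows up as a
discontinuity of the envelope's baseline band: a tall, narrow onset peak
followed by a sustained supra-threshold region. Detection is then a short
cascade of amplitude, width and power rules with no fitted parameters.

Processing of one record:

1. **Preprocessing** (per channel, zero phase):
   power-line notch at f₀ and harmonics → 50th-order FIR low-pass at
   35 Hz → first-order recursive DC notch
   H(z) = (1 − z⁻¹)/(1 − λz⁻¹), λ = 0.9991.
   The DC notch is the load-bearing stage: channel averaging is only
   meaningful once per-channel offsets and drift are gone.
2. **Feature signal**: arithmetic channel average → full-wave
   rectification → feature filter (band selection around 0.1–4.1 Hz) →
   moving RMS over 150 samples → division by the per-record maximum.
   Rectification folds the fast ictal oscillation into a positive baseline
   shift that survives the low-pass band selection; normalization lets all
   detection thresholds be fractions of one.
3. **Epoch detection**: local envelope maxima with height ≥ `amp_upper`
   are onset candidates; a candidate survives if its half-prominence width
   lies in [0.4, 1.8] s and the in-band power over its support reaches
   `seizAggressiveness`; survivors grow to the surrounding contiguous
   region with envelope ≥ `amp_lower`; regions closer than `seizLinterval`
   samples merge, and anything shorter than `seizLinterval` is dropped.
   The result is an ordered, disjoint epoch set, exportable as a binary
   mask (1 = seizure).
4. **Localization**: the same amplitude analysis re-applied per channel,
   restricted to the masked samples. Each channel's rectified,
   feature-filtered trace is reduced to its amplitude excursion
   (max − min); the median excursion is the threshold; channels above it
   are reported as the origin, and their 10–20 electrode-name prefixes
   vote for a cortical lobe (FP/F → frontal, T → temporal, C → central,
   P → parietal, O → occipital; boundary sites such as FT vote for both).
5. **Evaluation**: any-overlap event matching. TP = annotated seizures hit
   by at least one detection, FN = annotated seizures missed, FP =
   detections touching no annotation, TN = roster records with neither
   (record-level accounting; an hour-segment unit is available). Derived
   metrics: accuracy, specificity, sensitivity, precision, F-measure
   (harmonic mean of precision and sensitivity) and G-mean (geometric mean
   of sensitivity and specificity), all in percent, plus false positives
   per hour.

An assisted-manual path accepts externally picked onset/offset second
pairs in place of steps 3's peak rules; picks shorter than `width_min_s`
are flagged as not-a-seizure, and the same merge/minimum-length rules
apply.

## Parameters

| name | default | units | role |
|---|---|---|---|
| `lp_cutoff` / `lp_order` | 35 / 50 | Hz / – | noise/EMG low-pass before averaging |
| `powerline_f0` | 60 | Hz | mains notch (50 for European recordings; can be disabled) |
| `powerline_q` | 30 | – | quality factor of each notch section |
| `dc_lambda` | 0.9991 | – | DC-notch pole radius; −3 dB ≈ 0.037 Hz single-pass at 256 Hz |
| `band_lo` / `band_hi` | 0.1 / 4.1 | Hz | feature band around the ictal rhythm |
| `ff_order` | 30 | – | feature-filter FIR order |
| `rms_window` | 150 | samples | envelope window (~0.59 s at 256 Hz) |
| `seizLinterval` | 256 | samples | minimum epoch length and merge gap (1 s at 256 Hz) |
| `seizAggressiveness` | 200 | µV²·s | in-band power gate; useful range 180–220 |
| `amp_lower` | 0.075 | fraction of 1 | epoch-extent threshold; usual range 0.05–0.1 |
| `amp_upper` | 0.9 | fraction of 1 | onset-peak height threshold; usual range 0.8–1 |
| `width_min_s` / `width_max_s` | 0.4 / 1.8 | s | admissible onset-peak width |

Two calibration facts worth knowing. First, `seizAggressiveness` is
expressed in *unnormalized* channel-average units (µV²·s, integrated over
the candidate's half-prominence support), so it scales with montage size:
the background of an n-channel average shrinks as 1/√n, and the 180–220
range presumes a ~23-channel montage. Second, `amp_upper` acts on the
*per-record normalized* envelope, so it implicitly assumes that every
seizure onset in a record reaches a similar envelope amplitude; records
mixing events of very different amplitude need a lower `amp_upper`.

The duration rule (0.4–1.8 s) bounds the **onset-peak width**, not the
epoch duration — detected epochs routinely run 30–120 s. For manual picks
only the lower bound applies (a picked pair of 95 s is a seizure; one of
0.2 s is not).

## The synthetic generator

Real annotated EEG archives cannot ship with the package, so every claim
is exercised on a seeded generator (`seizefeat.simulate`) that emulates
the signal classes the detector must separate:

* pink-noise background (1/f spectral shaping; 30 µV SD per channel) with
  10 Hz alpha bursts, per-channel DC offsets (±50 µV), slow drift
  (15 µV below 0.05 Hz) and common-mode 60 Hz mains (8 µV);
* ictal events: a 1–4 Hz rhythmic discharge with a second harmonic
  (a spike-and-wave caricature) on a 6-channel subset at 8× background
  amplitude, ramped in and out, and opened by a stereotyped 3 Hz polyspike
  onset burst at 2.5× the sustained amplitude for 0.8 s. The stereotyped
  onset is a deliberate modelling choice: onsets are far more uniform than
  the evolving rhythm that follows, and it is what makes a near-1 onset
  threshold meaningful when one record holds several seizures;
* jaw/EMG artefacts: 0.1–0.3 s bursts at 20–35 Hz and 100 µV on a fixed
  *fraction* (~a quarter) of the montage, so their weight in the channel
  average is montage-size independent.

Generated ictal segments carry at least 3× the in-band RMS of the adjacent
background on their channels (asserted at generation time). Corpora are
keyed by (seed, record index); roughly one record in three is
seizure-free so the false-positive rate is measurable.

What the generator does **not** emulate: age-dependent (infant) rhythms,
electrode pops and detachment, chewing/ocular artefact morphology beyond
band-limited bursts, inter-channel correlation structure of real scalp
fields, and seizures whose onset lacks a high-amplitude discharge. Passing
the synthetic recovery suite therefore demonstrates that the
implementation realizes the method's mechanics — it is not a clinical
performance claim. The companion script `scripts/chbmit_report.py` runs
the identical pipeline over a user-supplied CHB-MIT download for external
validation.

## Numerical choices

* **Zero-phase filtering.** FIR stages use forward–backward filtering with
  odd-reflection padding (exactly symmetric already). IIR stages
  (power-line notch sections, DC notch) use a symmetrized form,
  ½·(F(x) + rev(F(rev x))), which commutes with time reversal *exactly*
  (reversal swaps the two terms) while preserving the squared magnitude
  response and the DC notch's exact null. IIR padding is *even* (mirror)
  reflection: odd reflection hands the padding a spurious mean of
  2·x₀ − (local mean), which the λ = 0.9991 pole drags into the record as
  a multi-second low-frequency transient — with common-mode mains this
  artefact survives channel averaging and can fake an onset peak. A causal
  mode (plain `lfilter`) is available for real-time-style processing.
* **Filter designs.** The 35 Hz low-pass is a Hamming windowed-sinc. The
  4.1 Hz feature low-pass is a least-squares design (passband 0–`band_hi`,
  stopband from `band_hi` + 12 Hz): at order 30 a windowed-sinc sags
  several percent by mid-band, while least-squares holds the passband to
  ~2% after forward–backward application. The 0.1 Hz high-pass stage
  exists behind `highpass_enabled` but is off by default — an order-30 FIR
  cannot act at 0.1 Hz at fs = 256, and the recursive DC notch already
  owns the low band edge (with it, the feature filter behaves as the
  low-pass alone).
* **Moving RMS** is centered; sample i averages
  x[i−74 … i+75] (for the even default window of 150), shrinking at the
  record edges so output length equals input length. Envelope steps are
  bounded by max|x|/√window in the interior.
* **Peaks.** Plateau peaks take the leftmost sample as the index (scipy's
  convention); widths are measured at half prominence; candidates clipped
  by the record boundary are evaluated on the available support.
  Candidate power is integrated over the half-prominence support because
  the power gate runs before any epoch extent exists; the full-epoch power
  is recomputed after growth and stored on the epoch.
* **Degenerate inputs.** An all-zero record yields a zero envelope with
  normalization factor 0 (no division error) and no detections; empty
  epoch sets produce header-only detection tables; metrics with zero
  denominators raise an undefined-metric signal and render as null, never
  as 0 or 100.
* **Time conventions.** Sample indices are 0-based; intervals are
  half-open [start, end) in samples internally; annotation files use
  seconds from record start, converted by floor(onset·fs) / ceil(end·fs).
* **EDF writing** quantizes to 16 bits with a symmetric physical range
  taken from the data and a symmetric digital range (±32767), so digital 0
  is exactly physical 0 and the round-trip error is bounded by half a
  quantization step.

## Open design points, as resolved here

* The "baseline discontinuity" that marks a seizure is operationalized as:
  an onset peak of height ≥ `amp_upper` with half-prominence width in
  [0.4, 1.8] s, whose surrounding envelope region ≥ `amp_lower` becomes
  the epoch. This is consistent with both the narrow onset-duration rule
  and multi-ten-second detected epochs.
* `amp_upper` is read as an onset threshold from below (a peak must be at
  least this tall), not as a saturation-rejection ceiling.
* Localization uses the rectified, feature-filtered per-channel trace (the
  same transform the detector applies to the average). The literal
  above-the-median rule selects up to half the montage by construction; a
  `margin` multiplier on the median (default 1.0 = literal rule,
  1.5 recommended for sparse selections) is exposed, and all per-channel
  scores are reported so users can re-threshold.
* Per-patient lobe labels are the plurality over that patient's epochs;
  two-way lobe ties produce compound labels (e.g. temporo-occipital),
  wider ties produce "mixed".
* Dataset-level summaries report both the unweighted mean of per-patient
  metrics (the benchmark-table footer convention) and the metrics of the
  pooled counts; the two generally differ and are labelled.

## Problem sizes

The parameter-recovery benchmark (`seizefeat.validation.parameter_recovery`,
also run by `scripts/acceptance.py`) simulates 50 records of 10 minutes at
23 channels / 256 Hz — a 1/6-scale stand-in for hour-long clinical files
that keeps the full benchmark under two minutes on one CPU while leaving
room for one to three full-length (30–120 s) seizures per record.
False positives per hour are computed over the actual simulated hours
(50 × 1/6 h), not inflated to hour-equivalents.

## Known limitations

* The power gate's absolute units tie the 180–220 range to ~23-channel
  montages; other montage sizes need a rescaled gate.
* Per-record normalization plus a high `amp_upper` assumes comparable
  onset amplitudes within a record; a weak seizure sharing a record with a
  much stronger one can be missed — consistent with the method's reported
  misses on brief or atypical events.
* Background/artefact coincidences occasionally clear the power gate in
  seizure-free records; the observed synthetic false-positive rate
  (≤ ~0.5/h, usually far lower) is the direct analogue of the method's
  documented false-detection rate on real data.
* Infant EEG, heavy movement artefact, and electrode-failure segments are
  outside both the generator and the method's stated operating envelope.
* The evaluator's record-level TN accounting follows the benchmark-table
  convention; it makes specificity depend on how recordings are split into
  files.
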