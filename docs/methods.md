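# Methods

## Scope and model

The package predicts SSRI treatment response (R vs NR, defined by a ≥50 %
pre/post BDI-II improvement) from pre-treatment resting EEG, and separately
discriminates MDD patients from healthy controls. The pipeline is:
band-pass + notch filtering → average reference → resampling to 140 Hz →
epoching → `db4` wavelet decomposition (delta/theta coefficients as
features; STFT, EMD, Welch PSD, coherence and P300 as comparison families)
→ z-scoring against the healthy-control sample → ROC rank-based feature
selection with correlation pruning (mRMR as the comparison selector) →
logistic regression → 100×10-fold stratified cross-validation → Wilcoxon
rank-sum scalp maps and PCA scatter.

## The synthetic cohort generator

No patient EEG is deposited, so the study conditions are emulated by a
generator whose defaults mirror the study design: 34 patients (16 R / 18 NR,
sexes balanced), 30 controls, 19-channel 10–20 montage, 256 samples/s, EC
and EO conditions, and BDI-II pre/post scores drawn from group-conditional
normals (means/SDs of the clinical table) under the constraint that the 50 %
rule reproduces the group label.

**Signal model.** Each channel is a sum over the five classical bands
(delta 0.5–4, theta 4–8.5, alpha(+low-beta) 8.5–17.5, beta 17.5–35, gamma
35–70 Hz) of band-limited Gaussian waveforms plus a 1/f background
(default 4 µV RMS) and optional blink/50 Hz artifacts. Default band RMS
amplitudes are 20/12/10/6/3 µV; the alpha amplitude doubles under EC
(Berger effect). Subject s's band-b amplitude at channel c is
`A_b · exp((μ_g + ε_{s,c,b})/2)` with `ε ~ N(0, σ²)`, σ = 0.3 (between-
subject SD of log band power, a typical inter-subject variability scale).
The treatment effect is planted as `μ_R − μ_NR = d·σ` in delta/theta
log-power at the effect channels (default F7, F8, T4; d = `effect_size`,
default 1.5). Controls sit `mdd_effect_size·σ` below the patient mean at
those channels so the diagnosis task is non-degenerate.

**Cohort-common waveforms.** The band waveform of each (channel, band,
condition) is a single unit-RMS template shared by the whole cohort and
scaled per subject; `waveform_idiosyncrasy` (default 0) mixes in
subject-specific band noise. This rank-one structure is deliberate: the
discriminative analysis ranks *individual time-locked wavelet
coefficients*, and for per-subject random-phase noise every coefficient is
symmetric about zero, so a group difference in band *power* (a variance
difference) is invisible to a per-coefficient ROC criterion
(P(X > Y) = ½ for symmetric zero-mean variables of any scales). Planted
amplitude effects reach the coefficient level only insofar as waveforms are
reproducible across subjects, which is what the generator's default
encodes. Consequences to keep in mind:

* Band powers, their planted group contrast, EC/EO modulation, spectra and
  coherence behave like the stated band model regardless of the template
  structure (the Welch log-power contrast oracle is exact up to a small 1/f
  dilution, because the template's in-band capture factor cancels in the
  log-power difference).
* Real resting EEG has no cohort-common phase; passing the recovery and CV
  suites demonstrates that the pipeline's selection and validation machinery
  is correct and leak-free under its own premises, not that raw wavelet
  coefficients would discriminate on real recordings.

**Artifacts.** Blinks are a stereotyped biphasic template injected at
Poisson times, maximal at Fp1/Fp2 with exponential spatial falloff; line
noise is a fixed-amplitude 50 Hz sinusoid with random phase. Both default
off. There is no volume-conduction head model.

## Preprocessing

* Zero-phase 4th-order Butterworth band-pass (0.1–70 Hz) followed by a
  2nd-order IIR notch (50 Hz, Q = 30), both forward-backward. No filter
  family is canonical here; Butterworth keeps the passband flat.
* Average reference replaces the infinity/REST reference, which requires a
  head model; the two have been reported comparably efficient, and linked-
  ear passthrough is available.
* Resampling to 140 Hz places the 5-level dyadic band edges at
  4.375 / 8.75 / 17.5 / 35 / 70 Hz, i.e. on the printed delta/theta band
  boundaries (≈4 and ≈8.5 Hz). Native-rate analysis is a config switch.
* Epoch = first 120 s of the cleaned record by default (which 2-minute
  window of the 5-minute protocol is used is otherwise arbitrary).
* A simple amplitude-threshold window-rejection utility exists (off by
  default); model-based ocular correction is out of scope.

## Feature extraction

* **DWT.** `pywt.wavedec`, symmetric extension, 5 levels of `db4`. Block
  lengths follow `l_k = floor((l_{k−1}−1)/2) + 4`. Blocks are named by the
  band containing their dyadic centre frequency, so at 140 Hz the final
  approximation plus the level-5 detail cover delta (0–4.375 Hz) and the
  level-4 detail is theta (4.375–8.75 Hz); alpha/beta/gamma blocks are
  discarded by default. (The source material's block labels are
  inconsistent — a 5-level decomposition is prescribed but the two lowest
  blocks are labelled A4/D4; the frequency semantics of the printed band
  table are authoritative here, and a 6 Hz tone indeed lands in the
  theta-mapped block.)
* **STFT.** Hamming window, 2 s window, 0.5 s hop (the more specific of two
  stated overlaps; configurable), 4096-point FFT; features are log10 band
  powers per frame for delta and theta.
* **EMD.** Envelope-mean sifting with cubic splines through maxima/minima,
  extrema mirrored beyond the boundaries (otherwise spline divergence at the
  edges corrupts every IMF). A candidate is accepted when the normalised
  squared difference between successive siftings falls below 0.2 *and* the
  two IMF conditions hold (|#extrema − #zero-crossings| ≤ 1, |mean|/RMS
  < 0.05); decomposition stops when the residue has fewer than two maxima or
  minima. Feature IMFs are those whose full-length-periodogram dominant
  frequency lies in delta/theta; IMFs below 1 % of the strongest IMF's
  energy are ignored as boundary artifacts. The exact EMD feature is not
  pinned down by the source; IMF samples are used, with the selection rule
  above.
* **Coherence.** Welch/CSD with 2 s segments and 50 % overlap, evaluated on
  the 2–30 Hz grid at 1 Hz steps; at least two averaging segments are
  required (a single segment gives the degenerate C ≡ 1).
* **P300.** Target-locked epochs, 100 ms pre-stimulus baseline, positive
  peak (not max |·|) of the average in 300–700 ms.

## Selection

* The ranking statistic is the ROC staircase sum from the printed
  pseudo-code: stable descending sort, cumulative tp/fp, trapezoid
  `auc = Σ Y·X − ½`. On tie-free data this equals Mann–Whitney AUC − ½
  exactly (verified against exhaustive pair counting); under value ties the
  stable sort makes the staircase order-dependent, ties being broken by
  original instance index.
* Ranking is by |auc| (signed values are kept in the trace); |auc| ties
  break by column index for determinism.
* Correlation pruning walks the ranking top-down and drops any feature with
  |Pearson r| ≥ 0.9 against an already-kept one (threshold not stated in the
  source; 0.9 is the package default, configurable). With the rank-one
  generator, coefficients within one channel-band are exactly collinear, so
  pruning is what lets the classifier combine several effect channels.
* mRMR uses 3 equal-frequency bins and the MID criterion (relevance minus
  mean redundancy), parameters the cited method leaves open.
* Selection scope: inside cross-validation, ranking/pruning always happen on
  the training fold only; whole-dataset ranking (used for the trace and the
  maps) is a separate, explicitly global computation.

## Classification and validation

* Logistic regression by maximum likelihood; an L2 term of strength 1e−6
  (sklearn C = 1e6) is a numerical guard against perfect separation, not
  regularization. Decision rule: R iff F(z) strictly exceeds 0.5.
* 10-fold stratified CV, 100 repeats with re-randomised folds; per-fold:
  standardize on training rows, rank/prune/select top-k on training rows,
  fit, evaluate the untouched test fold with train-derived statistics and
  indices. Confusion counts pool per repeat; metrics are mean ± SD over
  repeats; undefined metrics (empty denominators) are NaN, never 0.
* EC and EO instances of one subject share a fold by default
  (`group_by_subject`), preventing identity leakage; the row-level scheme is
  available for fidelity to the 68-instance design.
* The permutation null draws a fresh subject-level label permutation per
  repeat; a single fixed permutation on n = 34 retains chance correlations
  and sits visibly above the majority-class rate.
* Whether the control-based normalization was re-fit per fold in the source
  is unstated; when a control reference is supplied it is fit once on the
  (external) control sample, otherwise per-fold training statistics are
  used.

## Maps and scatter

* Per channel, instances are summarised by the mean of that channel's
  standardized features among the 100 top-ranked (all of the channel's
  features if none rank that high); groups are compared by a two-sided
  Wilcoxon rank-sum test at 5 %, giving the binary H per electrode, with
  optional sex/condition stratification. No correction across the 19
  channels by default (matching the per-channel 5 % maps); Benjamini–
  Hochberg is available.
* Normality gating uses a one-sample KS test of the standardized data
  against N(0,1).
* Interpolation: inverse-distance weighting of the two nearest electrodes on
  a schematic 2-D 10–20 layout; exact at electrode positions.
* The 2-D scatter uses plain linear PCA (the source's own implementation
  note names a plain principal-components routine despite the "kernel" name);
  first two components with variance-explained fractions.

## Numerical and size choices

* Truncation (not rounding) in the sample-size formula reproduces the
  printed n = 34 from 34.57.
* Monte-Carlo suites run on 10 s recordings with 8 s analysis epochs
  (≈3,000 delta/theta coefficients over 19 channels) — large enough for the
  planted d = 1.5 contrast to dominate, small enough to repeat 100 cohorts;
  the statistical conclusions (recovery rates, null calibration) do not
  depend on epoch length.
* All randomness flows through `numpy.random.default_rng` seeds; a fixed
  spec (including its seed) regenerates bit-identical cohorts.

## Known limitations

* The generator is a statistical stand-in, not electrophysiology: no
  volume conduction, no non-stationarity, no realistic artifact morphology
  beyond the stereotyped blink, and cohort-common band waveforms (see
  above).
* EDF files can be read (via mne) but not written; cohorts are exchanged as
  plain CSV.
* A reported per-channel wavelet coefficient count in the source (2825)
  is not reproducible from any stated length convention; coefficient counts
  here follow the declared recurrence.
* EMD at full recording length is expensive (spline envelopes per sifting
  pass); the wavelet path is the default for cohort-scale runs.
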