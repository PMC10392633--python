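# Methods

`ampero` quantifies quantal exocytosis from amperometric current
recordings. This note documents the models and procedures implemented,
the parameters that matter, the numerical choices, and what the
simulation-based tests do and do not demonstrate.

## Measurement model

Two recording modes are analysed identically downstream:

* **SCA (single-cell amperometry).** A disk carbon-fibre electrode is
  apposed to a cell; during a high-K⁺ stimulation window each exocytotic
  event produces a transient oxidation-current spike. A spike's charge
  reports the number of molecules *released* by one vesicle fusion.
* **IVIEC (intracellular vesicle impact electrochemical cytometry).** A
  nanotip electrode inside the cell adsorbs and ruptures vesicles; each
  spike's charge reports the number of molecules *stored* in one
  vesicle. Events are not locked to any stimulus.

Charge converts to a molecule count by Faraday's law, Q = n·N·F, with
n = 2 electrons for catecholamine oxidation (configurable), F = 96,485
C/mol, and N in moles scaled by Avogadro's number:

    molecules = Q / (n·F) · N_A          (Q in coulombs)

so 1 pC ↔ 3.121 × 10⁶ molecules at n = 2, and a 105,000-molecule event
carries ≈ 33.6 fC.

The **fraction of vesicular release** for a condition is the ratio of
the mean molecules released per SCA event to the mean molecules stored
per IVIEC vesicle, in percent. It is a ratio of group means: SCA and
IVIEC cells are distinct populations, so no per-cell pairing exists.
Fractions are reported at full precision and rounded to the nearest
integer percent. A percentile bootstrap CI (cell-level resampling,
independent in the two groups) accompanies each fraction; at ~17 cells
per group its empirical coverage is ≈ 93% rather than the nominal 95%,
the usual small-sample behaviour of percentile intervals on ratio
statistics.

## Filtering and spike detection

1. **Binomial smoothing** to a 1-kHz bandwidth (default). One pass of
   the normalised kernel (¼, ½, ¼) has amplitude response
   H(f) = cos²(πf/fs); p passes give cos^(2p). Requiring the −3 dB
   point at or below the cutoff f_c yields

       p ≥ ln 2 / (4 · ln(1/cos(π·f_c/fs)))

   and the smallest such integer (≥ 1) is used — p = 1 at fs = 5 kHz,
   f_c = 1 kHz. Edges are reflected; DC gain is exactly 1.
2. **Noise floor**: 1.4826 × MAD of the block-median-detrended filtered
   current over a quiescent window (pre-stimulation segment for SCA,
   first 10% of the trace for IVIEC, at least 100 samples). The MAD
   estimator tolerates sparse contaminating spikes; on a clean Gaussian
   window it is a consistent estimator of the SD.
3. **Threshold**: local maxima of baseline-corrected current exceeding
   5 × noise SD (the conventional detection rule; configurable).
4. **Baseline**: medians over non-overlapping 50-ms blocks, linearly
   interpolated to the sample grid. Detection runs twice: a first pass
   against the naive block-median baseline yields preliminary event
   extents; the baseline is then re-estimated from event-free samples
   only (blocks more than half covered by events are dropped and
   interpolated across) and peaks/extents are re-derived. Without the
   second pass the baseline rides up inside events and truncates their
   tails. A trace wholly covered by events falls back to the straight
   line between its endpoints.
5. **Event extents**: each peak extends to the nearest run of three
   consecutive samples below baseline + 1 × noise SD on either side
   (half-open [onset, end), 0-based indices). Requiring a run rather
   than a single sub-threshold sample stops lone noise dips from
   clipping the decay tail.
6. **Merging and splitting**: two maxima belong to one event when the
   valley between them stays above half the lower maximum (noise ripple
   on a flank), or when they are closer than `min_separation` (default
   3 ms) without the valley reaching the boundary level; the higher
   peak is kept. Genuinely separate peaks with overlapping extents are
   split at the inter-peak minimum.
7. **False-positive filters** (a deterministic surrogate for manual
   trace curation): minimum charge 1 fC, minimum width 1 ms, and at
   least 3 samples on the rising segment. An optional `stim_only` mode
   restricts SCA events to [stim_start, stim_end + 1 s]; it is off by
   default, since whether events outside the window should be counted
   is a protocol choice.

## Per-spike quantification

Charge is the trapezoidal integral of baseline-corrected current over
the event extent, clipped below at zero (only oxidation current carries
released molecules); 1 pA·s = 1000 fC. Kinetic parameters are measured
on the filtered trace with sub-sample linear interpolation of level
crossings:

* `i_max` — baseline-corrected peak current (pA);
* `t_half` — width at 50% of i_max, first upward to last downward
  crossing (ms);
* `t_rise` — 25% → 75% upward crossings on the rising limb (ms);
* `t_fall` — 75% → 25% downward crossings on the falling limb (ms).

Multi-crossing flanks (residual ripple) use the first crossing on the
rising limb and the last on the falling limb. Events too short or too
truncated for crossing estimation keep their charge and carry NaN shape
parameters; they are excluded from shape statistics only.

Hard truncation of the tail at the boundary level L loses ≈ L·τ of
charge per event (τ the decay time constant) — ~3% on average at the
default simulation conditions, up to ~8–10% for events near the
detection threshold. The pipeline therefore adds back an exponential
tail estimate L·t_fall/ln 3 per event (t_fall/ln 3 recovers τ for a
first-order decay); this halves the mean charge error on simulated
spikes and removes most of the systematic deficit. The correction is
skipped when t_fall is unavailable, and `quantify_events` applies it
only when given the boundary level (`tail_level`), so the plain
integral remains accessible.

## Group statistics

The statistical unit is the **cell**: per-event measures are summarised
per cell (mean and median), and groups are compared on per-cell means
with the unpaired two-sided Mann–Whitney rank-sum test (exact null
distribution when there are no ties and n₁·n₂ ≤ 400, otherwise the
normal approximation with tie and continuity corrections; the method
used is recorded). A pooled-event mode is provided because comparisons
in this field are sometimes made on pooled events; the choice is a
flag, not a default guess. Group summaries are mean ± SEM
(SD/√n_cells). No multiple-testing adjustment is applied to the
pairwise tests. Significance is conventionally read at p < 0.05.

## Fura-2 Ca²⁺ traces

Input is per-ROI intensity time series (image segmentation is out of
scope). The ratio r(t) = (F340 − bg340)/(F380 − bg380) is computed per
cell after background subtraction; frames with non-positive corrected
F380 are flagged NaN and excluded. Curves are averaged across cells on
the first trace's time grid (linear resampling), giving mean ± SEM per
time point; optional baseline normalisation subtracts each cell's mean
ratio over the first 5 s (the conventional pre-stimulus baseline).
Absolute ratios are averaged by default. Any uniform frame rate is
accepted.

## Synthetic-data generator

The generator exists so the pipeline can be exercised and validated
without experimental recordings. It emulates the standard protocol:
5 kHz digitisation, a 5-s stimulation window after a 2-s lead-in (SCA),
or a 60-s unstimulated recording (IVIEC).

Per trace: event onsets are a Poisson process (default 3 events/s; 4/s
in the bundled four-condition experiment) inside the window (SCA) or
across the trace (IVIEC); molecule counts are log-normal with the
condition's target mean and CV 0.8 (amperometric quantal sizes are
right-skewed; a CV near 0.8 is consistent with reported cell-to-cell
SEMs); charges follow from Faraday's law; each event is rendered as a
difference-of-exponentials pulse

    i(t) = c · (e^(−t/τ_d) − e^(−t/τ_r)),   τ_d > τ_r > 0,

scaled so its integral equals the charge (defaults τ_r = 0.5 ms,
τ_d = 3 ms, giving t_half ≈ 2.5 ms — typical for dense-core vesicle
spikes). White Gaussian noise (0.3 pA SD) and a sinusoidal drift (2 pA
amplitude, period twice the trace length, random phase) are added. The
ledger records onset, charge, molecules, and the analytic template peak
amplitude per event.

These distributional choices are modelling conventions of this package:
real recordings pin down only summary statistics (per-condition means,
stimulation timing, noise scale). Recovery tests against the simulator
therefore validate the *analysis code* — detection, integration,
statistics — not any biological claim; real spikes have feet,
flickering pores, correlated noise and electrode drift that the
generator does not emulate.

The Fura-2 generator produces 90-s two-channel recordings at 5 Hz with
a 5-s baseline, a 5-s stimulus ramp of configurable ratio amplitude,
exponential relaxation (τ = 15 s), constant channel backgrounds and
per-channel Gaussian noise, for ≥ 30 cells by default.

**Reproducibility.** All randomness flows from `SimulationConfig.seed`
via `numpy.random.default_rng`; the RNG draw order (event count, onset
times, molecule counts, drift phase, noise) is part of the contract.
Cell *i* of a condition uses seed `base + i`; the pipeline offsets
conditions by 1000 and modes by 500. Because this scheme is additive,
two simulations whose base seeds differ by less than these offsets
share cell streams; the pipeline therefore first spreads its
experiment-level seed over the 31-bit range with
`numpy.random.SeedSequence`, so distinct pipeline seeds — even
adjacent integers — give statistically independent experiments. When
calling `simulate_condition` directly, space base seeds by
≥ 1000·n_conditions if independence matters.

## Statistical resolution of the end-to-end recovery

A recovered fraction's sampling SD is ≈ CV/√n_events × fraction per
group. At 20 cells × ~20 SCA events per cell (CV 0.8), the released
mean carries ≈ 4% relative SE, so a single four-condition pipeline run
recovers each fraction with σ ≈ 2.5–3.7 points — commensurate with the
±5-point uncertainty implied by typical reported group SEMs (e.g.
105,000 ± 6,000 released over 176,000 ± 10,000 stored). Tests of the
recovery therefore either average several independent replicate runs
or use more cells; the problem sizes used are stated alongside each
result. Detection introduces a small net bias on fractions (≈ −1
point): tail truncation lowers released and stored means by ~1.5–3%
each and mostly cancels in the ratio.

## Defaults at a glance

| Parameter | Default | Meaning |
|---|---|---|
| sampling_rate | 5000 Hz | digitisation rate |
| filter_cutoff | 1000 Hz | −3 dB point of the binomial filter |
| threshold_multiplier | 5 | detection threshold in noise SDs |
| boundary_multiplier | 1 | event-extent level in noise SDs |
| min_separation | 3 ms | peak-merge distance (shallow valleys) |
| min_charge / min_width | 1 fC / 1 ms | false-positive filters |
| n_electrons | 2 | catecholamine oxidation |
| event_rate | 3 /s | Poisson event rate (4 /s in the bundled experiment) |
| molecules_cv | 0.8 | log-normal quantal-size spread |
| rise_tau / decay_tau | 0.5 / 3 ms | spike template time constants |
| noise_sd / drift_amplitude | 0.3 / 2 pA | baseline noise and drift |

## Limitations

* No pre-spike foot or flickering-pore kinetics; no deconvolution of
  overlapping events beyond valley splitting (overlaps at high event
  densities bias charges low).
* Event-extent truncation at the boundary level biases charge low by a
  few percent, most for near-threshold events.
* The cell-vs-pooled aggregation ambiguity is exposed as a flag, not
  resolved.
* Fura-2 analysis stops at ratio units; no Kd-based calibration to
  absolute Ca²⁺ concentration.
* CSV trace round-trips are exact to ≤ 1e-9 relative error, not
  bit-exact (use HDF5 for bit-exact archiving).
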