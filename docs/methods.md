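# Methods

`carodop` is a software twin of a hands-free carotid pulsed-wave Doppler
monitor for circulation checks during cardiac arrest, paired with a
physiologically calibrated scenario simulator so that every stage — IQ
acquisition, multigate spectral processing, envelope tracing, beat-wise
hemodynamics, dual-transducer angle correction, flow-state detection, and the
hierarchical TAV~MAP statistics — can be built and validated with no animal
data. This note records the models, the parameters that matter, and the
design choices made where the problem was genuinely open.

## 1. Scenario simulator

### Beat waveform

A beat is parameterised by peak systolic velocity `S` (PSV), systolic
duration `Ts`, a post-systolic level `D0`, an end-diastolic level `E` (EDV,
signed), and the period `T` (all velocities cm/s, durations s). The shape is
a raised-cosine systolic lobe (`D0 → S → D0` over `Ts`) followed by a
half-cosine diastolic decay (`D0 → E` over `T − Ts`). Both segments average
to the midpoint of their endpoints, giving the closed form

    mean = D0/2 + fs·S/2 + (1 − fs)·E/2,      fs = Ts/T,

which is inverted per beat: given the TAV target from the TAV~MAP coupling
and the scheduled PSV and EDV, the generator solves
`D0 = 2·TAV − fs·S − (1 − fs)·E`. This guarantees the beat mean equals the
coupling exactly while the waveform still attains the scheduled PSV and ends
at the scheduled EDV. A constant diastolic tail at the end-diastolic level
was considered and rejected: at the hypotensive nadir (PSV 73, TAV 16,
EDV −29 cm/s) a constant tail of −29 cm/s drags the beat mean far below 16
unless systole occupies most of the cycle, which is unphysiologic. With the
decaying tail, reverse flow is a late-diastolic phenomenon (the velocity
crosses zero during the decay and flattens at `E` before the next upstroke);
the flattening (zero slope at beat end) is deliberate so "end-diastolic
velocity" is a well-defined plateau rather than a single sample.

### Vena cava occlusion (VCO)

Mean arterial pressure ramps linearly in time from `baseline_map` (default
86 mmHg) to `nadir_map` (23 mmHg) over the sequence, with multiplicative
per-beat noise (SD 1.5%). Whether the in-vivo decline was linear or
exponential is not recoverable from pressure summaries alone; linear was
chosen as the simplest monotone model. Systolic/diastolic pressures, PSV and
EDV follow fixed affine maps anchored at the calibration pairs

| quantity | baseline | nadir |
|---|---|---|
| MAP (mmHg) | 86 | 23 |
| SBP (mmHg) | 111 | 33 |
| DBP (mmHg) | 66 | 18 |
| PSV (cm/s) | 102 | 73 |
| EDV (cm/s) | +10 | −29 |
| TAV (cm/s) | ~37 | ~16 |

The EDV ramp activates only below a systolic pressure of 80 mmHg (reverse
flow onset) and reaches −29 cm/s at the nominal nadir SBP of 33 mmHg. TAV
couples to MAP as `TAV = 8.3 + 0.333·MAP` (cm/s; quadratic term available,
default 0), chosen so the coupling passes through (86, ≈37) and (23, ≈16).
Per-beat TAV noise defaults to 1 cm/s. Heart rate is fixed at 90 bpm
(anesthetized pig range); systole lasts 0.25 s. Sequence duration is trimmed
to whole beats so every truth record covers a complete cycle.

### VF episodes and true PEA

A VF episode is: pulsatile baseline beats until `vf_onset`; a 1.5 s
broadband marker (velocity → white noise, SD 30 cm/s — the fibrillating
myocardium scatters the Doppler spectrum before flow stops); a no-flow
plateau (velocity → zero-mean noise, SD 2 cm/s; arterial pressure collapses
to a non-pulsatile ~15 mmHg); and ROSC after a defibrillation delay drawn
uniform on [15, 60] s (or fixed via `defib_delay`), never exceeding 60 s of
untreated VF. ECG events stop at onset and resume at ROSC, and the record
always keeps ≥ 6 s of restored circulation so ROSC is observable. The
5-minute spacing between consecutive episodes is carried as configuration
(`vf_episode_gap`), one episode per record.

True PEA keeps organized ECG events at the configured rate while systolic
pressure sits at `pea_sbp` (20 mmHg) and velocity is near-pulseless around
`pea_velocity` (10 cm/s): "aphasic" flow is modelled as ≤ 20% ECG-locked
amplitude modulation plus 1 cm/s noise.

### Studies and the variance structure

A study draws per-animal intercepts (SD 9.381 cm/s), optional per-animal
MAP/MAP² slopes, and per-sequence intercepts (SD 2.449 cm/s), all added to
the TAV~MAP coupling of each generated VCO sequence. The long-format table
samples MAP (from the per-beat schedule) at 1 Hz and sets
`TAV = coupling + effects + ε`, ε i.i.d. with SD 2.449 cm/s — exactly the
two-level nested structure the mixed model assumes, with variance split
88 : 6 : 6 and hence population ICCs 0.88 / 0.94. The default layout is 7
animals with (6,6,6,6,6,6,5) sequences = 41 sequences; durations are drawn
uniform on [30, 69] s and rescaled to a 50 s mean. Per-sequence baseline and
nadir MAP vary biologically (SD 6 and 2.5 mmHg). Randomness flows from a
single root seed through per-sequence child streams (`numpy.SeedSequence`),
making every dataset bit-reproducible.

## 2. IQ forward model

Each of the two transducers (half-angle ±30°, carrier 4 MHz, unfocused
30 × 6 mm aperture) sees the flow at `φ_k = α ∓ 30°`, where α is the vessel
inclination. 32 range gates span 8–45 mm. For every gate whose center depth
lies inside the 5 mm lumen (centered at 22 mm), the baseband signal is a sum
of 50 scatterer phasors: scatterer `i` sits on the gate's chord at radius
`r_i`, moves at `v_i(t) = v_center(t)·(1 − (r_i/R)^4)` (blunted profile),
and contributes `exp(j·2π∫ 2 f0 v_i cosφ_k / c dt)`. Summing phasors with
random initial phases produces physical spectral broadening from the in-gate
velocity spread, which single-tone synthesis would not.

Clutter (wall echo) is a +40 dB near-DC tone whose phase wanders slowly
(band-limited to ~20 Hz); keeping the wander band-limited matters — white
phase noise would scatter clutter power across the whole spectrum and no
wall filter could remove it, which is a modelling artifact rather than
physics. Thermal noise is complex white at −SNR dB (default 20 dB) relative
to the unit flow signal. Gates outside the lumen carry clutter + noise only.
Depth-dependent attenuation, beam profiles and transmit focusing are not
modelled (unfocused aperture, uniform amplitude across gates).

PRF defaults to 15 kHz: below the range-ambiguity bound c/(2·45 mm) =
17.1 kHz and with Nyquist (7.5 kHz) above the fastest expected axial
velocity (PSV ~142 cm/s × cos30° → 6.4 kHz). The synthesizer checks the
Nyquist condition per transducer and warns or refuses (configurable).

## 3. Measurement chain

* **Wall filter** — 4th-order Butterworth high-pass at 100 Hz on slow time,
  applied zero-phase (effective 8th order): DC attenuated ≫ 40 dB, tones
  above twice the cutoff passed within 1 dB. Velocities whose Doppler shift
  falls under the cutoff (|v_axial| ≲ 2 cm/s) are invisible by construction —
  the *blind band* every pulsed Doppler device has.
* **Spectrogram** — 10 ms Hann window, 75% overlap, two-sided; frequency
  mapped to uncorrected axial velocity `v = c·f/(2 f0)`. Edge frames whose
  window leaves the record are dropped.
* **Colour M-mode** — per gate and 20 ms frame, mean velocity from the
  lag-one autocorrelation phase (`v̄ = c·prf·arg R(1)/(4π f0)`, the Kasai
  estimator) and mean power.
* **Gate selection** — score each gate by variance of its mean-velocity
  trace in the cardiac band (0.5–4 Hz) × mean power; ties break shallower;
  the no-flow sentinel fires when even the best gate's in-band RMS is below
  2 cm/s.
* **Envelope** — per frame, the noise floor is the median bin power; bins
  below floor + 6 dB are discarded. Per direction the candidate is the
  smallest |v| containing 95% of the above-noise power; the composite takes
  the direction with more above-noise power, signed. Frames without credible
  flow (above-noise/noise < 2) are set to 0 and flagged low-quality rather
  than dropped, and a 5-frame median filter removes single-frame outliers.
* **Beats** — systolic peaks by prominence (default 20 cm/s) with a 0.25 s
  refractory, found on a 60 ms moving average of the envelope so that
  sign-flicker around the blind band cannot fake systoles; onsets are the
  last pre-peak minimum (end-diastole). Inter-onset gaps longer than 3 s
  (< 20 bpm) are not beats. Beat segmentation is deliberately self-contained
  (envelope only, no ECG) so the device needs no other leads; ECG events are
  used only by the PEA classifier.
* **Indices** — per beat: PSV = max envelope, EDV = median of the last
  ~12 ms (signed), TAV = mean (signed by default; a forward-only flag
  exists), RI = (PSV−EDV)/PSV, PI = (PSV−EDV)/TAV (NaN when TAV = 0),
  HR = 60/period. All are computed on the uncorrected axial envelope, which
  is why RI, PI and HR are insensitive to the inclination angle: the cosφ
  factor cancels in ratios and timings.
* **Angle correction** — per beat, the two per-transducer TAVs invert the
  cosine projections:
  `α = atan[(tav1 − tav2)/((tav1 + tav2)·tanθ0)]`,
  `v = (tav1 + tav2)/(2 cosθ0 cosα)` — the unique two-unknown solution for
  the stated geometry, exact to round-off (the round trip is tested at
  1e-9). The same per-beat α corrects PSV and EDV (averaged over both
  transducers). Correction is applied after the per-beat stage, mirroring a
  post-hoc analysis workflow.
* **Flow states** — consecutive 2 s windows: *pulsatile* when a detected
  beat with PSV ≥ 20 cm/s peaks in the window; otherwise *low_flow_pea*
  when ≥ 2 ECG events fall in the window (organized rhythm without pulse);
  otherwise *no_flow*. The 20 cm/s and 12 cm/s thresholds and the 2 s
  window are device configuration, not literature-derived constants.

## 4. Statistics

`fit_lmm` fits `TAV ~ MAP + MAP²` (MAP centered and scaled internally;
coefficients returned on the raw scale) with animal random intercepts and
sequence-within-animal variance components via `statsmodels` MixedLM;
REML is the default (with 7 animals, ML's downward bias in the animal
variance is material), ML is available. Random MAP/MAP² slopes per animal
can be added, but because the ICC is then no longer constant in MAP, ICCs
are **always** computed from the intercepts-only decomposition

    ICC_animal = σ²_a / (σ²_a + σ²_s + σ²_e),
    ICC_within = (σ²_a + σ²_s) / (σ²_a + σ²_s + σ²_e),

with the slope variances reported alongside. Confidence intervals use a
parametric bootstrap (default 200 refits on datasets simulated from the
fitted components over the observed design) because the sampling
distribution with ≤ 7 animals is far from normal; a warning flags > 20%
refit failures. Per-animal prediction curves (fixed polynomial + animal
intercept BLUP) are evaluated over each animal's observed MAP range and
refuse extrapolation beyond a 10% margin.

With 7 animals the ICC estimator is noticeably concave in the animal
variance, so the replicate mean of the estimated animal ICC sits slightly
below the population value (≈ 0.85 vs 0.88 over 20 replicates) — a
small-sample property of the estimator, not a calibration error.

## 5. Synchronization and formats

The acquisition and monitoring clocks share an electrical sync pulse every
6 s (jitter SD 5 ms). `align_clocks` matches pulse events by nearest
neighbour after a coarse median offset and fits `b = offset + (1+drift)·a`
by least squares; periodicity makes the offset identifiable only modulo one
interval, which overlapping recordings of the same pulses satisfy. Traces
and per-beat truth go to CSV, IQ to HDF5 (`/iq/t{1,2}/gateNNN` + `/meta`),
statistics to JSON; every CLI run writes a manifest (seed, config hash,
package versions, SHA-256 of all inputs/outputs) and all writers round-trip
exactly, including NaN sentinels.

## 6. What the simulator does and does not show

Passing tests demonstrate that the measurement chain recovers what the
forward model encodes: calibrated pressure/velocity anchors, beat counts,
event timing, variance structure. The simulator does **not** reproduce probe
repositioning or contact loss, chest-compression artifact, ECG waveform
morphology (events only), respiratory modulation, depth-dependent
attenuation, or inter-species waveform differences; recovery results
therefore bound algorithmic, not clinical, performance. Known limitations:
the blind band under the wall filter makes near-zero EDV unobservable (EDV
recovery is specified only for |EDV| above ~12 cm/s); the envelope's
percentile threshold biases extreme velocities by up to ~1 bin width; and
the angle inversion degrades as tav1 + tav2 → 0 (indeterminate at exactly
zero, rejected with an error).

## 7. Problem sizes used in validation

The packaged checks run the statistics at full scale (20 replicate studies
of 7 × 6 sequences × 60 s) and the signal chain at two scales: full default
geometry (32 gates, 15 kHz PRF, 50 s sequences) for the 10-sequence
calibration-recovery run, and a reduced probe (8 gates spanning 16–28 mm,
12 kHz PRF) for unit and event-detection tests, which preserves the physics
(the carotid gate layout around 22 mm and a Nyquist margin above the fastest
baseline systole) at a fraction of the compute.
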