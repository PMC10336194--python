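# carodop

A virtual hands-free carotid pulsed-wave Doppler monitor, built for studying
automated circulation checks during cardiac arrest.

Manual carotid pulse palpation during CPR is slow and unreliable, and
pulseless electrical activity (PEA) is frequently misdiagnosed. A fixed,
hands-free dual-transducer Doppler patch over the common carotid artery can
track blood velocity continuously — through controlled hypotension, through
ventricular fibrillation (VF) and defibrillation, and in true PEA — without
an operator. `carodop` implements that device as software and pairs it with
a physiologically calibrated scenario simulator, so the entire chain is
testable end to end with no animal or patient data:

1. **Scenario simulator** (`carodop.scenarios`) — paired arterial-pressure /
   centerline-velocity traces with per-beat ground truth: vena-cava-occlusion
   (VCO) hypotension (MAP 86 → 23 mmHg with growing reverse diastolic flow),
   VF episodes (flow cessation, defibrillation ≤ 60 s, ROSC), true PEA
   (organized ECG, SBP ≈ 20 mmHg, ~10 cm/s flow), plus full multi-animal
   studies with nested random effects and a 6 s two-clock sync-pulse channel.
2. **IQ forward model** (`carodop.synthesize`) — dual-transducer (±30°),
   32-gate (8–45 mm), 4 MHz complex-baseband synthesis by scatterer-phasor
   sums over a blunted lumen profile, with wall clutter and thermal noise.
3. **Measurement chain** (`carodop.processing`) — slow-time wall filter,
   spectrogram, colour M-mode (lag-one autocorrelation velocities), automatic
   gate selection, maximum-velocity envelope tracing, beat detection,
   per-beat PSV/EDV/TAV/RI/PI/HR, and flow-state classification
   (pulsatile / no_flow / low_flow_pea).
4. **Angle correction** — the two per-transducer time-averaged velocities
   (TAVs) invert the cosine projections exactly:

       tav_k = v · cos(α ∓ θ0)
       α = atan[(tav1 − tav2) / ((tav1 + tav2) · tan θ0)]
       v = (tav1 + tav2) / (2 cos θ0 cos α)

   RI = (PSV−EDV)/PSV, PI = (PSV−EDV)/TAV and HR are ratios/timings of
   velocities sharing the cos φ factor and are therefore angle-invariant.
5. **Study statistics** (`carodop.stats`) — two-level linear mixed model
   TAV ~ MAP + MAP² with animal and sequence-within-animal random
   intercepts (optional random slopes), variance-component intraclass
   correlations

       ICC_animal = σ²_a / (σ²_a + σ²_s + σ²_e)
       ICC_within = (σ²_a + σ²_s) / (σ²_a + σ²_s + σ²_e)

   with parametric-bootstrap confidence intervals and per-animal
   TAV-vs-MAP prediction curves.

## Worked example

`examples/` holds one short script per capability. Angle correction
(`python examples/03_angle_correction.py`):

```
true flow: 50.0 cm/s at 10.0 deg inclination
per-transducer TAVs: 46.985, 38.302 cm/s
recovered: 50.000 cm/s at 10.000 deg

TAVs (40, 20) cm/s -> inclination 30.0 deg, speed 40.0 cm/s
```

A 2:1 TAV ratio at the 30° half-angle means the flow axis is tilted 30°
toward transducer 1 (cos 0° = 1 vs cos 60° = 0.5).

Hierarchical statistics (`python examples/04_study_statistics.py`), on a
simulated 7-animal study whose generator variance split is 88 : 6 : 6:

```
study: 7 animals, 42 sequences, 2520 1 Hz observations
fixed effects: TAV = 2.97 + 0.354*MAP + -1.90e-04*MAP^2
variance components (cm^2/s^2): animal 116.8, sequence 5.9, residual 5.8
ICC animal : 0.91 (95% CI 0.66-0.95)
ICC within : 0.96 (95% CI 0.83-0.98)
```

The animal ICC is the share of TAV variance (at fixed MAP) attributable to
animal identity; the within-animal ICC adds the sequence level. The other
examples run the full virtual device on a hypotension sequence
(`02_virtual_device.py`) and classify a VF episode's flow states
(`05_flow_state_detection.py`).

A thin CLI mirrors the library for shell use:

```bash
carodop simulate  --config cfg.yaml --seed 1 --out run/
carodop synthesize --traces run/traces.csv --seed 1 --out run/
carodop process   --iq run/iq.h5 --ecg run/traces.csv --out run/
carodop analyze   --table study_table.csv --out run/
carodop e2e       --config cfg.yaml --seed 1 --out run/
```

Every run writes a manifest (seed, config hash, SHA-256 of all outputs);
exit codes are 0 ok / 2 config / 3 data / 4 convergence.

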