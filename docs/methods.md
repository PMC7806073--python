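# Methods

## Force model

The blade is modelled as a zero-thickness rectangular plate
(`blade_length × blade_height`, default 0.45 m × 0.25 m) at the end of a
rigid oar (`oar_length`, default 2.0 m) pivoting at the oarlock, in a
right-handed frame with x = boat forward and z = up. The horizontal oar
angle θ and vertical (elevation) angle δ set the oar direction
`u = (sin θ cos δ, cos θ cos δ, sin δ)`; low δ puts the blade in the
water. The longitudinal angle φ rotates the blade face about the oar
axis and is 0 (squared blade) for the task, though the API accepts any
value.

Forces are applied at a single blade reference point at `oar_length`
along the oar axis; no chord-wise force distribution is modelled. The
blade velocity relative to the water is the analytic time derivative of
that point in the boat frame plus the stream `boat_velocity · x̂` (the
boat itself is treated as fixed to a platform; boat speed is an
exogenous input, and there is no hull-drag or boat-dynamics model). The
angle of attack α ∈ [0°, 180°] is measured between the relative flow and
the blade chord (the oar axis): 0° is edge-on flow toward the tip, 90°
face-on.

Drag and lift magnitudes follow the quasi-steady plate law
`½ C ρ A_p |V|²`. The projected areas are orthographic: the face area
times |cos| of the angle between the face normal and, respectively, the
flow direction and the lift direction. The lift direction is the
component of the face normal perpendicular to the flow. At exactly zero
relative velocity both areas default to the full face area; the forces
are zero regardless.

The C_D/C_L lookup table is a configurable input (two-column CSV over an
α grid covering [0°, 180°], linear interpolation). The shipped default is
an *approximation*, not a calibrated blade table: smooth flat-plate-like
profiles `C_D = 2 sin²α` and `C_L = sin 2α` (drag peaking face-on, lift
peaking near 45° and vanishing in symmetric flow). Users with a measured
blade characteristic should load their own table.

## Reference stroke

The reference is a stylised stand-in with the task's specification —
period 2.5 s, spans 44° (θ) and 12.5° (δ), C² continuity — not a
recording of an expert stroke, which is unavailable. Both angles follow
a normalised periodic waveform; δ trails θ by 0.3 of a cycle, which
closes the (θ, δ) loop and places the δ minimum inside the drive
(in-water) phase. With the default single harmonic the waveform is a
pure cosine, so the peak-to-peak spans are exact by construction and the
extremes land on samples whenever `period·rate/2` is an integer. More
harmonics (a decaying cosine series) skew the drive/recovery asymmetry;
their span is normalised numerically on a dense grid (10⁵ points per
cycle, accurate far below the 1e-6 span tolerance).

Phase boundaries partition the cycle as catch 10%, drive 40%, release
10%, recovery 40% — a typical rowing split, configurable, since the true
phase durations are not published.

Sampling convention: a run of duration T at rate f contains `round(T·f)`
samples `t = 0 … T − 1/f` (right-exclusive), so each sample owns one
1/f slot and 120 s at 100 Hz is exactly 12 000 rows. The first sample
sits at the catch.

## Segmentation and cycle duration

Cycle boundaries are local minima of θ (the catch), at least
`min_cycle_separation_s` apart (default 1.5 s, rejecting noise-induced
double boundaries; half the nominal 2.5 s stroke is a safe margin for
the whole 22–26 spm band). Two edge rules make the segmentation
consistent with the sampling convention: the first sample counts as a
boundary when it is a one-sided minimum, and the trailing segment after
the last boundary counts as a final cycle when it holds at least 90% of
the median inter-boundary sample count.

A cycle's **duration** is defined as the span it occupies — the distance
to the next catch, `n_samples / rate` — rather than `t_last − t_first`
of its samples. With right-exclusive cycles the two differ by one sample
period; the chosen definition is the one under which a run of n whole
periods segments into exactly n cycles of exactly the nominal duration,
so stroke counts and cadences come out whole (48 strokes and
24.000 strokes/min for a noiseless 120 s run, not 47 and 24.1).

## Filtering

Per run, the first three and the last cycle are dropped (transition
from inactivity to rowing and back), then any cycle whose implied rate
60/duration lies outside the instructed 22–26 strokes/min band —
inclusive at both ends — is removed. Runs with zero survivors are
flagged with a warning and propagate NaN metrics; they are never
silently dropped from a metrics table.

## Normalised DTW

All four metrics use one dissimilarity: the minimum over admissible
warping paths (monotone unit steps, matched endpoints) of

```
(sum of local distances along the path) / (path length).
```

Normalising inside the minimisation makes the "average deviation per
matched pair" well-defined; the common alternative — plain DTW followed
by division by the length of *a* backtracked optimal path — depends on
tie-breaking among equal-cost paths. The fractional objective is solved
exactly by Dinkelbach iteration: repeated ordinary DTW passes on shifted
costs `d − λ`, updating λ to the cost/length ratio of the optimal
shifted path; with finitely many paths it terminates at the optimum,
in practice in 2–4 passes. The inner dynamic program is numba-compiled
(a 250×250 pair costs ~1 ms).

Local distance is Euclidean: in degrees on (θ, δ) points for the spatial
metrics, with θ and δ weighted equally (no published weighting), and
absolute difference on 1-D speed values for the velocity metrics. A
`temporal_shift_weight` term (penalty on the normalised-time offset of
matched pairs) exists in the local cost; the pipeline runs it at zero,
scoring shape only while the path monotonicity preserves causal order.

Velocity profiles are computed after resampling to 250 points, as the
magnitude of the angular velocity (θ̇, δ̇) in deg/s via central
differences over a time axis spanning the cycle's true duration — so a
stroke rowed fast scores a velocity error even though its resampled path
is unchanged. Angular space is used because the evaluation is defined on
the recorded oar angles.

Error metrics average each valid cycle's DTW distance to the resampled
reference stroke; variability metrics average over all unordered pairs
of the run's own cycles (leave-one-out designs would need a mean
trajectory, which DTW does not supply cheaply; pairwise means are
symmetric and comparable across runs).

## Synthetic rower

What the generator emulates, per stroke k of a run:

- duration `period · tempo_scale + N(0, cadence_jitter_sd)`, clipped to
  [0.6, 1.6] of the nominal period; optionally, with probability
  `outlier_rate`, an out-of-band duration (3.0 or 2.0 s) to exercise the
  cadence filter;
- angles = reference waveform at the within-cycle phase, plus a
  systematic bias pattern (one sinusoid per angle with per-run random
  phase, amplitude `spatial_bias_deg`, identical in every cycle), plus
  smooth per-cycle noise — random coefficients on
  `cos(2πku) − 1` and `sin(2πku)`, k ≤ 3, scaled to RMS
  `spatial_noise_deg`. All noise terms vanish at the cycle boundaries,
  so strokes join continuously and the catch sample itself is
  unperturbed (white noise on angles would be unphysical and would
  corrupt catch detection);
- density effect: departing from the nominal 1100 kg/m³ applies a
  monotone within-cycle time warp of amplitude
  `density_sensitivity · |ρ − 1100|` (capped at 0.9), which reshapes the
  speed profile while leaving the path shape intact — drag opposing the
  drive is primarily a *temporal* perturbation — plus a small δ
  excursion (0.5° per unit warp) at the water transitions for the
  secondary *spatial* (lift) effect;
- learning: bias, noise, jitter and the tempo deviation decay by
  `(1 − learning_rate)` per run performed.

Defaults (bias 0.8°, noise 0.6°, jitter 0.05 s, learning 1–4% per run,
density sensitivity ~1e-4 per kg/m³) were chosen once as plausible for
novice rowers producing errors of a fraction of a degree to a few
degrees; the magnitude of real density-induced shifts is only known
qualitatively, so these are plausibility defaults, not fits.

What it does **not** emulate: neuromuscular control, feedback
processing, within-stroke corrections, motivation, sensor noise or the
haptic control loop. Passing recovery tests therefore shows that the
*pipeline* orders injected effects correctly — not that real rowers
behave like the generator.

The protocol driver reproduces the study design: Day 1 = four 120 s
baselines (first always nominal C, then A/D/F shuffled per participant)
and six 120 s training sets in two blocks, each closed by a 60 s
no-feedback trial; Day 2 = 120 s long-term retention plus the same
training structure; Day 3 = final retention plus three 120 s transfers
(A/D/F, shuffled). FD trains entirely at C; VD follows a balanced random
order over B/C/E (each exactly twice per day) drawn once per cohort so
every VD participant shares it. One master seed spawns per-cohort,
per-participant and per-run substreams, so any single run is
reproducible in isolation.

## Numerical choices and degenerate inputs

- Trajectory files must be strictly monotone and uniform in time to
  1e-6 s; violations raise a format error naming the offending row.
- Coefficient lookups outside [0°, 180°] and resampling to fewer than 2
  points are errors; a stationary blade gets α = 90° by convention
  (forces vanish).
- DTW Dinkelbach termination tolerance is 1e-14 scaled by matrix size
  and magnitude — far below the 1e-12 agreement the oracle tests
  require; backtracking tie-breaks prefer the diagonal (the value is
  tie-break independent by construction).
- Fewer than two detected boundaries, or zero valid cycles, yield empty
  results with a RuntimeWarning; undefined metrics are NaN.

## Problem sizes

Parameter-recovery experiments (noise, bias and jitter grids; learning
curves) use 60 s runs — ≥ 19 valid cycles, enough for stable pairwise
variability estimates — with 20 seeds per grid point, keeping each grid
to roughly a minute of compute. The worked examples use the protocol's
own 120 s / 300 s durations. The `analysis/` drivers default to 2
participants per group (the study's 8 per group is a flag away) because
the pairwise DTW variability metrics dominate runtime at ~4 s per 120 s
run.

## Known limitations

- The reference loop shape and phase split are stylised; only period,
  spans and smoothness class match the task definition.
- The default coefficient table is a smooth approximation, and forces
  act at a single blade point; neither reproduces a calibrated simulator
  rendering.
- The density→performance mapping is qualitative; recovery tests
  validate ordering, not magnitudes.
- DTW pairwise variability is O(n²) in valid cycles per run.
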