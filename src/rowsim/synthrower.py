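"""Synthetic rower: participant-like runs and the 3-day study protocol.

Real participant recordings are available only on request, so this module
manufactures oar-angle runs with a controllable error/variability
structure, letting the evaluation pipeline be exercised (and its parameter
recovery validated) end to end.

A simulated stroke is the reference waveform warped and perturbed:

- a systematic *spatial bias* pattern (one low-frequency component with a
  per-run random phase, identical in every cycle);
- smooth per-cycle *spatial noise* built from a few random low-frequency
  periodic components that vanish at the cycle boundaries (white noise on
  angles would be unphysical and would break catch detection);
- a *tempo scale* on the stroke duration plus per-cycle Gaussian
  *cadence jitter*;
- a *density effect*: departing from the nominal water density mostly
  reshapes the within-cycle velocity profile (drag opposes the drive) and
  secondarily adds small vertical-angle excursions at the water
  transitions (lift), leaving the spatial path almost untouched;
- *learning*: bias, noise, jitter and tempo deviation decay exponentially
  with the number of runs already performed.

All randomness flows from one master seed through deterministic
substreams, so any single run is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .hydro import NOMINAL_DENSITY, WaterCondition, condition_by_label
from .reference import ReferenceSpec, Trajectory, reference_waveform

__all__ = [
    "RowerProfile",
    "SimulatedRun",
    "simulate_run",
    "protocol_schedule",
    "simulate_protocol",
]

#: Degrees of vertical-angle excursion per unit of density modulation
#: (the secondary, "lift", spatial effect of a density change).
_DENSITY_SPATIAL_GAIN = 0.5

#: Cap on the within-cycle time-warp amplitude (keeps the warp monotone).
_MAX_WARP = 0.9

_NOISE_HARMONICS = 3


@dataclass(frozen=True)
class RowerProfile:
    """Parameterisation of one synthetic participant.

    spatial_bias_deg
        Amplitude (degrees) of the systematic offset pattern added
        identically to every stroke.
    spatial_noise_deg
        RMS amplitude (degrees) of the smooth stroke-to-stroke spatial
        perturbation.
    tempo_scale
        Multiplicative stroke-duration factor (1 = on reference tempo).
    cadence_jitter_sd
        SD (s) of the per-cycle stroke-duration jitter.
    learning_rate
        Per-run exponential decay applied to bias, noise, jitter and the
        tempo deviation; 0 = no learning.
    density_sensitivity
        Maps |rho - nominal| (kg/m^3) to within-cycle velocity-profile
        distortion; 0 = insensitive to the water condition.
    outlier_rate
        Probability that a cycle is rowed at an out-of-band cadence
        (exercises the 22-26 strokes/min filter).
    seed
        Master RNG seed for this participant.
    """

    spatial_bias_deg: float = 0.8
    spatial_noise_deg: float = 0.6
    tempo_scale: float = 1.0
    cadence_jitter_sd: float = 0.05
    learning_rate: float = 0.0
    density_sensitivity: float = 1e-4
    outlier_rate: float = 0.0
    outlier_durations: tuple[float, ...] = (3.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spatial_bias_deg < 0 or self.spatial_noise_deg < 0 \
                or self.cadence_jitter_sd < 0:
            raise ValueError("amplitudes and SDs must be >= 0")
        if not self.tempo_scale > 0:
            raise ValueError("tempo_scale must be positive")
        if not 0 <= self.learning_rate < 1:
            raise ValueError("learning_rate must lie in [0, 1)")
        if not 0 <= self.outlier_rate <= 1:
            raise ValueError("outlier_rate must lie in [0, 1]")

    def attenuated(self, experience: int) -> "RowerProfile":
        """Profile after ``experience`` runs of practice."""
        g = (1.0 - self.learning_rate) ** max(experience, 0)
        return replace(self,
                       spatial_bias_deg=self.spatial_bias_deg * g,
                       spatial_noise_deg=self.spatial_noise_deg * g,
                       cadence_jitter_sd=self.cadence_jitter_sd * g,
                       tempo_scale=1.0 + (self.tempo_scale - 1.0) * g)


@dataclass(frozen=True)
class SimulatedRun:
    """One simulated training or test run with its provenance."""

    trajectory: Trajectory
    condition: WaterCondition
    run_label: str = ""
    group: str = ""
    day: int = 0
    participant_id: str = ""
    feedback: bool = False
    boundary_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    """Ground-truth cycle start times, s (for segmentation validation)."""

    cycle_durations: np.ndarray = field(default_factory=lambda: np.empty(0))
    """Ground-truth laid-out cycle durations, s (last one may exceed the
    run end and be truncated in the sampled trajectory)."""


def _smooth_noise(u: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Band-limited perturbation vanishing at the cycle boundaries.

    Basis: cos(2 pi k u) - 1 and sin(2 pi k u) for k = 1..H; all terms are
    zero at u = 0 and u = 1, so consecutive cycles join continuously and
    the catch sample itself is unperturbed.
    """
    out = np.zeros_like(u)
    for k in range(1, _NOISE_HARMONICS + 1):
        out += coeffs[2 * k - 2] * (np.cos(2 * np.pi * k * u) - 1.0)
        out += coeffs[2 * k - 1] * np.sin(2 * np.pi * k * u)
    return out


def _noise_coeffs(rng: np.random.Generator, rms_deg: float) -> np.ndarray:
    # var[c(cos-1)] = 3/2 c^2, var[b sin] = 1/2 b^2 time-averaged ->
    # total RMS = rms_deg when each coefficient has variance rms^2/6.
    return rng.normal(0.0, rms_deg / np.sqrt(6.0), size=2 * _NOISE_HARMONICS)


def _warp(u: np.ndarray, amount: float) -> np.ndarray:
    """Monotone within-cycle time reparameterisation, fixing u = 0 and 1."""
    return u - amount / (2 * np.pi) * np.sin(2 * np.pi * u)


def simulate_run(profile: RowerProfile, spec: ReferenceSpec | None = None,
                 condition: WaterCondition | None = None, duration: float = 120.0,
                 sample_rate: float = 100.0, experience: int = 0,
                 stream: int = 0, **run_meta) -> SimulatedRun:
    """Synthesize one oar-angle run.

    Deterministic given (profile.seed, stream); ``experience`` applies the
    profile's learning decay before synthesis.  Extra keyword arguments
    (run_label, group, day, participant_id, feedback) are attached to the
    returned SimulatedRun.
    """
    if spec is None:
        spec = ReferenceSpec()
    if condition is None:
        condition = condition_by_label("C")
    p = profile.attenuated(experience)
    rng = np.random.default_rng(np.random.SeedSequence([profile.seed & 0x7FFFFFFF,
                                                        stream]))
    period = spec.period * p.tempo_scale
    warp_amp = min(p.density_sensitivity * abs(condition.density - NOMINAL_DENSITY),
                   _MAX_WARP)

    # Systematic bias pattern: identical in every cycle of the run.
    bias_phase_th, bias_phase_de = rng.uniform(0.0, 2 * np.pi, size=2)

    # Lay out cycle start times until the run is covered.
    starts = [0.0]
    durations: list[float] = []
    while starts[-1] < duration:
        if p.outlier_rate > 0.0 and rng.random() < p.outlier_rate:
            d = float(rng.choice(np.asarray(p.outlier_durations)))
        else:
            d = period + rng.normal(0.0, p.cadence_jitter_sd)
            d = float(np.clip(d, 0.6 * spec.period, 1.6 * spec.period))
        durations.append(d)
        starts.append(starts[-1] + d)
    starts_arr = np.asarray(starts[:-1])

    n = int(round(duration * sample_rate))
    times = np.arange(n) / sample_rate
    theta = np.empty(n)
    delta = np.empty(n)
    edges = np.asarray(starts)
    idx = np.searchsorted(edges, times, side="right") - 1
    for k, dur in enumerate(durations):
        coeff_th = _noise_coeffs(rng, p.spatial_noise_deg)
        coeff_de = _noise_coeffs(rng, p.spatial_noise_deg)
        sel = idx == k
        if not np.any(sel):
            continue
        u = (times[sel] - edges[k]) / dur
        th_ref, de_ref = reference_waveform(_warp(u, warp_amp), spec)
        theta[sel] = (th_ref
                      + p.spatial_bias_deg * np.sin(2 * np.pi * u + bias_phase_th)
                      + _smooth_noise(u, coeff_th))
        delta[sel] = (de_ref
                      + p.spatial_bias_deg * np.sin(2 * np.pi * u + bias_phase_de)
                      + _smooth_noise(u, coeff_de)
                      + _DENSITY_SPATIAL_GAIN * warp_amp * np.sin(4 * np.pi * u))
    traj = Trajectory(times=times, theta=theta, delta=delta, sample_rate=sample_rate)
    return SimulatedRun(trajectory=traj, condition=condition,
                        boundary_times=starts_arr[starts_arr < duration],
                        cycle_durations=np.asarray(durations), **run_meta)


def _training_order(group: str, rng: np.random.Generator) -> list[str]:
    """Condition labels for one day's six training sets."""
    if group == "FD":
        return ["C"] * 6
    if group == "VD":
        order = ["B", "C", "E", "B", "C", "E"]
        rng.shuffle(order)
        return order
    raise ValueError(f"unknown group {group!r} (expected 'VD' or 'FD')")


def protocol_schedule(group: str, participant_rng: np.random.Generator,
                      vd_orders: dict[int, list[str]] | None = None
                      ) -> list[dict]:
    """The 3-day run plan for one participant.

    Day 1: four 120 s baselines — first always the nominal condition C,
    then A, D, F in a random order — followed by six 120 s training sets
    in two blocks of three, each block closed by a 60 s no-feedback trial.
    Day 2: 120 s long-term retention (C), then a training session like
    Day 1's.  Day 3: final retention (C) and three 120 s transfer tests
    (A, D, F) in random order.

    Training conditions are all C for the FD group; for VD they follow a
    balanced random order over B, C, E (each twice per day) supplied via
    ``vd_orders`` so that every VD participant shares the same order.
    """
    sched: list[dict] = []

    def add(day, label, cond, dur, feedback=False):
        sched.append({"day": day, "run_label": label, "condition": cond,
                      "duration": dur, "feedback": feedback})

    def baseline_label(prefix, cond):
        d = int(condition_by_label(cond).density)
        return f"{prefix}-d{d}"

    # Day 1: baselines
    add(1, "BL-d1100", "C", 120.0)
    others = ["A", "D", "F"]
    participant_rng.shuffle(others)
    for c in others:
        add(1, baseline_label("BL", c), c, 120.0)

    tr_index = 0
    for day in (1, 2):
        if day == 2:
            add(2, "RE2-d1100", "C", 120.0)
        if vd_orders is not None:
            order = vd_orders[day]
        else:
            order = _training_order(group, participant_rng)
        for block in range(2):
            for j in range(3):
                tr_index += 1
                add(day, f"TR{tr_index}", order[3 * block + j], 120.0, feedback=True)
            add(day, f"NF{2 * (day - 1) + block + 1}", "C", 60.0)

    # Day 3: final retention + transfers
    add(3, "RE3-d1100", "C", 120.0)
    transfers = ["A", "D", "F"]
    participant_rng.shuffle(transfers)
    for c in transfers:
        add(3, baseline_label("TRS", c), c, 120.0)
    return sched


def simulate_protocol(cohort_size: int, group: str,
                      profiles: list[RowerProfile] | None = None,
                      seed: int = 0, spec: ReferenceSpec | None = None,
                      sample_rate: float = 100.0) -> list[SimulatedRun]:
    """Simulate the full 3-day protocol for a cohort of one group.

    Every participant follows :func:`protocol_schedule`; VD participants
    all receive the same per-day balanced training order, drawn once at
    cohort level from ``seed``.  Runs accumulate practice: the profile's
    learning decay is applied per run performed.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    if group not in ("VD", "FD"):
        raise ValueError(f"unknown group {group!r} (expected 'VD' or 'FD')")
    master = np.random.SeedSequence(seed)
    cohort_ss, participants_ss = master.spawn(2)
    cohort_rng = np.random.default_rng(cohort_ss)
    vd_orders = {day: _training_order(group, cohort_rng) for day in (1, 2)}

    if profiles is None:
        prof_rng = np.random.default_rng(participants_ss)
        profiles = []
        for i in range(cohort_size):
            profiles.append(RowerProfile(
                spatial_bias_deg=float(prof_rng.uniform(0.5, 1.5)),
                spatial_noise_deg=float(prof_rng.uniform(0.4, 1.0)),
                tempo_scale=float(prof_rng.uniform(0.96, 1.04)),
                cadence_jitter_sd=float(prof_rng.uniform(0.02, 0.08)),
                learning_rate=float(prof_rng.uniform(0.01, 0.04)),
                density_sensitivity=float(prof_rng.uniform(0.5e-4, 2e-4)),
                seed=int(prof_rng.integers(0, 2**31 - 1)),
            ))
    if len(profiles) != cohort_size:
        raise ValueError("need one profile per participant")

    runs: list[SimulatedRun] = []
    for i, profile in enumerate(profiles):
        pid = f"{group}{i + 1:02d}"
        prng = np.random.default_rng(
            np.random.SeedSequence([seed & 0x7FFFFFFF, i]))
        sched = protocol_schedule(group, prng, vd_orders)
        for experience, entry in enumerate(sched):
            runs.append(simulate_run(
                profile, spec, condition_by_label(entry["condition"]),
                duration=entry["duration"], sample_rate=sample_rate,
                experience=experience, stream=experience,
                run_label=entry["run_label"], group=group, day=entry["day"],
                participant_id=pid, feedback=entry["feedback"]))
    return runs
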