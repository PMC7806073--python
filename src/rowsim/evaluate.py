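"""Kinematic evaluation: segmentation, filtering and the four DTW metrics.

A recorded run of (theta, delta) oar angles is cut into stroke cycles at
local minima of theta (the catch), transition cycles are excluded (the
first three and the last), cycles outside the instructed 22-26 strokes/min
cadence band are removed, and the survivors plus the reference stroke are
resampled to 250 points.  Accuracy and consistency are then scored with a
normalised dynamic-time-warping dissimilarity (temporal-shift weight zero):

- spatial error    eps_s : mean DTW distance of each stroke's (theta,
  delta) path to the reference path, degrees;
- spatial variability nu_s : mean pairwise DTW distance among the
  participant's own stroke paths, degrees;
- velocity error   eps_v : the same against the reference, on 1-D angular
  speed profiles, degrees/s;
- velocity variability nu_v : pairwise, on speed profiles, degrees/s.

Higher values mean lower accuracy / consistency.  Metrics that cannot be
computed (too few valid cycles) propagate as NaN, never as silent zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
from scipy.signal import find_peaks

from ._dtw import local_cost_matrix, normalized_dtw
from .reference import ReferenceSpec, Trajectory, generate_reference

__all__ = [
    "MetricConfig",
    "Cycle",
    "RunMetrics",
    "segment_cycles",
    "filter_cycles",
    "resample_cycle",
    "dtw_dissimilarity",
    "spatial_error",
    "spatial_variability",
    "velocity_error",
    "velocity_variability",
    "evaluate_run",
    "reference_cycle",
]


@dataclass(frozen=True)
class MetricConfig:
    """Evaluation-pipeline parameters.

    ``trailing_accept_fraction`` controls when the segment after the last
    detected catch counts as a final complete cycle: it must hold at least
    this fraction of the median inter-catch sample count.
    """

    resample_points: int = 250
    cadence_band_spm: tuple[float, float] = (22.0, 26.0)
    head_exclusions: int = 3
    tail_exclusions: int = 1
    temporal_shift_weight: float = 0.0
    min_cycle_separation_s: float = 1.5
    trailing_accept_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.resample_points < 2:
            raise ValueError("resample_points must be >= 2")
        lo, hi = self.cadence_band_spm
        if not lo < hi:
            raise ValueError("cadence band must have low < high")
        if self.temporal_shift_weight < 0:
            raise ValueError("temporal_shift_weight must be >= 0")
        if self.head_exclusions < 0 or self.tail_exclusions < 0:
            raise ValueError("exclusion counts must be >= 0")


@dataclass(frozen=True)
class Cycle:
    """One segmented stroke: its samples and the span it occupies.

    ``duration`` is the time the cycle occupies in the run — the distance
    to the next catch (n_samples / sample_rate for right-exclusive
    segments) — so that consecutive cycles tile the run and a nominal
    2.5 s stroke sampled at 100 Hz has duration exactly 2.5 s.
    """

    times: np.ndarray
    theta: np.ndarray
    delta: np.ndarray
    duration: float
    index_in_run: int

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.theta)) and np.all(np.isfinite(self.delta))):
            raise ValueError("cycle angles must be finite")

    def __len__(self) -> int:
        return self.times.size

    @property
    def cadence_spm(self) -> float:
        return 60.0 / self.duration


@dataclass(frozen=True)
class RunMetrics:
    """The four outcome metrics plus cycle bookkeeping for one run."""

    spatial_error: float
    velocity_error: float
    spatial_variability: float
    velocity_variability: float
    n_cycles_total: int
    n_cycles_valid: int

    def as_dict(self) -> dict[str, float | int]:
        return {
            "eps_s": self.spatial_error,
            "eps_v": self.velocity_error,
            "nu_s": self.spatial_variability,
            "nu_v": self.velocity_variability,
            "n_total": self.n_cycles_total,
            "n_valid": self.n_cycles_valid,
        }


def segment_cycles(traj: Trajectory, config: MetricConfig | None = None) -> list[Cycle]:
    """Cut a run into stroke cycles at local minima of theta (the catch).

    Catches must be separated by at least ``min_cycle_separation_s``.  The
    first sample counts as a catch when it is a one-sided minimum, and the
    trailing segment counts as a final cycle when it is long enough (see
    MetricConfig); head/tail fragments shorter than that are discarded.
    """
    if config is None:
        config = MetricConfig()
    theta = traj.theta
    n = theta.size
    rate = traj.sample_rate
    min_sep = max(1, int(round(config.min_cycle_separation_s * rate)))
    boundaries, _ = find_peaks(-theta, distance=min_sep)
    boundaries = list(boundaries)
    if n >= 2 and theta[0] < theta[1]:
        if not boundaries or boundaries[0] >= min_sep:
            boundaries.insert(0, 0)
    if len(boundaries) < 2:
        warnings.warn("fewer than two cycle boundaries found; no complete cycles",
                      RuntimeWarning, stacklevel=2)
        return []
    gaps = np.diff(boundaries)
    cycles: list[Cycle] = []
    for k, (b0, b1) in enumerate(zip(boundaries[:-1], boundaries[1:])):
        cycles.append(Cycle(times=traj.times[b0:b1], theta=theta[b0:b1],
                            delta=traj.delta[b0:b1],
                            duration=(b1 - b0) / rate, index_in_run=k))
    tail = n - boundaries[-1]
    if tail >= config.trailing_accept_fraction * float(np.median(gaps)):
        b0 = boundaries[-1]
        cycles.append(Cycle(times=traj.times[b0:], theta=theta[b0:],
                            delta=traj.delta[b0:],
                            duration=tail / rate, index_in_run=len(cycles)))
    return cycles


def filter_cycles(cycles: list[Cycle], config: MetricConfig | None = None) -> list[Cycle]:
    """Exclude transition cycles, then out-of-cadence cycles.

    Drops the first ``head_exclusions`` and last ``tail_exclusions`` cycles
    (rowing spin-up and wind-down), then removes any cycle whose implied
    stroke rate 60/duration falls outside the cadence band (inclusive).
    """
    if config is None:
        config = MetricConfig()
    tail = len(cycles) - config.tail_exclusions
    kept = cycles[config.head_exclusions:max(tail, config.head_exclusions)]
    lo, hi = config.cadence_band_spm
    valid = [c for c in kept if lo <= c.cadence_spm <= hi]
    if not valid:
        warnings.warn("no valid cycles after exclusion and cadence filtering",
                      RuntimeWarning, stacklevel=2)
    return valid


def resample_cycle(cycle: Cycle, n: int | None = None,
                   config: MetricConfig | None = None) -> Cycle:
    """Resample a cycle to exactly ``n`` points by linear interpolation.

    Interpolation runs over the cycle's own samples with endpoints
    preserved; the cycle's occupied duration is untouched.
    """
    if n is None:
        n = (config or MetricConfig()).resample_points
    if n < 2:
        raise ValueError("resample count must be >= 2")
    if len(cycle) < 2:
        raise ValueError("cycle must have at least 2 samples")
    t = np.linspace(cycle.times[0], cycle.times[-1], n)
    return replace(cycle,
                   times=t,
                   theta=np.interp(t, cycle.times, cycle.theta),
                   delta=np.interp(t, cycle.times, cycle.delta))


def dtw_dissimilarity(a: np.ndarray, b: np.ndarray,
                      config: MetricConfig | None = None) -> float:
    """Normalised DTW dissimilarity between two sample sequences.

    ``a`` and ``b`` are (n,) or (n, d) arrays of matching dimensionality.
    The value is the minimum over monotone, endpoint-matched warping paths
    of accumulated Euclidean local distance divided by path length.
    """
    if config is None:
        config = MetricConfig()
    d = local_cost_matrix(np.asarray(a, float), np.asarray(b, float),
                          config.temporal_shift_weight)
    return normalized_dtw(d)


def _path(cycle: Cycle) -> np.ndarray:
    return np.column_stack([cycle.theta, cycle.delta])


def _speed(cycle: Cycle) -> np.ndarray:
    """Angular speed profile of a (resampled) cycle, degrees/s.

    The time axis spans the cycle's true occupied duration, so tempo
    differences show up in the magnitude even after resampling.
    """
    t = np.linspace(0.0, cycle.duration, len(cycle))
    return np.hypot(np.gradient(cycle.theta, t), np.gradient(cycle.delta, t))


def reference_cycle(spec: ReferenceSpec | None = None,
                    config: MetricConfig | None = None,
                    sample_rate: float = 100.0) -> Cycle:
    """One reference stroke, resampled like a participant cycle."""
    if spec is None:
        spec = ReferenceSpec()
    if config is None:
        config = MetricConfig()
    traj = generate_reference(spec, duration=spec.period, sample_rate=sample_rate)
    cyc = Cycle(times=traj.times, theta=traj.theta, delta=traj.delta,
                duration=spec.period, index_in_run=-1)
    return resample_cycle(cyc, config.resample_points)


def _mean_vs_reference(items: list[np.ndarray], ref: np.ndarray,
                       config: MetricConfig) -> float:
    vals = [normalized_dtw(local_cost_matrix(x, ref, config.temporal_shift_weight))
            for x in items]
    return float(np.mean(vals))


def _mean_pairwise(items: list[np.ndarray], config: MetricConfig) -> float:
    vals = [normalized_dtw(local_cost_matrix(x, y, config.temporal_shift_weight))
            for x, y in combinations(items, 2)]
    return float(np.mean(vals))


def spatial_error(valid_cycles: list[Cycle], reference: Cycle,
                  config: MetricConfig | None = None) -> float:
    """Mean DTW deviation of each stroke path from the reference, degrees."""
    config = config or MetricConfig()
    if not valid_cycles:
        return float("nan")
    cycles = [resample_cycle(c, config.resample_points) for c in valid_cycles]
    return _mean_vs_reference([_path(c) for c in cycles], _path(reference), config)


def spatial_variability(valid_cycles: list[Cycle],
                        config: MetricConfig | None = None) -> float:
    """Mean pairwise DTW deviation among a run's own stroke paths, degrees."""
    config = config or MetricConfig()
    if len(valid_cycles) < 2:
        return float("nan")
    cycles = [resample_cycle(c, config.resample_points) for c in valid_cycles]
    return _mean_pairwise([_path(c) for c in cycles], config)


def velocity_error(valid_cycles: list[Cycle], reference: Cycle,
                   config: MetricConfig | None = None) -> float:
    """Mean DTW deviation of stroke speed profiles from the reference, deg/s."""
    config = config or MetricConfig()
    if not valid_cycles:
        return float("nan")
    cycles = [resample_cycle(c, config.resample_points) for c in valid_cycles]
    return _mean_vs_reference([_speed(c) for c in cycles], _speed(reference), config)


def velocity_variability(valid_cycles: list[Cycle],
                         config: MetricConfig | None = None) -> float:
    """Mean pairwise DTW deviation among stroke speed profiles, deg/s."""
    config = config or MetricConfig()
    if len(valid_cycles) < 2:
        return float("nan")
    cycles = [resample_cycle(c, config.resample_points) for c in valid_cycles]
    return _mean_pairwise([_speed(c) for c in cycles], config)


def evaluate_run(traj: Trajectory, reference: Cycle | ReferenceSpec | None = None,
                 config: MetricConfig | None = None) -> RunMetrics:
    """Full pipeline for one run: segment, filter, resample, score."""
    config = config or MetricConfig()
    if reference is None or isinstance(reference, ReferenceSpec):
        reference = reference_cycle(reference, config, sample_rate=traj.sample_rate)
    cycles = segment_cycles(traj, config)
    valid = filter_cycles(cycles, config) if cycles else []
    resampled = [resample_cycle(c, config.resample_points) for c in valid]
    paths = [_path(c) for c in resampled]
    speeds = [_speed(c) for c in resampled]
    ref_path, ref_speed = _path(reference), _speed(reference)
    nan = float("nan")
    return RunMetrics(
        spatial_error=_mean_vs_reference(paths, ref_path, config) if paths else nan,
        velocity_error=_mean_vs_reference(speeds, ref_speed, config) if speeds else nan,
        spatial_variability=_mean_pairwise(paths, config) if len(paths) >= 2 else nan,
        velocity_variability=_mean_pairwise(speeds, config) if len(speeds) >= 2 else nan,
        n_cycles_total=len(cycles),
        n_cycles_valid=len(valid),
    )
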