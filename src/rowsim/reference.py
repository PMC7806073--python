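"""Cyclic reference stroke trajectory.

The target movement is a smooth, periodic, C2-continuous loop in the two
recorded oar angles: theta (horizontal) and delta (vertical).  One stroke
lasts 2.5 s (24 strokes/min) and spans 44 degrees peak-to-peak in theta and
12.5 degrees in delta.  The stroke cycles through four phases — catch
(blade entry), drive (in-water pull, low delta), release (blade exit) and
recovery (return through the air, high delta).

The original expert recording is not available; the generator synthesises
a stand-in from a truncated periodic (Fourier) basis with a phase offset
between theta and delta so that (theta, delta) traces a closed
catch-drive-release-recovery loop with the specified period and spans.
The cycle starts at the catch, where theta is at its minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReferenceSpec",
    "Trajectory",
    "generate_reference",
    "phase_boundaries",
    "velocity_profile",
    "reference_waveform",
]

#: Fraction of the cycle by which the delta waveform trails the theta
#: waveform; places the delta minimum in mid-drive so the blade is "in the
#: water" during the drive and up during the recovery.
_DELTA_PHASE_LAG = 0.3


@dataclass(frozen=True)
class ReferenceSpec:
    """Parameters of the reference stroke.

    period
        Stroke duration in seconds (2.5 s = 24 strokes/min).
    theta_span, delta_span
        Peak-to-peak horizontal / vertical oar angle, degrees.
    phase_fractions
        Fractions of the cycle occupied by catch, drive, release and
        recovery; must sum to 1.
    harmonics
        Number of periodic basis terms per angle.  The default single
        harmonic gives an elliptical loop whose spans are exact by
        construction; more harmonics sharpen the drive/recovery asymmetry
        and are normalised numerically to the requested spans.
    """

    period: float = 2.5
    theta_span: float = 44.0
    delta_span: float = 12.5
    phase_fractions: tuple[float, float, float, float] = (0.1, 0.4, 0.1, 0.4)
    harmonics: int = 1
    theta_mid: float = 0.0
    delta_mid: float = 0.0

    def __post_init__(self) -> None:
        if not self.period > 0:
            raise ValueError("period must be positive")
        if not (self.theta_span > 0 and self.delta_span > 0):
            raise ValueError("angle spans must be positive")
        fr = np.asarray(self.phase_fractions, dtype=float)
        if fr.size != 4 or np.any(fr <= 0) or abs(fr.sum() - 1.0) > 1e-12:
            raise ValueError("phase_fractions must be four positive values summing to 1")
        if self.harmonics < 1:
            raise ValueError("harmonics must be >= 1")

    @property
    def cadence_spm(self) -> float:
        """Nominal cadence, strokes per minute."""
        return 60.0 / self.period


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled (time, theta, delta) series; angles in degrees."""

    times: np.ndarray
    theta: np.ndarray
    delta: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        th = np.asarray(self.theta, dtype=float)
        de = np.asarray(self.delta, dtype=float)
        if not (t.shape == th.shape == de.shape and t.ndim == 1):
            raise ValueError("times, theta, delta must be 1-D and equal length")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(np.abs(dt - 1.0 / self.sample_rate) > 1e-6):
                raise ValueError("times must be uniformly spaced at 1/sample_rate")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "theta", th)
        object.__setattr__(self, "delta", de)

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        """Span the samples cover, s (n samples at dt = n*dt)."""
        return len(self) / self.sample_rate


def _unit_waveform(u: np.ndarray, harmonics: int) -> np.ndarray:
    """Periodic basis waveform of unit nominal amplitude, minimum at u = 0.

    For one harmonic this is -cos(2 pi u).  Additional harmonics add a
    decaying cosine series that skews the shape while keeping it C-infinity
    and periodic.
    """
    x = 2 * np.pi * np.asarray(u, dtype=float)
    w = -np.cos(x)
    for k in range(2, harmonics + 1):
        w = w - ((-1) ** k) * np.cos(k * x) / k**2
    return w


def _normalised_waveform(u: np.ndarray, harmonics: int) -> np.ndarray:
    """Waveform rescaled to exact unit peak-to-peak and zero mid-range."""
    if harmonics == 1:
        return 0.5 * _unit_waveform(u, 1)
    dense = _unit_waveform(np.linspace(0.0, 1.0, 100_001), harmonics)
    lo, hi = dense.min(), dense.max()
    return (_unit_waveform(u, harmonics) - 0.5 * (lo + hi)) / (hi - lo)


def reference_waveform(u: np.ndarray | float, spec: ReferenceSpec | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate (theta, delta) in degrees at cycle phase ``u`` (cycles).

    ``u`` may be any real; the waveform has period 1.  The catch (minimum
    theta) is at integer phase; delta lags by a fixed fraction of the cycle
    so its low (in-water) band falls in the drive.
    """
    if spec is None:
        spec = ReferenceSpec()
    u = np.asarray(u, dtype=float)
    theta = spec.theta_mid + spec.theta_span * _normalised_waveform(u, spec.harmonics)
    delta = spec.delta_mid + spec.delta_span * _normalised_waveform(
        u - _DELTA_PHASE_LAG, spec.harmonics)
    return theta, delta


def generate_reference(spec: ReferenceSpec | None = None, duration: float = 120.0,
                       sample_rate: float = 100.0) -> Trajectory:
    """Sample the reference trajectory.

    Samples run from t = 0 to t = duration - 1/sample_rate (right-exclusive,
    so 120 s at 100 Hz gives exactly 12000 rows and each sample owns one
    1/sample_rate slot).  The first sample sits at the catch.
    """
    if spec is None:
        spec = ReferenceSpec()
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sample_rate < 20.0:
        raise ValueError("sample_rate must be at least 20 Hz")
    n = int(round(duration * sample_rate))
    times = np.arange(n) / sample_rate
    theta, delta = reference_waveform(times / spec.period, spec)
    return Trajectory(times=times, theta=theta, delta=delta, sample_rate=sample_rate)


def phase_boundaries(spec: ReferenceSpec | None = None
                     ) -> dict[str, tuple[float, float]]:
    """Contiguous [start, end) time intervals of the four stroke phases.

    Ordered catch -> drive -> release -> recovery, partitioning
    [0, period).
    """
    if spec is None:
        spec = ReferenceSpec()
    edges = spec.period * np.concatenate([[0.0], np.cumsum(spec.phase_fractions)])
    edges[-1] = spec.period  # exact partition despite rounding
    names = ("catch", "drive", "release", "recovery")
    return {name: (float(edges[i]), float(edges[i + 1]))
            for i, name in enumerate(names)}


def velocity_profile(traj: Trajectory) -> np.ndarray:
    """Angular speed |(dtheta/dt, ddelta/dt)| in degrees/s.

    Central differences in the interior, one-sided at the ends.
    """
    if len(traj) < 3:
        raise ValueError("velocity profile needs at least 3 samples")
    dth = np.gradient(traj.theta, traj.times)
    dde = np.gradient(traj.delta, traj.times)
    return np.hypot(dth, dde)
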