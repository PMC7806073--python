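"""Oar-blade hydrodynamics with a density-modulated virtual water model.

The blade is treated as a zero-thickness rectangular plate at the end of a
rigid oar pivoting at the oarlock.  Quasi-steady drag and lift are computed
from the blade velocity relative to the water,

    |F_D| = 1/2 * C_D(alpha) * rho * A_Dp * |V|**2
    |F_L| = 1/2 * C_L(alpha) * rho * A_Lp * |V|**2

where ``rho`` is the (virtual) water density, ``alpha`` the angle of attack
between the relative flow and the blade chord, and ``A_Dp`` / ``A_Lp`` the
orthographic projections of the blade face onto the planes normal to the
flow and to the lift direction.  Drag acts opposite the relative velocity;
lift acts perpendicular to it, in the plane spanned by the relative
velocity and the blade-face normal.

Coordinate frame (right-handed): x is boat forward, z is up, the oar pivots
at the origin.  ``theta`` is the horizontal oar angle, ``delta`` the
vertical (elevation) angle — low delta puts the blade in the water —
and ``phi`` the longitudinal (feathering) angle, 0 for a squared blade.
All public angles are in degrees; SI units internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OarGeometry",
    "OarState",
    "WaterCondition",
    "CoefficientTable",
    "BladeKinematics",
    "ProjectedAreas",
    "BladeForces",
    "NOMINAL_DENSITY",
    "DENSITY_RANGE",
    "relative_blade_velocity",
    "lookup_coefficients",
    "projected_areas",
    "blade_forces",
    "density_conditions",
    "default_coefficient_table",
]

#: Density of the nominal virtual water condition (kg/m^3).
NOMINAL_DENSITY = 1100.0

#: Admissible virtual-water density range (kg/m^3).
DENSITY_RANGE = (50.0, 4000.0)

_DEG = np.pi / 180.0


@dataclass(frozen=True)
class OarGeometry:
    """Oar and blade dimensions, metres.

    ``oar_length`` runs from the oarlock to the blade end; the blade is a
    rectangle ``blade_length`` x ``blade_height`` at the outboard end.
    """

    oar_length: float = 2.0
    blade_length: float = 0.45
    blade_height: float = 0.25

    def __post_init__(self) -> None:
        if not (self.oar_length > 0 and self.blade_length > 0 and self.blade_height > 0):
            raise ValueError("all oar dimensions must be strictly positive")
        if self.blade_length > self.oar_length:
            raise ValueError("blade_length cannot exceed oar_length")

    @property
    def face_area(self) -> float:
        """Full blade face area, m^2."""
        return self.blade_length * self.blade_height


@dataclass(frozen=True)
class OarState:
    """Instantaneous oar configuration.

    Angles in degrees, rates in degrees/s, boat velocity in m/s along the
    boat axis.  ``phi`` is 0 for the squared (vertical) blade the task
    mandates, but nonzero values are accepted.
    """

    theta: float = 0.0
    delta: float = 0.0
    phi: float = 0.0
    theta_rate: float = 0.0
    delta_rate: float = 0.0
    phi_rate: float = 0.0
    boat_velocity: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.theta, self.delta, self.phi,
                self.theta_rate, self.delta_rate, self.phi_rate,
                self.boat_velocity)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("oar state contains non-finite values")


@dataclass(frozen=True)
class WaterCondition:
    """A labelled virtual water density."""

    label: str
    density: float
    descriptor: str = ""
    display_color: str = ""

    def __post_init__(self) -> None:
        lo, hi = DENSITY_RANGE
        if not (lo <= self.density <= hi):
            raise ValueError(
                f"density {self.density} outside supported range {DENSITY_RANGE}"
            )


@dataclass(frozen=True)
class CoefficientTable:
    """Drag/lift coefficients tabulated against angle of attack (degrees).

    Looked up by linear interpolation; the grid must be strictly increasing
    and cover [0, 180] degrees.
    """

    alpha_grid: np.ndarray
    drag_coeffs: np.ndarray
    lift_coeffs: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha_grid, dtype=float)
        cd = np.asarray(self.drag_coeffs, dtype=float)
        cl = np.asarray(self.lift_coeffs, dtype=float)
        if not (a.ndim == 1 and a.shape == cd.shape == cl.shape):
            raise ValueError("alpha_grid, drag_coeffs, lift_coeffs must be 1-D and equal length")
        if not np.all(np.diff(a) > 0):
            raise ValueError("alpha_grid must be strictly increasing")
        if a[0] > 0.0 or a[-1] < 180.0:
            raise ValueError("coefficient table must cover [0, 180] degrees")
        if np.any(cd < 0):
            raise ValueError("drag coefficients must be non-negative")
        object.__setattr__(self, "alpha_grid", a)
        object.__setattr__(self, "drag_coeffs", cd)
        object.__setattr__(self, "lift_coeffs", cl)


@dataclass(frozen=True)
class BladeKinematics:
    """Blade position, velocity relative to water, and angle of attack."""

    rel_velocity: np.ndarray
    blade_position: np.ndarray
    alpha: float


@dataclass(frozen=True)
class ProjectedAreas:
    """Projected blade areas (m^2) for drag and lift."""

    drag_area: float
    lift_area: float


@dataclass(frozen=True)
class BladeForces:
    """Drag and lift force vectors, N."""

    drag_force: np.ndarray = field(default_factory=lambda: np.zeros(3))
    lift_force: np.ndarray = field(default_factory=lambda: np.zeros(3))


def _oar_direction(theta_rad: float, delta_rad: float) -> np.ndarray:
    """Unit vector from oarlock toward the blade."""
    cd = np.cos(delta_rad)
    return np.array([
        np.sin(theta_rad) * cd,
        np.cos(theta_rad) * cd,
        np.sin(delta_rad),
    ])


def blade_position(state: OarState, geometry: OarGeometry) -> np.ndarray:
    """Blade reference point (m): ``oar_length`` along the oar axis."""
    return geometry.oar_length * _oar_direction(state.theta * _DEG, state.delta * _DEG)


def _blade_normal(state: OarState) -> np.ndarray:
    """Unit normal of the blade face.

    For a squared blade (phi = 0) the normal is horizontal and
    perpendicular to the oar axis; phi rotates it about the oar axis.
    """
    th, de, ph = state.theta * _DEG, state.delta * _DEG, state.phi * _DEG
    u = _oar_direction(th, de)
    n0 = np.cross(u, np.array([0.0, 0.0, 1.0]))
    norm = np.linalg.norm(n0)
    if norm < 1e-12:
        raise ValueError("oar axis vertical: blade orientation undefined")
    n0 /= norm
    if ph == 0.0:
        return n0
    # Rodrigues rotation of the squared-blade normal about the oar axis.
    return (n0 * np.cos(ph) + np.cross(u, n0) * np.sin(ph)
            + u * np.dot(u, n0) * (1.0 - np.cos(ph)))


def relative_blade_velocity(state: OarState, geometry: OarGeometry) -> BladeKinematics:
    """Blade velocity relative to the water, and the angle of attack.

    The blade point sits at ``oar_length`` along the oar direction set by
    (theta, delta); its velocity in the boat frame is the analytic time
    derivative of that position given the angular rates.  The water streams
    past the (platform-fixed) boat at ``-boat_velocity`` along x, so the
    relative velocity is the blade velocity plus ``boat_velocity * x_hat``.

    The angle of attack is measured between the relative flow and the blade
    chord (the oar axis), in [0, 180] degrees: 0 is flow along the chord
    (edge-on, toward the blade tip), 90 face-on, 180 reversed chord-wise.
    """
    th, de = state.theta * _DEG, state.delta * _DEG
    thd, ded = state.theta_rate * _DEG, state.delta_rate * _DEG
    L = geometry.oar_length
    pos = L * _oar_direction(th, de)
    # d/dt of L * (sin th cos de, cos th cos de, sin de)
    vel = L * np.array([
        thd * np.cos(th) * np.cos(de) - ded * np.sin(th) * np.sin(de),
        -thd * np.sin(th) * np.cos(de) - ded * np.cos(th) * np.sin(de),
        ded * np.cos(de),
    ])
    rel = vel + np.array([state.boat_velocity, 0.0, 0.0])
    speed = np.linalg.norm(rel)
    if speed < 1e-12:
        alpha = 90.0  # stationary blade: conventional, forces vanish anyway
    else:
        chord = _oar_direction(th, de)
        cosa = np.clip(np.dot(rel / speed, chord), -1.0, 1.0)
        alpha = float(np.degrees(np.arccos(cosa)))
    return BladeKinematics(rel_velocity=rel, blade_position=pos, alpha=alpha)


def lookup_coefficients(table: CoefficientTable, alpha: float) -> tuple[float, float]:
    """Linearly interpolate (C_D, C_L) at an angle of attack in degrees."""
    if not np.isfinite(alpha) or alpha < 0.0 or alpha > 180.0:
        raise ValueError(f"angle of attack {alpha!r} outside [0, 180] degrees")
    cd = float(np.interp(alpha, table.alpha_grid, table.drag_coeffs))
    cl = float(np.interp(alpha, table.alpha_grid, table.lift_coeffs))
    return cd, cl


def _lift_direction(rel_unit: np.ndarray, normal: np.ndarray) -> np.ndarray | None:
    """Unit lift direction: blade-face normal deflected perpendicular to flow."""
    perp = normal - np.dot(normal, rel_unit) * rel_unit
    norm = np.linalg.norm(perp)
    if norm < 1e-12:
        return None  # face-on flow: no preferred lift direction (C_L ~ 0 there)
    return perp / norm


def projected_areas(state: OarState, geometry: OarGeometry,
                    kin: BladeKinematics) -> ProjectedAreas:
    """Orthographic projections of the blade face.

    ``drag_area`` projects the face onto the plane normal to the relative
    flow; ``lift_area`` onto the plane normal to the lift direction.  The
    blade is a zero-thickness plate, so an edge-on face projects to zero.
    With zero relative velocity both areas default to the full face area
    (the forces are zero regardless).
    """
    area = geometry.face_area
    speed = np.linalg.norm(kin.rel_velocity)
    if speed < 1e-12:
        return ProjectedAreas(drag_area=area, lift_area=area)
    rel_unit = kin.rel_velocity / speed
    n = _blade_normal(state)
    drag_area = area * abs(float(np.dot(n, rel_unit)))
    ldir = _lift_direction(rel_unit, n)
    lift_area = area * abs(float(np.dot(n, ldir))) if ldir is not None else area
    return ProjectedAreas(drag_area=drag_area, lift_area=lift_area)


def blade_forces(state: OarState, geometry: OarGeometry,
                 condition: WaterCondition, table: CoefficientTable) -> BladeForces:
    """Quasi-steady drag and lift force vectors on the blade."""
    kin = relative_blade_velocity(state, geometry)
    speed = np.linalg.norm(kin.rel_velocity)
    if speed < 1e-12:
        return BladeForces()
    rel_unit = kin.rel_velocity / speed
    cd, cl = lookup_coefficients(table, kin.alpha)
    areas = projected_areas(state, geometry, kin)
    rho = condition.density
    q = 0.5 * rho * speed ** 2  # dynamic pressure
    drag = -cd * areas.drag_area * q * rel_unit
    ldir = _lift_direction(rel_unit, _blade_normal(state))
    if ldir is None or cl == 0.0:
        lift = np.zeros(3)
    else:
        lift = cl * areas.lift_area * q * ldir
    return BladeForces(drag_force=drag, lift_force=lift)


_CONDITION_ROWS = (
    ("A", 200.0, "Very low", "Purple"),
    ("B", 400.0, "Low", "Orange"),
    ("C", 1100.0, "Normal", "Blue"),
    ("D", 1800.0, "Above-average", "Red"),
    ("E", 2500.0, "High", "Green"),
    ("F", 3200.0, "Very high", "Yellow"),
)


def density_conditions() -> list[WaterCondition]:
    """The six labelled virtual water conditions A-F."""
    return [WaterCondition(label=l, density=d, descriptor=s, display_color=c)
            for l, d, s, c in _CONDITION_ROWS]


def condition_by_label(label: str) -> WaterCondition:
    """Look up a water condition by its letter label."""
    for cond in density_conditions():
        if cond.label == label:
            return cond
    raise KeyError(f"unknown water condition {label!r}")


def default_coefficient_table(cd_max: float = 2.0, cl_max: float = 1.0,
                              step_deg: float = 1.0) -> CoefficientTable:
    """Smooth flat-plate-like coefficient profiles.

    An approximation standing in for a calibrated lookup table:
    ``C_D = cd_max * sin^2(alpha)`` (peak face-on at 90 degrees) and
    ``C_L = cl_max * sin(2 alpha)`` (zero at 0/90/180, peak near 45,
    sign-reversed past 90 where the chord-wise flow reverses).
    """
    alpha = np.arange(0.0, 180.0 + step_deg / 2, step_deg)
    a = np.radians(alpha)
    return CoefficientTable(
        alpha_grid=alpha,
        drag_coeffs=cd_max * np.sin(a) ** 2,
        lift_coeffs=cl_max * np.sin(2 * a),
    )
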