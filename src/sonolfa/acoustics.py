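"""One-dimensional standing-wave acoustophoresis: contrast factor, primary
radiation force, node structure, and overdamped particle migration.

Coordinate conventions
----------------------
Two coordinates appear in this module and must not be confused:

* ``x`` in :func:`primary_radiation_force` is the displacement from a
  pressure **node** along the propagation axis (the classical reference
  point for the time-averaged force on a small particle).
* Cavity positions (``pressure_nodes``, :func:`simulate_migration`) run
  from 0 at one wall to ``cavity_length`` at the other.  Both walls are
  treated as pressure antinodes, so the standing pressure profile is
  ``p(u) = P_a * cos(k u)`` and interior nodes sit at odd multiples of a
  quarter wavelength.  The two coordinates are related by
  ``x = u - lambda/4``.

For a positive acoustic contrast factor the force is restoring about the
pressure nodes, which is where dense, stiff particles collect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = [
    "BOLTZMANN_K",
    "ParticleSpec",
    "MediumSpec",
    "StandingWaveField",
    "TrajectoryResult",
    "water_at_298k",
    "acoustic_contrast_factor",
    "primary_radiation_force",
    "pressure_nodes",
    "simulate_migration",
    "enrichment_factor",
]

BOLTZMANN_K = 1.380649e-23  # J/K, exact (SI 2019)


@dataclass(frozen=True)
class ParticleSpec:
    """Mechanical description of a suspended (nano)particle.

    ``effective_cluster_radius`` lets callers scale drag and force to an
    aggregate of particles instead of a monomer: a single tens-of-nm
    particle experiences a radiation force far too weak to migrate on
    laboratory time scales, and collective effects are out of scope here.
    """

    radius: float  # m
    density_p: float  # kg/m^3
    compressibility_p: float  # 1/Pa
    effective_cluster_radius: float | None = None  # m

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("particle radius must be > 0")
        if self.density_p <= 0:
            raise ValueError("particle density must be > 0")
        if self.compressibility_p < 0:
            raise ValueError("particle compressibility must be >= 0")
        if self.effective_cluster_radius is not None and self.effective_cluster_radius <= 0:
            raise ValueError("effective_cluster_radius must be > 0 when given")

    @property
    def volume(self) -> float:
        """Particle volume (4/3) * pi * r^3 in m^3."""
        return (4.0 / 3.0) * math.pi * self.radius**3

    @property
    def hydrodynamic_radius(self) -> float:
        """Radius used for Stokes drag: the cluster radius if set."""
        return self.effective_cluster_radius or self.radius


@dataclass(frozen=True)
class MediumSpec:
    """Acoustic and hydrodynamic properties of the suspending fluid."""

    density_m: float  # kg/m^3
    compressibility_m: float  # 1/Pa
    sound_speed: float  # m/s
    dynamic_viscosity: float  # Pa s
    temperature: float = 298.0  # K

    def __post_init__(self) -> None:
        for name in ("density_m", "compressibility_m", "sound_speed", "dynamic_viscosity", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        c_implied = 1.0 / math.sqrt(self.density_m * self.compressibility_m)
        if abs(self.sound_speed - c_implied) / self.sound_speed >= 1e-3:
            raise ValueError(
                "sound_speed inconsistent with density/compressibility: "
                f"given {self.sound_speed:.4g} m/s, implied {c_implied:.4g} m/s"
            )


def water_at_298k() -> MediumSpec:
    """Water near room temperature; the default suspending medium."""
    rho = 997.0
    c = 1497.0
    return MediumSpec(
        density_m=rho,
        compressibility_m=1.0 / (rho * c * c),
        sound_speed=c,
        dynamic_viscosity=8.9e-4,
        temperature=298.0,
    )


@dataclass(frozen=True)
class StandingWaveField:
    """A 1D standing pressure wave in a cavity of length ``cavity_length``.

    The wavelength is derived from the medium's sound speed at
    construction time via :meth:`for_medium`, or passed explicitly.
    """

    pressure_amplitude: float  # Pa
    frequency: float  # Hz
    cavity_length: float  # m
    wavelength: float  # m

    def __post_init__(self) -> None:
        if self.pressure_amplitude < 0:
            raise ValueError("pressure_amplitude must be >= 0")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.cavity_length <= 0:
            raise ValueError("cavity_length must be > 0")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")

    @classmethod
    def for_medium(
        cls,
        medium: MediumSpec,
        pressure_amplitude: float,
        frequency: float,
        cavity_length: float,
    ) -> "StandingWaveField":
        return cls(
            pressure_amplitude=pressure_amplitude,
            frequency=frequency,
            cavity_length=cavity_length,
            wavelength=medium.sound_speed / frequency,
        )

    @property
    def wavenumber(self) -> float:
        """k = 2 pi / lambda."""
        return 2.0 * math.pi / self.wavelength

    def is_resonant(self, rel_tol: float = 1e-9) -> bool:
        """True when the cavity length is an integer number of half waves."""
        half_waves = 2.0 * self.cavity_length / self.wavelength
        return abs(half_waves - round(half_waves)) <= rel_tol * max(1.0, abs(half_waves))

    @property
    def mode_number(self) -> int:
        """Number of half wavelengths spanning the cavity (resonant fields)."""
        if not self.is_resonant():
            raise ValueError("field is not resonant; mode number undefined")
        return round(2.0 * self.cavity_length / self.wavelength)


@dataclass
class TrajectoryResult:
    """Particle positions over time plus aggregation summaries."""

    times: np.ndarray  # (n_times,)
    positions: np.ndarray  # (n_particles, n_times)
    converged_fraction: float
    enrichment_factor: float = dc_field(default=float("nan"))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.positions.ndim != 2:
            raise ValueError("times must be 1D and positions 2D")
        if self.positions.shape[1] != self.times.size:
            raise ValueError("positions and times disagree on n_times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def acoustic_contrast_factor(particle: ParticleSpec, medium: MediumSpec) -> float:
    """Dimensionless contrast factor deciding node vs antinode attraction.

    ``1 + 3 (rho_p - rho_m) / (2 rho_p + rho_m) - beta_p / beta_m``;
    positive for dense, stiff particles (node seekers), negative for
    light, compressible ones (antinode seekers).
    """
    rho_term = 3.0 * (particle.density_p - medium.density_m) / (
        2.0 * particle.density_p + medium.density_m
    )
    beta_term = particle.compressibility_p / medium.compressibility_m
    return 1.0 + rho_term - beta_term


def primary_radiation_force(
    x: float | np.ndarray,
    particle: ParticleSpec,
    medium: MediumSpec,
    field: StandingWaveField,
) -> float | np.ndarray:
    """Time-averaged radiation force at displacement ``x`` from a pressure node.

    F(x) = -(pi P_a^2 V_p beta_m / 2 lambda) * Phi * sin(2 k x)

    The force vanishes wherever ``sin(2 k x) = 0`` (nodes and antinodes)
    and, for a positive contrast factor, is restoring about the nodes.
    """
    phi = acoustic_contrast_factor(particle, medium)
    amplitude = (
        math.pi
        * field.pressure_amplitude**2
        * particle.volume
        * medium.compressibility_m
        / (2.0 * field.wavelength)
    )
    return -amplitude * phi * np.sin(2.0 * field.wavenumber * np.asarray(x, dtype=float))


def prf_amplitude(particle: ParticleSpec, medium: MediumSpec, field: StandingWaveField) -> float:
    """Peak magnitude of the primary radiation force, |F| at sin(2kx) = +/-1."""
    phi = acoustic_contrast_factor(particle, medium)
    return abs(
        math.pi
        * field.pressure_amplitude**2
        * particle.volume
        * medium.compressibility_m
        / (2.0 * field.wavelength)
        * phi
    )


def pressure_nodes(field: StandingWaveField, contrast_sign: int = 1) -> np.ndarray:
    """Stable equilibrium positions (cavity coordinates) of a resonant mode.

    With ``contrast_sign=+1`` these are the interior pressure nodes at odd
    quarter-wavelength positions (one per half wavelength, so mode *m* has
    exactly *m*); with ``contrast_sign=-1`` the interior pressure antinodes.

    Raises ``ValueError`` for a non-resonant field, whose mode structure
    is undefined in this 1D idealization.
    """
    if contrast_sign not in (1, -1):
        raise ValueError("contrast_sign must be +1 or -1")
    if not field.is_resonant():
        raise ValueError(
            "cavity length is not an integer number of half wavelengths; "
            "standing mode structure is undefined"
        )
    m = field.mode_number
    quarter = field.wavelength / 4.0
    if contrast_sign > 0:
        # interior pressure nodes: lambda/4, 3 lambda/4, ...
        return np.array([(2 * j + 1) * quarter for j in range(m)])
    # interior pressure antinodes: lambda/2, lambda, ... (walls excluded)
    return np.array([2 * j * quarter for j in range(1, m)])


def _cavity_force(
    u: np.ndarray,
    particle: ParticleSpec,
    medium: MediumSpec,
    field: StandingWaveField,
) -> np.ndarray:
    """Radiation force at cavity coordinate ``u`` (walls at antinodes)."""
    return primary_radiation_force(u - field.wavelength / 4.0, particle, medium, field)


def simulate_migration(
    initial_positions: np.ndarray,
    particle: ParticleSpec,
    medium: MediumSpec,
    field: StandingWaveField,
    duration: float,
    dt: float,
    brownian: bool = False,
    seed: int = 0,
    force_scale: float = 1.0,
    convergence_tol: float | None = None,
) -> TrajectoryResult:
    """Overdamped (Stokes-drag) Euler-Maruyama migration in the cavity.

    Update rule per step: ``u <- u + F(u) dt / (6 pi eta r)`` plus, when
    ``brownian`` is on, a Gaussian increment of standard deviation
    ``sqrt(2 k_B T dt / (6 pi eta r))``.  ``r`` is the particle's
    hydrodynamic radius (cluster radius when set).  ``force_scale``
    multiplies the deterministic force, a hook for aggregate-scale force
    scaling without touching the drag.

    Positions are clipped to the cavity.  Raises if the deterministic
    step could overshoot past an antinode (a quarter wavelength) in a
    single update, which breaks the monotone-descent guarantee.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if duration < dt:
        raise ValueError("duration must be >= dt")
    u0 = np.atleast_1d(np.asarray(initial_positions, dtype=float)).copy()
    if np.any(u0 < 0) or np.any(u0 > field.cavity_length):
        raise ValueError("initial positions must lie within the cavity")

    drag = 6.0 * math.pi * medium.dynamic_viscosity * particle.hydrodynamic_radius
    mobility = force_scale / drag
    max_step = prf_amplitude(particle, medium, field) * mobility * dt
    if max_step >= field.wavelength / 4.0:
        raise ValueError(
            f"dt too large: maximum deterministic step {max_step:.3g} m reaches "
            f"past an antinode (lambda/4 = {field.wavelength / 4.0:.3g} m)"
        )

    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    positions = np.empty((u0.size, n_steps + 1))
    positions[:, 0] = u0
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(2.0 * BOLTZMANN_K * medium.temperature * dt / drag) if brownian else 0.0

    u = u0
    for step in range(1, n_steps + 1):
        u = u + _cavity_force(u, particle, medium, field) * mobility * dt
        if brownian:
            u = u + rng.normal(0.0, sigma, size=u.shape)
        u = np.clip(u, 0.0, field.cavity_length)
        positions[:, step] = u

    tol = convergence_tol if convergence_tol is not None else 0.01 * field.wavelength
    phi = acoustic_contrast_factor(particle, medium)
    stable = pressure_nodes(field, 1 if phi >= 0 else -1) if field.is_resonant() else np.array([])
    if stable.size:
        dist = np.min(np.abs(u[:, None] - stable[None, :]), axis=1)
        converged = float(np.mean(dist <= tol))
    else:
        converged = 0.0
    return TrajectoryResult(times=times, positions=positions, converged_fraction=converged)


def enrichment_factor(
    traj: TrajectoryResult,
    window_half_width: float,
    field: StandingWaveField,
    contrast_sign: int = 1,
) -> float:
    """Final/initial particle count ratio inside node-centered windows.

    Windows of half-width ``window_half_width`` are placed on every stable
    equilibrium of the field; the factor is the count of particles inside
    any window at the final time divided by the count at the initial time.
    Equals 1 when positions never change; a uniform cloud collapsing
    entirely into a window covering a tenth of the cavity gives ~10.
    """
    if traj.positions.size == 0:
        raise ValueError("empty trajectory")
    if window_half_width <= 0:
        raise ValueError("window_half_width must be > 0")
    nodes = pressure_nodes(field, contrast_sign)
    if np.any(nodes - window_half_width < 0) or np.any(nodes + window_half_width > field.cavity_length):
        raise ValueError("window extends outside the cavity")

    def count_inside(col: np.ndarray) -> int:
        dist = np.min(np.abs(col[:, None] - nodes[None, :]), axis=1)
        return int(np.sum(dist <= window_half_width))

    n_initial = count_inside(traj.positions[:, 0])
    if n_initial == 0:
        raise ValueError("no particles start inside the window; factor undefined")
    return count_inside(traj.positions[:, -1]) / n_initial
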