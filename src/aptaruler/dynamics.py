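"""Overdamped Brownian dynamics of the tethered particle.

The particle's gap coordinate z diffuses in the potential of mean force
recovered from the Monte Carlo ensemble.  Inertia is negligible at this
scale, so the motion follows the overdamped Langevin equation integrated
with the Euler–Maruyama scheme:

    z(t+dt) = z(t) + (D/kT) F(z) dt + sqrt(2 D dt) xi,   xi ~ N(0,1)

with D from Stokes–Einstein, D = kT / (6 pi eta R), and reflecting
walls at z = 0 and at the top edge of the profile support (the tether
cannot extend beyond the range the Monte Carlo ensemble reaches).  D is
held constant in z (no near-wall hindrance): a
z-dependent mobility rescales the time axis but leaves the equilibrium
distribution — the only input to the optical signal — unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import EnergyProfile
from .tether import ParticleSpec

__all__ = [
    "MediumSpec",
    "Trajectory",
    "stokes_einstein",
    "simulate_trajectory",
    "trajectory_to_distribution",
]

BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass(frozen=True)
class MediumSpec:
    """Viscous bath; defaults are water at 298 K."""

    viscosity: float = 8.9e-4  # Pa s
    temperature: float = 298.0  # K

    def __post_init__(self) -> None:
        if self.viscosity <= 0 or self.temperature <= 0:
            raise ValueError("viscosity and temperature must be > 0")


@dataclass
class Trajectory:
    times: np.ndarray  # s
    z: np.ndarray  # nm
    dt: float  # s
    seed: int
    diffusion_coefficient: float  # m^2/s


def stokes_einstein(particle: ParticleSpec, medium: MediumSpec) -> float:
    """Free diffusion coefficient of the sphere, m^2/s."""
    radius_m = particle.radius * 1e-9
    return BOLTZMANN_J_PER_K * medium.temperature / (
        6.0 * np.pi * medium.viscosity * radius_m
    )


def simulate_trajectory(
    profile: EnergyProfile,
    particle: ParticleSpec = ParticleSpec(),
    medium: MediumSpec = MediumSpec(),
    dt: float = 1e-8,
    n_steps: int = 1_000_000,
    seed: int | None = None,
) -> Trajectory:
    """Euler–Maruyama integration of the gap coordinate.

    The initial position is drawn from the equilibrium density implied
    by the profile, which removes burn-in sensitivity.  The step is
    aborted if the thermal step length exceeds five profile bins: the
    force field would then be badly under-resolved per step.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if seed is None:
        raise ValueError("an explicit seed is required")

    d_m2_s = stokes_einstein(particle, medium)
    d_nm2_s = d_m2_s * 1e18
    sigma = float(np.sqrt(2.0 * d_nm2_s * dt))  # nm per step
    dz = profile.bin_width
    if sigma > 5.0 * dz:
        raise RuntimeError(
            f"thermal step {sigma:.3g} nm exceeds 5 profile bins "
            f"({5 * dz:.3g} nm); decrease dt or coarsen the profile"
        )

    rng = np.random.default_rng(seed)
    zb = profile.z_bins
    force = profile.force
    z0_edge = float(zb[0])
    n_bins = zb.size

    # equilibrium initial condition: bin choice + uniform jitter in bin
    p_eq = profile.equilibrium_density() * dz
    p_eq = p_eq / p_eq.sum()
    z = float(rng.choice(zb, p=p_eq) + rng.uniform(-0.5, 0.5) * dz)
    z = abs(z)

    mobility_dt = d_nm2_s * dt  # (D/kT) * dt with F in kT/nm
    noise = rng.standard_normal(n_steps) * sigma
    out = np.empty(n_steps + 1)
    out[0] = z
    z_top = float(zb[-1]) + 0.5 * dz  # reflecting upper edge of the support
    for i in range(n_steps):
        # linear force interpolation on the uniform bin grid
        x = (z - z0_edge) / dz
        if x <= 0.0:
            f = force[0]
        elif x >= n_bins - 1:
            f = force[-1]
        else:
            j = int(x)
            w = x - j
            f = force[j] * (1.0 - w) + force[j + 1] * w
        z = z + mobility_dt * f + noise[i]
        if z < 0.0:
            z = -z
        elif z > z_top:
            z = 2.0 * z_top - z
        out[i + 1] = z

    times = np.arange(n_steps + 1) * dt
    return Trajectory(
        times=times, z=out, dt=dt, seed=seed, diffusion_coefficient=d_m2_s
    )


def trajectory_to_distribution(
    traj: Trajectory, bin_width: float = 0.25, burn_in: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized gap histogram of the post-burn-in trajectory.

    Returns ``(bin_centers, density)`` with the density integrating to 1.
    """
    if not 0.0 <= burn_in < 1.0:
        raise ValueError("burn_in must be in [0, 1)")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    start = int(np.ceil(burn_in * traj.z.size))
    z = traj.z[start:]
    if z.size == 0:
        raise ValueError("burn_in discarded every sample")
    hi = max(float(z.max()), bin_width)
    edges = np.arange(int(np.ceil(hi / bin_width)) + 2) * bin_width
    density, edges = np.histogram(z, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density
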