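"""Potential of mean force from inverse Boltzmann statistics.

The Monte Carlo gap histogram p(z) is converted to an energy profile
E(z) = -kT ln p(z), shifted so its minimum is zero, and differentiated
to a force field F(z) = -dE/dz used by the Brownian-dynamics integrator.
Energies are kept in kT units throughout; the stored temperature is for
unit conversion only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EnergyProfile", "invert_boltzmann", "force_at"]

#: Energy assigned to never-visited bins: highest observed energy plus
#: this many kT.  Keeps the force field finite; equilibrium dynamics
#: essentially never visits these bins.
ZERO_BIN_PENALTY_KT = 5.0


@dataclass
class EnergyProfile:
    """z-binned free-energy profile (kT) and force field (kT/nm)."""

    z_bins: np.ndarray  # uniform bin centers, nm
    energy: np.ndarray  # kT, min shifted to 0
    force: np.ndarray  # kT/nm, -dE/dz
    temperature: float = 298.0  # K

    @property
    def bin_width(self) -> float:
        return float(self.z_bins[1] - self.z_bins[0])

    def equilibrium_density(self) -> np.ndarray:
        """Boltzmann weight exp(-E) renormalized to a probability density."""
        w = np.exp(-self.energy)
        return w / (w.sum() * self.bin_width)


def invert_boltzmann(
    z_bins: np.ndarray,
    density: np.ndarray,
    temperature: float = 298.0,
) -> EnergyProfile:
    """Invert a gap probability density into a potential of mean force.

    Parameters
    ----------
    z_bins
        Uniformly spaced bin centers (nm).
    density
        Non-negative probability density over the bins; must integrate
        to ~1 and populate at least 10 bins.
    temperature
        Bath temperature in K, stored for unit conversion.

    Notes
    -----
    Empty bins cannot carry ``-ln 0``; they are capped at the highest
    observed energy plus ``ZERO_BIN_PENALTY_KT``.  The force is the
    negative centered finite difference of the energy (one-sided at the
    endpoints).
    """
    z_bins = np.asarray(z_bins, dtype=float)
    density = np.asarray(density, dtype=float)
    if z_bins.ndim != 1 or z_bins.size < 2:
        raise ValueError("need at least two bins")
    if z_bins.shape != density.shape:
        raise ValueError("z_bins and density must have matching shapes")
    if np.any(density < 0):
        raise ValueError("density must be non-negative")
    dz = np.diff(z_bins)
    if not np.allclose(dz, dz[0], rtol=1e-6):
        raise ValueError("bins must be uniform")
    nonzero = density > 0
    if not nonzero.any():
        raise ValueError("all-zero histogram")
    if nonzero.sum() < 10:
        raise ValueError("need at least 10 non-empty bins")
    total = density.sum() * dz[0]
    if not np.isclose(total, 1.0, rtol=1e-3):
        raise ValueError(f"density integrates to {total:.4f}, expected 1")

    energy = np.full_like(density, np.nan)
    energy[nonzero] = -np.log(density[nonzero])
    energy[nonzero] -= np.nanmin(energy)
    energy[~nonzero] = np.nanmax(energy) + ZERO_BIN_PENALTY_KT
    force = -np.gradient(energy, z_bins)
    return EnergyProfile(z_bins=z_bins, energy=energy, force=force, temperature=temperature)


def force_at(profile: EnergyProfile, z: float | np.ndarray) -> float | np.ndarray:
    """Linearly interpolated force (kT/nm) at gap z.

    Below the first bin center the first-bin force is returned (the wall
    at z = 0 is handled as a reflecting boundary by the integrator, not
    through the force field).  Above the last bin the force continues
    linearly along the slope of the last two bins, which keeps an
    escaping particle pulled back toward the support.
    """
    z_arr = np.asarray(z, dtype=float)
    if np.isnan(z_arr).any():
        raise ValueError("NaN z")
    zb, f = profile.z_bins, profile.force
    out = np.interp(z_arr, zb, f)
    above = z_arr > zb[-1]
    if np.any(above):
        slope = (f[-1] - f[-2]) / (zb[-1] - zb[-2])
        out = np.where(above, f[-1] + slope * (z_arr - zb[-1]), out)
    return float(out) if np.isscalar(z) else out
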