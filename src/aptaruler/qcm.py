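"""Quartz-crystal-microbalance quantification via the Sauerbrey equation.

A rigid adsorbed layer lowers the resonance frequency of a quartz
crystal linearly in its areal mass:

    mass [ng/cm^2] = C * delta_f / n

with C the crystal's mass-sensitivity constant referenced to the
fundamental and n the overtone order of the monitored harmonic (n = 1
if the instrument already reports overtone-normalized frequency).  The
areal mass divided by the adsorbate molecular weight gives the surface
density in molecules/cm^2, from which coupling efficiencies and bound
fractions follow.

Crystal defaults are the standard 5-MHz AT-cut combination
(C = 17.7 ng cm^-2 Hz^-1, third overtone, raw frequency).  Frequency
drops are passed as magnitudes: a "33 Hz drop" is ``delta_f = 33``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CrystalSpec",
    "QCMTrace",
    "sauerbrey_mass",
    "sequence_mw",
    "surface_density",
    "fraction",
    "fit_binding_slope",
    "check_rigidity",
    "NUCLEOTIDE_RESIDUE_MASS",
    "END_MOD_MASS",
]

AVOGADRO = 6.02214076e23

# Average (anhydrous) masses of 2'-deoxynucleotide monophosphate
# residues as chained in an oligo, g/mol, per the standard synthesis-
# vendor convention (e.g. IDT): oligo MW = sum(residues) + TERMINAL_5OH.
NUCLEOTIDE_RESIDUE_MASS = {
    "A": 313.21,
    "C": 289.18,
    "G": 329.21,
    "T": 304.20,
}
#: Correction for a 5'-hydroxyl (no 5'-phosphate) oligo terminus, g/mol.
TERMINAL_5OH = -61.96

# Added masses of common terminal modifications, g/mol (synthesis-vendor
# catalog values).  The shipped aptamer carries a 5' amine and a 3' thiol.
END_MOD_MASS = {
    "5-amino-C6": 172.21,  # hexylamine linker via phosphate
    "3-thiol-C3": 106.18,  # reduced propyl-thiol linker
    "5-thiol-C6": 150.24,
    "none": 0.0,
}


@dataclass(frozen=True)
class CrystalSpec:
    fundamental_frequency: float = 5e6  # Hz
    sensitivity_constant: float = 17.7  # ng cm^-2 Hz^-1, at the fundamental
    overtone: int = 3  # odd harmonic monitored
    frequency_is_normalized: bool = False  # input delta_f already delta_f/n

    def __post_init__(self) -> None:
        if self.sensitivity_constant <= 0:
            raise ValueError("sensitivity_constant must be > 0")
        if self.overtone < 1 or self.overtone % 2 == 0:
            raise ValueError("overtone must be an odd integer >= 1")


@dataclass
class QCMTrace:
    """Frequency-shift time series with labeled process intervals."""

    times: np.ndarray  # s
    delta_f: np.ndarray  # Hz (signed, drops are negative-going)
    overtone: int = 3
    annotations: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.delta_f = np.asarray(self.delta_f, dtype=float)
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be ascending")

    def interval(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        if label not in self.annotations:
            raise KeyError(f"no interval labeled {label!r}; "
                           f"available: {sorted(self.annotations)}")
        t0, t1 = self.annotations[label]
        mask = (self.times >= t0) & (self.times <= t1)
        return self.times[mask], self.delta_f[mask]


def sauerbrey_mass(delta_f: float, crystal: CrystalSpec = CrystalSpec()) -> float:
    """Areal mass (ng/cm^2) of a rigid layer from a frequency drop (Hz).

    ``delta_f`` is the magnitude of the drop.  Raw overtone frequencies
    are divided by the overtone order; overtone-normalized inputs are
    used as-is.
    """
    if delta_f < 0:
        raise ValueError("pass the magnitude of the frequency drop")
    n = 1 if crystal.frequency_is_normalized else crystal.overtone
    return crystal.sensitivity_constant * delta_f / n


def sequence_mw(sequence: str, end_mods: tuple[str, ...] | list[str] = ()) -> float:
    """Average molecular weight (g/mol) of a synthetic ssDNA oligo.

    Sums per-residue monophosphate masses, applies the 5'-OH terminal
    correction, and adds the catalog masses of any terminal
    modifications listed in ``END_MOD_MASS``.
    """
    sequence = sequence.upper()
    if not sequence:
        raise ValueError("empty sequence")
    try:
        mw = sum(NUCLEOTIDE_RESIDUE_MASS[b] for b in sequence) + TERMINAL_5OH
    except KeyError as exc:
        raise ValueError(f"unknown base {exc.args[0]!r}") from None
    for mod in end_mods:
        if mod not in END_MOD_MASS:
            raise ValueError(f"unknown modification {mod!r}; "
                             f"known: {sorted(END_MOD_MASS)}")
        mw += END_MOD_MASS[mod]
    return float(mw)


def surface_density(mass_ng_per_cm2: float, mw_g_per_mol: float) -> float:
    """Molecules per cm^2 from areal mass (ng/cm^2) and MW (g/mol)."""
    if mass_ng_per_cm2 < 0 or mw_g_per_mol <= 0:
        raise ValueError("mass must be >= 0 and molecular weight > 0")
    return mass_ng_per_cm2 * 1e-9 / mw_g_per_mol * AVOGADRO


def fraction(numerator_density: float, denominator_density: float) -> float:
    """Ratio of two surface densities, in percent."""
    if denominator_density <= 0:
        raise ValueError("denominator density must be > 0")
    return 100.0 * numerator_density / denominator_density


def fit_binding_slope(trace: QCMTrace, interval_label: str) -> float:
    """OLS slope of delta_f vs time over a labeled interval, in Hz/min."""
    t, f = trace.interval(interval_label)
    if t.size < 3:
        raise ValueError(f"interval {interval_label!r} has fewer than 3 points")
    res = stats.linregress(t, f)
    return float(res.slope * 60.0)


def check_rigidity(
    delta_d: float,
    delta_f: float,
    crystal: CrystalSpec = CrystalSpec(),
    max_ratio: float = 4e-7,
) -> bool:
    """Warn when the film violates the rigid (Sauerbrey) assumption.

    Uses the common rule of thumb on dissipation per normalized
    frequency shift, |delta_D| / (delta_f / n); above ``max_ratio``
    (per Hz) the Sauerbrey mass underestimates the true layer.
    Returns True when the rigid-layer assumption looks safe.
    """
    if delta_f <= 0:
        raise ValueError("delta_f magnitude must be > 0")
    n = 1 if crystal.frequency_is_normalized else crystal.overtone
    ratio = abs(delta_d) / (delta_f / n)
    if ratio > max_ratio:
        warnings.warn(
            f"dissipation ratio {ratio:.2e} exceeds {max_ratio:.1e}; "
            "Sauerbrey rigidity assumption questionable",
            stacklevel=2,
        )
        return False
    return True
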