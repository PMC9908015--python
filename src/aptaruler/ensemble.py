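"""Ensemble-mode analysis: spectrum correction, calibration, LOD, stats.

In ensemble mode the microspectrometer averages the scattering of all
particles in its spot.  The pipeline here mirrors the experimental
processing chain: raw spectra are background-subtracted and normalized
by the excitation spectrum; the RG ratio is regressed on the natural
logarithm of the endotoxin concentration; the limit of detection is the
bracket between the highest concentration indistinguishable from blank
and the lowest distinguishable one; and group comparisons use Student's
t (two groups) or one-way ANOVA (three or more), significant at
p < 0.05.

The calibration axis is the natural logarithm: the experimentally fitted
line RG = 0.106 ln C + 0.902 evaluated at 500 EU/ml returns ~1.561,
matching the measured 1.563, which a base-10 axis does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .scattering import Spectrum

__all__ = [
    "CalibrationFit",
    "GroupComparison",
    "correct_spectrum",
    "fit_calibration",
    "predict_rg",
    "estimate_concentration",
    "estimate_lod",
    "eu_to_ng",
    "compare_groups",
]

ALPHA = 0.05

#: Activity-to-mass conversion for this LPS preparation: 10 EU per ng.
EU_PER_NG = 10.0


@dataclass
class CalibrationFit:
    """ln-linear calibration RG = slope * ln(C) + intercept."""

    slope: float  # RG per ln(EU/ml)
    intercept: float  # RG at 1 EU/ml
    r_squared: float
    concentrations: np.ndarray  # EU/ml, fitted levels
    rg_means: np.ndarray
    rg_sds: np.ndarray
    log_base: str = "ln"
    blank_rg: np.ndarray | None = None  # 0 EU/ml replicates, excluded from fit


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    group_labels: tuple[str, ...]
    test_name: str  # "student_t" | "welch_t" | "anova"
    df: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def correct_spectrum(
    raw: Spectrum, background: Spectrum, excitation: Spectrum
) -> Spectrum:
    """Background-subtract and excitation-normalize a raw spectrum.

    ``(raw - background) / excitation`` on the raw grid, clipped at
    zero.  Background and excitation are resampled to the raw grid by
    linear interpolation; their grids must cover it.
    """
    lam = raw.wavelengths

    def _resample(s: Spectrum, name: str) -> np.ndarray:
        if s.wavelengths[0] > lam[0] + 1e-9 or s.wavelengths[-1] < lam[-1] - 1e-9:
            raise ValueError(f"{name} grid does not cover the raw grid")
        return np.interp(lam, s.wavelengths, s.intensity)

    bg = _resample(background, "background")
    exc = _resample(excitation, "excitation")
    if np.any(exc <= 0):
        raise ValueError("excitation must be positive everywhere on the raw grid")
    corrected = np.clip((raw.intensity - bg) / exc, 0.0, None)
    meta = dict(raw.meta)
    meta["corrected"] = "background-subtracted, excitation-normalized"
    return Spectrum(lam.copy(), corrected, meta=meta)


def fit_calibration(
    concentrations: Sequence[float],
    rg_values: Sequence[Sequence[float]],
    fit_on_means: bool = True,
    log_base: str = "ln",
) -> CalibrationFit:
    """Ordinary least squares of RG on log concentration.

    Parameters
    ----------
    concentrations
        Concentration levels in EU/ml.  Zero-concentration blanks are
        excluded from the fit (log undefined) but stored on the result
        for blank-significance testing.
    rg_values
        Per-level replicate lists, aligned with ``concentrations``.
    fit_on_means
        Fit replicate means (the experimental convention of one point
        per level) rather than all replicates.
    log_base
        ``"ln"`` (default) or ``"log10"``.
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.size != len(rg_values):
        raise ValueError("concentrations and rg_values must align")
    if np.any(conc < 0):
        raise ValueError("negative concentration")
    blank_rg = None
    if np.any(conc == 0):
        blank_rg = np.concatenate(
            [np.asarray(r, float) for r, c in zip(rg_values, conc) if c == 0]
        )
    keep = conc > 0
    conc_fit = conc[keep]
    reps = [np.asarray(r, dtype=float) for r, k in zip(rg_values, keep) if k]
    if np.unique(conc_fit).size < 3:
        raise ValueError("need at least 3 distinct positive concentration levels")
    means = np.array([r.mean() for r in reps])
    sds = np.array([r.std(ddof=1) if r.size > 1 else 0.0 for r in reps])

    logf = np.log if log_base == "ln" else np.log10
    if log_base not in ("ln", "log10"):
        raise ValueError("log_base must be 'ln' or 'log10'")
    if fit_on_means:
        x = logf(conc_fit)
        y = means
    else:
        x = np.concatenate([np.full(r.size, logf(c)) for c, r in zip(conc_fit, reps)])
        y = np.concatenate(reps)
    res = stats.linregress(x, y)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        concentrations=conc_fit,
        rg_means=means,
        rg_sds=sds,
        log_base=log_base,
        blank_rg=blank_rg,
    )


def _logf(fit: CalibrationFit):
    return np.log if fit.log_base == "ln" else np.log10


def predict_rg(fit: CalibrationFit, concentration: float) -> float:
    """RG predicted by the calibration line at a concentration (EU/ml)."""
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    return fit.slope * float(_logf(fit)(concentration)) + fit.intercept


def estimate_concentration(fit: CalibrationFit, rg: float) -> float:
    """Invert the calibration line: concentration (EU/ml) at a given RG."""
    if fit.slope == 0:
        raise ValueError("cannot invert a zero-slope calibration")
    x = (rg - fit.intercept) / fit.slope
    return float(np.exp(x)) if fit.log_base == "ln" else float(10.0**x)


def estimate_lod(
    fit: CalibrationFit | None,
    measured_levels: Sequence[tuple[float, bool]],
) -> tuple[float, float]:
    """Bracket the limit of detection from blank-significance flags.

    ``measured_levels`` pairs each tested concentration with whether its
    RG differed significantly from the blank (``compare_groups`` at
    alpha = 0.05).  The LOD lies between the highest non-significant and
    the lowest significant concentration; flags must therefore be
    monotone in concentration.
    """
    levels = sorted(measured_levels, key=lambda cf: cf[0])
    flags = [bool(f) for _, f in levels]
    if all(flags) or not any(flags):
        raise ValueError(
            "open LOD bracket: need at least one non-significant and one "
            "significant level"
        )
    first_sig = flags.index(True)
    if any(flags[:first_sig]) or not all(flags[first_sig:]):
        raise ValueError("significance flags are not monotone in concentration")
    return (levels[first_sig - 1][0], levels[first_sig][0])


def eu_to_ng(concentration_eu_per_ml: float) -> float:
    """Convert endotoxin activity (EU/ml) to mass (ng/ml); 10 EU = 1 ng."""
    if concentration_eu_per_ml < 0:
        raise ValueError("concentration must be >= 0")
    return concentration_eu_per_ml / EU_PER_NG


def compare_groups(
    groups: Sequence[Sequence[float]],
    mode: str = "two-sample",
    labels: Sequence[str] | None = None,
    welch: bool = False,
) -> GroupComparison:
    """Student's t test (two groups) or one-way ANOVA (three or more)."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs n >= 2")
    if labels is None:
        labels = tuple(f"group{i}" for i in range(len(arrs)))
    labels = tuple(labels)

    if mode == "two-sample":
        if len(arrs) != 2:
            raise ValueError("two-sample mode requires exactly 2 groups")
        a, b = arrs
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                df = a.size + b.size - 2
                return GroupComparison(0.0, 1.0, labels, "student_t", df)
            raise ValueError(
                "degenerate variance: both groups constant with different means"
            )
        res = stats.ttest_ind(a, b, equal_var=not welch)
        name = "welch_t" if welch else "student_t"
        df = float(res.df)
        return GroupComparison(float(res.statistic), float(res.pvalue), labels, name, df)
    if mode == "multi":
        if len(arrs) < 3:
            raise ValueError("multi mode requires >= 3 groups")
        res = stats.f_oneway(*arrs)
        df = float(len(arrs) - 1)
        return GroupComparison(float(res.statistic), float(res.pvalue), labels, "anova", df)
    raise ValueError("mode must be 'two-sample' or 'multi'")
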