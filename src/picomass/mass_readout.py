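"""Picobalance mass bookkeeping.

Converts eigenfrequency pairs measured before and after cell attachment into
cell masses, corrects for the cell position along the cantilever beam, fits
frequency sweeps, converts photodiode volts to deflection, and assembles
time-resolved mass trajectories from consecutive sweeps.

The core relation treats the payload as a rigidly attached point mass:

    m* = (k_cant / 4 pi^2) (1 / f_after^2 - 1 / f_before^2).

A payload away from the free end contributes only phi(xi)^2 of its mass to
the modal mass (phi = first flexural clamped-free mode shape, normalized to
phi(1) = 1 at the tip), so the position-corrected mass is m* / phi(xi)^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lumped_model import (
    FitConvergenceError,
    ShoFit,
    SweepSpectrum,
    TWO_PI,
    fit_sho,
)

__all__ = [
    "MassMeasurement",
    "MassTrajectory",
    "mass_from_frequency_shift",
    "frequency_after_attachment",
    "mode_shape",
    "correct_for_position",
    "fit_sweep",
    "volts_to_meters",
    "mass_trajectory",
]

# first clamped-free Euler-Bernoulli root and the associated mode constant
_LAMBDA1 = 1.87510407
_SIGMA1 = (math.cosh(_LAMBDA1) + math.cos(_LAMBDA1)) / (
    math.sinh(_LAMBDA1) + math.sin(_LAMBDA1)
)

FLAG_OK = "ok"
FLAG_NEGATIVE = "negative_mass"
FLAG_FIT_FAILED = "fit_failed"


def mass_from_frequency_shift(spring_constant, f_before, f_after):
    """Apparent point mass from the eigenfrequency shift (rigid-payload law).

    Returns ``(k / 4 pi^2)(1/f_after^2 - 1/f_before^2)`` in kg.  A negative
    value (f_after > f_before, possible under noise) is returned as-is so
    that downstream averaging remains unbiased; callers flag it.
    """
    k = np.asarray(spring_constant, dtype=float)
    fb = np.asarray(f_before, dtype=float)
    fa = np.asarray(f_after, dtype=float)
    if np.any(k <= 0):
        raise ValueError("spring_constant must be strictly positive")
    if np.any(fb <= 0) or np.any(fa <= 0):
        raise ValueError("frequencies must be strictly positive")
    out = (k / TWO_PI**2) * (1.0 / fa**2 - 1.0 / fb**2)
    return float(out) if out.ndim == 0 else out


def frequency_after_attachment(spring_constant, f_before, mass):
    """Invert the rigid-payload law: eigenfrequency after adding ``mass``.

    ``1/f_after^2 = 1/f_before^2 + 4 pi^2 m / k``; the exact inverse of
    :func:`mass_from_frequency_shift`.
    """
    k = np.asarray(spring_constant, dtype=float)
    fb = np.asarray(f_before, dtype=float)
    if np.any(k <= 0) or np.any(fb <= 0):
        raise ValueError("spring_constant and f_before must be strictly positive")
    inv_sq = 1.0 / fb**2 + TWO_PI**2 * np.asarray(mass, dtype=float) / k
    out = 1.0 / np.sqrt(inv_sq)
    return float(out) if out.ndim == 0 else out


def mode_shape(position_fraction):
    """First flexural mode shape of a clamped-free beam, tip-normalized.

    ``phi(xi) = [cosh(l xi) - cos(l xi) - s (sinh(l xi) - sin(l xi))] / phi(1)``
    with l = 1.87510407 and s = (cosh l + cos l)/(sinh l + sin l).
    ``phi(0) = 0`` (clamped end), ``phi(1) = 1`` (free end), strictly
    increasing in between.
    """
    xi = np.asarray(position_fraction, dtype=float)
    if np.any(xi < 0) or np.any(xi > 1):
        raise ValueError("position_fraction must lie in [0, 1]")
    x = _LAMBDA1 * xi
    raw = np.cosh(x) - np.cos(x) - _SIGMA1 * (np.sinh(x) - np.sin(x))
    tip = (
        math.cosh(_LAMBDA1)
        - math.cos(_LAMBDA1)
        - _SIGMA1 * (math.sinh(_LAMBDA1) - math.sin(_LAMBDA1))
    )
    out = raw / tip
    return float(out) if out.ndim == 0 else out


def correct_for_position(apparent_mass, position_fraction, min_position: float = 0.2):
    """Total cell mass from the apparent mass and the cell position.

    ``m = m* / phi(xi)^2``.  Identity at the free end (xi = 1).  Positions
    below ``min_position`` are refused: there the correction factor exceeds
    ~40x and is dominated by position noise.
    """
    xi = np.asarray(position_fraction, dtype=float)
    if np.any(xi < min_position) or np.any(xi > 1):
        raise ValueError(
            f"position_fraction must lie in [{min_position}, 1]; the correction "
            "factor diverges toward the clamped end"
        )
    out = np.asarray(apparent_mass, dtype=float) / mode_shape(xi) ** 2
    return float(out) if out.ndim == 0 else out


def fit_sweep(spectrum: SweepSpectrum, fit_baseline: bool = False) -> ShoFit:
    """Fit a frequency sweep with the SHO amplitude model.

    Thin wrapper over the lumped-model SHO fit; returns the fitted
    eigenfrequency f0, quality factor, amplitude scale and RMS residual.
    """
    return fit_sho(spectrum, fit_baseline=fit_baseline)


def volts_to_meters(amplitude_v, sensitivity_v_per_m):
    """Optical-lever conversion of photodiode amplitude (V) to deflection (m)."""
    if not sensitivity_v_per_m > 0:
        raise ValueError("sensitivity_v_per_m must be strictly positive")
    out = np.asarray(amplitude_v, dtype=float) / sensitivity_v_per_m
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MassMeasurement:
    """One mass readout from a before/after eigenfrequency pair."""

    spring_constant: float
    f_before: float
    f_after: float
    position_fraction: float = 1.0
    timestamp: float | None = None

    @property
    def eigenfrequency_shift(self) -> float:
        return self.f_before - self.f_after

    @property
    def apparent_mass(self) -> float:
        return mass_from_frequency_shift(self.spring_constant, self.f_before, self.f_after)

    @property
    def corrected_mass(self) -> float:
        return correct_for_position(self.apparent_mass, self.position_fraction)

    @property
    def flag(self) -> str:
        return FLAG_NEGATIVE if self.apparent_mass < 0 else FLAG_OK


@dataclass(frozen=True)
class MassTrajectory:
    """Time series of position-corrected cell masses with quality flags."""

    times: np.ndarray
    masses: np.ndarray
    positions: np.ndarray
    flags: list[str]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.masses, dtype=float)
        p = np.asarray(self.positions, dtype=float)
        if not (t.size == m.size == p.size == len(self.flags)):
            raise ValueError("times, masses, positions, flags must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "masses", m)
        object.__setattr__(self, "positions", p)

    def rolling_median(self, window: int = 5) -> np.ndarray:
        """Optional rolling-median smoothing of the mass series (odd window)."""
        import pandas as pd

        return (
            pd.Series(self.masses)
            .rolling(window, center=True, min_periods=1)
            .median()
            .to_numpy()
        )


def mass_trajectory(
    sweeps: list[SweepSpectrum],
    f_before: float,
    spring_constant: float,
    positions,
) -> MassTrajectory:
    """Mass-vs-time from consecutive sweeps sharing one calibration.

    Each sweep (timestamped) is SHO-fitted for f_after, converted through the
    rigid-payload law, and position-corrected.  Non-converging fits are kept
    as NaN with a ``fit_failed`` flag; negative masses are flagged, not
    clipped.  Raises if every sweep fails.
    """
    if len(sweeps) == 0:
        raise ValueError("need at least one sweep")
    positions = np.broadcast_to(np.asarray(positions, dtype=float), (len(sweeps),))
    times, masses, flags = [], [], []
    for sweep, xi in zip(sweeps, positions):
        if sweep.timestamp is None:
            raise ValueError("every sweep needs a timestamp")
        times.append(sweep.timestamp)
        try:
            f_after = fit_sweep(sweep).f0
        except (FitConvergenceError, ValueError):
            masses.append(math.nan)
            flags.append(FLAG_FIT_FAILED)
            continue
        m_star = mass_from_frequency_shift(spring_constant, f_before, f_after)
        masses.append(correct_for_position(m_star, float(xi)))
        flags.append(FLAG_NEGATIVE if m_star < 0 else FLAG_OK)
    if all(f == FLAG_FIT_FAILED for f in flags):
        raise FitConvergenceError("all sweeps failed to fit")
    return MassTrajectory(
        times=np.asarray(times), masses=np.asarray(masses),
        positions=positions.copy(), flags=flags,
    )
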