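"""Two-degree-of-freedom lumped-mass model of a cell on an oscillating cantilever.

The cantilever is a driven damped harmonic oscillator (spring constant
``k_cant``, modal mass ``m_cant``, damping ``c_cant``).  The cell is a point
mass ``m_cell`` attached to the cantilever end through a Kelvin--Voigt
element, i.e. a spring ``k_cell`` and damper ``c_cell`` in parallel.  In the
frequency domain the payload loads the cantilever with a complex, frequency
dependent *effective dynamic mass*

    m_eff(w) = m_cell * K(w) / (K(w) - w^2 m_cell),     K(w) = k_cell + i w c_cell,

and the cantilever end deflection under a harmonic drive force F is

    X(w) = F / (k_cant - w^2 [m_cant + m_eff(w)] + i w c_cant).

Sign convention: all responses use the e^{+i w t} time convention, so
dissipation enters as ``+ i w c`` and the dissipative branch of the
effective mass satisfies ``Im{m_eff} <= 0`` (the payload extracts energy
from the cantilever).

The real part of ``m_eff`` evaluated at the cantilever eigenfrequency is the
closed-form mass readout accuracy

    m_app / m_real = 1 + f_cant^2 (f_cell^2 - f_cant^2)
                         / [ (f_cell^2 - f_cant^2)^2 + f_cant^2 f_cell^2 / Q_cell^2 ],

with ``f_cell = sqrt(k_cell / m_cell) / 2 pi`` the cell eigenfrequency and
``Q_cell = sqrt(k_cell m_cell) / c_cell`` its quality factor.  A cantilever
oscillating far above the cell eigenfrequency therefore underestimates the
cell mass; far below it, the whole cell follows the motion and the rigid
point-mass readout is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

TWO_PI = 2.0 * math.pi

__all__ = [
    "CantileverModel",
    "CellMechanicalModel",
    "SweepSpectrum",
    "ShoFit",
    "PoleError",
    "PeakNotBracketedError",
    "FitConvergenceError",
    "complex_coupling",
    "effective_dynamic_mass",
    "frequency_response",
    "apparent_eigenfrequency",
    "fit_sho",
    "simulate_apparent_mass",
    "readout_accuracy",
    "stiffening_trajectory",
    "linear_damping_rule",
    "constant_q_damping_rule",
    "default_grid",
]


class PoleError(ArithmeticError):
    """Raised when an exact undamped resonance pole is hit."""


class PeakNotBracketedError(ValueError):
    """Raised when a spectrum has no interior amplitude maximum."""


class FitConvergenceError(RuntimeError):
    """Raised when a nonlinear resonance fit fails to converge."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CantileverModel:
    """A rectangular microcantilever characterized in liquid.

    Parameters
    ----------
    spring_constant : float
        Static spring constant ``k_cant`` in N/m (Sader-calibrated input).
    eigenfrequency : float
        First-mode eigenfrequency ``f_N_cant`` in Hz, as measured in liquid.
    quality_factor : float
        Quality factor ``Q_cant`` of the first mode in the measurement
        medium (order 3 in aqueous buffer).
    """

    spring_constant: float
    eigenfrequency: float
    quality_factor: float

    def __post_init__(self) -> None:
        for name in ("spring_constant", "eigenfrequency", "quality_factor"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def modal_mass(self) -> float:
        """Effective modal mass ``k / (4 pi^2 f^2)`` in kg."""
        return self.spring_constant / (TWO_PI * self.eigenfrequency) ** 2

    @property
    def damping_coefficient(self) -> float:
        """Viscous damping ``sqrt(k m) / Q`` in N s/m."""
        return math.sqrt(self.spring_constant * self.modal_mass) / self.quality_factor


@dataclass(frozen=True)
class CellMechanicalModel:
    """Point-mass cell coupled to the cantilever by a Kelvin--Voigt element.

    ``coupling_stiffness`` (``k_cell``) and ``coupling_damping`` (``c_cell``)
    describe the spring/damper attachment; ``mass`` is the whole-cell mass.
    The derived ``eigenfrequency`` and ``quality_factor`` are the modal view
    of the same three numbers.  Optionally the stiffness can be tied to a
    Young's modulus through the shape factor, ``k_cell = E * F(S)``, and the
    damping to a viscosity scale, ``c_cell = mu * F(S)``.
    """

    mass: float
    coupling_stiffness: float = 0.0
    coupling_damping: float = 0.0
    elastic_modulus: float | None = None
    shape_factor: float | None = None
    viscosity_scale: float | None = None

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError("mass must be strictly positive")
        if self.coupling_stiffness < 0:
            raise ValueError("coupling_stiffness must be non-negative")
        if self.coupling_damping < 0:
            raise ValueError("coupling_damping must be non-negative")
        if self.elastic_modulus is not None and self.shape_factor is not None:
            k = self.elastic_modulus * self.shape_factor
            if not math.isclose(k, self.coupling_stiffness, rel_tol=1e-9):
                raise ValueError(
                    "inconsistent stiffness: k_cell != elastic_modulus * shape_factor"
                )

    @classmethod
    def from_modal(
        cls,
        mass: float,
        eigenfrequency: float,
        quality_factor: float,
        **extra: float | None,
    ) -> "CellMechanicalModel":
        """Build from (mass, f_N_cell, Q_cell) instead of (mass, k, c)."""
        if not (eigenfrequency > 0 and quality_factor > 0):
            raise ValueError("eigenfrequency and quality_factor must be positive")
        k = (TWO_PI * eigenfrequency) ** 2 * mass
        c = math.sqrt(k * mass) / quality_factor
        return cls(mass=mass, coupling_stiffness=k, coupling_damping=c, **extra)

    @property
    def eigenfrequency(self) -> float:
        """Cell eigenfrequency ``sqrt(k_cell / m) / 2 pi`` in Hz (0 for a free mass)."""
        return math.sqrt(self.coupling_stiffness / self.mass) / TWO_PI

    @property
    def quality_factor(self) -> float:
        """Quality factor ``sqrt(k_cell m) / c_cell`` (inf when undamped)."""
        if self.coupling_damping == 0.0:
            return math.inf
        return math.sqrt(self.coupling_stiffness * self.mass) / self.coupling_damping


@dataclass(frozen=True)
class SweepSpectrum:
    """A frequency sweep: complex end deflection per drive frequency.

    ``complex_response`` holds displacement (m) at each point of the strictly
    increasing ``frequency_grid`` (Hz); amplitude and (unwrapped) phase are
    derived views.  ``timestamp`` tags the sweep in a time series.
    """

    frequency_grid: np.ndarray
    complex_response: np.ndarray
    drive_amplitude: float | None = None
    timestamp: float | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.frequency_grid, dtype=float)
        resp = np.asarray(self.complex_response, dtype=complex)
        if grid.ndim != 1 or grid.size == 0:
            raise ValueError("frequency_grid must be a non-empty 1-D array")
        if resp.shape != grid.shape:
            raise ValueError("complex_response length must match frequency_grid")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("frequency_grid must be strictly increasing")
        object.__setattr__(self, "frequency_grid", grid)
        object.__setattr__(self, "complex_response", resp)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.complex_response)

    @property
    def phase(self) -> np.ndarray:
        return np.unwrap(np.angle(self.complex_response))

    def __len__(self) -> int:
        return self.frequency_grid.size


# ---------------------------------------------------------------------------
# Frequency-domain physics
# ---------------------------------------------------------------------------

def complex_coupling(cell: CellMechanicalModel, frequency) -> complex | np.ndarray:
    """Complex Kelvin--Voigt coupling stiffness ``K(w) = k_cell + i w c_cell``.

    ``frequency`` is in Hz; scalar or array.  With the e^{+iwt} convention
    the damper contributes the positive imaginary part.
    """
    f = np.asarray(frequency, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    k = cell.coupling_stiffness + 1j * TWO_PI * f * cell.coupling_damping
    return complex(k) if np.isscalar(frequency) else k


def effective_dynamic_mass(cell: CellMechanicalModel, frequency) -> complex | np.ndarray:
    """Complex mass the Kelvin--Voigt-coupled cell presents to the cantilever.

    ``m_eff(w) = m K(w) / (K(w) - w^2 m)``.  At zero frequency every
    attached compartment follows the motion and ``m_eff = m``; a free mass
    (k = c = 0) loads nothing.  An exact undamped pole (drive frequency at
    the cell resonance with c_cell = 0) raises :class:`PoleError`.
    """
    scalar = np.isscalar(frequency)
    f = np.atleast_1d(np.asarray(frequency, dtype=float))
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    omega = TWO_PI * f
    K = cell.coupling_stiffness + 1j * omega * cell.coupling_damping
    denom = K - omega**2 * cell.mass
    out = np.empty(f.shape, dtype=complex)

    attached = cell.coupling_stiffness > 0 or cell.coupling_damping > 0
    zero = f == 0.0
    out[zero] = cell.mass if attached else 0.0

    nz = ~zero
    if np.any(denom[nz] == 0):
        f_res = cell.eigenfrequency
        raise PoleError(
            f"undamped resonance pole: drive frequency equals the cell "
            f"eigenfrequency {f_res:.6g} Hz with zero coupling damping"
        )
    out[nz] = cell.mass * K[nz] / denom[nz]
    return complex(out[0]) if scalar else out


def readout_accuracy(f_cant, f_cell, q_cell) -> float | np.ndarray:
    """Closed-form mass readout accuracy ``m_app / m_real`` of the 2-DOF model.

    ``1 + f_cant^2 (f_cell^2 - f_cant^2) /
    [(f_cell^2 - f_cant^2)^2 + f_cant^2 f_cell^2 / Q_cell^2]``.

    Identically equal to ``Re{m_eff(2 pi f_cant)} / m``.  Equals 1 when the
    two eigenfrequencies coincide (finite Q), tends to 1 as ``f_cant -> 0``
    and to 0 as ``f_cant -> inf``.  Accepts arrays in ``f_cant``.
    """
    fc = np.asarray(f_cant, dtype=float)
    if np.any(fc <= 0) or not f_cell > 0:
        raise ValueError("frequencies must be strictly positive")
    if not q_cell > 0:
        raise ValueError("q_cell must be strictly positive")
    d = f_cell**2 - fc**2
    denom = d**2 + fc**2 * f_cell**2 / q_cell**2
    if np.any(denom == 0):
        raise PoleError("singular readout: f_cant equals f_cell at infinite Q")
    out = 1.0 + fc**2 * d / denom
    return float(out) if np.isscalar(f_cant) else out


def frequency_response(
    cantilever: CantileverModel,
    cell: CellMechanicalModel | None,
    frequency_grid,
    drive_force: float = 1e-12,
) -> SweepSpectrum:
    """Cantilever end deflection spectrum under a constant harmonic drive force.

    With a cell attached the payload enters as ``m_eff(w)``; without one the
    response is the plain driven damped oscillator, whose zero-frequency
    amplitude is ``F / k_cant``.
    """
    grid = np.asarray(frequency_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("frequency_grid must be a non-empty 1-D array")
    if not np.all(grid > 0):
        raise ValueError("frequency_grid must be strictly positive")
    if not drive_force > 0:
        raise ValueError("drive_force must be strictly positive")

    omega = TWO_PI * grid
    m_eff = effective_dynamic_mass(cell, grid) if cell is not None else 0.0
    denom = (
        cantilever.spring_constant
        - omega**2 * (cantilever.modal_mass + m_eff)
        + 1j * omega * cantilever.damping_coefficient
    )
    return SweepSpectrum(frequency_grid=grid, complex_response=drive_force / denom)


# ---------------------------------------------------------------------------
# Eigenfrequency extraction (SHO assumption)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShoFit:
    """Result of a driven-damped-oscillator amplitude fit."""

    f0: float
    q: float
    scale: float
    baseline: float
    residual: float
    converged: bool


def _interior_peak_index(amplitude: np.ndarray) -> int:
    i = int(np.argmax(amplitude))
    if i == 0 or i == amplitude.size - 1:
        raise PeakNotBracketedError(
            "amplitude maximum lies on the grid boundary; peak not bracketed"
        )
    return i


def _parabolic_peak(freq: np.ndarray, log_amp: np.ndarray, i: int) -> float:
    # vertex of the parabola through the three points around the maximum
    x0, x1, x2 = freq[i - 1 : i + 2]
    y0, y1, y2 = log_amp[i - 1 : i + 2]
    d = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / d
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / d
    if a >= 0:
        return float(x1)
    return float(-b / (2 * a))


def _halfpower_q(freq: np.ndarray, amp: np.ndarray, i: int, f_peak: float) -> float:
    """Rough Q from the -3 dB amplitude bandwidth around the peak."""
    target = amp[i] / math.sqrt(2.0)
    lo = hi = None
    for j in range(i, 0, -1):
        if amp[j - 1] < target <= amp[j]:
            lo = np.interp(target, [amp[j - 1], amp[j]], [freq[j - 1], freq[j]])
            break
    for j in range(i, freq.size - 1):
        if amp[j + 1] < target <= amp[j]:
            hi = np.interp(target, [amp[j + 1], amp[j]], [freq[j + 1], freq[j]])
            break
    if lo is None or hi is None or hi <= lo:
        return 2.0  # bandwidth not bracketed; generic moderate-Q guess
    return max(f_peak / (hi - lo), 0.6)


def _sho_amplitude(f: np.ndarray, f0: float, q: float, scale: float, baseline: float):
    u = f / f0
    return scale / np.sqrt((1.0 - u**2) ** 2 + (u / q) ** 2) + baseline


def fit_sho(
    spectrum: SweepSpectrum,
    fit_baseline: bool = False,
) -> ShoFit:
    """Least-squares fit of the SHO amplitude response to a sweep.

    Model: ``A(f) = s / sqrt((1 - u^2)^2 + (u/Q)^2) + b`` with ``u = f/f0``.
    ``f0, Q, s`` are optimized in log-space (positivity); the constant
    baseline ``b`` is optional and fixed at 0 by default.
    """
    freq = spectrum.frequency_grid
    amp = spectrum.amplitude
    if freq.size < 7:
        raise PeakNotBracketedError("need at least 7 points bracketing the peak")
    i = _interior_peak_index(amp)
    with np.errstate(divide="ignore"):
        log_amp = np.log(np.maximum(amp, 1e-300))
    f_peak = _parabolic_peak(freq, log_amp, i)
    q0 = _halfpower_q(freq, amp, i, f_peak)
    # undo the SHO peak-position bias for the f0 start value
    f0_start = f_peak / math.sqrt(1 - 1 / (2 * q0**2)) if q0 > 0.75 else f_peak

    # normalize amplitude and frequency scales so the solver is well conditioned
    a_scale = float(amp[i])
    amp_n = amp / a_scale
    freq_n = freq / f0_start
    s0 = 1.0 / _sho_amplitude(np.array([f_peak / f0_start]), 1.0, q0, 1.0, 0.0)[0]

    def residuals(theta):
        f0, q, s = np.exp(theta[:3])
        b = theta[3] if fit_baseline else 0.0
        return _sho_amplitude(freq_n, f0, q, s, b) - amp_n

    theta0 = [0.0, math.log(q0), math.log(max(s0, 1e-300))]
    if fit_baseline:
        theta0.append(0.0)
    result = least_squares(residuals, theta0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not result.success:
        raise FitConvergenceError(
            f"SHO fit did not converge: {result.message} (status {result.status})"
        )
    f0, q, s = np.exp(result.x[:3])
    f0 *= f0_start
    s *= a_scale
    b = float(result.x[3]) * a_scale if fit_baseline else 0.0
    resid = float(np.sqrt(np.mean(result.fun**2))) * a_scale
    return ShoFit(f0=float(f0), q=float(q), scale=float(s), baseline=b,
                  residual=resid, converged=True)


def apparent_eigenfrequency(
    spectrum: SweepSpectrum,
    method: Literal["peak", "sho_fit"] = "sho_fit",
) -> float:
    """Eigenfrequency read from a sweep, assuming a simple harmonic oscillator.

    ``sho_fit`` (default) returns the f0 parameter of :func:`fit_sho`.
    ``peak`` interpolates the log-amplitude maximum parabolically and
    de-biases it back to f0 with the SHO peak formula
    ``f_peak = f0 sqrt(1 - 1/(2 Q^2))`` using a half-power Q estimate.
    """
    if method == "sho_fit":
        return fit_sho(spectrum).f0
    if method == "peak":
        freq, amp = spectrum.frequency_grid, spectrum.amplitude
        if freq.size < 7:
            raise PeakNotBracketedError("need at least 7 points bracketing the peak")
        i = _interior_peak_index(amp)
        with np.errstate(divide="ignore"):
            f_peak = _parabolic_peak(freq, np.log(np.maximum(amp, 1e-300)), i)
        q = _halfpower_q(freq, amp, i, f_peak)
        if q > 1 / math.sqrt(2):
            return f_peak / math.sqrt(1 - 1 / (2 * q**2))
        return f_peak
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Simulated mass readout
# ---------------------------------------------------------------------------

def default_grid(f_center: float, n: int = 2001, span: float = 5.0) -> np.ndarray:
    """Coarse sweep grid: ``n`` log-spaced points on [f_center/span, f_center*span]."""
    return np.geomspace(f_center / span, f_center * span, n)


def _refined_fit(cantilever, cell, drive_force=1e-12, n_coarse=2001, n_fine=801):
    """Two-stage apparent-eigenfrequency fit: coarse log sweep, then a linear
    window of +-3 amplitude half-widths around the detected peak."""
    coarse = frequency_response(
        cantilever, cell, default_grid(cantilever.eigenfrequency, n_coarse), drive_force
    )
    i = _interior_peak_index(coarse.amplitude)
    f_peak = coarse.frequency_grid[i]
    q_est = _halfpower_q(coarse.frequency_grid, coarse.amplitude, i, f_peak)
    half_width = f_peak / (2 * q_est)
    lo = max(f_peak - 3 * half_width, coarse.frequency_grid[0])
    hi = min(f_peak + 3 * half_width, coarse.frequency_grid[-1])
    fine = frequency_response(cantilever, cell, np.linspace(lo, hi, n_fine), drive_force)
    return fit_sho(fine)


def simulate_apparent_mass(
    cantilever: CantileverModel,
    cell: CellMechanicalModel,
    n_coarse: int = 2001,
    n_fine: int = 801,
) -> float:
    """Apparent cell mass from a full 2-DOF sweep simulation.

    Runs the sweep without and with the cell, extracts both apparent
    eigenfrequencies under the SHO assumption, and applies the rigid
    point-mass relation ``m* = (k/4 pi^2)(1/f_after^2 - 1/f_before^2)``.
    In the small-mass-ratio, high-Q_cant limit this converges to
    ``Re{m_eff(2 pi f_N_cant)}``, i.e. to the closed-form readout law.
    """
    f_before = _refined_fit(cantilever, None, n_coarse=n_coarse, n_fine=n_fine).f0
    f_after = _refined_fit(cantilever, cell, n_coarse=n_coarse, n_fine=n_fine).f0
    k = cantilever.spring_constant
    return (k / (TWO_PI**2)) * (1.0 / f_after**2 - 1.0 / f_before**2)


# ---------------------------------------------------------------------------
# Stiffening trajectories (cell shape change as a stiffness ramp)
# ---------------------------------------------------------------------------

def linear_damping_rule(
    c_min: float = 5.0e-8,
    beta: float = 3.5e-5,
) -> Callable[[float, float], float]:
    """Damping increasing linearly with stiffness: ``c = c_min + beta k``.

    Defaults: ``c_min = mu_min * F(S)`` with a minimal viscosity scale
    mu_min = 2.5 mPa s and shape factor F(S) = 2e-5 m, and ``beta`` chosen so
    the cell quality factor stays near 0.3 over the physiological ramp.
    """
    def rule(k_cell: float, mass: float) -> float:
        return c_min + beta * k_cell
    return rule


def constant_q_damping_rule(q: float = 0.3) -> Callable[[float, float], float]:
    """Damping that pins the cell quality factor: ``c = sqrt(k m) / Q``."""
    if not q > 0:
        raise ValueError("q must be strictly positive")
    def rule(k_cell: float, mass: float) -> float:
        return math.sqrt(k_cell * mass) / q
    return rule


def stiffening_trajectory(
    cantilever: CantileverModel,
    cell_mass: float,
    k_grid,
    damping_rule: Callable[[float, float], float] | None = None,
    method: Literal["closed_form", "full_2dof"] = "closed_form",
) -> pd.DataFrame:
    """Mass readout fraction along a linear cell-stiffness ramp.

    Emulates the shape-change-driven stiffening of an adhering cell: for
    each ``k_cell`` on the ramp the damping follows ``damping_rule(k, m)``
    (default :func:`linear_damping_rule`) and the readout fraction
    ``m_app/m_real`` is evaluated either through the closed-form law
    (fast path) or through the full 2-DOF sweep simulation.

    Returns a DataFrame with columns ``k_cell, f_cell_hz, q_cell, ratio``.
    """
    k_grid = np.asarray(k_grid, dtype=float)
    if np.any(k_grid < 0):
        raise ValueError("k_grid must be non-negative")
    if np.any(np.diff(k_grid) <= 0):
        raise ValueError("k_grid must be strictly increasing")
    rule = damping_rule or linear_damping_rule()

    rows = []
    for k in k_grid:
        c = rule(float(k), cell_mass)
        cell = CellMechanicalModel(mass=cell_mass, coupling_stiffness=float(k),
                                   coupling_damping=c)
        if k == 0.0:
            # free mass: nothing couples, readout fraction ~ 0 (exactly 0 in
            # the closed-form sense of a vanishing eigenfrequency)
            ratio = (
                simulate_apparent_mass(cantilever, cell) / cell_mass
                if method == "full_2dof" and c > 0
                else 0.0
            )
        elif method == "closed_form":
            ratio = readout_accuracy(
                cantilever.eigenfrequency, cell.eigenfrequency, cell.quality_factor
            )
        else:
            ratio = simulate_apparent_mass(cantilever, cell) / cell_mass
        rows.append(
            {
                "k_cell": float(k),
                "f_cell_hz": cell.eigenfrequency,
                "q_cell": cell.quality_factor if k > 0 else 0.0,
                "ratio": float(ratio),
            }
        )
    return pd.DataFrame(rows)
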