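"""Seeded generators emulating the picobalance study's inputs.

Every generator is a pure function of its spec and an explicit seed, so the
whole analysis chain is testable without instrument data.  The defaults
reproduce the study conditions: a HeLa-like population with mass
3.14 +- 0.26 ng, population-average cell eigenfrequency 14.4 kHz at
Q_cell = 0.3, cantilever banks spanning 3-110 kHz, multiplicative lognormal
readout noise (CV 0.4), a stiffening ramp of k_cell from 0 to 0.4 N/m, and
glutaraldehyde crosslinking (stiffness x3, mass x0.8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .lumped_model import (
    CantileverModel,
    CellMechanicalModel,
    SweepSpectrum,
    TWO_PI,
    constant_q_damping_rule,
    default_grid,
    frequency_response,
    readout_accuracy,
    simulate_apparent_mass,
)

__all__ = [
    "PopulationSpec",
    "CantileverBankSpec",
    "GrowthProfile",
    "make_ensemble_experiment",
    "make_noisy_sweep",
    "make_growth_experiment",
    "collagen_like_profile",
    "stiffening_ramp_profile",
    "apply_crosslinking",
    "make_coulter_sample",
    "lognormal_sigma",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Generating parameters of the synthetic cell population (SI units).

    Between-cell eigenfrequency spread defaults to zero because the readout
    law is fitted as a population average; the SD knob exists for
    robustness studies.  ``noise_cv`` is the coefficient of variation of
    the multiplicative lognormal measurement noise on the apparent mass.
    """

    mass_mean: float = 3.14e-12
    mass_sd: float = 0.26e-12
    f_cell_mean: float = 14.4e3
    f_cell_sd: float = 0.0
    q_cell: float = 0.3
    noise_cv: float = 0.4

    def __post_init__(self) -> None:
        if not (self.mass_mean > 0 and self.f_cell_mean > 0 and self.q_cell > 0):
            raise ValueError("mass_mean, f_cell_mean, q_cell must be positive")
        if self.mass_sd < 0 or self.f_cell_sd < 0 or self.noise_cv < 0:
            raise ValueError("spreads must be non-negative")


# Table-style cantilever classes: (label, (f_lo, f_hi) Hz, (k_lo, k_hi) N/m)
_DEFAULT_BANK = (
    ("90-110 kHz", (90e3, 110e3), (7.8, 11.6)),
    ("60-80 kHz", (60e3, 80e3), (8.1, 15.6)),
    ("45 kHz", (40e3, 50e3), (2.3, 3.2)),
    ("25 kHz", (20e3, 30e3), (2.2, 2.5)),
    ("15 kHz", (10e3, 20e3), (0.2, 0.8)),
    ("3-8 kHz", (3e3, 8e3), (0.09, 0.3)),
)


@dataclass(frozen=True)
class CantileverBankSpec:
    """Bank of rectangular cantilever classes and their liquid Q.

    Each class is (label, eigenfrequency range in Hz, spring-constant range
    in N/m).  ``q_liquid`` defaults to 3, a typical first-mode value for
    such levers in aqueous medium (an assumption, exposed in config).
    """

    classes: tuple = _DEFAULT_BANK
    q_liquid: float = 3.0

    def __post_init__(self) -> None:
        labels = [c[0] for c in self.classes]
        if len(set(labels)) != len(labels):
            raise ValueError("cantilever class labels must be unique")
        for _, (flo, fhi), (klo, khi) in self.classes:
            if not (0 < flo <= fhi and 0 < klo <= khi):
                raise ValueError("class ranges must be positive and ordered")
        if not self.q_liquid > 0:
            raise ValueError("q_liquid must be positive")

    def draw(self, f_cant: float, rng: np.random.Generator) -> CantileverModel:
        """A cantilever at eigenfrequency ``f_cant``, spring constant drawn
        from the nearest class's range."""
        def dist(cls):
            flo, fhi = cls[1]
            return 0.0 if flo <= f_cant <= fhi else min(abs(f_cant - flo), abs(f_cant - fhi))
        _, _, (klo, khi) = min(self.classes, key=dist)
        return CantileverModel(
            spring_constant=float(rng.uniform(klo, khi)),
            eigenfrequency=float(f_cant),
            quality_factor=self.q_liquid,
        )


def lognormal_sigma(cv: float) -> float:
    """Log-scale sigma of a mean-one lognormal with coefficient of variation cv."""
    return math.sqrt(math.log(1.0 + cv**2))


def _lognoise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    s = lognormal_sigma(cv)
    return rng.lognormal(mean=-0.5 * s**2, sigma=s, size=size)


def make_ensemble_experiment(
    pop: PopulationSpec | None = None,
    bank: CantileverBankSpec | None = None,
    n: int = 178,
    f_range: tuple[float, float] = (3e3, 110e3),
    mode: str = "closed_form",
    seed: int = 0,
) -> pd.DataFrame:
    """One cell per cantilever across the frequency bank (relative-mass scan).

    For each of ``n`` cells: draw a cantilever eigenfrequency uniformly on
    ``f_range``, a cell mass from the population, evaluate the readout
    either through the closed-form accuracy law (``closed_form``) or the
    full 2-DOF sweep simulation (``full_2dof``), and apply multiplicative
    lognormal noise.  The reported ratio uses the population-mean reference
    mass, matching how the instrument data are normalized.

    Returns a DataFrame with columns
    ``f_cant_hz, m_app, m_real, ratio, m_cell, f_cell_hz, q_cell`` (SI).
    """
    pop = pop or PopulationSpec()
    bank = bank or CantileverBankSpec()
    if n < 1:
        raise ValueError("n must be at least 1")
    if mode not in ("closed_form", "full_2dof"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)

    f_cant = rng.uniform(f_range[0], f_range[1], n)
    masses = np.abs(rng.normal(pop.mass_mean, pop.mass_sd, n))
    if pop.f_cell_sd > 0:
        f_cells = np.abs(rng.normal(pop.f_cell_mean, pop.f_cell_sd, n))
    else:
        f_cells = np.full(n, pop.f_cell_mean)
    noise = _lognoise(rng, pop.noise_cv, n)

    if mode == "closed_form":
        frac = np.array(
            [readout_accuracy(fc, fcell, pop.q_cell) for fc, fcell in zip(f_cant, f_cells)]
        )
    else:
        frac = np.empty(n)
        for i in range(n):
            cant = bank.draw(f_cant[i], rng)
            cell = CellMechanicalModel.from_modal(masses[i], f_cells[i], pop.q_cell)
            frac[i] = simulate_apparent_mass(cant, cell) / masses[i]

    m_app = frac * masses * noise
    m_real = pop.mass_mean
    return pd.DataFrame(
        {
            "f_cant_hz": f_cant,
            "m_app": m_app,
            "m_real": m_real,
            "ratio": m_app / m_real,
            "m_cell": masses,
            "f_cell_hz": f_cells,
            "q_cell": pop.q_cell,
        }
    )


def make_noisy_sweep(
    cantilever: CantileverModel,
    cell: CellMechanicalModel | None = None,
    noise_cv: float = 0.05,
    n_points: int = 401,
    seed: int = 0,
    grid: np.ndarray | None = None,
    peak_amplitude: float = 0.16e-9,
    phase_sd: float = 0.0,
    timestamp: float | None = None,
) -> SweepSpectrum:
    """A 2-DOF sweep with multiplicative Gaussian amplitude noise.

    The drive force is scaled so the bare-cantilever resonance amplitude is
    ``peak_amplitude`` (default 0.16 nm, the typical photothermal
    oscillation amplitude of these levers).  ``phase_sd`` adds independent
    Gaussian phase noise in radians.  Deterministic under ``seed``.
    """
    if noise_cv < 0 or phase_sd < 0:
        raise ValueError("noise levels must be non-negative")
    if grid is None:
        f0 = cantilever.eigenfrequency
        q = cantilever.quality_factor
        half = f0 / (2 * q)
        grid = np.linspace(max(f0 - 4 * half, f0 * 0.05), f0 + 4 * half, n_points)
    # bare-lever peak amplitude ~ (F/k) * Q at resonance
    drive = peak_amplitude * cantilever.spring_constant / cantilever.quality_factor
    clean = frequency_response(cantilever, cell, grid, drive_force=drive)
    rng = np.random.default_rng(seed)
    amp = clean.amplitude * (1.0 + rng.normal(0.0, noise_cv, grid.size)) if noise_cv else clean.amplitude
    amp = np.abs(amp)
    phase = np.angle(clean.complex_response)
    if phase_sd:
        phase = phase + rng.normal(0.0, phase_sd, grid.size)
    return SweepSpectrum(
        frequency_grid=grid,
        complex_response=amp * np.exp(1j * phase),
        drive_amplitude=peak_amplitude,
        timestamp=timestamp,
    )


# ---------------------------------------------------------------------------
# Growth experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthProfile:
    """Phenomenological mass/stiffness time course of an adhering cell.

    ``mass(t)`` and ``stiffness(t)`` give the true cell mass (kg) and
    coupling stiffness (N/m) at time t (s); damping follows a constant-Q
    rule by default.  Substrate biology enters only through these curves.
    """

    mass: callable
    stiffness: callable
    q_cell: float = 0.3

    def cell_at(self, t: float) -> CellMechanicalModel:
        m = float(self.mass(t))
        k = float(self.stiffness(t))
        c = constant_q_damping_rule(self.q_cell)(k, m) if k > 0 else 0.0
        return CellMechanicalModel(mass=m, coupling_stiffness=k, coupling_damping=c)


def _f_cell_for_ratio(target: float, f_cant: float, q: float) -> float:
    """Invert the readout law for f_cell on the soft branch (f_cell < f_cant)."""
    if not 0 < target < 1:
        raise ValueError("target ratio must lie in (0, 1) on the soft branch")
    lo, hi = 1e2, f_cant * (1 - 1e-9)
    return brentq(lambda f: readout_accuracy(f_cant, f, q) - target, lo, hi, xtol=1e-6)


def collagen_like_profile(
    f_cant: float = 70e3,
    m_app_start: float = 0.59e-12,
    m_app_end: float = 3.04e-12,
    m_real: float = 3.14e-12,
    q_cell: float = 0.3,
    duration: float = 7200.0,
) -> GrowthProfile:
    """Stiffening time course calibrated to a collagen-substrate growth curve.

    The true cell mass is held at the population reference while the
    coupling stiffness ramps linearly between the values whose closed-form
    readout on an ``f_cant`` lever gives the prescribed apparent masses at
    t = 0 and t = duration (0.59 -> 3.04 ng on a ~70 kHz lever by default).
    """
    f_start = _f_cell_for_ratio(m_app_start / m_real, f_cant, q_cell)
    f_end = _f_cell_for_ratio(m_app_end / m_real, f_cant, q_cell)
    k_start = (TWO_PI * f_start) ** 2 * m_real
    k_end = (TWO_PI * f_end) ** 2 * m_real

    def stiffness(t: float) -> float:
        u = min(max(t / duration, 0.0), 1.0)
        return k_start + (k_end - k_start) * u

    return GrowthProfile(mass=lambda t: m_real, stiffness=stiffness, q_cell=q_cell)


def stiffening_ramp_profile(
    k_start: float = 0.0,
    k_end: float = 0.4,
    mass: float = 3.14e-12,
    q_cell: float = 0.3,
    duration: float = 7200.0,
) -> GrowthProfile:
    """Linear k_cell ramp (default 0 -> 0.4 N/m) at constant true mass."""

    def stiffness(t: float) -> float:
        u = min(max(t / duration, 0.0), 1.0)
        return k_start + (k_end - k_start) * u

    return GrowthProfile(mass=lambda t: mass, stiffness=stiffness, q_cell=q_cell)


def make_growth_experiment(
    profile: GrowthProfile,
    cantilever: CantileverModel,
    duration: float = 7200.0,
    dt: float = 10.0,
    noise_cv: float = 0.01,
    n_points: int = 401,
    seed: int = 0,
) -> tuple[list[SweepSpectrum], pd.DataFrame]:
    """Time series of noisy sweeps along a growth profile, plus the truth table.

    One sweep every ``dt`` seconds for ``duration`` seconds on a fixed
    cantilever whose payload follows the profile.  The truth table gives
    per time point the true mass, stiffness, cell eigenfrequency, and the
    closed-form expected apparent mass.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + dt / 2, dt)
    sweeps, truth = [], []
    for t in times:
        cell = profile.cell_at(float(t))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sweeps.append(
            make_noisy_sweep(
                cantilever, cell, noise_cv=noise_cv, n_points=n_points,
                seed=sub_seed, timestamp=float(t),
            )
        )
        f_cell = cell.eigenfrequency
        expected = (
            readout_accuracy(cantilever.eigenfrequency, f_cell, profile.q_cell) * cell.mass
            if f_cell > 0
            else 0.0
        )
        truth.append(
            {
                "time_s": float(t),
                "mass": cell.mass,
                "k_cell": cell.coupling_stiffness,
                "f_cell_hz": f_cell,
                "expected_apparent_mass": expected,
            }
        )
    return sweeps, pd.DataFrame(truth)


def apply_crosslinking(
    cell: CellMechanicalModel,
    stiffness_factor: float = 3.0,
    mass_factor: float = 0.8,
) -> CellMechanicalModel:
    """Glutaraldehyde crosslinking: stiffen ~3x, shrink mass ~20%.

    The damping coefficient is kept (c = mu F(S) with both the viscosity
    scale and shape factor unchanged), so the quality factor is recomputed
    from the new stiffness and mass; the eigenfrequency rises by
    ``sqrt(stiffness_factor / mass_factor)``.
    """
    if not (stiffness_factor > 0 and mass_factor > 0):
        raise ValueError("crosslinking factors must be strictly positive")
    return replace(
        cell,
        mass=cell.mass * mass_factor,
        coupling_stiffness=cell.coupling_stiffness * stiffness_factor,
        elastic_modulus=None,
        shape_factor=None,
    )


def make_coulter_sample(
    n: int = 3000,
    mean_diameter: float = 17.8e-6,
    sd: float = 0.5e-6,
    seed: int = 0,
    gate: tuple[float, float] = (9e-6, 24e-6),
) -> np.ndarray:
    """Normal diameters truncated to the Coulter gate (m).

    The default mean of 17.8 um is the mass-equivalent diameter of the
    reference cell mass at density 1.06 g/cm^3, inside the 16-20 um
    selection window used for the measured cells.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not (gate[0] < mean_diameter < gate[1]):
        raise ValueError("mean_diameter must lie inside the gate")
    rng = np.random.default_rng(seed)
    out = np.empty(0)
    while out.size < n:
        draw = rng.normal(mean_diameter, sd, 2 * (n - out.size) + 16)
        out = np.concatenate([out, draw[(draw >= gate[0]) & (draw <= gate[1])]])
    return out[:n]
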