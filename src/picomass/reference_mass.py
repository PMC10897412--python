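"""Reference (ground-truth) masses from size measurements.

Suspended rounded cells and calibration beads are treated as spheres:
``m = rho * pi d^3 / 6``.  Coulter-counter diameter distributions become
reference mass distributions at a constant cell density (default
1.06 g/cm^3; glass beads 1.8 g/cm^3).  A diameter gate (default 9-24 um,
the Coulter acquisition window for these cells) removes debris and
doublets.  Chemical crosslinking shrinks the cell volume, which is modelled
as a multiplicative mass factor (default 0.8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "CELL_DENSITY",
    "BEAD_DENSITY",
    "DEFAULT_GATE",
    "SizeDistribution",
    "MassSummary",
    "sphere_mass",
    "mass_equivalent_diameter",
    "distribution_to_mass",
    "crosslink_reference",
]

CELL_DENSITY = 1060.0   # kg/m^3
BEAD_DENSITY = 1800.0   # kg/m^3
DEFAULT_GATE = (9e-6, 24e-6)  # m


def sphere_mass(diameter, density):
    """Mass of a sphere: ``rho pi d^3 / 6`` (SI units)."""
    d = np.asarray(diameter, dtype=float)
    if np.any(d < 0):
        raise ValueError("diameter must be non-negative")
    if not density > 0:
        raise ValueError("density must be strictly positive")
    out = density * math.pi * d**3 / 6.0
    return float(out) if out.ndim == 0 else out


def mass_equivalent_diameter(mass, density):
    """Diameter of the sphere of given mass: inverse of :func:`sphere_mass`."""
    m = np.asarray(mass, dtype=float)
    if np.any(m < 0):
        raise ValueError("mass must be non-negative")
    if not density > 0:
        raise ValueError("density must be strictly positive")
    out = (6.0 * m / (density * math.pi)) ** (1.0 / 3.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SizeDistribution:
    """Specimen diameters (m) with a density and a diameter gate.

    ``diameters`` may come from per-particle lists or from histogram bin
    centers expanded by counts (the histogram path approximates every
    particle in a bin by its center).  ``repeats`` optionally labels
    independent experimental repeats for two-level summaries.
    """

    diameters: np.ndarray
    density: float = CELL_DENSITY
    gate: tuple[float, float] = DEFAULT_GATE
    repeats: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        if d.ndim != 1 or d.size < 1:
            raise ValueError("diameters must be a non-empty 1-D array")
        if not self.density > 0:
            raise ValueError("density must be strictly positive")
        lo, hi = self.gate
        if not (0 < lo < hi):
            raise ValueError("gate must satisfy 0 < lo < hi")
        object.__setattr__(self, "diameters", d)
        if self.repeats is not None:
            rep = np.asarray(self.repeats)
            if rep.shape != d.shape:
                raise ValueError("repeats must match diameters in length")
            object.__setattr__(self, "repeats", rep)

    @classmethod
    def from_histogram(
        cls, bin_centers, counts, density: float = CELL_DENSITY,
        gate: tuple[float, float] = DEFAULT_GATE,
    ) -> "SizeDistribution":
        centers = np.asarray(bin_centers, dtype=float)
        n = np.asarray(counts)
        if np.any(n < 0) or not np.issubdtype(n.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        return cls(diameters=np.repeat(centers, n), density=density, gate=gate)

    def gated(self) -> "SizeDistribution":
        """Apply the diameter gate (idempotent).  Errors if nothing survives."""
        lo, hi = self.gate
        keep = (self.diameters >= lo) & (self.diameters <= hi)
        if not np.any(keep):
            raise ValueError(
                f"no diameters inside the gate [{lo * 1e6:.3g}, {hi * 1e6:.3g}] um"
            )
        rep = self.repeats[keep] if self.repeats is not None else None
        return replace(self, diameters=self.diameters[keep], repeats=rep)


@dataclass(frozen=True)
class MassSummary:
    """Per-specimen masses with summary statistics (SI units)."""

    masses: np.ndarray
    mean: float
    sd: float
    n: int
    mass_equivalent_diameter: float
    per_repeat: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "mean_mass_ng": self.mean * 1e12,
            "sd_mass_ng": self.sd * 1e12,
            "n": self.n,
            "mass_equivalent_diameter_um": self.mass_equivalent_diameter * 1e6,
        }
        if self.per_repeat is not None:
            out["repeat_means_ng"] = (self.per_repeat["mean_mass"] * 1e12).tolist()
            out["between_repeat_sd_ng"] = float(
                self.per_repeat["mean_mass"].std(ddof=1) * 1e12
            )
        return out


def distribution_to_mass(dist: SizeDistribution) -> MassSummary:
    """Convert a gated diameter distribution to a mass distribution.

    Returns per-specimen sphere masses plus mean, SD (across specimens),
    count, and the mass-equivalent mean diameter.  When repeat labels are
    present the summary also carries per-repeat means, so both the
    within-population and the across-repeat spread are available.
    """
    gated = dist.gated()
    masses = sphere_mass(gated.diameters, gated.density)
    mean = float(np.mean(masses))
    sd = float(np.std(masses, ddof=1)) if masses.size > 1 else 0.0
    per_repeat = None
    if gated.repeats is not None:
        per_repeat = (
            pd.DataFrame({"repeat": gated.repeats, "mass": masses})
            .groupby("repeat")["mass"]
            .agg(mean_mass="mean", sd_mass="std", n="count")
            .reset_index()
        )
    return MassSummary(
        masses=masses,
        mean=mean,
        sd=sd,
        n=int(masses.size),
        mass_equivalent_diameter=mass_equivalent_diameter(mean, gated.density),
        per_repeat=per_repeat,
    )


def crosslink_reference(dist: SizeDistribution, factor: float = 0.8) -> SizeDistribution:
    """Volume shrinkage of chemically crosslinked cells as a mass factor.

    Scales every mass by ``factor`` (default 0.8, i.e. the ~20% volume
    shrinkage seen after glutaraldehyde fixation), implemented as a
    diameter rescale by ``factor^(1/3)`` at constant density.
    """
    if not factor > 0:
        raise ValueError("crosslinking mass factor must be strictly positive")
    scale = factor ** (1.0 / 3.0)
    # widen the gate consistently so already-gated specimens stay in
    lo, hi = dist.gate
    return replace(
        dist,
        diameters=dist.diameters * scale,
        gate=(lo * scale, hi * scale),
    )
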