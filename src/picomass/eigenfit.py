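"""Ensemble inference of the population-average cell eigenfrequency and Q.

A bank of cantilevers with eigenfrequencies spanning well below to well
above the cell eigenfrequency each weighs cells of the same population; the
relative readout ``m_app / m_real`` as a function of the cantilever
eigenfrequency traces the closed-form readout-accuracy law.  Nonlinear
least squares on those points extracts the population-average cell
eigenfrequency ``f_N_cell`` and quality factor ``Q_cell``; Eq.-2-style
algebra then converts the eigenfrequency into a whole-cell spring constant
(``k = 4 pi^2 m f^2``) and, given a geometry shape factor, a Young's
modulus (``E = k / F(S)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .lumped_model import TWO_PI, readout_accuracy

__all__ = [
    "EnsembleFitResult",
    "bin_ensemble",
    "fit_readout_curve",
    "cell_stiffness",
    "youngs_modulus",
    "RIGID_LIMIT_FLAG",
]

RIGID_LIMIT_FLAG = "rigid_limit"

# default fit bounds, Hz and dimensionless
F_CELL_BOUNDS = (0.5e3, 500e3)
Q_CELL_BOUNDS = (0.01, 100.0)


def bin_ensemble(
    f_cant,
    ratio,
    n_bins: int = 7,
) -> pd.DataFrame:
    """Bin relative-mass points into equidistant cantilever-frequency bins.

    Bins are equidistant on the linear frequency axis over [min, max].
    Empty bins are dropped (noted in the ``empty`` attribute of the frame).
    Returns a DataFrame with columns ``center_hz, mean_ratio, sd_ratio, count``.
    """
    f = np.asarray(f_cant, dtype=float)
    r = np.asarray(ratio, dtype=float)
    if f.size != r.size:
        raise ValueError("f_cant and ratio must have equal length")
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    if f.size < 1:
        raise ValueError("need at least one point")
    lo, hi = f.min(), f.max()
    if lo == hi:
        raise ValueError("all points share one cantilever frequency; cannot bin")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(f, edges[1:-1]), 0, n_bins - 1)
    rows, empty = [], []
    for b in range(n_bins):
        sel = idx == b
        center = 0.5 * (edges[b] + edges[b + 1])
        if not np.any(sel):
            empty.append(center)
            continue
        vals = r[sel]
        rows.append(
            {
                "center_hz": center,
                "mean_ratio": float(vals.mean()),
                "sd_ratio": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "count": int(vals.size),
            }
        )
    frame = pd.DataFrame(rows)
    frame.attrs["empty_bin_centers_hz"] = empty
    return frame


@dataclass(frozen=True)
class EnsembleFitResult:
    """Fitted population-average cell parameters with uncertainties."""

    f_cell_hat: float
    q_cell_hat: float
    f_cell_se: float
    q_cell_se: float
    covariance: np.ndarray
    n_points: int
    bins: pd.DataFrame
    residual: float
    converged: bool
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "f_cell_hz": self.f_cell_hat,
            "f_cell_se_hz": self.f_cell_se,
            "q_cell": self.q_cell_hat,
            "q_cell_se": self.q_cell_se,
            "n": self.n_points,
            "flags": list(self.flags),
            "bins": self.bins.to_dict(orient="records"),
        }


_LOG_BOUNDS = (
    [math.log(F_CELL_BOUNDS[0]), math.log(Q_CELL_BOUNDS[0])],
    [math.log(F_CELL_BOUNDS[1]), math.log(Q_CELL_BOUNDS[1])],
)
# canonical multi-start positions (f_cell Hz, Q); random restarts are added
_CANONICAL_STARTS = ((20e3, 0.5), (14e3, 0.3), (40e3, 1.0), (8e3, 0.15))


def _multistart(residuals, starts):
    best = None
    for theta0 in starts:
        res = least_squares(residuals, theta0, bounds=_LOG_BOUNDS,
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError("readout-curve fit failed to converge from all starts")
    return best


def fit_readout_curve(
    f_cant,
    ratio,
    fit_on: Literal["raw", "binned"] = "raw",
    weighting: Literal["lognormal", "unweighted"] = "lognormal",
    noise_cv: float | None = None,
    n_bins: int = 7,
    n_starts: int = 5,
    seed: int = 0,
    rigid_tol: float = 0.05,
    n_bootstrap: int = 0,
) -> EnsembleFitResult:
    """Fit the readout-accuracy law to (f_cant, m_app/m_real) points.

    The measurement scatter on the apparent mass is multiplicative, so the
    default weighting is the matching lognormal maximum likelihood: least
    squares on log-ratios against ``log model - s^2/2`` (the offset keeps
    the mean-one noise convention), with the log-noise scale ``s`` either
    derived from ``noise_cv`` or estimated from the residual spread by a
    short fixed-point iteration.  ``weighting="unweighted"`` gives plain
    linear-space least squares; ``fit_on="binned"`` fits the
    inverse-variance-weighted means of the equidistant bins instead of the
    raw points.

    The optimization runs in log-parameters inside the bounds
    f_cell in [0.5, 500] kHz, Q in [0.01, 100], restarted from canonical
    plus ``n_starts`` seeded random positions (the cost surface has a
    degenerate dashpot-like valley at low f_cell, low Q).  Standard errors
    come from the Jacobian covariance scaled by the residual variance; set
    ``n_bootstrap > 0`` for a seeded nonparametric bootstrap instead.

    Data flat at ratio 1 carry no information on f_cell beyond a lower
    bound: such rigid payloads are reported with the ``rigid_limit`` flag,
    f_cell_hat set to the highest probed cantilever frequency, and NaN
    standard errors.
    """
    f_all = np.asarray(f_cant, dtype=float)
    r_all = np.asarray(ratio, dtype=float)
    if f_all.size != r_all.size:
        raise ValueError("f_cant and ratio must have equal length")
    if f_all.size < 5:
        raise ValueError("need at least 5 points to fit")
    if not np.all(np.isfinite(r_all)):
        raise ValueError("ratios must be finite")
    bins = bin_ensemble(f_all, r_all, n_bins=n_bins)

    # rigid payloads: readout flat at 1 across the whole bank
    if np.all(np.abs(bins["mean_ratio"].to_numpy() - 1.0) <= rigid_tol):
        return EnsembleFitResult(
            f_cell_hat=float(f_all.max()),
            q_cell_hat=math.nan,
            f_cell_se=math.nan,
            q_cell_se=math.nan,
            covariance=np.full((2, 2), math.nan),
            n_points=int(f_all.size),
            bins=bins,
            residual=float(np.std(r_all - 1.0)),
            converged=True,
            flags=(RIGID_LIMIT_FLAG,),
        )

    rng = np.random.default_rng(seed)
    starts = [(math.log(fc), math.log(q)) for fc, q in _CANONICAL_STARTS]
    for _ in range(n_starts):
        starts.append(
            (
                rng.uniform(math.log(F_CELL_BOUNDS[0] * 2), math.log(F_CELL_BOUNDS[1] / 2)),
                rng.uniform(math.log(Q_CELL_BOUNDS[0] * 2), math.log(Q_CELL_BOUNDS[1] / 2)),
            )
        )

    flags: list[str] = []

    def solve(f, r, weights=None, offset_stages=0, fixed_offset=None):
        """One full multi-start solve; lognormal mode iterates the offset."""
        if weights is None and fixed_offset is None and offset_stages == 0:
            def residuals(theta):
                return readout_accuracy(f, *np.exp(theta)) - r
            return _multistart(residuals, starts), residuals
        if weights is not None:
            def residuals(theta):
                return (readout_accuracy(f, *np.exp(theta)) - r) * weights
            return _multistart(residuals, starts), residuals
        # lognormal maximum likelihood on log-ratios
        logr = np.log(r)
        offset = fixed_offset if fixed_offset is not None else 0.0
        best = None
        for _ in range(offset_stages if fixed_offset is None else 1):
            def residuals(theta, off=offset):
                m = readout_accuracy(f, *np.exp(theta))
                return np.log(np.maximum(m, 1e-300)) - off - logr
            st = starts + ([tuple(best.x)] if best is not None else [])
            best = _multistart(residuals, st)
            if fixed_offset is None:
                offset = float(np.var(residuals(best.x))) / 2.0
        def final_residuals(theta, off=offset):
            m = readout_accuracy(f, *np.exp(theta))
            return np.log(np.maximum(m, 1e-300)) - off - logr
        return best, final_residuals

    if fit_on == "binned":
        f = bins["center_hz"].to_numpy()
        r = bins["mean_ratio"].to_numpy()
        sd = bins["sd_ratio"].to_numpy() / np.sqrt(bins["count"].to_numpy())
        sd = np.where(sd > 0, sd, np.nanmax(sd) if np.any(sd > 0) else 1.0)
        best, residuals = solve(f, r, weights=1.0 / sd)
    elif fit_on != "raw":
        raise ValueError(f"unknown fit_on {fit_on!r}")
    elif weighting == "unweighted":
        f, r = f_all, r_all
        best, residuals = solve(f, r, weights=np.ones_like(r))
    elif weighting == "lognormal":
        keep = r_all > 0
        n_dropped = int(np.sum(~keep))
        if n_dropped:
            flags.append(f"dropped_nonpositive:{n_dropped}")
        f, r = f_all[keep], r_all[keep]
        if f.size < 5:
            raise ValueError("fewer than 5 positive ratios for lognormal weighting")
        fixed = math.log(1.0 + noise_cv**2) / 2.0 if noise_cv is not None else None
        best, residuals = solve(f, r, offset_stages=3, fixed_offset=fixed)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    f_hat, q_hat = np.exp(best.x)
    dof = max(f.size - 2, 1)
    s2 = 2 * best.cost / dof
    jtj = best.jac.T @ best.jac
    try:
        cov_log = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov_log = np.full((2, 2), math.nan)
    # delta method back from log-parameters
    scale = np.diag([f_hat, q_hat])
    cov = scale @ cov_log @ scale

    if n_bootstrap > 0:
        boot = np.empty((n_bootstrap, 2))
        for b in range(n_bootstrap):
            idx = rng.integers(0, f.size, f.size)
            def boot_resid(theta, fi=f[idx], ri=r[idx]):
                return readout_accuracy(fi, *np.exp(theta)) - ri
            res_b = least_squares(boot_resid, best.x, bounds=_LOG_BOUNDS)
            boot[b] = np.exp(res_b.x)
        cov = np.cov(boot.T)

    se = np.sqrt(np.diag(cov))
    return EnsembleFitResult(
        f_cell_hat=float(f_hat),
        q_cell_hat=float(q_hat),
        f_cell_se=float(se[0]),
        q_cell_se=float(se[1]),
        covariance=cov,
        n_points=int(f.size),
        bins=bins,
        residual=float(np.sqrt(2 * best.cost / f.size)),
        converged=True,
        flags=tuple(flags),
    )


def cell_stiffness(f_cell, mass):
    """Whole-cell spring constant ``k = 4 pi^2 m f^2`` (N/m)."""
    f = np.asarray(f_cell, dtype=float)
    m = np.asarray(mass, dtype=float)
    if np.any(f < 0) or np.any(m <= 0):
        raise ValueError("f_cell must be >= 0 and mass > 0")
    out = TWO_PI**2 * m * f**2
    return float(out) if out.ndim == 0 else out


def youngs_modulus(stiffness, shape_factor):
    """Whole-cell Young's modulus ``E = k / F(S)`` (Pa).

    The shape factor F(S) is a geometry-dependent length relating the
    whole-cell spring constant to the elastic modulus; it must be supplied
    by the user (typically from a finite-element model of the cell shape).
    """
    if shape_factor is None:
        raise ValueError(
            "FEM-derived shape factor required: supply F(S) in meters to "
            "convert stiffness into a Young's modulus"
        )
    if not shape_factor > 0:
        raise ValueError("shape_factor must be strictly positive")
    k = np.asarray(stiffness, dtype=float)
    if np.any(k < 0):
        raise ValueError("stiffness must be non-negative")
    out = k / shape_factor
    return float(out) if out.ndim == 0 else out
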