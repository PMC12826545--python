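"""Elliptical anisotropy estimation across imaging angles.

In a transversely isotropic material the apparent modulus traces an
origin-centered polar ellipse over imaging angle (180° period).  Fitting
that ellipse to a metric's values at the four protocol angles (0°, 30°,
60°, 90° — Nyquist sampling of the half-period) yields the degree of
anisotropy (DoA), the ratio of the major to minor axis lengths, together
with an R² describing how elliptical the data actually are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .phantom import PROTOCOL_ANGLES_DEG, modulus_at_angle

__all__ = ["AngleSet", "EllipseFit", "fit_ellipse", "doa_table"]


@dataclass(frozen=True)
class AngleSet:
    """One metric's ROI values across the imaging angles for one acquisition."""

    angles_deg: tuple[float, ...]
    values: tuple[float, ...]
    metric: str = "RE"
    compression_mm: int = 0
    subject_id: str = ""

    def __post_init__(self) -> None:
        if len(self.angles_deg) != len(self.values):
            raise ValueError("angles and values must pair up")
        if any(not np.isfinite(v) or v <= 0 for v in self.values):
            raise ValueError("angle-set values must be positive and finite")

    @property
    def in_protocol(self) -> bool:
        """True when exactly the four protocol angles are present."""
        return tuple(sorted(self.angles_deg)) == tuple(float(a) for a in PROTOCOL_ANGLES_DEG)


@dataclass(frozen=True)
class EllipseFit:
    """Origin-centered polar ellipse (a ≥ b) with orientation phi ∈ [0, 180).

    ``doa = a / b``; ``r2`` is NaN (degenerate) when the four values are
    identical, i.e. SStot = 0 — a perfect circle has no variance to explain.
    """

    a: float
    b: float
    phi_deg: float
    doa: float
    r2: float

    @property
    def degenerate_r2(self) -> bool:
        return not np.isfinite(self.r2)


def _ellipse_radius(theta_deg, a, b, phi_deg):
    # polar ellipse with semi-major a along phi
    return modulus_at_angle(a, b, phi_deg, theta_deg)


def fit_ellipse(angle_set: AngleSet) -> EllipseFit:
    """Least-squares fit of the polar-ellipse law to per-angle values.

    Multi-start over an orientation grid {0, 15, ..., 165}°; semi-axes are
    optimized in log space for positivity.  ``a >= b`` is enforced by a
    swap-and-rotate; when a == b the orientation is 0 by convention.
    """
    theta = np.asarray(angle_set.angles_deg, dtype=float)
    y = np.asarray(angle_set.values, dtype=float)

    def resid(p):
        la, lb, phi = p
        return _ellipse_radius(theta, np.exp(la), np.exp(lb), phi) - y

    vmax, vmin = float(y.max()), float(y.min())
    starts: list[np.ndarray] = []
    # analytic seed: 1/r(θ)² is linear in (1, cos 2θ, sin 2θ), so a linear
    # solve gives (a, b, phi) directly on noise-free elliptical data
    rad2 = np.deg2rad(2.0 * theta)
    A = np.column_stack([np.ones_like(rad2), np.cos(rad2), np.sin(rad2)])
    c0, c1, c2 = np.linalg.lstsq(A, 1.0 / y**2, rcond=None)[0]
    amp = np.hypot(c1, c2)
    if c0 - amp > 0:
        a0 = 1.0 / np.sqrt(c0 - amp)  # semi-axis along phi
        b0 = 1.0 / np.sqrt(c0 + amp)
        phi0 = np.rad2deg(np.arctan2(-c2, -c1)) / 2.0
        starts.append(np.array([np.log(a0), np.log(b0), phi0]))
    starts += [
        np.array([np.log(vmax), np.log(max(vmin, 1e-12)), phi0])
        for phi0 in np.arange(0.0, 180.0, 15.0)
    ]
    best = None
    tiny = 1e-16 * float((y**2).sum())
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, method="lm", xtol=1e-15, ftol=1e-15)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost <= tiny:
            break
    if best is None:
        raise RuntimeError("ellipse fit failed from every start")

    a, b = np.exp(best.x[0]), np.exp(best.x[1])
    phi = best.x[2]
    if b > a:
        a, b = b, a
        phi += 90.0
    phi = float(np.mod(phi, 180.0))
    rel_tol = 1e-9 * max(a, b)
    if abs(a - b) <= rel_tol:
        phi = 0.0

    ss_res = float(np.sum(resid(best.x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return EllipseFit(a=float(a), b=float(b), phi_deg=phi, doa=float(a / b), r2=r2)


def doa_table(angle_sets: list[AngleSet]) -> pd.DataFrame:
    """Tidy DoA table: one row per (subject, metric, compression).

    Rows whose ellipse fit fails are kept with NaN results and
    ``missing=True`` rather than dropped.
    """
    rows = []
    for aset in angle_sets:
        row = {
            "subject_id": aset.subject_id,
            "metric": aset.metric,
            "compression_mm": aset.compression_mm,
            "in_protocol": aset.in_protocol,
        }
        try:
            fit = fit_ellipse(aset)
            row.update(
                a=fit.a, b=fit.b, phi_deg=fit.phi_deg, doa=fit.doa, r2=fit.r2, missing=False
            )
        except (ValueError, RuntimeError):
            row.update(a=np.nan, b=np.nan, phi_deg=np.nan, doa=np.nan, r2=np.nan, missing=True)
        rows.append(row)
    cols = ["subject_id", "metric", "compression_mm", "a", "b", "phi_deg", "doa", "r2",
            "in_protocol", "missing"]
    return pd.DataFrame(rows, columns=cols)
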