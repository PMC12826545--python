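"""PD / RE / RV parametric imaging by mass-spring-damper fitting.

Each tracked pixel's displacement-vs-slow-time curve is reduced to peak
displacement (PD) and fit to the same closed-form MSD response used by the
generator, yielding relative elasticity (RE, the restoring constant per
unit nominal push force) and relative viscosity (RV, the damping constant
per unit nominal push force).  The nominal mass constant and push
amplitude are shared unit conventions with :mod:`visrkit.phantom`, not
estimated quantities.

Two fitting paths are provided: :func:`fit_msd` is the reference
single-curve fit (bounded trust-region least squares with a 3×3 log-spaced
multi-start), and :func:`fit_msd_batch` is an equivalent vectorized fitter
(coarse log-grid initialization plus a damped Gauss-Newton polish in log
space) used to fit whole images at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import least_squares

from .phantom import AcquisitionParams, SequenceTiming, _msd_batch_fast, msd_response
from .tracking import DisplacementField

__all__ = ["FitOptions", "VisRMaps", "fit_msd", "fit_msd_batch", "visr_image"]

NOMINAL_AMPLITUDE = AcquisitionParams().push_amplitude


@dataclass(frozen=True)
class FitOptions:
    """MSD-fit configuration.

    Bounds are generous around the physiologic module-unit range; the
    coarse grid initializes the batch fitter; ``min_valid_fraction`` is the
    share of fit-window samples that must be valid for a pixel to be fit.
    """

    amplitude: float = NOMINAL_AMPLITUDE
    re_bounds: tuple[float, float] = (0.05, 500.0)
    rv_bounds: tuple[float, float] = (0.02, 300.0)
    grid_points: int = 24
    max_iter: int = 30
    min_valid_fraction: float = 0.8
    #: estimate a constant displacement offset alongside (re, rv): tracked
    #: curves carry a kernel-specific DC bias (shared-reference speckle and
    #: noise) that would otherwise leak into the recovery-rate estimate
    fit_offset: bool = True
    #: axial running-mean half-window (in pixels) applied to the
    #: displacement field before fitting; adjacent kernels overlap 75%, so
    #: this trades little resolution for less estimate jitter
    axial_smooth: int = 3


@dataclass
class VisRMaps:
    """PD (µm), RE, RV parametric images with a shared validity mask."""

    pd: np.ndarray
    re: np.ndarray
    rv: np.ndarray
    fit_error: np.ndarray
    valid: np.ndarray
    axial_positions_mm: np.ndarray
    lateral_positions_mm: np.ndarray
    focal_depth_mm: float = 20.0


def _fit_times(timing: SequenceTiming) -> tuple[np.ndarray, np.ndarray]:
    """Fit-window event indices and times: everything from the first push on."""
    idx = np.arange(timing.n_reference, timing.n_events)
    return idx, timing.event_times_ms[idx]


def fit_msd(
    curve: np.ndarray,
    timing: SequenceTiming,
    opts: FitOptions = FitOptions(),
    times_ms: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Fit (re, rv) of the MSD model to one displacement curve.

    ``curve`` holds displacement in µm at the fit-window events (from the
    first push onward); pass ``times_ms`` to override the grid.  Returns
    ``(re, rv, fit_error)`` with ``fit_error`` the RMS residual in µm.
    Raises ``ValueError`` on degenerate (flat or too-short) curves.
    """
    y = np.asarray(curve, dtype=float)
    if times_ms is None:
        _, times_ms = _fit_times(timing)
        if y.size == timing.n_events:  # full-ensemble curve: drop references
            y = y[timing.n_reference :]
    times_ms = np.asarray(times_ms, dtype=float)
    if y.size != times_ms.size:
        raise ValueError("curve and time grid lengths differ")
    if y.size < 10:
        raise ValueError("need at least 10 samples to fit the MSD model")
    if np.ptp(y) < 1e-12:
        raise ValueError("degenerate flat displacement curve")

    lb = np.log([opts.re_bounds[0], opts.rv_bounds[0]])
    ub = np.log([opts.re_bounds[1], opts.rv_bounds[1]])

    def resid(theta):
        re, rv = np.exp(theta)
        r = msd_response(re, rv, timing, times_ms, amplitude=opts.amplitude) - y
        if opts.fit_offset:
            r = r - r.mean()  # optimal constant offset solved in closed form
        return r

    starts = [
        np.array([lr, lv])
        for lr in np.linspace(lb[0] + 0.15 * (ub[0] - lb[0]), ub[0] - 0.15 * (ub[0] - lb[0]), 3)
        for lv in np.linspace(lb[1] + 0.15 * (ub[1] - lb[1]), ub[1] - 0.15 * (ub[1] - lb[1]), 3)
    ]
    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), method="trf", xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("MSD fit failed from every start")
    re, rv = np.exp(best.x)
    rms = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    return float(re), float(rv), rms


def _model_batch(theta: np.ndarray, windows, t: np.ndarray, amplitude: float) -> np.ndarray:
    re, rv = np.exp(theta[:, 0]), np.exp(theta[:, 1])
    return _msd_batch_fast(re, rv, t, windows, amplitude)


def fit_msd_batch(
    curves: np.ndarray,
    timing: SequenceTiming,
    opts: FitOptions = FitOptions(),
    times_ms: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized MSD fit of many curves at once.

    Initialization scans a log-spaced (re, rv) grid (the model curves are
    precomputed once, so the scan is a single matrix product), then a
    damped Gauss-Newton iteration in log-parameter space polishes every
    curve in parallel.  Agrees with :func:`fit_msd` to optimizer tolerance.

    Returns ``(re, rv, rms_error)`` arrays of length ``curves.shape[0]``.
    """
    y = np.asarray(curves, dtype=float)
    if y.ndim != 2:
        raise ValueError("curves must be (n_curves, n_samples)")
    if times_ms is None:
        _, times_ms = _fit_times(timing)
        if y.shape[1] == timing.n_events:
            y = y[:, timing.n_reference :]
    t = np.asarray(times_ms, dtype=float)

    windows = timing.forcing_windows()

    def model(theta):
        m = _model_batch(theta, windows, t, opts.amplitude)
        return m - m.mean(axis=1, keepdims=True) if opts.fit_offset else m

    if opts.fit_offset:
        y = y - y.mean(axis=1, keepdims=True)

    g = opts.grid_points
    gre = np.exp(np.linspace(*np.log(opts.re_bounds), g))
    grv = np.exp(np.linspace(*np.log(opts.rv_bounds), g))
    RE, RV = np.meshgrid(gre, grv, indexing="ij")
    C = _msd_batch_fast(RE.ravel(), RV.ravel(), t, windows, opts.amplitude)
    if opts.fit_offset:
        C = C - C.mean(axis=1, keepdims=True)
    # SSE_ij = |y_i|^2 - 2 y_i.c_j + |c_j|^2, argmin over grid j
    sse_grid = (y**2).sum(1)[:, None] - 2.0 * y @ C.T + (C**2).sum(1)[None, :]
    j0 = np.argmin(sse_grid, axis=1)
    theta = np.log(np.column_stack([RE.ravel()[j0], RV.ravel()[j0]]))

    lb = np.log([opts.re_bounds[0], opts.rv_bounds[0]])
    ub = np.log([opts.re_bounds[1], opts.rv_bounds[1]])
    lam = np.full(y.shape[0], 1e-3)
    f = model(theta)
    r = f - y
    sse = (r**2).sum(1)
    h = 1e-6
    stall = 0
    for _ in range(opts.max_iter):
        J = np.empty(y.shape + (2,))
        for k in range(2):
            tk = theta.copy()
            tk[:, k] += h
            J[:, :, k] = (model(tk) - f) / h
        grad = np.einsum("ntk,nt->nk", J, r)
        H = np.einsum("ntk,ntl->nkl", J, J)
        # Levenberg damping on the diagonal, 2x2 solve in closed form
        a = H[:, 0, 0] * (1 + lam)
        d = H[:, 1, 1] * (1 + lam)
        b = H[:, 0, 1]
        det = a * d - b * b
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        dx0 = -(d * grad[:, 0] - b * grad[:, 1]) / det
        dx1 = -(-b * grad[:, 0] + a * grad[:, 1]) / det
        theta_try = np.clip(theta + np.column_stack([dx0, dx1]), lb, ub)
        f_try = model(theta_try)
        sse_try = ((f_try - y) ** 2).sum(1)
        better = sse_try < sse
        improvement = np.where(better, (sse - sse_try) / np.maximum(sse, 1e-300), 0.0)
        theta = np.where(better[:, None], theta_try, theta)
        f = np.where(better[:, None], f_try, f)
        sse = np.where(better, sse_try, sse)
        r = f - y
        lam = np.where(better, lam / 3.0, lam * 10.0)
        lam = np.clip(lam, 1e-12, 1e8)
        # converged when several consecutive iterations achieve nothing
        # (single rejected steps just raise the damping and retry)
        stall = stall + 1 if improvement.max(initial=0.0) < 1e-12 else 0
        if stall >= 3:
            break

    re, rv = np.exp(theta[:, 0]), np.exp(theta[:, 1])
    rms = np.sqrt(sse / y.shape[1])
    return re, rv, rms


def visr_image(
    disp: DisplacementField,
    timing: SequenceTiming,
    opts: FitOptions = FitOptions(),
    focal_depth_mm: float = 20.0,
) -> VisRMaps:
    """Form PD / RE / RV parametric maps from a tracked displacement field.

    PD is the per-pixel maximum displacement over the tracked events; RE
    and RV come from the batch MSD fit of the fit-window curve.  A pixel is
    valid when enough of its fit-window estimates pass the correlation gate
    and its curve is not degenerate; invalid pixels carry NaN.
    """
    if disp.disp.shape[1] != timing.n_events:
        raise ValueError("displacement field and timing disagree on event count")
    idx, t = _fit_times(timing)
    n_ax, _, n_lat = disp.shape

    disp_arr = disp.disp
    if opts.axial_smooth > 1:
        disp_arr = uniform_filter1d(disp_arr, opts.axial_smooth, axis=0, mode="nearest")
    curves = disp_arr[:, idx, :]  # (ax, T, lat)
    valid_frac = disp.valid[:, idx, :].mean(axis=1)
    flat = np.ptp(curves, axis=1) < 1e-12
    pixel_ok = (valid_frac >= opts.min_valid_fraction) & ~flat

    pd = np.full((n_ax, n_lat), np.nan)
    re = np.full((n_ax, n_lat), np.nan)
    rv = np.full((n_ax, n_lat), np.nan)
    err = np.full((n_ax, n_lat), np.nan)

    track_events = np.arange(timing.n_reference, timing.n_events)
    pd_all = disp_arr[:, track_events, :].max(axis=1)
    pd[pixel_ok] = pd_all[pixel_ok]

    if pixel_ok.any():
        y = curves.transpose(0, 2, 1)[pixel_ok]  # (n_valid, T)
        re_v, rv_v, err_v = fit_msd_batch(y, timing, opts, times_ms=t)
        re[pixel_ok] = re_v
        rv[pixel_ok] = rv_v
        err[pixel_ok] = err_v

    return VisRMaps(
        pd=pd,
        re=re,
        rv=rv,
        fit_error=err,
        valid=pixel_ok & np.isfinite(re),
        axial_positions_mm=disp.axial_positions_mm.copy(),
        lateral_positions_mm=disp.lateral_positions_mm.copy(),
        focal_depth_mm=focal_depth_mm,
    )
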