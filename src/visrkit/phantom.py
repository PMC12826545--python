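"""Synthetic tissue phantoms and ARFI-sequence RF synthesis.

This module generates the raw material the rest of the package consumes:

* :class:`SequenceTiming` — the two-push ARFI ensemble timing (slow-time
  schedule of reference, push, and tracking events);
* :func:`msd_response` — the exact closed-form displacement response of a
  1-D mass-spring-damper (MSD) driven by the two push windows.  The same
  forward model is used to synthesize tissue motion and, in
  :mod:`visrkit.visr`, as the model fitted back to tracked displacement;
* :func:`modulus_at_angle` — the polar-ellipse law describing how the
  apparent modulus of a transversely isotropic (TI) material varies with
  imaging angle;
* :class:`TissuePhantom` / :func:`synthesize_rf` — fully developed speckle
  phantoms and band-limited RF A-line synthesis across the tracking
  ensemble;
* :func:`make_cohort` — seeded synthetic subjects (dense / non-dense
  groups) imaged at three compression levels and four angles, mirroring
  the acquisition protocol of a clinical VisR compression study.

Units are consistent throughout: depth and lateral position in mm,
displacement in µm, slow time in ms, fast-time sampling in MHz.  Elastic
and viscous constants (RE, RV) are "relative" — expressed per unit of the
nominal push amplitude — so only ratios and percent changes are
meaningful, exactly as in VisR imaging where the applied acoustic force is
unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy.signal import fftconvolve

__all__ = [
    "SequenceTiming",
    "MechanicalGroundTruth",
    "TwoLayerMech",
    "Geometry",
    "TissuePhantom",
    "AcquisitionParams",
    "RFEnsemble",
    "CohortConfig",
    "Subject",
    "msd_response",
    "modulus_at_angle",
    "make_phantom",
    "apply_compression",
    "arfi_displacement_schedule",
    "synthesize_rf",
    "acquire",
    "make_cohort",
]

COMPRESSION_LEVELS_MM = (0, 2, 5)
PROTOCOL_ANGLES_DEG = (0, 30, 60, 90)

#: Nominal MSD mass constant (module units).  Fixed, never fitted: RE and RV
#: are defined relative to this unit convention and to the nominal push
#: amplitude, mirroring how VisR parameters are relative to the (unknown)
#: applied force.
M0 = 1.0


# ---------------------------------------------------------------------------
# sequence timing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceTiming:
    """Slow-time schedule of the two-push ARFI tracking ensemble.

    The ensemble is: ``n_reference`` reference pulses, a first push,
    ``n_tracks_between_pushes`` tracking pulses, a second push, and
    ``n_tracks_after`` tracking pulses, all at pulse repetition frequency
    ``prf``.  Each push lasts ``push_cycles / push_freq``.
    """

    n_reference: int = 2
    n_tracks_between_pushes: int = 8
    n_tracks_after: int = 43
    prf_khz: float = 11.5
    push_cycles: int = 300
    push_freq_mhz: float = 4.21
    track_freq_mhz: float = 6.15
    track_cycles: int = 2

    def __post_init__(self) -> None:
        if self.prf_khz <= 0:
            raise ValueError("prf must be positive")
        if self.push_cycles <= 0 or self.push_freq_mhz <= 0:
            raise ValueError("push duration must be positive")

    @property
    def n_events(self) -> int:
        """Total slow-time events: references + 2 pushes + tracking pulses."""
        return self.n_reference + 2 + self.n_tracks_between_pushes + self.n_tracks_after

    @property
    def event_times_ms(self) -> np.ndarray:
        """Times of the slow-time events, starting at the first reference."""
        return np.arange(self.n_events) / self.prf_khz

    @property
    def push_duration_ms(self) -> float:
        return self.push_cycles / (self.push_freq_mhz * 1e3)

    @property
    def push_onsets_ms(self) -> tuple[float, float]:
        """Onset times of the two pushes.

        The first push starts once the reference events are done; the second
        follows after the inter-push tracking interval
        (``n_tracks_between_pushes / prf``).
        """
        t1 = self.n_reference / self.prf_khz
        t2 = t1 + self.n_tracks_between_pushes / self.prf_khz
        return (t1, t2)

    def forcing_windows(self) -> list[tuple[float, float]]:
        dur = self.push_duration_ms
        wins = [(t, t + dur) for t in self.push_onsets_ms]
        for (a0, a1), (b0, _) in zip(wins[:-1], wins[1:]):
            if b0 < a1:
                raise ValueError("push windows overlap; check timing")
        return wins


# ---------------------------------------------------------------------------
# mass-spring-damper forward model
# ---------------------------------------------------------------------------

def _step_response(t: np.ndarray, re: np.ndarray, rv: np.ndarray, m0: float) -> np.ndarray:
    """Unit-step response of ``m0 x'' + rv x' + re x = 1``, zero for t < 0.

    Evaluated in closed form from the characteristic roots; complex
    arithmetic covers the underdamped case transparently.  ``re`` and ``rv``
    broadcast against each other, ``t`` is appended as a trailing axis.
    """
    re = np.asarray(re, dtype=float)[..., None]
    rv = np.asarray(rv, dtype=float)[..., None]
    t = np.asarray(t, dtype=float)

    disc = np.asarray(rv**2 - 4.0 * m0 * re, dtype=complex)
    sq = np.sqrt(disc)
    r1 = (-rv + sq) / (2.0 * m0)
    r2 = (-rv - sq) / (2.0 * m0)

    tp = np.where(t > 0.0, t, 0.0)
    degenerate = np.abs(r1 - r2) < 1e-9 * (np.abs(r1) + np.abs(r2) + 1e-300)
    denom = np.where(degenerate, 1.0, r2 - r1)
    transient = (r2 * np.exp(r1 * tp) - r1 * np.exp(r2 * tp)) / denom
    # critically damped limit: (1 + |r| t) e^{r t}
    crit = (1.0 - r1 * tp) * np.exp(r1 * tp)
    transient = np.where(degenerate, crit, transient)

    out = (1.0 - transient).real / re
    return np.where(t > 0.0, out, 0.0)


def _msd_batch_fast(
    re: np.ndarray,
    rv: np.ndarray,
    t: np.ndarray,
    windows: list[tuple[float, float]],
    amplitude: float,
    m0: float = M0,
) -> np.ndarray:
    """Closed-form MSD ensemble response for 1-D parameter vectors.

    Same mathematics as :func:`msd_response` but factored so the two
    characteristic exponentials are evaluated once and reused for every
    step edge — the hot path of batch fitting.  Exactly repeated roots are
    nudged by a relatively negligible amount instead of branching.
    """
    re = np.atleast_1d(np.asarray(re, dtype=float))
    rv = np.atleast_1d(np.asarray(rv, dtype=float))
    t = np.asarray(t, dtype=float)
    sq = np.sqrt(np.asarray(rv**2 - 4.0 * m0 * re, dtype=complex))
    eps = 1e-9 * (rv + 1.0)
    sq = np.where(np.abs(sq) < eps, eps.astype(complex), sq)
    r1 = (-rv + sq) / (2.0 * m0)
    r2 = (-rv - sq) / (2.0 * m0)
    E1 = np.exp(np.multiply.outer(r1, t))
    E2 = np.exp(np.multiply.outer(r2, t))
    denom = r2 - r1
    x = np.zeros((re.size, t.size))
    for on, off in windows:
        for s, sign in ((on, 1.0), (off, -1.0)):
            cols = t > s
            if not cols.any():
                continue
            a1 = (r2 * np.exp(-r1 * s) / denom)[:, None]
            a2 = (r1 * np.exp(-r2 * s) / denom)[:, None]
            step = (1.0 - (a1 * E1[:, cols] - a2 * E2[:, cols])).real / re[:, None]
            x[:, cols] += sign * step
    return amplitude * x


def msd_response(
    re,
    rv,
    timing: SequenceTiming,
    t=None,
    amplitude: float = 1.0,
    m0: float = M0,
) -> np.ndarray:
    """Displacement x(t) of the MSD driven by the two-push ARFI schedule.

    Solves ``m0 x'' + rv x' + re x = f(t)`` exactly (piecewise closed form,
    no numeric integration), with ``f(t) = amplitude`` inside each push
    window and zero otherwise, and ``x(0) = x'(0) = 0``.

    Parameters
    ----------
    re, rv : float or array_like
        Relative elasticity (restoring constant, per-µm per unit force) and
        relative viscosity (damping constant, per-ms per unit force).  Arrays
        broadcast; the returned array has shape ``broadcast(re, rv) + t.shape``.
    timing : SequenceTiming
        Defines push onsets and duration.
    t : array_like, optional
        Slow-time grid in ms, measured from the first reference event.
        Defaults to ``timing.event_times_ms``.
    amplitude : float
        Push force amplitude in module units.  Displacement is linear in it.
    m0 : float
        Nominal mass constant; a unit convention, not a fit parameter.

    Returns
    -------
    ndarray
        Displacement in µm on the grid ``t``.
    """
    re_a = np.asarray(re, dtype=float)
    rv_a = np.asarray(rv, dtype=float)
    if np.any(re_a <= 0) or np.any(rv_a <= 0):
        raise ValueError("re and rv must be positive")
    if t is None:
        t = timing.event_times_ms
    t = np.atleast_1d(np.asarray(t, dtype=float))

    x = np.zeros(np.broadcast_shapes(re_a.shape, rv_a.shape) + t.shape)
    for on, off in timing.forcing_windows():
        x = x + _step_response(t - on, re_a, rv_a, m0)
        x = x - _step_response(t - off, re_a, rv_a, m0)
    out = amplitude * x
    if np.isscalar(re) and np.isscalar(rv) and np.ndim(t) <= 1:
        return out.reshape(t.shape)
    return out


def modulus_at_angle(m_long, m_trans, aos_angle_deg, theta_deg):
    """Apparent modulus of a TI material at imaging angle ``theta_deg``.

    Polar-ellipse law: the modulus traces an origin-centered ellipse with
    semi-axes ``m_long`` (along the material axis of symmetry) and
    ``m_trans`` (across it),

    ``r(θ) = m_long m_trans / sqrt(m_trans² cos²Δ + m_long² sin²Δ)``,

    with ``Δ = θ − aos_angle``.  180°-periodic and bounded between the two
    moduli.
    """
    m_long = np.asarray(m_long, dtype=float)
    m_trans = np.asarray(m_trans, dtype=float)
    if np.any(m_long <= 0) or np.any(m_trans <= 0):
        raise ValueError("moduli must be positive")
    delta = np.deg2rad(np.asarray(theta_deg, dtype=float) - aos_angle_deg)
    r = m_long * m_trans / np.sqrt(
        (m_trans * np.cos(delta)) ** 2 + (m_long * np.sin(delta)) ** 2
    )
    return r if r.ndim else float(r)


# ---------------------------------------------------------------------------
# mechanics ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MechanicalGroundTruth:
    """Homogeneous TI viscoelastic ground truth for one subject.

    ``re_*``/``rv_*`` are the longitudinal/transverse relative elasticity and
    viscosity (module units, per nominal push amplitude);
    ``aos_angle_deg`` is the in-plane material axis of symmetry;
    ``stiffening_per_mm`` the fractional modulus increase per mm of applied
    surface compression (may be negative: the compression–modulus relation
    in vivo is not monotone for all tissues).
    """

    re_long: float
    re_trans: float
    rv_long: float
    rv_trans: float
    aos_angle_deg: float = 0.0
    stiffening_per_mm: float = 0.0
    dense: bool = False

    def __post_init__(self) -> None:
        if min(self.re_long, self.re_trans, self.rv_long, self.rv_trans) <= 0:
            raise ValueError("moduli must be positive")

    def params_at(self, depth_mm, theta_deg):
        """(re, rv) at imaging angle ``theta_deg``; depth-independent here."""
        re = modulus_at_angle(self.re_long, self.re_trans, self.aos_angle_deg, theta_deg)
        rv = modulus_at_angle(self.rv_long, self.rv_trans, self.aos_angle_deg, theta_deg)
        depth_mm = np.asarray(depth_mm, dtype=float)
        return np.broadcast_to(re, depth_mm.shape).copy(), np.broadcast_to(rv, depth_mm.shape).copy()

    @property
    def doa_re(self) -> float:
        """Ground-truth degree of anisotropy of RE (max/min over angle)."""
        hi, lo = max(self.re_long, self.re_trans), min(self.re_long, self.re_trans)
        return hi / lo

    @property
    def doa_rv(self) -> float:
        hi, lo = max(self.rv_long, self.rv_trans), min(self.rv_long, self.rv_trans)
        return hi / lo

    def scaled(self, factor: float) -> "MechanicalGroundTruth":
        return replace(
            self,
            re_long=self.re_long * factor,
            re_trans=self.re_trans * factor,
            rv_long=self.rv_long * factor,
            rv_trans=self.rv_trans * factor,
        )


@dataclass(frozen=True)
class TwoLayerMech:
    """Two stacked homogeneous layers with an interface at a given depth.

    Used for the adaptive-ROI experiments where an echogenic layer of
    distinct stiffness crosses the focal region under compression.
    ``echogenicity_bottom`` scales scatterer amplitudes below the interface.
    """

    top: MechanicalGroundTruth
    bottom: MechanicalGroundTruth
    interface_depth_mm: float
    echogenicity_bottom: float = 2.5

    # the group/stiffening attributes of the top layer stand in for the subject
    @property
    def dense(self) -> bool:
        return self.top.dense

    @property
    def stiffening_per_mm(self) -> float:
        return self.top.stiffening_per_mm

    def params_at(self, depth_mm, theta_deg):
        depth_mm = np.asarray(depth_mm, dtype=float)
        re_t, rv_t = self.top.params_at(depth_mm, theta_deg)
        re_b, rv_b = self.bottom.params_at(depth_mm, theta_deg)
        below = depth_mm >= self.interface_depth_mm
        return np.where(below, re_b, re_t), np.where(below, rv_b, rv_t)

    def scaled(self, factor: float) -> "TwoLayerMech":
        return replace(self, top=self.top.scaled(factor), bottom=self.bottom.scaled(factor))


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Geometry:
    """Imaging geometry: 40 beam lines across a 2-cm field of view."""

    lateral_span_mm: float = 20.0
    n_lines: int = 40
    axial_min_mm: float = 5.0
    axial_max_mm: float = 35.0
    focal_depth_mm: float = 20.0

    @property
    def line_positions_mm(self) -> np.ndarray:
        half = self.lateral_span_mm / 2.0
        return np.linspace(-half, half, self.n_lines)


@dataclass(frozen=True)
class TissuePhantom:
    """Point-scatterer field plus mechanical ground truth.

    ``scatterers`` is an (N, 3) array of (axial mm, lateral mm, amplitude).
    """

    scatterers: np.ndarray
    geometry: Geometry
    mech: MechanicalGroundTruth | TwoLayerMech
    seed: int
    compression_mm: int = 0

    @property
    def n_scatterers(self) -> int:
        return self.scatterers.shape[0]


def make_phantom(
    mech: MechanicalGroundTruth | TwoLayerMech,
    seed: int,
    geometry: Geometry = Geometry(),
    scatterers_per_mm2: float = 55.0,
) -> TissuePhantom:
    """Draw a fully developed speckle phantom.

    The resolution cell is ~0.25 mm (axial pulse length, 2 cycles at
    6.15 MHz) × ~0.8 mm (lateral beam FWHM), i.e. ~0.2 mm², so the default
    density of 55 scatterers/mm² puts ≥10 scatterers per cell — the usual
    criterion for fully developed speckle.  Amplitudes are standard normal;
    a lateral margin of 2 mm beyond the field of view keeps edge lines
    fully insonified.
    """
    rng = default_rng(seed)
    margin = 2.0
    lat_lo = -geometry.lateral_span_mm / 2 - margin
    lat_hi = geometry.lateral_span_mm / 2 + margin
    area = (geometry.axial_max_mm - geometry.axial_min_mm) * (lat_hi - lat_lo)
    n = int(round(scatterers_per_mm2 * area))
    if n < 1:
        raise ValueError("scatterer density too low")
    ax = rng.uniform(geometry.axial_min_mm, geometry.axial_max_mm, n)
    lat = rng.uniform(lat_lo, lat_hi, n)
    amp = rng.standard_normal(n)
    if isinstance(mech, TwoLayerMech):
        amp = np.where(ax >= mech.interface_depth_mm, amp * mech.echogenicity_bottom, amp)
    scat = np.column_stack([ax, lat, amp])
    return TissuePhantom(scatterers=scat, geometry=geometry, mech=mech, seed=int(seed))


def apply_compression(phantom: TissuePhantom, compression_mm: int) -> TissuePhantom:
    """Pre-load the phantom with axial surface compression.

    Moduli stiffen geometrically, ``×(1 + stiffening_per_mm)**compression``,
    and scatterers shift toward the transducer under a uniform strain of
    ``compression / focal_depth`` (depth d maps to d·(1 − strain)).  For a
    two-layer phantom the interface depth compresses the same way.
    """
    if compression_mm not in COMPRESSION_LEVELS_MM:
        raise ValueError(f"unsupported compression {compression_mm!r} (expected one of {COMPRESSION_LEVELS_MM})")
    if compression_mm == 0:
        return phantom
    strain = compression_mm / phantom.geometry.focal_depth_mm
    factor = (1.0 + phantom.mech.stiffening_per_mm) ** compression_mm
    mech = phantom.mech.scaled(factor)
    if isinstance(mech, TwoLayerMech):
        mech = replace(mech, interface_depth_mm=mech.interface_depth_mm * (1.0 - strain))
    scat = phantom.scatterers.copy()
    scat[:, 0] *= 1.0 - strain
    return replace(phantom, scatterers=scat, mech=mech, compression_mm=int(compression_mm))


# ---------------------------------------------------------------------------
# RF synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionParams:
    """Everything about one synthetic acquisition other than the tissue.

    ``push_amplitude`` is the nominal ARFI force amplitude in module units
    (shared by the MSD fitter as a unit convention); the push spatial profile
    is separably Gaussian with the given axial/lateral widths.  The tracking
    beam is a Gaussian lateral sensitivity profile.  ``axial_window_mm``
    restricts RF synthesis to the depth band that is actually tracked.
    """

    timing: SequenceTiming = SequenceTiming()
    fs_mhz: float = 40.0
    c_m_s: float = 1540.0
    snr_db: float = 20.0
    push_amplitude: float = 600.0
    push_sigma_axial_mm: float = 8.0
    push_sigma_lateral_mm: float = 1.0
    track_sigma_lateral_mm: float = 0.35
    axial_window_mm: tuple[float, float] = (14.0, 26.0)

    def __post_init__(self) -> None:
        if self.fs_mhz < 4.0 * self.timing.track_freq_mhz:
            raise ValueError("fs must be at least 4x the tracking frequency")

    @property
    def sample_pitch_mm(self) -> float:
        """Axial spacing of RF samples: c / (2 fs)."""
        return self.c_m_s / (2.0 * self.fs_mhz * 1e6) * 1e3


@dataclass
class RFEnsemble:
    """RF A-line time series across the slow-time tracking ensemble.

    ``samples`` has shape (fast-time sample, slow-time event, lateral line),
    float32.  ``axial_start_mm`` locates sample 0.
    """

    samples: np.ndarray
    fs_mhz: float
    c_m_s: float
    timing: SequenceTiming
    axial_start_mm: float
    line_positions_mm: np.ndarray
    compression_mm: int = 0
    angle_deg: int = 0
    seed: int = 0
    ground_truth: dict | None = None

    @property
    def sample_pitch_mm(self) -> float:
        return self.c_m_s / (2.0 * self.fs_mhz * 1e6) * 1e3

    @property
    def axial_positions_mm(self) -> np.ndarray:
        return self.axial_start_mm + np.arange(self.samples.shape[0]) * self.sample_pitch_mm


# 8-tap Kaiser-windowed sinc for band-limited sub-sample delta placement
_TAPS = np.arange(-3, 5)
_KAISER_BETA = 8.0
_KAISER_HALF = 4.0
_LUT_STEPS = 1024
_DELAY_LUT: np.ndarray | None = None


def _frac_delay_weights(frac: np.ndarray) -> np.ndarray:
    """Windowed-sinc weights placing a unit delta at fractional offset frac."""
    x = _TAPS[None, :] - frac[:, None]
    arg = 1.0 - (x / _KAISER_HALF) ** 2
    win = np.where(arg > 0, np.i0(_KAISER_BETA * np.sqrt(np.clip(arg, 0, None))), 0.0)
    return np.sinc(x) * win / np.i0(_KAISER_BETA)


def _delay_lut() -> np.ndarray:
    """Fractional delays quantized to 1/1024 sample (~0.02 µm at 40 MHz).

    The quantization is far below tracking precision and incoherent across
    the thousands of scatterers in a resolution cell, so it behaves as
    dither rather than bias.
    """
    global _DELAY_LUT
    if _DELAY_LUT is None:
        _DELAY_LUT = _frac_delay_weights(np.arange(_LUT_STEPS + 1) / _LUT_STEPS)
    return _DELAY_LUT


def _tracking_pulse(params: AcquisitionParams) -> np.ndarray:
    """Gaussian-enveloped cosine at the tracking frequency."""
    f0 = params.timing.track_freq_mhz
    dt_us = 1.0 / params.fs_mhz
    sigma_us = params.timing.track_cycles / f0 / 2.355  # FWHM = pulse length
    half = int(np.ceil(3.5 * sigma_us / dt_us))
    t = np.arange(-half, half + 1) * dt_us
    return np.exp(-0.5 * (t / sigma_us) ** 2) * np.cos(2 * np.pi * f0 * t)


def synthesize_rf(
    phantom: TissuePhantom,
    displacement_schedule,
    seed: int,
    params: AcquisitionParams = AcquisitionParams(),
    angle_deg: int = 0,
) -> RFEnsemble:
    """Render the RF tracking ensemble for every beam line.

    Each A-line is the superposition of a band-limited pulse centered at
    every scatterer's instantaneous axial position (scatterer depth plus its
    scheduled axial displacement at that slow-time event), weighted by a
    Gaussian lateral beam profile, sampled at ``fs``, with seeded white
    noise at the configured SNR.  Identical seeds give bit-identical output.

    Parameters
    ----------
    displacement_schedule : ndarray or callable
        Either an (n_scatterers, n_events) array of axial displacements in
        µm applied identically for every line, or a callable
        ``schedule(line_lat_mm, scatterer_indices) -> (n_sub, n_events)``
        evaluated per line (used for push profiles centered on each line).
    """
    if phantom.n_scatterers == 0:
        raise ValueError("phantom has no scatterers")
    if params.snr_db is not None and np.isfinite(params.snr_db) and params.snr_db <= 0:
        raise ValueError("snr_db must be positive (use np.inf for noise-free)")

    timing = params.timing
    n_events = timing.n_events
    z0, z1 = params.axial_window_mm
    dz = params.sample_pitch_mm
    n_samples = int(round((z1 - z0) / dz))
    pulse = _tracking_pulse(params)
    pad = len(pulse) // 2 + len(_TAPS) + 2

    scat = phantom.scatterers
    lines = phantom.geometry.line_positions_mm
    lat_support = 3.5 * params.track_sigma_lateral_mm

    rf = np.zeros((n_samples, n_events, phantom.geometry.n_lines), dtype=np.float64)
    for j, x_line in enumerate(lines):
        dlat = scat[:, 1] - x_line
        in_beam = np.abs(dlat) <= lat_support
        in_depth = (scat[:, 0] > z0 - 0.5) & (scat[:, 0] < z1 + 0.5)
        idx = np.flatnonzero(in_beam & in_depth)
        if idx.size == 0:
            continue
        w_amp = scat[idx, 2] * np.exp(-0.5 * (dlat[idx] / params.track_sigma_lateral_mm) ** 2)
        if callable(displacement_schedule):
            u = np.asarray(displacement_schedule(x_line, idx), dtype=float)
        else:
            u = np.asarray(displacement_schedule, dtype=float)[idx]
        if u.shape != (idx.size, n_events):
            raise ValueError("displacement schedule has wrong shape")
        # instantaneous depth -> fractional sample position (padded grid)
        pos = (scat[idx, 0][:, None] + u * 1e-3 - z0) / dz + pad
        base = np.floor(pos).astype(np.int64)
        qi = np.round((pos - base) * _LUT_STEPS).astype(np.intp)
        wts = _delay_lut()[qi] * w_amp[:, None, None]  # (scat, events, taps)
        n_pad = n_samples + 2 * pad
        tap_idx = base[:, :, None] + _TAPS[None, None, :]
        ok = ((tap_idx >= 0) & (tap_idx < n_pad)).ravel()
        flat_idx = (tap_idx + np.arange(n_events)[None, :, None] * n_pad).ravel()
        delta = np.bincount(
            flat_idx[ok], weights=wts.ravel()[ok], minlength=n_events * n_pad
        ).reshape(n_events, n_pad)
        line_rf = fftconvolve(delta, pulse[None, :], mode="same", axes=1)
        rf[:, :, j] = line_rf[:, pad : pad + n_samples].T

    if params.snr_db is not None and np.isfinite(params.snr_db):
        rng = default_rng(seed)
        sigma = float(np.sqrt(np.mean(rf**2))) * 10.0 ** (-params.snr_db / 20.0)
        rf = rf + rng.normal(0.0, sigma, rf.shape)

    return RFEnsemble(
        samples=rf.astype(np.float32),
        fs_mhz=params.fs_mhz,
        c_m_s=params.c_m_s,
        timing=timing,
        axial_start_mm=z0,
        line_positions_mm=lines.copy(),
        compression_mm=phantom.compression_mm,
        angle_deg=int(angle_deg),
        seed=int(seed),
    )


def arfi_displacement_schedule(
    phantom: TissuePhantom,
    params: AcquisitionParams,
    angle_deg: float,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Per-line MSD displacement schedule under the two-push ARFI forcing.

    Every scatterer follows the closed-form MSD response for its local
    (re, rv) at this imaging angle, scaled by a separable Gaussian push
    profile centered on the focal depth and on the active beam line.
    """
    timing = params.timing
    fd = phantom.geometry.focal_depth_mm

    def schedule(line_lat_mm: float, idx: np.ndarray) -> np.ndarray:
        z = phantom.scatterers[idx, 0]
        lat = phantom.scatterers[idx, 1]
        re, rv = phantom.mech.params_at(z, angle_deg)
        # evaluate one curve per distinct (re, rv); homogeneous tissue -> 1
        pairs = np.column_stack([re, rv])
        uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
        curves = msd_response(
            uniq[:, 0], uniq[:, 1], timing, amplitude=params.push_amplitude
        ).reshape(len(uniq), -1)
        w = np.exp(-0.5 * ((z - fd) / params.push_sigma_axial_mm) ** 2)
        w *= np.exp(-0.5 * ((lat - line_lat_mm) / params.push_sigma_lateral_mm) ** 2)
        return w[:, None] * curves[inv]

    return schedule


def acquire(
    phantom: TissuePhantom,
    angle_deg: int,
    params: AcquisitionParams,
    seed: int,
) -> RFEnsemble:
    """Synthesize one full acquisition (push + tracking) at one angle."""
    sched = arfi_displacement_schedule(phantom, params, angle_deg)
    rf = synthesize_rf(phantom, sched, seed=seed, params=params, angle_deg=angle_deg)
    mech = phantom.mech
    if isinstance(mech, MechanicalGroundTruth):
        re_f, rv_f = mech.params_at(np.array(phantom.geometry.focal_depth_mm), angle_deg)
        rf.ground_truth = {
            "re_focal": float(re_f),
            "rv_focal": float(rv_f),
            "aos_angle_deg": mech.aos_angle_deg,
            "doa_re": mech.doa_re,
            "doa_rv": mech.doa_rv,
            "stiffening_per_mm": mech.stiffening_per_mm,
            "dense": mech.dense,
        }
    return rf


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Distributions for the synthetic compression-study cohort.

    Transverse moduli are log-normal; per-metric degree of anisotropy is
    uniform (the clinical range for non-tumor mammary tissue is roughly
    1–4, mostly 2–4); the material axis of symmetry is uniform in [0, 180)
    because its alignment is not known a priori.  Dense-breast subjects draw
    a larger compression-stiffening rate than non-dense subjects,
    reproducing the stronger stiffening under pre-load seen in dense
    breasts.
    """

    re_trans_median: float = 10.0
    re_trans_sigma_log: float = 0.18
    rv_trans_median: float = 5.0
    rv_trans_sigma_log: float = 0.18
    doa_re_range: tuple[float, float] = (1.5, 3.5)
    doa_rv_range: tuple[float, float] = (1.5, 3.0)
    stiffening_dense: tuple[float, float] = (0.06, 0.015)  # mean, sd per mm
    stiffening_nondense: tuple[float, float] = (0.025, 0.008)
    isotropic: bool = False
    acquisition: AcquisitionParams = AcquisitionParams()
    geometry: Geometry = Geometry()
    scatterers_per_mm2: float = 55.0
    compressions_mm: tuple[int, ...] = COMPRESSION_LEVELS_MM
    angles_deg: tuple[int, ...] = PROTOCOL_ANGLES_DEG

    def __post_init__(self) -> None:
        for lo, hi in (self.doa_re_range, self.doa_rv_range):
            if not (1.0 <= lo <= hi):
                raise ValueError("DoA range must satisfy 1 <= lo <= hi")


def _subject_seed(master_seed: int, subject_index: int, *extra: int) -> int:
    ss = SeedSequence(entropy=master_seed, spawn_key=(subject_index, *extra))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def draw_mechanics(config: CohortConfig, dense: bool, rng) -> MechanicalGroundTruth:
    """Draw one subject's TI ground truth from the cohort distributions."""
    re_trans = config.re_trans_median * np.exp(rng.normal(0.0, config.re_trans_sigma_log))
    rv_trans = config.rv_trans_median * np.exp(rng.normal(0.0, config.rv_trans_sigma_log))
    if config.isotropic:
        doa_re = doa_rv = 1.0
    else:
        doa_re = rng.uniform(*config.doa_re_range)
        doa_rv = rng.uniform(*config.doa_rv_range)
    mean, sd = config.stiffening_dense if dense else config.stiffening_nondense
    return MechanicalGroundTruth(
        re_long=re_trans * doa_re,
        re_trans=re_trans,
        rv_long=rv_trans * doa_rv,
        rv_trans=rv_trans,
        aos_angle_deg=float(rng.uniform(0.0, 180.0)),
        stiffening_per_mm=float(rng.normal(mean, sd)),
        dense=dense,
    )


@dataclass
class Subject:
    """One synthetic study participant.

    Acquisitions are generated on demand (an RF ensemble is tens of MB;
    a cohort holds phantoms and ground truth, not 240 rendered ensembles).
    ``acquisition(compression_mm, angle_deg)`` is deterministic in the
    subject's seed.
    """

    subject_id: str
    index: int
    dense: bool
    mech: MechanicalGroundTruth
    phantom: TissuePhantom
    config: CohortConfig
    master_seed: int

    @property
    def acquisition_keys(self) -> list[tuple[int, int]]:
        return [(c, a) for c in self.config.compressions_mm for a in self.config.angles_deg]

    def compressed_phantom(self, compression_mm: int) -> TissuePhantom:
        return apply_compression(self.phantom, compression_mm)

    def acquisition(self, compression_mm: int, angle_deg: int) -> RFEnsemble:
        ci = self.config.compressions_mm.index(compression_mm)
        ai = self.config.angles_deg.index(angle_deg)
        seed = _subject_seed(self.master_seed, self.index, 1 + ci, ai)
        return acquire(
            self.compressed_phantom(compression_mm),
            angle_deg,
            self.config.acquisition,
            seed=seed,
        )


def make_cohort(
    n_dense: int,
    n_nondense: int,
    config: CohortConfig = CohortConfig(),
    seed: int = 0,
) -> list[Subject]:
    """Generate a seeded synthetic cohort.

    Subjects are ordered dense-first.  Per-subject ground truth, scatterer
    field, and per-acquisition noise streams are derived from the master
    seed through fixed ``SeedSequence`` spawn keys, so the whole cohort is
    bit-reproducible.
    """
    if n_dense < 0 or n_nondense < 0:
        raise ValueError("subject counts must be non-negative")
    subjects: list[Subject] = []
    for i in range(n_dense + n_nondense):
        dense = i < n_dense
        rng = default_rng(SeedSequence(entropy=seed, spawn_key=(i, 0)))
        mech = draw_mechanics(config, dense, rng)
        phantom = make_phantom(
            mech,
            seed=_subject_seed(seed, i, 99),
            geometry=config.geometry,
            scatterers_per_mm2=config.scatterers_per_mm2,
        )
        subjects.append(
            Subject(
                subject_id=f"S{i + 1:02d}",
                index=i,
                dense=dense,
                mech=mech,
                phantom=phantom,
                config=config,
                master_seed=int(seed),
            )
        )
    return subjects
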