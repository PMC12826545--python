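"""Forward model, phantom mechanics, and cohort generator tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from visrkit.phantom import (
    AcquisitionParams,
    CohortConfig,
    MechanicalGroundTruth,
    SequenceTiming,
    TwoLayerMech,
    apply_compression,
    draw_mechanics,
    make_cohort,
    make_phantom,
    modulus_at_angle,
    msd_response,
    synthesize_rf,
)


def rk4_msd_oracle(re, rv, timing, t_grid, amplitude=1.0, m0=1.0, dt=1e-4):
    """Fixed-step RK4 integration of the MSD ODE, independent of the closed form."""
    windows = timing.forcing_windows()

    def force(tt):
        return amplitude if any(a <= tt < b for a, b in windows) else 0.0

    def deriv(tt, x, v):
        return v, (force(tt) - rv * v - re * x) / m0

    out = np.zeros_like(t_grid)
    x = v = 0.0
    tt, oi = 0.0, 0
    n = int(np.ceil(t_grid[-1] / dt))
    for _ in range(n + 1):
        while oi < len(t_grid) and t_grid[oi] <= tt + 1e-12:
            out[oi] = x
            oi += 1
        k1x, k1v = deriv(tt, x, v)
        k2x, k2v = deriv(tt + dt / 2, x + dt / 2 * k1x, v + dt / 2 * k1v)
        k3x, k3v = deriv(tt + dt / 2, x + dt / 2 * k2x, v + dt / 2 * k2v)
        k4x, k4v = deriv(tt + dt, x + dt * k3x, v + dt * k3v)
        x += dt / 6 * (k1x + 2 * k2x + 2 * k3x + k4x)
        v += dt / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)
        tt += dt
    return out


class TestSequenceTiming:
    def test_event_budget(self, timing):
        # 2 references + 2 pushes + 8 + 43 tracking pulses
        assert timing.n_events == 55
        assert timing.event_times_ms[0] == 0.0
        assert np.allclose(np.diff(timing.event_times_ms), 1.0 / timing.prf_khz)

    def test_push_schedule_arithmetic(self, timing):
        on1, on2 = timing.push_onsets_ms
        assert on2 - on1 == pytest.approx(8.0 / 11.5, abs=1e-12)
        assert timing.push_duration_ms == pytest.approx(300 / 4210, rel=1e-9)

    def test_overlapping_pushes_rejected(self):
        bad = SequenceTiming(push_cycles=300, push_freq_mhz=0.3)  # 1-ms pushes
        with pytest.raises(ValueError, match="overlap"):
            bad.forcing_windows()


class TestMsdResponse:
    def test_matches_rk4_oracle(self, timing):
        x = msd_response(0.05, 0.2, timing)
        ref = rk4_msd_oracle(0.05, 0.2, timing, timing.event_times_ms)
        assert np.max(np.abs(x - ref)) / np.max(np.abs(ref)) < 1e-3

    def test_infinite_stiffness_limit(self, timing):
        x = msd_response(1e9, 1.0, timing)
        assert np.max(np.abs(x)) < 1e-6

    def test_zero_forcing(self, timing):
        x = msd_response(10.0, 5.0, timing, amplitude=0.0)
        assert np.all(x == 0.0)

    def test_initial_rest(self, timing):
        x = msd_response(10.0, 5.0, timing)
        # nothing moves before the first push
        pre = timing.event_times_ms < timing.push_onsets_ms[0]
        assert np.all(x[pre] == 0.0)

    def test_amplitude_linearity(self, timing):
        x1 = msd_response(10.0, 5.0, timing, amplitude=1.0)
        x2 = msd_response(10.0, 5.0, timing, amplitude=2.0)
        assert np.allclose(x2, 2.0 * x1, rtol=1e-12)

    def test_peak_monotone_in_stiffness(self, timing):
        peaks = [msd_response(re, 5.0, timing).max() for re in (2.0, 5.0, 10.0, 25.0, 60.0)]
        assert np.all(np.diff(peaks) < 0)

    def test_rejects_nonpositive_parameters(self, timing):
        with pytest.raises(ValueError):
            msd_response(-1.0, 5.0, timing)
        with pytest.raises(ValueError):
            msd_response(10.0, 0.0, timing)

    def test_critical_damping_continuous(self, timing):
        # closed form must not blow up where the roots coalesce (rv^2 = 4 re)
        re = 9.0
        x_crit = msd_response(re, 2 * np.sqrt(re), timing)
        x_near = msd_response(re, 2 * np.sqrt(re) * (1 + 1e-7), timing)
        assert np.allclose(x_crit, x_near, rtol=1e-4, atol=1e-12)


class TestModulusAtAngle:
    def test_on_axis_and_worked_value(self):
        assert modulus_at_angle(4.0, 2.0, 30.0, 30.0) == pytest.approx(4.0)
        assert modulus_at_angle(4.0, 2.0, 0.0, 45.0) == pytest.approx(8.0 / np.sqrt(10.0))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        m_long=st.floats(0.5, 50.0),
        m_trans=st.floats(0.5, 50.0),
        aos=st.floats(0.0, 180.0),
        theta=st.floats(-360.0, 360.0),
    )
    def test_periodic_and_bounded(self, m_long, m_trans, aos, theta):
        r = modulus_at_angle(m_long, m_trans, aos, theta)
        assert min(m_long, m_trans) - 1e-9 <= r <= max(m_long, m_trans) + 1e-9
        assert r == pytest.approx(modulus_at_angle(m_long, m_trans, aos, theta + 180.0), rel=1e-9)

    def test_isotropic_constant(self):
        th = np.linspace(0, 180, 13)
        assert np.allclose(modulus_at_angle(3.0, 3.0, 77.0, th), 3.0)


class TestCompression:
    def mech(self, s=0.05):
        return MechanicalGroundTruth(10.0, 5.0, 6.0, 3.0, stiffening_per_mm=s)

    def test_zero_compression_identity(self):
        ph = make_phantom(self.mech(), seed=0)
        assert apply_compression(ph, 0) is ph

    def test_stiffening_arithmetic(self):
        ph = make_phantom(self.mech(0.05), seed=0)
        out = apply_compression(ph, 2)
        assert out.mech.re_long == pytest.approx(10.0 * 1.05**2)
        assert out.mech.rv_trans == pytest.approx(3.0 * 1.1025)

    def test_uniform_strain_shift(self):
        ph = make_phantom(self.mech(0.0), seed=0)
        out = apply_compression(ph, 5)
        # 5 mm over a 20-mm focal depth is 25% strain; shift = strain x depth
        assert np.allclose(out.scatterers[:, 0], ph.scatterers[:, 0] * 0.75)
        assert np.array_equal(out.scatterers[:, 1:], ph.scatterers[:, 1:])

    def test_zero_stiffening_preserves_moduli(self):
        ph = make_phantom(self.mech(0.0), seed=0)
        out = apply_compression(ph, 5)
        assert out.mech.re_long == ph.mech.re_long

    def test_unsupported_level(self):
        ph = make_phantom(self.mech(), seed=0)
        with pytest.raises(ValueError):
            apply_compression(ph, 3)

    def test_two_layer_interface_compresses(self):
        mech = TwoLayerMech(self.mech(0.0), self.mech(0.0), interface_depth_mm=22.0)
        ph = make_phantom(mech, seed=0)
        out = apply_compression(ph, 2)
        assert out.mech.interface_depth_mm == pytest.approx(22.0 * 0.9)


class TestSynthesis:
    def test_determinism(self, homogeneous_phantom, acq_params):
        u = np.zeros((homogeneous_phantom.n_scatterers, acq_params.timing.n_events))
        a = synthesize_rf(homogeneous_phantom, u, seed=5, params=acq_params)
        b = synthesize_rf(homogeneous_phantom, u, seed=5, params=acq_params)
        assert np.array_equal(a.samples, b.samples)

    def test_static_tissue_noise_free(self, homogeneous_phantom):
        params = AcquisitionParams(snr_db=np.inf)
        u = np.zeros((homogeneous_phantom.n_scatterers, params.timing.n_events))
        rf = synthesize_rf(homogeneous_phantom, u, seed=5, params=params)
        assert np.array_equal(rf.samples[:, 0, :], rf.samples[:, 30, :])

    def test_rejects_bad_inputs(self, homogeneous_phantom):
        with pytest.raises(ValueError, match="snr"):
            synthesize_rf(
                homogeneous_phantom,
                np.zeros((homogeneous_phantom.n_scatterers, 55)),
                seed=0,
                params=AcquisitionParams(snr_db=-3.0),
            )

    def test_speckle_density(self, homogeneous_phantom):
        geom = homogeneous_phantom.geometry
        area = (geom.axial_max_mm - geom.axial_min_mm) * geom.lateral_span_mm
        # >= 10 scatterers per ~0.2 mm^2 resolution cell
        assert homogeneous_phantom.n_scatterers / area >= 48.0


class TestCohort:
    def test_protocol_shape(self):
        cohort = make_cohort(2, 1, seed=0)
        assert len(cohort) == 3
        assert [s.dense for s in cohort] == [True, True, False]
        # 3 compressions x 4 angles per subject
        assert all(len(s.acquisition_keys) == 12 for s in cohort)
        assert cohort[0].subject_id == "S01"

    def test_empty_cohort(self):
        assert make_cohort(0, 0, seed=0) == []

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(-1, 0, seed=0)

    def test_ground_truth_doa_distribution(self):
        # the drawn DoA matches the configured uniform law (KS, 200 subjects)
        cfg = CohortConfig()
        rng = np.random.default_rng(123)
        doas = np.array([draw_mechanics(cfg, False, rng).doa_re for _ in range(200)])
        lo, hi = cfg.doa_re_range
        assert kstest(doas, "uniform", args=(lo, hi - lo)).pvalue > 0.01

    def test_isotropic_config(self):
        cfg = CohortConfig(isotropic=True)
        rng = np.random.default_rng(5)
        m = draw_mechanics(cfg, True, rng)
        assert m.doa_re == 1.0 and m.doa_rv == 1.0

    def test_dense_group_stiffening_larger(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(9)
        dense = [draw_mechanics(cfg, True, rng).stiffening_per_mm for _ in range(50)]
        nond = [draw_mechanics(cfg, False, rng).stiffening_per_mm for _ in range(50)]
        assert np.mean(dense) > np.mean(nond)

    def test_cohort_reproducible(self):
        a = make_cohort(1, 1, seed=3)
        b = make_cohort(1, 1, seed=3)
        assert np.array_equal(a[0].phantom.scatterers, b[0].phantom.scatterers)
        assert a[1].mech == b[1].mech

    def test_acquisition_deterministic(self):
        subj = make_cohort(1, 0, seed=4)[0]
        rf1 = subj.acquisition(2, 30)
        rf2 = subj.acquisition(2, 30)
        assert np.array_equal(rf1.samples, rf2.samples)
        assert rf1.compression_mm == 2 and rf1.angle_deg == 30
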