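"""Unit and property tests for the Hertz/BEC/Ting force-curve analysis."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mechanoflim import (
    CurveRejected,
    ForceCurve,
    PLRParams,
    ProbeGeometry,
    bec_factor,
    detect_contact_point,
    fit_hertz,
    fit_viscoelastic,
    hertz_force,
    solve_t1,
    ting_force,
)
from mechanoflim.afm_mechanics import (
    IndentationHistory,
    aggregate_cell_mechanics,
    build_topography,
    select_central_region,
)
from mechanoflim.synthetic_data import (
    PLRGroundTruth,
    RampProtocol,
    simulate_plr_force_curve,
)

from oracles import (
    TriangularHistory,
    hertz_closed_form_N,
    oracle_t1,
)


# ---------------------------------------------------------------- BEC


class TestBecFactor:
    def test_semi_infinite_and_zero_depth_limits(self):
        assert bec_factor(500.0, 70.0, np.inf) == 1.0
        assert bec_factor(0.0, 70.0, 3000.0) == 1.0

    @given(
        delta=st.floats(1.0, 2000.0),
        R=st.floats(10.0, 200.0),
        h=st.floats(500.0, 50000.0),
    )
    def test_multiplier_at_least_one(self, delta, R, h):
        assert bec_factor(delta, R, h) >= 1.0

    def test_monotone_in_depth_and_thickness(self):
        delta = np.linspace(0.0, 1500.0, 50)
        f = bec_factor(delta, 70.0, 4000.0)
        assert np.all(np.diff(f) >= 0)
        for d in (200.0, 800.0, 1400.0):
            assert bec_factor(d, 70.0, 2000.0) > bec_factor(d, 70.0, 4000.0)

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clamped"):
            a = bec_factor(4000.0, 1000.0, 500.0)
        assert np.isfinite(a)


# ---------------------------------------------------------------- Hertz


class TestHertz:
    def test_closed_form_point(self):
        # spherical tip R = 100 nm, E = 1 kPa, nu = 0.5, delta = 1 um
        probe = ProbeGeometry(tip_radius_nm=100.0)
        F = hertz_force(1000.0, 1000.0, probe, bec=False)
        assert F == pytest.approx(0.562, abs=0.001)
        assert F * 1e-9 == pytest.approx(
            hertz_closed_form_N(1e-6, 1000.0, 100e-9), rel=1e-12
        )

    def test_noiseless_modulus_recovery(self, elastic_history, probe):
        res = fit_hertz(elastic_history, probe, bec=False)
        assert res.E_hertz_Pa == pytest.approx(1000.0, rel=1e-6)

    def test_thin_sample_needs_bec(self, probe, ramp):
        truth = PLRGroundTruth(E0_Pa=1000.0, thickness_nm=2000.0)
        curve = simulate_plr_force_curve(truth, probe, ramp)
        h_naive = detect_contact_point(curve)
        E_no_bec = fit_hertz(h_naive, probe, thickness_nm=np.inf, bec=False).E_hertz_Pa
        h = detect_contact_point(curve, thickness_nm=2000.0)
        E_bec = fit_hertz(h, probe, thickness_nm=2000.0).E_hertz_Pa
        assert E_no_bec > 1.15 * 1000.0  # uncorrected fit overestimates
        assert E_bec == pytest.approx(1000.0, rel=0.05)


# ---------------------------------------------------------------- contact


class TestContactDetection:
    def test_noiseless_contact_recovered_exactly(self, elastic_curve, elastic_history):
        assert elastic_history.z0_um == pytest.approx(
            elastic_curve.meta["z0_um"], abs=1e-9
        )
        assert elastic_history.delta_nm[0] == 0.0

    def test_noisy_monte_carlo_median_within_two_steps(self, probe, ramp):
        rng = np.random.default_rng(11)
        step_um = ramp.piezo_speed_um_s * ramp.dt_s
        errs = []
        for i in range(100):
            curve = simulate_plr_force_curve(
                PLRGroundTruth(E0_Pa=1500.0),
                probe,
                ramp,
                noise_sd_nN=0.05 * ramp.trigger_force_nN,
                rng=rng,
                seed=None,
            )
            hist = detect_contact_point(curve)
            errs.append(abs(hist.z0_um - curve.meta["z0_um"]))
        assert np.median(errs) < 2.0 * step_um

    def test_all_zero_force_rejected(self, probe, ramp, elastic_curve):
        flat = ForceCurve(
            t_s=elastic_curve.t_s,
            z_um=elastic_curve.z_um,
            force_nN=np.zeros_like(elastic_curve.force_nN),
            probe=probe,
            n_approach=elastic_curve.n_approach,
        )
        with pytest.raises(CurveRejected, match="no_contact"):
            detect_contact_point(flat)


# ---------------------------------------------------------------- Ting


class TestTingForward:
    def test_elastic_limit_retract_retraces_approach(self, elastic_history, probe):
        """alpha=0, eta=0: the hereditary model collapses to Hertz and the
        retract force retraces the approach at equal indentation."""
        p = PLRParams(E0_Pa=1000.0, alpha=0.0, eta_Pa_s=0.0)
        F = ting_force(elastic_history, p, probe, bec=False)
        F_hz = hertz_force(elastic_history.delta_nm, 1000.0, probe, bec=False)
        peak = F_hz.max()
        assert np.max(np.abs(F - F_hz)) < 1e-3 * peak

    def test_dashpot_strictly_increases_approach_force(self, probe, ramp):
        h = detect_contact_point(
            simulate_plr_force_curve(
                PLRGroundTruth(E0_Pa=1000.0, alpha=0.2), probe, ramp
            )
        )
        F0 = ting_force(h, PLRParams(1000.0, 0.2, 0.0), probe)
        F1 = ting_force(h, PLRParams(1000.0, 0.2, 1.0), probe)
        sl = slice(1, h.i_peak + 1)
        in_contact = h.delta_nm[sl] > 0
        assert np.all((F1[sl] - F0[sl])[in_contact] > 0)

    def test_continuity_at_phase_boundary(self, probe):
        """eta = 0: the model force is continuous at t_m (the post-peak drop
        is a resolution effect of the steep unloading slope and shrinks as
        the sampling is refined)."""
        drops = []
        for n in (128, 512):
            ramp_n = RampProtocol(samples_per_phase=n)
            h = detect_contact_point(
                simulate_plr_force_curve(
                    PLRGroundTruth(E0_Pa=1000.0, alpha=0.2), probe, ramp_n
                )
            )
            F = ting_force(h, PLRParams(1000.0, 0.2, 0.0), probe)
            i = h.i_peak
            drops.append(abs(F[i + 1] - F[i]) / F.max())
        assert drops[1] < 0.6 * drops[0]
        assert drops[1] < 0.1

    def test_force_zero_after_detachment(self, probe, ramp):
        h = detect_contact_point(
            simulate_plr_force_curve(
                PLRGroundTruth(E0_Pa=1000.0, alpha=0.3, eta_Pa_s=2.0), probe, ramp
            )
        )
        p = PLRParams(1000.0, 0.3, 2.0)
        F = ting_force(h, p, probe)
        # find detachment: t1 hits zero before the end of the retract
        tail = F[-5:]
        assert np.allclose(tail, 0.0, atol=1e-9)


class TestSolveT1:
    def test_t1_equals_t_at_phase_boundary(self, elastic_history):
        p = PLRParams(1000.0, 0.0, 0.0)
        tm = elastic_history.t_m_s
        assert solve_t1(tm, elastic_history, p) == pytest.approx(tm)

    def test_elastic_symmetric_ramp_closed_form(self, elastic_history):
        """Constant kernel, symmetric triangle: delta(t1) = delta(t) gives
        t1 = 2 t_m - t exactly."""
        p = PLRParams(1000.0, 0.0, 0.0)
        tm = elastic_history.t_m_s
        for f in (1.1, 1.3, 1.5, 1.7, 1.9):
            assert solve_t1(f * tm, elastic_history, p) == pytest.approx(
                (2.0 - f) * tm, abs=1e-12
            )

    def test_asymmetric_retract_matches_bisection_oracle(self):
        """alpha=0.3, retract twice as fast as approach: the analytic
        per-segment inversion agrees with brute-force bisection on the
        quadrature-evaluated condition to 1e-6 * t_m."""
        v, tm = 183e-6, 4e-3
        n = 200
        t_app = np.linspace(0.0, tm, n)
        t_ret = tm + np.linspace(0.0, tm / 2.0, n)[1:]
        t = np.concatenate([t_app, t_ret])
        delta = np.where(t <= tm, v * t, np.clip(v * tm - 2 * v * (t - tm), 0, None))
        hist = IndentationHistory(
            t_s=t, delta_nm=delta * 1e9, force_nN=np.zeros_like(t),
            i_peak=n - 1, z0_um=0.0, baseline_nN=0.0, contact_index=0,
        )
        tri = TriangularHistory(v_app=v, t_m=tm, v_ret=2 * v)
        p = PLRParams(1000.0, 0.3, 0.0)
        for tq in [1.05 * tm, 1.2 * tm, 1.4 * tm]:
            t1_impl = solve_t1(float(tq), hist, p)
            t1_orc = oracle_t1(float(tq), tri, 1000.0, 0.3, 0.0)
            assert abs(t1_impl - t1_orc) < 1e-6 * tm

    def test_monotone_non_increasing_and_detachment_sentinel(self, probe, ramp):
        c = simulate_plr_force_curve(
            PLRGroundTruth(E0_Pa=1000.0, alpha=0.3, eta_Pa_s=2.0), probe, ramp
        )
        h = detect_contact_point(c)
        p = PLRParams(1000.0, 0.3, 2.0)
        tm = h.t_m_s
        # query times within the active unloading ramp (monotone unloading is
        # the regime where t1 is guaranteed non-increasing)
        ts = np.linspace(1.01 * tm, 1.9 * tm, 40)
        t1s = np.array([solve_t1(float(x), h, p) for x in ts])
        assert np.all(np.diff(t1s) <= 1e-12)
        assert np.all((t1s >= 0.0) & (t1s <= tm))
        assert t1s[-1] == 0.0  # dashpot-driven early detachment sentinel

    def test_pre_peak_query_rejected(self, elastic_history):
        with pytest.raises(ValueError):
            solve_t1(0.5 * elastic_history.t_m_s, elastic_history,
                     PLRParams(1000.0, 0.0, 0.0))


# ---------------------------------------------------------------- fitting


class TestViscoelasticFit:
    def test_noiseless_round_trip(self, plr_history, probe):
        p = fit_viscoelastic(plr_history, probe)
        assert p.E0_Pa == pytest.approx(1000.0, rel=0.01)
        assert p.alpha == pytest.approx(0.2, abs=0.005)
        assert p.eta_Pa_s == pytest.approx(1.0, rel=0.02)
        assert p.converged

    def test_model_nesting_constrained_fit_equals_hertz(self, elastic_history, probe):
        hz = fit_hertz(elastic_history, probe, bec=False)
        p = fit_viscoelastic(
            elastic_history, probe, bec=False, fix_alpha=0.0, fix_eta=0.0,
            refine_contact=False,
        )
        assert p.E0_Pa == pytest.approx(hz.E_hertz_Pa, rel=0.01)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PLRParams(E0_Pa=-1.0, alpha=0.2, eta_Pa_s=0.0)
        with pytest.raises(ValueError):
            PLRParams(E0_Pa=100.0, alpha=1.5, eta_Pa_s=0.0)
        with pytest.raises(ValueError):
            PLRParams(E0_Pa=100.0, alpha=0.2, eta_Pa_s=-0.1)


# ---------------------------------------------------------------- maps


def _cap_heights(n, height_nm=5000.0, radius_px=10.0):
    yy, xx = np.mgrid[0:n, 0:n]
    r2 = (xx - n / 2) ** 2 + (yy - n / 2) ** 2
    Rs = (radius_px**2 + (height_nm / 500.0) ** 2) / (2 * height_nm / 500.0)
    h = np.sqrt(np.clip(Rs**2 - r2, 0, None)) - (Rs - height_nm / 500.0)
    return np.clip(h, 0, None) * 500.0


class TestTopography:
    def test_planted_tilt_removed(self):
        ny = nx = 24
        yy, xx = np.mgrid[0:ny, 0:nx]
        pixel = 1.5  # um
        a, b = 15.0, -8.0  # nm per um
        z0 = 5.0 + (a * xx * pixel + b * yy * pixel) * 1e-3  # flat, tilted substrate
        height, mask, tilt = build_topography(z0, pixel)
        # residual tilt of the corrected surface < 1 nm / um
        resid_slope = np.abs(np.diff(height, axis=1)).max() / pixel
        assert resid_slope < 1.0
        assert np.abs(np.median(height)) < 1.0
        assert not mask.any()  # everything is substrate

    def test_background_mask_below_200nm(self):
        z0 = np.full((16, 16), 5.0)
        z0[4:8, 4:8] -= 150e-3  # 150 nm features: below the background cut
        z0[10:13, 10:13] -= 900e-3  # 900 nm cell
        height, mask, _ = build_topography(z0, 1.0)
        assert not mask[4:8, 4:8].any()
        assert mask[10:13, 10:13].all()

    def test_no_substrate_warns_and_skips_tilt(self):
        z0 = np.linspace(1.0, 2.0, 9).reshape(3, 3)  # 3x3: < 10 substrate px
        with pytest.warns(RuntimeWarning, match="substrate"):
            build_topography(z0, 1.0, min_substrate_pixels=10)


class TestCentralRegion:
    def test_uniform_plateau_fully_retained(self):
        h = np.zeros((12, 12))
        h[3:9, 3:9] = 1000.0
        mask = h >= 200.0
        central = select_central_region(h, mask)
        assert (central == mask).all()

    def test_hemisphere_keeps_half_height_disc(self):
        h = _cap_heights(25, height_nm=5000.0, radius_px=10.0)
        mask = h >= 200.0
        central = select_central_region(h, mask)
        expect = h >= 0.5 * h.max()
        assert (central == expect).all()

    def test_two_cells_thresholded_independently(self):
        h = np.zeros((12, 30))
        h[3:9, 3:9] = 4000.0   # tall cell
        h[3:9, 20:26] = 1000.0  # short cell: would vanish under a global cut
        mask = h >= 200.0
        central = select_central_region(h, mask)
        assert central[3:9, 20:26].all()
        assert central[3:9, 3:9].all()


class TestAggregation:
    def _table(self, values, flags=None):
        import pandas as pd

        n = len(values)
        flags = flags or ["ok"] * n
        return pd.DataFrame(
            {
                "pixel_i": np.zeros(n, int),
                "pixel_j": np.arange(n),
                "E_hertz_Pa": values,
                "E0_Pa": np.nan,
                "alpha": np.nan,
                "eta_Pas": np.nan,
                "height_nm": np.ones(n) * 1000,
                "flag": flags,
            }
        )

    def test_fifty_fifty_mixture_gives_midpoint(self):
        tab = self._table([1000.0] * 20 + [3000.0] * 20)
        mask = np.ones((1, 40), bool)
        agg = aggregate_cell_mechanics(tab, mask)
        assert agg["mean_E_hertz_Pa"] == pytest.approx(2000.0)

    def test_rejected_pixels_excluded_and_counted(self):
        tab = self._table([1000.0] * 30 + [99999.0] * 5,
                          ["ok"] * 30 + ["no_contact"] * 5)
        mask = np.ones((1, 35), bool)
        agg = aggregate_cell_mechanics(tab, mask)
        assert agg["mean_E_hertz_Pa"] == pytest.approx(1000.0)
        assert agg["n_rejected"] == 5

    def test_too_few_pixels_excludes_map(self):
        tab = self._table([1000.0] * 10)
        mask = np.ones((1, 10), bool)
        with pytest.raises(ValueError, match="excluded"):
            aggregate_cell_mechanics(tab, mask, min_pixels=20)
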