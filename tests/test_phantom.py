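"""Tests of the digital cardiac phantom and flow-tube simulation."""

import dataclasses
import math

import numpy as np
import pytest

from vsperf.errors import InvalidInputError
from vsperf.phantom import (
    LABEL_LV,
    LABEL_RV,
    LABEL_SECTOR_BASE,
    N_SECTORS,
    AcquisitionProtocol,
    BolusKinetics,
    FlowWaveform,
    PhantomConfig,
    PhantomGeometry,
    aif_area,
    aif_concentration,
    aif_peak_time,
    build_label_map,
    myocardial_concentration,
    sample_velocity_field,
    sector_label,
    simulate_flow_phantom,
    simulate_series,
)


class TestLabelMap:
    def test_compartments_disjoint_and_present(self):
        labels = build_label_map(PhantomGeometry())
        assert (labels == LABEL_LV).sum() > 0
        assert (labels == LABEL_RV).sum() > 0
        for s in range(1, N_SECTORS + 1):
            assert (labels == sector_label(s)).sum() > 0
        # LV mask disjoint from myocardium by construction of label codes
        assert not np.any((labels == LABEL_LV) & (labels >= LABEL_SECTOR_BASE))

    def test_sectors_equal_area_at_fine_resolution(self):
        geom = PhantomGeometry(matrix_size=120, pixel_mm=1.0)
        labels = build_label_map(geom)
        counts = np.array([(labels == sector_label(s)).sum()
                           for s in range(1, N_SECTORS + 1)])
        assert np.all(np.abs(counts - counts.mean()) <= 0.05 * counts.mean())

    def test_zero_wall_thickness_rejected(self):
        with pytest.raises(InvalidInputError):
            PhantomGeometry(myo_inner_mm=21.0, myo_outer_mm=21.0)

    def test_geometry_must_fit_matrix(self):
        with pytest.raises(InvalidInputError):
            PhantomGeometry(myo_outer_mm=80.0)

    def test_deterministic(self):
        geom = PhantomGeometry()
        assert np.array_equal(build_label_map(geom), build_label_map(geom))


class TestVelocityField:
    def test_zero_sd_gives_piecewise_constant(self):
        flow = FlowWaveform(lv_systole=(33.4, 0.0), myocardium=(-0.82, 0.0),
                            rv=(25.0, 0.0), boundary_layer_fraction=0.0)
        labels = build_label_map(PhantomGeometry())
        v = sample_velocity_field(labels, flow, rng=0)
        assert np.allclose(v[labels == LABEL_LV], 33.4)
        assert np.allclose(v[labels >= LABEL_SECTOR_BASE], -0.82)
        assert np.allclose(v[labels == LABEL_RV], 25.0)

    def test_lv_sample_mean_matches_distribution(self):
        geom = PhantomGeometry(matrix_size=160, pixel_mm=0.7)
        flow = FlowWaveform(boundary_layer_fraction=0.0)
        labels = build_label_map(geom)
        v = sample_velocity_field(labels, flow, rng=3)
        lv = v[labels == LABEL_LV]
        se = lv.std(ddof=1) / math.sqrt(lv.size)
        assert abs(lv.mean() - 33.4) < 3 * se

    def test_myocardial_speeds_bounded_by_gaussian_quantile(self):
        labels = build_label_map(PhantomGeometry())
        v = sample_velocity_field(labels, FlowWaveform(), rng=5)
        myo = np.abs(v[labels >= LABEL_SECTOR_BASE])
        # |mean| + 2 sd ~ 11 cm/s for the default myocardial distribution
        assert np.quantile(myo, 0.95) <= 11.5

    def test_boundary_taper_slows_wall_adjacent_blood(self):
        geom = PhantomGeometry()
        flow = FlowWaveform(lv_systole=(33.4, 0.0),
                            boundary_layer_fraction=0.3)
        labels = build_label_map(geom)
        v = sample_velocity_field(labels, flow, rng=0, geometry=geom)
        lv = v[labels == LABEL_LV]
        assert lv.min() < 33.4 - 1e-9 and lv.max() == pytest.approx(33.4)


class TestKinetics:
    def test_zero_before_arrival(self):
        kin = BolusKinetics()
        t = np.linspace(0, kin.arrival_delay_s, 7)
        assert np.all(aif_concentration(t, kin) == 0.0)

    def test_peak_at_delay_plus_bc(self):
        kin = BolusKinetics()
        t = np.linspace(0, 20, 200001)
        c = aif_concentration(t, kin)
        assert t[np.argmax(c)] == pytest.approx(aif_peak_time(kin), abs=1e-3)
        assert c.max() == pytest.approx(1.0, rel=1e-9)  # peak-normalized default

    def test_area_closed_form_vs_quadrature(self):
        kin = BolusKinetics()
        t = np.linspace(0, 200, 2_000_001)
        numeric = np.trapezoid(aif_concentration(t, kin), t)
        assert numeric == pytest.approx(aif_area(kin), rel=1e-6)

    def test_zero_flow_gives_zero_uptake(self):
        kin = dataclasses.replace(BolusKinetics(), mbf_ml_g_min=(0.0,) * 6)
        t = np.linspace(0, 20, 101)
        assert np.all(myocardial_concentration(t, kin, sector=1) == 0.0)

    def test_myocardial_peak_lags_lv_peak_2_to_3_s(self):
        kin = BolusKinetics()
        t = np.arange(0, 25, 0.01)
        lv_peak = t[np.argmax(aif_concentration(t, kin))]
        myo_peak = t[np.argmax(myocardial_concentration(t, kin, sector=1))]
        assert 2.0 <= myo_peak - lv_peak <= 3.0

    def test_doubling_mbf_steepens_early_upslope(self):
        base = BolusKinetics()
        double = dataclasses.replace(base, mbf_ml_g_min=(8.0,) * 6)
        t = np.arange(0, 10, 0.02)
        c1 = myocardial_concentration(t, base, sector=1)
        c2 = myocardial_concentration(t, double, sector=1)
        assert np.max(np.gradient(c2, t)) > np.max(np.gradient(c1, t))

    def test_defect_sector_reduces_uptake(self):
        kin = BolusKinetics()
        prot = AcquisitionProtocol(defect_sector=2, defect_flow_fraction=0.3)
        t = np.arange(0, 15, 0.05)
        healthy = myocardial_concentration(t, kin, sector=1, protocol=prot)
        infarct = myocardial_concentration(t, kin, sector=2, protocol=prot)
        assert infarct.max() < healthy.max()


class TestSimulateSeries:
    def test_same_seed_bit_identical(self, default_config):
        a = simulate_series(default_config)
        b = simulate_series(default_config)
        assert np.array_equal(a.series.data, b.series.data)
        assert np.array_equal(a.velocity_map, b.velocity_map)
        assert a.truth_curves.equals(b.truth_curves)

    def test_different_seed_differs(self, default_config):
        a = simulate_series(default_config)
        b = simulate_series(default_config.with_seed(2))
        assert not np.array_equal(a.series.data, b.series.data)

    def test_conventional_uniform_concentration_scales_as_sin60(self):
        # noiseless, no blur/taper, flat bolus after arrival: tissue-free
        # blood compartments carry amplitude sin(60 deg) exactly
        cfg = PhantomConfig()
        kin = dataclasses.replace(cfg.kinetics, tau_c_s=50.0, shape_b=0.001,
                                  mbf_ml_g_min=(0.0,) * 6)
        prot = dataclasses.replace(cfg.protocol, noise_sigma=0.0, psf_fwhm_mm=0.0)
        flow = dataclasses.replace(cfg.flow, boundary_layer_fraction=0.0)
        rel = dataclasses.replace(cfg.relaxation, t1_blood_s=1e9)
        cfg = dataclasses.replace(cfg, kinetics=kin, protocol=prot, flow=flow,
                                  relaxation=rel).with_mode("conventional")
        res = simulate_series(cfg)
        n = res.series.n_frames - 1
        lv = res.series.data[n][res.labels == LABEL_LV]
        expected = (aif_concentration(res.series.frame_times_s[n], kin)
                    * cfg.relaxation.polarization * math.sin(math.radians(60))
                    * math.exp(-res.series.meta["te_ms"] / cfg.relaxation.t2star_ms))
        assert np.allclose(lv, expected, rtol=1e-9)

    def test_blood_pool_suppression_over_threefold(self, sim_results):
        conv = sim_results["conventional"]
        vs = sim_results["velocity_selective"]
        lv = conv.labels == LABEL_LV
        ratio = (conv.series.data[:, lv].mean(axis=1).max()
                 / vs.series.data[:, lv].mean(axis=1).max())
        assert ratio >= 3.0

    def test_suppression_grows_with_lv_velocity_spread(self):
        ratios = []
        for sd in (0.0, 6.2, 15.0):
            cfg = PhantomConfig()
            flow = dataclasses.replace(cfg.flow, lv_systole=(33.4, sd),
                                       boundary_layer_fraction=0.0)
            prot = dataclasses.replace(cfg.protocol, noise_sigma=0.0)
            cfg = dataclasses.replace(cfg, flow=flow, protocol=prot)
            out = {m: simulate_series(cfg.with_mode(m))
                   for m in ("conventional", "velocity_selective")}
            lv = out["conventional"].labels == LABEL_LV
            peak = {m: r.series.data[:, lv].mean(axis=1).max()
                    for m, r in out.items()}
            ratios.append(peak["conventional"] / peak["velocity_selective"])
        assert ratios[0] > ratios[1] > ratios[2]

    def test_noiseless_sector_curves_nonnegative_unimodal(self, noiseless_results):
        truth = noiseless_results["velocity_selective"].truth_curves
        lv = truth["lv"].to_numpy()
        start = int(np.nonzero(lv > 0.05 * lv.max())[0][0])  # LV bolus arrival
        for s in range(1, N_SECTORS + 1):
            y = truth[f"sector_{s}"].to_numpy()
            assert np.all(y >= -1e-15)
            y = y[start:]  # first pass; earlier frames carry RV-transit spill
            peak = int(np.argmax(y))
            assert np.all(np.diff(y[: peak + 1]) >= -1e-12)
            assert np.all(np.diff(y[peak:]) <= 1e-12)

    def test_frame_times_are_heartbeats(self, sim_results):
        series = sim_results["conventional"].series
        assert series.tr_s == pytest.approx(60.0 / 120.0)
        assert series.n_frames == 40


class TestFlowPhantom:
    def test_nominal_encoding_suppresses_flow_over_80pct(self):
        df = simulate_flow_phantom(48.0, "plug", 0.1, venc_list=(48.0,))
        assert 1.0 - df.flow_rel.iloc[0] > 0.80

    def test_static_compartment_unsuppressed_up_to_t2star(self):
        df = simulate_flow_phantom(48.0, "plug", 0.1,
                                   venc_list=(24.0, 48.0), t2star_ms=25.0)
        from vsperf.physics import te_penalty

        for _, row in df.iterrows():
            t2w = math.exp(-(te_penalty(row.venc_cm_s) - 10.2) / 25.0)
            assert row.static_rel == pytest.approx(t2w, rel=1e-9)

    def test_half_venc_recovers_most_signal(self):
        df = simulate_flow_phantom(48.0, "plug", 0.1, venc_list=(24.0, 48.0))
        half = df[df.venc_cm_s == 24.0].flow_rel.iloc[0]
        nominal = df[df.venc_cm_s == 48.0].flow_rel.iloc[0]
        assert half > 0.6 and half > 3 * nominal

    def test_parabolic_profile_less_suppressed_than_plug(self):
        plug = simulate_flow_phantom(48.0, "plug", 0.05, venc_list=(48.0,))
        para = simulate_flow_phantom(48.0, "parabolic", 0.05, venc_list=(48.0,))
        assert para.flow_rel.iloc[0] > plug.flow_rel.iloc[0]


class TestProtocolValidation:
    def test_too_few_frames_rejected(self):
        with pytest.raises(InvalidInputError):
            AcquisitionProtocol(n_frames=10)

    def test_defect_sector_range(self):
        with pytest.raises(InvalidInputError):
            AcquisitionProtocol(defect_sector=7)

    def test_myocardial_mean_velocity_capped(self):
        with pytest.raises(InvalidInputError):
            FlowWaveform(myocardium=(-9.0, 5.2))
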