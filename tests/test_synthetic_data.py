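"""Generator contracts: twitch kernel, record rendering, presets,
population statistics and the auxiliary-assay generators."""

import numpy as np
import pytest

import cardiokymo as ck
from cardiokymo.aux_assays import cell_volume, respirometry_analyze
from cardiokymo.errors import ParameterError
from cardiokymo.synthetic_data import (
    TRUTH_GRID_DT_S, CellTruth, EndpointGains, ctrl_preset, default_meta, dox_preset, generate_cross_section,
    generate_population, generate_respirometry_trace, generate_two_color_field,
    generate_zstack, simulate_cell_record, twitch_kernel,
    twitch_kernel_peak_time)


class TestTwitchKernel:
    def test_causality_and_decay(self):
        k = twitch_kernel(np.array([-1.0, -1e-9, 50.0]), 0.02, 0.10)
        assert k[0] == 0.0 and k[1] == 0.0
        assert k[2] < 1e-12

    def test_closed_form_peak_time(self):
        t = np.linspace(0, 1, 2_000_001)
        k = twitch_kernel(t, 0.02, 0.10)
        assert t[np.argmax(k)] == pytest.approx(0.02 * np.log(6), abs=1e-6)
        assert twitch_kernel_peak_time(0.02, 0.10) == \
            pytest.approx(0.02 * np.log(6), rel=1e-12)

    def test_peak_normalized(self):
        t = np.linspace(0, 2, 400_001)
        assert twitch_kernel(t, 0.02, 0.12).max() == pytest.approx(1.0, abs=1e-6)

    def test_ill_conditioned_taus_rejected(self):
        with pytest.raises(ParameterError):
            twitch_kernel(np.array([0.1]), 0.1, 0.1)
        with pytest.raises(ParameterError):
            twitch_kernel(np.array([0.1]), 0.1, 0.05)


class TestSimulatedRecord:
    def test_null_cell_is_constant(self, protocol_1hz):
        truth = CellTruth(shortening_frac=0.0, ca_amplitude=0.0)
        rec = simulate_cell_record(truth, EndpointGains(), protocol_1hz,
                                   seed=0, shot_noise=False, read_noise_sd=0.0,
                                   quantize=False)
        img = rec.kymo.image
        assert np.all(img == img[0])          # every line identical
        assert rec.contraction_truth is None
        assert rec.transient_truth is None

    def test_ground_truth_shortening_is_l0_times_frac(self, clean_record):
        # L0 = 120 um, frac = 0.08 -> 9.6 um (up to sub-0.1% twitch overlap)
        assert clean_record.contraction_truth.shortening_um == \
            pytest.approx(9.6, abs=0.05)

    def test_symmetric_edge_motion(self, clean_record):
        mask = ck.binarize(clean_record.kymo)
        trace = ck.extract_length_trace(mask, clean_record.kymo.meta,
                                        kymo=clean_record.kymo)
        center = 0.5 * (trace.left_edge_px + trace.right_edge_px)
        assert np.ptp(center) < 0.02          # pixels

    def test_determinism_under_seed(self, protocol_1hz):
        a = simulate_cell_record(CellTruth(), EndpointGains(), protocol_1hz, seed=9)
        b = simulate_cell_record(CellTruth(), EndpointGains(), protocol_1hz, seed=9)
        np.testing.assert_array_equal(a.kymo.image, b.kymo.image)

    def test_cell_must_fit_on_scan_line(self, protocol_1hz):
        meta = default_meta(protocol_1hz, n_pixels=256)   # 51.2 um scan
        with pytest.raises(ck.CardioKymoError):
            simulate_cell_record(CellTruth(), EndpointGains(), protocol_1hz,
                                 meta=meta, seed=0)


def _brute_force_truth(truth: CellTruth, meta, beats=(2, 3)):
    """Independent dense-grid recomputation of the ground-truth beat
    parameters from the closed-form traces (straightforward code, shared
    with nothing in the package)."""
    onsets = np.array(meta.stimulus_onsets)
    t = np.arange(0.0, meta.duration_s, TRUTH_GRID_DT_S)

    def kern(ts, tc, tr):
        tp = tc * np.log(1 + tr / tc)
        norm = 1.0 / ((1 - np.exp(-tp / tc)) * np.exp(-tp / tr))
        out = norm * (1 - np.exp(-ts / tc)) * np.exp(-ts / tr)
        return np.where(ts >= 0, out, 0.0)

    act = sum(kern(t - o, truth.contract_tau_s, truth.relax_tau_s) for o in onsets)
    L = truth.rest_length_um * (1 - truth.shortening_frac * act)
    vel = -np.gradient(L, t)

    def cross(y, k, thr):
        if k > 0 and (y[k - 1] - thr) * (y[k] - thr) < 0:
            return t[k - 1] + (y[k - 1] - thr) / (y[k - 1] - y[k]) * \
                (t[k] - t[k - 1])
        return t[k]

    def parab(y, k, kind):
        a, b, c = y[k - 1], y[k], y[k + 1]
        strict = (a > b and c > b) if kind == "min" else (a < b and c < b)
        den = a - 2 * b + c
        if not strict or den == 0:
            return t[k], y[k]
        d = np.clip(0.5 * (a - c) / den, -0.5, 0.5)
        return t[k] + d * TRUTH_GRID_DT_S, b - 0.25 * (a - c) * d

    rows = []
    for bi in beats:
        w0 = onsets[bi]
        w1 = onsets[bi + 1] if bi + 1 < len(onsets) else t[-1] + TRUTH_GRID_DT_S
        sel = np.flatnonzero((t >= w0) & (t < w1))
        dia = L[(t >= w0 - 0.05) & (t < w0)].mean()
        kmin = sel[np.argmin(L[sel])]
        tmin, lmin = parab(L, kmin, "min")
        short = dia - lmin
        thr = dia - 0.10 * short
        kon = sel[(L[sel] <= thr) & (sel <= kmin)][0]
        vmax = vel[sel[0]:kmin + 1].max()
        after = sel[sel > kmin]
        krec = after[L[after] >= lmin + 0.5 * short][0]
        rows.append((short, 100 * short / dia, vmax,
                     tmin - cross(L, kon, thr),
                     cross(L, krec, lmin + 0.5 * short) - tmin))
    return np.mean(rows, axis=0)


class TestGroundTruthSelfConsistency:
    def test_analytic_equals_brute_force(self, clean_record):
        """The returned ground truth must equal an independent dense-grid
        brute-force computation; max velocity is grid-limited at the onset
        kink of the kernel, so it is compared at 1e-3 relative instead of
        1e-6."""
        got = clean_record.contraction_truth
        short, pct, vmax, ttps, tthr = _brute_force_truth(
            clean_record.effective_truth, clean_record.kymo.meta)
        assert got.shortening_um == pytest.approx(short, rel=1e-6)
        assert got.shortening_pct == pytest.approx(pct, rel=1e-6)
        assert got.ttps_s == pytest.approx(ttps, rel=1e-6)
        assert got.tthr_s == pytest.approx(tthr, rel=1e-6)
        assert got.max_velocity_um_s == pytest.approx(vmax, rel=1e-3)


class TestEndpointGains:
    def test_shortening_gain_scales_truth(self, protocol_1hz):
        base = simulate_cell_record(CellTruth(), EndpointGains(), protocol_1hz,
                                    seed=0, shot_noise=False, read_noise_sd=0,
                                    quantize=False)
        up = simulate_cell_record(CellTruth(),
                                  EndpointGains(shortening=1.2, max_velocity=1.2),
                                  protocol_1hz, seed=0, shot_noise=False,
                                  read_noise_sd=0, quantize=False)
        ratio = up.contraction_truth.shortening_um / \
            base.contraction_truth.shortening_um
        assert ratio == pytest.approx(1.2, rel=1e-3)

    def test_velocity_gain_via_time_scaling(self, protocol_1hz):
        base = simulate_cell_record(CellTruth(), EndpointGains(), protocol_1hz,
                                    seed=0, shot_noise=False, read_noise_sd=0,
                                    quantize=False)
        g = EndpointGains(shortening=1.2, max_velocity=1.17)
        up = simulate_cell_record(CellTruth(), g, protocol_1hz, seed=0,
                                  shot_noise=False, read_noise_sd=0,
                                  quantize=False)
        vr = up.contraction_truth.max_velocity_um_s / \
            base.contraction_truth.max_velocity_um_s
        sr = up.contraction_truth.shortening_um / \
            base.contraction_truth.shortening_um
        assert sr == pytest.approx(1.2, rel=1e-3)
        assert vr == pytest.approx(1.17, rel=5e-3)

    def test_amplitude_gain_acts_on_peak_ratio(self, protocol_1hz):
        base = simulate_cell_record(CellTruth(), EndpointGains(), protocol_1hz,
                                    seed=0, shot_noise=False, read_noise_sd=0,
                                    quantize=False)
        g = EndpointGains(ca_amplitude=0.85, raise_rate=0.85)
        down = simulate_cell_record(CellTruth(), g, protocol_1hz, seed=0,
                                    shot_noise=False, read_noise_sd=0,
                                    quantize=False)
        ratio = down.transient_truth.amplitude / base.transient_truth.amplitude
        assert ratio == pytest.approx(0.85, rel=1e-3)
        # equal amplitude and raise-rate multipliers leave time-to-peak alone
        assert down.transient_truth.time_to_peak_s == \
            pytest.approx(base.transient_truth.time_to_peak_s, abs=2e-4)

    def test_monotonicity_in_preset_multiplier(self, protocol_1hz):
        gains = [EndpointGains(shortening=s, max_velocity=s)
                 for s in (0.8, 1.0, 1.2)]
        shorts = [simulate_cell_record(CellTruth(), g, protocol_1hz, seed=0,
                                       shot_noise=False, read_noise_sd=0,
                                       quantize=False).contraction_truth
                  .shortening_um for g in gains]
        assert shorts[0] < shorts[1] < shorts[2]


class TestPresets:
    def test_ctrl_baseline_is_identity(self):
        assert ctrl_preset().baseline.is_identity

    def test_zero_noise_gain_is_baseline(self):
        p = dox_preset()
        assert p.gains_for(1.0, 0.0) == p.baseline

    def test_printed_noise_gains(self):
        g05 = ctrl_preset().gains_for(0.5, 0.10)
        g1 = ctrl_preset().gains_for(1.0, 0.10)
        assert g05.shortening == pytest.approx(1.20)
        assert g05.max_velocity == pytest.approx(1.17)
        assert g1.shortening == pytest.approx(1.16)

    def test_dox_baseline_multipliers(self):
        b = dox_preset().baseline
        assert (b.shortening, b.max_velocity, b.ca_amplitude, b.raise_rate) == \
            (0.83, 0.88, 0.85, 0.85)

    def test_dox_rescue_gains_return_to_ctrl_baseline(self):
        total = dox_preset().gains_for(1.0, 0.20)
        assert total.shortening == pytest.approx(1.0)
        assert total.ca_amplitude == pytest.approx(1.0)
        assert total.raise_rate == pytest.approx(1.0)
        assert total.max_velocity == pytest.approx(0.88)

    def test_dox_morphometry_and_respirometry_presets(self):
        c, d = ctrl_preset(), dox_preset()
        assert d.volume_um3 == pytest.approx(0.70 * c.volume_um3)
        assert d.area_um2 == pytest.approx(0.80 * c.area_um2)
        cr, dr = dict(c.respirometry_rates), dict(d.respirometry_rates)
        assert dr["state3"] == pytest.approx(0.5 * cr["state3"])
        assert dr["uncoupled"] == pytest.approx(0.5 * cr["uncoupled"])


class TestPopulation:
    def test_population_mean_matches_preset(self):
        recs = list(generate_population(ctrl_preset(), 1.0, 0.0, base_seed=21,
                                        n_animals=2, cells_per_animal=20,
                                        shot_noise=False, read_noise_sd=0,
                                        quantize=False))
        fracs = np.array([r.cell_truth.shortening_frac for r in recs])
        se = 0.08 * np.sqrt(0.15 ** 2 / len(fracs) + 0.05 ** 2 / 2)
        assert abs(fracs.mean() - 0.08) < 3 * se

    def test_yoked_latents_across_groups_and_conditions(self):
        kw = dict(n_animals=1, cells_per_animal=3, shot_noise=False,
                  read_noise_sd=0, quantize=False)
        ctrl = list(generate_population(ctrl_preset(), 1.0, 0.0, base_seed=5, **kw))
        dox = list(generate_population(dox_preset(), 1.0, 0.0, base_seed=5, **kw))
        noisy = list(generate_population(ctrl_preset(), 1.0, 0.10, base_seed=5, **kw))
        for c, d, n in zip(ctrl, dox, noisy):
            assert c.cell_truth == d.cell_truth
            assert c.cell_truth == n.cell_truth

    def test_no_edge_leaves_scan_line(self):
        for r in generate_population(ctrl_preset(), 1.0, 0.0, base_seed=2,
                                     n_animals=1, cells_per_animal=10):
            half_px = 0.5 * r.effective_truth.rest_length_um / \
                r.kymo.meta.pixel_size_um
            c = r.effective_truth.cell_center_px
            assert c - half_px >= 0
            assert c + half_px <= r.kymo.meta.n_pixels


class TestAssayGenerators:
    def test_zstack_voxel_count_matches_target(self):
        _, true_vol = generate_zstack(30_000.0, voxel=(0.5, 0.5, 1.0), seed=3)
        count = true_vol / 0.25
        assert abs(count - 120_000) < 0.01 * 120_000     # one-shell error

    def test_noiseless_stack_roundtrip_exact(self):
        stack, true_vol = generate_zstack(8_000.0, voxel=(0.5, 0.5, 1.0),
                                          seed=0, noise_sd=0.0)
        est = cell_volume(stack, (0.5, 0.5, 1.0), method="fixed", value=55.0)
        assert est == true_vol

    def test_zstack_too_small_target(self):
        with pytest.raises(ParameterError):
            generate_zstack(0.01, voxel=(0.5, 0.5, 1.0))

    def test_cross_section_area_truth(self):
        mask, true_area = generate_cross_section(280.0, pixel_size_um=0.25,
                                                 seed=2)
        assert true_area == pytest.approx(mask.sum() * 0.25 ** 2)
        assert true_area == pytest.approx(280.0, rel=0.05)

    def test_two_color_field_fractions(self):
        labels, fr = generate_two_color_field(0.1, size=(256, 256), seed=1)
        se = np.sqrt(0.1 * 0.9 / labels.size)
        assert abs(fr["blue"] - 0.1) < 3 * se
        assert set(np.unique(labels)) <= {0, 1, 2}

    def test_respirometry_roundtrip(self):
        rates = {"basal": 8, "state3": 10, "state4": 2, "uncoupled": 45,
                 "non_mito": 2, "tmpd_asc": 50, "kcn_resistant": 10}
        clean = generate_respirometry_trace(rates, noise_sd=0.0, seed=0)
        res = respirometry_analyze(clean)
        assert res.rcr == pytest.approx(5.0)
        noisy = generate_respirometry_trace(rates, noise_sd=0.5, seed=4)
        nres = respirometry_analyze(noisy)
        for state, rate in rates.items():
            n = ((clean["event"] != "").cumsum() > 0).sum()  # samples exist
            assert nres.fluxes[state] == pytest.approx(
                rate, abs=3 * 0.5 / np.sqrt(55))   # >=55 samples per segment

    def test_unordered_events_rejected(self):
        with pytest.raises(ParameterError):
            generate_respirometry_trace(
                event_times=(("digitonin", 60.0), ("succinate", 50.0)))
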