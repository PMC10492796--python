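"""Binarization, edge extraction and contraction-parameter contracts."""

import numpy as np
import pytest

import cardiokymo as ck
from cardiokymo.errors import (DegenerateInputError, NoResponseError,
                               SegmentationError)
from cardiokymo.kymo_shortening import (binarize, contraction_params_from_length,
                                        extract_length_trace)
from cardiokymo.records import AcquisitionMeta
from cardiokymo.synthetic_data import _noiseless_traces


def _meta(n_lines, n_pixels=800, onsets=()):
    return AcquisitionMeta(line_period_s=0.002, pixel_size_um=0.2,
                           n_lines=n_lines, n_pixels=n_pixels,
                           stimulus_onsets=onsets)


class TestBinarize:
    def test_two_level_image_exact(self):
        img = np.full((50, 800), 10.0)
        img[:, 100:700] = 100.0
        mask = binarize(img)
        expected = np.zeros_like(img, dtype=bool)
        expected[:, 100:700] = True
        np.testing.assert_array_equal(mask, expected)

    def test_otsu_matches_brute_force_intraclass_variance(self):
        # 8-level toy histogram; brute-force search over inter-level
        # thresholds for the split minimizing within-class variance
        levels = np.array([5, 20, 30, 42, 60, 110, 140, 180])
        counts = np.array([500, 300, 200, 120, 80, 150, 220, 430])
        img = np.repeat(levels, counts).astype(np.uint8).reshape(40, 50)
        best, best_score = None, np.inf
        for cut in 0.5 * (levels[:-1] + levels[1:]):
            lo, hi = img[img <= cut], img[img > cut]
            score = len(lo) * lo.var() + len(hi) * hi.var()
            if score < best_score:
                best, best_score = cut, score
        mask = binarize(img, min_size=0)
        np.testing.assert_array_equal(mask, img > best)

    def test_polarity_flag_recovers_same_mask(self):
        img = np.full((50, 800), 10.0)
        img[:, 100:700] = 100.0
        inverted = 110.0 - img
        np.testing.assert_array_equal(binarize(img),
                                      binarize(inverted, polarity="dark"))

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            binarize(np.full((10, 10), 7.0))


class TestExtractLengthTrace:
    def test_constant_run_integer_mode(self):
        mask = np.zeros((100, 800), dtype=bool)
        mask[:, 100:700] = True                      # 600 px * 0.2 um = 120 um
        trace = extract_length_trace(mask, _meta(100), subpixel=False)
        np.testing.assert_allclose(trace.length_um, 120.0)

    def test_single_pixel_hole_does_not_shrink_length(self):
        mask = np.zeros((100, 800), dtype=bool)
        mask[:, 100:700] = True
        mask[:, 400] = False
        trace = extract_length_trace(mask, _meta(100), subpixel=False)
        np.testing.assert_allclose(trace.length_um, 120.0)

    def test_median_filter_suppresses_single_line_dropout(self):
        mask = np.zeros((100, 800), dtype=bool)
        mask[:, 100:700] = True
        mask[50, 100:300] = False                    # one corrupted line
        trace = extract_length_trace(mask, _meta(100), subpixel=False)
        np.testing.assert_allclose(trace.length_um, 120.0)

    def test_empty_line_raises_with_index(self):
        mask = np.zeros((100, 800), dtype=bool)
        mask[:, 100:700] = True
        mask[42, :] = False
        with pytest.raises(SegmentationError) as err:
            extract_length_trace(mask, _meta(100), subpixel=False)
        assert err.value.line_index == 42

    def test_roundtrip_against_generator_truth(self, noisy_record):
        mask = ck.binarize(noisy_record.kymo)
        trace = ck.extract_length_trace(mask, noisy_record.kymo.meta,
                                        kymo=noisy_record.kymo)
        t = noisy_record.kymo.meta.line_times_s
        true_len, _ = _noiseless_traces(
            noisy_record.effective_truth,
            np.array(noisy_record.kymo.meta.stimulus_onsets), t)
        err = np.abs(trace.length_um - true_len)
        assert err.max() <= 2 * noisy_record.kymo.meta.pixel_size_um


class TestContractionParams:
    def test_constant_trace_is_no_response(self):
        t = np.arange(0, 2.0, 0.002)
        with pytest.raises(NoResponseError):
            contraction_params_from_length(t, np.full_like(t, 120.0), [0.5],
                                           beats_to_average=(0,))

    def test_triangular_dip_closed_form(self):
        # linear fall 120 -> 110 um over 100 ms, linear recovery over 200 ms
        t = np.arange(0, 1.0, 0.002)
        L = np.full_like(t, 120.0)
        fall = (t > 0.2) & (t <= 0.3)
        L[fall] = 120.0 - 100.0 * (t[fall] - 0.2)
        rise = (t > 0.3) & (t <= 0.5)
        L[rise] = 110.0 + 50.0 * (t[rise] - 0.3)
        cp = contraction_params_from_length(t, L, [0.2], beats_to_average=(0,),
                                            smooth_window=None)
        assert cp.shortening_um == pytest.approx(10.0, abs=0.02)
        assert cp.max_velocity_um_s == pytest.approx(100.0, rel=1e-6)
        assert cp.tthr_s == pytest.approx(0.100, abs=0.002)

    def test_noiseless_record_matches_truth(self, clean_record):
        row = ck.analyze_kymograph(clean_record.kymo, smooth_window=None)
        truth = clean_record.contraction_truth
        meta = clean_record.kymo.meta
        assert abs(row["shortening_um"] - truth.shortening_um) <= meta.pixel_size_um
        assert abs(row["ttps_s"] - truth.ttps_s) <= meta.line_period_s
        assert abs(row["tthr_s"] - truth.tthr_s) <= meta.line_period_s
        assert abs(row["max_velocity_um_s"] - truth.max_velocity_um_s) <= \
            meta.pixel_size_um / meta.line_period_s

    def test_pixel_scale_equivariance(self, clean_record):
        mask = ck.binarize(clean_record.kymo)
        trace = ck.extract_length_trace(mask, clean_record.kymo.meta,
                                        kymo=clean_record.kymo)
        onsets = clean_record.kymo.meta.stimulus_onsets
        base = contraction_params_from_length(trace.t, trace.length_um, onsets)
        c = 3.0
        scaled = contraction_params_from_length(trace.t, c * trace.length_um,
                                                onsets)
        assert scaled.shortening_um == pytest.approx(c * base.shortening_um,
                                                     rel=1e-9)
        assert scaled.max_velocity_um_s == pytest.approx(
            c * base.max_velocity_um_s, rel=1e-9)
        assert scaled.shortening_pct == pytest.approx(base.shortening_pct,
                                                      rel=1e-9)
        assert scaled.ttps_s == pytest.approx(base.ttps_s, rel=1e-9)
        assert scaled.tthr_s == pytest.approx(base.tthr_s, rel=1e-9)

    def test_time_scale_equivariance(self, clean_record):
        mask = ck.binarize(clean_record.kymo)
        trace = ck.extract_length_trace(mask, clean_record.kymo.meta,
                                        kymo=clean_record.kymo)
        onsets = np.array(clean_record.kymo.meta.stimulus_onsets)
        base = contraction_params_from_length(trace.t, trace.length_um, onsets)
        c = 2.0
        # second-denominated analysis windows scale along with the time axis
        scaled = contraction_params_from_length(c * trace.t, trace.length_um,
                                                c * onsets,
                                                diastolic_window_s=c * 0.05)
        assert scaled.ttps_s == pytest.approx(c * base.ttps_s, rel=1e-9)
        assert scaled.tthr_s == pytest.approx(c * base.tthr_s, rel=1e-9)
        assert scaled.max_velocity_um_s == pytest.approx(
            base.max_velocity_um_s / c, rel=1e-9)
        assert scaled.shortening_um == pytest.approx(base.shortening_um,
                                                     rel=1e-9)

    def test_shortening_ordering_matches_truth(self, protocol_1hz):
        vals = []
        for frac in (0.05, 0.08, 0.12):
            truth = ck.CellTruth(shortening_frac=frac)
            rec = ck.simulate_cell_record(truth, ck.EndpointGains(), protocol_1hz,
                                          seed=0, shot_noise=False,
                                          read_noise_sd=0, quantize=False)
            vals.append(ck.analyze_kymograph(rec.kymo)["shortening_um"])
        assert vals[0] < vals[1] < vals[2]
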