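"""Pixel-wise fitting: closed forms, grid-search oracles, noise behavior."""

import dataclasses

import numpy as np
import pytest

import t2phantom as tp
from t2phantom.fitting import (
    fit_molli_t1,
    fit_t1_inversion_recovery,
    fit_t2_monoexponential,
    reconstruct_map,
)
from t2phantom.simulate import (
    ImageStack,
    REFERENCE_TE_MS,
    REFERENCE_TI_MS,
    add_noise,
    ir_gre_protocol,
    molli_protocol,
    simulate_inversion_recovery,
    simulate_molli,
    simulate_spin_echo,
    spin_echo_protocol,
)


def stack_from_rows(rows, t, protocol, name):
    """Wrap per-pixel sample rows (npx, nt) as a 1-row image stack."""
    rows = np.asarray(rows, dtype=float)
    frames = rows.T[:, None, :]  # (nt, 1, npx)
    return ImageStack(
        frames=frames,
        frame_parameter=np.asarray(t, dtype=float),
        parameter_name=name,
        protocol=protocol,
    )


def t2_grid_oracle(t, y, grid):
    """Independent dense grid search over T2 for S = A exp(-t/T2)."""
    best = (np.inf, np.nan)
    for t2 in grid:
        e = np.exp(-np.asarray(t) / t2)
        a = float(e @ y) / float(e @ e)
        rss = float(((y - a * e) ** 2).sum())
        if rss < best[0]:
            best = (rss, t2)
    return best[1]


class TestT2Fit:
    def test_two_point_log_ratio(self):
        st = stack_from_rows(
            [[np.exp(-0.2), np.exp(-0.4)]], [10.0, 20.0], spin_echo_protocol((10.0, 20.0)), "TE_ms"
        )
        pm = fit_t2_monoexponential(st)
        assert pm.values[0, 0] == pytest.approx(50.0, abs=1e-4)

    def test_reference_te_list_matches_dense_grid_oracle(self):
        t = np.array(REFERENCE_TE_MS, dtype=float)
        y = 0.8 * np.exp(-t / 45.0)
        st = stack_from_rows([y], t, spin_echo_protocol(), "TE_ms")
        pm = fit_t2_monoexponential(st)
        oracle = t2_grid_oracle(t, y, np.arange(1.0, 300.0, 0.001))
        assert pm.values[0, 0] == pytest.approx(45.0, abs=1e-4)
        assert pm.values[0, 0] == pytest.approx(oracle, abs=2e-3)

    def test_all_nonpositive_pixel_flagged_not_raised(self):
        st = stack_from_rows(
            [[-1.0, -0.5], [1.0, 0.5]], [10.0, 20.0], spin_echo_protocol((10.0, 20.0)), "TE_ms"
        )
        pm = fit_t2_monoexponential(st)
        assert not pm.converged[0, 0]
        assert np.isnan(pm.values[0, 0])
        assert pm.converged[0, 1]

    def test_offset_variant_recovers_baseline(self):
        t = np.array(REFERENCE_TE_MS, dtype=float)
        y = 0.7 * np.exp(-t / 50.0) + 0.05
        st = stack_from_rows([y], t, spin_echo_protocol(), "TE_ms")
        pm = fit_t2_monoexponential(st, with_offset=True)
        assert pm.values[0, 0] == pytest.approx(50.0, rel=1e-4)
        assert pm.aux["offset"][0, 0] == pytest.approx(0.05, abs=1e-5)

    def test_rician_noise_mean_bias_below_one_percent(self):
        """SNR 100 spin-echo repeats: mean fitted T2 within 1 % of truth."""
        t = np.array(REFERENCE_TE_MS, dtype=float)
        clean = np.tile(np.exp(-t / 45.0), (500, 1))
        st = stack_from_rows(clean, t, spin_echo_protocol(), "TE_ms")
        noisy = add_noise(st, 0.01, seed=11)
        pm = fit_t2_monoexponential(noisy)
        assert np.nanmean(pm.values) == pytest.approx(45.0, rel=0.01)

    def test_frame_permutation_invariance(self):
        rng = np.random.default_rng(0)
        t = np.array(REFERENCE_TE_MS, dtype=float)
        y = np.exp(-t / 60.0) + 0.01 * rng.standard_normal(t.size)
        perm = rng.permutation(t.size)
        st1 = stack_from_rows([y], t, spin_echo_protocol(), "TE_ms")
        st2 = stack_from_rows([y[perm]], t[perm], spin_echo_protocol(), "TE_ms")
        v1 = fit_t2_monoexponential(st1).values[0, 0]
        v2 = fit_t2_monoexponential(st2).values[0, 0]
        assert v1 == pytest.approx(v2, rel=1e-12)


class TestIRFit:
    def test_reference_ti_list_recovers_long_and_short_t1(self, uniform_truth):
        for t1 in (1090.0, 100.0):
            st = simulate_inversion_recovery(uniform_truth(t1, 50.0))
            pm = fit_t1_inversion_recovery(st)
            assert pm.values[0, 0] == pytest.approx(t1, rel=1e-3)

    def test_flip_index_matches_zero_crossing_enumeration(self):
        """The chosen polarity flip index equals the number of samples before
        the true zero crossing TI0 = T1 ln(B/A), by exhaustive enumeration."""
        t = np.array(REFERENCE_TI_MS, dtype=float)
        for t1, a, b in [(400.0, 1.0, 2.0), (900.0, 1.0, 1.9), (1500.0, 0.8, 1.7)]:
            y = np.abs(a - b * np.exp(-t / t1))
            st = stack_from_rows([y], t, ir_gre_protocol(), "TI_ms")
            pm = fit_t1_inversion_recovery(st)
            expected_flip = int(np.sum(t < t1 * np.log(b / a)))
            assert pm.aux["flip_index"][0, 0] == expected_flip
            assert pm.values[0, 0] == pytest.approx(t1, rel=1e-4)

    def test_signed_data_fit_without_restoration(self):
        t = np.array(REFERENCE_TI_MS, dtype=float)
        y = 1.0 - 2.0 * np.exp(-t / 700.0)
        st = stack_from_rows([y], t, ir_gre_protocol(), "TI_ms")
        pm = fit_t1_inversion_recovery(st, magnitude=False)
        assert pm.values[0, 0] == pytest.approx(700.0, rel=1e-5)


class TestMolliFit:
    def test_b_equals_2a_correction_is_neutral(self):
        t = np.linspace(100.0, 3800.0, 8)
        y = np.abs(1.0 - 2.0 * np.exp(-t / 800.0))
        st = stack_from_rows([y], t, molli_protocol(1.5), "TI_ms")
        pm = fit_molli_t1(st)
        assert pm.values[0, 0] == pytest.approx(800.0, rel=1e-5)
        assert pm.aux["t1_star"][0, 0] == pytest.approx(800.0, rel=1e-5)

    def test_saturation_like_data_flagged_t1_star_retained(self):
        # B < A: Look-Locker correction undefined
        t = np.linspace(100.0, 3800.0, 8)
        y = np.abs(1.0 - 0.5 * np.exp(-t / 800.0))
        st = stack_from_rows([y], t, molli_protocol(1.5), "TI_ms")
        pm = fit_molli_t1(st)
        assert not pm.converged[0, 0]
        assert np.isnan(pm.values[0, 0])
        assert np.isfinite(pm.aux["t1_star"][0, 0])

    def test_simulated_molli_corrected_t1_accuracy(self, uniform_truth):
        """Default 35-degree protocol: corrected T1 within 7 % of truth over
        the native-myocardium range, and the correction always inflates the
        apparent T1* towards truth."""
        for t1 in (400.0, 700.0, 1000.0, 1300.0):
            st = simulate_molli(uniform_truth(t1, 50.0), molli_protocol(1.5))
            pm = fit_molli_t1(st)
            corrected = pm.values[0, 0]
            apparent = pm.aux["t1_star"][0, 0]
            assert corrected == pytest.approx(t1, rel=0.07)
            assert corrected > apparent
            assert abs(corrected - t1) < abs(apparent - t1)


class TestReconstructMap:
    def test_dispatch_identity_for_se(self, truth_1p5t, roi_mask):
        st = simulate_spin_echo(truth_1p5t)
        direct = fit_t2_monoexponential(st, roi_mask)
        via = reconstruct_map(st, "t2_monoexp", mask=roi_mask)
        assert np.array_equal(direct.values, via.values, equal_nan=True)

    def test_background_excluded_not_fitted(self, truth_1p5t):
        st = simulate_spin_echo(truth_1p5t)
        pm = reconstruct_map(st, "t2_monoexp", truth=truth_1p5t)
        bg = truth_1p5t.label_map == 0
        assert not pm.converged[bg].any() if bg.any() else True
        assert pm.fitted_mask is not None
        assert np.array_equal(pm.fitted_mask, truth_1p5t.label_map > 0)

    def test_method_sequence_mismatch_rejected(self, truth_1p5t):
        st = simulate_spin_echo(truth_1p5t)
        with pytest.raises(ValueError, match="expects sequence"):
            reconstruct_map(st, "ir_t1")
        with pytest.raises(ValueError, match="unknown method"):
            reconstruct_map(st, "nope")

    def test_noiseless_phantom_tube_medians_exact(self, truth_1p5t, rois_1p5t):
        st = simulate_spin_echo(truth_1p5t)
        pm = reconstruct_map(st, "t2_monoexp", truth=truth_1p5t)
        for roi in rois_1p5t:
            med = np.nanmedian(pm.values[roi.mask])
            want = truth_1p5t.t2_map[roi.mask][0]
            assert med == pytest.approx(want, rel=1e-3)

    def test_rmse_nondecreasing_in_noise(self):
        """Fitted-T2 RMSE grows with the noise level (200 repeats each)."""
        t = np.array(REFERENCE_TE_MS, dtype=float)
        clean = np.tile(np.exp(-t / 45.0), (200, 1))
        st = stack_from_rows(clean, t, spin_echo_protocol(), "TE_ms")
        rmse = []
        for i, sd in enumerate((0.002, 0.01, 0.05)):
            pm = fit_t2_monoexponential(add_noise(st, sd, seed=100 + i))
            rmse.append(float(np.sqrt(np.nanmean((pm.values - 45.0) ** 2))))
        assert rmse[0] < rmse[1] < rmse[2]
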