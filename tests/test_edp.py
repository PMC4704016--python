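"""Fourier electron-density reconstruction: amplitudes, symmetry,
head-to-head distance, truncation correction and water layer."""

import numpy as np
import pytest

import lamdiff as ld
from lamdiff.edp import (
    DEFAULT_SIGNS,
    FourierAmplitudes,
    amplitudes_from_peaks,
    edp_from_series,
    measure_dpp,
    reconstruct,
    sign_scan,
    truncation_correct,
    water_layer,
)
from lamdiff.lamellar import assess_point, group_series
from lamdiff.peakfit import Peak

from conftest import random_gel_model


def series_with_areas(d_nm, areas):
    q1 = 2 * np.pi / (d_nm * 10)
    peaks = [
        Peak(q0=h * q1, area=a, fwhm=0.002, height=a / 0.002)
        for h, a in enumerate(areas, start=1)
        if a > 0
    ] + [
        Peak(q0=h * q1, area=1e-12, fwhm=0.002, height=1.0)
        for h, a in enumerate(areas, start=1)
        if a == 0
    ]
    (s,) = group_series(sorted(peaks, key=lambda p: p.q0))
    return s


def true_amplitudes(model, n_orders):
    qh = 2 * np.pi * np.arange(1, n_orders + 1) / (model.d * 10)
    f = ld.analytic_form_factor(model, qh)
    return FourierAmplitudes(
        d=model.d,
        intensities=tuple((f / np.arange(1, n_orders + 1)) ** 2),
        magnitudes=tuple(np.abs(f)),
    ), tuple(1 if v >= 0 else -1 for v in f)


class TestAmplitudes:
    def test_equal_magnitude_construction(self):
        s = series_with_areas(4.99, [100.0, 25.0, 100.0 / 9.0])
        amps = amplitudes_from_peaks(s)
        assert np.allclose(amps.magnitudes, 10.0, rtol=1e-6)

    def test_gapped_orders_rejected(self):
        from lamdiff.lamellar import LamellarSeries, OrderAssignment

        q1 = 2 * np.pi / 49.9
        gapped = LamellarSeries(
            q1=q1,
            orders=[
                OrderAssignment(1, Peak(q0=q1, area=100.0, fwhm=0.002, height=1.0), 0.0),
                OrderAssignment(3, Peak(q0=3 * q1, area=10.0, fwhm=0.002, height=1.0), 0.0),
            ],
        )
        with pytest.raises(ValueError, match="missing order"):
            amplitudes_from_peaks(gapped)

    def test_roundtrip_matches_forward_form_factor(self):
        """Amplitudes fitted from synthetic profiles reproduce
        |F(2 pi h / d)| up to one common scale.  Averaged over repeat
        exposures so Poisson noise on the weak third order drops below
        the comparison tolerance."""
        model = ld.BilayerEDPModel.gel_default()
        inst = ld.InstrumentConfig()
        mags = []
        for seed in range(12):
            profile = ld.synthesize_profile(
                [(model, ld.LamellarStackModel.gel_default())], inst, seed=seed
            )
            s = next(s for s in assess_point(profile).series if s.n_orders == 3)
            mags.append(amplitudes_from_peaks(s).magnitudes)
        mags = np.mean(mags, axis=0)
        qh = 2 * np.pi * np.arange(1, 4) / (model.d * 10)
        f_true = np.abs(ld.analytic_form_factor(model, qh))
        scale = np.sum(f_true * mags) / np.sum(mags**2)
        assert np.allclose(scale * mags, f_true, rtol=0.03)


class TestReconstruct:
    def test_single_order_is_plain_cosine(self):
        amps = FourierAmplitudes(d=5.0, intensities=(1.0,), magnitudes=(1.0,))
        prof = reconstruct(amps, signs=(1,), n_z=101)
        assert np.allclose(prof.rho, np.cos(2 * np.pi * prof.z / 5.0), atol=1e-12)

    def test_flipping_all_signs_negates_profile(self):
        amps = FourierAmplitudes(
            d=4.99, intensities=(100.0, 25.0, 9.0), magnitudes=(10.0, 10.0, 9.0)
        )
        a = reconstruct(amps, signs=(-1, -1, 1))
        b = reconstruct(amps, signs=(1, 1, -1))
        assert np.allclose(a.rho, -b.rho, atol=1e-14)

    def test_mirror_symmetry_machine_precision_all_sign_choices(self):
        import itertools

        amps = FourierAmplitudes(
            d=4.99, intensities=(1.0, 1.0, 1.0), magnitudes=(5.0, 3.0, 1.0)
        )
        for signs in itertools.product((-1, 1), repeat=3):
            prof = reconstruct(amps, signs=signs)
            assert np.array_equal(prof.rho, prof.rho[::-1])

    def test_linearity_before_normalization(self):
        amps = FourierAmplitudes(
            d=5.0, intensities=(1.0, 1.0), magnitudes=(4.0, 2.0)
        )
        scaled = FourierAmplitudes(
            d=5.0, intensities=(9.0, 9.0), magnitudes=(12.0, 6.0)
        )
        a = reconstruct(amps, signs=(-1, -1), normalize=False)
        b = reconstruct(scaled, signs=(-1, -1), normalize=False)
        assert np.allclose(b.rho, 3.0 * a.rho, rtol=1e-12)

    def test_five_order_reconstruction_locates_headgroups(self):
        # a smooth bilayer whose 5-order synthesis is nearly converged
        model = ld.BilayerEDPModel(
            (
                ld.GaussianComponent(1.67, 0.30, 1.0, 1),
                ld.GaussianComponent(-1.67, 0.30, 1.0, 1),
                ld.GaussianComponent(0.0, 0.45, 0.9, -1),
            ),
            d=4.99,
        )
        amps, signs = true_amplitudes(model, 5)
        prof = measure_dpp(reconstruct(amps, signs=signs))
        assert prof.d_pp_raw / 2 == pytest.approx(1.67, rel=0.02)

    def test_undersampled_grid_rejected(self):
        amps = FourierAmplitudes(
            d=5.0, intensities=(1.0, 1.0, 1.0), magnitudes=(1.0, 1.0, 1.0)
        )
        with pytest.raises(ValueError, match="undersamples"):
            reconstruct(amps, signs=(-1, -1, 1), n_z=8)


class TestMeasureDpp:
    def test_boundary_maximum_flagged(self):
        amps = FourierAmplitudes(d=5.0, intensities=(1.0,), magnitudes=(1.0,))
        prof = measure_dpp(reconstruct(amps, signs=(-1,)))
        assert prof.boundary_flag

    def test_truncation_pulls_dpp_inward(self):
        """3-order synthesis underestimates d_pp relative to 5 orders on
        every tested model (the systematic truncation error)."""
        rng = np.random.default_rng(31)
        for _ in range(20):
            model = random_gel_model(rng)
            a3, s3 = true_amplitudes(model, 3)
            a5, s5 = true_amplitudes(model, 5)
            d3 = measure_dpp(reconstruct(a3, signs=s3)).d_pp_raw
            d5 = measure_dpp(reconstruct(a5, signs=s5)).d_pp_raw
            assert d3 < d5


class TestCorrectionAndWater:
    def test_three_order_factor_gives_published_arithmetic(self):
        d_pp, factor = truncation_correct(3.03, 3)
        assert round(d_pp, 2) == 3.33
        assert factor == 1.10

    def test_four_orders_unchanged(self):
        assert truncation_correct(3.5, 4)[0] == 3.5

    def test_plain_arithmetic(self):
        assert truncation_correct(2.0, 3)[0] == pytest.approx(2.2)

    def test_missing_table_entry_rejected(self):
        with pytest.raises(KeyError):
            truncation_correct(3.0, 7)

    @pytest.mark.parametrize(
        "d,d_pp,expected",
        [(4.99, 3.33, 1.66), (6.40, 4.57, 1.83), (5.0, 2.5, 2.5)],
    )
    def test_water_layer_difference(self, d, d_pp, expected):
        assert water_layer(d, d_pp) == pytest.approx(expected, abs=1e-9)

    def test_inverted_thickness_rejected(self):
        with pytest.raises(ValueError):
            water_layer(4.0, 4.5)


class TestPipelineRecovery:
    def test_corrected_dpp_and_water_layer_recover_truth(self):
        """Full-chain parameter recovery on seeded synthetic gel stacks:
        the 3-order + 10%-correction route lands within 5% of the true
        head-to-head distance on average, and the water layer within
        0.15 nm."""
        rng = np.random.default_rng(2024)
        inst = ld.InstrumentConfig()
        rel_errs, dw_errs = [], []
        for _ in range(50):
            model = random_gel_model(rng)
            prof = ld.synthesize_profile(
                [(model, ld.LamellarStackModel.gel_default(d=model.d))],
                inst,
                seed=int(rng.integers(2**31)),
            )
            pp = assess_point(prof)
            s = next(s for s in pp.series if s.n_orders >= 3)
            e = edp_from_series(s)
            rel_errs.append(abs(e.d_pp / model.d_pp_true - 1.0))
            dw_errs.append(abs(e.d_w - (model.d - model.d_pp_true)))
        assert np.mean(rel_errs) < 0.05
        assert np.mean(dw_errs) < 0.15

    def test_default_signs_match_true_form_factor_signs(self):
        model = ld.BilayerEDPModel.gel_default()
        assert model.form_factor_signs(3) == DEFAULT_SIGNS[3]


class TestSignScan:
    def test_scan_enumerates_all_sign_choices(self):
        amps = FourierAmplitudes(
            d=4.99, intensities=(100.0, 20.0, 2.0), magnitudes=(10.0, 9.0, 4.0)
        )
        table = sign_scan(amps)
        assert len(table) == 8
        assert table["signs"].nunique() == 8

    def test_standard_convention_ranks_high_for_gel_like_amps(self, gel_profile):
        pp = assess_point(gel_profile)
        s = next(s for s in pp.series if s.n_orders == 3)
        table = sign_scan(amplitudes_from_peaks(s))
        assert table.iloc[0]["signs"] == "--+"
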