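"""Forward simulator: form factor, structure factor, profile synthesis,
powder-image rendering and the labelled phase grid."""

import numpy as np
import pytest

import lamdiff as ld
from lamdiff.reduction import azimuthal_integrate

from conftest import quadrature_form_factor, random_gel_model


class TestFormFactor:
    def test_zero_q_equals_total_integrated_density(self):
        m = ld.BilayerEDPModel.gel_default()
        expected = sum(
            c.sign * c.amplitude * np.sqrt(2 * np.pi) * c.sigma * 10.0
            for c in m.components
        )
        assert ld.analytic_form_factor(m, np.array([0.0]))[0] == pytest.approx(expected)

    def test_matches_quadrature_oracle_on_random_models(self):
        rng = np.random.default_rng(11)
        q = np.linspace(0.02, 0.6, 25)
        for _ in range(100):
            m = random_gel_model(rng)
            f = ld.analytic_form_factor(m, q)
            f_num = quadrature_form_factor(m, q)
            assert np.allclose(f, f_num, rtol=1e-6, atol=1e-9 * np.abs(f).max())

    def test_single_pair_matches_quadrature(self):
        m = ld.BilayerEDPModel(
            (
                ld.GaussianComponent(2.0, 0.3, 1.0, 1),
                ld.GaussianComponent(-2.0, 0.3, 1.0, 1),
            ),
            d=6.0,
        )
        q = np.array([np.pi / 2 / 10.0])  # pi/2 per nm, expressed in 1/Angstrom
        assert ld.analytic_form_factor(m, q)[0] == pytest.approx(
            quadrature_form_factor(m, q)[0], rel=1e-6
        )

    def test_mirror_negation_leaves_f_unchanged(self):
        m = ld.BilayerEDPModel.gel_default()
        flipped = ld.BilayerEDPModel(
            tuple(
                ld.GaussianComponent(-c.center, c.sigma, c.amplitude, c.sign)
                for c in m.components
            ),
            d=m.d,
        )
        q = np.linspace(0.02, 0.45, 50)
        assert np.allclose(
            ld.analytic_form_factor(m, q), ld.analytic_form_factor(flipped, q)
        )

    def test_asymmetric_model_rejected(self):
        with pytest.raises(ValueError, match="mirror-symmetric"):
            ld.BilayerEDPModel(
                (
                    ld.GaussianComponent(1.67, 0.12, 1.0, 1),
                    ld.GaussianComponent(-1.5, 0.12, 1.0, 1),
                    ld.GaussianComponent(0.0, 0.13, 1.4, -1),
                ),
                d=4.99,
            )


class TestStructureFactor:
    def test_peak_centers_at_integer_multiples(self):
        # d = 4.99 nm puts orders at 0.1259, 0.2518, 0.3777 1/Angstrom
        stack = ld.LamellarStackModel.gel_default(d=4.99)
        q = np.linspace(0.02, 0.45, 5000)
        s = ld.structure_factor(stack, q)
        from scipy.signal import find_peaks

        idx, _ = find_peaks(s, height=0.5)
        centers = q[idx]
        assert np.allclose(centers[:3], [0.1259, 0.2518, 0.3777], atol=2e-4)

    def test_flat_widths_match_per_peak_construction(self):
        stack = ld.LamellarStackModel("gel", d=5.0, w1=0.004, beta=0.0, eta=0.0)
        q = np.linspace(0.02, 0.45, 2000)
        s = ld.structure_factor(stack, q)
        sig = 0.004 / (2 * np.sqrt(2 * np.log(2)))
        q1 = 2 * np.pi / 50.0
        oracle = np.zeros_like(q)
        for h in range(1, 5):
            oracle += np.exp(-0.5 * ((q - h * q1) / sig) ** 2)
        assert np.allclose(s, oracle, atol=1e-12)

    def test_infinite_damping_kills_every_order(self):
        stack = ld.LamellarStackModel("fluid", d=7.0, w1=0.01, eta=1e6)
        q = np.linspace(0.02, 0.45, 500)
        assert np.all(ld.structure_factor(stack, q) < 1e-12)


class TestSynthesize:
    def test_background_only_profile_has_poisson_mean(self, instrument):
        import dataclasses

        inst = dataclasses.replace(instrument, background=(40.0,))
        prof = ld.synthesize_profile([], inst, seed=3)
        mean = prof.intensity.mean()
        se = np.sqrt(40.0 / prof.q.size)
        assert abs(mean - 40.0) < 3 * se

    def test_gel_profile_has_three_maxima_below_qmax(self, gel_profile):
        from lamdiff.peakfit import estimate_baseline, detect_peaks

        base = estimate_baseline(gel_profile)
        cand = detect_peaks(gel_profile, base)
        assert len(cand) == 3
        assert np.all(gel_profile.q[cand] < 0.45)

    def test_same_seed_gives_identical_bytes(self, instrument):
        pops = [
            (ld.BilayerEDPModel.gel_default(), ld.LamellarStackModel.gel_default())
        ]
        a = ld.synthesize_profile(pops, instrument, seed=42)
        b = ld.synthesize_profile(pops, instrument, seed=42)
        assert a.intensity.tobytes() == b.intensity.tobytes()
        assert a.q.tobytes() == b.q.tobytes()

    def test_overfull_volume_fractions_rejected(self, instrument):
        pops = [
            (ld.BilayerEDPModel.gel_default(), ld.LamellarStackModel.gel_default(phi=0.7)),
            (
                ld.BilayerEDPModel.fluid_default(),
                ld.LamellarStackModel.fluid_default(phi=0.7),
            ),
        ]
        with pytest.raises(ValueError, match="volume fractions"):
            ld.synthesize_profile(pops, instrument)

    def test_empty_synthesis_without_background_rejected(self):
        inst = ld.InstrumentConfig(background=(0.0,))
        with pytest.raises(ValueError, match="nothing to synthesize"):
            ld.synthesize_profile([], inst)


@pytest.mark.parametrize(
    "d", [4.5, 4.99, 5.5], ids=["d4.5", "d4.99", "d5.5"]
)
def test_gel_order_count_is_three_across_d_range(d, instrument):
    """Default gel stacks show exactly 3 orders below the 0.45 cutoff."""
    from lamdiff.peakfit import estimate_baseline, detect_peaks

    prof = ld.synthesize_profile(
        [(ld.BilayerEDPModel.gel_default(d=d), ld.LamellarStackModel.gel_default(d=d))],
        instrument,
        seed=21,
    )
    base = estimate_baseline(prof)
    assert len(detect_peaks(prof, base)) == 3


@pytest.mark.parametrize(
    "d", [6.5, 7.0, 7.5], ids=["d6.5", "d7.0", "d7.5"]
)
def test_fluid_order_count_is_two_across_d_range(d, instrument):
    """Default fluid stacks show exactly 2 orders: fluctuation damping
    suppresses everything beyond h = 2."""
    from lamdiff.peakfit import estimate_baseline, detect_peaks

    prof = ld.synthesize_profile(
        [
            (
                ld.BilayerEDPModel.fluid_default(d=d),
                ld.LamellarStackModel.fluid_default(d=d),
            )
        ],
        instrument,
        seed=22,
    )
    base = estimate_baseline(prof)
    assert len(detect_peaks(prof, base)) == 2


class TestRenderImage:
    def small_instrument(self, **kw):
        kw.setdefault("n_pixels", 64)
        kw.setdefault("beam_center", (32.0, 32.0))
        kw.setdefault("pixel_size", 4.4)
        return ld.InstrumentConfig(**kw)

    def test_delta_ring_radius_matches_geometry_inversion(self):
        g = self.small_instrument(seed=1)
        qstar = 0.25

        def lam(q):
            return 5000.0 * (np.abs(q - qstar) < 0.004)

        img = ld.render_powder_image(lam, g)
        # expected radius in px: r = D tan(2 asin(q lambda / 4 pi)) / pixel
        r_exp = (
            g.distance
            * np.tan(2 * np.arcsin(qstar * g.wavelength / (4 * np.pi)))
            / (g.pixel_size * 1e-3)
        )
        ny, nx = img.counts.shape
        y, x = np.mgrid[0:ny, 0:nx]
        r = np.hypot(x - g.beam_center[0], y - g.beam_center[1])
        lit = img.counts > 0
        assert abs(np.median(r[lit]) - r_exp) < 1.0

    def test_render_integrate_round_trip(self):
        g = self.small_instrument(n_pixels=128, beam_center=(64.0, 64.0),
                                  pixel_size=2.2, seed=5)

        def lam(q):
            return 200.0 + 3000.0 * np.exp(-0.5 * ((q - 0.2) / 0.01) ** 2)

        img = ld.render_powder_image(lam, g)
        prof = azimuthal_integrate(img, n_bins=60)
        npix = prof.bin_npix
        # expected per-bin mean from the true lambda at every pixel
        # (bin centers alone misrepresent steep peak flanks)
        qpix = img.pixel_q().ravel()
        lo, hi = qpix.min(), qpix.max()
        idx = np.minimum(((qpix - lo) / ((hi - lo) / 60)).astype(int), 59)
        expected = np.bincount(idx, weights=lam(qpix), minlength=60) / np.maximum(
            npix, 1
        )
        ok = npix > 0
        resid = prof.intensity[ok] - expected[ok]
        tol = 3.0 * np.sqrt(expected[ok] / npix[ok])
        assert np.mean(np.abs(resid) <= tol) > 0.99

    def test_flat_intensity_is_azimuthally_uniform(self):
        from scipy.stats import chi2

        g = self.small_instrument(seed=6)
        img = ld.render_powder_image(lambda q: np.full_like(q, 100.0), g)
        ny, nx = img.counts.shape
        y, x = np.mgrid[0:ny, 0:nx]
        phi = np.arctan2(y - g.beam_center[1], x - g.beam_center[0])
        r = np.hypot(x - g.beam_center[0], y - g.beam_center[1])
        ring = (r > 10) & (r < 30)
        bins = np.digitize(phi[ring], np.linspace(-np.pi, np.pi, 13)) - 1
        sums = np.bincount(bins, weights=img.counts[ring], minlength=12)
        npix = np.bincount(bins, minlength=12)
        expected = 100.0 * npix
        stat = np.sum((sums - expected) ** 2 / expected)
        assert stat < chi2.ppf(0.99, df=11)

    def test_beam_center_outside_image_rejected(self):
        g = self.small_instrument(beam_center=(500.0, 32.0))
        with pytest.raises(ValueError, match="beam center"):
            ld.render_powder_image(lambda q: np.full_like(q, 10.0), g)


class TestPhaseGrid:
    def test_rule_examples(self):
        rules = ld.PhaseRules()
        assert rules.state(0.1, 25.0)[0] == "coexistence"
        assert rules.state(0.1, 35.0)[0] == "fluid"
        assert rules.state(2.5, 35.0)[0] == "fluid"
        assert rules.state(0.0, 20.0)[0] == "gel"

    def test_coexistence_point_carries_both_repeat_distances(self):
        pts = ld.generate_phase_grid([0.1], [25.0], seed=3)
        (p,) = pts
        assert p.state == "coexistence"
        assert p.d_gel == pytest.approx(4.99, abs=0.05)
        assert p.d_fluid == pytest.approx(7.00, abs=0.01)
        assert p.waxs is not None  # gel fraction present -> chain peak recorded

    def test_contradictory_rules_rejected_at_construction(self):
        with pytest.raises(ValueError, match="contradictory"):
            ld.PhaseRules(gel_only_max_temp=35.0, fluid_onset_temp=30.0)

    def test_grid_is_deterministic_for_fixed_seed(self):
        a = ld.generate_phase_grid([0.1], [20.0, 25.0], seed=5, with_waxs=False)
        b = ld.generate_phase_grid([0.1], [20.0, 25.0], seed=5, with_waxs=False)
        for pa, pb in zip(a, b):
            assert pa.saxs.intensity.tobytes() == pb.saxs.intensity.tobytes()

    def test_ripple_region_flagged_not_invented(self):
        pts = ld.generate_phase_grid([0.0], [37.0], seed=4, with_waxs=False)
        assert pts[0].state == "gel"
        assert pts[0].ripple_flag
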