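"""Reduction chain: baseline removal, Gaussian peak fitting against known
truth, and lattice indexing with an independent grid-search oracle."""

import numpy as np
import pytest

from lamdiff import (
    AcquisitionModel,
    BilayerModel,
    Diffractogram,
    classify_phase,
    fit_peaks,
    index_lattice,
    subtract_background,
    synthesize_diffractogram,
    synthesize_nonlamellar,
)
from lamdiff.reduction import BraggPeak, PeakSet, auto_exclusion_windows, q_from_two_theta


def _gauss_scan(centers, areas, width=0.004, baseline=lambda q: 0.0 * q):
    q = np.arange(0.06, 0.51, 0.0005)
    y = baseline(q)
    for c, a in zip(centers, areas):
        y = y + a / (width * np.sqrt(2 * np.pi)) * np.exp(-((q - c) ** 2) / (2 * width**2))
    return Diffractogram(q, y, np.full_like(q, 1.0))


def _peakset(centers, se=1e-4):
    return PeakSet(
        [BraggPeak(c, se, 0.004, 1e-4, 100.0, 1.0) for c in centers]
    )


class TestBackground:
    def test_constant_baseline_recovered(self):
        d = _gauss_scan([0.125, 0.25], [50, 20], baseline=lambda q: 0 * q + 7.0)
        excl = [(0.10, 0.15), (0.22, 0.28)]
        out = subtract_background(d, "constant", excl)
        mask = (d.q < 0.10) | (d.q > 0.28)
        # residual tails of the excluded peaks set the attainable accuracy
        assert np.allclose(out.intensity[mask], 0.0, atol=1e-4)

    def test_linear_baseline_removed(self):
        d = _gauss_scan([0.125], [50], baseline=lambda q: 3.0 + 40.0 * q)
        out = subtract_background(d, "linear", [(0.10, 0.15)])
        mask = (d.q < 0.10) | (d.q > 0.15)
        assert np.allclose(out.intensity[mask], 0.0, atol=1e-4)

    def test_polynomial_background_leaves_intensities_unbiased(self):
        model, acq = BilayerModel(), AcquisitionModel(
            noise_scale=1.0, seed=5, background=(120.0, -300.0, 400.0)
        )
        with_bg = synthesize_diffractogram(model, acq)
        clean = synthesize_diffractogram(
            model, AcquisitionModel(noise_scale=1.0, seed=5, background=(0.0,))
        )
        sub = subtract_background(with_bg, "polynomial", auto_exclusion_windows(with_bg), degree=2)
        p_bg = fit_peaks(sub).sorted()
        p_clean = fit_peaks(clean).sorted()
        assert len(p_bg) == len(p_clean)
        for a, b in zip(p_bg, p_clean):
            tol = 3 * np.hypot(a.intensity_se, b.intensity_se)
            assert abs(a.integrated_intensity - b.integrated_intensity) <= tol

    def test_all_points_excluded_rejected(self):
        d = _gauss_scan([0.125], [50])
        with pytest.raises(ValueError, match="excluded"):
            subtract_background(d, "constant", [(d.q[0], d.q[-1])])


class TestFitPeaks:
    def test_single_noiseless_gaussian_exact_area(self):
        A0, w0 = 500.0, 0.004
        d = _gauss_scan([0.2], [A0 * w0 * np.sqrt(2 * np.pi)], width=w0)
        pk = fit_peaks(d, min_snr=0).peaks[0]
        assert pk.integrated_intensity == pytest.approx(A0 * w0 * np.sqrt(2 * np.pi), rel=1e-6)
        assert pk.center == pytest.approx(0.2, abs=1e-7)
        assert pk.width == pytest.approx(w0, rel=1e-5)

    def test_two_close_peaks_cofitted_within_one_percent(self):
        w = 0.004
        truth = {0.200: 40.0, 0.200 + 5 * w: 25.0}
        d = _gauss_scan(list(truth), list(truth.values()), width=w)
        ps = fit_peaks(d, min_snr=0).sorted()
        assert len(ps) == 2
        for pk, (c0, a0) in zip(ps, truth.items()):
            assert pk.center == pytest.approx(c0, abs=1e-5)
            assert pk.integrated_intensity == pytest.approx(a0, rel=0.01)

    def test_no_detectable_peak_rejected(self):
        q = np.arange(0.06, 0.51, 0.001)
        d = Diffractogram(q, np.full_like(q, 5.0), np.full_like(q, 1.0))
        with pytest.raises(ValueError, match="peak"):
            fit_peaks(d)

    def test_three_sigma_coverage_on_seeded_noise(self):
        """Fitted-intensity 3-SE intervals cover the truth >= 95% of the time."""
        model = BilayerModel()
        from lamdiff import model_form_factors

        f = model_form_factors(model, 4)
        truth = {
            n: 1e12 * f[n - 1] ** 2 / (2 * np.pi * n / model.D)
            for n in range(1, 5)
        }
        n_rep, covered, total = 200, 0, 0
        for seed in range(n_rep):
            acq = AcquisitionModel(noise_scale=1.0, seed=seed, background=(0.0,))
            d = synthesize_diffractogram(model, acq)
            for pk in fit_peaks(d):
                n = int(round(pk.center / (2 * np.pi / model.D)))
                if n in truth:
                    total += 1
                    if abs(pk.integrated_intensity - truth[n]) <= 3 * pk.intensity_se:
                        covered += 1
        assert total >= 0.95 * 4 * n_rep
        assert covered / total >= 0.95


class TestIndexing:
    def test_exact_lamellar_series(self):
        ps = _peakset([2 * np.pi * n / 50.0 for n in range(1, 5)])
        asg = index_lattice(ps)
        assert asg.phase_class == "lamellar"
        assert asg.lattices[0].D == pytest.approx(50.0, rel=1e-9)
        assert [asg.assignment[i][1] for i in range(4)] == [1, 2, 3, 4]

    def test_single_peak_low_confidence(self):
        asg = index_lattice(_peakset([0.1247]))
        assert asg.phase_class == "lamellar"
        assert asg.low_confidence
        assert asg.lattices[0].D == pytest.approx(2 * np.pi / 0.1247, rel=1e-9)

    def test_missing_low_orders_still_indexed(self):
        # orders 2..4 only (first order below the q window)
        ps = _peakset([2 * np.pi * n / 44.0 for n in (2, 3, 4)])
        asg = index_lattice(ps)
        assert asg.phase_class == "lamellar"
        assert asg.lattices[0].D == pytest.approx(44.0, rel=1e-6)

    def test_least_squares_matches_grid_search_oracle(self, rng):
        """WLS slope through the origin vs brute-force search over D."""
        for _ in range(10):
            D_true = rng.uniform(35, 75)
            centers = [2 * np.pi * n / D_true for n in range(1, 5)]
            asg = index_lattice(_peakset(centers))
            grid = np.linspace(30, 80, 200_001)
            cost = [
                sum((c - 2 * np.pi * round(c * Dg / (2 * np.pi)) / Dg) ** 2 for c in centers)
                for Dg in grid
            ]
            D_grid = grid[int(np.argmin(cost))]
            assert asg.lattices[0].D == pytest.approx(D_grid, rel=1e-4)
            assert asg.lattices[0].D == pytest.approx(D_true, rel=1e-9)

    def test_coexisting_lamellar_lattices_recovered(self):
        D1, D2 = 45.2, 48.6
        centers = sorted(
            [2 * np.pi * n / D1 for n in range(1, 4)] + [2 * np.pi * n / D2 for n in range(1, 4)]
        )
        asg = index_lattice(_peakset(centers))
        assert asg.phase_class == "coexisting_lamellar"
        got = sorted(lat.D for lat in asg.lattices)
        assert got[0] == pytest.approx(D1, rel=0.005)
        assert got[1] == pytest.approx(D2, rel=0.005)

    def test_unindexable_peaks_flagged(self):
        asg = index_lattice(_peakset([0.10, 0.137, 0.261, 0.349]))
        assert asg.phase_class == "unindexed"


class TestClassify:
    def test_integer_ratio_series_is_lamellar(self):
        cls, why = classify_phase(index_lattice(_peakset([0.1, 0.2, 0.3, 0.4])))
        assert cls == "lamellar"
        assert "q_n" in why

    def test_sqrt3_ratio_series_is_hexagonal(self):
        q1 = 0.15
        cls, why = classify_phase(
            index_lattice(_peakset([q1, q1 * 1.732, q1 * 2.0, q1 * 2.646]))
        )
        assert cls == "hexagonal"

    def test_generated_hexagonal_scan_round_trip(self, noiseless_acq):
        d = synthesize_nonlamellar(0.15, noiseless_acq)
        cls, _ = classify_phase(index_lattice(fit_peaks(d, min_snr=0)))
        assert cls == "hexagonal"

    @pytest.mark.parametrize("scale", [0.5, 1.0, 2.3])
    def test_classification_invariant_under_q_rescaling(self, scale):
        base = [0.12, 0.12 * np.sqrt(3), 0.24]
        asg = index_lattice(_peakset([scale * c for c in base]))
        assert asg.phase_class == "hexagonal"
        ref = index_lattice(_peakset(base))
        assert asg.lattices[0].D * scale == pytest.approx(ref.lattices[0].D, rel=1e-6)


def test_two_theta_conversion():
    # q = 2 pi sin(2 theta) / lambda at the instrument wavelength
    assert q_from_two_theta(5.2, 4.55) == pytest.approx(
        2 * np.pi * np.sin(np.deg2rad(5.2)) / 4.55
    )
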