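"""Lorentz correction and contrast-variation phase determination, checked
against the generator's analytic signed form factors."""

import numpy as np
import pandas as pd
import pytest

from lamdiff import (
    AcquisitionModel,
    BilayerModel,
    assign_phases,
    fit_peaks,
    index_lattice,
    lorentz_correct,
    model_form_factors,
    synthesize_contrast_series,
)
from lamdiff.phasing import StructureFactorTable, _water_transform
from lamdiff.reduction import BraggPeak, PeakSet
from lamdiff.synthetic import random_model

FRACTIONS = [0.08, 0.2, 0.5, 1.0]


def analytic_sf_table(model: BilayerModel, orders: int = 4, fractions=FRACTIONS, se=1e-8):
    """Noiseless structure-factor table from the closed-form form factors."""
    rows = []
    for x in fractions:
        f = model_form_factors(model.with_contrast(x), orders)
        for n in range(1, orders + 1):
            rows.append(
                {"order": n, "x_D2O": x, "amplitude": abs(f[n - 1]), "amplitude_se": se, "flagged": False}
            )
    return StructureFactorTable(pd.DataFrame(rows), lorentz_exponent=1.0, D=model.D)


def _indexed_peakset(D, intensities, ses=None):
    peaks = []
    for n, inten in enumerate(intensities, start=1):
        se = 1.0 if ses is None else ses[n - 1]
        pk = BraggPeak(2 * np.pi * n / D, 1e-5, 0.004, 1e-5, inten, se)
        pk.order, pk.lattice_id = n, 0
        peaks.append(pk)
    return PeakSet(peaks)


class TestLorentzCorrect:
    def _assignment(self, D=50.0):
        ps = _indexed_peakset(D, [4.0])
        return index_lattice(ps)

    def test_amplitude_is_sqrt_of_q_weighted_intensity(self):
        D = 2 * np.pi  # q_1 = 1
        asg = index_lattice(_indexed_peakset(D, [4.0]))
        sf = lorentz_correct({0.08: _indexed_peakset(D, [4.0])}, asg, p=1.0)
        assert sf.table["amplitude"].iloc[0] == pytest.approx(2.0, rel=1e-9)

    def test_zero_exponent_disables_correction(self):
        D = 4 * 2 * np.pi  # q_1 = 0.25
        asg = index_lattice(_indexed_peakset(D, [4.0]))
        sf = lorentz_correct({0.08: _indexed_peakset(D, [4.0])}, asg, p=0.0)
        assert sf.table["amplitude"].iloc[0] == pytest.approx(2.0, rel=1e-9)

    def test_negative_intensity_zeroed_and_flagged(self):
        D = 50.0
        asg = index_lattice(_indexed_peakset(D, [10.0, -3.0]))
        sf = lorentz_correct({0.08: _indexed_peakset(D, [10.0, -3.0])}, asg)
        row = sf.table[sf.table["order"] == 2].iloc[0]
        assert row["amplitude"] == 0.0
        assert bool(row["flagged"])

    def test_round_trip_recovers_analytic_amplitudes(self, default_model):
        """Generator applies q^-1; correction with p=1 must undo it."""
        acq = AcquisitionModel(noise_scale=1.0, seed=3)
        series = synthesize_contrast_series(default_model, FRACTIONS, acq)
        peaks_by_x, asg = {}, None
        for d in series:
            ps = fit_peaks(d)
            peaks_by_x[d.meta["x_D2O"]] = ps
            if d.meta["x_D2O"] == 0.08:
                asg = index_lattice(ps)
        sf = lorentz_correct(peaks_by_x, asg, p=1.0)
        scale = np.sqrt(acq.intensity_scale)
        for x in FRACTIONS:
            f_true = np.abs(model_form_factors(default_model.with_contrast(x), 4))
            sub = sf.amplitudes_at(x)
            for _, row in sub.iterrows():
                truth = scale * f_true[int(row["order"]) - 1]
                assert abs(row["amplitude"] - truth) <= max(3 * row["amplitude_se"], 1e-3 * truth)


class TestAssignPhases:
    def test_all_positive_affine_truth(self):
        """Signed f_n positive at every contrast, slopes following the
        water transform: every nu comes out +1 with perfect linearity."""
        D = 50.0
        n = np.arange(1, 5)
        w = _water_transform(13.0, 2.5, 2 * np.pi * n / D, n.astype(float))
        rows = []
        for x in FRACTIONS:
            vals = 10.0 * np.abs(w) + w * x  # positive everywhere
            assert np.all(vals > 0)
            for i in range(4):
                rows.append(
                    {"order": i + 1, "x_D2O": x, "amplitude": vals[i], "amplitude_se": 1e-6}
                )
        sf = StructureFactorTable(pd.DataFrame(rows), lorentz_exponent=1.0, D=D)
        ph = assign_phases(sf)
        assert all(v == 1 for v in ph.nu.values())
        assert all(f["r2"] == pytest.approx(1.0, abs=1e-9) for f in ph.fits.values())

    def test_default_pc_like_series_gives_minus_minus_plus_minus(self, default_model):
        ph = assign_phases(analytic_sf_table(default_model))
        assert [ph.nu[n] for n in (1, 2, 3, 4)] == [-1, -1, 1, -1]
        assert ph.water_slab["width"] == pytest.approx(
            default_model.D - default_model.D_B_true, rel=0.01
        )

    def test_randomized_models_recover_analytic_signs(self):
        rng = np.random.default_rng(99)
        n_models, n_ok = 60, 0
        for _ in range(n_models):
            m = random_model(rng)
            ph = assign_phases(analytic_sf_table(m))
            truth = np.sign(model_form_factors(m, 4))
            if all(ph.nu[n] == truth[n - 1] for n in (1, 2, 3, 4)):
                n_ok += 1
        assert n_ok / n_models >= 0.95

    def test_invariant_under_uniform_amplitude_rescaling(self, default_model):
        sf1 = analytic_sf_table(default_model)
        sf2 = StructureFactorTable(
            sf1.table.assign(
                amplitude=sf1.table["amplitude"] * 137.0,
                amplitude_se=sf1.table["amplitude_se"] * 137.0,
            ),
            lorentz_exponent=1.0,
            D=default_model.D,
        )
        assert assign_phases(sf1).nu == assign_phases(sf2).nu

    def test_single_contrast_rejected(self, default_model):
        sf = analytic_sf_table(default_model, fractions=[0.08])
        with pytest.raises(ValueError, match="one contrast"):
            assign_phases(sf)

    def test_ambiguity_flagged_for_contrast_independent_order(self):
        # amplitudes identical across contrasts: every pattern fits equally
        rows = [
            {"order": 1, "x_D2O": x, "amplitude": 5.0, "amplitude_se": 1e-6}
            for x in FRACTIONS
        ]
        sf = StructureFactorTable(pd.DataFrame(rows), lorentz_exponent=1.0, D=50.0)
        ph = assign_phases(sf)
        assert ph.ambiguous[1]


class TestTableInvariants:
    def test_duplicate_order_fraction_rejected(self):
        rows = [
            {"order": 1, "x_D2O": 0.08, "amplitude": 1.0, "amplitude_se": 0.1},
            {"order": 1, "x_D2O": 0.08, "amplitude": 2.0, "amplitude_se": 0.1},
        ]
        with pytest.raises(ValueError, match="duplicate"):
            StructureFactorTable(pd.DataFrame(rows), lorentz_exponent=1.0, D=50.0)

    def test_negative_amplitude_rejected(self):
        rows = [{"order": 1, "x_D2O": 0.08, "amplitude": -1.0, "amplitude_se": 0.1}]
        with pytest.raises(ValueError, match="non-negative"):
            StructureFactorTable(pd.DataFrame(rows), lorentz_exponent=1.0, D=50.0)

    def test_lorentz_requires_lamellar_assignment(self):
        from lamdiff.reduction import LatticeAssignment

        asg = LatticeAssignment("hexagonal", [], {}, {})
        with pytest.raises(ValueError, match="lamellar"):
            lorentz_correct({0.08: PeakSet([])}, asg)
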