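"""Exact-mass arithmetic, peak alignment, signal filters, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from starchlink.metabolomics import (
    PeakList,
    align_peaks,
    amp_adduct_mz,
    annotation_summary,
    deprotonated_mz,
    filter_mass_defect,
    filter_occurrence,
    filter_snr,
    fit_calibration,
    monoisotopic_mass,
    quantify,
    read_peaklist,
    write_peaklist,
)
from starchlink.tables import TableError

from conftest import make_table


class TestMonoisotopicMass:
    def test_water(self):
        assert monoisotopic_mass("H2O") == pytest.approx(18.010565, abs=5e-7)

    def test_butyric_acid(self):
        assert monoisotopic_mass("C4H8O2") == pytest.approx(88.052429, abs=5e-7)

    def test_empty_formula_rejected(self):
        with pytest.raises(TableError, match="empty"):
            monoisotopic_mass("")

    def test_unsupported_element_named(self):
        with pytest.raises(TableError, match="Se"):
            monoisotopic_mass("C2H6Se")

    def test_agrees_with_independent_mass_table(self):
        """Cross-check against a second atomic-mass source (pyteomics)."""
        pyteomics_mass = pytest.importorskip("pyteomics.mass")
        for formula in ("C4H8O2", "C12H24O2", "C12H13N2", "C6H12O6S", "H3PO4"):
            independent = pyteomics_mass.calculate_mass(formula=formula)
            assert monoisotopic_mass(formula) == pytest.approx(
                independent, abs=1e-4
            )

    @given(st.integers(1, 30), st.integers(1, 60), st.integers(0, 10))
    @settings(max_examples=25, deadline=None)
    def test_mass_is_additive_in_atom_counts(self, c, h, o):
        formula = {"C": c, "H": h}
        if o:
            formula["O"] = o
        total = monoisotopic_mass(formula)
        parts = c * monoisotopic_mass("C") + h * monoisotopic_mass("H")
        if o:
            parts += o * monoisotopic_mass("O")
        assert total == pytest.approx(parts, abs=1e-9)


class TestIonArithmetic:
    def test_deprotonated_lauric_acid(self):
        assert round(deprotonated_mz("C12H24O2"), 5) == 199.17035

    def test_deprotonated_capric_acid_within_assignment_error(self):
        mz = deprotonated_mz("C10H20O2")
        assert round(mz, 5) == 171.13905
        assert abs(mz - 171.13906) / 171.13906 * 1e6 < 0.2  # ppm

    def test_deprotonation_inverse(self):
        assert deprotonated_mz("C4H8O2") + 1.007276 == pytest.approx(
            monoisotopic_mass("C4H8O2"), abs=1e-12
        )

    def test_no_hydrogen_rejected(self):
        with pytest.raises(TableError, match="hydrogen"):
            deprotonated_mz("CO2")

    @pytest.mark.parametrize(
        "formula, expected",
        [("C3H6O2", 241.1341), ("C4H8O2", 255.1497), ("C5H10O2", 269.1654)],
        ids=["propionic", "butyric", "valeric"],
    )
    def test_amp_derivatized_scfa(self, formula, expected):
        assert round(amp_adduct_mz(formula), 4) == expected


class TestSnrFilter:
    def test_threshold_inclusive(self):
        pl = PeakList("s", [(100.0, 1.0, 3.9), (101.0, 1.0, 4.0),
                            (102.0, 1.0, 10.0)])
        assert len(filter_snr(pl, 4.0)) == 2

    def test_zero_threshold_identity(self):
        pl = PeakList("s", [(100.0, 1.0, 0.5), (101.0, 2.0, 9.0)])
        assert len(filter_snr(pl, 0.0)) == 2

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        peaks = [(100 + i, float(rng.random()), float(rng.random() * 10))
                 for i in range(50)]
        pl = PeakList("s", peaks)
        kept = filter_snr(pl, 4.0)
        assert len(kept) == sum(1 for p in peaks if p[2] >= 4.0)

    def test_missing_snr_instructs_to_skip(self):
        pl = PeakList("s", [(100.0, 1.0)])
        with pytest.raises(TableError, match="skip"):
            filter_snr(pl)


class TestAlignment:
    def test_within_tolerance_merges(self):
        lists = [PeakList("a", [(200.00000, 5.0)]),
                 PeakList("b", [(200.00010, 7.0)])]  # 0.5 ppm apart
        aligned = align_peaks(lists, ppm_tol=1.0)
        assert aligned.n_features == 1

    def test_outside_tolerance_splits(self):
        lists = [PeakList("a", [(200.0000, 5.0)]),
                 PeakList("b", [(200.0004, 7.0)])]  # 2 ppm apart
        aligned = align_peaks(lists, ppm_tol=1.0)
        assert aligned.n_features == 2

    def test_order_independent(self):
        rng = np.random.default_rng(1)
        base = 150 * (1 + 20e-6) ** np.arange(30)
        lists = []
        for sid in ("s1", "s2", "s3"):
            jitter = base * (1 + rng.uniform(-0.3, 0.3, base.size) * 1e-6)
            lists.append(PeakList(sid, [(m, float(rng.random()) + 0.1)
                                        for m in jitter]))
        forward = align_peaks(lists, 1.0)
        backward = align_peaks(list(reversed(lists)), 1.0)
        assert forward.feature_ids == backward.feature_ids
        assert forward.data.loc[forward.sample_ids].equals(
            backward.data.loc[forward.sample_ids]
        )

    def test_members_within_tolerance_of_consensus(self):
        rng = np.random.default_rng(2)
        base = 300 * (1 + 15e-6) ** np.arange(40)
        lists = []
        for sid in range(5):
            jitter = base * (1 + rng.uniform(-0.4, 0.4, base.size) * 1e-6)
            lists.append(PeakList(f"s{sid}", [(m, 1.0) for m in jitter]))
        aligned = align_peaks(lists, 1.0)
        for fid in aligned.feature_ids:
            consensus = float(fid)
            col = aligned.data[fid].dropna()
            assert len(col) >= 1

    def test_peaklist_io_round_trip(self, tmp_path):
        pl = PeakList("s1", [(100.123456, 5000.0, 12.0), (250.5, 1.0, 4.0)])
        path = tmp_path / "s1.txt"
        write_peaklist(pl, path)
        back = read_peaklist(path)
        assert back.sample_id == "s1"
        assert np.allclose(np.array(back.peaks), np.array(pl.peaks))


class TestMatrixFilters:
    def _matrix(self):
        rng = np.random.default_rng(3)
        matrix = rng.random((45, 8)) * 1e6
        mask = rng.random((45, 8)) < 0.5
        matrix[mask] = np.nan
        mzs = ["171.13905", "722.85000", "200.00010", "350.12345",
               "400.90000", "150.00001", "555.79999", "610.81234"]
        table = make_table(np.nan_to_num(matrix), layer="metabolite",
                           feature_ids=mzs)
        table.data[table.data == 0.0] = np.nan
        table = table.replace(table.data.mask(np.isnan(matrix)))
        return table

    def test_occurrence_boundary(self):
        matrix = np.full((45, 2), np.nan)
        matrix[:4, 0] = 1.0  # present 4 of 45 -> removed
        matrix[:5, 1] = 1.0  # present 5 -> kept
        table = make_table(np.nan_to_num(matrix), layer="metabolite",
                           feature_ids=["100.1", "100.2"])
        table = table.replace(table.data.mask(np.isnan(matrix)))
        kept = filter_occurrence(table, 5)
        assert kept.feature_ids == ["100.2"]

    def test_occurrence_matches_brute_force(self):
        table = self._matrix()
        kept = filter_occurrence(table, 5)
        expected = [f for f in table.feature_ids
                    if table.data[f].notna().sum() >= 5]
        assert kept.feature_ids == expected

    def test_mass_defect_removes_above_point_eight(self):
        table = make_table([[1.0, 2.0]], layer="metabolite",
                           feature_ids=["722.85000", "171.13905"])
        kept = filter_mass_defect(table, 0.8)
        assert kept.feature_ids == ["171.13905"]

    def test_filters_commute(self):
        table = self._matrix()
        a = filter_mass_defect(filter_occurrence(table, 5), 0.8)
        b = filter_occurrence(filter_mass_defect(table, 0.8), 5)
        assert a.feature_ids == b.feature_ids
        assert a.data.equals(b.data)


class TestCalibration:
    def test_exact_line(self):
        points = [(x, 2.0 * x + 1.0) for x in range(1, 9)]
        curve = fit_calibration(points)
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(1.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_noisy_line_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        x = np.linspace(1, 8, 8)
        y = 3.5 * x + 7 + rng.normal(0, 0.5, 8)
        curve = fit_calibration(list(zip(x, y)))
        # closed-form OLS oracle
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        assert curve.slope == pytest.approx(slope, abs=1e-10)
        assert curve.intercept == pytest.approx(intercept, abs=1e-10)

    def test_single_concentration_rejected(self):
        with pytest.raises(TableError, match="distinct"):
            fit_calibration([(1.0, 2.0), (1.0, 3.0)])

    def test_published_butyric_curve_inversion(self):
        from starchlink.metabolomics import CalibrationCurve

        curve = CalibrationCurve("butyric acid", 59_940.0, 16_956.0, 0.9981)
        assert quantify(curve, 616_356.0) == pytest.approx(10.0)
        assert quantify(curve, curve.intercept) == 0.0

    @given(st.floats(0.1, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_quantify_inverts_fit_on_exact_line(self, x0):
        points = [(float(x), 59_940.0 * x + 16_956.0) for x in range(1, 9)]
        curve = fit_calibration(points)
        response = 59_940.0 * x0 + 16_956.0
        assert quantify(curve, response) == pytest.approx(x0, rel=1e-9)


class TestAnnotationSummary:
    def test_published_unknown_fraction(self):
        n = 5552
        table = make_table(np.ones((1, n)), layer="metabolite",
                           feature_ids=[f"m{i}" for i in range(n)])
        categories = {}
        for i in range(n):
            categories[f"m{i}"] = "formula_only" if i < 3416 else "compound"
        report = annotation_summary(table, categories)
        assert report["formula_only"]["count"] == 3416
        assert report["formula_only"]["percent"] == 62
        assert report["compound"]["count"] == 2136
        assert report["compound"]["percent"] == 38

    def test_single_category_is_hundred_percent(self):
        table = make_table(np.ones((1, 3)), layer="metabolite")
        report = annotation_summary(table, {f: "none" for f in table.feature_ids})
        assert report["none"]["percent"] == 100
        assert report["compound"]["count"] == 0
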