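"""Dose tables and quintic mapping functions."""

import numpy as np
import pytest

from cylbrachy import (
    CylinderApplicator, DoseTable, InsufficientDataError, MappingPolynomial,
    MappingRangeError, PlannerContext, SourceSpec, build_dose_table,
    consistency_report, evaluate_mapping, fit_mapping,
    load_reference_polynomials, load_reference_tables, reference_mapping,
    round_to_10,
)

DIAMETERS = (2.5, 3.0, 3.5)
DIRECTIONS = ("to_surface", "to_5mm")


@pytest.fixture(scope="module")
def tables():
    return load_reference_tables()


@pytest.fixture(scope="module")
def polys():
    return load_reference_polynomials()


class TestReferenceData:
    def test_three_nine_row_tables(self, tables):
        assert set(tables) == set(DIAMETERS)
        for t in tables.values():
            assert t.rows.shape == (9, 2)

    def test_table_invariants_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            DoseTable(3.0, [[300, 500], [300, 600]])
        with pytest.raises(ValueError, match="surface dose must exceed"):
            DoseTable(3.0, [[300, 290], [400, 500]])

    @pytest.mark.parametrize("diameter", DIAMETERS)
    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_polynomials_reproduce_their_table(self, tables, polys, diameter, direction):
        """The published coefficients (doses in Gy) track the published table;
        the worst row across all six functions deviates 2.25%, every other
        row is within 1.6% — this is what pins the polynomial unit to Gy."""
        rep = consistency_report(tables[diameter], polys[(diameter, direction)])
        assert rep["residual_pct"].abs().max() < 2.25

    def test_nearest_10_rounding_recovers_tabulated_prescriptions(self, polys):
        cases = [
            (2.5, "to_surface", 300.0, 500.0),
            (2.5, "to_surface", 430.0, 700.0),
            (2.5, "to_surface", 850.0, 1350.0),
            (2.5, "to_5mm", 500.0, 300.0),
            (3.0, "to_surface", 700.0, 1050.0),
            (3.0, "to_5mm", 500.0, 340.0),
            (3.5, "to_surface", 850.0, 1250.0),
            (3.5, "to_5mm", 500.0, 360.0),
        ]
        for diam, direction, dose, expected in cases:
            raw = evaluate_mapping(polys[(diam, direction)], dose)
            assert round_to_10(raw) == expected, (diam, direction, dose)


class TestMappingProperties:
    @pytest.mark.parametrize("diameter", DIAMETERS)
    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_strictly_increasing_on_domain(self, polys, diameter, direction):
        assert polys[(diameter, direction)].is_monotone()

    @pytest.mark.parametrize("diameter", DIAMETERS)
    def test_surface_exceeds_depth_dose(self, polys, diameter):
        fwd = polys[(diameter, "to_surface")]
        bwd = polys[(diameter, "to_5mm")]
        x = np.linspace(*fwd.valid_domain, 200)
        assert np.all(fwd.evaluate_gy(x) > x)
        x = np.linspace(*bwd.valid_domain, 200)
        assert np.all(bwd.evaluate_gy(x) < x)

    @pytest.mark.parametrize("diameter", DIAMETERS)
    def test_round_trip_within_2pct(self, tables, polys, diameter):
        """Forward then backward mapping returns the starting dose within 2%
        (composed in Gy: the top row's intermediate surface dose can land a
        hair beyond the fitted range, where the guarded call would refuse)."""
        fwd = polys[(diameter, "to_surface")]
        bwd = polys[(diameter, "to_5mm")]
        for d5 in tables[diameter].dose_5mm / 100.0:
            back = bwd.evaluate_gy(fwd.evaluate_gy(d5))
            assert back == pytest.approx(d5, rel=0.02)

    def test_out_of_domain_rejected(self, polys):
        poly = polys[(2.5, "to_surface")]
        with pytest.raises(MappingRangeError, match="interpolation"):
            poly(200.0)
        with pytest.raises(MappingRangeError):
            poly(900.0)

    def test_rounding_helper(self):
        assert round_to_10(1351.8) == 1350.0
        assert round_to_10(296.0) == 300.0


class TestFitMapping:
    @pytest.mark.parametrize("diameter", DIAMETERS)
    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_refit_reproduces_table(self, tables, diameter, direction):
        """A fresh least-squares quintic tracks each published table closely.

        The 2.5 and 3.5 cm tables refit to within 0.5% and 1.3%; the 3.0 cm
        table carries one outlying row (500 cGy <-> 730 cGy, which both the
        published quintic and any fresh refit place near 745 cGy) that leaves
        a 1.62% residual, so the honest bound across all tables is 1.65%.
        """
        table = tables[diameter]
        poly = fit_mapping(table, direction)
        pred = poly.evaluate_gy(table.source_column(direction) / 100.0) * 100.0
        rel = np.abs(pred - table.target_column(direction)) / table.target_column(direction)
        assert rel.max() < 0.0165
        if diameter == 2.5:
            assert rel.max() < 0.005

    def test_refit_at_550_matches_880(self, tables):
        poly = fit_mapping(tables[2.5], "to_surface")
        assert poly(550.0) == pytest.approx(880.0, rel=0.015)

    def test_exact_quintic_data_recovered(self):
        coeffs = (0.001, -0.02, 0.3, -1.0, 3.0, 1.0)
        x = np.linspace(3.0, 9.0, 9)
        y = np.polyval(coeffs, x)
        table = DoseTable(3.0, np.column_stack([x, y]) * 100.0)
        poly = fit_mapping(table, "to_surface")
        np.testing.assert_allclose(poly.evaluate_gy(x), y, rtol=1e-8)

    def test_too_few_rows(self):
        rows = np.column_stack([np.arange(300, 900, 100), np.arange(500, 1100, 100)])
        with pytest.raises(InsufficientDataError):
            fit_mapping(DoseTable(3.0, rows), "to_surface")

    def test_six_coefficients_required(self):
        with pytest.raises(ValueError, match="six"):
            MappingPolynomial(3.0, "to_surface", (1.0, 2.0), (3.0, 8.5))


class TestDiameterMapping:
    def test_exact_table_rows_take_precedence(self, tables):
        m = reference_mapping(3.0)
        # tabulated pair 500 -> 730 (the quintic alone would give ~746)
        assert m.to_surface(500.0) == 730.0
        assert m.to_5mm(730.0) == 500.0

    def test_between_rows_uses_the_quintic(self):
        m = reference_mapping(3.0)
        got = m.to_surface(650.0)
        assert 910.0 < got < 1050.0  # between the bracketing table rows

    def test_unknown_diameter(self):
        with pytest.raises(KeyError, match="2.5/3.0/3.5"):
            reference_mapping(4.0)


@pytest.fixture(scope="module")
def built():
    ctx = PlannerContext(source=SourceSpec.unit_kernel("point"))
    cyl = CylinderApplicator(diameter=3.0)
    return build_dose_table(ctx, cyl, [300, 400, 500, 600, 700, 800, 900],
                            anchor_site="depth5mm")


class TestBuildDoseTable:
    def test_columns_increasing_and_ordered(self, built):
        assert np.all(np.diff(built.dose_5mm) > 0)
        assert np.all(np.diff(built.dose_surface) > 0)
        assert np.all(built.dose_surface > built.dose_5mm)
        assert built.flags == ()

    def test_correspondents_scale_linearly(self):
        """Dose is linear in dwell time, so doubling the anchor level doubles
        the mean dose at the other site exactly (checked before rounding)."""
        from cylbrachy import (PrescriptionSpec, generate_dwell_positions,
                               generate_reference_lines, optimize_dwell_times)
        source = SourceSpec.unit_kernel("point")
        cyl = CylinderApplicator(diameter=3.0)
        dwells = generate_dwell_positions(cyl)
        refs = generate_reference_lines(cyl)
        means = []
        for level in (400.0, 800.0):
            rx = PrescriptionSpec(primary_site="depth5mm", primary_dose=level)
            sol = optimize_dwell_times(source, dwells, refs, rx)
            means.append(float(np.mean(sol.doses("surface"))))
        assert means[1] == pytest.approx(2.0 * means[0], rel=1e-9)

    def test_surface_anchor_direction(self):
        ctx = PlannerContext(source=SourceSpec.unit_kernel("point"))
        cyl = CylinderApplicator(diameter=3.0)
        table = build_dose_table(ctx, cyl, [500, 600, 700, 800, 900, 1000, 1100],
                                 anchor_site="surface")
        assert np.all(table.dose_surface == [500, 600, 700, 800, 900, 1000, 1100])
        assert np.all(table.dose_surface > table.dose_5mm)
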