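"""Dwell-time optimization: closed forms, grid oracles, smoothing behavior,
and the four plan factories."""

import numpy as np
import pytest

from cylbrachy import (
    ConfigurationError, DosePoint, DwellPosition, DwellTimeModel,
    PrescriptionSpec, ReferencePointSet, SourceSpec,
    dose_rate_matrix, make_plan, optimize_dwell_times, reference_mapping,
)


def tiny_refs(points):
    """A ReferencePointSet from explicit DosePoints (test scaffolding)."""
    return ReferencePointSet(points=tuple(points), spacing=0.25, apex_angular_samples=9)


def axis_dwells(zs):
    u = np.array([0.0, 0.0, 1.0])
    return [DwellPosition(i, np.array([0.0, 0.0, z]), u) for i, z in enumerate(zs)]


@pytest.fixture(scope="module")
def unit():
    return SourceSpec.unit_kernel("point")


class TestClosedForm:
    def test_single_dwell_single_point(self, unit):
        """With one dwell and one point the optimum is t* = Rx / rate."""
        refs = tiny_refs([DosePoint([1.5, 0.0, 0.0], "surface", "left")])
        rx = PrescriptionSpec(primary_site="surface", primary_dose=500.0, smoothing=0.0)
        sol = optimize_dwell_times(unit, axis_dwells([0.0]), refs, rx)
        rate = dose_rate_matrix(unit, axis_dwells([0.0]), refs.points)[0, 0]
        assert sol.times[0] == pytest.approx(500.0 / rate, rel=1e-9)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-12)
        assert sol.coverage_fraction["surface"] == 1.0


def grid_best_objective(model, t_ref, n=200):
    """Brute-force oracle: best objective on an n-per-dimension grid over
    [0, 2 t_ref] per dwell."""
    k = len(model.dwells)
    axes = [np.linspace(0.0, 2.0 * t_ref, n)] * k
    best = np.inf
    # chunked cartesian evaluation to bound memory at n**k points
    mesh = np.meshgrid(*axes, indexing="ij")
    T = np.stack([m.ravel() for m in mesh], axis=1)
    for chunk in np.array_split(T, max(1, T.shape[0] // 200_000)):
        resid = chunk @ model.design.T - model.targets
        J = (model.weights * resid**2).sum(axis=1)
        if model.lambda_s > 0:
            J = J + model.lambda_s * ((chunk @ model.diff.T) ** 2).sum(axis=1)
        best = min(best, float(J.min()))
    return best


class TestGridOracle:
    @pytest.mark.parametrize("n_dwells", [2, 3])
    def test_nnls_dominates_grid(self, unit, n_dwells):
        zs = [0.0, 0.5, 1.0][:n_dwells]
        pts = [
            DosePoint([1.5, 0.0, 0.0], "surface", "left"),
            DosePoint([1.5, 0.0, 0.5], "surface", "left"),
            DosePoint([0.0, 0.0, 2.0], "surface", "apex"),
        ]
        rx = PrescriptionSpec(primary_site="surface", primary_dose=400.0, smoothing=0.0)
        model = DwellTimeModel(unit, axis_dwells(zs), tiny_refs(pts), rx)
        sol = model.fit()
        t_ref = max(sol.times.max(), 1.0)
        n = 200 if n_dwells == 2 else 60
        best = grid_best_objective(model, t_ref, n=n)
        assert sol.objective_value <= best + 1e-9


class TestSmoothing:
    def test_huge_smoothing_equalizes_times(self, unit, cyl3_dwells, cyl3_refs):
        rx = PrescriptionSpec(primary_site="surface", primary_dose=500.0, smoothing=300.0)
        sol = optimize_dwell_times(unit, cyl3_dwells, cyl3_refs, rx,
                                   smoothing_scale=1e9)
        t = sol.times
        assert (t.max() - t.min()) / t.mean() < 1e-3

    def test_monotone_smoothing_path(self, unit, cyl3_dwells, cyl3_refs):
        """Raising the smoothing dial never roughens the dwell profile."""
        roughness = []
        for dial in [0.0, 30.0, 100.0, 200.0, 300.0]:
            rx = PrescriptionSpec(primary_site="surface", primary_dose=500.0,
                                  smoothing=dial)
            model = DwellTimeModel(unit, cyl3_dwells, cyl3_refs, rx,
                                   smoothing_scale=1.0e2)
            t = model.fit().times
            roughness.append(float(np.sum(np.diff(t) ** 2)))
        assert all(b <= a + 1e-9 for a, b in zip(roughness, roughness[1:]))

    def test_objective_breakdown_identity(self, ir192, cyl3_dwells, cyl3_refs):
        rx = make_plan("P2_5mm&Sur", dose_5mm=700.0, dose_surface=1050.0)
        sol = optimize_dwell_times(ir192, cyl3_dwells, cyl3_refs, rx)
        fid, smo = sol.term_breakdown
        assert sol.objective_value == pytest.approx(fid + smo, rel=1e-9)
        assert np.all(sol.times >= 0.0)


class TestDegenerateProblems:
    def test_rank_deficiency_reported(self, unit):
        # two dwells, one point, no smoothing: a flat valley of optima
        refs = tiny_refs([DosePoint([1.5, 0.0, 0.25], "surface", "left")])
        rx = PrescriptionSpec(primary_site="surface", primary_dose=500.0, smoothing=0.0)
        sol = optimize_dwell_times(unit, axis_dwells([0.0, 0.5]), refs, rx)
        assert sol.converged is False

    def test_prescribed_site_without_points(self, unit):
        refs = tiny_refs([DosePoint([1.5, 0.0, 0.0], "surface", "left")])
        rx = PrescriptionSpec(primary_site="depth5mm", primary_dose=500.0)
        with pytest.raises(ConfigurationError, match="no points"):
            DwellTimeModel(unit, axis_dwells([0.0]), refs, rx)

    def test_at_least_one_dwell(self, unit, cyl3_refs):
        rx = PrescriptionSpec(primary_site="surface", primary_dose=500.0)
        with pytest.raises(ConfigurationError, match="dwell"):
            DwellTimeModel(unit, [], cyl3_refs, rx)


class TestPrescriptionValidation:
    def test_priority_ordering_enforced(self):
        bad_primary = {("surface", "left"): 90.0, ("surface", "right"): 90.0,
                       ("surface", "apex"): 120.0}
        with pytest.raises(ValueError, match="exceed 100"):
            PrescriptionSpec(primary_site="surface", primary_dose=500.0,
                             priority_map=bad_primary)
        bad_apex = {("surface", "left"): 110.0, ("surface", "right"): 110.0,
                    ("surface", "apex"): 115.0}
        with pytest.raises(ValueError, match="10-50"):
            PrescriptionSpec(primary_site="surface", primary_dose=500.0,
                             priority_map=bad_apex)

    def test_secondary_needs_dose(self):
        with pytest.raises(ConfigurationError, match="secondary_dose"):
            PrescriptionSpec(primary_site="surface", primary_dose=500.0,
                             secondary_site="depth5mm")

    def test_smoothing_dial_range(self):
        with pytest.raises(ValueError, match="smoothing"):
            PrescriptionSpec(primary_site="surface", primary_dose=500.0, smoothing=301.0)


class TestMakePlan:
    def test_dual_plan_with_both_doses(self):
        rx = make_plan("P2_5mm&Sur", dose_5mm=700.0, dose_surface=1050.0)
        assert rx.primary_site == "depth5mm" and rx.primary_dose == 700.0
        assert rx.secondary_site == "surface" and rx.secondary_dose == 1050.0

    def test_single_site_plan(self):
        rx = make_plan("P1_5mm", dose_5mm=600.0)
        assert rx.primary_site == "depth5mm"
        assert rx.secondary_site is None

    def test_surface_primary_reversed_priorities(self):
        p2 = make_plan("P2_5mm&Sur", dose_5mm=700.0, dose_surface=1050.0)
        p4 = make_plan("P4_Sur&5mm", dose_5mm=700.0, dose_surface=1050.0)
        assert p2.priority_map[("depth5mm", "left")] > 100
        assert p2.priority_map[("surface", "left")] < 80
        assert p4.priority_map[("surface", "left")] > 100
        assert p4.priority_map[("depth5mm", "left")] < 80

    def test_mapped_secondary_dose(self):
        """950 cGy on the surface of the 2.5 cm cylinder maps to 600 cGy at
        5 mm depth."""
        rx = make_plan("P4_Sur&5mm", dose_surface=950.0,
                       mapping_ctx=reference_mapping(2.5))
        assert rx.secondary_dose == pytest.approx(600.0)

    def test_missing_dose_without_mapping(self):
        with pytest.raises(ConfigurationError, match="mapping"):
            make_plan("P2_5mm&Sur", dose_5mm=700.0)
        with pytest.raises(ConfigurationError):
            make_plan("P3_Sur")

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown plan method"):
            make_plan("P5_magic", dose_5mm=700.0)
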