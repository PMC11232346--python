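"""Objective template, gEUD, penalty terms and their gradients."""

import numpy as np
import pytest

from autoplan.aux_structures import build_aux_structures
from autoplan.dose import DoseGrid
from autoplan.grid import RoiMask
from autoplan.objectives import (ObjectiveKind, ObjectiveSpec, default_template,
                                 geud, geud_gradient, objective_term,
                                 term_value_and_gradient, total_objective)
from autoplan.phantom import Prescription
from conftest import make_grid, sphere_mask

K = ObjectiveKind
PRESC = 50.4


class TestTemplate:
    @pytest.fixture(scope="class")
    def template(self, coarse_case):
        aux = build_aux_structures(coarse_case)
        return default_template(aux, coarse_case.prescription), aux

    def test_has_25_rows(self, template):
        tpl, _ = template
        assert len(tpl) == 25

    def test_rectum_row_as_printed(self, template):
        tpl, _ = template
        rows = [s for s in tpl if s.roi_name == "rectum"]
        assert len(rows) == 1
        r = rows[0]
        assert r.kind is K.MAX_DVH and r.target_gy == 38.0
        assert r.volume_pct == 60.0 and r.weight == 2e9

    def test_bag_row_uses_per_patient_volume(self, template):
        tpl, aux = template
        bag_rows = [s for s in tpl if s.roi_name == "bag"]
        assert len(bag_rows) == 1
        assert bag_rows[0].volume_pct == float(aux.bag_volume_pct)

    def test_ptv_eud_row(self, template):
        tpl, _ = template
        row = [s for s in tpl if s.roi_name == "PTV"][0]
        assert row.kind is K.MAX_EUD and row.eud_a == 150.0 and row.target_gy == 52.0

    def test_all_rois_resolvable(self, template, coarse_case):
        tpl, aux = template
        known = set(coarse_case.structures) | set(aux.masks)
        assert set(tpl.roi_names()) <= known

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ObjectiveSpec("x", K.MAX_DVH, 40.0, 1.0)           # missing volume
        with pytest.raises(ValueError):
            ObjectiveSpec("x", K.MAX_EUD, 0.0, 1.0)            # missing eud_a
        with pytest.raises(ValueError):
            ObjectiveSpec("x", K.MAX_DOSE, 40.0, 0.0)          # zero weight


class TestGeud:
    def test_a1_is_mean(self):
        assert geud([2.0, 4.0], 1.0) == pytest.approx(3.0)

    def test_uniform_dose_any_a(self):
        for a in (0.5, 1.0, 2.0, 8.0, 150.0, -5.0):
            assert geud([7.0] * 5, a) == pytest.approx(7.0)

    def test_a2_power_mean(self):
        assert geud([2.0, 4.0], 2.0) == pytest.approx(np.sqrt(10.0))

    def test_monotone_in_a(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(1, 60, size=50)
        vals = [geud(d, a) for a in (0.5, 1, 2, 5, 20, 80)]
        assert all(x <= y + 1e-9 for x, y in zip(vals, vals[1:]))

    def test_large_a_approaches_max(self):
        d = np.array([10.0, 31.0, 46.0, 50.0])
        assert geud(d, 150.0) == pytest.approx(d.max(), rel=0.01)

    def test_errors(self):
        with pytest.raises(ValueError):
            geud([], 1.0)
        with pytest.raises(ValueError):
            geud([1.0], 0.0)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(5, 55, size=12)
        for a in (1.0, 2.0, 8.0, 150.0):
            g = geud_gradient(d, a)
            fd = np.empty_like(d)
            h = 1e-6
            for i in range(d.size):
                dp, dm = d.copy(), d.copy()
                dp[i] += h
                dm[i] -= h
                fd[i] = (geud(dp, a) - geud(dm, a)) / (2 * h)
            np.testing.assert_allclose(g, fd, rtol=1e-4, atol=1e-8)


class TestTermValues:
    def test_max_dose_satisfied_is_zero(self):
        spec = ObjectiveSpec("r", K.MAX_DOSE, 50.0, 1e9)
        v, g = term_value_and_gradient(spec, np.full(10, 45.0), PRESC)
        assert v == 0.0 and np.all(g == 0.0)

    def test_max_dvh_within_allowance_is_zero(self):
        # 40 % of voxels above threshold, 60 % allowed -> no excess volume
        spec = ObjectiveSpec("r", K.MAX_DVH, 38.0, 2e9, volume_pct=60.0)
        d = np.array([10.0] * 6 + [50.0] * 4)
        v, g = term_value_and_gradient(spec, d, PRESC)
        assert v == 0.0 and np.all(g == 0.0)

    def test_max_dvh_penalizes_cheapest_excess(self):
        # 60 % above threshold with 40 % allowed: only the coolest excess
        # voxels (below the current D_40%) are pushed down
        spec = ObjectiveSpec("r", K.MAX_DVH, 30.0, 1.0, volume_pct=40.0)
        d = np.array([10.0, 20.0, 35.0, 40.0, 50.0])
        v, g = term_value_and_gradient(spec, d, PRESC)
        assert v > 0
        assert g[2] > 0                     # 35: the single excess voxel
        assert g[3] == 0.0 and g[4] == 0.0  # hottest voxels kept (inside allowance)
        assert g[0] == g[1] == 0.0          # below threshold

    def test_max_eud_zero_target_uniform(self):
        spec = ObjectiveSpec("r", K.MAX_EUD, 0.0, 2.0, eud_a=1.0)
        d = np.full(8, 12.0)
        v, _ = term_value_and_gradient(spec, d, PRESC)
        assert v == pytest.approx(2.0 * 12.0 ** 2 / PRESC ** 2)

    def test_zero_dose_only_min_terms_active(self):
        d = np.zeros(10)
        for kind, kw in ((K.MAX_DOSE, {}), (K.MAX_DVH, dict(volume_pct=50.0)),
                         (K.MAX_EUD, dict(eud_a=1.0))):
            v, _ = term_value_and_gradient(
                ObjectiveSpec("r", kind, 10.0, 1.0, **kw), d, PRESC)
            assert v == 0.0
        v, _ = term_value_and_gradient(
            ObjectiveSpec("r", K.MIN_DOSE, 10.0, 1.0), d, PRESC)
        assert v > 0
        v, _ = term_value_and_gradient(
            ObjectiveSpec("r", K.MIN_DVH, 10.0, 1.0, volume_pct=50.0), d, PRESC)
        assert v > 0

    def test_weight_scales_value(self):
        d = np.linspace(30, 60, 10)
        s1 = ObjectiveSpec("r", K.MAX_DOSE, 40.0, 1.0)
        s2 = ObjectiveSpec("r", K.MAX_DOSE, 40.0, 2.0)
        v1, _ = term_value_and_gradient(s1, d, PRESC)
        v2, _ = term_value_and_gradient(s2, d, PRESC)
        assert v2 == pytest.approx(2 * v1)


SPECS_FOR_FD = [
    ObjectiveSpec("r", K.MAX_DOSE, 40.0, 3.0),
    ObjectiveSpec("r", K.MIN_DOSE, 45.0, 2.0),
    ObjectiveSpec("r", K.MAX_DVH, 35.0, 1.5, volume_pct=40.0),
    ObjectiveSpec("r", K.MIN_DVH, 48.0, 1.5, volume_pct=60.0),
    ObjectiveSpec("r", K.MAX_EUD, 20.0, 2.5, eud_a=1.0),
    ObjectiveSpec("r", K.MAX_EUD, 10.0, 2.5, eud_a=4.0),
]


class TestGradients:
    @pytest.mark.parametrize("spec", SPECS_FOR_FD,
                             ids=lambda s: f"{s.kind.value}-a{s.eud_a}")
    def test_term_gradient_vs_central_differences(self, spec):
        """Analytic gradients match central finite differences to 1e-4
        relative (DVH voxel selections frozen during the check)."""
        rng = np.random.default_rng(3)
        d = rng.uniform(10, 55, size=10)
        frozen = None
        if spec.kind in (K.MAX_DVH, K.MIN_DVH):
            frozen = float(np.percentile(d, 100 - spec.volume_pct))
        v0, g = term_value_and_gradient(spec, d, PRESC, frozen_dvh_dose=frozen)
        h = 1e-5
        for i in range(d.size):
            dp, dm = d.copy(), d.copy()
            dp[i] += h
            dm[i] -= h
            vp, _ = term_value_and_gradient(spec, dp, PRESC, frozen_dvh_dose=frozen)
            vm, _ = term_value_and_gradient(spec, dm, PRESC, frozen_dvh_dose=frozen)
            fd = (vp - vm) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-9)


class TestTotalObjective:
    def test_composition_on_grid(self):
        g = make_grid((12, 12, 12), 2.0)
        roi_a = sphere_mask(g, (0, 0, 0), 8.0, "a")
        roi_b = sphere_mask(g, (4, 0, 0), 6.0, "b")
        rng = np.random.default_rng(5)
        dose = DoseGrid(grid=g, values=rng.uniform(0, 60, g.shape))
        from autoplan.objectives import ObjectiveTemplate
        tpl = ObjectiveTemplate(
            specs=[ObjectiveSpec("a", K.MAX_DOSE, 30.0, 2.0),
                   ObjectiveSpec("b", K.MIN_DOSE, 45.0, 1.0)],
            prescription=Prescription())
        total, grad = total_objective(tpl, dose, {"a": roi_a, "b": roi_b})
        va, ga = objective_term(tpl.specs[0], dose, roi_a, PRESC)
        vb, gb = objective_term(tpl.specs[1], dose, roi_b, PRESC)
        assert total == pytest.approx(va + vb)
        np.testing.assert_allclose(grad, ga + gb)

    def test_unknown_roi_rejected(self):
        g = make_grid((8, 8, 8), 2.0)
        dose = DoseGrid(grid=g, values=np.zeros(g.shape))
        from autoplan.objectives import ObjectiveTemplate
        tpl = ObjectiveTemplate(specs=[ObjectiveSpec("ghost", K.MAX_DOSE, 1.0, 1.0)],
                                prescription=Prescription())
        with pytest.raises(KeyError):
            total_objective(tpl, dose, {})

    def test_empty_mask_contributes_zero(self):
        g = make_grid((8, 8, 8), 2.0)
        dose = DoseGrid(grid=g, values=np.full(g.shape, 50.0))
        empty = RoiMask("e", g, np.zeros(g.shape, bool))
        v, grad = objective_term(ObjectiveSpec("e", K.MAX_DOSE, 1.0, 1.0),
                                 dose, empty, PRESC)
        assert v == 0.0 and np.all(grad == 0.0)
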