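"""FLNe/SLN quantification, aggregation rules and matrix ordering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import marmoconn as mc
from marmoconn import phantom, quantify
from marmoconn.template import Injection, UnassignableError


def make_injection(inj_id="I0", area=2, center=(0.0, 0.0, 6.5), r_ex=0.3):
    return Injection(id=inj_id, tracer="FB", center=np.array(center),
                     assigned_area=area, volume=0.01, exclusion_radius=r_ex)


def make_cells(spec):
    """spec: list of (injection_id, area, lamina, count) -> cell table."""
    rows = []
    for inj_id, area, lamina, count in spec:
        for _ in range(count):
            rows.append((inj_id, "FB", 0.0, 0.0, 0.0, area, lamina))
    return pd.DataFrame(
        rows, columns=["injection_id", "tracer", "x_mm", "y_mm", "z_mm", "area", "lamina"]
    )


class TestAssignArea:
    def test_point_inside_area_voxel_returns_its_label(self, small_phantom):
        tpl = small_phantom[0]
        p = tpl.midthickness[100]
        assert quantify.assign_area(p, tpl) == tpl.label_at(p)

    def test_white_matter_point_snaps_to_nearest_area_within_tolerance(self, small_phantom):
        """Brute-force oracle: nearest gray voxel center over the whole grid."""
        tpl = small_phantom[0]
        p = np.array([0.0, 0.0, 5.3])  # in white matter, ~0.2 mm under cortex
        assert tpl.label_at(p) == 1
        gray_idx = np.argwhere(tpl.gray_mask)
        pts = tpl.voxel_to_world(gray_idx)
        nearest = np.argmin(np.linalg.norm(pts - p, axis=1))
        expect = tpl.labels[tuple(gray_idx[nearest])]
        assert quantify.assign_area(p, tpl, tolerance=0.8) == expect

    def test_point_far_outside_brain_is_unassignable(self, small_phantom):
        with pytest.raises(UnassignableError):
            quantify.assign_area(np.array([0.0, 0.0, 9.9]), small_phantom[0], tolerance=0.5)


class TestFlne:
    def test_worked_example_80_20(self):
        cells = make_cells([("I0", 3, "supra", 80), ("I0", 4, "supra", 20),
                            ("I0", 2, "supra", 50)])
        flne = quantify.compute_flne(cells, make_injection(area=2))
        assert flne[3] == pytest.approx(0.80)
        assert flne[4] == pytest.approx(0.20)
        assert 2 not in flne.index

    def test_single_extrinsic_source_is_one(self):
        cells = make_cells([("I0", 3, "infra", 7)])
        flne = quantify.compute_flne(cells, make_injection(area=2))
        assert flne[3] == 1.0

    def test_only_intrinsic_cells_is_undefined(self):
        cells = make_cells([("I0", 2, "supra", 50)])
        with pytest.raises(ValueError):
            quantify.compute_flne(cells, make_injection(area=2))

    @given(st.lists(st.integers(min_value=0, max_value=500), min_size=2, max_size=8))
    def test_extrinsic_sum_is_one_for_any_counts(self, counts):
        spec = [("I0", 3 + i, "supra", c) for i, c in enumerate(counts)]
        cells = make_cells(spec + [("I0", 2, "supra", 10)])
        if sum(counts) == 0:
            with pytest.raises(ValueError):
                quantify.compute_flne(cells, make_injection(area=2))
        else:
            flne = quantify.compute_flne(cells, make_injection(area=2))
            assert flne.sum() == pytest.approx(1.0, abs=1e-12)

    def test_per_injection_flne_sums_to_one_on_phantom(self, small_phantom):
        _, injections, cells, _ = small_phantom
        for inj in injections:
            assert quantify.compute_flne(cells, inj).sum() == pytest.approx(1.0, abs=1e-12)


class TestSln:
    def test_worked_example_075(self):
        cells = make_cells([("I0", 3, "supra", 30), ("I0", 3, "infra", 10)])
        sln = quantify.compute_sln(cells, make_injection(area=2))
        assert sln[3] == pytest.approx(0.75)

    def test_no_layer4_source_is_undefined(self):
        cells = make_cells([("I0", 3, "supra", 30), ("I0", 3, "infra", 10)])
        sln = quantify.compute_sln(cells, make_injection(area=2), no_layer4={3})
        assert np.isnan(sln[3])

    def test_zero_count_projection_is_absent(self):
        cells = make_cells([("I0", 3, "supra", 5)])
        sln = quantify.compute_sln(cells, make_injection(area=2))
        assert 4 not in sln.index

    def test_sln_in_unit_interval_on_phantom(self, small_phantom):
        _, injections, cells, _ = small_phantom
        for inj in injections:
            sln = quantify.compute_sln(cells, inj).dropna()
            assert ((sln >= 0) & (sln <= 1)).all()


class TestAggregation:
    def test_unobserved_projection_counts_as_zero_in_mean(self):
        # two injections into area 2: FLNe_3 = 0.2 and not observed -> 0.10
        cells = make_cells([
            ("I0", 3, "supra", 20), ("I0", 4, "supra", 80),
            ("I1", 4, "supra", 50),
        ])
        injections = [make_injection("I0", 2), make_injection("I1", 2)]
        mats = quantify.aggregate_by_area(cells, injections)
        assert mats.flne.loc[3, 2] == pytest.approx(0.10)

    def test_observed_only_averaging_is_available(self):
        cells = make_cells([
            ("I0", 3, "supra", 20), ("I0", 4, "supra", 80),
            ("I1", 4, "supra", 50),
        ])
        injections = [make_injection("I0", 2), make_injection("I1", 2)]
        mats = quantify.aggregate_by_area(cells, injections, unobserved_as_zero=False)
        assert mats.flne.loc[3, 2] == pytest.approx(0.20)

    def test_sln_pools_counts_before_dividing(self):
        # inj1: 3 supra / 1 infra; inj2: 1 supra / 3 infra -> 4/8 = 0.5
        cells = make_cells([
            ("I0", 3, "supra", 3), ("I0", 3, "infra", 1), ("I0", 4, "supra", 1),
            ("I1", 3, "supra", 1), ("I1", 3, "infra", 3), ("I1", 4, "supra", 1),
        ])
        injections = [make_injection("I0", 2), make_injection("I1", 2)]
        mats = quantify.aggregate_by_area(cells, injections)
        assert mats.sln.loc[3, 2] == pytest.approx(0.5)

    def test_single_injection_aggregate_equals_per_injection(self, small_phantom):
        _, injections, cells, _ = small_phantom
        inj = injections[0]
        mats = quantify.aggregate_by_area(cells, [inj])
        per = mats.per_injection_flne[inj.id]
        for src in per.index:
            assert mats.flne.loc[src, inj.assigned_area] == pytest.approx(per[src])

    def test_pooled_sln_between_min_and_max_of_contributors(self, small_phantom):
        _, injections, cells, _ = small_phantom
        mats = quantify.aggregate_by_area(cells, injections)
        per = mats.per_injection_sln
        for src in mats.sln.index:
            for tgt in mats.sln.columns:
                pooled = mats.sln.loc[src, tgt]
                if np.isnan(pooled):
                    continue
                contrib = [
                    per[i].get(src, np.nan)
                    for i, a in mats.injection_targets.items() if a == tgt
                ]
                contrib = [c for c in contrib if not np.isnan(c)]
                assert min(contrib) - 1e-12 <= pooled <= max(contrib) + 1e-12

    def test_flne_recovers_planted_weights(self, small_cfg, small_phantom):
        """Mean FLNe over 5 replicate injections matches the planted extrinsic
        distribution within binomial sampling error (z-test, alpha=0.01)."""
        tpl, _, _, dmat = small_phantom
        target = int(tpl.area_ids[0])
        reps = phantom.place_injections(tpl, [target] * 5, small_cfg)
        cells = phantom.simulate_cells(tpl, reps, small_cfg, dmat=dmat)
        probs = phantom.expected_source_distribution(small_cfg, tpl, target, dmat)
        extr = probs.drop(labels=[target])
        expect = extr / extr.sum()
        n_ext = [len(cells[(cells.injection_id == r.id) & (cells.area != target)])
                 for r in reps]
        flnes = pd.DataFrame([quantify.compute_flne(cells, r) for r in reps])
        mean_flne = flnes.fillna(0.0).mean()
        for src in expect.index:
            p = expect[src]
            se = np.sqrt(np.mean([p * (1 - p) / n for n in n_ext]) / len(reps))
            z = abs(mean_flne.get(src, 0.0) - p) / se
            assert z < 2.58  # alpha = 0.01 two-sided


class TestClusterOrder:
    def test_two_areas_is_a_deterministic_permutation(self):
        m = pd.DataFrame([[0.1, 0.5], [0.6, 0.2]], index=[2, 3], columns=[2, 3])
        order = quantify.cluster_order(m)
        assert sorted(order) == [2, 3]
        assert order == quantify.cluster_order(m)

    def test_identical_profiles_are_adjacent(self):
        rng = np.random.default_rng(0)
        prof = rng.random((5, 4))
        prof[3] = prof[1]  # rows 1 and 3 identical
        m = pd.DataFrame(prof, index=[2, 3, 4, 5, 6], columns=[10, 11, 12, 13])
        order = quantify.cluster_order(m)
        assert abs(order.index(3) - order.index(5)) == 1

    def test_row_permutation_preserves_twin_adjacency(self):
        rng = np.random.default_rng(1)
        prof = rng.random((5, 4))
        prof[4] = prof[0]
        m = pd.DataFrame(prof, index=[2, 3, 4, 5, 6], columns=[10, 11, 12, 13])
        perm = [4, 2, 6, 3, 5]
        order = quantify.cluster_order(m.loc[perm])
        assert abs(order.index(2) - order.index(6)) == 1

    def test_single_area_raises(self):
        m = pd.DataFrame([[0.1]], index=[2], columns=[2])
        with pytest.raises(ValueError):
            quantify.cluster_order(m)
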