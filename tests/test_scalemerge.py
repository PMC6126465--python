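"""Symmetry mapping, tolerance, scaling, merging and statistics."""

import copy
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from isomerge.reflio import KeywordSet, UnitCell
from isomerge.scalemerge import (
    SymmetryOps,
    ToleranceError,
    UnconnectedGroupError,
    check_tolerance,
    compute_stats,
    map_to_unique,
    merge,
    merge_group,
    scale_datasets,
    theoretical_unique_count,
)

from conftest import make_dataset


P1 = SymmetryOps.from_symbol("P 1")
P21 = SymmetryOps.from_symbol("P 21")
P212121 = SymmetryOps.from_symbol("P 21 21 21")


class TestSymmetryOps:
    def test_identity_and_closure_enforced(self):
        with pytest.raises(ValueError, match="identity"):
            SymmetryOps("broken", (((-1, 0, 0), (0, -1, 0), (0, 0, 1)),))

    @pytest.mark.parametrize(
        "symbol,n_rot", [("P 1", 1), ("P 2", 2), ("P 21", 2), ("P 2 2 2", 4),
                         ("P 21 21 21", 4), ("P 4", 4), ("P 6", 6)]
    )
    def test_shipped_groups(self, symbol, n_rot):
        ops = SymmetryOps.from_symbol(symbol)
        assert len(ops.rotations) == n_rot

    def test_friedel_pair_p1(self):
        key = map_to_unique(np.array([[-1, 2, 3]]), P1)
        assert tuple(key[0]) == (1, -2, -3)

    def test_identity_no_friedel(self):
        ops = SymmetryOps("P 1", (np.eye(3, dtype=int),), friedel=False)
        hkl = np.array([[-1, 2, 3], [4, -5, 6]])
        np.testing.assert_array_equal(map_to_unique(hkl, ops), hkl)

    @pytest.mark.parametrize("ops", [P1, P21, P212121, SymmetryOps.from_symbol("P 4")])
    def test_orbit_members_share_key(self, ops):
        rng = np.random.default_rng(1)
        hkl = rng.integers(-9, 10, (200, 3))
        hkl[(hkl == 0).all(axis=1)] = [1, 1, 1]
        keys = map_to_unique(hkl, ops)
        mats = ops.matrix_stack()
        for m in mats:
            keys_m = map_to_unique(hkl @ m, ops)
            np.testing.assert_array_equal(keys, keys_m)

    def test_rotation_convention_matches_gemmi(self):
        import gemmi

        sg = gemmi.SpaceGroup("P 4")
        rng = np.random.default_rng(2)
        hkl = rng.integers(-6, 7, (50, 3))
        for op in sg.operations():
            rot = (np.asarray(op.rot) / gemmi.Op.DEN).astype(int)
            ours = hkl @ rot
            theirs = np.array([op.apply_to_hkl(list(map(int, row))) for row in hkl])
            np.testing.assert_array_equal(ours, theirs)


class TestCheckTolerance:
    def test_identical_cells_pass(self):
        c = UnitCell(50, 60, 70, 90, 90, 90)
        assert check_tolerance([c, c], 2.0)[0]

    def test_three_percent_edge_fails_default(self):
        a = UnitCell(100, 100, 100, 90, 90, 90)
        b = UnitCell(103, 100, 100, 90, 90, 90)
        ok, msg = check_tolerance([a, b], 2.0)
        assert not ok
        assert "differ" in msg

    def test_tolerance_100_always_passes(self):
        a = UnitCell(100, 100, 100, 90, 90, 90)
        b = UnitCell(150, 100, 100, 90, 90, 70)
        assert check_tolerance([a, b], 100.0)[0]

    def test_angle_difference_checked(self):
        a = UnitCell(100, 100, 100, 90, 90, 90)
        b = UnitCell(100, 100, 100, 90, 90, 86)
        assert not check_tolerance([a, b], 2.0)[0]


class TestScaleDatasets:
    def test_doubled_copy_recovers_half(self, small_dataset):
        d2 = copy.deepcopy(small_dataset)
        d2.serial = 2
        d2.observations = d2.observations.assign(
            intensity=d2.observations["intensity"] * 2.0,
            sigma=d2.observations["sigma"] * 2.0,
        )
        scales, scaled = scale_datasets([small_dataset, d2], P1, KeywordSet())
        k2, B2 = scales[2]
        assert k2 == pytest.approx(0.5, abs=1e-6)
        assert B2 == pytest.approx(0.0, abs=1e-6)

    def test_noiseless_scale_recovery(self, two_group_sim):
        """Planted (k, B) recovered within one isomorphous group."""
        datasets, records = two_group_sim
        group, recs = datasets[:5], records[:5]
        ops = SymmetryOps.from_symbol(group[0].spacegroup)
        scales, _ = scale_datasets(group, ops, KeywordSet())
        k_ref, B_ref = recs[0]["k"], recs[0]["B"]
        for ds, rec in zip(group, recs):
            k, B = scales[ds.serial]
            assert k == pytest.approx(k_ref / rec["k"], rel=1e-4)
            assert B == pytest.approx(B_ref - rec["B"], abs=1e-4)

    def test_single_dataset_identity(self, small_dataset):
        scales, scaled = scale_datasets([small_dataset], P1, KeywordSet())
        assert scales[1] == (1.0, 0.0)
        np.testing.assert_allclose(
            scaled["intensity"], small_dataset.observations["intensity"]
        )

    def test_unconnected_group_rejected(self):
        obs_a = pd.DataFrame(
            {"h": [1, 1], "k": [0, 0], "l": [0, 0], "intensity": [10.0, 12.0],
             "sigma": 1.0, "image": [1, 2]}
        )
        obs_b = pd.DataFrame(
            {"h": [0, 0], "k": [2, 2], "l": [0, 0], "intensity": [10.0, 12.0],
             "sigma": 1.0, "image": [1, 2]}
        )
        a = make_dataset(serial=1, obs=obs_a)
        b = make_dataset(serial=2, obs=obs_b)
        with pytest.raises(UnconnectedGroupError):
            scale_datasets([a, b], P1, KeywordSet())

    def test_resolution_high_filters(self, small_dataset):
        kw = KeywordSet(resolution_high=15.0)
        _, scaled = scale_datasets([small_dataset], P1, kw)
        assert (scaled["s"] <= 1 / 15.0**2 + 1e-9).all()


class TestMerge:
    def frame(self, rows):
        return pd.DataFrame(
            rows, columns=["key_h", "key_k", "key_l", "intensity", "sigma", "serial", "image", "s"]
        )

    def test_equal_weights(self):
        scaled = self.frame([(1, 0, 0, 10.0, 1.0, 1, 1, 0.01), (1, 0, 0, 10.0, 1.0, 2, 1, 0.01)])
        out = merge(scaled)
        assert len(out) == 1
        assert out["intensity"][0] == pytest.approx(10.0)
        assert out["sigma"][0] == pytest.approx(1 / math.sqrt(2))

    def test_hand_weighted_mean(self):
        scaled = self.frame([(1, 0, 0, 10.0, 1.0, 1, 1, 0.01), (1, 0, 0, 20.0, 2.0, 2, 1, 0.01)])
        out = merge(scaled)
        assert out["intensity"][0] == pytest.approx(12.0)
        assert out["sigma"][0] == pytest.approx((5 / 4) ** -0.5)

    def test_permutation_invariance(self):
        rows = [(1, 0, 0, 10.0, 1.0, 1, 1, 0.01), (2, 0, 0, 5.0, 0.5, 1, 2, 0.04),
                (1, 0, 0, 11.0, 2.0, 2, 1, 0.01)]
        a = merge(self.frame(rows))
        b = merge(self.frame(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)


class TestComputeStats:
    def two_obs_case(self):
        scaled = pd.DataFrame(
            {"key_h": [1, 1], "key_k": [0, 0], "key_l": [0, 0],
             "intensity": [10.0, 12.0], "sigma": [1.0, 1.0],
             "serial": [1, 2], "image": [1, 1], "s": [0.01, 0.01]}
        )
        merged = merge(scaled)
        cell = UnitCell(10, 10, 10, 90, 90, 90)
        return compute_stats(scaled, merged, cell, P1, d_min=5.0, seed=0)

    def test_hand_computed_r_statistics(self):
        st = self.two_obs_case()
        assert st.r_merge == pytest.approx(2 / 22, abs=1e-6)
        assert st.r_meas == pytest.approx(math.sqrt(2) * 2 / 22, abs=1e-6)
        assert st.r_pim == pytest.approx(2 / 22, abs=1e-6)  # n=2: r_pim == r_merge

    def test_identical_halves_give_cc_one(self, small_dataset):
        d2 = copy.deepcopy(small_dataset)
        d2.serial = 2
        scales, scaled = scale_datasets([small_dataset, d2], P1, KeywordSet())
        st = compute_stats(scaled, merge(scaled), small_dataset.cell, P1, d_min=5.0, seed=1)
        assert st.cc_half == pytest.approx(1.0, abs=1e-12)

    def test_completeness_denominator_p1_brute_force(self):
        cell = UnitCell(10, 10, 10, 90, 90, 90)
        # exhaustive count over |h|,|k|,|l| <= 2 with d >= 5, Friedel-unique
        seen = set()
        for h in range(-2, 3):
            for k in range(-2, 3):
                for l in range(-2, 3):
                    if (h, k, l) == (0, 0, 0):
                        continue
                    if cell.inv_d2(np.array([[h, k, l]]))[0] <= 1 / 25 + 1e-9:
                        seen.add(max((h, k, l), (-h, -k, -l)))
        assert theoretical_unique_count(cell, P1, 5.0) == len(seen)

    @pytest.mark.parametrize("ops", [P1, P21])
    def test_completeness_denominator_vs_enumeration(self, ops):
        cell = UnitCell(12, 15, 18, 90, 90, 90)
        d_min = 3.0
        seen = set()
        lim = 7
        for h, k, l in itertools.product(range(-lim, lim + 1), repeat=3):
            if (h, k, l) == (0, 0, 0):
                continue
            if cell.inv_d2(np.array([[h, k, l]]))[0] > 1 / d_min**2 + 1e-9:
                continue
            orbit = []
            for m in ops.matrix_stack():
                orbit.append(tuple(np.array([h, k, l]) @ m))
            seen.add(max(orbit))
        assert theoretical_unique_count(cell, ops, d_min) == len(seen)

    def test_r_statistic_ordering(self, two_group_sim):
        datasets, _ = two_group_sim
        ops = SymmetryOps.from_symbol(datasets[0].spacegroup)
        for seed in range(3):
            rng = np.random.default_rng(seed)
            pick = rng.choice(5, size=3, replace=False)
            group = [copy.deepcopy(datasets[int(i)]) for i in pick]
            for g in group:
                g.observations = g.observations.assign(
                    intensity=g.observations["intensity"] * (1 + rng.normal(0, 0.1, g.n_obs))
                )
            scales, scaled = scale_datasets(sorted(group, key=lambda d: d.serial), ops, KeywordSet())
            st = compute_stats(scaled, merge(scaled), group[0].cell, ops, d_min=3.0, seed=seed)
            assert st.r_meas >= st.r_merge >= st.r_pim >= 0

    def test_global_rescale_invariance(self, two_group_sim):
        datasets, _ = two_group_sim
        ops = SymmetryOps.from_symbol(datasets[0].spacegroup)
        group = [copy.deepcopy(d) for d in datasets[:3]]
        _, scaled = scale_datasets(group, ops, KeywordSet())
        st1 = compute_stats(scaled, merge(scaled), group[0].cell, ops, d_min=3.0, seed=5)
        for g in group:
            g.observations = g.observations.assign(
                intensity=g.observations["intensity"] * 7.5,
                sigma=g.observations["sigma"] * 7.5,
            )
        _, scaled2 = scale_datasets(group, ops, KeywordSet())
        st2 = compute_stats(scaled2, merge(scaled2), group[0].cell, ops, d_min=3.0, seed=5)
        assert st2.r_meas == pytest.approx(st1.r_meas, rel=1e-6)
        assert st2.completeness == st1.completeness
        assert st2.cc_half == pytest.approx(st1.cc_half, rel=1e-6)

    def test_all_singletons_r_absent(self):
        scaled = pd.DataFrame(
            {"key_h": [1, 2], "key_k": [0, 0], "key_l": [0, 0],
             "intensity": [10.0, 12.0], "sigma": [1.0, 1.0],
             "serial": [1, 1], "image": [1, 1], "s": [0.01, 0.04]}
        )
        st = compute_stats(scaled, merge(scaled), UnitCell(10, 10, 10, 90, 90, 90),
                           P1, d_min=5.0, seed=0)
        assert st.r_merge is None and st.r_meas is None and st.r_pim is None
        assert st.completeness > 0


class TestMergeGroup:
    def test_noiseless_cluster_quality(self, two_group_sim):
        datasets, _ = two_group_sim
        result = merge_group(datasets[:5], keywords=KeywordSet())
        assert result.stats.r_meas < 0.01
        assert result.stats.cc_half > 0.999

    def test_tolerance_failure_raises(self, two_group_sim):
        datasets, _ = two_group_sim
        with pytest.raises(ToleranceError):
            merge_group([datasets[0], datasets[9]], keywords=KeywordSet(tolerance=2.0))

    def test_duplicate_dataset_doubles_multiplicity(self, small_dataset):
        r1 = merge_group([small_dataset], keywords=KeywordSet())
        d2 = copy.deepcopy(small_dataset)
        d2.serial = 2
        r2 = merge_group([small_dataset, d2], keywords=KeywordSet())
        assert r2.stats.multiplicity == pytest.approx(2 * r1.stats.multiplicity)
        assert r2.stats.completeness == pytest.approx(r1.stats.completeness)

    def test_reference_scales_identity(self, two_group_sim):
        datasets, _ = two_group_sim
        result = merge_group(datasets[:4], keywords=KeywordSet())
        k, B = result.scales[1]
        assert (k, B) == (1.0, 0.0)
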