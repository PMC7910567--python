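import numpy as np
import pytest

from icekit.core import Configuration, IceKitError, NoNeighborsError
from icekit.icedetect import (
    SwitchingParams,
    classify_ice,
    largest_ice_cluster,
    q6_vector,
    rational_switch,
    rdf,
    s6,
    s6_values,
    solvation_shell,
)
from icekit.synthio import build_ice_ih

from conftest import make_gas_config
from oracles import brute_clusters, brute_s6


def water_pair_config(positions, box=(3.0, 3.0, 3.0), pbc="xyz"):
    n = len(positions)
    return Configuration(
        positions,
        ["O"] * n,
        ["water_O"] * n,
        box,
        pbc_mode=pbc,
    )


class TestRationalSwitch:
    def test_clamps_to_one_at_d0(self):
        p = SwitchingParams(r0=0.35, d0=0.1)
        assert rational_switch(0.1, p) == 1.0
        assert rational_switch(0.05, p) == 1.0

    def test_analytic_limit_at_x_equal_one(self):
        p = SwitchingParams(r0=0.35, d0=0.0, n=6, m=12)
        assert rational_switch(0.35, p) == pytest.approx(0.5, abs=1e-12)

    def test_vanishes_beyond_three_r0(self):
        p = SwitchingParams(r0=0.35, d0=0.0)
        r = np.linspace(3 * 0.35, 5.0, 50)
        assert np.all(rational_switch(r, p) < 1e-6)

    def test_non_increasing(self):
        p = SwitchingParams()
        r = np.linspace(0.0, 1.2, 500)
        w = rational_switch(r, p)
        assert np.all(np.diff(w) <= 1e-12)
        assert np.all((w >= 0) & (w <= 1))

    def test_invalid_exponents_rejected(self):
        with pytest.raises(IceKitError):
            SwitchingParams(n=12, m=6)
        with pytest.raises(IceKitError):
            SwitchingParams(r0=-1.0)


class TestQ6Vector:
    def test_single_neighbor_along_z(self):
        cfg = water_pair_config([[1.0, 1.0, 1.0], [1.0, 1.0, 1.28]])
        q = q6_vector(cfg, 0)
        expected_m0 = np.sqrt(13.0 / (4.0 * np.pi))
        assert q[6] == pytest.approx(expected_m0, rel=1e-10)
        others = np.delete(q, 6)
        assert np.max(np.abs(others)) < 1e-12

    def test_rotation_about_z_preserves_moduli(self):
        rng = np.random.default_rng(0)
        base = np.array([1.5, 1.5, 1.5])
        nbrs = base + 0.27 * rng.normal(size=(6, 3)) / np.linalg.norm(
            rng.normal(size=(6, 3)), axis=1, keepdims=True
        )
        cfg = water_pair_config(np.vstack([base, nbrs]))
        q_a = q6_vector(cfg, 0)
        ang = 0.7
        rot = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        )
        rotated = (np.vstack([base, nbrs]) - base) @ rot.T + base
        q_b = q6_vector(water_pair_config(rotated), 0)
        assert np.allclose(np.abs(q_a), np.abs(q_b), atol=1e-10)

    def test_interior_matches_brute_force(self, ice_slab, default_params):
        ow, q6, _ = brute_s6(ice_slab, default_params.switching)
        q_impl = q6_vector(ice_slab, int(ow[10]))
        assert np.allclose(q_impl, q6[10], atol=1e-10)

    def test_isolated_molecule_raises(self):
        cfg = water_pair_config([[0.5, 0.5, 0.5], [2.5, 2.5, 2.5]], box=(6, 6, 6))
        with pytest.raises(NoNeighborsError):
            q6_vector(cfg, 0)


class TestS6:
    def test_identical_environments_give_one(self):
        # translation-identical environments: a z-chain with periodic imaging
        cfg = water_pair_config(
            [[0.5, 0.5, 0.0], [0.5, 0.5, 0.28], [0.5, 0.5, 0.56]],
            box=(3.0, 3.0, 0.84),
        )
        for i in range(3):
            assert s6(cfg, i) == pytest.approx(1.0, abs=1e-12)

    def test_perfect_ih_interior_above_threshold(self, ice_slab):
        ow, vals = s6_values(ice_slab)
        assert np.all(vals > 0.45)

    def test_ideal_gas_below_threshold(self):
        cfg = make_gas_config(891, (3.0, 3.0, 3.0), seed=11)
        ow, vals = s6_values(cfg)
        assert np.mean(vals > 0.45) < 0.01

    def test_matches_brute_force(self, default_params):
        cfg = make_gas_config(60, (2.0, 2.0, 2.0), seed=3)
        ow, vals = s6_values(cfg, default_params.switching)
        ow_b, _, vals_b = brute_s6(cfg, default_params.switching)
        assert np.array_equal(ow, ow_b)
        assert np.allclose(vals, vals_b, atol=1e-10, equal_nan=True)

    def test_bounded_when_normalized(self):
        cfg = make_gas_config(120, (2.5, 2.5, 2.5), seed=8)
        _, vals = s6_values(cfg)
        ok = ~np.isnan(vals)
        assert np.all(vals[ok] <= 1.0 + 1e-12)
        assert np.all(vals[ok] >= -1.0 - 1e-12)

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(5)
        pts = 1.5 + 0.8 * rng.random((30, 3))
        big = (20.0, 20.0, 20.0)  # effectively no imaging
        cfg_a = water_pair_config(pts, box=big)
        _, v_a = s6_values(cfg_a)
        ang = 1.1
        rot = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        )
        moved = pts @ rot.T + np.array([3.0, 2.0, 1.0])
        cfg_b = water_pair_config(moved, box=big)
        _, v_b = s6_values(cfg_b)
        assert np.allclose(v_a, v_b, atol=1e-8, equal_nan=True)


class TestClassifyIce:
    def test_all_liquid_fixture(self):
        # bulk-density ideal gas: essentially no ice at the 0.45 threshold
        # (sparse gases are excluded on purpose: an isolated mutual pair is
        # a translation-identical environment and scores s6 = 1)
        cfg = make_gas_config(891, (3, 3, 3), seed=2, min_dist=0.26)
        labels = classify_ice(cfg)
        assert labels.n_ice <= 2

    def test_threshold_above_bound_gives_zero_ice(self, ice_slab):
        labels = classify_ice(ice_slab, threshold=1.01)
        assert labels.n_ice == 0

    def test_monotonicity_in_threshold(self):
        cfg = make_gas_config(200, (2.5, 2.5, 2.5), seed=6)
        counts = [classify_ice(cfg, threshold=t).n_ice for t in (0.0, 0.2, 0.45, 0.7)]
        assert counts == sorted(counts, reverse=True)

    def test_perfect_lattice_recall(self, ice_slab):
        labels = classify_ice(ice_slab)
        assert labels.n_ice == ice_slab.n_waters

    def test_isolated_molecules_labeled_liquid(self):
        cfg = water_pair_config([[1, 1, 1], [5, 5, 5]], box=(10, 10, 10))
        labels = classify_ice(cfg)
        assert labels.n_ice == 0
        assert np.isnan(labels.s6).all()


class TestLargestCluster:
    def test_no_ice_gives_zero(self):
        cfg = make_gas_config(50, (3, 3, 3), seed=4, min_dist=0.3)
        labels = largest_ice_cluster(cfg, classify_ice(cfg, threshold=1.01))
        assert labels.largest_cluster_size == 0

    def test_two_separated_blocks(self):
        # 10- and 20-molecule chains of fake "ice" separated by > cutoff
        pos = [[0.3 + 0.3 * k, 0.5, 0.5] for k in range(10)]
        pos += [[0.3 + 0.3 * k, 0.5, 3.0] for k in range(20)]
        cfg = water_pair_config(pos, box=(12.0, 6.0, 6.0))
        labels = classify_ice(cfg, threshold=-2.0)  # force all ice
        labels = largest_ice_cluster(cfg, labels, link_cutoff=0.35)
        assert labels.largest_cluster_size == 20
        assert labels.cluster_id is not None
        assert np.sum(labels.cluster_id == 0) == 20

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            cfg = make_gas_config(
                int(rng.integers(20, 120)), (2.5, 2.5, 2.5), seed=100 + trial
            )
            labels = classify_ice(cfg, threshold=-2.0)
            labels = largest_ice_cluster(cfg, labels, link_cutoff=0.45)
            groups = brute_clusters(cfg, labels.water_indices, labels.ice, 0.45)
            impl_groups = set()
            for cid in np.unique(labels.cluster_id[labels.cluster_id >= 0]):
                impl_groups.add(
                    frozenset(labels.water_indices[labels.cluster_id == cid].tolist())
                )
            assert impl_groups == set(groups)
            assert labels.largest_cluster_size == max(len(g) for g in groups)


class TestRdf:
    def test_two_atoms_single_bin(self):
        cfg = Configuration(
            [[0.5, 0.5, 0.5], [0.8, 0.5, 0.5]],
            ["C", "O"],
            ["methylene_C", "water_O"],
            [2.0, 2.0, 2.0],
        )
        r, g = rdf(cfg, "methylene_C", "water_O", 0.9, 0.05)
        occupied = np.flatnonzero(g > 0)
        assert len(occupied) == 1
        assert r[occupied[0]] == pytest.approx(0.325)  # bin [0.30, 0.35)

    def test_r_max_validation(self, liquid_box):
        with pytest.raises(IceKitError):
            rdf(liquid_box, "water_O", "water_O", 2.0, 0.05)

    def test_empty_roles_rejected(self, liquid_box):
        with pytest.raises(IceKitError):
            rdf(liquid_box, "methylene_C", "water_O", 1.0)


class TestSolvationShell:
    def _with_methyl(self, waters, methyl=(1.5, 1.5, 1.5)):
        pos = [list(methyl)] + [list(w) for w in waters]
        species = ["C"] + ["O"] * len(waters)
        role = ["methylene_C"] + ["water_O"] * len(waters)
        return Configuration(pos, species, role, [3.0, 3.0, 3.0])

    def test_no_water_within_cutoff(self):
        cfg = self._with_methyl([(0.2, 0.2, 0.2)])
        labels = classify_ice(cfg)
        rep = solvation_shell(cfg, labels)
        assert rep.n_total[0] == 0

    def test_five_liquid_waters(self):
        # 5 waters at 0.30-0.40 nm from the methyl, embedded in a random
        # bulk gas so their environments are genuinely disordered
        from icekit.synthio.liquid import insert_points

        rng = np.random.default_rng(7)
        box = np.array([3.0, 3.0, 3.0])
        methyl = np.array([1.5, 1.5, 1.5])
        dirs = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1]], float
        )
        radii = [0.30, 0.325, 0.35, 0.375, 0.40]
        shell = np.array([methyl + r * d for r, d in zip(radii, dirs)])
        gas = insert_points(
            700, box, 0.25, rng,
            avoid=np.vstack([methyl[None, :], shell]), avoid_dist=0.25,
        )
        gas = gas[np.linalg.norm(gas - methyl, axis=1) > 0.46]
        waters = np.vstack([shell, gas])
        cfg = Configuration(
            np.vstack([methyl[None, :], waters]),
            ["C"] + ["O"] * len(waters),
            ["methylene_C"] + ["water_O"] * len(waters),
            box,
        )
        labels = classify_ice(cfg)
        rep = solvation_shell(cfg, labels, cutoff=0.45)
        assert rep.n_total[0] == 5
        assert rep.n_ice_like[0] == 0

    def test_boundary_water_excluded(self):
        # distance is the double closest to 0.45, equal to the cutoff value
        cfg = Configuration(
            [[0.0, 1.5, 1.5], [0.45, 1.5, 1.5]],
            ["C", "O"],
            ["methylene_C", "water_O"],
            [3.0, 3.0, 3.0],
        )
        labels = classify_ice(cfg)
        rep = solvation_shell(cfg, labels, cutoff=0.45)
        assert rep.n_total[0] == 0

    def test_requires_methylene(self, liquid_box):
        labels = classify_ice(liquid_box)
        with pytest.raises(IceKitError):
            solvation_shell(liquid_box, labels)
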