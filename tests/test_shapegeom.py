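import numpy as np
import pytest
from scipy.spatial import ConvexHull

from icekit.core import Configuration, DegenerateInputError, IceKitError
from icekit.icedetect import classify_ice, largest_ice_cluster
from icekit.shapegeom import (
    alpha_area_2d,
    alpha_shape_volume,
    contact_area,
    front_advancement,
    front_profile,
    min_image_distance,
    surface_coverage,
)

from oracles import brute_rmi


def regular_tetrahedron(edge=0.1):
    return edge * np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [0.5, np.sqrt(3) / 2, 0.0],
            [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)],
        ]
    )


class TestAlphaVolume:
    def test_three_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            alpha_shape_volume(np.zeros((3, 3)))

    def test_coplanar_rejected_or_zero(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        # jittered coplanar set: volume must be essentially zero
        try:
            res = alpha_shape_volume(pts, alpha=2.0)
            assert res.volume_A3 < 1e-6
        except DegenerateInputError:
            pass

    def test_regular_tetrahedron_exact(self):
        edge = 0.1
        res = alpha_shape_volume(regular_tetrahedron(edge), alpha=0.17)
        expected_nm3 = edge**3 / (6.0 * np.sqrt(2.0))
        assert res.volume_A3 == pytest.approx(expected_nm3 * 1000.0, rel=1e-6)

    def test_tetrahedron_excluded_for_small_alpha(self):
        # circumradius of a 0.1-edge regular tetrahedron is ~0.0612 nm
        res = alpha_shape_volume(regular_tetrahedron(0.1), alpha=0.05)
        assert res.volume_A3 == 0.0

    def test_filled_cube_within_ten_percent(self):
        g = np.arange(0.0, 1.0001, 0.05)
        pts = np.array([[x, y, z] for x in g for y in g for z in g])
        res = alpha_shape_volume(pts, alpha=0.17)
        assert res.volume_A3 == pytest.approx(1000.0, rel=0.10)

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(0)
        pts = rng.random((60, 3))
        vols = [alpha_shape_volume(pts, a).volume_A3 for a in (0.1, 0.2, 0.4, 0.8)]
        assert vols == sorted(vols)

    def test_converges_to_convex_hull(self):
        rng = np.random.default_rng(1)
        pts = rng.random((80, 3))
        hull = ConvexHull(pts).volume * 1000.0
        res = alpha_shape_volume(pts, alpha=1e3)
        assert res.volume_A3 == pytest.approx(hull, rel=1e-6)

    def test_translation_rotation_invariance(self):
        rng = np.random.default_rng(2)
        pts = rng.random((50, 3))
        v0 = alpha_shape_volume(pts, 0.3).volume_A3
        ang = 0.9
        rot = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        )
        moved = pts @ rot.T + 5.0
        v1 = alpha_shape_volume(moved, 0.3).volume_A3
        assert v1 == pytest.approx(v0, rel=1e-6)


class TestAlphaArea:
    def test_right_triangle_area(self):
        pts = np.array([[0, 0], [0.1, 0], [0, 0.1]])
        res = alpha_area_2d(pts, alpha=0.17)
        assert res.area_nm2 == pytest.approx(0.005, rel=1e-6)

    def test_collinear_zero(self):
        pts = np.array([[0, 0], [0.1, 0], [0.2, 0], [0.3, 0]])
        assert alpha_area_2d(pts).area_nm2 == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            alpha_area_2d(np.zeros((2, 2)))

    def test_rotation_invariance(self):
        rng = np.random.default_rng(3)
        pts = 0.3 * rng.random((30, 2))
        a0 = alpha_area_2d(pts, 0.17).area_nm2
        ang = 1.3
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        a1 = alpha_area_2d(pts @ rot.T, 0.17).area_nm2
        assert a1 == pytest.approx(a0, abs=1e-10 + 1e-6 * a0)


class TestContactArea:
    def test_bound_proximity_selection(self):
        # 3 hydroxyl O hovering 0.3 nm above a fake ice sheet; 3 far away
        pos, species, role, bonds = [], [], [], []
        for i in range(4):
            for j in range(4):
                pos.append([0.3 * i + 0.5, 0.3 * j + 0.5, 1.0])
                species.append("O")
                role.append("water_O")
        near = [[0.6, 0.6, 1.3], [0.8, 0.6, 1.3], [0.6, 0.8, 1.3]]
        far = [[2.5, 2.5, 2.5], [2.7, 2.5, 2.5], [2.5, 2.7, 2.5]]
        for p in near + far:
            pos.append(p)
            species.append("O")
            role.append("hydroxyl_O")
        cfg = Configuration(pos, species, role, [4.0, 4.0, 4.0])
        labels = largest_ice_cluster(cfg, classify_ice(cfg, threshold=-2.0), 0.35)
        res = contact_area(cfg, labels, alpha=0.25, bound_only=True)
        assert res.n_vertices == 3
        assert res.area_nm2 == pytest.approx(0.5 * 0.2 * 0.2, rel=1e-6)

    def test_no_polymer_rejected(self, ice_slab):
        labels = largest_ice_cluster(ice_slab, classify_ice(ice_slab), 0.35)
        with pytest.raises(IceKitError):
            contact_area(ice_slab, labels)


class TestMinImageDistance:
    def _poly(self, positions, box, pbc="xy"):
        n = len(positions)
        return Configuration(
            positions, ["C"] * n, ["backbone_C"] * n, box, pbc_mode=pbc
        )

    def test_single_atom(self):
        cfg = self._poly([[2.0, 2.0, 2.0]], [4.0, 4.0, 8.0])
        assert min_image_distance(cfg) == pytest.approx(4.0)

    def test_segment_along_x(self):
        cfg = self._poly([[1.0, 2.0, 2.0], [2.5, 2.0, 2.0]], [4.0, 6.0, 8.0])
        assert min_image_distance(cfg) == pytest.approx(2.5)

    @pytest.mark.parametrize("pbc", ["xy", "xyz"])
    def test_matches_image_oracle(self, pbc):
        rng = np.random.default_rng(0)
        for trial in range(10):
            n = int(rng.integers(2, 12))
            box = 2.0 + 3.0 * rng.random(3)
            pts = rng.random((n, 3)) * box
            cfg = self._poly(pts, box, pbc)
            assert min_image_distance(cfg) == pytest.approx(
                brute_rmi(pts, box, pbc), rel=1e-12
            )

    def test_lower_bound_inequality(self):
        rng = np.random.default_rng(5)
        box = np.array([5.0, 6.0, 7.0])
        pts = 2.0 + rng.random((8, 3))  # fully inside, extent <= sqrt(3)
        cfg = self._poly(pts, box)
        extent = np.max(
            np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        )
        assert min_image_distance(cfg) >= min(box[0], box[1]) - extent - 1e-12


class TestFrontProfile:
    def _composite(self, z_lo, z_hi, box_z=8.0):
        """Fake slab: dense fake-ice layer between z_lo..z_hi plus liquid."""
        rng = np.random.default_rng(0)
        pos, role = [], []
        # ice: regular grid
        zs = np.arange(z_lo + 0.05, z_hi, 0.1)
        for z in zs:
            for i in range(6):
                for j in range(6):
                    pos.append([0.25 + 0.3 * i, 0.25 + 0.3 * j, z])
                    role.append("water_O")
        n_ice = len(pos)
        # liquid above and below, sparse (fraction < 0.5 per bin)
        for _ in range(300):
            z = rng.random() * box_z
            if z_lo - 0.2 < z < z_hi + 0.2:
                continue
            pos.append([rng.random() * 2.0, rng.random() * 2.0, z])
            role.append("water_O")
        cfg = Configuration(
            pos, ["O"] * len(pos), role, [2.0, 2.0, box_z], pbc_mode="xy"
        )
        s6 = np.array([1.0] * n_ice + [0.0] * (len(pos) - n_ice))
        from icekit.icedetect import IceLabels, largest_ice_cluster

        labels = IceLabels(
            np.arange(len(pos)), s6, s6 > 0.45, 0.45
        )
        return cfg, largest_ice_cluster(cfg, labels, 0.35)

    def test_slab_fronts_recovered(self):
        cfg, labels = self._composite(2.0, 6.0)
        prof = front_profile(cfg, labels, bin_width=0.05)
        assert prof.lower_front == pytest.approx(2.0, abs=0.1)
        assert prof.upper_front == pytest.approx(6.0, abs=0.1)
        assert np.all((prof.ice_fraction >= 0) & (prof.ice_fraction <= 1))
        assert prof.upper_front >= prof.lower_front

    def test_all_ice_fronts_at_edges(self):
        cfg, labels = self._composite(0.0, 8.0)
        prof = front_profile(cfg, labels, bin_width=0.05)
        assert prof.lower_front == pytest.approx(0.0, abs=0.1)
        assert prof.upper_front == pytest.approx(8.0, abs=0.1)

    def test_advancement_three_angstrom_per_frame(self):
        profiles = []
        for k in range(4):
            cfg, labels = self._composite(3.0 - 0.3 * k, 5.0 + 0.3 * k)
            profiles.append(front_profile(cfg, labels, 0.05))
        adv = front_advancement(profiles)
        assert np.allclose(np.diff(adv), 3.0, atol=1.0)

    def test_no_ice_rejected(self):
        cfg, labels = self._composite(2.0, 6.0)
        labels.ice[:] = False
        labels.cluster_id[:] = -1
        labels.largest_cluster_size = 0
        with pytest.raises(IceKitError):
            front_profile(cfg, labels)


class TestSurfaceCoverage:
    def test_zero_polymers(self):
        assert surface_coverage(0, [5.0, 5.0, 10.0]) == 0.0

    def test_size_m_worked_example(self):
        # one polymer on a 26.1 nm^2 cross-section -> 0.04 polymers/nm^2
        box = [np.sqrt(26.1), np.sqrt(26.1), 10.0]
        assert round(surface_coverage(1, box), 2) == 0.04

    def test_size_s(self):
        box = [np.sqrt(13.3), np.sqrt(13.3), 10.0]
        assert surface_coverage(2, box) == pytest.approx(0.150, abs=5e-4)

    def test_invalid_box(self):
        with pytest.raises(IceKitError):
            surface_coverage(1, [0.0, 5.0, 5.0])
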