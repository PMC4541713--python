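import itertools
import math

import numpy as np
import pytest

from idiotopo import (Triangulation2D, Z2EdgeConfig, deficit_angles,
                      octahedron, read_off, regge_action, sigma_from_state,
                      state_from_sigma, tetrahedron, torus16,
                      triangle_geometry, write_off, z2_regge_partition)
from idiotopo.regge import partition_scan


def naive_z2_partition(tri, l_amp, x, zeta, alpha):
    """Independent nested-loop oracle over all sign configurations, computing
    the action from per-configuration areas and deficit angles directly."""
    Z = 0.0
    n_valid = 0
    for signs in itertools.product((-1, 1), repeat=tri.n_edges):
        cfg = Z2EdgeConfig(sigma=np.array(signs), l_amp=l_amp, alpha=alpha)
        if not cfg.is_valid(tri):
            continue
        n_valid += 1
        q = cfg.q
        area = sum(triangle_geometry(q[e1], q[e2], q[e3])[0]
                   for e1, e2, e3 in tri.triangle_edges())
        deficit = float(deficit_angles(tri, cfg).sum())
        action = x * (area - zeta * deficit)
        Z += float(np.prod(q ** -alpha)) * math.exp(-action)
    return Z, n_valid


class TestTriangulation:
    @pytest.mark.parametrize("tri,V,E,F,chi", [
        (tetrahedron(), 4, 6, 4, 2),
        (octahedron(), 6, 12, 8, 2),
        (torus16(), 8, 24, 16, 0),
    ])
    def test_fixture_counts_and_euler(self, tri, V, E, F, chi):
        assert tri.n_vertices == V and tri.n_edges == E
        assert len(tri.triangles) == F
        assert tri.euler_characteristic() == chi

    def test_open_surface_rejected(self):
        with pytest.raises(ValueError, match="closed"):
            Triangulation2D(3, [(0, 1, 2)])

    def test_off_roundtrip(self, tmp_path):
        tri = torus16()
        p = tmp_path / "torus.off"
        write_off(tri, str(p))
        tri2 = read_off(str(p))
        assert tri2.triangles == tri.triangles
        assert tri2.n_vertices == tri.n_vertices


class TestTriangleGeometry:
    def test_equilateral(self):
        area, angles = triangle_geometry(1, 1, 1)
        assert area == pytest.approx(math.sqrt(3) / 4)
        assert np.allclose(angles, math.pi / 3)

    def test_right_isoceles(self):
        area, angles = triangle_geometry(1, 1, 2)
        assert area == pytest.approx(0.5)
        assert sorted(angles) == pytest.approx([math.pi / 4, math.pi / 4,
                                                math.pi / 2])

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="triangle inequality"):
            triangle_geometry(1, 1, 4)

    def test_angles_sum_to_pi(self):
        rng = np.random.default_rng(30)
        for _ in range(20):
            q = 1 + 0.8 * rng.uniform(-1, 1, 3)
            try:
                _, angles = triangle_geometry(*q)
            except ValueError:
                continue
            assert sum(angles) == pytest.approx(math.pi, abs=1e-12)


class TestDeficitAngles:
    def test_flat_tetrahedron_deficits(self):
        cfg = Z2EdgeConfig(sigma=np.ones(6, int), l_amp=0.0)
        deficits = deficit_angles(tetrahedron(), cfg)
        assert np.allclose(deficits, math.pi)

    @pytest.mark.parametrize("tri,chi", [(tetrahedron(), 2), (octahedron(), 2),
                                         (torus16(), 0)])
    def test_gauss_bonnet(self, tri, chi):
        rng = np.random.default_rng(31)
        done = 0
        while done < 20:
            cfg = Z2EdgeConfig(sigma=rng.choice([-1, 1], tri.n_edges),
                               l_amp=float(rng.uniform(0, 0.6)))
            if not cfg.is_valid(tri):
                continue
            total = float(deficit_angles(tri, cfg).sum())
            assert total == pytest.approx(2 * math.pi * chi, abs=1e-9)
            done += 1

    def test_invalid_config_rejected(self):
        # l close to 1 makes (1-l, 1-l, 1+l) strongly violating
        tri = tetrahedron()
        sigma = np.array([1, -1, -1, 1, 1, 1])
        cfg = Z2EdgeConfig(sigma=sigma, l_amp=0.99)
        if not cfg.is_valid(tri):
            with pytest.raises(ValueError):
                deficit_angles(tri, cfg)


class TestReggeAction:
    def test_zeta_zero_is_total_area(self):
        tri = tetrahedron()
        cfg = Z2EdgeConfig(sigma=np.ones(6, int), l_amp=0.0)
        assert regge_action(tri, cfg, x=2.0, zeta=0.0) == \
            pytest.approx(2.0 * 4 * math.sqrt(3) / 4)

    def test_flat_tetrahedron_closed_form(self):
        cfg = Z2EdgeConfig(sigma=np.ones(6, int), l_amp=0.0)
        A = regge_action(tetrahedron(), cfg, x=1.0, zeta=1.0)
        assert A == pytest.approx(math.sqrt(3) - 4 * math.pi)

    def test_linear_in_x(self):
        rng = np.random.default_rng(32)
        tri = octahedron()
        cfg = Z2EdgeConfig(sigma=rng.choice([-1, 1], 12), l_amp=0.3)
        A1 = regge_action(tri, cfg, x=1.0, zeta=0.7)
        A2 = regge_action(tri, cfg, x=2.0, zeta=0.7)
        assert A2 == pytest.approx(2 * A1)


class TestZ2Partition:
    def test_zero_amplitude_all_configs_identical(self):
        tri = tetrahedron()
        cfg = Z2EdgeConfig(sigma=np.ones(6, int), l_amp=0.0)
        A = regge_action(tri, cfg, x=1.0, zeta=1.0)
        Z = z2_regge_partition(tri, 0.0, 1.0, 1.0, 0.0)
        assert Z == pytest.approx(2 ** 6 * math.exp(-A), rel=1e-12)

    @pytest.mark.parametrize("l_amp,alpha", [(0.3, 0.0), (0.5, 1.5)])
    def test_matches_nested_loop_oracle_on_tetrahedron(self, l_amp, alpha):
        tri = tetrahedron()
        Z, n_valid = z2_regge_partition(tri, l_amp, 1.0, 1.0, alpha,
                                        return_count=True)
        Z_ref, n_ref = naive_z2_partition(tri, l_amp, 1.0, 1.0, alpha)
        assert n_valid == n_ref
        assert Z == pytest.approx(Z_ref, rel=1e-12)

    def test_large_amplitude_excludes_configs(self):
        Z, n_valid = z2_regge_partition(tetrahedron(), 0.95, 1.0, 1.0, 0.0,
                                        return_count=True)
        assert n_valid < 2 ** 6
        _, n_ref = naive_z2_partition(tetrahedron(), 0.95, 1.0, 1.0, 0.0)
        assert n_valid == n_ref

    def test_monotone_decreasing_in_x_for_positive_action(self):
        tri = tetrahedron()
        zs = [z2_regge_partition(tri, 0.2, x, 0.0, 0.0) for x in (0.5, 1.0, 2.0)]
        assert zs[0] > zs[1] > zs[2]

    def test_global_flip_pairs_valid_configs(self):
        """At moderate amplitude every σ -> -σ partner of a valid tetrahedron
        configuration is itself valid, so valid configurations pair up and
        the state sum can be folded over the flip at alpha = 0."""
        tri = tetrahedron()
        l_amp = 0.4  # below the 3/5 threshold where two-short-one-long fails
        folded = 0.0
        for signs in itertools.product((-1, 1), repeat=tri.n_edges):
            cfg = Z2EdgeConfig(sigma=np.array(signs), l_amp=l_amp)
            flipped = Z2EdgeConfig(sigma=-np.array(signs), l_amp=l_amp)
            assert cfg.is_valid(tri) and flipped.is_valid(tri)
            if signs[0] == 1:  # one representative per {σ, -σ} pair
                for rep in (cfg, flipped):
                    folded += math.exp(-regge_action(tri, rep, 1.0, 1.0))
        assert folded == pytest.approx(z2_regge_partition(tri, l_amp, 1.0, 1.0),
                                       rel=1e-12)

    def test_cap_enforced(self):
        with pytest.raises(ValueError, match="cap"):
            z2_regge_partition(torus16(), 0.1, 1.0, 1.0, cap=20)

    def test_partition_scan_table(self):
        df = partition_scan(tetrahedron(), [0.0, 0.3], 1.0, 1.0)
        assert list(df.columns) == ["l_amp", "x", "zeta", "alpha", "Z",
                                    "n_valid_configs"]
        assert df["n_valid_configs"].iloc[0] == 64


class TestStateConversion:
    def test_roundtrip(self):
        c = np.array([0, 1, 1, 0, 1])
        assert np.array_equal(state_from_sigma(sigma_from_state(c)), c)

    def test_sigma_values(self):
        assert np.array_equal(sigma_from_state([0, 1]), [-1, 1])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sigma_from_state([0, 2])
        with pytest.raises(ValueError):
            state_from_sigma([0, 1])
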