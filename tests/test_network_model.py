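import itertools

import numpy as np
import pytest

from idiotopo import (CouplingModel, ImmuneState, clique_complex, energy,
                      heaviside, linear_mean_field, multilinear_mean_field)
from idiotopo.network_model import (read_higher_json, read_pairwise_tsv,
                                    read_states_csv, write_higher_json,
                                    write_pairwise_tsv, write_states_csv)

from conftest import random_pairwise_model


class TestHeaviside:
    @pytest.mark.parametrize("x,expected", [(-0.5, 0), (2.0, 1), (0.0, 1),
                                            (-1e-12, 0), (1e-12, 1)])
    def test_threshold_convention(self, x, expected):
        assert heaviside(x) == expected

    def test_zero_is_configurable(self):
        assert heaviside(0.0, at_zero=0) == 0

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            heaviside(float("nan"))


class TestImmuneState:
    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            ImmuneState(c=(0, 2))

    def test_array_roundtrip(self):
        s = ImmuneState.from_array(np.array([1, 0, 1]))
        assert tuple(s.as_array()) == (1, 0, 1)


class TestCouplingModel:
    def test_rejects_nonzero_diagonal(self):
        with pytest.raises(ValueError, match="diagonal"):
            CouplingModel(N=2, pairwise=np.array([[1.0, 0], [0, 0]]))

    def test_rejects_asymmetry(self):
        with pytest.raises(ValueError, match="symmetric"):
            CouplingModel(N=2, pairwise=np.array([[0, 1.0], [0.5, 0]]))

    def test_rejects_bad_higher_key(self):
        with pytest.raises(ValueError):
            CouplingModel(N=4, higher={(2, 1, 0): -1.0})
        with pytest.raises(ValueError):
            CouplingModel(N=3, higher={(0, 1): -1.0})

    def test_strict_range_enforced(self):
        J = np.array([[0, 1.5], [1.5, 0]])
        CouplingModel(N=2, pairwise=J)  # allowed by default
        with pytest.raises(ValueError, match="strict_range"):
            CouplingModel(N=2, pairwise=J, strict_range=True)


class TestLinearMeanField:
    def test_hand_examples(self, pair_model):
        assert linear_mean_field([1, 1], pair_model).h == (0.5, 0.5)
        m = CouplingModel(N=2, S=-0.2, pairwise=np.array([[0, 1.0], [1.0, 0]]))
        h = linear_mean_field([0, 1], m).as_array()
        assert np.allclose(h, [0.8, -0.2])

    def test_all_zero_state_gives_threshold(self):
        m = random_pairwise_model(np.random.default_rng(0), 5, S=0.7)
        assert np.allclose(linear_mean_field([0] * 5, m).as_array(), 0.7)

    def test_length_mismatch_errors(self, pair_model):
        with pytest.raises(ValueError):
            linear_mean_field([1, 0, 1], pair_model)


class TestMultilinearMeanField:
    def test_pairwise_only_reduces_to_linear(self):
        rng = np.random.default_rng(1)
        m = random_pairwise_model(rng, 6)
        cx = m.complex()
        for _ in range(10):
            c = rng.integers(0, 2, 6)
            assert np.allclose(multilinear_mean_field(c, m, cx).as_array(),
                               linear_mean_field(c, m).as_array())

    def test_triangle_contribution(self):
        J = np.full((3, 3), -0.5); np.fill_diagonal(J, 0)
        m = CouplingModel(N=3, pairwise=J, higher={(0, 1, 2): -1.0})
        cx = m.complex()
        h = multilinear_mean_field([1, 1, 1], m, cx).as_array()
        # pairwise part -1 per vertex, triangle adds -1*c_j*c_k = -1
        assert np.allclose(h, [-2.0, -2.0, -2.0])
        h = multilinear_mean_field([1, 0, 1], m, cx).as_array()
        assert h[0] == pytest.approx(-0.5)  # triangle annihilated by c_1 = 0

    def test_multilinearity_zeroing(self):
        """Zeroing c_j removes exactly the simplex terms containing j."""
        rng = np.random.default_rng(2)
        J = np.full((4, 4), -0.3); np.fill_diagonal(J, 0)
        m = CouplingModel(N=4, pairwise=J,
                          higher={(0, 1, 2): -0.7, (0, 1, 3): 0.4,
                                  (0, 1, 2, 3): -0.2})
        cx = m.complex()
        c = np.array([1, 1, 0, 1])
        h_drop = multilinear_mean_field(c, m, cx).as_array()
        # vertex 3 loses the pairwise J_32 term and the 4-cell, keeps (0,1,3)
        assert h_drop[3] == pytest.approx(m.S + J[3, 0] + J[3, 1] + 0.4)

    def test_non_simplex_key_errors(self):
        m = CouplingModel(N=3, higher={(0, 1, 2): -1.0})
        cx = clique_complex([(0, 1)], N=3)  # no triangle present
        with pytest.raises(ValueError, match="not a simplex"):
            multilinear_mean_field([1, 1, 1], m, cx)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            m = random_pairwise_model(rng, 6, edge_prob=0.6)
            cx = m.complex()
            c = rng.integers(0, 2, 6)
            perm = rng.permutation(6)
            h = multilinear_mean_field(c, m, cx).as_array()
            Jp = m.pairwise[np.ix_(perm, perm)]
            mp = CouplingModel(N=6, S=m.S, pairwise=Jp)
            hp = multilinear_mean_field(c[perm], mp, mp.complex()).as_array()
            assert np.allclose(hp, h[perm])


class TestEnergy:
    def test_zero_state_zero_energy(self):
        m = random_pairwise_model(np.random.default_rng(4), 5, S=1.3)
        assert energy([0] * 5, m) == 0.0

    def test_two_body_double_count(self, pair_model):
        assert energy([1, 1], pair_model) == pytest.approx(1.0)  # 2J

    def test_single_vertex_threshold(self):
        m = CouplingModel(N=1, S=0.3)
        assert energy([1], m) == pytest.approx(0.3)

    def test_symmetry_double_count_identity(self):
        """Pairwise-only, S=0: E(c) = 2 Σ_{i<k} J_ik c_i c_k, all configs."""
        rng = np.random.default_rng(5)
        for N in (3, 5, 8):
            m = random_pairwise_model(rng, N)
            for c in itertools.product((0, 1), repeat=N):
                c = np.array(c)
                expected = 2 * sum(m.pairwise[i, k] * c[i] * c[k]
                                   for i in range(N) for k in range(i + 1, N))
                assert energy(c, m) == pytest.approx(expected, abs=1e-12)


class TestFileFormats:
    def test_pairwise_tsv_roundtrip(self, tmp_path):
        m = random_pairwise_model(np.random.default_rng(6), 6, S=-0.1)
        p = tmp_path / "pairwise.tsv"
        write_pairwise_tsv(m, str(p))
        m2 = read_pairwise_tsv(str(p), N=6, S=-0.1)
        assert np.allclose(m.pairwise, m2.pairwise)

    def test_higher_json_roundtrip(self, tmp_path):
        higher = {(0, 1, 2): -0.25, (1, 2, 3, 4): 0.5}
        p = tmp_path / "higher.json"
        write_higher_json(higher, str(p))
        assert read_higher_json(str(p)) == higher

    def test_states_csv_roundtrip(self, tmp_path):
        states = [ImmuneState((1, 0, 1)), ImmuneState((0, 0, 1))]
        p = tmp_path / "states.csv"
        write_states_csv(states, str(p))
        assert read_states_csv(str(p)) == states
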