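"""State space, propensities, and the sparse generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burstfit import ParameterSet, StateSpace, build_rate_matrix, build_two_state_model
from burstfit.model import ModelSpec, Reaction


class TestStateSpace:
    def test_size_and_bijection(self):
        space = StateSpace(M=500, p=3)
        assert space.N == 3 * 501 == 1503
        rho1, m = space.states()
        idx = space.index(rho1, m)
        assert np.array_equal(idx, np.arange(space.N))
        r2, m2 = space.decode(idx)
        assert np.array_equal(r2, rho1) and np.array_equal(m2, m)

    def test_out_of_range_rejected(self):
        space = StateSpace(M=10, p=3)
        with pytest.raises(IndexError):
            space.index(3, 0)
        with pytest.raises(IndexError):
            space.index(0, 11)
        with pytest.raises(IndexError):
            space.decode(space.N)


class TestTwoStateModel:
    def test_diploid_structure(self, two_state):
        assert two_state.p == 3
        assert len(two_state.reactions) == 4

    def test_haploid_activation_saturates(self):
        model = build_two_state_model(1)
        assert model.p == 2
        theta = {"k1": 0.7, "k0": 0.2, "mu0": 0.0, "mu1": 1.0, "delta": 0.1}
        acts = model.propensities(np.array([1]), np.array([0]), theta)[0]
        assert acts[0] == 0.0  # no inactive allele left to activate

    def test_propensity_values(self, two_state):
        theta = {"k1": 0.01, "k0": 0.1, "mu0": 0.01, "mu1": 2.0, "delta": 0.05}
        vals = [a[0] for a in two_state.propensities(np.array([1]), np.array([3]), theta)]
        assert vals == pytest.approx([0.01, 0.1, 2.01, 0.15])

    def test_invalid_allele_count(self):
        with pytest.raises(ValueError):
            build_two_state_model(0)

    def test_reaction_stoichiometry_validated(self):
        with pytest.raises(ValueError):
            Reaction("bad", (1, 1), lambda r, m, th: r)
        with pytest.raises(ValueError):
            Reaction("bad", (0, 2), lambda r, m, th: r)


class TestParameterSet:
    def test_free_vector_roundtrip(self, k1_preset):
        assert k1_preset.free_names == ("k1_U", "k1_S", "k0", "mu0", "mu1")
        vec = k1_preset.to_free_vector()
        assert vec == pytest.approx([0.01, 1.0, 0.1, 0.01, 2.0])
        again = k1_preset.with_free_vector(vec * 2)
        assert again.to_free_vector() == pytest.approx(vec * 2)
        assert again.values_U["delta"] == 0.05  # fixed parameter untouched

    def test_non_stimulus_mismatch_rejected(self, two_state):
        model = ModelSpec(2, two_state.reactions, two_state.parameter_names, ("k1",))
        vu = {"k1": 0.1, "k0": 0.1, "mu0": 0.1, "mu1": 1.0, "delta": 0.05}
        vs = dict(vu, k0=0.2)  # k0 not a stimulus parameter
        with pytest.raises(ValueError, match="k0"):
            ParameterSet(model, vu, vs)

    def test_negative_values_rejected(self, two_state):
        vu = {"k1": -0.1, "k0": 0.1, "mu0": 0.1, "mu1": 1.0, "delta": 0.05}
        with pytest.raises(ValueError):
            ParameterSet(two_state, vu, dict(vu))


def _dense_generator_oracle(model, theta, space):
    """Independent brute-force enumeration of all transitions."""
    A = np.zeros((space.N, space.N))
    for rho in range(space.p):
        for m in range(space.M + 1):
            i = rho * (space.M + 1) + m
            props = model.propensities(np.array([rho]), np.array([m]), theta)
            for reaction, a in zip(model.reactions, props):
                d_rho, d_m = reaction.stoich
                r2, m2 = rho + d_rho, m + d_m
                if 0 <= r2 < space.p and 0 <= m2 <= space.M:
                    j = r2 * (space.M + 1) + m2
                    A[j, i] += a[0]
                    A[i, i] -= a[0]
    return A


class TestRateMatrix:
    def test_matches_dense_enumeration(self, two_state):
        space = StateSpace(M=2, p=3)
        theta = {"k1": 0.3, "k0": 0.7, "mu0": 0.2, "mu1": 1.1, "delta": 0.4}
        A = build_rate_matrix(two_state, theta, space).toarray()
        assert A == pytest.approx(_dense_generator_oracle(two_state, theta, space))

    def test_dimension(self, two_state):
        A = build_rate_matrix(
            two_state,
            {"k1": 0.01, "k0": 0.1, "mu0": 0.01, "mu1": 2.0, "delta": 0.05},
            StateSpace(M=500, p=3),
        )
        assert A.shape == (1503, 1503)

    def test_zero_rates_give_zero_matrix(self, two_state):
        theta = dict.fromkeys(two_state.parameter_names, 0.0)
        A = build_rate_matrix(two_state, theta, StateSpace(M=10, p=3))
        assert A.nnz == 0

    def test_negative_theta_rejected(self, two_state):
        theta = {"k1": -1.0, "k0": 0.1, "mu0": 0.01, "mu1": 2.0, "delta": 0.05}
        with pytest.raises(ValueError):
            build_rate_matrix(two_state, theta, StateSpace(M=10, p=3))

    def test_space_model_mismatch_rejected(self, two_state):
        theta = dict.fromkeys(two_state.parameter_names, 0.1)
        with pytest.raises(ValueError):
            build_rate_matrix(two_state, theta, StateSpace(M=10, p=2))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        k1=st.floats(0, 5), k0=st.floats(0, 5), mu0=st.floats(0, 5),
        mu1=st.floats(0, 10), delta=st.floats(0.001, 2),
    )
    def test_probability_conservation(self, two_state, k1, k0, mu0, mu1, delta):
        """Columns of the generator sum to zero for any nonnegative rates."""
        theta = {"k1": k1, "k0": k0, "mu0": mu0, "mu1": mu1, "delta": delta}
        A = build_rate_matrix(two_state, theta, StateSpace(M=15, p=3))
        scale = max(np.abs(A.data).max(), 1.0) if A.nnz else 1.0
        assert np.abs(np.asarray(A.sum(axis=0))).max() <= 1e-12 * scale

    def test_sign_pattern(self, two_state, theta_basic):
        A = build_rate_matrix(two_state, theta_basic, StateSpace(M=30, p=3)).tocoo()
        off = A.row != A.col
        assert np.all(A.data[off] >= 0)
        assert np.all(A.diagonal() <= 0)

    def test_promoter_lumping_is_birth_death(self, two_state, theta_basic):
        """Summing mRNA states per promoter block recovers the 3-state
        promoter chain with rates 2k1, k1 up and k0, 2k0 down."""
        space = StateSpace(M=12, p=3)
        A = build_rate_matrix(two_state, theta_basic, space).toarray()
        k1, k0 = theta_basic["k1"], theta_basic["k0"]
        expected_up = {0: 2 * k1, 1: k1, 2: 0.0}
        expected_down = {0: 0.0, 1: k0, 2: 2 * k0}
        for rho in range(3):
            for m in range(space.M + 1):
                col = A[:, rho * 13 + m]
                for r2, expected in (
                    (rho + 1, expected_up[rho]),
                    (rho - 1, expected_down[rho]),
                ):
                    if 0 <= r2 <= 2:
                        flow = col[r2 * 13 : (r2 + 1) * 13].sum()
                        assert flow == pytest.approx(expected, abs=1e-14)

    def test_absorbing_variant_leaks_at_boundary(self, two_state, theta_basic):
        space = StateSpace(M=5, p=3)
        A = build_rate_matrix(two_state, theta_basic, space, absorbing=True)
        colsums = np.asarray(A.sum(axis=0)).ravel()
        boundary = [space.index(r, space.M) for r in range(3)]
        assert np.all(colsums[boundary] < 0)  # synthesis outflow retained
        interior = np.setdiff1d(np.arange(space.N), boundary)
        assert np.abs(colsums[interior]).max() < 1e-14
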