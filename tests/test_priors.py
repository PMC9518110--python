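import numpy as np
import pytest
from scipy import stats

from stcar.data import PanelData
from stcar.graphs import RegionGraph, lattice_graph
from stcar.priors import (
    ModelSpec,
    ModelStructures,
    ParameterState,
    apply_constraints,
    gmrf_logkernel,
    linear_predictor,
    log_posterior,
    log_prior,
    poisson_loglik,
)
from stcar.structures import icar_structure, interaction_structure, rw1_structure


def random_constrained_state(data, spec, seed):
    rng = np.random.default_rng(seed)
    st = ParameterState(
        alpha=rng.normal(), beta=rng.normal(size=data.m),
        u=rng.normal(size=data.n), v=rng.normal(size=data.n),
        gamma=rng.normal(size=data.Z), psi=rng.normal(size=(data.n, data.Z)),
        tau_u=rng.uniform(0.5, 5), tau_v=rng.uniform(0.5, 5),
        tau_gamma=rng.uniform(0.5, 5), tau_psi=rng.uniform(0.5, 5),
    )
    return apply_constraints(st, spec, data.graph)


def dense_log_posterior(state, spec, data, structures):
    """Brute-force oracle: explicit loops + scipy densities + dense matrices."""
    lp = 0.0
    for i in range(data.n):
        for t in range(data.Z):
            eta = (state.alpha + float(data.X[i, t] @ state.beta) + state.u[i]
                   + state.v[i] + state.gamma[t] + state.psi[i, t])
            lp += stats.poisson.logpmf(data.Y[i, t], data.E[i, t] * np.exp(eta))
    tb = spec.beta_prior_precision
    for b in state.beta:
        lp += 0.5 * np.log(tb) - 0.5 * tb * (b - spec.beta_prior_mean) ** 2
    fields = {"u": state.u, "v": state.v, "gamma": state.gamma,
              "psi": state.psi.ravel()}
    for blk in spec.active_blocks:
        R = structures[blk].dense()
        tau = state.tau(blk)
        lp += 0.5 * structures[blk].rank * np.log(tau)
        lp -= 0.5 * tau * fields[blk] @ R @ fields[blk]
        lp += stats.gamma.logpdf(tau, a=spec.hyper_shape[blk],
                                 scale=1.0 / spec.hyper_rate[blk])
    return lp


@pytest.fixture()
def tiny_data(path3_graph):
    rng = np.random.default_rng(9)
    n, Z = 3, 4
    N = np.full((n, Z), 200.0)
    Y = rng.poisson(30, size=(n, Z))
    E = N * Y.sum() / N.sum()
    X = rng.normal(size=(n, Z, 2))
    return PanelData(path3_graph, Y, N, E, X, ("x1", "x2"))


class TestGmrfLogkernel:
    def test_zero_field_gives_rank_term_only(self, path3_graph):
        R = icar_structure(path3_graph)
        assert gmrf_logkernel(np.zeros(3), R, 2.0) == pytest.approx(
            0.5 * R.rank * np.log(2.0))

    def test_path_icar_hand_value(self, path3_graph):
        R = icar_structure(path3_graph)
        # qf of (1,0,-1) on the path = (1-0)^2 + (0+1)^2 = 2; tau=1 -> -1
        assert gmrf_logkernel(np.array([1.0, 0.0, -1.0]), R, 1.0) == pytest.approx(-1.0)

    def test_dimension_mismatch_rejected(self, path3_graph):
        with pytest.raises(ValueError):
            gmrf_logkernel(np.zeros(5), icar_structure(path3_graph), 1.0)

    @pytest.mark.parametrize("Z", [3, 5])
    def test_matches_constrained_gaussian_by_eigendecomposition(self, Z):
        """Kernel differences equal the exact constrained-Gaussian log-density
        differences, brute-forced from the spectral decomposition."""
        R = rw1_structure(Z)
        tau = 1.7
        w, V = np.linalg.eigh(R.dense())
        keep = w > 1e-8
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=Z)
            y = rng.normal(size=Z)
            x -= x.mean()  # constrain to the row space
            y -= y.mean()
            exact = -0.5 * tau * (x @ V[:, keep] * w[keep] @ (V[:, keep].T @ x))
            exact -= -0.5 * tau * (y @ V[:, keep] * w[keep] @ (V[:, keep].T @ y))
            ours = gmrf_logkernel(x, R, tau) - gmrf_logkernel(y, R, tau)
            assert ours == pytest.approx(exact, abs=1e-8)


class TestLinearPredictorAndLoglik:
    def test_null_state_gives_mu_equal_E(self, tiny_data):
        st = ParameterState.zeros(3, 4, 2)
        f = linear_predictor(tiny_data, st)
        np.testing.assert_allclose(f.eta, 0.0)
        np.testing.assert_allclose(f.mu, tiny_data.E)

    def test_intercept_only_scales_by_e(self, tiny_data):
        st = ParameterState.zeros(3, 4, 2)
        st.alpha = 1.0
        f = linear_predictor(tiny_data, st)
        np.testing.assert_allclose(f.mu / tiny_data.E, np.e)

    def test_all_terms_sum(self):
        g = RegionGraph(("A",), ((),))
        data = PanelData(g, [[3]], [[10.0]], [[2.0]], np.full((1, 1, 1), 1.0), ("x",))
        st = ParameterState(alpha=0.5, beta=np.array([0.25]), u=np.array([0.1]),
                            v=np.array([0.05]), gamma=np.array([-0.2]),
                            psi=np.array([[0.3]]))
        assert linear_predictor(data, st).eta[0, 0] == pytest.approx(1.0)

    def test_dimension_mismatch_names_block(self, tiny_data):
        st = ParameterState.zeros(3, 4, 2)
        st.u = np.zeros(5)
        with pytest.raises(ValueError, match="'u'"):
            linear_predictor(tiny_data, st)

    def test_poisson_loglik_hand_values(self):
        g = RegionGraph(("A",), ((),))
        d0 = PanelData(g, [[0]], [[1.0]], [[1.0]], np.zeros((1, 1, 0)))
        st = ParameterState.zeros(1, 1, 0)
        assert poisson_loglik(d0, linear_predictor(d0, st)) == pytest.approx(-1.0)
        d2 = PanelData(g, [[2]], [[1.0]], [[1.0]], np.zeros((1, 1, 0)))
        assert poisson_loglik(d2, linear_predictor(d2, st)) == pytest.approx(
            -1.0 - np.log(2.0))

    def test_loglik_invariant_to_cell_shuffling(self, tiny_data):
        st = ParameterState.zeros(3, 4, 2)
        st.alpha = 0.3
        base = poisson_loglik(tiny_data, linear_predictor(tiny_data, st))
        perm = np.random.default_rng(1).permutation(3)
        g2 = RegionGraph(tuple(f"R{i}" for i in range(3)), ((), (), ()))
        shuffled = PanelData(g2, tiny_data.Y[perm], tiny_data.N[perm],
                             tiny_data.E[perm], tiny_data.X[perm], ("x1", "x2"))
        assert poisson_loglik(shuffled, linear_predictor(shuffled, st)) == pytest.approx(base)

    def test_cellwise_mle_at_log_ratio(self):
        g = RegionGraph(("A",), ((),))
        d = PanelData(g, [[7]], [[10.0]], [[2.0]], np.zeros((1, 1, 0)))
        st = ParameterState.zeros(1, 1, 0)
        best = np.log(7.0 / 2.0)
        ll = []
        for eta in (best - 0.1, best, best + 0.1):
            st.alpha = eta
            ll.append(poisson_loglik(d, linear_predictor(d, st)))
        assert ll[1] > ll[0] and ll[1] > ll[2]


class TestLogPrior:
    def test_zero_fields_unit_precisions_closed_form(self, tiny_data):
        spec = ModelSpec(interaction_type="I")
        structures = ModelStructures(tiny_data.graph, tiny_data.Z, spec)
        st = ParameterState.zeros(3, 4, 2)
        got = log_prior(st, spec, structures)
        expected = 2 * 0.5 * np.log(1e-3)  # beta kernel at its maximum
        expected += 4 * stats.gamma.logpdf(1.0, a=1.0, scale=1.0 / 5e-4)
        assert got == pytest.approx(expected)

    def test_doubling_tau_v_adds_rank_and_hyperprior_terms(self, tiny_data):
        spec = ModelSpec()
        structures = ModelStructures(tiny_data.graph, tiny_data.Z, spec)
        st = ParameterState.zeros(3, 4, 2)
        base = log_prior(st, spec, structures)
        st.tau_v = 2.0
        delta = log_prior(st, spec, structures) - base
        expected = 0.5 * 3 * np.log(2.0) + (
            stats.gamma.logpdf(2.0, a=1.0, scale=1 / 5e-4)
            - stats.gamma.logpdf(1.0, a=1.0, scale=1 / 5e-4))
        assert delta == pytest.approx(expected)

    def test_type_i_kernel_is_sum_of_iid_gaussian_kernels(self, tiny_data):
        spec = ModelSpec(interaction_type="I")
        structures = ModelStructures(tiny_data.graph, tiny_data.Z, spec)
        psi = np.random.default_rng(2).normal(size=12)
        tau = 3.0
        got = gmrf_logkernel(psi, structures["psi"], tau)
        iid = np.sum(0.5 * np.log(tau) - 0.5 * tau * psi**2)
        assert got == pytest.approx(iid)

    def test_constraint_violation_rejected(self, tiny_data):
        spec = ModelSpec()
        structures = ModelStructures(tiny_data.graph, tiny_data.Z, spec)
        st = ParameterState.zeros(3, 4, 2)
        st.u = np.array([1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="sum-to-zero"):
            log_prior(st, spec, structures)


class TestApplyConstraints:
    def test_constant_u_moves_to_alpha(self, path3_graph):
        spec = ModelSpec()
        st = ParameterState.zeros(3, 4, 0)
        st.u = np.ones(3)
        out = apply_constraints(st, spec, path3_graph)
        np.testing.assert_allclose(out.u, 0.0, atol=1e-12)
        assert out.alpha == pytest.approx(1.0)

    def test_type_ii_row_means_move_to_u(self, path3_graph):
        spec = ModelSpec(interaction_type="II")
        st = ParameterState.zeros(3, 2, 0)
        st.psi = np.array([[1.0, 1.0], [0.0, 0.0], [0.0, 0.0]])
        out = apply_constraints(st, spec, path3_graph)
        np.testing.assert_allclose(out.psi, 0.0, atol=1e-12)
        # row mean 1 went to u[0], then u was recentred into alpha
        np.testing.assert_allclose(out.u, [2 / 3, -1 / 3, -1 / 3], atol=1e-12)
        assert out.alpha == pytest.approx(1 / 3)

    @pytest.mark.parametrize("interaction", ["none", "I", "II", "III"])
    def test_eta_invariance_for_random_states(self, tiny_data, interaction):
        spec = ModelSpec(interaction_type=interaction)
        rng = np.random.default_rng(7)
        st = ParameterState(
            alpha=rng.normal(), beta=rng.normal(size=2),
            u=rng.normal(size=3), v=rng.normal(size=3),
            gamma=rng.normal(size=4), psi=rng.normal(size=(3, 4)))
        before = linear_predictor(tiny_data, st).eta
        after = linear_predictor(tiny_data, apply_constraints(st, spec, tiny_data.graph)).eta
        np.testing.assert_allclose(after, before, atol=1e-10)

    def test_eta_invariance_on_disconnected_graph(self):
        g = RegionGraph.from_neighbour_ids({"A": ["B"], "B": ["A"], "C": []})
        data = PanelData(g, [[2, 3]] * 3, [[10.0, 10.0]] * 3,
                         [[2.5, 2.5]] * 3, np.zeros((3, 2, 0)))
        spec = ModelSpec()
        rng = np.random.default_rng(3)
        st = ParameterState(alpha=0.1, beta=np.zeros(0), u=rng.normal(size=3),
                            v=rng.normal(size=3), gamma=rng.normal(size=2),
                            psi=np.zeros((3, 2)))
        out = apply_constraints(st, spec, g)
        np.testing.assert_allclose(
            linear_predictor(data, out).eta, linear_predictor(data, st).eta, atol=1e-10)
        labels = g.component_labels
        for c in range(g.n_components):
            assert abs(out.u[labels == c].sum()) < 1e-10


class TestLogPosterior:
    @pytest.mark.parametrize("interaction", ["none", "I", "II", "III"])
    def test_matches_dense_brute_force(self, tiny_data, interaction):
        spec = ModelSpec(interaction_type=interaction)
        structures = ModelStructures(tiny_data.graph, tiny_data.Z, spec)
        for seed in (1, 2):
            st = random_constrained_state(tiny_data, spec, seed)
            ours = log_posterior(st, spec, tiny_data, structures)
            oracle = dense_log_posterior(st, spec, tiny_data, structures)
            assert ours == pytest.approx(oracle, abs=1e-8)

    def test_differences_match_brute_force(self, tiny_data):
        spec = ModelSpec(interaction_type="II")
        structures = ModelStructures(tiny_data.graph, tiny_data.Z, spec)
        s1 = random_constrained_state(tiny_data, spec, 10)
        s2 = random_constrained_state(tiny_data, spec, 11)
        ours = (log_posterior(s1, spec, tiny_data, structures)
                - log_posterior(s2, spec, tiny_data, structures))
        oracle = (dense_log_posterior(s1, spec, tiny_data, structures)
                  - dense_log_posterior(s2, spec, tiny_data, structures))
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_alpha_gamma_aliasing_invariance(self, tiny_data):
        """Shifting a constant between alpha and gamma, then re-constraining,
        leaves the posterior unchanged."""
        spec = ModelSpec()
        structures = ModelStructures(tiny_data.graph, tiny_data.Z, spec)
        st = random_constrained_state(tiny_data, spec, 21)
        base = log_posterior(st, spec, tiny_data, structures)
        shifted = st.copy()
        shifted.alpha += 0.7
        shifted.gamma -= 0.7
        shifted = apply_constraints(shifted, spec, tiny_data.graph)
        assert log_posterior(shifted, spec, tiny_data, structures) == pytest.approx(base)


class TestModelSpec:
    def test_interaction_requires_both_main_effects(self):
        with pytest.raises(ValueError, match="interaction"):
            ModelSpec(interaction_type="II", include_temporal=False)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(threshold=0.0)

    def test_serialization_round_trip(self):
        spec = ModelSpec(interaction_type="III", hyper_shape={"u": 2.0},
                         hyper_rate={"psi": 1e-3}, threshold=1.5)
        again = ModelSpec.from_dict(spec.to_dict())
        assert again == spec
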