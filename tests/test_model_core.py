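"""Specification tables, RAM assembly, implied moments and df bookkeeping."""

import numpy as np
import pytest

import lcspanel as L
from lcspanel.model_core import (
    ModelSpecError,
    ParameterTable,
    VariableSet,
    assemble,
    implied_moments,
    model_df,
)


def _simple_vars():
    return VariableSet(("x", "y"), latent=frozenset())


class TestAssemble:
    def test_all_fixed_rows_populate_matrices(self):
        t = ParameterTable(_simple_vars())
        t.path("x", "y", free=False, value=0.5)
        t.cov("x", free=False, value=2.0)
        t.cov("y", free=False, value=1.0)
        t.mean("x", free=False, value=3.0)
        ram = assemble(t, np.array([]))
        assert ram.A[1, 0] == 0.5
        assert ram.S[0, 0] == 2.0 and ram.S[1, 1] == 1.0
        assert ram.M[0] == 3.0 and ram.M[1] == 0.0

    def test_equality_group_shares_one_entry(self):
        v = VariableSet(("a", "b", "g"), latent={"g"})
        t = ParameterTable(v)
        t.path("g", "a", label="load")
        t.path("g", "b", label="load")
        t.cov("g", free=False, value=1.0)
        ram = assemble(t, [0.7])
        assert ram.A[0, 2] == 0.7 and ram.A[1, 2] == 0.7
        assert t.n_free == 1

    def test_theta_length_mismatch_raises(self):
        t = ParameterTable(_simple_vars())
        t.cov("x", value=1.0)
        with pytest.raises(ModelSpecError, match="free parameters"):
            assemble(t, [1.0, 2.0])

    def test_duplicate_row_raises(self):
        t = ParameterTable(_simple_vars())
        t.cov("x", "y")
        with pytest.raises(ModelSpecError, match="duplicate"):
            t.cov("y", "x")  # covariance rows are unordered pairs

    def test_unknown_variable_raises(self):
        t = ParameterTable(_simple_vars())
        with pytest.raises(ModelSpecError, match="unknown variable"):
            t.path("x", "z")

    def test_free_variance_needs_positive_start(self):
        t = ParameterTable(_simple_vars())
        with pytest.raises(ModelSpecError, match="positive start"):
            t.cov("x", value=0.0)

    def test_mutualism_spec_matches_hand_built_adjacency(self):
        """Cell-by-cell cross-check of the bidirectional-coupling model
        against an independently written adjacency listing."""
        spec = L.build_bivariate_lcs()
        theta = np.arange(1.0, spec.n_free + 1)
        ram = assemble(spec, theta)
        names = list(ram.names)
        i = {n: names.index(n) for n in names}
        by_label = dict(zip(spec.free_labels, theta))
        # fixed unit paths of the latent-change decomposition Y2 = Y1 + dY
        fixed_units = [
            ("voc1", "voc2"), ("d_voc", "voc2"), ("mat1", "mat2"), ("d_mat", "mat2"),
        ]
        for src, tgt in fixed_units:
            assert ram.A[i[tgt], i[src]] == 1.0
        free_paths = {
            ("age", "voc1"): "voc1_on_age",
            ("age", "mat1"): "mat1_on_age",
            ("voc1", "d_voc"): "beta_voc",
            ("mat1", "d_mat"): "beta_mat",
            ("voc1", "d_mat"): "gamma_voc_to_dmat",
            ("mat1", "d_voc"): "gamma_mat_to_dvoc",
        }
        for (src, tgt), label in free_paths.items():
            assert ram.A[i[tgt], i[src]] == by_label[label]
        # every other A cell is zero
        expected_nonzero = {(i[t], i[s]) for s, t in fixed_units}
        expected_nonzero |= {(i[t], i[s]) for (s, t) in free_paths}
        nz = set(zip(*np.nonzero(ram.A)))
        assert nz == expected_nonzero
        # S: free variances/covariances, wave-2 residuals fixed at zero
        assert ram.S[i["voc2"], i["voc2"]] == 0.0
        assert ram.S[i["mat2"], i["mat2"]] == 0.0
        assert ram.S[i["voc1"], i["mat1"]] == by_label["wave1_resid_cov"]
        assert ram.S[i["d_voc"], i["d_mat"]] == by_label["change_resid_cov"]
        assert ram.S[i["d_voc"], i["d_voc"]] == by_label["dvoc_var"]
        # M: free intercepts for age/wave-1/changes, zero for wave-2 scores
        assert ram.M[i["voc2"]] == 0.0 and ram.M[i["mat2"]] == 0.0
        assert ram.M[i["d_voc"]] == by_label["alpha_voc"]


class TestImpliedMoments:
    def test_no_paths_identity_covariance(self):
        t = ParameterTable(_simple_vars())
        t.cov("x", free=False, value=1.0)
        t.cov("y", free=False, value=1.0)
        mu, sigma = implied_moments(assemble(t, []))
        assert np.allclose(mu, 0.0)
        assert np.allclose(sigma, np.eye(2))

    def test_unit_regression_propagates_covariance(self):
        t = ParameterTable(_simple_vars())
        t.path("x", "y", free=False, value=1.0)
        t.cov("x", free=False, value=1.0)
        t.cov("y", free=False, value=0.0)
        mu, sigma = implied_moments(assemble(t, []))
        assert np.allclose(sigma, [[1.0, 1.0], [1.0, 1.0]])

    def test_cycle_raises_structural_error(self):
        t = ParameterTable(_simple_vars())
        t.path("x", "y", free=False, value=1.0)
        t.path("y", "x", free=False, value=1.0)
        t.cov("x", free=False, value=1.0)
        t.cov("y", free=False, value=1.0)
        with pytest.raises(L.StructuralCycleError):
            implied_moments(assemble(t, []))

    def test_univariate_lcs_moments_match_simulation_oracle(self):
        """Implied moments of a univariate latent-change structure agree
        with brute-force simulation of the structural equations."""
        beta, base_var, resid_var, int1, alpha = -0.3, 9.0, 4.0, 10.0, 10.0
        v = VariableSet(("y1", "y2", "dy"), latent={"dy"})
        t = ParameterTable(v)
        t.path("y1", "y2", free=False, value=1.0)
        t.path("dy", "y2", free=False, value=1.0)
        t.path("y1", "dy", free=False, value=beta)
        t.cov("y1", free=False, value=base_var)
        t.cov("dy", free=False, value=resid_var)
        t.mean("y1", free=False, value=int1)
        t.mean("dy", free=False, value=alpha)
        mu, sigma = implied_moments(assemble(t, []))

        rng = np.random.default_rng(42)
        n = 1_000_000
        y1 = int1 + np.sqrt(base_var) * rng.standard_normal(n)
        dy = alpha + beta * y1 + np.sqrt(resid_var) * rng.standard_normal(n)
        y2 = y1 + dy
        sim = np.column_stack([y1, y2])
        mc_mu = sim.mean(axis=0)
        mc_sigma = np.cov(sim, rowvar=False)
        # 3 Monte-Carlo standard errors
        se_mu = sim.std(axis=0) / np.sqrt(n)
        assert np.all(np.abs(mu - mc_mu) < 3 * se_mu)
        assert np.allclose(sigma, mc_sigma, rtol=0.01, atol=0.01)

    @pytest.mark.parametrize(
        "builder",
        [
            lambda: L.build_bivariate_lcs(),
            lambda: L.build_bivariate_lcs({"mat_to_dvoc"}),
            lambda: L.build_g_model(),
            lambda: L.build_univariate_lcs("vocabulary"),
        ],
    )
    def test_implied_sigma_symmetric_pd_near_start(self, builder):
        spec = builder()
        rng = np.random.default_rng(3)
        start = spec.start_values()
        for _ in range(20):
            theta = start + 0.05 * rng.standard_normal(start.size) * (1 + np.abs(start))
            # keep variances positive under the perturbation
            compiled = spec.compile()
            theta[compiled.is_variance] = np.abs(theta[compiled.is_variance]) + 0.1
            _, sigma = implied_moments(assemble(spec, theta))
            assert np.allclose(sigma, sigma.T, atol=1e-12)
            assert np.all(np.linalg.eigvalsh(sigma) > 0)


class TestModelDf:
    @pytest.mark.parametrize(
        "spec_fn, expected",
        [
            (lambda: L.build_bivariate_lcs(), 2),
            (lambda: L.build_bivariate_lcs({"mat_to_dvoc"}), 3),
            (lambda: L.build_g_model(), 3),
            (lambda: L.build_univariate_lcs("vocabulary"), 1),
            (lambda: L.build_univariate_lcs("matrix"), 1),
            (lambda: L.build_bivariate_lcs(set()), 4),
        ],
    )
    def test_builder_df(self, spec_fn, expected):
        assert model_df(spec_fn()) == expected

    def test_investment_frees_one_fewer_than_mutualism(self):
        assert (
            model_df(L.build_bivariate_lcs({"mat_to_dvoc"}))
            - model_df(L.build_bivariate_lcs())
            == 1
        )

    def test_saturated_spec_has_zero_df(self):
        v = VariableSet(("x", "y"))
        t = ParameterTable(v)
        t.cov("x", value=1.0)
        t.cov("y", value=1.0)
        t.cov("x", "y")
        t.mean("x")
        t.mean("y")
        assert model_df(t) == 0

    def test_overparameterized_raises(self):
        # one observed variable (2 moments) but 4 free parameters
        t = ParameterTable(VariableSet(("x", "z"), latent={"z"}))
        t.cov("x", value=1.0)
        t.mean("x")
        t.path("z", "x")
        t.cov("z", value=1.0)
        with pytest.raises(ModelSpecError, match="over-parameterized"):
            model_df(t)


def test_text_round_trip_preserves_spec():
    spec = L.build_g_model(invariance="strong")
    text = spec.to_text()
    back = ParameterTable.from_text(text)
    assert back.variables == spec.variables
    assert back.free_labels == spec.free_labels
    assert [(r.slot, r.source, r.target, r.free, r.value, r.label) for r in back.rows] == [
        (r.slot, r.source, r.target, r.free, r.value, r.label) for r in spec.rows
    ]
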