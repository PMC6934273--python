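"""Connectivity, convexity, correlations and variance decomposition."""

import itertools
from math import factorial

import numpy as np
import pandas as pd
import pytest

from gbcpop.analysis import (
    connected_components,
    convexity_test,
    neighbor_count,
    pairwise_correlations,
    polynomial_design,
    polynomial_fit,
    transform_outputs,
    variance_contribution,
)
from gbcpop.population import PARAM_NAMES, build_grid, desk_grid


def brute_force_neighbors(order):
    """Enumerate {-1,0,1}^6 offsets with 1..order nonzero entries."""
    count = 0
    for offset in itertools.product((-1, 0, 1), repeat=6):
        nz = sum(1 for o in offset if o != 0)
        if 1 <= nz <= order:
            count += 1
    return count


class TestConnectivity:
    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_neighbor_formula_matches_enumeration(self, order):
        assert neighbor_count(order) == brute_force_neighbors(order)

    def test_interior_point_has_12_order1_neighbors(self):
        assert neighbor_count(1) == 12

    def test_single_instance_one_cluster(self):
        _, n = connected_components([100], desk_grid(), order=1)
        assert n == 1

    def test_two_step_diagonal_pair(self):
        grid = desk_grid()
        # two instances differing by one step in each of two dimensions
        a = np.ravel_multi_index((0, 0, 0, 0, 0, 0), grid.shape)
        b = np.ravel_multi_index((1, 1, 0, 0, 0, 0), grid.shape)
        _, n1 = connected_components([a, b], grid, order=1)
        _, n2 = connected_components([a, b], grid, order=2)
        assert (n1, n2) == (2, 1)

    def test_cluster_count_monotone_in_order(self, rng):
        grid = desk_grid()
        ids = rng.choice(grid.size, size=60, replace=False)
        counts = [connected_components(ids, grid, order=o)[1] for o in (1, 2, 3)]
        assert counts[0] >= counts[1] >= counts[2]


class TestConvexity:
    def accepted_frame(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        grid = build_grid()
        ids = rng.choice(grid.size, size=n, replace=False)
        return pd.DataFrame([grid.params_at(i).as_dict() for i in ids])

    def test_child_bookkeeping(self):
        frac, children = convexity_test(self.accepted_frame(), lambda p: True,
                                        n_pairs=10, n_interp=3, seed=1)
        assert len(children) == 30
        assert frac == 1.0
        assert sorted(children.fraction.unique()) == [0.25, 0.5, 0.75]

    def test_identical_parents_give_identical_children(self):
        row = self.accepted_frame(n=1).iloc[0].to_dict()
        frame = pd.DataFrame([row, row])
        _, children = convexity_test(frame, lambda p: True, n_pairs=3, seed=2)
        for name in PARAM_NAMES:
            assert np.allclose(children[name], row[name])

    def test_m_e_rounded_to_integer(self):
        frame = self.accepted_frame()
        _, children = convexity_test(frame, lambda p: True, n_pairs=5, seed=3)
        assert (children.m_e == children.m_e.round()).all()

    def test_requires_two_parents(self):
        with pytest.raises(ValueError):
            convexity_test(self.accepted_frame(n=1), lambda p: True)


class TestCorrelations:
    def test_independent_parameters_uncorrelated(self, rng):
        df = pd.DataFrame({n: rng.random(10_000) for n in PARAM_NAMES})
        r, _, flag = pairwise_correlations(df)
        off = r.to_numpy()[~np.eye(6, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)
        assert not flag.to_numpy().any()

    def test_duplicated_column_perfectly_correlated(self, rng):
        x = rng.random(100)
        df = pd.DataFrame({n: (x if n in ("m_e", "w_e") else rng.random(100))
                           for n in PARAM_NAMES})
        r, p, flag = pairwise_correlations(df)
        assert r.loc["m_e", "w_e"] == pytest.approx(1.0)
        assert flag.loc["m_e", "w_e"]

    def test_anticorrelated_pair(self, rng):
        x = rng.random(100)
        cols = {n: rng.random(100) for n in PARAM_NAMES}
        cols["m_e"], cols["w_e"] = x, -x
        r, _, _ = pairwise_correlations(pd.DataFrame(cols))
        assert r.loc["m_e", "w_e"] == pytest.approx(-1.0)

    def test_zero_variance_flagged_nan(self, rng):
        cols = {n: rng.random(50) for n in PARAM_NAMES}
        cols["t_r"] = np.full(50, 1.2)
        r, _, _ = pairwise_correlations(pd.DataFrame(cols))
        assert np.isnan(r.loc["t_r", "m_e"])


def random_params(rng, n=400):
    return pd.DataFrame({name: rng.random(n) + 0.5 for name in PARAM_NAMES})


def factorial_params():
    """2-level full factorial over the six parameters (orthogonal design)."""
    levels = np.array(list(itertools.product((0.5, 1.5), repeat=6)))
    return pd.DataFrame(levels, columns=list(PARAM_NAMES))


class TestPolynomialFit:
    @pytest.mark.parametrize("degree,n_terms", [(1, 6), (2, 27), (3, 83)])
    def test_basis_sizes(self, rng, degree, n_terms):
        X = random_params(rng, 50).to_numpy()
        Z, names = polynomial_design(X, degree)
        assert Z.shape[1] == n_terms == len(names)

    def test_exact_linear_output(self, rng):
        params = random_params(rng)
        y = 2.0 * params["m_e"] - 3.0 * params["s_a"] + 0.5
        outputs = params.copy()
        outputs["cv_prime"] = y
        for col in ("sr", "dr"):
            outputs[col] = np.exp(y / 10)
        for col in ("vs", "ei"):
            outputs[col] = 1 - np.exp(-np.abs(y))
        fit = polynomial_fit(params, outputs, degree=1)
        assert fit.r2["cv_prime"] == pytest.approx(1.0, abs=1e-12)

    def test_product_output_needs_quadratic(self, rng):
        params = random_params(rng)
        z = (params - params.mean()) / params.std(ddof=0)
        y = (z["m_e"] * z["w_e"]).to_numpy()
        outputs = params.copy()
        outputs["cv_prime"] = y
        outputs[["sr", "dr"]] = 1.0
        outputs[["vs", "ei"]] = 0.5
        lin = polynomial_fit(params, outputs, 1).r2["cv_prime"]
        quad = polynomial_fit(params, outputs, 2).r2["cv_prime"]
        assert lin < 0.2
        assert quad == pytest.approx(1.0, abs=1e-10)

    def test_nested_r2_monotone(self, rng):
        params = random_params(rng, 300)
        outputs = params.copy()
        outputs["cv_prime"] = rng.random(300)
        outputs[["sr", "dr"]] = 1.0
        outputs[["vs", "ei"]] = 0.5
        r2 = [polynomial_fit(params, outputs, d).r2["cv_prime"] for d in (1, 2, 3)]
        assert r2[0] <= r2[1] + 1e-12 <= r2[2] + 1e-12

    def test_out_of_domain_rows_excluded_and_counted(self, rng):
        params = random_params(rng, 100)
        outputs = params.copy()
        outputs["cv_prime"] = rng.random(100)
        outputs[["sr", "dr"]] = 1.0
        outputs["vs"] = np.r_[np.ones(5), rng.random(95) * 0.9]
        outputs["ei"] = 0.5
        fit = polynomial_fit(params, outputs, 1)
        assert fit.n_excluded["vs"] == 5
        assert fit.n_used["vs"] == 95

    def test_rank_deficient_design_raises(self, rng):
        x = rng.random(80)
        cols = {n: rng.random(80) for n in PARAM_NAMES}
        cols["m_e"] = x
        cols["w_e"] = 2 * x  # collinear after z-scoring
        params = pd.DataFrame(cols)
        outputs = params.copy()
        outputs["cv_prime"] = rng.random(80)
        outputs[["sr", "dr"]] = 1.0
        outputs[["vs", "ei"]] = 0.5
        with pytest.raises(np.linalg.LinAlgError):
            polynomial_fit(params, outputs, 1)


def subset_r2(Z, y):
    """R2 of OLS on each subset of the six linear columns (oracle)."""
    out = {}
    yc = y - y.mean()
    ss = np.sum(yc**2)
    for r in range(7):
        for S in itertools.combinations(range(6), r):
            if not S:
                out[S] = 0.0
                continue
            A = np.column_stack([np.ones(len(y)), Z[:, list(S)]])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            out[S] = 1.0 - np.sum((y - A @ coef) ** 2) / ss
    return out


def shapley_oracle(Z, y):
    """Direct Shapley values of R2 over the six predictors."""
    r2 = subset_r2(Z, y)
    phi = np.zeros(6)
    for j in range(6):
        for S, val in r2.items():
            if j in S:
                continue
            Sj = tuple(sorted(S + (j,)))
            w = factorial(len(S)) * factorial(5 - len(S)) / factorial(6)
            phi[j] += w * (r2[Sj] - val)
    return phi


class TestVarianceContribution:
    def test_linear_gains_sum_to_total_r2(self, rng):
        params = random_params(rng, 200)
        y = (params["m_e"] + 0.3 * params["t_r"]
             + 0.1 * rng.standard_normal(200)).to_numpy()
        gains = variance_contribution(params, y, degree=1)
        Z, _ = polynomial_design(params.to_numpy(), 1)
        A = np.column_stack([np.ones(200), Z])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        r2 = 1 - np.sum((y - A @ coef) ** 2) / np.sum((y - y.mean()) ** 2)
        assert gains.sum() == pytest.approx(r2, abs=1e-10)

    def test_linear_gains_are_shapley_values(self, rng):
        params = random_params(rng, 150)
        y = rng.standard_normal(150)
        gains = variance_contribution(params, y, degree=1)
        Z, _ = polynomial_design(params.to_numpy(), 1)
        assert np.allclose(gains.to_numpy(), shapley_oracle(Z, y), atol=1e-10)

    def test_single_parameter_output(self):
        # orthogonal 2-level factorial design: gains attribute exactly
        params = factorial_params()
        y = params["t_r"].to_numpy()
        gains = variance_contribution(params, y, degree=1)
        assert gains["t_r"] == pytest.approx(1.0, abs=1e-10)
        assert gains.drop("t_r").abs().max() < 1e-10

    def test_quadratic_mode_finds_interaction_term(self):
        params = factorial_params()
        z = (params - params.mean()) / params.std(ddof=0)
        y = (z["m_e"] * z["w_e"]).to_numpy()
        gains = variance_contribution(params, y, degree=2, n_orderings=40,
                                      seed=4)
        assert gains.idxmax() == "m_e w_e"
        assert gains.max() == pytest.approx(1.0, abs=1e-10)
        assert gains.sum() == pytest.approx(1.0, abs=1e-8)


class TestTransforms:
    def test_transforms_and_domains(self):
        table = pd.DataFrame({
            "sr": [10.0, 0.0], "dr": [200.0, 5.0], "cv_prime": [0.8, 0.7],
            "vs": [0.95, 1.0], "ei": [0.9, 0.5],
        })
        out = transform_outputs(table)
        vals, mask = out["sr"]
        assert mask.tolist() == [True, False]
        assert vals[0] == pytest.approx(np.log(10.0))
        vals, mask = out["vs"]
        assert mask.tolist() == [True, False]
        assert vals[0] == pytest.approx(np.log(0.05))
        # log(1-VS) display transform is monotone decreasing in VS
        vs = np.linspace(0.0, 0.99, 50)
        assert np.all(np.diff(np.log(1 - vs)) < 0)
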