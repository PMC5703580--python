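"""Growth LP, lexicographic cost minimization and constraint validation."""

import itertools

import numpy as np
import pytest

from chemoflux.fixtures import FixtureSpec, generate_fixture
from chemoflux.model import (
    Exchange,
    Medium,
    MetabolicModel,
    UnboundedModelError,
    minimize_cost_at_optimum,
    solve_fba,
    uptake_bound,
    validate_solution,
)

Z0 = (2 * 0.5 + 38 * 0.45 - 1.0625) / 348  # toy optimum at nutrient excess


def brute_force_max_z(model, medium, xi, tol=1e-9):
    """Independent LP oracle: enumerate polytope vertices exhaustively.

    Variables x = [r+, r-, u, z].  A vertex solves the metabolite balances
    plus enough tight inequality rows (variable bounds and the crowding
    budget); the optimum is the best feasible vertex.  Only viable for a
    handful of reactions.
    """
    n_r = len(model.reactions)
    ex = model.external_metabolites
    n = 2 * n_r + len(ex) + 1
    A_eq = np.zeros((len(model.metabolites), n))
    A_eq[:, :n_r] = model.S
    A_eq[:, n_r:2 * n_r] = -model.S
    for j, m in enumerate(ex):
        A_eq[model.metabolites.index(m), 2 * n_r + j] = 1.0
    A_eq[:, -1] = -model.biomass_vector()
    b_eq = model.maintenance_vector()

    G_rows, h_vals = [], []

    def add(vec, rhs):
        G_rows.append(vec)
        h_vals.append(rhs)

    cost = np.zeros(n)
    cost[:n_r] = model.cost_fwd
    cost[n_r:2 * n_r] = model.cost_rev
    add(cost, model.budget)
    lbs = np.zeros(n)
    ubs = np.full(n, np.inf)
    ubs[:n_r] = np.maximum(model.ub, 0.0)
    ubs[n_r:2 * n_r] = np.maximum(-model.lb, 0.0)
    for j, m in enumerate(ex):
        e = model.exchanges[m]
        lbs[2 * n_r + j] = -e.L
        ubs[2 * n_r + j] = uptake_bound(e.V, medium.conc(m), xi)
    for i in range(n):
        if np.isfinite(lbs[i]):
            row = np.zeros(n)
            row[i] = -1.0
            add(row, -lbs[i])
        if np.isfinite(ubs[i]):
            row = np.zeros(n)
            row[i] = 1.0
            add(row, ubs[i])
    G = np.array(G_rows)
    h = np.array(h_vals)

    m_eq = A_eq.shape[0]
    best = None
    for rows in itertools.combinations(range(len(G)), n - m_eq):
        A = np.vstack([A_eq, G[list(rows)]])
        b = np.concatenate([b_eq, h[list(rows)]])
        if np.linalg.matrix_rank(A) < n:
            continue
        x, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.max(np.abs(A @ x - b)) > tol:
            continue
        if np.any(G @ x > h + tol) or np.max(np.abs(A_eq @ x - b_eq)) > tol:
            continue
        if best is None or x[-1] > best:
            best = x[-1]
    return best


class TestSolveFBA:
    def test_toy_optimum_at_nutrient_excess(self, toy_system):
        model, medium, _ = toy_system
        sol = solve_fba(model, medium, 0.0)
        assert sol.optimal
        assert sol.exchanges["S"] == pytest.approx(0.5, abs=1e-9)
        assert sol.fluxes["respiration"] == pytest.approx(0.45, abs=1e-9)
        assert sol.exchanges["W"] == pytest.approx(-0.05, abs=1e-9)
        assert sol.z == pytest.approx(Z0, abs=1e-9)

    def test_infeasible_beyond_medium_depth(self, toy_system):
        model, medium, _ = toy_system
        sol = solve_fba(model, medium, 600.0)
        assert sol.status == "infeasible"

    def test_vanishing_budget_forbids_costly_maintenance(self, toy_system):
        model, medium, _ = toy_system
        model = MetabolicModel(
            metabolites=model.metabolites, reactions=model.reactions,
            S=model.S, lb=model.lb, ub=model.ub,
            cost_fwd=model.cost_fwd, cost_rev=model.cost_rev,
            budget=1e-12, biomass=model.biomass,
            maintenance=model.maintenance, exchanges=model.exchanges)
        # respiration is budget-capped at ~0; glycolysis alone cannot pay e
        assert solve_fba(model, medium, 100.0).status == "infeasible"

    def test_unbounded_model_raises(self):
        model = MetabolicModel(
            metabolites=["A"], reactions=["noop"], S=np.zeros((1, 1)),
            lb=np.zeros(1), ub=np.zeros(1), cost_fwd=np.zeros(1),
            cost_rev=np.zeros(1), budget=1.0, biomass={"A": 1.0},
            maintenance={}, exchanges={"A": Exchange(V=np.inf, L=np.inf)})
        with pytest.raises(UnboundedModelError):
            solve_fba(model, Medium({"A": np.inf}), 1.0)

    @pytest.mark.parametrize("xi", [0.0, 5.0, 31.0, 120.0, 400.0])
    def test_vertex_oracle_equivalence(self, toy_system, xi):
        model, medium, _ = toy_system
        assert solve_fba(model, medium, xi).z == pytest.approx(
            brute_force_max_z(model, medium, xi), abs=1e-7)

    @pytest.mark.parametrize("seed", range(5))
    def test_z_nonincreasing_in_xi_on_random_fixtures(self, seed):
        fx = generate_fixture(FixtureSpec(topology="branched", seed=seed))
        grid = np.geomspace(0.1, 2000.0, 25)
        z_prev = np.inf
        for xi in grid:
            sol = solve_fba(fx.model, fx.medium, xi, lexicographic=False)
            if not sol.optimal:
                break
            assert sol.z <= z_prev + 1e-9
            z_prev = sol.z

    def test_doubling_medium_never_decreases_growth(self, toy_system):
        model, medium, _ = toy_system
        for xi in (0.0, 20.0, 50.0, 300.0):
            z1 = solve_fba(model, medium, xi).z
            z2 = solve_fba(model, medium.scaled(2.0), xi).z
            assert z2 >= z1 - 1e-9


class TestCostMinimization:
    def test_unique_vertex_unchanged(self, toy_system):
        model, medium, _ = toy_system
        first = solve_fba(model, medium, 0.0, lexicographic=False)
        sol = minimize_cost_at_optimum(model, medium, 0.0, first.z)
        assert sol.exchanges["S"] == pytest.approx(0.5, abs=1e-9)
        assert sol.fluxes["respiration"] == pytest.approx(0.45, abs=1e-9)
        assert sol.cost <= first.cost + 1e-9

    def test_two_path_network_routes_through_cheap_pathway(self):
        # two parallel routes S -> E with identical yield, different cost
        model = MetabolicModel(
            metabolites=["S", "E"], reactions=["cheap", "costly"],
            S=np.array([[-1.0, -1.0], [1.0, 1.0]]),
            lb=np.zeros(2), ub=np.full(2, np.inf),
            cost_fwd=np.array([0.1, 0.5]), cost_rev=np.zeros(2),
            budget=100.0, biomass={"E": 1.0}, maintenance={},
            exchanges={"S": Exchange(V=1.0, L=0.0)})
        medium = Medium({"S": 10.0})
        sol = solve_fba(model, medium, 0.0)
        assert sol.z == pytest.approx(1.0, abs=1e-9)
        assert sol.fluxes["cheap"] == pytest.approx(1.0, abs=1e-9)
        assert sol.fluxes["costly"] == pytest.approx(0.0, abs=1e-9)
        assert sol.cost == pytest.approx(0.1, abs=1e-9)

    def test_reported_cost_matches_definition(self, toy_system):
        model, medium, _ = toy_system
        sol = solve_fba(model, medium, 10.0)
        alpha = sum(model.cost_fwd[k] * sol.r_plus[r]
                    + model.cost_rev[k] * sol.r_minus[r]
                    for k, r in enumerate(model.reactions))
        assert sol.cost == pytest.approx(alpha, abs=1e-12)


class TestValidateSolution:
    def test_clean_solution_passes(self, toy_system):
        model, medium, _ = toy_system
        sol = solve_fba(model, medium, 25.0)
        assert validate_solution(model, medium, 25.0, sol) == []

    def test_budget_bound_is_inclusive(self, toy_system):
        model, medium, _ = toy_system
        sol = solve_fba(model, medium, 0.0)  # respiration at capacity: alpha = C
        assert sol.cost == pytest.approx(model.budget, abs=1e-9)
        assert validate_solution(model, medium, 0.0, sol) == []

    def test_corrupted_exchange_flags_its_balance_row(self, toy_system):
        model, medium, _ = toy_system
        sol = solve_fba(model, medium, 10.0)
        sol.exchanges["S"] += 1.0
        violations = validate_solution(model, medium, 10.0, sol)
        balance = {v.constraint for v in violations
                   if v.constraint.startswith("balance")}
        assert balance == {"balance[S]"}
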