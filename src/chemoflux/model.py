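"""Constrained metabolic model and the growth-maximizing linear program.

The cell is described by a stoichiometric network with per-direction flux
costs bounded by a crowding budget, a biomass composition vector, constant
maintenance demands and exchange kinetics.  The culture couples to the cell
through a single scalar, ``xi = X/D`` (inverse cell-specific perfusion
rate): the uptake of an external metabolite ``i`` is bounded by
``min(V_i, c_i/xi)``, where ``c_i`` is its concentration in the feed medium
and ``V_i`` the transporter-limited maximum uptake rate.

Units: fluxes in mmol/gDW/h, concentrations in mM, biomass rate in 1/h,
``xi`` in gDW*h/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

#: absolute residual tolerance for constraint checks (model units)
RESIDUAL_TOL = 1e-6

#: relative tolerance used to pin z in the second (cost-minimizing) stage
Z_FIX_RTOL = 1e-9


class UnboundedModelError(RuntimeError):
    """The LP is unbounded: some flux direction has no bound and no cost."""


class InconsistentStageError(RuntimeError):
    """Second-stage LP infeasible at the first-stage optimum."""


@dataclass(frozen=True)
class Exchange:
    """Exchange kinetics of one external metabolite.

    ``V`` is the maximum uptake rate (mmol/gDW/h, ``inf`` allowed) and
    ``L`` the secretion permission: 0 forbids secretion, ``inf`` allows it.
    """

    V: float = np.inf
    L: float = 0.0

    def __post_init__(self) -> None:
        if self.V < 0:
            raise ValueError("maximum uptake V must be >= 0")
        if self.L not in (0.0, np.inf):
            raise ValueError("secretion permission L must be 0 or inf")


@dataclass
class Medium:
    """Feed-medium concentrations ``c_i`` (mM); absent metabolites are 0."""

    concentrations: dict[str, float] = field(default_factory=dict)

    def conc(self, metabolite: str) -> float:
        c = self.concentrations.get(metabolite, 0.0)
        if c < 0:
            raise ValueError(f"negative medium concentration for {metabolite}")
        return c

    def scaled(self, factor: float) -> "Medium":
        return Medium({m: c * factor for m, c in self.concentrations.items()})


@dataclass
class MetabolicModel:
    """Static data of the intracellular LP.

    Attributes
    ----------
    metabolites, reactions:
        Ordered identifier lists.
    S:
        Dense stoichiometric matrix, shape ``(n_metabolites, n_reactions)``;
        ``S[i, k] > 0`` if metabolite ``i`` is produced by reaction ``k``.
    lb, ub:
        Reversibility bounds per reaction (conventionally in
        ``{-inf, 0, +inf}``; finite values are honoured).
    cost_fwd, cost_rev:
        Per-direction flux costs (cost units per mmol/gDW/h).
    budget:
        Crowding budget ``C``; the cost-weighted flux sum may not exceed it.
    biomass:
        ``y_i`` — mmol of metabolite ``i`` drained per gDW of biomass made.
    maintenance:
        ``e_i`` — constant growth-independent drain (mmol/gDW/h).
    exchanges:
        Per external metabolite, the :class:`Exchange` kinetics; only
        metabolites listed here can cross the cell boundary.
    """

    metabolites: list[str]
    reactions: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    cost_fwd: np.ndarray
    cost_rev: np.ndarray
    budget: float
    biomass: dict[str, float]
    maintenance: dict[str, float]
    exchanges: dict[str, Exchange]

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.cost_fwd = np.asarray(self.cost_fwd, dtype=float)
        self.cost_rev = np.asarray(self.cost_rev, dtype=float)
        self.validate()

    # -- structural invariants -------------------------------------------
    def validate(self) -> None:
        n_m, n_r = len(self.metabolites), len(self.reactions)
        if self.S.shape != (n_m, n_r):
            raise ValueError(f"S has shape {self.S.shape}, expected {(n_m, n_r)}")
        for arr, name in ((self.lb, "lb"), (self.ub, "ub"),
                          (self.cost_fwd, "cost_fwd"), (self.cost_rev, "cost_rev")):
            if arr.shape != (n_r,):
                raise ValueError(f"{name} must have one entry per reaction")
        if np.any(self.lb > self.ub):
            raise ValueError("lb > ub for some reaction")
        if np.any(self.cost_fwd < 0) or np.any(self.cost_rev < 0):
            raise ValueError("flux costs must be >= 0")
        if not self.budget > 0:
            raise ValueError("crowding budget C must be > 0")
        met_set = set(self.metabolites)
        for d, name in ((self.biomass, "biomass"), (self.maintenance, "maintenance")):
            for m, v in d.items():
                if m not in met_set:
                    raise ValueError(f"{name} refers to unknown metabolite {m}")
                if v < 0:
                    raise ValueError(f"{name} coefficient for {m} must be >= 0")
        for m in self.exchanges:
            if m not in met_set:
                raise ValueError(f"exchange annotation for unknown metabolite {m}")

    # -- convenience -----------------------------------------------------
    @property
    def external_metabolites(self) -> list[str]:
        return [m for m in self.metabolites if m in self.exchanges]

    def met_index(self, metabolite: str) -> int:
        return self.metabolites.index(metabolite)

    def biomass_vector(self) -> np.ndarray:
        return np.array([self.biomass.get(m, 0.0) for m in self.metabolites])

    def maintenance_vector(self) -> np.ndarray:
        return np.array([self.maintenance.get(m, 0.0) for m in self.metabolites])


@dataclass
class FluxSolution:
    """One LP solution: fluxes, exchanges, biomass rate and realized cost.

    Exchange sign convention: ``u_i > 0`` is consumption from the culture,
    ``u_i < 0`` secretion into it.
    """

    status: str                       # "optimal" | "infeasible"
    z: float = 0.0                    # biomass synthesis rate (1/h)
    fluxes: dict[str, float] = field(default_factory=dict)
    r_plus: dict[str, float] = field(default_factory=dict)
    r_minus: dict[str, float] = field(default_factory=dict)
    exchanges: dict[str, float] = field(default_factory=dict)
    cost: float = 0.0                 # realized alpha (cost units)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def uptake_bound(V: float, c: float, xi: float) -> float:
    """Upper bound ``min(V, c/xi)`` with the xi -> 0 limit convention.

    At ``xi = 0`` the bound is ``V`` for any metabolite present in the
    medium (``c > 0``) and 0 for one absent from it (0/0 := 0).  Infinite
    ``c`` means availability never limits: the bound is ``V`` alone.
    """
    if c == 0.0:
        return 0.0
    if not np.isfinite(c) or xi == 0.0:
        return V
    return min(V, c / xi)


def _solve_lp(c, A_ub, b_ub, A_eq, b_eq, bounds):
    """LP solve contract: returns (status, x) with status in
    {"optimal", "infeasible", "unbounded", "error"}."""
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    status = {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(res.status, "error")
    return status, res.x


class _LPBuilder:
    """Assemble the split-flux LP at a given xi.

    Variables are ordered ``[r+ (n_r), r- (n_r), u (n_ex), z]``.  The
    balance at every metabolite reads ``sum_k N_ik r_k + u_i = e_i + y_i z``
    (``u_i`` present only for external metabolites).
    """

    def __init__(self, model: MetabolicModel, medium: Medium, xi: float,
                 uptake_caps: dict[str, float] | None = None):
        self.model = model
        n_r = len(model.reactions)
        ex_mets = model.external_metabolites
        self.ex_mets = ex_mets
        n_ex = len(ex_mets)
        self.n_r, self.n_ex = n_r, n_ex
        n_var = 2 * n_r + n_ex + 1
        self.n_var = n_var

        S = model.S
        n_m = len(model.metabolites)
        A_eq = np.zeros((n_m, n_var))
        A_eq[:, :n_r] = S
        A_eq[:, n_r:2 * n_r] = -S
        for j, m in enumerate(ex_mets):
            A_eq[model.met_index(m), 2 * n_r + j] = 1.0
        A_eq[:, -1] = -model.biomass_vector()
        self.A_eq = A_eq
        self.b_eq = model.maintenance_vector()

        # crowding budget row
        cost_row = np.zeros(n_var)
        cost_row[:n_r] = model.cost_fwd
        cost_row[n_r:2 * n_r] = model.cost_rev
        self.cost_row = cost_row
        self.A_ub = cost_row[None, :]
        self.b_ub = np.array([model.budget])

        bounds: list[tuple[float, float]] = []
        for k in range(n_r):
            bounds.append((0.0, max(model.ub[k], 0.0)))
        for k in range(n_r):
            bounds.append((0.0, max(-model.lb[k], 0.0)))
        for m in ex_mets:
            ex = model.exchanges[m]
            if uptake_caps is not None and m in uptake_caps:
                hi = min(ex.V, uptake_caps[m])
            else:
                hi = uptake_bound(ex.V, medium.conc(m), xi)
            bounds.append((-ex.L, hi))
        bounds.append((0.0, np.inf))  # z
        self.bounds = bounds

    def to_solution(self, x: np.ndarray) -> FluxSolution:
        n_r, n_ex = self.n_r, self.n_ex
        rp = x[:n_r]
        rm = x[n_r:2 * n_r]
        u = x[2 * n_r:2 * n_r + n_ex]
        rxns = self.model.reactions
        return FluxSolution(
            status="optimal",
            z=float(x[-1]),
            fluxes={r: float(rp[k] - rm[k]) for k, r in enumerate(rxns)},
            r_plus={r: float(rp[k]) for k, r in enumerate(rxns)},
            r_minus={r: float(rm[k]) for k, r in enumerate(rxns)},
            exchanges={m: float(u[j]) for j, m in enumerate(self.ex_mets)},
            cost=float(self.cost_row @ x),
        )


def solve_fba(model: MetabolicModel, medium: Medium, xi: float,
              lexicographic: bool = True,
              uptake_caps: dict[str, float] | None = None) -> FluxSolution:
    """Maximize biomass synthesis ``z`` at a given ``xi``.

    Among all z-optimal flux vectors the one of minimum crowding cost is
    returned (two-stage lexicographic solve) unless ``lexicographic`` is
    off.  Infeasibility — the medium cannot meet maintenance at this cell
    load, i.e. ``xi`` beyond the medium depth — is reported in the status
    flag, not raised.

    ``uptake_caps`` overrides the availability side of the uptake bound
    (the bound becomes ``min(V_i, cap_i)``); dynamic simulation and the
    Jacobian check use it to impose transient availability.
    """
    if xi < 0:
        raise ValueError("xi must be >= 0")
    lp = _LPBuilder(model, medium, xi, uptake_caps)
    obj = np.zeros(lp.n_var)
    obj[-1] = -1.0  # maximize z
    status, x = _solve_lp(obj, lp.A_ub, lp.b_ub, lp.A_eq, lp.b_eq, lp.bounds)
    if status == "infeasible":
        return FluxSolution(status="infeasible")
    if status == "unbounded":
        free = [m for m in lp.ex_mets
                if not np.isfinite(uptake_bound(model.exchanges[m].V,
                                                medium.conc(m), xi))]
        raise UnboundedModelError(
            "growth LP is unbounded; check bounds/costs on exchanges "
            f"with infinite uptake: {free or 'none'}")
    if status != "optimal":
        raise RuntimeError("LP solver failure in growth stage")
    z_opt = float(x[-1])
    if not lexicographic:
        return lp.to_solution(x)
    return _min_cost_stage(lp, z_opt)


def minimize_cost_at_optimum(model: MetabolicModel, medium: Medium, xi: float,
                             z_opt: float) -> FluxSolution:
    """Among flux vectors achieving ``z_opt``, return one of minimum cost."""
    lp = _LPBuilder(model, medium, xi)
    return _min_cost_stage(lp, z_opt)


def _min_cost_stage(lp: _LPBuilder, z_opt: float) -> FluxSolution:
    # pin z exactly first; fall back to a tiny relative slack if the exact
    # pin is numerically infeasible
    for lo in (z_opt, z_opt * (1.0 - Z_FIX_RTOL) - 1e-15):
        bounds = list(lp.bounds)
        bounds[-1] = (lo, max(z_opt, lo))
        status, x = _solve_lp(lp.cost_row, lp.A_ub, lp.b_ub, lp.A_eq, lp.b_eq,
                              bounds)
        if status == "optimal":
            return lp.to_solution(x)
    raise InconsistentStageError(
        f"cost-minimizing stage failed (status={status}) at z={z_opt}")


@dataclass(frozen=True)
class Violation:
    constraint: str
    residual: float
    tolerance: float


def validate_solution(model: MetabolicModel, medium: Medium, xi: float,
                      sol: FluxSolution, tol: float = RESIDUAL_TOL) -> list[Violation]:
    """Check an optimal solution against every constraint.

    Returns one record per violated constraint (empty list if none):
    metabolite balances, the crowding budget, reversibility bounds and the
    xi-coupled exchange bounds.  The budget is an inclusive bound.
    """
    if not sol.optimal:
        raise ValueError("validate_solution expects an optimal solution")
    out: list[Violation] = []
    r = np.array([sol.fluxes[k] for k in model.reactions])
    u = {m: sol.exchanges.get(m, 0.0) for m in model.external_metabolites}
    # metabolite balances
    net = model.S @ r
    y = model.biomass_vector()
    e = model.maintenance_vector()
    for i, m in enumerate(model.metabolites):
        resid = net[i] + u.get(m, 0.0) - e[i] - y[i] * sol.z
        if abs(resid) > tol:
            out.append(Violation(f"balance[{m}]", float(resid), tol))
    # crowding budget
    rp = np.array([sol.r_plus[k] for k in model.reactions])
    rm = np.array([sol.r_minus[k] for k in model.reactions])
    alpha = float(model.cost_fwd @ rp + model.cost_rev @ rm)
    if alpha > model.budget + tol:
        out.append(Violation("crowding_budget", alpha - model.budget, tol))
    if np.any(rp < -tol) or np.any(rm < -tol):
        out.append(Violation("split_nonnegativity",
                             float(min(rp.min(), rm.min())), tol))
    # reversibility
    for k, rx in enumerate(model.reactions):
        if r[k] < model.lb[k] - tol or r[k] > model.ub[k] + tol:
            out.append(Violation(f"reversibility[{rx}]", float(r[k]), tol))
    # exchange bounds
    for m, ex in model.exchanges.items():
        hi = uptake_bound(ex.V, medium.conc(m), xi)
        if u[m] > hi + tol:
            out.append(Violation(f"uptake[{m}]", u[m] - hi, tol))
        if u[m] < -ex.L - tol:
            out.append(Violation(f"secretion[{m}]", u[m] + ex.L, tol))
    return out
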