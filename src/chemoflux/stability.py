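"""Stability classification, bifurcation diagram and multistable windows.

A steady state of the culture is unstable exactly where the effective
growth rate ``mu*(xi)`` is locally increasing, and stable otherwise
(plateaus included).  Since ``D* = mu*/phi``, folds of the X-vs-D
bifurcation diagram sit at local extrema of ``mu*``; between two folds
several branches can coexist at the same dilution rate, which is the
multistable (hysteresis) regime.  Without toxic feedback ``mu* = z*`` is
non-increasing in ``xi``, so ``D*(xi)`` is one-to-one and no multistable
window can exist.

An independent cross-check is provided by the Jacobian eigenvalues of the
bioreactor balance equations at the steady state, computed by central
finite differences on a reduced dynamical system in which growth-limiting
nutrients (pinned at zero concentration) are eliminated through the
supply-balance relation ``u_i = c_i D / X``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .model import Medium, MetabolicModel, solve_fba
from .steady_state import (
    SteadyStateCurve,
    SteadyStatePoint,
    ToxicitySpec,
    effective_growth,
    solve_point,
)


def default_slope_threshold(curve: SteadyStateCurve) -> float:
    """Scale-aware plateau threshold: 1e-4 x mu*(0) / xi_m."""
    pts = curve.feasible_points
    mu0 = pts[0].mu_star
    xi_max = pts[-1].xi
    return 1e-4 * abs(mu0) / xi_max


def classify_stability(curve: SteadyStateCurve,
                       eps_slope: float | None = None) -> SteadyStateCurve:
    """Flag each feasible point stable/unstable from the slope of ``mu*``.

    Uses centered finite differences (one-sided at the ends); a point is
    unstable iff the local slope exceeds ``+eps_slope``.  Flags depend only
    on ``mu*(xi)`` and are therefore independent of phi.
    """
    pts = curve.feasible_points
    if len(pts) < 3:
        raise ValueError("need at least three feasible points to classify")
    if eps_slope is None:
        eps_slope = default_slope_threshold(curve)
    xi = np.array([p.xi for p in pts])
    mu = np.array([p.mu_star for p in pts])
    slope = np.gradient(mu, xi)
    for p, s in zip(pts, slope):
        p.stable = bool(s <= eps_slope)
    return curve


@dataclass
class Branch:
    """Maximal xi-interval of constant stability class."""

    xi: np.ndarray
    D: np.ndarray
    X: np.ndarray
    stable: bool

    @property
    def D_range(self) -> tuple[float, float]:
        return float(self.D.min()), float(self.D.max())

    def covers(self, D: float) -> bool:
        lo, hi = self.D_range
        return lo <= D <= hi

    def X_at(self, D: float) -> float:
        """Interpolate the branch cell density at a dilution rate."""
        order = np.argsort(self.D)
        return float(np.interp(D, self.D[order], self.X[order]))


@dataclass
class BifurcationDiagram:
    """X-vs-D diagram: branches, folds and multistable D-windows.

    The washout branch (X = 0, any D; stable for D above the washout rate)
    is kept as metadata, never merged into the X > 0 branches.
    """

    branches: list[Branch]
    folds: list[tuple[float, float]]          # (xi, D)
    windows: list[tuple[float, float]]        # (D_lo, D_hi)
    phi: float
    washout_D_max: float | None = None
    meta: dict = field(default_factory=dict)

    def n_states(self, D: float) -> int:
        """Number of coexisting X > 0 steady states at dilution rate D."""
        return sum(1 for b in self.branches if b.covers(D))


def _refined_fold(mu_fn, xi_lo, xi_hi, sign: float, rtol: float) -> tuple[float, float]:
    """Locate a local extremum of mu* in [xi_lo, xi_hi] by bounded search."""
    res = minimize_scalar(lambda x: -sign * mu_fn(x), bounds=(xi_lo, xi_hi),
                          method="bounded",
                          options={"xatol": rtol * max(xi_hi, 1e-12)})
    return float(res.x), float(sign * -res.fun)


def build_diagram(curve: SteadyStateCurve, model: MetabolicModel | None = None,
                  medium: Medium | None = None, tox: ToxicitySpec | None = None,
                  rtol: float = 1e-5) -> BifurcationDiagram:
    """Assemble the bifurcation diagram from a classified curve.

    Folds are detected at sign changes of the discrete derivative of
    ``D*(xi)`` and, when the model is supplied, refined by bounded scalar
    search (re-solving the LP) to relative xi precision ``rtol``.
    Multistable windows are the dilution-rate intervals bounded by fold
    D-values on which more than one branch coexists.
    """
    pts = [p for p in curve.feasible_points if p.mu_star > 0]
    if any(p.stable is None for p in pts):
        curve = classify_stability(curve)
        pts = [p for p in curve.feasible_points if p.mu_star > 0]
    xi = np.array([p.xi for p in pts])
    D = np.array([p.D_star for p in pts])
    X = np.array([p.X_star for p in pts])
    stable = np.array([p.stable for p in pts])

    mu_fn = None
    if model is not None and medium is not None and tox is not None:
        mu_fn = lambda x: solve_point(model, medium, tox, float(x),
                                      curve.phi).mu_star  # noqa: E731

    folds: list[tuple[float, float]] = []
    dD = np.diff(D) / np.diff(xi)
    for i in np.flatnonzero(np.sign(dD[:-1]) * np.sign(dD[1:]) < 0):
        sign = 1.0 if dD[i] > 0 else -1.0  # +1: local max of D*, -1: local min
        if mu_fn is not None:
            fx, fmu = _refined_fold(mu_fn, xi[i], xi[i + 2], sign, rtol)
            folds.append((fx, fmu / curve.phi))
        else:
            folds.append((float(xi[i + 1]), float(D[i + 1])))

    # branches: maximal runs of constant stability flag
    branches: list[Branch] = []
    start = 0
    for i in range(1, len(pts) + 1):
        if i == len(pts) or stable[i] != stable[start]:
            branches.append(Branch(xi=xi[start:i], D=D[start:i],
                                   X=X[start:i], stable=bool(stable[start])))
            start = i

    # windows: intervals between fold D-values covered by > 1 branch
    windows: list[tuple[float, float]] = []
    fold_Ds = sorted(d for _, d in folds)
    edges = [0.0] + fold_Ds + [float(D.max())]
    for lo, hi in zip(edges, edges[1:]):
        if hi - lo <= 0:
            continue
        mid = 0.5 * (lo + hi)
        if sum(1 for b in branches if b.covers(mid)) > 1:
            if windows and abs(windows[-1][1] - lo) < 1e-12 * max(1.0, hi):
                windows[-1] = (windows[-1][0], hi)
            else:
                windows.append((lo, hi))
    return BifurcationDiagram(branches=branches, folds=folds, windows=windows,
                              phi=curve.phi,
                              washout_D_max=float(D[0]) if xi[0] == 0 else None,
                              meta={"n_points": len(pts)})


@dataclass
class EigenCheck:
    max_real: float
    eigenvalues: np.ndarray
    state_labels: list[str]

    @property
    def stable(self) -> bool:
        return self.max_real < 0


def jacobian_eigen_check(model: MetabolicModel, medium: Medium,
                         tox: ToxicitySpec, point: SteadyStatePoint,
                         phi: float = 1.0, perturbation: float = 1e-6,
                         s_zero_tol: float = 1e-7,
                         eq_tol: float = 1e-6) -> EigenCheck:
    """Jacobian eigenvalues of the bioreactor balances at a steady state.

    The dynamical state is the cell density plus the culture concentration
    of every tracked (finite-feed) external metabolite.  Metabolites that
    are growth-limiting at the point (steady concentration at zero) are
    eliminated: on the slow manifold their uptake equals the supply,
    ``u_i = c_i D / X``.  The Jacobian of the remaining smooth system is
    formed by central differences of relative step ``perturbation`` and its
    eigenvalues returned; the point must satisfy the steady-state balances
    to within ``eq_tol`` (relative).

    The washout equilibrium (X = 0) is handled analytically: its rates are
    ``mu(0) - phi D`` along the cell-density axis and ``-D`` along each
    concentration axis.
    """
    D = point.D_star
    tracked = [m for m in model.external_metabolites
               if np.isfinite(medium.conc(m))]
    if point.X_star == 0.0 or not point.feasible:
        if not np.isfinite(D) or D < 0:
            raise ValueError("washout point needs a dilution rate D_star")
        mu0 = solve_point(model, medium, tox, 0.0, phi).mu_star
        eig = np.array([mu0 - phi * D] + [-D] * len(tracked))
        return EigenCheck(float(eig.max()), eig, ["X"] + tracked)

    limiting = [m for m in tracked
                if point.s_star[m] <= s_zero_tol and point.u_star[m] > 0]
    free = [m for m in tracked if m not in limiting]

    def rhs(state: np.ndarray) -> np.ndarray:
        X = state[0]
        s = dict(zip(free, state[1:]))
        caps = {m: medium.conc(m) * D / X for m in limiting}
        caps.update({m: np.inf for m in free})
        sol = solve_fba(model, medium, 0.0, uptake_caps=caps)
        if not sol.optimal:
            raise RuntimeError("LP infeasible while perturbing around the "
                               "steady state")
        s_full = dict(s)
        s_full.update({m: 0.0 for m in limiting})
        mu = effective_growth(sol.z, s_full, tox)
        f = [(mu - phi * D) * X]
        for m in free:
            f.append(-sol.exchanges[m] * X - (s[m] - medium.conc(m)) * D)
        return np.array(f)

    x0 = np.array([point.X_star] + [point.s_star[m] for m in free])
    f0 = rhs(x0)
    scale = np.maximum(np.abs(x0), 1.0)
    if np.any(np.abs(f0) > eq_tol * np.maximum(scale * max(D, 1e-6), 1e-9)):
        raise ValueError(f"point is not at equilibrium: residual {f0}")
    n = x0.size
    J = np.zeros((n, n))
    for j in range(n):
        h = perturbation * scale[j]
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (rhs(xp) - rhs(xm)) / (2 * h)
    eig = np.linalg.eigvals(J)
    return EigenCheck(float(eig.real.max()), eig, ["X"] + free)
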