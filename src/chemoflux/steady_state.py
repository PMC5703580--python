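"""Steady states of the continuous culture as functions of xi = X/D.

In steady state every macroscopic variable of the bioreactor is a function
of the single parameter ``xi`` (inverse cell-specific perfusion rate):

- the growth-maximizing LP at ``xi`` yields the biomass rate ``z*(xi)`` and
  exchanges ``u*(xi)``;
- culture concentrations follow as ``s_i* = c_i - u_i* xi``;
- toxic byproducts feed back on growth, ``mu* = z* - sigma(s*)`` (death
  rate) or ``mu* = z* K(s*)`` (yield factor);
- the dilution rate and cell density of the steady state are
  ``D* = mu*/phi`` and ``X* = xi mu*/phi``, with ``phi`` the bleeding
  coefficient (fraction of cells leaving with the outflow).

``D_max = D*(0)`` is the washout dilution rate; ``xi_m`` (the medium depth)
is the largest xi at which maintenance can still be met.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .model import (
    RESIDUAL_TOL,
    FluxSolution,
    Medium,
    MetabolicModel,
    solve_fba,
    uptake_bound,
)


class DegenerateMediumError(RuntimeError):
    """The medium cannot sustain maintenance even at vanishing cell load."""


@dataclass(frozen=True)
class ToxicitySpec:
    """Feedback of toxic byproducts on the effective growth rate.

    ``death_rate``: ``mu = z - sum_j tau_j s_j`` with linear death-rate
    coefficients ``tau_j`` (1/h/mM); negative ``mu`` is legal and means the
    population decays.  ``yield_factor``: ``mu = z prod_j (1 + s_j/K_j)^-1``
    with half-inhibition constants ``K_j`` (mM), so ``0 <= mu <= z``.
    """

    mechanism: str = "death_rate"
    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mechanism not in ("death_rate", "yield_factor"):
            raise ValueError(f"unknown toxicity mechanism {self.mechanism!r}")
        for m, v in self.coefficients.items():
            if v < 0:
                raise ValueError(f"toxicity coefficient for {m} must be >= 0")

    @staticmethod
    def none() -> "ToxicitySpec":
        return ToxicitySpec("death_rate", {})


def effective_growth(z_star: float, s_star: dict[str, float],
                     tox: ToxicitySpec) -> float:
    """Apply the toxicity feedback to the biomass synthesis rate."""
    if tox.mechanism == "death_rate":
        sigma = sum(tau * s_star.get(m, 0.0) for m, tau in tox.coefficients.items())
        return z_star - sigma
    K = 1.0
    for m, half in tox.coefficients.items():
        K *= 1.0 / (1.0 + s_star.get(m, 0.0) / half)
    return z_star * K


def steady_concentrations(u_star: dict[str, float], xi: float,
                          medium: Medium) -> dict[str, float]:
    """Stationary culture concentrations ``s_i = c_i - u_i xi``.

    Secreted metabolites (``u_i < 0``) accumulate above their feed level.
    A consumed metabolite may touch zero (it is then limiting); values
    below ``-tol`` indicate an upstream violation of the uptake bound and
    raise.  Metabolites fed at infinite concentration stay infinite.
    """
    tol = RESIDUAL_TOL * max(1.0, xi)
    s: dict[str, float] = {}
    for m, u in u_star.items():
        c = medium.conc(m)
        if not np.isfinite(c):
            s[m] = np.inf
            continue
        val = c - u * xi
        if val < -tol:
            raise RuntimeError(
                f"negative steady concentration for {m}: {val:.3e} "
                "(uptake bound violated upstream)")
        if val < 0:
            warnings.warn(f"clipping s[{m}] = {val:.3e} to 0", stacklevel=2)
            val = 0.0
        s[m] = val
    return s


@dataclass(frozen=True)
class PhaseSignature:
    """Qualitative exchange mode: who is secreted, who limits growth."""

    secreted: frozenset[str]
    limiting: frozenset[str]


@dataclass
class SteadyStatePoint:
    xi: float
    feasible: bool
    z_star: float = np.nan
    u_star: dict[str, float] = field(default_factory=dict)
    s_star: dict[str, float] = field(default_factory=dict)
    mu_star: float = np.nan
    D_star: float = np.nan
    X_star: float = np.nan
    phase: PhaseSignature | None = None
    stable: bool | None = None
    solution: FluxSolution | None = None


@dataclass
class SteadyStateCurve:
    """Per-xi steady-state records over an increasing xi grid."""

    points: list[SteadyStatePoint]
    phi: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        xis = [p.xi for p in self.points]
        if any(b <= a for a, b in zip(xis, xis[1:])):
            raise ValueError("xi grid must be strictly increasing")

    @property
    def feasible_points(self) -> list[SteadyStatePoint]:
        return [p for p in self.points if p.feasible]

    def array(self, attr: str, feasible_only: bool = True) -> np.ndarray:
        pts = self.feasible_points if feasible_only else self.points
        return np.array([getattr(p, attr) for p in pts], dtype=float)


def active_flux_threshold(model: MetabolicModel) -> float:
    """Scale-aware zero test for exchanges: 1e-6 x max finite V."""
    finite = [ex.V for ex in model.exchanges.values() if np.isfinite(ex.V)]
    return 1e-6 * max(finite) if finite else 1e-6


def _signature(model: MetabolicModel, medium: Medium, xi: float,
               u: dict[str, float], eps_u: float) -> PhaseSignature:
    secreted = frozenset(m for m, v in u.items() if v < -eps_u)
    limiting: set[str] = set()
    if xi > 0:
        for m, v in u.items():
            c = medium.conc(m)
            if not np.isfinite(c) or c == 0.0:
                continue
            avail = c / xi
            ex = model.exchanges[m]
            # limiting = the availability side of min(V, c/xi) is active
            if avail <= ex.V + eps_u and abs(v - avail) < eps_u:
                limiting.add(m)
    return PhaseSignature(secreted, frozenset(limiting))


def solve_point(model: MetabolicModel, medium: Medium, tox: ToxicitySpec,
                xi: float, phi: float) -> SteadyStatePoint:
    """Full steady-state description at one xi (or an infeasible marker)."""
    sol = solve_fba(model, medium, xi)
    if not sol.optimal:
        return SteadyStatePoint(xi=xi, feasible=False)
    s = steady_concentrations(sol.exchanges, xi, medium)
    mu = effective_growth(sol.z, s, tox)
    eps_u = active_flux_threshold(model)
    return SteadyStatePoint(
        xi=xi, feasible=True, z_star=sol.z, u_star=dict(sol.exchanges),
        s_star=s, mu_star=mu, D_star=mu / phi, X_star=xi * mu / phi,
        phase=_signature(model, medium, xi, sol.exchanges, eps_u),
        solution=sol)


def scan(model: MetabolicModel, medium: Medium, tox: ToxicitySpec,
         xi_grid, phi: float = 1.0) -> SteadyStateCurve:
    """Map a xi grid to the steady-state curve.

    Each grid point is solved independently: growth LP, stationary
    concentrations, toxicity-corrected growth, then ``D* = mu*/phi`` and
    ``X* = xi mu*/phi``.  Points beyond the medium depth are kept as
    infeasible markers.
    """
    xi_grid = np.asarray(list(xi_grid), dtype=float)
    if xi_grid.size == 0:
        raise ValueError("empty xi grid")
    if np.any(xi_grid < 0) or np.any(np.diff(xi_grid) <= 0):
        raise ValueError("xi grid must be strictly increasing and >= 0")
    if not 0.0 < phi <= 1.0:
        raise ValueError("bleeding coefficient phi must lie in (0, 1]")
    points = [solve_point(model, medium, tox, xi, phi) for xi in xi_grid]
    if not any(p.feasible for p in points):
        raise DegenerateMediumError(
            "no feasible steady state on the grid (medium depth <= 0?)")
    return SteadyStateCurve(points=points, phi=phi,
                            meta={"grid": "explicit", "n": len(points)})


def washout_rate(model: MetabolicModel, medium: Medium, tox: ToxicitySpec,
                 phi: float = 1.0) -> float:
    """Washout dilution rate ``D_max = mu*(0+)/phi`` (1/h).

    Computed at the xi -> 0 limit, where secreted byproducts are infinitely
    diluted (their steady concentration vanishes), so toxicity from
    secretion does not affect the washout rate.
    """
    pt = solve_point(model, medium, tox, 0.0, phi)
    if not pt.feasible:
        raise DegenerateMediumError("infeasible at xi = 0: medium cannot "
                                    "support growth at all")
    return pt.D_star


def find_xi_max(model: MetabolicModel, medium: Medium,
                upper_probe: float = 1e9, rtol: float = 1e-6) -> float:
    """Medium depth ``xi_m``: feasibility boundary of the xi scan.

    Located by bisection on LP feasibility to relative width ``rtol``.
    Returns ``inf`` when still feasible at ``upper_probe`` (degenerate
    no-maintenance case).
    """
    if not solve_fba(model, medium, 0.0, lexicographic=False).optimal:
        raise DegenerateMediumError("infeasible at xi = 0 (medium depth <= 0)")
    lo, hi = 0.0, 1.0
    while solve_fba(model, medium, hi, lexicographic=False).optimal:
        lo = hi
        hi *= 2.0
        if hi > upper_probe:
            return np.inf
    while hi - lo > rtol * hi:
        mid = 0.5 * (lo + hi)
        if solve_fba(model, medium, mid, lexicographic=False).optimal:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def make_xi_grid(model: MetabolicModel, medium: Medium, n: int = 80,
                 lo_factor: float = 1e-4, xi_max: float | None = None) -> np.ndarray:
    """Geometric xi grid from ``xi_m * lo_factor`` to ``xi_m``, plus xi = 0."""
    if xi_max is None:
        xi_max = find_xi_max(model, medium)
    if not np.isfinite(xi_max):
        raise ValueError("xi_m is infinite; pass an explicit xi_max")
    inner = np.geomspace(xi_max * lo_factor, xi_max * (1 - 1e-9), n)
    return np.concatenate(([0.0], inner))


@dataclass(frozen=True)
class PhaseBoundary:
    """A change of exchange mode, bracketed to [xi_lo, xi_hi]."""

    xi_lo: float
    xi_hi: float
    left: PhaseSignature
    right: PhaseSignature

    @property
    def xi(self) -> float:
        return 0.5 * (self.xi_lo + self.xi_hi)


def detect_phases(curve: SteadyStateCurve, model: MetabolicModel | None = None,
                  medium: Medium | None = None, rtol: float = 1e-6
                  ) -> list[PhaseBoundary]:
    """Boundaries between qualitatively distinct exchange modes.

    A boundary is emitted between consecutive feasible grid points whose
    phase signatures differ.  When the model is supplied, each boundary is
    localized by bisection (re-solving the LP) to relative precision
    ``rtol``, independent of the grid spacing.
    """
    pts = curve.feasible_points
    if len(pts) < 2:
        raise ValueError("need at least two feasible points")
    eps_u = active_flux_threshold(model) if model is not None else None
    out: list[PhaseBoundary] = []
    for a, b in zip(pts, pts[1:]):
        if a.phase == b.phase:
            continue
        lo, hi = a.xi, b.xi
        sig_lo, sig_hi = a.phase, b.phase
        if model is not None and medium is not None:
            while hi - lo > rtol * max(hi, 1e-12):
                mid = 0.5 * (lo + hi)
                sol = solve_fba(model, medium, mid)
                if not sol.optimal:
                    break
                sig = _signature(model, medium, mid, sol.exchanges, eps_u)
                if sig == sig_lo:
                    lo = mid
                else:
                    hi, sig_hi = mid, sig
        out.append(PhaseBoundary(lo, hi, sig_lo, sig_hi))
    return out


def scan_auto(model: MetabolicModel, medium: Medium, tox: ToxicitySpec,
              phi: float = 1.0, n: int = 80, lo_factor: float = 1e-4,
              xi_max: float | None = None, refine: bool = True
              ) -> SteadyStateCurve:
    """Scan on an automatic geometric grid with local refinement.

    After a first pass, extra points are inserted around detected phase
    boundaries and around sign changes of the finite-difference slope of
    ``mu*`` so that folds and metabolic switches are well resolved.
    """
    grid = make_xi_grid(model, medium, n=n, lo_factor=lo_factor, xi_max=xi_max)
    curve = scan(model, medium, tox, grid, phi)
    if not refine:
        return curve
    extra: list[float] = []
    for b in detect_phases(curve, model, medium):
        for f in (1e-2, 1e-3, 1e-4):
            extra += [b.xi * (1 - f), b.xi, b.xi * (1 + f)]
    pts = curve.feasible_points
    xi = np.array([p.xi for p in pts])
    mu = np.array([p.mu_star for p in pts])
    dmu = np.diff(mu) / np.diff(xi)
    for i in np.flatnonzero(np.sign(dmu[:-1]) != np.sign(dmu[1:])):
        extra += list(np.linspace(xi[i], xi[i + 2], 9)[1:-1])
    known = {p.xi for p in curve.points}
    new = sorted(x for x in set(extra) if x not in known and x > 0)
    merged = sorted(known | set(new))
    pts_by_xi = {p.xi: p for p in curve.points}
    points = [pts_by_xi.get(x) or solve_point(model, medium, tox, x, phi)
              for x in merged]
    return SteadyStateCurve(points=points, phi=phi,
                            meta={"grid": "auto", "n": len(points)})


def rescale_phi(curve: SteadyStateCurve, phi: float) -> SteadyStateCurve:
    """Same steady states under a different bleeding coefficient.

    ``u*``, ``s*``, ``mu*`` are phi-independent; ``D*`` and ``X*`` scale as
    1/phi, so the diagram (phi D*, phi X*) is invariant.
    """
    if not 0.0 < phi <= 1.0:
        raise ValueError("phi must lie in (0, 1]")
    pts = [replace(p, D_star=p.mu_star / phi if p.feasible else np.nan,
                   X_star=p.xi * p.mu_star / phi if p.feasible else np.nan)
           for p in curve.points]
    return SteadyStateCurve(points=pts, phi=phi, meta=dict(curve.meta))
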