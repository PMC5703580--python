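"""Dynamic simulation of the bioreactor with instantaneous FBA.

Integrates the culture balances

    dX/dt  = (mu - phi D(t)) X
    ds_i/dt = -u_i X - (s_i - c_i) D(t)

where at every step the cellular rates ``(z, u)`` come from the
growth-maximizing LP and ``mu`` applies the toxicity feedback at the
instantaneous concentrations.  During transients the uptake of a tracked
metabolite is capped by availability over the step,
``u_i <= min(V_i, s_i / (X h))`` with ``h`` the current step size, so no
concentration can be driven negative within a step; this replaces the
steady-state-only supply bound ``c_i/xi``.  The integrator is an explicit
adaptive Heun (trapezoidal predictor-corrector) with step rejection on
overshoot — the right-hand side is only piecewise smooth because the LP
solution jumps between vertices, so a high-order smooth method would gain
nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import Medium, MetabolicModel, solve_fba
from .steady_state import SteadyStateCurve, ToxicitySpec, effective_growth
from .stability import BifurcationDiagram
from .units import HOURS_PER_DAY


@dataclass(frozen=True)
class DilutionSchedule:
    """Dilution rate over time: constant or piecewise-linear in the knots.

    Knot times are hours, rates 1/h.  Between knots the rate is linearly
    interpolated; beyond the last knot it is held constant.  ``phi`` is the
    bleeding coefficient of the run.
    """

    knots: tuple[tuple[float, float], ...]
    phi: float = 1.0

    def __post_init__(self) -> None:
        times = [t for t, _ in self.knots]
        if not times:
            raise ValueError("schedule needs at least one knot")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("knot times must be strictly increasing")
        if any(d < 0 for _, d in self.knots):
            raise ValueError("dilution rate must be >= 0")
        if not 0.0 < self.phi <= 1.0:
            raise ValueError("phi must lie in (0, 1]")

    @staticmethod
    def constant(D: float, phi: float = 1.0) -> "DilutionSchedule":
        return DilutionSchedule(((0.0, D),), phi)

    @staticmethod
    def from_days(knots_day: list[tuple[float, float]],
                  phi: float = 1.0) -> "DilutionSchedule":
        """Knots given as (time in days, D in 1/day)."""
        return DilutionSchedule(tuple((t * HOURS_PER_DAY, d / HOURS_PER_DAY)
                                      for t, d in knots_day), phi)

    def evaluate(self, t: float) -> float:
        if t < 0:
            raise ValueError("t must be >= 0")
        times = np.array([k[0] for k in self.knots])
        vals = np.array([k[1] for k in self.knots])
        return float(np.interp(t, times, vals))

    __call__ = evaluate


def evaluate_schedule(schedule: DilutionSchedule, t: float) -> float:
    return schedule.evaluate(t)


@dataclass
class Trajectory:
    """Sampled run: state, instantaneous cellular rates and event log."""

    t: np.ndarray                       # h
    X: np.ndarray                       # gDW/L
    s: dict[str, np.ndarray]            # mM
    u: dict[str, np.ndarray]            # mmol/gDW/h
    z: np.ndarray                       # 1/h
    mu: np.ndarray                      # 1/h
    D: np.ndarray                       # 1/h
    events: list[tuple[float, str]] = field(default_factory=list)

    @property
    def terminal(self) -> dict:
        return {"t": float(self.t[-1]), "X": float(self.X[-1]),
                "D": float(self.D[-1]),
                "s": {m: float(v[-1]) for m, v in self.s.items()}}


def _cell_rates(model: MetabolicModel, medium: Medium, tox: ToxicitySpec,
                s: dict[str, float], X: float, h: float, D: float):
    """Instantaneous (z, mu, u) under the availability-capped LP.

    The cap per tracked metabolite is the uptake that would exactly drain
    it to zero in one explicit Euler step of size ``h``, counting the feed
    inflow and dilution outflow over the step:
    ``u <= (s (1 - D h) + c D h) / (X h)``.  As ``s -> 0`` this tends to
    the steady supply bound ``c D / X``.
    """
    caps = {}
    for m, val in s.items():
        if X * h <= 0:
            caps[m] = np.inf
            continue
        avail = max(val * (1.0 - D * h), 0.0) + medium.conc(m) * D * h
        caps[m] = avail / (X * h)
    sol = solve_fba(model, medium, 0.0, uptake_caps=caps)
    if not sol.optimal:
        # maintenance unmet: cells stop synthesizing biomass and only decay
        mu = effective_growth(0.0, s, tox) if tox.mechanism == "death_rate" else 0.0
        return 0.0, mu, {m: 0.0 for m in model.external_metabolites}, False
    mu = effective_growth(sol.z, s, tox)
    return sol.z, mu, dict(sol.exchanges), True


def simulate(model: MetabolicModel, medium: Medium, tox: ToxicitySpec,
             schedule: DilutionSchedule, X0: float,
             s0: dict[str, float] | None = None, t_end: float = 480.0,
             output_dt: float = 6.0, rel_tol: float = 1e-3,
             dt_min: float = 1e-5) -> Trajectory:
    """Integrate the culture from inoculum ``X0`` under a dilution schedule.

    ``s0`` defaults to fresh medium (``s_i = c_i``, zero for metabolites the
    medium lacks); metabolites fed at infinite concentration are not
    tracked.  Output is sampled every ``output_dt`` hours; internally the
    step adapts between ``dt_min`` and ``output_dt`` with halving on
    negative-concentration overshoot or a Euler/Heun discrepancy above
    ``rel_tol``.  An infeasible LP mid-run switches to the cell-death
    branch (z = 0) and is logged, not raised.
    """
    if X0 <= 0:
        raise ValueError("X0 must be > 0")
    tracked = [m for m in model.external_metabolites
               if np.isfinite(medium.conc(m))]
    if s0 is None:
        s = {m: medium.conc(m) for m in tracked}
    else:
        s = {m: float(s0.get(m, medium.conc(m))) for m in tracked}
        if any(v < 0 for v in s.values()):
            raise ValueError("initial concentrations must be >= 0")
    phi = schedule.phi

    out_t = [0.0]
    out_X = [X0]
    out_s = {m: [s[m]] for m in tracked}
    out_u = {m: [np.nan] for m in tracked}
    out_z, out_mu, out_D = [np.nan], [np.nan], [schedule(0.0)]
    events: list[tuple[float, str]] = []

    t, X = 0.0, X0
    prev_ok = True
    dt = output_dt / 4.0
    next_out = output_dt
    washed_out = False
    exhausted: set[str] = set()
    last = (np.nan, np.nan, {m: np.nan for m in tracked})  # z, mu, u

    def derivs(t_, X_, s_, h):
        D_ = schedule(t_)
        z_, mu_, u_, ok = _cell_rates(model, medium, tox, s_, X_, h, D_)
        dX = (mu_ - phi * D_) * X_
        ds = {m: -u_.get(m, 0.0) * X_ - (s_[m] - medium.conc(m)) * D_
              for m in tracked}
        return dX, ds, (z_, mu_, u_), ok

    neg_tol = {m: 1e-9 * max(medium.conc(m), 1.0) for m in tracked}
    # concentration scale for the relative error test: a metabolite far below
    # the overall feed scale should not throttle the step
    conc_scale = max([medium.conc(m) for m in tracked
                      if medium.conc(m) > 0] or [1.0])
    while t < t_end - 1e-12:
        h = min(dt, next_out - t, t_end - t)
        dX1, ds1, rates1, ok1 = derivs(t, X, s, h)
        X_e = X + h * dX1
        s_e = {m: s[m] + h * ds1[m] for m in tracked}
        overshoot = X_e < 0 or any(v < -neg_tol[m] for m, v in s_e.items())
        if overshoot and h > dt_min:
            dt = max(h / 2.0, dt_min)
            continue
        X_e = max(X_e, 0.0)
        s_e = {m: max(v, 0.0) for m, v in s_e.items()}
        dX2, ds2, _, _ = derivs(t + h, X_e, s_e, h)
        X_n = X + 0.5 * h * (dX1 + dX2)
        s_n = {m: s[m] + 0.5 * h * (ds1[m] + ds2[m]) for m in tracked}
        overshoot = X_n < 0 or any(v < -neg_tol[m] for m, v in s_n.items())
        err = abs(X_n - X_e) / max(abs(X_n), 1e-8 * X0)
        for m in tracked:
            err = max(err, abs(s_n[m] - s_e[m])
                      / max(abs(s_n[m]), 1e-2 * conc_scale))
        if (overshoot or err > rel_tol) and h > dt_min:
            dt = max(h / 2.0, dt_min)
            continue
        # accept
        if not ok1 and prev_ok:
            events.append((t, "lp_infeasible"))
        prev_ok = ok1
        t += h
        X = max(X_n, 0.0)
        s = {m: max(v, 0.0) for m, v in s_n.items()}
        last = rates1
        dt = min(dt * 1.3, output_dt)
        if not washed_out and X < 1e-12 * X0:
            events.append((t, "washout"))
            washed_out = True
        for m in tracked:
            if m not in exhausted and medium.conc(m) > 0 \
                    and s[m] <= 1e-4 * medium.conc(m):
                events.append((t, f"nutrient_exhausted:{m}"))
                exhausted.add(m)
        if t >= next_out - 1e-9 or t >= t_end - 1e-12:
            out_t.append(t)
            out_X.append(X)
            for m in tracked:
                out_s[m].append(s[m])
                out_u[m].append(last[2].get(m, np.nan))
            out_z.append(last[0])
            out_mu.append(last[1])
            out_D.append(schedule(t))
            next_out = min(next_out + output_dt, t_end)

    return Trajectory(
        t=np.array(out_t), X=np.array(out_X),
        s={m: np.array(v) for m, v in out_s.items()},
        u={m: np.array(v) for m, v in out_u.items()},
        z=np.array(out_z), mu=np.array(out_mu), D=np.array(out_D),
        events=events)


def assign_branch(diagram: BifurcationDiagram, D: float, X: float,
                  washout_tol: float = 1e-6) -> int | str:
    """Index of the nearest branch at dilution rate D ('washout' if X ~ 0)."""
    if X < washout_tol:
        return "washout"
    best, best_dist = None, np.inf
    for i, b in enumerate(diagram.branches):
        lo, hi = b.D_range
        if not (lo - 1e-9 <= D <= hi + 1e-9):
            continue
        dist = abs(X - b.X_at(D))
        if dist < best_dist:
            best, best_dist = i, dist
    if best is None:  # no branch covers D
        return "washout" if diagram.washout_D_max and D > diagram.washout_D_max \
            else -1
    return best


def ramp_into_window(window_lo: float, D_target: float, phi: float = 1.0,
                     t_hold: float = 300.0, t_ramp: float = 120.0
                     ) -> DilutionSchedule:
    """Schedule that first establishes the high-density state, then ramps.

    Holds ``D = window_lo / 2`` (below the lower fold, where only the
    high-density branch exists) for ``t_hold`` hours, then ramps linearly
    to ``D_target`` over ``t_ramp`` hours and stays there.  The hold must
    be long enough for the culture to grow up from the inoculum; with a
    growth-rate surplus ``g`` (1/h) the required hold is about
    ``ln(X_final/X0)/g``.
    """
    D0 = 0.5 * window_lo
    return DilutionSchedule(((0.0, D0), (t_hold, D0),
                             (t_hold + t_ramp, D_target)), phi)


@dataclass
class PathDependenceResult:
    constant_run: Trajectory
    ramp_run: Trajectory
    constant_branch: int | str
    ramp_branch: int | str


def path_dependence_experiment(model: MetabolicModel, medium: Medium,
                               tox: ToxicitySpec, D_target: float,
                               ramp_schedule: DilutionSchedule,
                               t_end: float, X0: float = 1e-3,
                               output_dt: float = 12.0,
                               diagram: BifurcationDiagram | None = None,
                               curve: SteadyStateCurve | None = None
                               ) -> PathDependenceResult:
    """Constant-D versus ramped-D protocol at the same final dilution rate.

    Run (a) applies ``D_target`` from the start; run (b) follows
    ``ramp_schedule`` (which must end at ``D_target``).  Inside a
    multistable window the two protocols land on different branches of the
    bifurcation diagram; outside, they must agree.
    """
    from .stability import build_diagram  # local to avoid cycle at import
    from .steady_state import scan_auto

    phi = ramp_schedule.phi
    if abs(ramp_schedule(t_end) - D_target) > 1e-9 * max(D_target, 1e-9):
        raise ValueError("ramp schedule must end at D_target")
    if diagram is None:
        if curve is None:
            curve = scan_auto(model, medium, tox, phi=phi, n=100)
        diagram = build_diagram(curve, model, medium, tox)
    if not any(lo < D_target < hi for lo, hi in diagram.windows):
        warnings.warn("D_target lies outside every multistable window; both "
                      "protocols should reach the same branch", stacklevel=2)
    run_a = simulate(model, medium, tox, DilutionSchedule.constant(D_target, phi),
                     X0=X0, t_end=t_end, output_dt=output_dt)
    run_b = simulate(model, medium, tox, ramp_schedule,
                     X0=X0, t_end=t_end, output_dt=output_dt)
    return PathDependenceResult(
        constant_run=run_a, ramp_run=run_b,
        constant_branch=assign_branch(diagram, D_target, run_a.X[-1]),
        ramp_branch=assign_branch(diagram, D_target, run_b.X[-1]))
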