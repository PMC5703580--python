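"""Deterministic synthetic metabolic networks for testing.

Three topologies:

``toy``
    The solvable overflow network with its default reference parameters.
``chain``
    A linear pathway: one substrate, a chain of 1:1 conversions, a final
    energy-yielding step.  Growth is a single-path computation, so
    ``z*(xi) = (Y min(V, c/xi) - e) / y`` is known in closed form and is
    recorded alongside the model.
``branched``
    A randomized overflow network (fermentation-like and respiration-like
    branches with a crowding-limited high-yield branch), i.e. the toy
    topology with parameters drawn from ranges that respect its
    assumptions; the closed forms still apply.

All draws are reproducible from the given seed; an infeasible draw is
re-drawn a bounded number of times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Exchange, Medium, MetabolicModel, solve_fba
from .steady_state import ToxicitySpec
from .toy import ToyParams, toy_as_generic_model, toy_growth

_MAX_ATTEMPTS = 20


@dataclass(frozen=True)
class FixtureSpec:
    topology: str = "chain"          # toy | chain | branched
    n_reactions: int = 5
    seed: int = 0
    cost_range: tuple[float, float] = (0.05, 0.5)
    yield_range: tuple[int, int] = (10, 40)

    def __post_init__(self) -> None:
        if self.topology not in ("toy", "chain", "branched"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.n_reactions < 2:
            raise ValueError("need at least two reactions")


@dataclass
class Fixture:
    model: MetabolicModel
    medium: Medium
    toxicity: ToxicitySpec
    params: dict = field(default_factory=dict)
    expected_z = None  # callable xi -> z*, set when a closed form exists

    def __iter__(self):
        yield from (self.model, self.medium, self.toxicity)


def generate_fixture(spec: FixtureSpec) -> Fixture:
    rng = np.random.default_rng(spec.seed)
    for _ in range(_MAX_ATTEMPTS):
        fx = _draw(spec, rng)
        if solve_fba(fx.model, fx.medium, 0.0, lexicographic=False).optimal:
            return fx
    raise RuntimeError(f"no feasible fixture after {_MAX_ATTEMPTS} draws "
                       f"({spec})")


def _draw(spec: FixtureSpec, rng: np.random.Generator) -> Fixture:
    if spec.topology == "toy":
        p = ToyParams()
        model, medium, tox = toy_as_generic_model(p)
        fx = Fixture(model, medium, tox, params={"toy": p})
        fx.expected_z = lambda xi: toy_growth(p, xi)[0]
        return fx
    if spec.topology == "chain":
        return _chain(spec, rng)
    return _branched(spec, rng)


def _chain(spec: FixtureSpec, rng: np.random.Generator) -> Fixture:
    n = spec.n_reactions
    Y = int(rng.integers(*spec.yield_range))
    V = float(rng.uniform(0.2, 1.0))
    c = float(rng.uniform(5.0, 30.0))
    y = float(rng.uniform(100.0, 500.0))
    e = float(rng.uniform(0.1, 0.5)) * Y * V  # feasible at xi = 0
    mets = [f"M{i}" for i in range(n)] + ["E"]
    rxns = [f"step{i}" for i in range(n)]
    S = np.zeros((n + 1, n))
    for k in range(n - 1):
        S[k, k] = -1.0
        S[k + 1, k] = 1.0
    S[n - 1, n - 1] = -1.0
    S[n, n - 1] = Y
    costs = rng.uniform(*spec.cost_range, size=n)
    budget = float(10.0 * costs.sum() * V)
    model = MetabolicModel(
        metabolites=mets, reactions=rxns, S=S,
        lb=np.zeros(n), ub=np.full(n, np.inf),
        cost_fwd=costs, cost_rev=np.zeros(n),
        budget=budget, biomass={"E": y}, maintenance={"E": e},
        exchanges={"M0": Exchange(V=V, L=0.0)})
    medium = Medium({"M0": c})
    fx = Fixture(model, medium, ToxicitySpec.none(),
                 params={"Y": Y, "V": V, "c": c, "y": y, "e": e})

    def expected_z(xi: float) -> float:
        u = V if xi == 0 else min(V, c / xi)
        return (Y * u - e) / y

    fx.expected_z = expected_z
    return fx


def _branched(spec: FixtureSpec, rng: np.random.Generator) -> Fixture:
    for _ in range(_MAX_ATTEMPTS):
        N_F = float(rng.integers(1, 6))
        N_R = float(rng.integers(10, 51))
        if N_F >= N_R:
            continue
        V = float(rng.uniform(0.2, 1.0))
        r_max = float(rng.uniform(0.5, 1.0)) * V
        e = float(rng.uniform(0.2, 0.8)) * (N_F + N_R) * r_max
        if e / (N_F + N_R) > r_max:
            continue
        p = ToyParams(N_F=N_F, N_R=N_R, r_max=r_max, e=e,
                      y=float(rng.uniform(100.0, 500.0)), V=V,
                      tau=float(rng.uniform(0.0, 0.005)),
                      c=float(rng.uniform(5.0, 30.0)))
        model, medium, tox = toy_as_generic_model(p)
        fx = Fixture(model, medium, tox, params={"toy": p})
        fx.expected_z = lambda xi, p=p: toy_growth(p, xi)[0]
        return fx
    raise RuntimeError("no valid branched parameter draw")
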