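"""Analytically solvable overflow-metabolism network.

A single carbon source S is taken up at rate ``u <= min(V, c/xi)`` and
processed into an intermediate P (yielding ``N_F`` energy units per unit S,
fermentation-like).  P is either fully oxidized at rate ``r <= r_max``
(yielding ``N_R`` more energy units, respiration-like) or overflows as a
secreted waste W at rate ``-v``.  Energy E pays a constant maintenance
drain ``e`` and fuels biomass synthesis at yield ``y``; W is toxic, adding
a death rate ``tau * w`` to the growth balance.

Because growth maximization saturates both upper bounds, every steady-state
quantity has a closed form in xi, which makes this network the exact oracle
for the LP pipeline, the stability classifier and the dynamic integrator:

- ``u = min(V, c/xi)``, ``r = min(u, r_max)``, ``v = r - u``
- ``z = (N_F u + N_R r - e) / y``
- ``s* = c - min(V xi, c)``, ``w* = max(0, c - s* - r_max xi)``
- ``mu* = z - tau w*``

with three thresholds ``xi_0 = c/V`` (nutrient excess ends),
``xi_sec = c/r_max`` (waste secretion stops) and ``xi_m = c/u_m``
(maintenance fails), where ``u_m = e/(N_F + N_R)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Exchange, Medium, MetabolicModel
from .steady_state import ToxicitySpec
from .units import DW_PER_CELL_DEFAULT


class MaintenanceInfeasible(RuntimeError):
    """xi >= xi_m: the maintenance demand cannot be met."""


@dataclass(frozen=True)
class ToyParams:
    """Reference constants of the solvable network.

    ``N_F = 2`` and ``N_R = 38`` are the ATP yields of glycolysis and
    respiration; ``e`` a mammalian-typical ATP maintenance drain;
    ``r_max`` the respiratory capacity; ``V`` the glucose transporter
    limit; ``y`` the energy cost of biomass chosen so the maximum growth
    rate is about one per day; ``tau`` a lactate-like linear toxicity;
    ``c`` a standard medium glucose concentration.
    """

    N_F: float = 2.0
    N_R: float = 38.0
    r_max: float = 0.45      # mmol/gDW/h
    e: float = 1.0625        # mmol/gDW/h
    y: float = 348.0         # mmol/gDW
    V: float = 0.5           # mmol/gDW/h
    tau: float = 0.0022      # 1/h/mM
    c: float = 15.0          # mM
    dry_weight_per_cell: float = DW_PER_CELL_DEFAULT  # g

    def __post_init__(self) -> None:
        if not self.N_F < self.N_R:
            raise ValueError("requires N_F < N_R (fermentation yields less)")
        for name in ("N_F", "N_R", "r_max", "e", "y", "V", "c",
                     "dry_weight_per_cell"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.u_m > self.r_max:
            raise ValueError("requires u_m = e/(N_F+N_R) <= r_max "
                             "(growth without waste secretion possible)")

    @property
    def u_m(self) -> float:
        """Minimum uptake sustaining maintenance (mmol/gDW/h)."""
        return self.e / (self.N_F + self.N_R)


@dataclass(frozen=True)
class ToyThresholds:
    xi_0: float    # nutrient excess -> competition
    xi_sec: float  # overflow -> pure respiration
    xi_m: float    # medium depth


def toy_thresholds(params: ToyParams) -> ToyThresholds:
    return ToyThresholds(xi_0=params.c / params.V,
                         xi_sec=params.c / params.r_max,
                         xi_m=params.c / params.u_m)


def toy_fluxes(params: ToyParams, xi: float) -> tuple[float, float, float]:
    """Closed-form optimal fluxes ``(u, r, v)`` at a given xi."""
    if xi < 0:
        raise ValueError("xi must be >= 0")
    u = params.V if xi == 0 else min(params.V, params.c / xi)
    r = min(u, params.r_max)
    v = r - u
    return u, r, v


def toy_concentrations(params: ToyParams, xi: float) -> tuple[float, float]:
    """Closed-form stationary concentrations ``(s*, w*)`` at a given xi."""
    if xi < 0:
        raise ValueError("xi must be >= 0")
    s = params.c - min(params.V * xi, params.c)
    w = max(0.0, params.c - s - params.r_max * xi)
    return s, w


def toy_growth(params: ToyParams, xi: float) -> tuple[float, float]:
    """Closed-form ``(z, mu)`` at a given xi; raises beyond the medium depth."""
    thr = toy_thresholds(params)
    if xi >= thr.xi_m:
        raise MaintenanceInfeasible(f"xi = {xi} >= xi_m = {thr.xi_m}")
    u, r, _ = toy_fluxes(params, xi)
    z = (params.N_F * u + params.N_R * r - params.e) / params.y
    _, w = toy_concentrations(params, xi)
    return z, z - params.tau * w


def toy_curve(params: ToyParams, xi: float):
    """All closed-form steady quantities (u, r, v, z, mu, s, w) at one xi."""
    u, r, v = toy_fluxes(params, xi)
    z, mu = toy_growth(params, xi)
    s, w = toy_concentrations(params, xi)
    return {"u": u, "r": r, "v": v, "z": z, "mu": mu, "s": s, "w": w}


def toy_as_generic_model(params: ToyParams | None = None,
                         crowding: bool = True
                         ) -> tuple[MetabolicModel, Medium, ToxicitySpec]:
    """Encode the network as a generic :class:`MetabolicModel`.

    Metabolites: S and W external, P and E internal.  Reactions:
    glycolysis (S -> P + N_F E), respiration (P -> N_R E) and waste export
    (P -> W); biomass drains ``y`` units of E per gDW and maintenance
    drains E at rate ``e``.  With ``crowding=True`` (default) the
    respiratory cap is realized through the crowding budget — respiration
    carries cost ``C/r_max`` and everything else is free — so the generic
    LP exercises the cost constraint.  ``crowding=False`` instead imposes
    ``r <= r_max`` as a hard bound (kept for differential testing).
    """
    p = params or ToyParams()
    metabolites = ["S", "P", "E", "W"]
    reactions = ["glycolysis", "respiration", "waste_export"]
    S = np.array([
        # glyc  resp  export
        [-1.0, 0.0, 0.0],            # S
        [1.0, -1.0, -1.0],           # P
        [p.N_F, p.N_R, 0.0],         # E
        [0.0, 0.0, 1.0],             # W
    ])
    if crowding:
        budget = 1.0
        cost_fwd = np.array([0.0, budget / p.r_max, 0.0])
        ub = np.array([np.inf, np.inf, np.inf])
    else:
        budget = 1.0
        cost_fwd = np.zeros(3)
        ub = np.array([np.inf, p.r_max, np.inf])
    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        S=S,
        lb=np.zeros(3),
        ub=ub,
        cost_fwd=cost_fwd,
        cost_rev=np.zeros(3),
        budget=budget,
        biomass={"E": p.y},
        maintenance={"E": p.e},
        exchanges={"S": Exchange(V=p.V, L=0.0),
                   "W": Exchange(V=0.0, L=np.inf)},
    )
    medium = Medium({"S": p.c, "W": 0.0})
    tox = ToxicitySpec("death_rate", {"W": p.tau} if p.tau > 0 else {})
    return model, medium, tox
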