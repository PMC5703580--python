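"""Reading and writing models, media tables, curves and trajectories.

Model exchange format is COBRA JSON or SBML L3 FBC (via COBRApy), with
sidecar TSV tables carrying what those formats do not: per-direction flux
costs (`costs.tsv`: reaction_id, alpha_fwd, alpha_rev), feed-medium
concentrations (`media.tsv`: metabolite_id, conc_mM, literal ``inf``
allowed), maximum uptake rates (`uptake.tsv`: metabolite_id, V_max),
maintenance drains (`maintenance.tsv`: metabolite_id, rate) and scalar
metadata (`meta.tsv`: key, value — crowding budget, dry weight per cell).

Conventions mirrored onto cobra objects: the biomass pseudo-reaction is
named ``biomass`` (objective), maintenance drains are fixed-flux reactions
``MAINT_<met>``, exchanges are ``EX_<met>`` with cobra's sign convention
(positive flux = export, so our uptake is minus the exchange flux).
Infinite bounds are stored as +/-1e6 in the files.

All tabular outputs are tab-separated with ``.`` decimals and ``inf``
literals; floats are printed with 17 significant digits so a written curve
re-reads bitwise identically in internal units.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Exchange, Medium, MetabolicModel
from .steady_state import (
    PhaseSignature,
    SteadyStateCurve,
    SteadyStatePoint,
    ToxicitySpec,
)
from .units import DW_PER_CELL_DEFAULT, convert

_INF_BOUND = 1e6  # stands for an infinite bound inside model files
_FLOAT_FMT = "%.17g"

#: conventional ids of proteinogenic amino acids in *_e-suffixed models
AMINO_ACID_IDS = tuple(
    f"{a}_L_e" for a in
    ("ala arg asn asp cys gln glu gly his ile leu lys met phe pro ser thr "
     "trp tyr val").split()) + ("gly_e",)


def _unfreeze(bound: float) -> float:
    if bound >= _INF_BOUND:
        return np.inf
    if bound <= -_INF_BOUND:
        return -np.inf
    return bound


def _freeze(bound: float) -> float:
    if math.isinf(bound):
        return _INF_BOUND if bound > 0 else -_INF_BOUND
    return bound


# ---------------------------------------------------------------------------
# model read / write
# ---------------------------------------------------------------------------

def read_model(model_path, costs=None, media=None, uptake=None,
               maintenance=None, meta=None, toxicity=None,
               budget: float | None = None,
               amino_acid_rule: bool = False, v_glc: float = 0.5,
               amino_acid_ids: tuple[str, ...] = AMINO_ACID_IDS,
               ) -> tuple[MetabolicModel, Medium, ToxicitySpec]:
    """Assemble a model from COBRA JSON/SBML plus sidecar tables.

    Reactions missing from the cost table get the median of the provided
    cost values; metabolites missing from the uptake table get ``V = inf``
    (or ``v_glc/10`` for amino acids when ``amino_acid_rule`` is on);
    metabolites missing from the media table get concentration 0.
    """
    import cobra.io

    model_path = Path(model_path)
    if model_path.suffix == ".json":
        cm = cobra.io.load_json_model(str(model_path))
    elif model_path.suffix in (".xml", ".sbml"):
        cm = cobra.io.read_sbml_model(str(model_path))
    else:
        raise ValueError(f"unsupported model format {model_path.suffix!r}")

    meta_kv = _read_kv(meta) if meta else {}
    if budget is None:
        budget = float(meta_kv.get("budget", np.inf))

    biomass_rxn = None
    maint: dict[str, float] = {}
    core = []
    exch = []
    for rxn in cm.reactions:
        if rxn.id == "biomass" or rxn.objective_coefficient:
            if biomass_rxn is not None and rxn.id != biomass_rxn.id:
                raise ValueError("multiple biomass/objective reactions")
            biomass_rxn = rxn
        elif rxn.id.startswith("MAINT_"):
            met = rxn.id[len("MAINT_"):]
            maint[met] = float(rxn.lower_bound)
        elif rxn.id.startswith("EX_") or rxn.boundary:
            exch.append(rxn)
        else:
            core.append(rxn)
    if biomass_rxn is None:
        raise ValueError("no biomass reaction (objective) in model")
    if maintenance:
        for _, row in _read_table(maintenance, ["metabolite_id", "rate"]).iterrows():
            maint[row.metabolite_id] = float(row.rate)

    metabolites = [m.id for m in cm.metabolites]
    met_set = set(metabolites)
    n_r = len(core)
    S = np.zeros((len(metabolites), n_r))
    midx = {m: i for i, m in enumerate(metabolites)}
    lb = np.zeros(n_r)
    ub = np.zeros(n_r)
    for k, rxn in enumerate(core):
        for met, coef in rxn.metabolites.items():
            S[midx[met.id], k] = coef
        lb[k] = _unfreeze(rxn.lower_bound)
        ub[k] = _unfreeze(rxn.upper_bound)

    biomass = {met.id: -coef for met, coef in biomass_rxn.metabolites.items()
               if coef < 0}

    # costs: median imputation for reactions absent from the table
    cost_fwd = np.full(n_r, np.nan)
    cost_rev = np.full(n_r, np.nan)
    if costs:
        tab = _read_table(costs, ["reaction_id", "alpha_fwd", "alpha_rev"])
        ridx = {r.id: k for k, r in enumerate(core)}
        for _, row in tab.iterrows():
            if row.reaction_id not in ridx:
                raise ValueError(f"cost table names unknown reaction "
                                 f"{row.reaction_id}")
            cost_fwd[ridx[row.reaction_id]] = float(row.alpha_fwd)
            cost_rev[ridx[row.reaction_id]] = float(row.alpha_rev)
    provided = np.concatenate([cost_fwd[~np.isnan(cost_fwd)],
                               cost_rev[~np.isnan(cost_rev)]])
    fill = float(np.median(provided)) if provided.size else 0.0
    cost_fwd = np.where(np.isnan(cost_fwd), fill, cost_fwd)
    cost_rev = np.where(np.isnan(cost_rev), fill, cost_rev)

    # exchanges: V from the uptake table (fallback: -lb of EX_), L from ub
    v_table: dict[str, float] = {}
    if uptake:
        for _, row in _read_table(uptake, ["metabolite_id", "V_max"]).iterrows():
            if row.metabolite_id not in met_set:
                raise ValueError(f"uptake table names unknown metabolite "
                                 f"{row.metabolite_id}")
            v_table[row.metabolite_id] = float(row.V_max)
    exchanges: dict[str, Exchange] = {}
    for rxn in exch:
        (met,) = rxn.metabolites
        V = v_table.get(met.id)
        if V is None and amino_acid_rule and met.id in amino_acid_ids:
            V = v_glc / 10.0
        if V is None:
            V = -_unfreeze(rxn.lower_bound)
            V = V if V > 0 else np.inf
        L = np.inf if rxn.upper_bound > 0 else 0.0
        exchanges[met.id] = Exchange(V=V, L=L)

    medium = Medium({})
    if media:
        tab = _read_table(media, ["metabolite_id", "conc_mM"])
        for _, row in tab.iterrows():
            if row.metabolite_id not in met_set:
                raise ValueError(f"media table names unknown metabolite "
                                 f"{row.metabolite_id}")
            medium.concentrations[row.metabolite_id] = float(row.conc_mM)

    for m in maint:
        if m not in met_set:
            raise ValueError(f"maintenance names unknown metabolite {m}")

    tox = read_toxicity(toxicity) if toxicity else ToxicitySpec.none()
    model = MetabolicModel(
        metabolites=metabolites, reactions=[r.id for r in core], S=S,
        lb=lb, ub=ub, cost_fwd=cost_fwd, cost_rev=cost_rev, budget=budget,
        biomass=biomass, maintenance=maint, exchanges=exchanges)
    return model, medium, tox


def write_model_dir(model: MetabolicModel, medium: Medium, dirpath,
                    tox: ToxicitySpec | None = None,
                    dry_weight_per_cell: float = DW_PER_CELL_DEFAULT) -> Path:
    """Serialize a model as ``model.json`` + sidecar TSVs in a directory."""
    import cobra
    import cobra.io

    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    cm = cobra.Model("model")
    ex_mets = set(model.exchanges)
    cmets = {m: cobra.Metabolite(m, compartment="e" if m in ex_mets else "c")
             for m in model.metabolites}
    for k, rid in enumerate(model.reactions):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = _freeze(model.lb[k])
        rxn.upper_bound = _freeze(model.ub[k])
        rxn.add_metabolites({cmets[m]: model.S[i, k]
                             for i, m in enumerate(model.metabolites)
                             if model.S[i, k] != 0})
        cm.add_reactions([rxn])
    bio = cobra.Reaction("biomass")
    bio.lower_bound, bio.upper_bound = 0.0, _INF_BOUND
    bio.add_metabolites({cmets[m]: -y for m, y in model.biomass.items()})
    cm.add_reactions([bio])
    cm.objective = "biomass"
    for m, rate in model.maintenance.items():
        rxn = cobra.Reaction(f"MAINT_{m}")
        rxn.lower_bound = rxn.upper_bound = rate
        rxn.add_metabolites({cmets[m]: -1.0})
        cm.add_reactions([rxn])
    for m, ex in model.exchanges.items():
        rxn = cobra.Reaction(f"EX_{m}")
        rxn.lower_bound = -_freeze(ex.V)
        rxn.upper_bound = _freeze(ex.L)
        rxn.add_metabolites({cmets[m]: -1.0})
        cm.add_reactions([rxn])
    cobra.io.save_json_model(cm, str(dirpath / "model.json"))

    _write_table(dirpath / "costs.tsv",
                 pd.DataFrame({"reaction_id": model.reactions,
                               "alpha_fwd": model.cost_fwd,
                               "alpha_rev": model.cost_rev}))
    _write_table(dirpath / "media.tsv",
                 pd.DataFrame({"metabolite_id": list(medium.concentrations),
                               "conc_mM": list(medium.concentrations.values())}))
    _write_table(dirpath / "uptake.tsv",
                 pd.DataFrame({"metabolite_id": list(model.exchanges),
                               "V_max": [e.V for e in model.exchanges.values()]}))
    _write_table(dirpath / "maintenance.tsv",
                 pd.DataFrame({"metabolite_id": list(model.maintenance),
                               "rate": list(model.maintenance.values())}))
    _write_table(dirpath / "meta.tsv",
                 pd.DataFrame({"key": ["budget", "dry_weight_per_cell"],
                               "value": [model.budget, dry_weight_per_cell]}))
    if tox is not None:
        write_toxicity(tox, dirpath / "toxicity.tsv")
    return dirpath


def read_model_dir(dirpath, **kwargs
                   ) -> tuple[MetabolicModel, Medium, ToxicitySpec]:
    dirpath = Path(dirpath)
    opt = {}
    for key, fname in (("costs", "costs.tsv"), ("media", "media.tsv"),
                       ("uptake", "uptake.tsv"),
                       ("maintenance", "maintenance.tsv"),
                       ("meta", "meta.tsv"), ("toxicity", "toxicity.tsv")):
        if (dirpath / fname).exists():
            opt[key] = dirpath / fname
    opt.update(kwargs)
    return read_model(dirpath / "model.json", **opt)


# ---------------------------------------------------------------------------
# toxicity config
# ---------------------------------------------------------------------------

def read_toxicity(path) -> ToxicitySpec:
    """Key-value file: row ``mechanism <name>`` plus one row per metabolite."""
    kv = _read_kv(path)
    mech = kv.pop("mechanism", "death_rate")
    return ToxicitySpec(mech, {m: float(v) for m, v in kv.items()})


def write_toxicity(tox: ToxicitySpec, path) -> None:
    rows = [("mechanism", tox.mechanism)]
    rows += [(m, _FLOAT_FMT % v) for m, v in tox.coefficients.items()]
    _write_table(Path(path), pd.DataFrame(rows, columns=["key", "value"]))


def _read_kv(path) -> dict[str, str]:
    tab = _read_table(path, ["key", "value"])
    return dict(zip(tab.key.astype(str), tab.value))


# ---------------------------------------------------------------------------
# tabular helpers
# ---------------------------------------------------------------------------

def _read_table(path, columns) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(columns) - set(tab.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return tab


def _write_table(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# curve / trajectory / diagram writers
# ---------------------------------------------------------------------------

def _phase_str(sig) -> tuple[str, str]:
    if sig is None:
        return "", ""
    return ";".join(sorted(sig.secreted)), ";".join(sorted(sig.limiting))


def curve_frame(curve: SteadyStateCurve,
                dry_weight_per_cell: float = DW_PER_CELL_DEFAULT
                ) -> pd.DataFrame:
    """One row per xi grid point, internal units plus day/cell units."""
    mets = sorted({m for p in curve.points for m in p.u_star})
    rows = []
    for p in curve.points:
        sec, lim = _phase_str(p.phase)
        row = {
            "xi_gDW_h_per_L": p.xi,
            "xi_Mcells_day_per_mL": convert(p.xi, "gDW*h/L", "Mcells*day/mL",
                                            dry_weight_per_cell),
            "feasible": int(p.feasible),
            "z_per_h": p.z_star,
            "mu_per_h": p.mu_star,
            "mu_per_day": p.mu_star * 24.0,
            "D_per_h": p.D_star,
            "D_per_day": p.D_star * 24.0,
            "X_gDW_per_L": p.X_star,
            "X_Mcells_per_mL": convert(p.X_star, "gDW/L", "Mcells/mL",
                                       dry_weight_per_cell)
            if p.feasible else np.nan,
            "stable": "" if p.stable is None else int(p.stable),
            "secreted": sec,
            "limiting": lim,
        }
        for m in mets:
            row[f"u_{m}_mmol_gDW_h"] = p.u_star.get(m, np.nan)
            row[f"s_{m}_mM"] = p.s_star.get(m, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def write_curve(curve: SteadyStateCurve, path,
                dry_weight_per_cell: float = DW_PER_CELL_DEFAULT) -> None:
    _write_table(Path(path), curve_frame(curve, dry_weight_per_cell))


def read_curve(path, phi: float = 1.0) -> SteadyStateCurve:
    """Rebuild a steady-state curve from a written TSV (internal units)."""
    tab = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""],
                      float_precision="round_trip")
    mets = [c[2:-len("_mmol_gDW_h")] for c in tab.columns
            if c.startswith("u_") and c.endswith("_mmol_gDW_h")]
    points = []
    for _, r in tab.iterrows():
        feas = bool(int(r.feasible))
        phase = None
        if feas:
            sec = str(r.secreted) if r.secreted == r.secreted else ""
            lim = str(r.limiting) if r.limiting == r.limiting else ""
            phase = PhaseSignature(
                frozenset(x for x in sec.split(";") if x),
                frozenset(x for x in lim.split(";") if x))
        stable = None
        if str(r.stable) not in ("", "nan"):
            stable = bool(int(float(r.stable)))
        points.append(SteadyStatePoint(
            xi=float(r.xi_gDW_h_per_L), feasible=feas,
            z_star=float(r.z_per_h), mu_star=float(r.mu_per_h),
            D_star=float(r.D_per_h), X_star=float(r.X_gDW_per_L),
            u_star={m: float(r[f"u_{m}_mmol_gDW_h"]) for m in mets} if feas else {},
            s_star={m: float(r[f"s_{m}_mM"]) for m in mets} if feas else {},
            phase=phase, stable=stable))
    return SteadyStateCurve(points=points, phi=phi, meta={"source": str(path)})


def write_trajectory(traj, path) -> None:
    mets = sorted(traj.s)
    df = pd.DataFrame({"t_h": traj.t, "t_day": traj.t / 24.0,
                       "X_gDW_per_L": traj.X,
                       "D_per_h": traj.D, "D_per_day": traj.D * 24.0,
                       "z_per_h": traj.z, "mu_per_h": traj.mu})
    for m in mets:
        df[f"s_{m}_mM"] = traj.s[m]
        df[f"u_{m}_mmol_gDW_h"] = traj.u[m]
    _write_table(Path(path), df)
    if traj.events:
        with open(path, "a") as fh:
            for t, label in traj.events:
                fh.write(f"# event\t{_FLOAT_FMT % t}\t{label}\n")


def write_diagram(diagram, path) -> None:
    """Branch samples as rows, folds/windows/washout as a summary block."""
    rows = []
    for i, b in enumerate(diagram.branches):
        for xi, D, X in zip(b.xi, b.D, b.X):
            rows.append({"branch": i, "stable": int(b.stable),
                         "xi_gDW_h_per_L": xi, "D_per_h": D,
                         "D_per_day": D * 24.0, "X_gDW_per_L": X})
    _write_table(Path(path), pd.DataFrame(rows))
    with open(path, "a") as fh:
        for xi, D in diagram.folds:
            fh.write(f"# fold\txi={_FLOAT_FMT % xi}\tD_per_h={_FLOAT_FMT % D}"
                     f"\tD_per_day={_FLOAT_FMT % (D * 24)}\n")
        for lo, hi in diagram.windows:
            fh.write(f"# window\tD_per_h=[{_FLOAT_FMT % lo},{_FLOAT_FMT % hi}]"
                     f"\tD_per_day=[{_FLOAT_FMT % (lo * 24)},"
                     f"{_FLOAT_FMT % (hi * 24)}]\n")
        if diagram.washout_D_max is not None:
            fh.write(f"# washout_D_max\tD_per_h="
                     f"{_FLOAT_FMT % diagram.washout_D_max}\n")


def read_schedule(path, phi: float = 1.0):
    """TSV of (time_day, D_per_day) knots -> DilutionSchedule (internal h)."""
    from .dynamics import DilutionSchedule

    tab = _read_table(path, ["time_day", "D_per_day"])
    knots = [(float(r.time_day), float(r.D_per_day)) for _, r in tab.iterrows()]
    return DilutionSchedule.from_days(knots, phi)
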