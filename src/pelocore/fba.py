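"""Flux balance analysis: LP formulation and the study's objective modes.

All simulations are anaerobic minimal-medium problems: the metabolites in the
condition's free-exchange set may enter and leave the network freely, electron
donors/acceptors are given maximum uptake rates, and every other extracellular
metabolite may only leave the system. Fluxes are in mmol/gdw/h (the biomass
reaction in 1/h).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model import Model

#: metabolites allowed to freely enter and leave the network by default
DEFAULT_FREE_EXCHANGES = ("co2", "h", "h2o", "k", "mg", "nh4", "pi", "so4")

BOUND_TOL = 1e-9
MASS_BALANCE_TOL = 1e-6


class FBAError(RuntimeError):
    pass


class InfeasibleError(FBAError):
    pass


@dataclass(frozen=True)
class Condition:
    """One simulation's constraint set: medium, fixed fluxes and objective.

    ``free_exchanges`` are extracellular metabolite base ids (no compartment
    suffix) whose exchanges are unbounded in both directions. ``uptake_limits``
    maps metabolite base ids to maximum uptake rates; all other exchanges are
    secretion-only. ``fixed_fluxes`` and ``closed_reactions`` address reaction
    ids directly.
    """

    free_exchanges: tuple[str, ...] = DEFAULT_FREE_EXCHANGES
    uptake_limits: dict = field(default_factory=dict)
    fixed_fluxes: dict = field(default_factory=dict)
    objective: tuple[str, str] | None = None  # (reaction id, "max" | "min")
    closed_reactions: tuple[str, ...] = ()

    def with_(self, **kwargs) -> "Condition":
        return replace(self, **kwargs)


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: pd.Series
    model_id: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, rid: str) -> float:
        return float(self.fluxes[rid])


def _apply_condition(model: Model, cond: Condition) -> list[tuple[float, float]]:
    """Translate model bounds + medium policy + fixed fluxes into LP bounds."""
    rxn_ids = set(model.reaction_ids)
    for rid in list(cond.fixed_fluxes) + list(cond.closed_reactions):
        if rid not in rxn_ids:
            raise KeyError(f"condition references unknown reaction {rid!r}")
    exchange_met = {}
    for rid in model.exchange_ids():
        (mid,) = model.reaction(rid).stoichiometry
        exchange_met[rid] = mid[:-2] if mid.endswith("_e") else mid

    bounds = []
    for r in model.reactions:
        lb, ub = r.lower_bound, r.upper_bound
        if r.id in exchange_met:
            base = exchange_met[r.id]
            if base in cond.free_exchanges:
                lb, ub = -np.inf, np.inf
            elif base in cond.uptake_limits:
                lb, ub = -float(cond.uptake_limits[base]), np.inf
            else:
                lb, ub = 0.0, np.inf
        if r.id in cond.closed_reactions:
            lb, ub = 0.0, 0.0
        if r.id in cond.fixed_fluxes:
            val = float(cond.fixed_fluxes[r.id])
            lb, ub = val, val
        bounds.append((lb, ub))
    return bounds


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def solve_fba(model: Model, cond: Condition) -> FluxSolution:
    """Solve max/min c.v subject to S.v = 0, bounds, fixed fluxes and medium
    limits; solver status is reported faithfully (unbounded objectives are
    never silently clipped)."""
    if cond.objective is None:
        raise ValueError("condition carries no objective")
    obj_rxn, sense = cond.objective
    if sense not in ("max", "min"):
        raise ValueError(f"objective sense must be max|min, got {sense!r}")
    S, _, rxns = model.stoichiometric_matrix()
    if obj_rxn not in rxns:
        raise KeyError(f"objective reaction {obj_rxn!r} not in model {model.id!r}")
    bounds = _apply_condition(model, cond)
    c = np.zeros(len(rxns))
    c[rxns.index(obj_rxn)] = -1.0 if sense == "max" else 1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return FluxSolution(status, float("nan"), pd.Series(np.nan, index=rxns), model.id)
    v = res.x
    imbalance = np.max(np.abs(S @ v)) if len(v) else 0.0
    scale = max(1.0, float(np.max(np.abs(v))) if len(v) else 1.0)
    if imbalance > MASS_BALANCE_TOL * scale:
        raise FBAError(
            f"solver returned mass-imbalanced solution for model {model.id!r} "
            f"(|S.v|={imbalance:.2e})"
        )
    obj = float(v[rxns.index(obj_rxn)])
    return FluxSolution("optimal", obj, pd.Series(v, index=rxns), model.id)


def optimal_growth(model: Model, cond: Condition, substrate: str, uptake: float) -> FluxSolution:
    """Maximize biomass with the substrate exchange fixed at ``-uptake``."""
    if uptake <= 0:
        raise ValueError("uptake must be > 0")
    ex = model.exchange_for(substrate)
    return solve_fba(
        model,
        cond.with_(
            fixed_fluxes={**cond.fixed_fluxes, ex: -uptake},
            objective=(model.biomass_reaction_id, "max"),
        ),
    )


def min_substrate_at_growth(model: Model, cond: Condition, substrate: str, mu: float) -> FluxSolution:
    """Fix the growth rate and minimize substrate uptake magnitude (implemented
    as maximizing the signed, uptake-negative exchange flux toward zero)."""
    if mu < 0:
        raise ValueError("mu must be >= 0")
    ex = model.exchange_for(substrate)
    base = substrate[:-2] if substrate.endswith("_e") else substrate
    limits = dict(cond.uptake_limits)
    limits.setdefault(base, 1000.0)
    return solve_fba(
        model,
        cond.with_(
            uptake_limits=limits,
            fixed_fluxes={**cond.fixed_fluxes, model.biomass_reaction_id: mu},
            objective=(ex, "max"),
        ),
    )


def _zero_gam(model: Model) -> Model:
    """Return a copy with the growth-associated ATP term removed from the
    biomass reaction (the ATP/ADP/Pi/water/proton coefficients), so that a
    maximum-ATP fit captures total growth-associated ATP in its slope."""
    out = model.copy()
    biomass = out.reaction(out.biomass_reaction_id)
    for mid in ("atp_c", "adp_c", "pi_c", "h2o_c", "h_c"):
        biomass.stoichiometry.pop(mid, None)
    return out


def max_atp(model: Model, cond: Condition, fixed: dict | None = None) -> FluxSolution:
    """Maximize flux through the ATP maintenance reaction under fixed measured
    fluxes; the biomass GAM coefficient is zeroed for this mode so growth-
    associated ATP appears in the maintenance flux."""
    m = _zero_gam(model)
    atpm = m.reaction(m.atpm_reaction_id)
    atpm.lower_bound = 0.0
    return solve_fba(
        m,
        cond.with_(
            fixed_fluxes={**cond.fixed_fluxes, **(fixed or {})},
            objective=(m.atpm_reaction_id, "max"),
        ),
    )


#: conjugate returned when testing producibility of a currency precursor
_DEMAND_CONJUGATE = {
    "atp_c": "adp_c",
    "nadph_c": "nadp_c",
    "nadh_c": "nad_c",
    "accoa_c": "coa_c",
}

PRODUCIBILITY_THRESHOLD = 1e-6


def biomass_producibility(model: Model, cond: Condition) -> pd.DataFrame:
    """Per-precursor gap report: for each biomass precursor a temporary demand
    reaction is added and its maximal flux tested against a small positive
    threshold. Currency precursors (ATP, NAD(P)H, acetyl-CoA) are demanded as
    conversions to their conjugate form, since a core model cannot synthesize
    the cofactor moiety de novo."""
    biomass = model.reaction(model.biomass_reaction_id)
    precursors = [mid for mid, coeff in biomass.stoichiometry.items() if coeff < 0 and mid != "h2o_c"]
    rows = []
    for mid in precursors:
        probe = model.copy()
        bm = probe.reaction(probe.biomass_reaction_id)
        bm.lower_bound = 0.0
        bm.upper_bound = 0.0
        stoich = {mid: -1.0}
        if mid in _DEMAND_CONJUGATE:
            stoich[_DEMAND_CONJUGATE[mid]] = 1.0
        from .model import Reaction

        probe.reactions.append(
            Reaction(id="DM_probe", name=f"demand {mid}", stoichiometry=stoich, lower_bound=0.0, upper_bound=1000.0)
        )
        sol = solve_fba(probe, cond.with_(objective=("DM_probe", "max")))
        vmax = sol.objective_value if sol.optimal else 0.0
        rows.append(
            {
                "precursor": mid,
                "max_flux": vmax if np.isfinite(vmax) else np.inf,
                "producible": bool(sol.optimal and vmax > PRODUCIBILITY_THRESHOLD),
            }
        )
    return pd.DataFrame(rows).set_index("precursor")
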