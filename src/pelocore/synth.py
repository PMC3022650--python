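"""Synthetic-data generators.

Everything the calibration and validation analyses consume can be generated
here without external data: chemostat observations with the linear maintenance
structure qATP = GAM*mu + nGAM (plus optional multiplicative Gaussian noise,
truncated at +/-3 sigma so fluxes never change sign), fermentative growth-yield
records, and small random feasible stoichiometric toy networks whose LP optima
are computed by exhaustive basic-solution enumeration and stored alongside the
network. All generators are pure functions of their inputs and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np

from .calibration import ChemostatObservation, YieldRecord
from .fba import Condition, min_substrate_at_growth
from .model import Metabolite, Model, Reaction
from .reconstructions import EnergyParams
from .scenarios import pcar_fermentation, ppro_fermentation, scenario_condition


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    dilution_rates: tuple = (0.03, 0.04, 0.05, 0.06)  # 1/h
    noise_sd: float = 0.0  # multiplicative, as a fraction of the flux


class GenerationError(RuntimeError):
    pass


def _noisy(value: float, sd: float, rng: np.random.Generator) -> float:
    if sd == 0:
        return value
    eps = float(np.clip(rng.normal(0.0, sd), -3 * sd, 3 * sd))
    return value * (1.0 + eps)


def gen_chemostat_obs(
    model: Model, ep: EnergyParams, cfg: GeneratorConfig
) -> list[ChemostatObservation]:
    """Acetoin-chemostat observations: for each dilution rate, solve
    minimal-uptake fermentative growth with the model's embedded GAM/nGAM and
    record the acetoin uptake and acetate secretion fluxes."""
    rng = np.random.default_rng(cfg.seed)
    cond = scenario_condition(pcar_fermentation("actn"), model)
    obs = []
    for mu in cfg.dilution_rates:
        sol = min_substrate_at_growth(model, cond, "actn", mu)
        if not sol.optimal:
            raise GenerationError(f"model infeasible at dilution rate {mu:g}")
        u = sol.flux(model.exchange_for("actn"))
        a = sol.flux(model.exchange_for("ac"))
        obs.append(
            ChemostatObservation(
                mu=mu,
                fluxes={
                    model.exchange_for("actn"): _noisy(u, cfg.noise_sd, rng),
                    model.exchange_for("ac"): _noisy(a, cfg.noise_sd, rng),
                },
            )
        )
    return obs


def gen_yield_records(
    model: Model,
    ep: EnergyParams,
    substrates: tuple = ("btd", "actn", "lac"),
    seed: int = 0,
    mu: float = 0.144,
    noise_sd: float = 0.0,
) -> list[YieldRecord]:
    """Fermentative growth-yield records: fixed-growth minimal-uptake
    simulation per substrate, converted to gdw per mmol substrate."""
    rng = np.random.default_rng(seed)
    records = []
    for sub in substrates:
        cond = scenario_condition(ppro_fermentation(sub), model)
        sol = min_substrate_at_growth(model, cond, sub, mu)
        if not sol.optimal:
            raise GenerationError(f"substrate {sub!r} infeasible at mu={mu:g}")
        uptake = -sol.flux(model.exchange_for(sub))
        records.append(
            YieldRecord(
                substrate=sub,
                mu=mu,
                yield_gdw_per_mmol=_noisy(mu / uptake, noise_sd, rng),
            )
        )
    return records


# ---------------------------------------------------------------------------
# random toy networks with enumerated LP optima
# ---------------------------------------------------------------------------

_BIG = 1e5  # stand-in for unbounded exchange sides during enumeration


def enumerate_lp_optimum(S: np.ndarray, c: np.ndarray, bounds: list) -> float:
    """Exhaustive basic-feasible-solution optimum of max c.v s.t. S.v = 0 and
    finite box bounds — the independent LP oracle (no solver involved).

    Every vertex of the polytope has n - rank(S) variables at a bound and the
    rest solved from the balance equations; all bases and bound assignments
    are enumerated. Infinite bound sides are boxed at a large constant, which
    leaves the optimum unchanged for networks whose optimal vertices are
    interiorly bounded by conservation."""
    S = np.asarray(S, dtype=float)
    m, n = S.shape
    lo = np.array([-_BIG if not np.isfinite(b[0]) else b[0] for b in bounds])
    hi = np.array([_BIG if not np.isfinite(b[1]) else b[1] for b in bounds])
    r = int(np.linalg.matrix_rank(S)) if S.size else 0
    if r:
        from scipy.linalg import qr

        _, _, piv = qr(S.T, pivoting=True)
        Sr = S[sorted(piv[:r])]
    else:
        Sr = np.zeros((0, n))
    best = -np.inf
    tol = 1e-7
    for basis in combinations(range(n), r):
        B = Sr[:, basis]
        if r and abs(np.linalg.det(B)) < 1e-10:
            continue
        nonbasic = [j for j in range(n) if j not in basis]
        for choice in product((0, 1), repeat=len(nonbasic)):
            x = np.zeros(n)
            for j, side in zip(nonbasic, choice):
                x[j] = lo[j] if side == 0 else hi[j]
            if r:
                rhs = -Sr[:, nonbasic] @ x[nonbasic] if nonbasic else np.zeros(r)
                x[list(basis)] = np.linalg.solve(B, rhs)
            if np.any(x < lo - tol) or np.any(x > hi + tol):
                continue
            best = max(best, float(c @ x))
    return best


def toy_condition(model: Model) -> Condition:
    """The solving condition stored with a generated toy network."""
    ann = model.annotations
    return Condition(
        free_exchanges=(),
        uptake_limits={ann["substrate"]: ann["uptake_limit"]},
        objective=(ann["objective_exchange"], "max"),
    )


def _toy_bounds_for_condition(model: Model) -> list:
    """Bounds as the FBA engine applies them, for the enumeration oracle."""
    from .fba import _apply_condition

    return _apply_condition(model, toy_condition(model))


def gen_toy_network(n_mets: int = 4, n_rxns: int = 8, seed: int = 0) -> Model:
    """Random connected exchange-conversion-exchange network (n_mets <= 6
    internal metabolites, n_rxns <= 8 reactions excluding the two inert
    biomass/ATPM placeholders) with random positive coefficients. The
    brute-force enumerated optimum of maximizing the product exchange is
    stored in ``annotations['enumerated_optimum']``; degenerate draws with a
    zero optimum are regenerated deterministically."""
    if not 2 <= n_mets <= 6:
        raise ValueError("n_mets must lie in [2, 6]")
    if not n_mets + 3 <= n_rxns <= 8:
        raise ValueError(f"n_rxns must lie in [{n_mets + 3}, 8]")
    for attempt in range(20):
        model = _gen_toy_once(n_mets, n_rxns, seed + 7919 * attempt)
        if model.annotations["enumerated_optimum"] > 1e-6:
            return model
    raise GenerationError("could not draw a non-degenerate toy network")


def _gen_toy_once(n_mets: int, n_rxns: int, seed: int) -> Model:
    rng = np.random.default_rng(seed)
    k = n_mets
    mets = [Metabolite(f"x{i}_c", compartment="c") for i in range(1, k + 1)]
    mets += [Metabolite("x1_e", compartment="e"), Metabolite(f"x{k}_e", compartment="e")]
    cap = 100.0
    uptake_limit = float(np.round(rng.uniform(4, 12), 1))
    rxns = [
        Reaction("EX_x1_e", "substrate exchange", {"x1_e": -1.0}, -cap, cap, "", "Other"),
        Reaction(f"EX_x{k}_e", "product exchange", {f"x{k}_e": -1.0}, -cap, cap, "", "Other"),
        Reaction("T_in", "substrate transport", {"x1_e": -1.0, "x1_c": 1.0}, 0.0, cap, "", "Transport"),
        Reaction("T_out", "product transport", {f"x{k}_c": -1.0, f"x{k}_e": 1.0}, 0.0, cap, "", "Transport"),
    ]
    for i in range(1, k):  # spine guaranteeing connectivity
        a, b = int(rng.integers(1, 3)), int(rng.integers(1, 3))
        lb = -cap if rng.random() < 0.3 else 0.0
        rxns.append(
            Reaction(f"R{i}", f"conversion x{i}->x{i + 1}",
                     {f"x{i}_c": -float(a), f"x{i + 1}_c": float(b)}, lb, cap, "", "Central Metabolism")
        )
    extra = n_rxns - len(rxns)
    for t in range(extra):
        i, j = sorted(rng.choice(np.arange(1, k + 1), size=2, replace=False))
        a, b = int(rng.integers(1, 3)), int(rng.integers(1, 3))
        lb = -cap if rng.random() < 0.3 else 0.0
        rxns.append(
            Reaction(f"E{t}", f"extra conversion x{i}->x{j}",
                     {f"x{i}_c": -float(a), f"x{j}_c": float(b)}, lb, cap, "", "Central Metabolism")
        )
    # inert designated pseudo-reactions so the model passes validation
    rxns.append(Reaction("BIOMASS", "placeholder biomass", {f"x{k}_c": -1.0}, 0.0, 0.0, "", "Other"))
    rxns.append(Reaction("ATPM", "placeholder maintenance", {"x1_c": -1.0}, 0.0, 0.0, "", "Other"))

    model = Model(
        f"toy_{seed}", "synthetic toy network", mets, rxns, "BIOMASS", "ATPM",
        annotations={
            "substrate": "x1",
            "uptake_limit": uptake_limit,
            "objective_exchange": f"EX_x{k}_e",
        },
    )
    S, _, rxn_ids = model.stoichiometric_matrix()
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(f"EX_x{k}_e")] = 1.0
    bounds = _toy_bounds_for_condition(model)
    model.annotations["enumerated_optimum"] = enumerate_lp_optimum(S, c, bounds)
    return model
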