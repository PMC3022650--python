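"""Stoichiometric model data structures, validation and expression closure.

The models are two-compartment (cytosol ``c``, extracellular ``e``); the
chemiosmotic bookkeeping of proton-translocating reactions is expressed as
cytosol -> extracellular proton movement. Exchange reactions touch exactly one
extracellular metabolite; the sign convention is negative flux = uptake into
the network, positive = secretion, used everywhere in the package.
"""

from __future__ import annotations

import copy as _copy
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .gpr import MalformedGPRError, evaluate_ast, genes_in, parse_gpr

COMPARTMENTS = ("c", "e")

#: the nine functional classifications reactions are categorized into
SUBSYSTEMS = (
    "Amino Acid Metabolism",
    "Carbohydrate Metabolism",
    "Central Metabolism",
    "Cofactor Metabolism",
    "Energy Metabolism",
    "Lipid Metabolism",
    "Nucleotide Metabolism",
    "Transport",
    "Other",
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula like ``C4H8O2`` into an element->count map."""
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        m = _FORMULA_TOKEN.match(formula, pos)
        if m is None or m.end() == pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    return counts


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: str = ""
    subsystem: str = "Other"

    def __post_init__(self):
        self.stoichiometry = {k: float(v) for k, v in self.stoichiometry.items()}
        self.lower_bound = float(self.lower_bound)
        self.upper_bound = float(self.upper_bound)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def gene_set(self) -> set[str]:
        return genes_in(parse_gpr(self.gpr))


@dataclass
class ExpressionProfile:
    """Gene expression levels and the closure threshold.

    Reactions whose GPR cannot be satisfied by the genes expressed at or above
    ``threshold`` are closed during simulations.
    """

    levels: dict[str, float] = field(default_factory=dict)
    threshold: float = 0.0

    def __post_init__(self):
        if self.threshold < 0:
            raise ValueError("closure threshold must be >= 0")

    def expressed(self) -> set[str]:
        return {g for g, lv in self.levels.items() if lv >= self.threshold}


class Model:
    """A metabolic model: metabolites, reactions and designated pseudo-reactions."""

    def __init__(
        self,
        id: str,
        species: str,
        metabolites: list[Metabolite],
        reactions: list[Reaction],
        biomass_reaction_id: str,
        atpm_reaction_id: str,
        annotations: dict | None = None,
    ):
        self.id = id
        self.species = species
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.biomass_reaction_id = biomass_reaction_id
        self.atpm_reaction_id = atpm_reaction_id
        self.annotations = dict(annotations or {})

    # -- lookup helpers -------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.gene_set()
        return out

    def exchange_ids(self) -> list[str]:
        """Reactions touching exactly one metabolite (other than the biomass
        and ATPM pseudo-reactions), i.e. boundary exchanges."""
        special = {self.biomass_reaction_id, self.atpm_reaction_id}
        return [
            r.id
            for r in self.reactions
            if len(r.stoichiometry) == 1 and r.id not in special
        ]

    def exchange_for(self, met_base: str) -> str:
        """Exchange reaction id for an extracellular metabolite (base id
        without the compartment suffix, or a full ``*_e`` id)."""
        target = met_base if met_base.endswith("_e") else f"{met_base}_e"
        for rid in self.exchange_ids():
            (mid,) = self.reaction(rid).stoichiometry
            if mid == target:
                return rid
        raise KeyError(f"no exchange for metabolite {target!r}")

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        mets = self.metabolite_ids
        rxns = self.reaction_ids
        mindex = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(rxns)))
        for j, r in enumerate(self.reactions):
            for mid, coeff in r.stoichiometry.items():
                S[mindex[mid], j] = coeff
        return S, mets, rxns

    def copy(self) -> "Model":
        return _copy.deepcopy(self)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<Model {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )


@dataclass
class Violation:
    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.message}"


def _balance_violations(model: Model, rxn: Reaction) -> list[Violation]:
    met_formulas = {}
    for mid in rxn.stoichiometry:
        f = model.metabolite(mid).formula
        if f is None:
            return []  # only reactions whose metabolites all carry formulas
        met_formulas[mid] = parse_formula(f)
    totals: dict[str, float] = {}
    for mid, coeff in rxn.stoichiometry.items():
        for el, n in met_formulas[mid].items():
            totals[el] = totals.get(el, 0.0) + coeff * n
    bad = sorted(el for el, t in totals.items() if abs(t) > 1e-9)
    if bad:
        return [
            Violation(
                "elemental-imbalance",
                f"reaction {rxn.id!r} is unbalanced in {', '.join(bad)}",
            )
        ]
    return []


def validate_model(model: Model, check_charge: bool = False) -> list[Violation]:
    """Check all model invariants; returns a list of violations (empty = valid).

    Elemental balance is checked for every reaction whose participating
    metabolites all carry formulas; exchange, biomass and ATPM reactions are
    exempt. Charge balance is optional and off by default.
    """
    v: list[Violation] = []
    seen_m: set[str] = set()
    for m in model.metabolites:
        if m.id in seen_m:
            v.append(Violation("duplicate-metabolite", f"duplicate metabolite id {m.id!r}"))
        seen_m.add(m.id)
        if m.compartment not in COMPARTMENTS:
            v.append(
                Violation(
                    "unknown-compartment",
                    f"metabolite {m.id!r} has compartment {m.compartment!r}; "
                    f"expected one of {COMPARTMENTS}",
                )
            )
    seen_r: set[str] = set()
    for r in model.reactions:
        if r.id in seen_r:
            v.append(Violation("duplicate-reaction", f"duplicate reaction id {r.id!r}"))
        seen_r.add(r.id)
        if not r.stoichiometry:
            v.append(Violation("empty-reaction", f"reaction {r.id!r} has no metabolites"))
        for mid in r.stoichiometry:
            if mid not in seen_m:
                v.append(
                    Violation(
                        "missing-metabolite",
                        f"reaction {r.id!r} references unknown metabolite {mid!r}",
                    )
                )
        if r.lower_bound > r.upper_bound:
            v.append(
                Violation("bad-bounds", f"reaction {r.id!r} has lower_bound > upper_bound")
            )
        if r.subsystem not in SUBSYSTEMS:
            v.append(
                Violation(
                    "unknown-subsystem",
                    f"reaction {r.id!r} subsystem {r.subsystem!r} not in the "
                    "nine functional classifications",
                )
            )
        try:
            parse_gpr(r.gpr)
        except MalformedGPRError as exc:
            v.append(Violation("malformed-gpr", f"reaction {r.id!r}: {exc}"))

    if model.biomass_reaction_id not in seen_r:
        v.append(
            Violation("missing-biomass", f"biomass reaction {model.biomass_reaction_id!r} absent")
        )
    if model.atpm_reaction_id not in seen_r:
        v.append(
            Violation("missing-atpm", f"ATPM reaction {model.atpm_reaction_id!r} absent")
        )

    exempt = {model.biomass_reaction_id, model.atpm_reaction_id}
    exchange_ids = set(model.exchange_ids())
    for r in model.reactions:
        if r.id in exempt:
            continue
        if r.id in exchange_ids:
            (mid,) = r.stoichiometry
            if mid in seen_m and model.metabolite(mid).compartment != "e":
                v.append(
                    Violation(
                        "bad-exchange",
                        f"exchange {r.id!r} touches non-extracellular metabolite {mid!r}",
                    )
                )
            continue
        if all(mid in seen_m for mid in r.stoichiometry):
            v.extend(_balance_violations(model, r))
            if check_charge:
                charges = [model.metabolite(mid).charge for mid in r.stoichiometry]
                if all(c is not None for c in charges):
                    total = sum(
                        coeff * model.metabolite(mid).charge
                        for mid, coeff in r.stoichiometry.items()
                    )
                    if abs(total) > 1e-9:
                        v.append(
                            Violation(
                                "charge-imbalance",
                                f"reaction {r.id!r} has net charge {total:g}",
                            )
                        )
    return v


def evaluate_gpr(rxn: Reaction, expressed: set[str]) -> bool:
    """True iff at least one AND-group of the reaction's GPR has all its genes
    expressed; reactions with an empty GPR are always active."""
    return evaluate_ast(parse_gpr(rxn.gpr), expressed)


def apply_expression_closure(model: Model, profile: ExpressionProfile) -> Model:
    """Close (zero both bounds of) reactions whose GPR is unsatisfied by the
    genes expressed at or above the profile threshold.

    Genes the profile does not measure carry no evidence for closure and are
    treated as expressed, so an empty profile is the identity. Non-gene
    reactions, the biomass and ATPM pseudo-reactions and exchanges are never
    closed. Profile genes absent from the model are ignored with a warning.
    """
    model_genes = model.genes
    unknown = sorted(set(profile.levels) - model_genes)
    if unknown:
        warnings.warn(
            f"expression profile contains {len(unknown)} gene id(s) not in the "
            f"model (e.g. {unknown[0]!r}); ignored",
            stacklevel=2,
        )
    silenced = {g for g, lv in profile.levels.items() if lv < profile.threshold}
    expressed = model_genes - silenced
    out = model.copy()
    protected = set(out.exchange_ids()) | {out.biomass_reaction_id, out.atpm_reaction_id}
    for r in out.reactions:
        if r.id in protected or not r.gpr.strip():
            continue
        if not evaluate_gpr(r, expressed):
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    return out
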