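"""Curated core reconstructions of *Pelobacter* central metabolism.

Programmatic builders return validated two-compartment models of the
fermentative/respiratory core of *P. carbinolicus* and *P. propionicus*:
acetoin/2,3-butanediol degradation through the acetoin (DCPIP) oxidoreductase
system, substrate-level phosphorylation via phosphate acetyltransferase +
acetate kinase, the methylmalonyl-CoA propionate route (P. propionicus), the
NAD-linked hydrogenase, the two sulfur reductases (SRE, SRE2) with the
extracellular nonenzymatic sulfide/Fe(III) shuttle reaction FE3Rs, a full TCA
cycle whose quinone pool has no route to elemental sulfur, and a lumped
biomass demand.

Energy parameters (GAM, nGAM, SRE/SRE2 H+/2e-, ATP-synthase H+/ATP) enter as
an :class:`EnergyParams` contract; the lumped biomass composition as a
:class:`BiomassSpec`.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

from .model import Metabolite, Model, Reaction, validate_model

M = 1000.0  # default flux cap, mmol/gdw/h

# elemental formulas (charged-species forms, self-consistent with explicit
# protons in every reaction)
_FORMULAS = {
    "h": "H",
    "h2o": "H2O",
    "h2": "H2",
    "co2": "CO2",
    "nh4": "H4N",
    "pi": "HO4P",
    "so4": "O4S",
    "k": "K",
    "mg": "Mg",
    "hs": "HS",
    "s0": "S",
    "fe3": "Fe",
    "fe2": "Fe",
    "atp": "C10H12N5O13P3",
    "adp": "C10H12N5O10P2",
    "nad": "C21H26N7O14P2",
    "nadh": "C21H27N7O14P2",
    "nadp": "C21H25N7O17P3",
    "nadph": "C21H26N7O17P3",
    "coa": "C21H32N7O16P3S",
    "accoa": "C23H34N7O17P3S",
    "ppcoa": "C24H36N7O17P3S",
    "btcoa": "C25H38N7O17P3S",
    "succoa": "C25H35N7O19P3S",
    "mmcoa": "C25H35N7O19P3S",
    "ac": "C2H3O2",
    "for": "CHO2",
    "lac": "C3H5O3",
    "ppa": "C3H5O2",
    "but": "C4H7O2",
    "pyr": "C3H3O3",
    "oaa": "C4H2O5",
    "mal": "C4H4O5",
    "fum": "C4H2O4",
    "succ": "C4H4O4",
    "cit": "C6H5O7",
    "icit": "C6H5O7",
    "akg": "C5H4O5",
    "etoh": "C2H6O",
    "acald": "C2H4O",
    "actn": "C4H8O2",
    "btd": "C4H10O2",
    "eg": "C2H6O2",
    "poh": "C3H8O",
    "ppal": "C3H6O",
    "btoh": "C4H10O",
    "btal": "C4H8O",
    "mq": "C16H16O2",
    "mqh2": "C16H18O2",
    "fdox": "Fe2S2",
    "fdred": "H2Fe2S2",
}

_NAMES = {
    "actn": "acetoin",
    "btd": "(R,R)-2,3-butanediol",
    "eg": "ethylene glycol",
    "etoh": "ethanol",
    "acald": "acetaldehyde",
    "accoa": "acetyl-CoA",
    "ac": "acetate",
    "for": "formate",
    "lac": "D-lactate",
    "ppa": "propionate",
    "poh": "1-propanol",
    "ppal": "propionaldehyde",
    "ppcoa": "propionyl-CoA",
    "btoh": "1-butanol",
    "btal": "butyraldehyde",
    "btcoa": "butyryl-CoA",
    "but": "butyrate",
    "mmcoa": "(S)-methylmalonyl-CoA",
    "hs": "hydrogen sulfide (HS-)",
    "s0": "elemental sulfur",
    "fe3": "Fe(III)",
    "fe2": "Fe(II)",
    "mq": "menaquinone (oxidized)",
    "mqh2": "menaquinol",
    "fdox": "ferredoxin (oxidized)",
    "fdred": "ferredoxin (reduced)",
}


@dataclass(frozen=True)
class EnergyParams:
    """The calibrated energy contract of a core model.

    gam: growth-associated maintenance, mmol ATP/gdw.
    ngam: non-growth-associated maintenance, mmol ATP/gdw/h (ATPM lower bound).
    sre_h_per_2e / sre2_h_per_2e: protons translocated per electron pair by the
    hydrogen- and NADPH-dependent sulfur reductases (standard grid {1, 2}).
    atp_synthase_h_per_atp: periplasmic protons consumed per ATP synthesized.
    """

    gam: float = 97.5
    ngam: float = 0.844
    sre_h_per_2e: float = 2
    sre2_h_per_2e: float = 1
    atp_synthase_h_per_atp: float = 3.0

    def __post_init__(self):
        if self.gam < 0 or self.ngam < 0:
            raise ValueError("gam and ngam must be >= 0")
        if self.sre_h_per_2e <= 0 or self.sre2_h_per_2e <= 0:
            raise ValueError("H+/2e- ratios must be positive")
        if self.atp_synthase_h_per_atp <= 1:
            raise ValueError("ATP synthase H+/ATP must exceed 1")

    @classmethod
    def pcar_defaults(cls) -> "EnergyParams":
        return cls(gam=97.5, ngam=0.844, sre_h_per_2e=2, sre2_h_per_2e=1)

    @classmethod
    def ppro_defaults(cls) -> "EnergyParams":
        return cls(gam=97.5, ngam=2.80, sre_h_per_2e=2, sre2_h_per_2e=1)


@dataclass(frozen=True)
class BiomassSpec:
    """Lumped biomass composition (mmol precursor per gdw biomass).

    The core models keep only the carbon, nitrogen, redox and ATP channels of
    the biomass demand: acetyl-CoA (carbon skeletons), NADPH (anabolic
    reducing power), ammonium (nitrogen) and the GAM ATP term. ``gam=None``
    takes the value from the EnergyParams at assembly.
    """

    acetyl_coa: float = 21.0
    nadph: float = 8.0
    nh4: float = 10.0
    gam: float | None = None

    def __post_init__(self):
        for name in ("acetyl_coa", "nadph", "nh4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} coefficient must be >= 0")
        if self.gam is not None and self.gam < 0:
            raise ValueError("gam coefficient must be >= 0")

    def resolved(self, ep: EnergyParams) -> "BiomassSpec":
        return self if self.gam is not None else replace(self, gam=ep.gam)


def _met(base: str, comp: str) -> Metabolite:
    return Metabolite(
        id=f"{base}_{comp}",
        name=_NAMES.get(base, base),
        compartment=comp,
        formula=_FORMULAS.get(base),
    )


def _biomass_stoich(bs: BiomassSpec) -> dict[str, float]:
    g = bs.gam or 0.0
    st = {
        "accoa_c": -bs.acetyl_coa,
        "coa_c": bs.acetyl_coa,
        "nadph_c": -bs.nadph,
        "nadp_c": bs.nadph,
        "nh4_c": -bs.nh4,
    }
    if g:
        st.update({"atp_c": -g, "h2o_c": -g, "adp_c": g, "pi_c": g, "h_c": g})
    return {k: v for k, v in st.items() if v != 0.0}


def set_biomass_composition(model: Model, bs: BiomassSpec) -> None:
    """Rewrite the biomass demand reaction in place from a (resolved) spec."""
    if bs.gam is None:
        raise ValueError("BiomassSpec must be resolved (gam set) before assembly")
    model.reaction(model.biomass_reaction_id).stoichiometry = _biomass_stoich(bs)
    model.annotations["biomass"] = {
        "acetyl_coa": bs.acetyl_coa,
        "nadph": bs.nadph,
        "nh4": bs.nh4,
        "gam": bs.gam,
    }


def _shared_core(ep: EnergyParams, species: str) -> tuple[list[Metabolite], list[Reaction]]:
    cyt = [
        "h", "h2o", "h2", "co2", "nh4", "pi", "so4", "k", "mg",
        "atp", "adp", "nad", "nadh", "nadp", "nadph", "coa", "accoa",
        "ac", "acald", "etoh", "actn", "btd", "pyr", "oaa", "mal", "fum",
        "succ", "succoa", "cit", "icit", "akg", "mq", "mqh2", "fdox", "fdred",
    ]
    ext = [
        "h", "h2o", "h2", "co2", "nh4", "pi", "so4", "k", "mg",
        "ac", "etoh", "actn", "btd", "acald", "hs", "s0", "fe3", "fe2",
    ]
    mets = [_met(b, "c") for b in cyt] + [_met(b, "e") for b in ext]

    acor_gpr = (
        "Pcar_0343 & Pcar_0344 & Pcar_0345 & Pcar_0347"
        if species == "pcar"
        else "Ppro_1131 & Ppro_1132 & Ppro_1133 & Ppro_1137"
    )

    n1 = ep.sre_h_per_2e
    n2 = ep.sre2_h_per_2e
    m_h = ep.atp_synthase_h_per_atp

    r = []

    def add(rid, name, st, lb, ub, gpr="", sub="Central Metabolism"):
        r.append(Reaction(rid, name, st, lb, ub, gpr, sub))

    # exchanges (negative flux = uptake)
    for b in ext:
        add(f"EX_{b}_e", f"{_NAMES.get(b, b)} exchange", {f"{b}_e": -1.0}, -M, M, sub="Other")

    # free diffusion of neutral solutes and small gases; acetaldehyde is
    # volatile, so its loss channel exists (secretion-only by default)
    for b in ("actn", "btd", "etoh", "acald", "h2", "co2", "h2o", "nh4", "k", "mg"):
        add(f"TD_{b}", f"{_NAMES.get(b, b)} diffusion", {f"{b}_e": -1.0, f"{b}_c": 1.0}, -M, M, sub="Transport")
    add("PIt", "phosphate/proton symport", {"pi_e": -1.0, "h_e": -1.0, "pi_c": 1.0, "h_c": 1.0}, -M, M, sub="Transport")
    add(
        "SO4t", "sulfate/proton symport",
        {"so4_e": -1.0, "h_e": -2.0, "so4_c": 1.0, "h_c": 2.0}, 0, M,
        gpr="Pcar_0676" if species == "pcar" else "", sub="Transport",
    )
    add("ACt", "acetate/proton symport", {"ac_c": -1.0, "h_c": -1.0, "ac_e": 1.0, "h_e": 1.0}, -M, M, sub="Transport")

    # acetoin / butanediol degradation and acetyl-CoA handling
    add("BTDD", "2,3-butanediol dehydrogenase", {"btd_c": -1, "nad_c": -1, "actn_c": 1, "nadh_c": 1, "h_c": 1}, 0, M)
    add("ACOR", "acetoin:DCPIP oxidoreductase",
        {"actn_c": -1, "coa_c": -1, "nad_c": -1, "acald_c": 1, "accoa_c": 1, "nadh_c": 1, "h_c": 1}, 0, M,
        gpr=acor_gpr)
    add("ACALD", "acetaldehyde CoA dehydrogenase",
        {"acald_c": -1, "coa_c": -1, "nad_c": -1, "accoa_c": 1, "nadh_c": 1, "h_c": 1}, -M, M,
        gpr="Pcar_2758" if species == "pcar" else "Ppro_0899 or Ppro_1923")
    add("ACKr", "phosphate acetyltransferase + acetate kinase (net)",
        {"accoa_c": -1, "adp_c": -1, "pi_c": -1, "ac_c": 1, "atp_c": 1, "coa_c": 1}, -M, M,
        gpr="Pcar_2542 & Pcar_2543" if species == "pcar" else "")

    # pyruvate node and anaplerosis
    add("POR", "pyruvate:ferredoxin oxidoreductase (reversible)",
        {"accoa_c": -1, "co2_c": -1, "fdred_c": -1, "pyr_c": 1, "coa_c": 1, "fdox_c": 1, "h_c": 1}, -M, M)
    add("FNR", "NADH:ferredoxin reductase",
        {"nadh_c": -1, "h_c": -1, "fdox_c": -1, "nad_c": 1, "fdred_c": 1}, -M, M)
    add("PC", "pyruvate carboxylase",
        {"pyr_c": -1, "co2_c": -1, "atp_c": -1, "h2o_c": -1, "oaa_c": 1, "adp_c": 1, "pi_c": 1, "h_c": 2}, 0, M)

    # TCA cycle; the quinone pool has no route to elemental sulfur, so
    # succinate oxidation cannot be coupled to sulfur reduction
    add("CS", "citrate synthase", {"accoa_c": -1, "oaa_c": -1, "h2o_c": -1, "cit_c": 1, "coa_c": 1, "h_c": 1}, 0, M)
    add("ACONT", "aconitase", {"cit_c": -1, "icit_c": 1}, -M, M)
    add("ICDHy", "isocitrate dehydrogenase (NADP)",
        {"icit_c": -1, "nadp_c": -1, "akg_c": 1, "co2_c": 1, "nadph_c": 1}, -M, M)
    add("AKGDH", "2-oxoglutarate dehydrogenase",
        {"akg_c": -1, "coa_c": -1, "nad_c": -1, "succoa_c": 1, "co2_c": 1, "nadh_c": 1}, 0, M)
    add("SUCOAS", "succinyl-CoA synthetase",
        {"succoa_c": -1, "adp_c": -1, "pi_c": -1, "succ_c": 1, "coa_c": 1, "atp_c": 1}, -M, M)
    add("SUCDq", "succinate dehydrogenase (menaquinone)",
        {"succ_c": -1, "mq_c": -1, "fum_c": 1, "mqh2_c": 1}, -M, M)
    add("FUM", "fumarase", {"fum_c": -1, "h2o_c": -1, "mal_c": 1}, -M, M)
    add("MDH", "malate dehydrogenase", {"mal_c": -1, "nad_c": -1, "oaa_c": 1, "nadh_c": 1, "h_c": 1}, -M, M)

    # redox carriers and energy metabolism
    add("HYD", "NAD-linked hydrogenase", {"nadh_c": -1, "h_c": -1, "h2_c": 1, "nad_c": 1}, -M, M,
        sub="Energy Metabolism")
    add("THD", "transhydrogenase", {"nadh_c": -1, "nadp_c": -1, "nad_c": 1, "nadph_c": 1}, -M, M,
        sub="Energy Metabolism")
    add("SRE", "sulfur reductase (H2)",
        {"h2_c": -1, "s0_e": -1, "h_c": -n1, "hs_e": 1, "h_e": n1 + 1}, 0, M, sub="Energy Metabolism")
    add("SRE2", "sulfur reductase (NADPH)",
        {"nadph_c": -1, "s0_e": -1, "h_c": -n2, "nadp_c": 1, "hs_e": 1, "h_e": n2}, 0, M,
        sub="Energy Metabolism")
    add("FE3Rs", "extracellular nonenzymatic Fe(III) reduction by sulfide",
        {"fe3_e": -2, "hs_e": -1, "fe2_e": 2, "s0_e": 1, "h_e": 1}, 0, M, sub="Energy Metabolism")
    add("ATPS", "ATP synthase",
        {"h_e": -m_h, "adp_c": -1, "pi_c": -1, "atp_c": 1, "h2o_c": 1, "h_c": m_h - 1}, -M, M,
        sub="Energy Metabolism")

    add("ATPM", "ATP maintenance requirement",
        {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1}, ep.ngam, M, sub="Other")
    add("BIOMASS", "biomass demand", {}, 0, M, sub="Other")
    return mets, r


def build_pcar_core(ep: EnergyParams | None = None, bs: BiomassSpec | None = None) -> Model:
    """Core model of *P. carbinolicus*: acetoin/2,3-butanediol/ethylene glycol
    fermentation to acetate + ethanol, H2/formate production for syntrophy,
    and S0/Fe(III) reduction through the sulfide shuttle."""
    ep = ep or EnergyParams.pcar_defaults()
    bs = (bs or BiomassSpec()).resolved(ep)
    mets, rxns = _shared_core(ep, "pcar")
    mets += [_met("eg", "c"), _met("eg", "e"), _met("for", "c"), _met("for", "e")]

    extra = [
        Reaction("EX_eg_e", "ethylene glycol exchange", {"eg_e": -1.0}, -M, M, "", "Other"),
        Reaction("EX_for_e", "formate exchange", {"for_e": -1.0}, -M, M, "", "Other"),
        Reaction("TD_eg", "ethylene glycol diffusion", {"eg_e": -1.0, "eg_c": 1.0}, -M, M, "", "Transport"),
        Reaction("TD_for", "formate diffusion", {"for_e": -1.0, "for_c": 1.0}, -M, M, "", "Transport"),
        Reaction("EGDH", "ethylene glycol dehydratase", {"eg_c": -1, "acald_c": 1, "h2o_c": 1}, 0, M,
                 "", "Central Metabolism"),
        Reaction("PFL", "pyruvate formate lyase", {"pyr_c": -1, "coa_c": -1, "accoa_c": 1, "for_c": 1}, 0, M,
                 "", "Central Metabolism"),
        Reaction("FDH", "formate dehydrogenase", {"for_c": -1, "nad_c": -1, "co2_c": 1, "nadh_c": 1}, -M, M,
                 "", "Central Metabolism"),
        # second alcohol dehydrogenase gene copy: shipped as an isozyme pair
        Reaction("ALCD", "alcohol dehydrogenase (adh-1)",
                 {"etoh_c": -1, "nad_c": -1, "acald_c": 1, "nadh_c": 1, "h_c": 1}, -M, M,
                 "Pcar_0251", "Central Metabolism"),
        Reaction("ALCD2", "alcohol dehydrogenase (adh-2)",
                 {"etoh_c": -1, "nad_c": -1, "acald_c": 1, "nadh_c": 1, "h_c": 1}, -M, M,
                 "Pcar_0255", "Central Metabolism"),
    ]
    model = Model("pcar_core", "Pelobacter carbinolicus", mets, rxns + extra, "BIOMASS", "ATPM",
                  annotations={"gam": ep.gam, "ngam": ep.ngam,
                               "sre_h_per_2e": ep.sre_h_per_2e, "sre2_h_per_2e": ep.sre2_h_per_2e,
                               "atp_synthase_h_per_atp": ep.atp_synthase_h_per_atp})
    set_biomass_composition(model, bs)
    _assert_valid(model)
    return model


def build_ppro_core(
    ep: EnergyParams | None = None,
    bs: BiomassSpec | None = None,
    frd_h_per_2e: float = 2,
    lactate_transport: str = "antiport",
) -> Model:
    """Core model of *P. propionicus*: fermentation of acetoin, 2,3-butanediol,
    ethanol, lactate, propanol and butanol to acetate + propionate (butyrate
    for butanol) through the methylmalonyl-CoA pathway, with a
    proton-translocating membrane fumarate reductase and a lactate/proton
    antiporter for energy conservation.

    ``lactate_transport`` selects the uptake variant: ``antiport`` (exports one
    periplasmic proton per lactate), ``symport`` (electroneutral) or
    ``diffusion`` (anion uniport, dissipating one proton charge).
    """
    ep = ep or EnergyParams.ppro_defaults()
    bs = (bs or BiomassSpec()).resolved(ep)
    mets, rxns = _shared_core(ep, "ppro")
    mets += [
        _met("lac", "c"), _met("lac", "e"), _met("ppa", "c"), _met("ppa", "e"),
        _met("poh", "c"), _met("poh", "e"), _met("ppal", "c"), _met("ppcoa", "c"),
        _met("btoh", "c"), _met("btoh", "e"), _met("btal", "c"), _met("btcoa", "c"),
        _met("but", "c"), _met("but", "e"), _met("mmcoa", "c"),
    ]
    k = frd_h_per_2e
    lac_stoich = {
        "antiport": {"lac_e": -1.0, "h_c": -1.0, "lac_c": 1.0, "h_e": 1.0},
        "symport": {"lac_e": -1.0, "lac_c": 1.0},
        "diffusion": {"lac_e": -1.0, "h_e": -1.0, "lac_c": 1.0, "h_c": 1.0},
    }
    if lactate_transport not in lac_stoich:
        raise ValueError(f"unknown lactate transport variant {lactate_transport!r}")

    extra = [
        Reaction(f"EX_{b}_e", f"{_NAMES.get(b, b)} exchange", {f"{b}_e": -1.0}, -M, M, "", "Other")
        for b in ("lac", "ppa", "poh", "btoh", "but")
    ] + [
        Reaction("TD_poh", "propanol diffusion", {"poh_e": -1.0, "poh_c": 1.0}, -M, M, "", "Transport"),
        Reaction("TD_btoh", "butanol diffusion", {"btoh_e": -1.0, "btoh_c": 1.0}, -M, M, "", "Transport"),
        Reaction("LACt", f"lactate transport ({lactate_transport})", lac_stoich[lactate_transport],
                 -M, M, "", "Transport"),
        Reaction("PPAt", "propionate/proton symport", {"ppa_c": -1.0, "h_c": -1.0, "ppa_e": 1.0, "h_e": 1.0},
                 -M, M, "", "Transport"),
        Reaction("BUTt", "butyrate/proton symport", {"but_c": -1.0, "h_c": -1.0, "but_e": 1.0, "h_e": 1.0},
                 -M, M, "", "Transport"),
        Reaction("ALCD", "alcohol dehydrogenase",
                 {"etoh_c": -1, "nad_c": -1, "acald_c": 1, "nadh_c": 1, "h_c": 1}, -M, M,
                 "", "Central Metabolism"),
        Reaction("LDH", "D-lactate dehydrogenase",
                 {"lac_c": -1, "nad_c": -1, "pyr_c": 1, "nadh_c": 1, "h_c": 1}, -M, M,
                 "", "Central Metabolism"),
        Reaction("FRDm", "membrane fumarate reductase (proton-translocating)",
                 {"nadh_c": -1, "fum_c": -1, "h_c": -(k + 1), "nad_c": 1, "succ_c": 1, "h_e": k},
                 0, M, "", "Energy Metabolism"),
        Reaction("MMM", "methylmalonyl-CoA mutase + epimerase (lumped)",
                 {"succoa_c": -1, "mmcoa_c": 1}, -M, M, "Ppro_1367 & Ppro_1368", "Central Metabolism"),
        Reaction("MMTC", "methylmalonyl-CoA:pyruvate transcarboxylase",
                 {"mmcoa_c": -1, "pyr_c": -1, "ppcoa_c": 1, "oaa_c": 1}, -M, M, "", "Central Metabolism"),
        Reaction("PSCT", "propionyl-CoA:succinate CoA-transferase",
                 {"ppcoa_c": -1, "succ_c": -1, "ppa_c": 1, "succoa_c": 1}, -M, M, "", "Central Metabolism"),
        Reaction("PACT", "propionyl-CoA:acetate CoA-transferase",
                 {"ppcoa_c": -1, "ac_c": -1, "ppa_c": 1, "accoa_c": 1}, -M, M, "", "Central Metabolism"),
        Reaction("POHDH", "propanol dehydrogenase",
                 {"poh_c": -1, "nad_c": -1, "ppal_c": 1, "nadh_c": 1, "h_c": 1}, -M, M,
                 "", "Central Metabolism"),
        Reaction("PPALD", "propionaldehyde CoA dehydrogenase",
                 {"ppal_c": -1, "coa_c": -1, "nad_c": -1, "ppcoa_c": 1, "nadh_c": 1, "h_c": 1}, -M, M,
                 "", "Central Metabolism"),
        Reaction("BTOHDH", "butanol dehydrogenase",
                 {"btoh_c": -1, "nad_c": -1, "btal_c": 1, "nadh_c": 1, "h_c": 1}, -M, M,
                 "", "Central Metabolism"),
        Reaction("BTALD", "butyraldehyde CoA dehydrogenase",
                 {"btal_c": -1, "coa_c": -1, "nad_c": -1, "btcoa_c": 1, "nadh_c": 1, "h_c": 1}, -M, M,
                 "", "Central Metabolism"),
        Reaction("BACT", "butyryl-CoA:acetate CoA-transferase",
                 {"btcoa_c": -1, "ac_c": -1, "but_c": 1, "accoa_c": 1}, -M, M, "", "Central Metabolism"),
        # present on the genome; physiological role unclear, closed by default
        Reaction("CITL", "citrate lyase (closed by default)",
                 {"cit_c": -1, "ac_c": 1, "oaa_c": 1}, 0, 0, "", "Central Metabolism"),
    ]
    model = Model("ppro_core", "Pelobacter propionicus", mets, rxns + extra, "BIOMASS", "ATPM",
                  annotations={"gam": ep.gam, "ngam": ep.ngam,
                               "sre_h_per_2e": ep.sre_h_per_2e, "sre2_h_per_2e": ep.sre2_h_per_2e,
                               "atp_synthase_h_per_atp": ep.atp_synthase_h_per_atp,
                               "frd_h_per_2e": k, "lactate_transport": lactate_transport})
    set_biomass_composition(model, bs)
    _assert_valid(model)
    return model


def _assert_valid(model: Model) -> None:
    violations = validate_model(model)
    if violations:
        raise ValueError(
            f"built model {model.id!r} fails validation: "
            + "; ".join(str(v) for v in violations)
        )


def calibrate_biomass(
    model: Model,
    targets: list[tuple],
    free: tuple[str, ...] = ("acetyl_coa",),
    bound_fraction: float = 0.5,
    grid_points: int = 41,
) -> BiomassSpec:
    """Grid search over free lumped-biomass coefficients against observed
    scenario ratios.

    ``targets`` is a list of ``(predict_fn, observed)`` pairs where
    ``predict_fn(model) -> float`` computes a scenario ratio on a candidate
    model. The free coefficients are searched on a uniform grid within
    ``±bound_fraction`` of their current values, minimizing the summed squared
    relative error; deterministic given the grid (ties break toward smaller
    coefficients). An empty ``free`` set returns the current spec unchanged.
    """
    current = model.annotations.get("biomass")
    if current is None:
        raise ValueError("model carries no lumped-biomass annotation to calibrate")
    if not targets:
        raise ValueError("at least one calibration target is required")
    spec = BiomassSpec(
        acetyl_coa=current["acetyl_coa"], nadph=current["nadph"],
        nh4=current["nh4"], gam=current["gam"],
    )
    if not free:
        return spec
    for name in free:
        if name not in ("acetyl_coa", "nadph", "nh4", "gam"):
            raise ValueError(f"unknown biomass coefficient {name!r}")

    import numpy as np

    grids = [
        np.linspace(getattr(spec, name) * (1 - bound_fraction),
                    getattr(spec, name) * (1 + bound_fraction), grid_points)
        for name in free
    ]
    best_sse, best_vals = None, None
    work = model.copy()
    for values in itertools.product(*grids):
        cand = replace(spec, **dict(zip(free, (float(v) for v in values))))
        set_biomass_composition(work, cand)
        sse = 0.0
        for predict, observed in targets:
            pred = predict(work)
            sse += ((pred - observed) / observed) ** 2
        if best_sse is None or sse < best_sse - 1e-12:
            best_sse, best_vals = sse, values
    if best_sse > 1e-6:
        warnings.warn(
            f"calibration residual {best_sse:.3g} > 0 at the grid optimum; "
            "targets not exactly reachable within the coefficient bounds",
            stacklevel=2,
        )
    return replace(spec, **dict(zip(free, (float(v) for v in best_vals))))
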