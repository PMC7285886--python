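"""Gut microbial community models and their attachment to the host's
large-intestinal lumen.

Strain models share the host's luminal metabolite namespace (``met[luLI]``).
A community model is the abundance-weighted union of strain submodels: each
strain's reactions are prefixed with its id, a community biomass reaction
consumes the strain biomass metabolites at their normalized relative
abundances, and the community biomass is excreted fecally. Attaching a
community to a whole-body model fixes the community growth (default 1/day,
daily fecal biomass turnover) and couples every strain reaction to the
strain's own biomass with a microbial coupling factor (default 400).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .model import (DEFAULT_BIG, CouplingConstraint, Metabolite, Reaction,
                    StoichiometricModel, split_met_id)
from .simulate import fba

MICROBE_COUPLING_FACTOR = 400.0
COMMUNITY_BIOMASS_ID = "communityBiomass"
COMMUNITY_BIOMASS_MET = "microbeBiomass[luLI]"
LUMEN = "luLI"


@dataclass
class MicrobeModel:
    model: StoichiometricModel
    biomass_reaction: str
    taxonomy: dict[str, str] = field(default_factory=dict)  # rank -> name

    def __post_init__(self):
        if not self.model.has_reaction(self.biomass_reaction):
            raise KeyError(f"{self.model.id}: biomass reaction "
                           f"{self.biomass_reaction!r} not in model")

    @property
    def strain_id(self) -> str:
        return self.model.id


@dataclass
class AbundanceProfile:
    abundances: dict[str, float]  # strain id -> relative abundance (sums to 1)
    coverage: float = 1.0         # fraction of the raw sample that was mapped

    def __post_init__(self):
        for strain, a in self.abundances.items():
            if a < 0:
                raise ValueError(f"{strain}: negative abundance")


def normalize_abundances(raw: Mapping[str, float],
                         model_catalog: Iterable[str]) -> AbundanceProfile:
    """Drop strains absent from the model catalog and renormalize.

    coverage = mapped abundance / total abundance of the raw profile.
    """
    catalog = set(model_catalog)
    total = float(sum(raw.values()))
    if total <= 0:
        raise ValueError("all-zero abundance profile")
    mapped = {s: a for s, a in raw.items() if s in catalog and a > 0}
    mapped_total = float(sum(mapped.values()))
    if mapped_total <= 0:
        raise ValueError("no strain of the profile maps to the model catalog")
    return AbundanceProfile({s: a / mapped_total for s, a in mapped.items()},
                            coverage=mapped_total / total)


@dataclass
class CommunityModel:
    model: StoichiometricModel
    profile: AbundanceProfile
    strain_biomass: dict[str, str]  # strain id -> prefixed biomass reaction id


def build_community(strains: list[MicrobeModel],
                    profile: AbundanceProfile) -> CommunityModel:
    """Abundance-weighted community sharing the large-intestinal lumen.

    Strain-internal metabolites/reactions get strain prefixes; [luLI]
    metabolites stay unprefixed (shared). The community biomass reaction
    consumes each strain's biomass metabolite at its normalized abundance and
    produces a community biomass metabolite in the lumen.
    """
    by_id = {s.strain_id: s for s in strains}
    missing = set(profile.abundances) - set(by_id)
    if missing:
        raise KeyError(f"profile strains without models: {sorted(missing)}")

    comm = StoichiometricModel("community")
    comm.compartments[LUMEN] = "Lumen, large intestine"
    strain_biomass: dict[str, str] = {}
    biomass_mets: dict[str, str] = {}

    for strain_id, abundance in sorted(profile.abundances.items()):
        if abundance == 0:
            continue
        strain = by_id[strain_id]
        prefix = f"{strain_id}_"
        for met in strain.model.metabolites:
            mid = met.id if met.compartment == LUMEN else f"{prefix}{met.base_id}[{met.compartment}]"
            if not comm.has_metabolite(mid):
                comm.add_metabolite(Metabolite(mid, met.name, met.compartment,
                                               met.formula, met.charge,
                                               met.molecular_weight))
        for rxn in strain.model.reactions:
            stoich = {}
            for m, c in rxn.stoichiometry.items():
                base, compartment = split_met_id(m)
                mid = m if compartment == LUMEN else f"{prefix}{base}[{compartment}]"
                stoich[mid] = c
            comm.add_reaction(Reaction(f"{prefix}{rxn.id}", stoich, rxn.lb, rxn.ub,
                                       rxn.gpr, rxn.subsystem, organ=prefix))
        strain_biomass[strain_id] = f"{prefix}{strain.biomass_reaction}"
        # the strain's biomass product is its dummy biomass metabolite
        bio_rxn = comm.get_reaction(strain_biomass[strain_id])
        products = [m for m, c in bio_rxn.stoichiometry.items() if c > 0]
        bio_mets = [m for m in products if "biomass" in m.lower()]
        if not bio_mets:
            raise ValueError(f"{strain_id}: biomass reaction produces no biomass metabolite")
        biomass_mets[strain_id] = bio_mets[0]

    comm.add_metabolite(Metabolite(COMMUNITY_BIOMASS_MET, "community biomass", LUMEN))
    stoich = {biomass_mets[s]: -float(a)
              for s, a in sorted(profile.abundances.items()) if a > 0}
    stoich[COMMUNITY_BIOMASS_MET] = 1.0
    comm.add_reaction(Reaction(COMMUNITY_BIOMASS_ID, stoich, 0.0, DEFAULT_BIG,
                               subsystem="community biomass"))
    comm.objective = {COMMUNITY_BIOMASS_ID: 1.0}
    return CommunityModel(comm, profile, strain_biomass)


def attach_to_host(wbm: StoichiometricModel, community: CommunityModel,
                   community_growth: float = 1.0,
                   coupling_factor: float = MICROBE_COUPLING_FACTOR) -> StoichiometricModel:
    """Merge a community into the host's large-intestinal lumen (myWBM).

    The community biomass flux is fixed to *community_growth* (per day);
    strain reactions are coupled to the strain's biomass with the microbial
    coupling factor. Microbial lumen metabolites unknown to the host gain a
    luminal transit to feces and a fecal exchange so they can leave the body.
    """
    if not any(m.compartment == LUMEN for m in wbm.metabolites):
        raise KeyError(f"host model has no [{LUMEN}] compartment")
    my = wbm.copy(f"{wbm.id}_my")
    host_lumen = {m.id for m in wbm.metabolites if m.compartment == LUMEN}

    for met in community.model.metabolites:
        if not my.has_metabolite(met.id):
            my.add_metabolite(met.copy())
    for rxn in community.model.reactions:
        my.add_reaction(rxn.copy())
    for c in community.model.coupling:
        my.coupling.append(CouplingConstraint(c.coupled_reaction,
                                              c.anchor_reaction, c.factor))

    # fix community growth (daily fecal turnover)
    growth = my.get_reaction(COMMUNITY_BIOMASS_ID)
    growth.lb = growth.ub = community_growth

    # couple strain reactions to strain biomass
    for strain_id, bio_rid in community.strain_biomass.items():
        prefix = f"{strain_id}_"
        for rxn in my.reactions:
            if rxn.id.startswith(prefix) and rxn.id != bio_rid:
                my.coupling.append(CouplingConstraint(rxn.id, bio_rid,
                                                      coupling_factor))

    # exit routes for microbial metabolites the host does not know
    for met in community.model.metabolites:
        if met.compartment != LUMEN or met.id in host_lumen:
            continue
        base = met.base_id
        fe_id = f"{base}[fe]"
        if not my.has_metabolite(fe_id):
            my.add_metabolite(Metabolite(fe_id, met.name, "fe", met.formula,
                                         met.charge, met.molecular_weight))
        tr = f"TR_{base}_{LUMEN}_fe"
        if not my.has_reaction(tr):
            my.add_reaction(Reaction(tr, {met.id: -1.0, fe_id: 1.0}, 0.0,
                                     DEFAULT_BIG, subsystem="biofluid flow"))
        ex = f"EX_{base}[fe]"
        if not my.has_reaction(ex):
            my.add_reaction(Reaction(ex, {fe_id: -1.0}, 0.0, DEFAULT_BIG,
                                     subsystem="excretion"))
    return my


def fold_change(germfree_wbm: StoichiometricModel, my_wbm: StoichiometricModel,
                reaction: str, tol: float = 1e-9) -> float:
    """Ratio of maximal flux through *reaction* with vs without microbiome.

    A germ-free maximum of ~0 with a positive microbiome-associated maximum
    is reported as +inf.
    """
    for m in (germfree_wbm, my_wbm):
        if not m.has_reaction(reaction):
            raise KeyError(f"reaction {reaction!r} absent from {m.id}")
    gf = fba(germfree_wbm, {reaction: 1.0}, "max")
    my = fba(my_wbm, {reaction: 1.0}, "max")
    gf_max = gf.objective_value if gf.optimal else 0.0
    my_max = my.objective_value if my.optimal else 0.0
    if abs(gf_max) <= tol:
        return float("inf") if my_max > tol else 1.0
    return my_max / gf_max


def taxon_ratio(profile: AbundanceProfile, taxonomy: Mapping[str, Mapping[str, str]],
                num_class: str, den_class: str, rank: str = "class") -> float:
    """Abundance ratio of two taxa (e.g. Bacteroidia/Clostridia); +inf when
    the denominator class is absent."""
    known = {label for tax in taxonomy.values() for label in tax.values()}
    for label in (num_class, den_class):
        if label not in known:
            raise KeyError(f"unknown taxon label {label!r}")
    num = sum(a for s, a in profile.abundances.items()
              if taxonomy.get(s, {}).get(rank) == num_class)
    den = sum(a for s, a in profile.abundances.items()
              if taxonomy.get(s, {}).get(rank) == den_class)
    if den == 0:
        return float("inf")
    return num / den


def secretion_potential(model: StoichiometricModel, metabolite: str,
                        community_growth: Optional[float] = None) -> float:
    """Maximal secretion flux of a metabolite into the shared lumen.

    Works on a strain model or a community model; for the latter,
    *community_growth* (if given) fixes the community biomass flux while
    maximizing the luminal exchange of the metabolite.
    """
    mid = f"{metabolite}[{LUMEN}]"
    if not model.has_metabolite(mid):
        raise KeyError(f"metabolite {mid!r} not in the lumen namespace")
    work = model.copy(f"{model.id}_secretion")
    rid = f"__secretion_DM_{metabolite}"
    work.add_reaction(Reaction(rid, {mid: -1.0}, 0.0, DEFAULT_BIG))
    # in situ the gut lumen supplies substrates and carries away byproducts:
    # free temporary exchanges for every other luminal metabolite
    for met in model.metabolites:
        if met.compartment == LUMEN and met.id != mid:
            work.add_reaction(Reaction(f"__lumen_EX_{met.id}", {met.id: -1.0},
                                       -DEFAULT_BIG, DEFAULT_BIG))
    # standalone strain: biomass products need a growth-dilution outlet so ATP
    # can turn over (in a community model the community biomass plays this role)
    dilution_ids = []
    if not work.has_reaction(COMMUNITY_BIOMASS_ID):
        for met in model.metabolites:
            if "biomass" in met.base_id.lower():
                rid_d = f"__dilution_DM_{met.id}"
                work.add_reaction(Reaction(rid_d, {met.id: -1.0}, 0.0, DEFAULT_BIG))
                dilution_ids.append(rid_d)
    fixed = None
    if community_growth is not None:
        if work.has_reaction(COMMUNITY_BIOMASS_ID):
            fixed = {COMMUNITY_BIOMASS_ID: community_growth}
        elif dilution_ids:
            fixed = {dilution_ids[0]: community_growth}
    sol = fba(work, {rid: 1.0}, "max", fixed=fixed)
    return sol.objective_value if sol.optimal else 0.0
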