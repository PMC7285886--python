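"""Deterministic synthetic "toy body": a small human-like base network, nine
organs wired through biofluid compartments, physiology/metabolomics/diet
tables, an IEM catalog and four gut microbes — everything the other modules
need, generated in memory with no downloads.

The base network is a caricature of central metabolism built from lumped but
element-conserving reactions (formulas are tracked; deliberately mass-losing
lumps are irreversible, so nothing can be created from nothing):

* anaerobic glycolysis with the textbook net yield of 2 ATP/glucose;
* mitochondrial oxidation driven by an explicit proton cycle (an
  oxidation-driven proton export and an ATP synthase), tuned so that complete
  aerobic oxidation of one glucose yields exactly 31 ATP;
* liver-only gluconeogenesis and urea synthesis, a muscle-only alanine
  synthesis and liver/kidney/gut alanine deamination (Cori and Cahill cycle
  substrate);
* aromatic amino-acid neurotransmitter toys (Phe -> Tyr -> dopamine,
  Trp -> serotonin, Glu -> GABA, His -> histamine);
* liver ethanol oxidation (alcohol dehydrogenase), p-cresol sulfonation, and
  a colonocyte butyrate-CoA ligase feeding mitochondrial oxidation;
* glycogen storage in liver, muscle and adipose tissue.

Red blood cells lack mitochondria and use the noTrTr biomass; liver, heart
and kidney carry the regenerative biomass variant.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .assembly import (BiofluidLink, BiofluidMap, Flow, OrganSpec,
                       WholeBodyObjective, add_storage, compose_biomass,
                       compose_whole_body_maintenance, replicate_base,
                       wire_biofluids)
from .consistency import fastcc
from .microbiome import MicrobeModel, build_community, normalize_abundances, attach_to_host
from .model import (DEFAULT_BIG, Metabolite, Reaction, StoichiometricModel,
                    set_default_bounds, snapshot_default_bounds)
from .pscm import DietSpec, MetabolitePanel, PhysiologyParameters, apply_pscm

# ---------------------------------------------------------------------------
# Base metabolites: (base id, name, formula, MW g/mol)
# ---------------------------------------------------------------------------

_BASE_METS = [
    ("glc_D", "D-glucose", "C6H12O6", 180.16),
    ("lac_L", "L-lactate", "C3H6O3", 90.08),
    ("ala_L", "L-alanine", "C3H7NO2", 89.09),
    ("glu_L", "L-glutamate", "C5H9NO4", 147.13),
    ("nh3", "ammonia", "H3N", 17.03),
    ("urea", "urea", "CH4N2O", 60.06),
    ("atp", "ATP", "C10H16N5O13P3", 507.18),
    ("adp", "ADP", "C10H15N5O10P2", 427.20),
    ("amp", "AMP", "C10H14N5O7P", 347.22),
    ("pi", "phosphate", "H3O4P", 98.00),
    ("h", "proton", "H", 1.008),
    ("h2o", "water", "H2O", 18.02),
    ("o2", "oxygen", "O2", 32.00),
    ("co2", "carbon dioxide", "CO2", 44.01),
    ("phe_L", "L-phenylalanine", "C9H11NO2", 165.19),
    ("tyr_L", "L-tyrosine", "C9H11NO3", 181.19),
    ("trp_L", "L-tryptophan", "C11H12N2O2", 204.23),
    ("his_L", "L-histidine", "C6H9N3O2", 155.15),
    ("dopa", "dopamine", "C8H11NO2", 153.18),
    ("srtn", "serotonin", "C10H12N2O", 176.21),
    ("gaba", "4-aminobutanoate", "C4H9NO2", 103.12),
    ("hista", "histamine", "C5H9N3", 111.15),
    ("pcresol", "p-cresol", "C7H8O", 108.14),
    ("pcsulf", "p-cresol sulfate", "C7H8O4S", 188.20),
    ("so4", "sulfate", "H2O4S", 98.08),
    ("but", "butyrate", "C4H8O2", 88.11),
    ("butcoa", "activated butyrate (toy)", "C4H10O3", 106.12),
    ("etoh", "ethanol", "C2H6O", 46.07),
    ("acald", "acetaldehyde", "C2H4O", 44.05),
    ("ac", "acetate", "C2H4O2", 60.05),
    ("h2", "dihydrogen", "H2", 2.016),
    ("glycogen", "glycogen unit (toy)", "C6H12O6", 180.16),
    ("proteome", "proteome pseudo-metabolite", None, None),
    ("transcriptome", "transcriptome pseudo-metabolite", None, None),
]
_MET_INFO = {m[0]: m for m in _BASE_METS}

# circulating metabolites: present in [e] and wired through the biofluids
CIRCULATING = ["glc_D", "lac_L", "ala_L", "glu_L", "nh3", "urea", "phe_L",
               "tyr_L", "trp_L", "his_L", "dopa", "srtn", "gaba", "hista",
               "pcresol", "pcsulf", "so4", "but", "etoh", "o2", "co2",
               "h2o", "pi"]

_MITO_METS = ["lac_L", "o2", "co2", "h2o", "pi", "atp", "adp", "h", "ac", "butcoa"]
_CYto_ONLY = None  # every base metabolite exists in [c]

# reaction definitions: id -> (stoich by (base, comp), reversible, gpr)
_R = {
    # cytosolic core
    "GLYCL": ({("glc_D", "c"): -1, ("adp", "c"): -2, ("pi", "c"): -2,
               ("lac_L", "c"): 2, ("atp", "c"): 2, ("h2o", "c"): 2},
              False, "TOY_GCK and TOY_PFKM"),
    "GLUCONEO": ({("lac_L", "c"): -2, ("atp", "c"): -6, ("h2o", "c"): -6,
                  ("glc_D", "c"): 1, ("adp", "c"): 6, ("pi", "c"): 6},
                 False, "TOY_PC and TOY_PCK1"),
    "DM_atp_c_": ({("atp", "c"): -1, ("h2o", "c"): -1,
                   ("adp", "c"): 1, ("pi", "c"): 1}, False, None),
    "ADK1": ({("amp", "c"): -1, ("atp", "c"): -1, ("adp", "c"): 2},
             True, "TOY_AK1"),
    "ALADEAM": ({("ala_L", "c"): -1, ("h2o", "c"): -1,
                 ("lac_L", "c"): 1, ("nh3", "c"): 1}, False, "TOY_GPT"),
    "ALASYN": ({("lac_L", "c"): -1, ("nh3", "c"): -1,
                ("ala_L", "c"): 1, ("h2o", "c"): 1}, False, "TOY_GPT2"),
    "GLUDEAM": ({("glu_L", "c"): -1, ("o2", "c"): -1.5,
                 ("lac_L", "c"): 1, ("nh3", "c"): 1, ("co2", "c"): 2},
                False, "TOY_GLUD1"),
    "UREASYN": ({("nh3", "c"): -2, ("co2", "c"): -1, ("atp", "c"): -3,
                 ("h2o", "c"): -2, ("urea", "c"): 1, ("adp", "c"): 3,
                 ("pi", "c"): 3}, False, "TOY_CPS1"),
    "PHETHL": ({("phe_L", "c"): -1, ("o2", "c"): -0.5, ("tyr_L", "c"): 1},
               False, "TOY_PAH"),
    "TYRDOPA": ({("tyr_L", "c"): -1, ("o2", "c"): -0.5,
                 ("dopa", "c"): 1, ("co2", "c"): 1}, False, "TOY_TH"),
    "TRPHTR": ({("trp_L", "c"): -1, ("o2", "c"): -0.5,
                ("srtn", "c"): 1, ("co2", "c"): 1}, False, "TOY_TPH2"),
    "GLUDC": ({("glu_L", "c"): -1, ("gaba", "c"): 1, ("co2", "c"): 1},
              False, "TOY_GAD1"),
    "HISDC": ({("his_L", "c"): -1, ("hista", "c"): 1, ("co2", "c"): 1},
              False, "TOY_HDC"),
    "ALCD2if": ({("etoh", "c"): -1, ("o2", "c"): -0.5,
                 ("acald", "c"): 1, ("h2o", "c"): 1},
                False, "TOY_ADH1B or TOY_ADH1C"),
    "ACALD2x": ({("acald", "c"): -1, ("o2", "c"): -0.5, ("ac", "c"): 1},
                False, "TOY_ALDH2"),
    "PCSF": ({("pcresol", "c"): -1, ("so4", "c"): -1, ("atp", "c"): -1,
              ("pcsulf", "c"): 1, ("adp", "c"): 1, ("pi", "c"): 1},
             False, "TOY_SULT1A1"),
    "BUTCOAL": ({("but", "c"): -1, ("atp", "c"): -1, ("h2o", "c"): -2,
                 ("butcoa", "c"): 1, ("adp", "c"): 1, ("pi", "c"): 1},
                False, "TOY_ACSM3"),
    "GLYCS": ({("glc_D", "c"): -1, ("atp", "c"): -1, ("h2o", "c"): -1,
               ("glycogen", "c"): 1, ("adp", "c"): 1, ("pi", "c"): 1},
              False, "TOY_GYS1"),
    "GLYCP": ({("glycogen", "c"): -1, ("glc_D", "c"): 1}, False, "TOY_PYGL"),
    # mitochondrial transporters
    "t_LACm": ({("lac_L", "c"): -1, ("lac_L", "m"): 1}, True, None),
    "t_O2m": ({("o2", "c"): -1, ("o2", "m"): 1}, True, None),
    "t_CO2m": ({("co2", "c"): -1, ("co2", "m"): 1}, True, None),
    "t_H2Om": ({("h2o", "c"): -1, ("h2o", "m"): 1}, True, None),
    "t_PIm": ({("pi", "c"): -1, ("pi", "m"): 1}, True, None),
    "t_ACm": ({("ac", "c"): -1, ("ac", "m"): 1}, True, None),
    "t_BTCm": ({("butcoa", "c"): -1, ("butcoa", "m"): 1}, False, None),
    "ANTm": ({("atp", "m"): -1, ("adp", "c"): -1,
              ("atp", "c"): 1, ("adp", "m"): 1}, True, "TOY_SLC25A4"),
    # mitochondrial oxidation: substrate oxidation exports protons, the ATP
    # synthase re-imports them at 2 h+/ATP, giving 14.5 ATP/lactate and thus
    # 2 + 2*14.5 = 31 ATP per glucose aerobically
    "LACDHm": ({("lac_L", "m"): -1, ("o2", "m"): -3, ("h", "m"): -29,
                ("co2", "m"): 3, ("h2o", "m"): 3, ("h", "c"): 29},
               False, "TOY_NDUFS1 and TOY_COX4I1"),
    "ACDHm": ({("ac", "m"): -1, ("o2", "m"): -2, ("h", "m"): -20,
               ("co2", "m"): 2, ("h2o", "m"): 2, ("h", "c"): 20},
              False, "TOY_ACO2"),
    "BUTDHm": ({("butcoa", "m"): -1, ("o2", "m"): -5, ("h", "m"): -40,
                ("co2", "m"): 4, ("h2o", "m"): 5, ("h", "c"): 40},
               False, "TOY_ACADS"),
    "ATPS4m": ({("adp", "m"): -1, ("pi", "m"): -1, ("h", "c"): -2,
                ("atp", "m"): 1, ("h2o", "m"): 1, ("h", "m"): 2},
               False, "TOY_ATP5F1A"),
}

# organ-restricted reactions (absent everywhere else)
ORGAN_RESTRICTIONS = {
    "GLUCONEO": {"Liver_"},
    "ALADEAM": {"Liver_", "Kidney_", "sIEC_"},
    "ALASYN": {"Muscle_"},
    "UREASYN": {"Liver_"},
    "PHETHL": {"Liver_"},
    "TYRDOPA": {"Brain_"},
    "TRPHTR": {"Brain_"},
    "GLUDC": {"Brain_"},
    "HISDC": {"Brain_"},
    "ALCD2if": {"Liver_"},
    "ACALD2x": {"Liver_"},
    "PCSF": {"Liver_"},
    "BUTCOAL": {"Colon_"},
    "GLYCS": {"Liver_", "Muscle_", "Adipocytes_"},
    "GLYCP": {"Liver_", "Muscle_", "Adipocytes_"},
}

STORAGE_ORGANS = {"Liver_": ["glycogen"], "Muscle_": ["glycogen"],
                  "Adipocytes_": ["glycogen"]}

BBB_BLOCKED = ["dopa", "srtn", "gaba", "hista", "pcsulf"]
BBB_ALLOWED = ["glc_D", "lac_L", "o2", "co2", "phe_L", "tyr_L", "trp_L",
               "his_L", "glu_L", "ala_L", "h2o", "pi", "nh3", "urea",
               "etoh", "so4"]

# whole-body maintenance coefficients for the nine toy organs
# (weight-derived reference values; weight_fraction = coefficient / 100)
TOY_WB_COEFFICIENTS = {
    "Adipocytes_": 21.4286, "Brain_": 2.0, "Colon_": 0.428571,
    "Heart_": 0.472857, "Kidney_": 0.442857, "Liver_": 2.57143,
    "Muscle_": 40.0, "sIEC_": 0.914286, "RBC_": 3.53571,
}

# toy biomass: the printed maintenance energetics (20.7045 ATP of which
# 0.053446 becomes transcriptome AMP) over the amino acids present in the toy
_TOY_AA = {"ala_L": 0.50563, "glu_L": 0.38587, "phe_L": 0.25947,
           "tyr_L": 0.15967, "trp_L": 0.013306, "his_L": 0.12641}
_ATP_TOTAL = 20.7045
_AMP_PART = 0.053446
_HYDROLYSIS = _ATP_TOTAL - _AMP_PART

_TOY_MAINTENANCE = {
    "atp": -_ATP_TOTAL,
    "h2o": -(_HYDROLYSIS + 2 * _AMP_PART),
    "glc_D": -0.27519,
    **{aa: -c for aa, c in _TOY_AA.items()},
    "adp": _HYDROLYSIS,
    "pi": _HYDROLYSIS + 2 * _AMP_PART,
    "proteome": 1.0,
    "transcriptome": 1.0,
}
_TOY_NOTRTR = {"atp": -_ATP_TOTAL, "h2o": -_ATP_TOTAL,
               "adp": _ATP_TOTAL, "pi": _ATP_TOTAL}

TOY_BIOMASS_TABLE = {
    "maintenance": _TOY_MAINTENANCE,
    "full": _TOY_MAINTENANCE,
    "noTrTr": _TOY_NOTRTR,
    "degradation": {
        "PROTEOME_DEGRx": {"proteome": -1.0, **_TOY_AA},
        "TRANSCRIPTOME_DEGRx": {"transcriptome": -1.0, "amp": _AMP_PART},
    },
}


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def _met(base: str, comp: str) -> Metabolite:
    _, name, formula, mw = _MET_INFO[base]
    return Metabolite(f"{base}[{comp}]", name, comp, formula, None, mw)


def toy_base_model() -> StoichiometricModel:
    """The organ-agnostic base network (no boundary reactions)."""
    m = StoichiometricModel("toy_base")
    m.compartments = {"c": "cytosol", "m": "mitochondrion", "e": "extracellular"}
    for base, *_ in _BASE_METS:
        m.add_metabolite(_met(base, "c"))
    for base in _MITO_METS:
        m.add_metabolite(_met(base, "m"))
    for base in CIRCULATING:
        m.add_metabolite(_met(base, "e"))
    for rid, (stoich, rev, gpr) in _R.items():
        m.add_reaction(Reaction(
            rid, {f"{b}[{c}]": float(v) for (b, c), v in stoich.items()},
            -DEFAULT_BIG if rev else 0.0, DEFAULT_BIG, gpr))
    for base in CIRCULATING:
        m.add_reaction(Reaction(f"t_{base}e",
                                {f"{base}[e]": -1.0, f"{base}[c]": 1.0},
                                -DEFAULT_BIG, DEFAULT_BIG))
    return m


def open_base(base: StoichiometricModel) -> StoichiometricModel:
    """Base model plus open [e] exchanges, for standalone consistency tests."""
    m = base.copy(base.id + "_open")
    for met_base in CIRCULATING:
        m.add_reaction(Reaction(f"EX_{met_base}[e]", {f"{met_base}[e]": -1.0},
                                -DEFAULT_BIG, DEFAULT_BIG))
    return m


def toy_organs(variant: str = "default") -> list[OrganSpec]:
    def links(*specs):
        return [BiofluidLink(*s) if isinstance(s, tuple) else s for s in specs]

    colon_lumen = BiofluidLink("luLI", "uptake")
    if variant == "fragile":
        # the colon loses its absorptive capacity: the small intestine becomes
        # the only route from the gut lumen into the body
        colon_lumen = BiofluidLink("luLI", "secrete")

    organs = [
        OrganSpec("liver", "Liver_", biofluids=links(
            ("bc", "both"), ("bp", "uptake")),
            weight_fraction=0.0257143, biomass_variant="full"),
        OrganSpec("skeletal muscle", "Muscle_", biofluids=links(("bc", "both")),
                  weight_fraction=0.40),
        OrganSpec("brain", "Brain_", biofluids=[
            BiofluidLink("bc", "both", bbb_filtered=True),
            BiofluidLink("csf", "secrete")],
            weight_fraction=0.02),
        OrganSpec("kidney", "Kidney_", biofluids=[
            BiofluidLink("bc", "both"),
            BiofluidLink("u", "filter", filter_source="bc")],
            weight_fraction=0.00442857, biomass_variant="full"),
        OrganSpec("colon", "Colon_", biofluids=[
            BiofluidLink("bc", "uptake"), BiofluidLink("bp", "secrete"),
            colon_lumen],
            weight_fraction=0.00428571),
        OrganSpec("heart", "Heart_", biofluids=links(("bc", "both")),
                  weight_fraction=0.00472857, biomass_variant="full"),
        OrganSpec("adipose tissue", "Adipocytes_", biofluids=links(("bc", "both")),
                  weight_fraction=0.214286),
        OrganSpec("small intestinal epithelium", "sIEC_", biofluids=[
            BiofluidLink("bc", "uptake"), BiofluidLink("bp", "secrete"),
            BiofluidLink("luSI", "uptake")],
            weight_fraction=0.00914286),
        OrganSpec("red blood cell", "RBC_", biofluids=links(("bc", "both")),
                  organelles_absent=["m"], weight_fraction=0.0353571,
                  biomass_variant="noTrTr"),
    ]
    return organs


def toy_biofluid_map() -> BiofluidMap:
    comps = [(c, d) for c, d in
             [("d", "Diet"), ("lu", "Lumen"), ("luSI", "Lumen, small intestine"),
              ("luLI", "Lumen, large intestine"), ("fe", "Feces"),
              ("bc", "Blood, circulation"), ("bp", "Blood, portal vein"),
              ("csf", "Cerebrospinal fluid"), ("u", "Urine"), ("a", "Air")]]
    return BiofluidMap(
        compartments=comps,
        flows=[Flow("d", "lu"), Flow("lu", "luSI"), Flow("luSI", "luLI"),
               Flow("luLI", "fe"), Flow("csf", "bc"),
               Flow("a", "bc", {"o2"}), Flow("bc", "a", {"co2"})],
        restricted={"a": {"o2", "co2"}},
        excluded={"u": {"nh3"}},
        boundary={"d": "diet", "fe": "excretion", "u": "excretion", "a": "air"},
    )


def toy_physiology(**overrides) -> PhysiologyParameters:
    params = dict(
        sex="male", body_weight=70.0, height=170.0,
        heart_rate=67.0, stroke_volume=75.0, hematocrit=0.45,
        gfr_fraction=0.20, urine_volume=1.4, csf_flow=0.5,
        organ_blood_flow_fraction={
            "Liver_": 0.25, "Kidney_": 0.19, "Muscle_": 0.17, "Brain_": 0.12,
            "Heart_": 0.04, "Colon_": 0.04, "Adipocytes_": 0.05,
            "sIEC_": 0.10, "RBC_": 0.04},
        organ_weight_fraction={tag: c / 100.0
                               for tag, c in TOY_WB_COEFFICIENTS.items()},
    )
    params.update(overrides)
    return PhysiologyParameters(**params)


def toy_plasma_panel() -> MetabolitePanel:
    return MetabolitePanel("bc", {
        "glc_D": (3.0, 8.0), "lac_L": (0.5, 2.0), "ala_L": (0.2, 0.6),
        "glu_L": (0.03, 0.1), "o2": (2.0, 5.0), "phe_L": (0.04, 0.12),
        "tyr_L": (0.03, 0.1), "urea": (2.0, 8.0), "so4": (0.2, 0.5)})


def toy_urine_panel() -> MetabolitePanel:
    return MetabolitePanel("u", {
        "urea": (10.0, 500.0), "glc_D": (0.0, 0.3), "lac_L": (0.0, 1.0),
        "phe_L": (0.0, 2.0), "tyr_L": (0.0, 2.0), "dopa": (0.0, 0.05),
        "srtn": (0.0, 0.05), "gaba": (0.0, 0.05), "hista": (0.0, 0.05),
        "pcsulf": (0.0, 1.0), "etoh": (0.0, 1.0)})


def toy_csf_panel() -> MetabolitePanel:
    return MetabolitePanel("csf", {
        "lac_L": (0.9, 2.5), "dopa": (0.0, 0.05), "srtn": (0.0, 0.05),
        "gaba": (0.0, 0.05), "hista": (0.0, 0.05)})


def toy_diet() -> DietSpec:
    return DietSpec({
        "glc_D": 800.0, "ala_L": 30.0, "glu_L": 40.0, "phe_L": 15.0,
        "tyr_L": 10.0, "trp_L": 5.0, "his_L": 10.0, "so4": 20.0,
        "etoh": 20.0, "h2o": 3000.0, "pi": 50.0}, energy_kcal=650.0)


def toy_iem_catalog():
    from .analyses import IemTask
    return [
        IemTask("PKU_toy", ["TOY_PAH"],
                [("phe_L", "bc", "increased"), ("tyr_L", "bc", "decreased")]),
        IemTask("ADH_isozyme_control", ["TOY_ADH1B"],
                [("etoh", "bc", "increased")]),
        IemTask("GAD_deficiency_toy", ["TOY_GAD1"],
                [("gaba", "csf", "decreased")]),
    ]


def toy_expression() -> pd.DataFrame:
    """Gene-by-organ expression toy (already scaled to [0, 1])."""
    organs = list(TOY_WB_COEFFICIENTS)
    genes = sorted({g for _, (_, _, gpr) in _R.items() if gpr
                    for g in gpr.replace("(", " ").replace(")", " ").split()
                    if g not in ("and", "or")})
    df = pd.DataFrame(0.05, index=genes, columns=organs)
    df.loc[:, :] = 0.05
    housekeeping = ["TOY_GCK", "TOY_PFKM", "TOY_AK1", "TOY_SLC25A4",
                    "TOY_NDUFS1", "TOY_COX4I1", "TOY_ATP5F1A", "TOY_GLUD1"]
    df.loc[housekeeping, :] = 0.8
    df.loc[["TOY_NDUFS1", "TOY_COX4I1", "TOY_ATP5F1A", "TOY_SLC25A4"], "RBC_"] = 0.0
    for rid, tags in ORGAN_RESTRICTIONS.items():
        gpr = _R[rid][2]
        if not gpr:
            continue
        genes_r = [g for g in gpr.replace("(", " ").replace(")", " ").split()
                   if g not in ("and", "or")]
        for tag in tags:
            df.loc[genes_r, tag] = 0.9
    return df


# ---------------------------------------------------------------------------
# Microbes
# ---------------------------------------------------------------------------

def _microbe(strain_id: str, reactions: dict, biomass_precursors: dict,
             lumen_mets: Iterable[str], taxonomy: dict) -> MicrobeModel:
    m = StoichiometricModel(strain_id)
    m.compartments = {"c": "cytosol", "luLI": "Lumen, large intestine"}
    bases = {b for stoich in reactions.values() for (b, _c) in stoich} | \
            set(biomass_precursors) | {"atp", "adp", "pi", "h2o"}
    for base in sorted(bases):
        m.add_metabolite(_met(base, "c"))
    for base in lumen_mets:
        m.add_metabolite(_met(base, "luLI"))
        m.add_reaction(Reaction(f"t_{base}", {f"{base}[luLI]": -1.0,
                                              f"{base}[c]": 1.0},
                                -DEFAULT_BIG, DEFAULT_BIG))
    for rid, stoich in reactions.items():
        m.add_reaction(Reaction(rid, {f"{b}[c]": float(v)
                                      for (b, _comp), v in stoich.items()},
                                0.0, DEFAULT_BIG))
    m.add_metabolite(Metabolite("biomass[c]", "strain biomass", "c"))
    stoich = {f"{b}[c]": -float(v) for b, v in biomass_precursors.items()}
    stoich.update({"adp[c]": 20.0, "pi[c]": 20.0, "biomass[c]": 1.0})
    m.add_reaction(Reaction("BIOMASS", stoich, 0.0, DEFAULT_BIG))
    m.objective = {"BIOMASS": 1.0}
    return MicrobeModel(m, "BIOMASS", taxonomy)


def toy_microbes() -> list[MicrobeModel]:
    bio = {"glc_D": 0.1, "atp": 20.0, "h2o": 20.0}
    ferment = lambda prods: {("glc_D", "c"): -1, ("adp", "c"): -2,
                             ("pi", "c"): -2, ("atp", "c"): 2,
                             ("h2o", "c"): 2, **prods}
    return [
        _microbe("Faecalibacterium_toyii",
                 {"FERM_BUT": ferment({("but", "c"): 1, ("co2", "c"): 2,
                                       ("h2", "c"): 2})},
                 bio, ["glc_D", "but", "co2", "h2"],
                 {"phylum": "Firmicutes", "class": "Clostridia",
                  "genus": "Faecalibacterium", "species": "toyii"}),
        _microbe("Clostridium_toyense",
                 {"FERM_ETOH": ferment({("etoh", "c"): 2, ("co2", "c"): 2})},
                 bio, ["glc_D", "etoh", "co2"],
                 {"phylum": "Firmicutes", "class": "Clostridia",
                  "genus": "Clostridium", "species": "toyense"}),
        _microbe("Bacteroides_toyii",
                 {"FERM_LAC": ferment({("lac_L", "c"): 2}),
                  "GLUDC_m": {("glu_L", "c"): -1, ("gaba", "c"): 1,
                              ("co2", "c"): 1}},
                 bio, ["glc_D", "lac_L", "glu_L", "gaba", "co2"],
                 {"phylum": "Bacteroidetes", "class": "Bacteroidia",
                  "genus": "Bacteroides", "species": "toyii"}),
        _microbe("Clostridioides_toydifficile",
                 {"FERM_LAC": ferment({("lac_L", "c"): 2}),
                  "TYR2PCR": {("tyr_L", "c"): -1, ("h2o", "c"): -1,
                              ("pcresol", "c"): 1, ("nh3", "c"): 1,
                              ("co2", "c"): 1}},
                 bio, ["glc_D", "lac_L", "tyr_L", "pcresol", "nh3", "co2"],
                 {"phylum": "Firmicutes", "class": "Clostridia",
                  "genus": "Clostridioides", "species": "toydifficile"}),
    ]


def toy_taxonomy(microbes: Optional[list[MicrobeModel]] = None) -> dict:
    microbes = microbes if microbes is not None else toy_microbes()
    return {m.strain_id: dict(m.taxonomy) for m in microbes}

BUTYRATE_PRODUCER = "Faecalibacterium_toyii"


# ---------------------------------------------------------------------------
# The assembled toy body
# ---------------------------------------------------------------------------

@dataclass
class ToyBody:
    wbm: StoichiometricModel
    base: StoichiometricModel
    organs: list[OrganSpec]
    biofluid_map: BiofluidMap
    physiology: PhysiologyParameters
    plasma_panel: MetabolitePanel
    urine_panel: MetabolitePanel
    csf_panel: MetabolitePanel
    diet: DietSpec
    iem_catalog: list
    microbes: list[MicrobeModel]
    taxonomy: dict
    bbb_allowed: list[str]
    bbb_blocked: list[str]
    seed: int = 0
    variant: str = "default"

    def constrained_model(self, physiology: Optional[PhysiologyParameters] = None,
                          couple: bool = True) -> StoichiometricModel:
        """Copy of the WBM with the full PSCM stack applied."""
        model = self.wbm.copy(self.wbm.id + "_pscm")
        apply_pscm(model, physiology or self.physiology, self.plasma_panel,
                   self.urine_panel, self.csf_panel, self.diet, couple=couple)
        return model

    def with_microbiome(self, abundances: dict,
                        physiology: Optional[PhysiologyParameters] = None,
                        community_growth: float = 1.0) -> StoichiometricModel:
        """Microbiome-associated constrained WBM (myWBM)."""
        profile = normalize_abundances(
            abundances, [m.strain_id for m in self.microbes])
        community = build_community(self.microbes, profile)
        host = self.constrained_model(physiology)
        return attach_to_host(host, community, community_growth)


def _duplicate_for_redundancy(wbm: StoichiometricModel) -> None:
    """Add scaled parallel copies of the load-bearing reactions so that most
    single-reaction removals leave a backup route (the 'redundant' variant).
    Coefficients are doubled so the copies are not literal duplicates."""
    critical_bases = {"glc_D", "lac_L", "ala_L", "glu_L", "urea", "o2", "co2",
                      "h2o", "pi", "nh3"}
    critical_core = {"GLYCL", "GLUCONEO", "UREASYN", "GLUDEAM", "ALADEAM",
                     "ALASYN", "DM_atp_c_", "LACDHm", "ATPS4m", "ANTm",
                     "t_LACm", "t_O2m", "t_CO2m", "t_H2Om", "t_PIm"}
    to_copy = []
    for rxn in wbm.reactions:
        stem = rxn.id if not rxn.organ else rxn.id[len(rxn.organ):]
        if rxn.organ and (stem in critical_core or stem.startswith("biomass_")
                          or stem.startswith("t_") and stem[2:-1] in critical_bases):
            to_copy.append(rxn)
        elif stem.startswith(("TR_", "EX_", "Diet_EX_", "FILT_")):
            base = stem.split("[")[0].split("_", 2)[-1] if stem.startswith("TR_") \
                else stem.rsplit("[", 1)[0].split("EX_")[-1].replace("FILT_", "")
            if any(b in stem for b in critical_bases):
                to_copy.append(rxn)
        elif stem.startswith("PROTEOME") or stem.startswith("TRANSCRIPTOME"):
            to_copy.append(rxn)
        elif "EX_" in stem and any(f"EX_{b}[" in stem for b in critical_bases):
            to_copy.append(rxn)
    for rxn in to_copy:
        alt = Reaction(rxn.id + "_ALT",
                       {m: 2.0 * c for m, c in rxn.stoichiometry.items()},
                       rxn.lb, rxn.ub, rxn.gpr, rxn.subsystem, rxn.organ)
        wbm.add_reaction(alt)


_TOY_CACHE: dict = {}


def make_toy_body(seed: int = 0, variant: str = "default") -> ToyBody:
    """Assemble the toy whole-body model deterministically.

    variants: 'default'; 'fragile' (colon cannot absorb — less redundancy, for
    essentiality tests); 'redundant' (parallel copies of load-bearing
    reactions, for robustness tests).
    """
    if variant not in ("default", "fragile", "redundant"):
        raise ValueError(f"unknown variant {variant!r}")
    key = (seed, variant)
    if key not in _TOY_CACHE:
        _TOY_CACHE[key] = _build_toy_body(seed, variant)
    return _copy.deepcopy(_TOY_CACHE[key])


def _build_toy_body(seed: int, variant: str) -> ToyBody:
    base = toy_base_model()
    organs = toy_organs(variant)
    bmap = toy_biofluid_map()

    meta = replicate_base(base, organs, sex="both")
    # organ-restricted reactions: closed outside their organs
    for stem, allowed in ORGAN_RESTRICTIONS.items():
        for organ in organs:
            if organ.tag in allowed:
                continue
            rid = f"{organ.tag}{stem}"
            if meta.has_reaction(rid):
                rxn = meta.get_reaction(rid)
                rxn.lb = rxn.ub = 0.0

    wire_biofluids(meta, organs, bmap, BBB_ALLOWED, BBB_BLOCKED)
    for organ in organs:
        compose_biomass(organ, TOY_BIOMASS_TABLE, model=meta)
        if organ.tag in STORAGE_ORGANS:
            add_storage(meta, organ, STORAGE_ORGANS[organ.tag], phase="feeding")
    compose_whole_body_maintenance(
        meta, WholeBodyObjective({t: c for t, c in TOY_WB_COEFFICIENTS.items()
                                  if any(o.tag == t for o in organs)}))
    set_default_bounds(meta)

    # drop flux-inconsistent reactions (organ-restricted copies, RBC
    # mitochondria, dead ends) so the shipped model passes the QC suite
    removed = fastcc(meta).removed
    meta.remove_reactions(removed)
    meta.prune_unused_metabolites()

    if variant == "redundant":
        _duplicate_for_redundancy(meta)
    meta.id = f"toy_wbm_{variant}"
    meta.annotations["variant"] = variant
    meta.annotations["seed"] = seed
    snapshot_default_bounds(meta)

    microbes = toy_microbes()
    return ToyBody(
        wbm=meta, base=base, organs=organs, biofluid_map=bmap,
        physiology=toy_physiology(), plasma_panel=toy_plasma_panel(),
        urine_panel=toy_urine_panel(), csf_panel=toy_csf_panel(),
        diet=toy_diet(), iem_catalog=toy_iem_catalog(), microbes=microbes,
        taxonomy=toy_taxonomy(microbes), bbb_allowed=list(BBB_ALLOWED),
        bbb_blocked=list(BBB_BLOCKED), seed=seed, variant=variant)


def set_storage_phase(wbm: StoichiometricModel, phase: str) -> StoichiometricModel:
    """Switch organ storage between feeding (deposit) and fasting (release)."""
    if phase not in ("feeding", "fasting"):
        raise ValueError(f"unknown phase {phase!r}")
    for rxn in wbm.reactions:
        stem = rxn.id if not rxn.organ else rxn.id[len(rxn.organ):]
        if stem.startswith("sink_"):
            if phase == "feeding":
                rxn.lb, rxn.ub = 0.0, DEFAULT_BIG
            else:
                rxn.lb, rxn.ub = -DEFAULT_BIG, 0.0
    return wbm


# ---------------------------------------------------------------------------
# Synthetic cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortMember:
    member_id: str
    physiology: PhysiologyParameters
    abundances: dict[str, float]
    producer_abundance: float  # ground-truth butyrate-producer share


def make_toy_cohort(n: int, seed: int = 0) -> list[CohortMember]:
    """n synthetic individuals: physiology varied within realistic ranges and
    a Dirichlet strain-abundance profile over the four toy microbes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    strains = [m.strain_id for m in toy_microbes()]
    members = []
    for i in range(n):
        phys = toy_physiology(
            sex="female" if rng.random() < 0.5 else "male",
            body_weight=float(rng.uniform(55, 90)),
            height=float(rng.uniform(155, 190)),
            heart_rate=float(rng.uniform(60, 75)),
            stroke_volume=float(rng.uniform(65, 85)),
            hematocrit=float(rng.uniform(0.38, 0.48)),
        )
        ab = rng.dirichlet(np.full(len(strains), 2.0))
        abundances = {s: float(a) for s, a in zip(strains, ab)}
        members.append(CohortMember(
            f"toy{i:03d}", phys, abundances,
            abundances[BUTYRATE_PRODUCER]))
    return members


# ---------------------------------------------------------------------------
# Demo dataset writer (used by the CLI)
# ---------------------------------------------------------------------------

def write_dataset(toy: ToyBody, outdir) -> None:
    """Write the complete toy dataset as TSV/JSON/SBML files."""
    import json
    import os

    from .model import write_json, write_sbml, write_tsv

    os.makedirs(outdir, exist_ok=True)
    join = lambda name: os.path.join(outdir, name)

    write_json(toy.wbm, join("toy_wbm.json"))
    write_json(toy.base, join("toy_base.json"))
    write_tsv(toy.wbm, join("toy_wbm_reactions.tsv"), join("toy_wbm_metabolites.tsv"))
    try:
        write_sbml(toy.wbm, join("toy_wbm.xml"))
    except ImportError:
        pass

    pd.DataFrame([{
        "name": o.name, "tag": o.tag, "sex": o.sex,
        "weight_fraction": o.weight_fraction,
        "biomass_variant": o.biomass_variant,
        "organelles_absent": ";".join(o.organelles_absent),
        "biofluids": ";".join(f"{l.compartment}:{l.direction}" for l in o.biofluids),
    } for o in toy.organs]).to_csv(join("organs.tsv"), sep="\t", index=False)

    pd.DataFrame([{"code": c, "description": d}
                  for c, d in toy.biofluid_map.compartments]
                 ).to_csv(join("biofluids.tsv"), sep="\t", index=False)

    for panel, name in [(toy.plasma_panel, "plasma_panel.tsv"),
                        (toy.urine_panel, "urine_panel.tsv"),
                        (toy.csf_panel, "csf_panel.tsv")]:
        pd.DataFrame([{"metabolite": k, "conc_min": lo, "conc_max": hi}
                      for k, (lo, hi) in panel.items()]
                     ).to_csv(join(name), sep="\t", index=False)

    pd.DataFrame([{"metabolite": k, "intake": v}
                  for k, v in toy.diet.intakes.items()]
                 ).to_csv(join("diet.tsv"), sep="\t", index=False)

    phys = toy.physiology
    pd.DataFrame([
        {"parameter": "sex", "value": phys.sex},
        {"parameter": "body_weight_kg", "value": phys.body_weight},
        {"parameter": "height_cm", "value": phys.height},
        {"parameter": "heart_rate_per_min", "value": phys.heart_rate},
        {"parameter": "stroke_volume_ml", "value": phys.stroke_volume},
        {"parameter": "cardiac_output_ml_per_min", "value": phys.cardiac_output},
        {"parameter": "hematocrit", "value": phys.hematocrit},
        {"parameter": "gfr_fraction", "value": phys.gfr_fraction},
        {"parameter": "urine_volume_l_per_day", "value": phys.urine_volume},
        {"parameter": "csf_flow_l_per_day", "value": phys.csf_flow},
    ]).to_csv(join("physiology.tsv"), sep="\t", index=False)

    pd.DataFrame([{"iem": t.iem_id, "genes": ";".join(t.genes),
                   "biomarker": met, "biofluid": fluid, "expected": direction}
                  for t in toy.iem_catalog
                  for met, fluid, direction in t.biomarkers]
                 ).to_csv(join("iem_catalog.tsv"), sep="\t", index=False)

    for microbe in toy.microbes:
        write_json(microbe.model, join(f"microbe_{microbe.strain_id}.json"))
    pd.DataFrame([{"strain": s, **tax} for s, tax in toy.taxonomy.items()]
                 ).to_csv(join("taxonomy.tsv"), sep="\t", index=False)

    with open(join("bbb_lists.json"), "w") as fh:
        json.dump({"allowed": toy.bbb_allowed, "blocked": toy.bbb_blocked}, fh,
                  indent=1)
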