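"""assembly: organ replication, biofluid wiring, biomass, organ extraction."""

import pytest

from wholebody import (BIOFLUID_COMPARTMENTS, DEFAULT_BIG,
                       REFERENCE_BIOMASS_TABLE,
                       REFERENCE_WHOLE_BODY_COEFFICIENTS,
                       WHOLE_BODY_OBJECTIVE_ID, BiofluidLink, BiofluidMap,
                       Flow, Metabolite, OrganSpec, WholeBodyObjective,
                       add_storage, bbb_permits, compose_biomass,
                       compose_whole_body_maintenance, default_biofluid_map,
                       extract_organ_model, proteomics_to_core, replicate_base,
                       wire_biofluids)
from wholebody.fixtures import toy_base_model

import pandas as pd


def tiny_base():
    m = toy_base_model()
    return m


def two_organs():
    return [
        OrganSpec("liver", "Liver_", biofluids=[BiofluidLink("bc", "both"),
                                                BiofluidLink("bp", "uptake")]),
        OrganSpec("kidney", "Kidney_", biofluids=[
            BiofluidLink("bc", "both"),
            BiofluidLink("u", "filter", filter_source="bc")]),
    ]


# ---------------------------------------------------------------------------
# Replication
# ---------------------------------------------------------------------------

def test_replicate_base_counts_and_prefixes():
    base = tiny_base()
    meta = replicate_base(base, two_organs())
    assert len(meta.reactions) == 2 * len(base.reactions)
    assert meta.has_reaction("Liver_GLYCL")
    assert meta.has_metabolite("Kidney_glc_D[c]")
    assert meta.get_reaction("Liver_GLYCL").organ == "Liver_"
    assert meta.annotations["organ_tags"] == ["Liver_", "Kidney_"]


def test_replicate_base_closes_absent_organelles():
    base = tiny_base()
    organs = [OrganSpec("red blood cell", "RBC_",
                        biofluids=[BiofluidLink("bc", "both")],
                        organelles_absent=["m"])]
    meta = replicate_base(base, organs)
    r = meta.get_reaction("RBC_ATPS4m")
    assert r.lb == r.ub == 0.0
    assert meta.get_reaction("RBC_GLYCL").ub > 0


def test_replicate_base_sex_filter_and_duplicate_tags():
    base = tiny_base()
    organs = [OrganSpec("prostate", "Prostate_", sex="male",
                        biofluids=[BiofluidLink("bc", "both")])]
    meta = replicate_base(base, organs, sex="female")
    assert len(meta.reactions) == 0
    with pytest.raises(ValueError):
        replicate_base(base, [organs[0], organs[0]])


# ---------------------------------------------------------------------------
# Blood-brain barrier
# ---------------------------------------------------------------------------

def test_bbb_permits_rules():
    allowed, blocked = ["glc_D"], ["dopa"]
    small = Metabolite("x[bc]", molecular_weight=180.0)
    big = Metabolite("y[bc]", molecular_weight=600.0)
    unknown = Metabolite("z[bc]")
    assert bbb_permits(Metabolite("glc_D[bc]", molecular_weight=900.0),
                       allowed, blocked)          # allow-list beats the cutoff
    assert not bbb_permits(Metabolite("dopa[bc]", molecular_weight=153.0),
                           allowed, blocked)      # block-list beats the cutoff
    assert bbb_permits(small, allowed, blocked)   # < 500 Da passes
    assert not bbb_permits(big, allowed, blocked)  # >= 500 Da blocked
    assert bbb_permits(unknown, allowed, blocked)  # unknown mass: permissive
    with pytest.raises(ValueError):
        bbb_permits(Metabolite("glc_D[bc]"), ["glc_D"], ["glc_D"])
    # organ-prefixed base ids match the bare names
    assert not bbb_permits(Metabolite("Brain_dopa[e]", molecular_weight=153.0),
                           allowed, blocked)


# ---------------------------------------------------------------------------
# Biofluid wiring
# ---------------------------------------------------------------------------

def wired():
    base = tiny_base()
    organs = two_organs()
    meta = replicate_base(base, organs)
    bmap = BiofluidMap(
        flows=[Flow("d", "lu"), Flow("lu", "luSI"), Flow("luSI", "luLI"),
               Flow("luLI", "fe"), Flow("csf", "bc")],
        boundary={"d": "diet", "fe": "excretion", "u": "excretion", "a": "air"})
    wire_biofluids(meta, organs, bmap)
    return meta


def test_wire_biofluids_transport_naming_and_direction():
    meta = wired()
    both = meta.get_reaction("Liver_EX_glc_D[bc]_[e]")
    assert both.stoichiometry == {"glc_D[bc]": -1.0, "Liver_glc_D[e]": 1.0}
    assert (both.lb, both.ub) == (-DEFAULT_BIG, DEFAULT_BIG)
    uptake = meta.get_reaction("Liver_EX_glc_D[bp]_[e]")
    assert (uptake.lb, uptake.ub) == (0.0, DEFAULT_BIG)  # positive = uptake


def test_wire_biofluids_kidney_filtration():
    meta = wired()
    filt = meta.get_reaction("Kidney_FILT_glc_D")
    assert filt.stoichiometry == {"glc_D[bc]": -1.0, "glc_D[u]": 1.0}
    assert (filt.lb, filt.ub) == (0.0, DEFAULT_BIG)
    reab = meta.get_reaction("Kidney_EX_glc_D[u]_[e]")
    assert (reab.lb, reab.ub) == (0.0, DEFAULT_BIG)  # reabsorption only
    assert meta.has_reaction("EX_glc_D[u]")          # urinary excretion


def test_wire_biofluids_luminal_chain_and_boundaries():
    meta = wired()
    for src, dst in [("d", "lu"), ("lu", "luSI"), ("luSI", "luLI"),
                     ("luLI", "fe")]:
        r = meta.get_reaction(f"TR_glc_D_{src}_{dst}")
        assert r.lb == 0.0  # luminal flow is unidirectional
    diet = meta.get_reaction("Diet_EX_glc_D[d]")
    assert (diet.lb, diet.ub) == (-DEFAULT_BIG, 0.0)
    fecal = meta.get_reaction("EX_glc_D[fe]")
    assert (fecal.lb, fecal.ub) == (0.0, DEFAULT_BIG)


def test_wire_biofluids_bbb_filtering(toy):
    # the shipped toy brain is BBB-filtered: dopamine has no brain transport
    assert not toy.wbm.has_reaction("Brain_EX_dopa[bc]_[e]")
    assert toy.wbm.has_reaction("Brain_EX_glc_D[bc]_[e]")
    # dopamine still reaches the blood via CSF return and leaves in urine
    assert toy.wbm.has_reaction("TR_dopa_csf_bc")
    assert toy.wbm.has_reaction("Kidney_FILT_dopa")


def test_biofluid_map_validation():
    bmap = BiofluidMap(flows=[Flow("lu", "luSI"), Flow("luSI", "lu")])
    with pytest.raises(ValueError):
        bmap.validate()
    with pytest.raises(ValueError):
        BiofluidMap(flows=[Flow("d", "nowhere")]).validate()
    default_biofluid_map().validate()  # the canonical anatomy is valid
    assert [c for c, _ in BIOFLUID_COMPARTMENTS] == [
        "d", "lu", "luSI", "luLI", "fe", "bc", "bp", "bd", "csf", "u",
        "sw", "mi", "a"]


# ---------------------------------------------------------------------------
# Biomass and the whole-body maintenance reaction
# ---------------------------------------------------------------------------

def test_compose_biomass_matches_reference_table():
    organ = OrganSpec("liver", "Liver_", biomass_variant="maintenance")
    rxns = compose_biomass(organ)  # no model: return the reactions only
    main = next(r for r in rxns if r.id == "Liver_biomass_maintenance")
    ref = REFERENCE_BIOMASS_TABLE["maintenance"]
    assert main.stoichiometry["Liver_atp[c]"] == ref["atp"] == -20.7045
    assert main.stoichiometry["Liver_h2o[c]"] == -20.6508
    assert main.stoichiometry[
        "Liver_biomass_maintenance_dummy_objective[c]"] == 1.0
    degr = next(r for r in rxns if r.id == "Liver_TRANSCRIPTOME_DEGRx")
    assert degr.stoichiometry["Liver_amp[c]"] == pytest.approx(0.053446)


def test_compose_biomass_notrtr_has_no_amino_acids():
    organ = OrganSpec("red blood cell", "RBC_", biomass_variant="noTrTr")
    rxns = compose_biomass(organ)
    main = next(r for r in rxns if "biomass" in r.id)
    assert not any("ala_L" in m or "proteome" in m or "transcriptome" in m
                   for m in main.stoichiometry)
    # without proteome/transcriptome products their degradation reactions are
    # omitted; the lipid membrane is still turned over
    ids = {r.id for r in rxns}
    assert "RBC_PROTEOME_DEGRx" not in ids
    assert "RBC_TRANSCRIPTOME_DEGRx" not in ids
    assert "RBC_LIPID_DEGRx" in ids


def test_compose_biomass_missing_precursor_raises():
    model = toy_base_model()
    organ = OrganSpec("liver", "Liver_", biomass_variant="maintenance")
    with pytest.raises(KeyError):
        # the toy base lacks the reference lipids (pail_hs etc.)
        compose_biomass(organ, REFERENCE_BIOMASS_TABLE, model=model)


def test_whole_body_maintenance_reaction(toy):
    maint = toy.wbm.get_reaction(WHOLE_BODY_OBJECTIVE_ID)
    assert toy.wbm.objective == {WHOLE_BODY_OBJECTIVE_ID: 1.0}
    assert maint.stoichiometry[
        "Muscle_biomass_maintenance_dummy_objective[c]"] == -40.0
    assert maint.stoichiometry[
        "Brain_biomass_maintenance_dummy_objective[c]"] == -2.0
    # reference coefficients carry the printed values
    assert REFERENCE_WHOLE_BODY_COEFFICIENTS["Muscle_"] == 40.0
    assert REFERENCE_WHOLE_BODY_COEFFICIENTS["Adipocytes_"] == 21.4286


def test_whole_body_objective_validation():
    with pytest.raises(ValueError):
        WholeBodyObjective({"Liver_": 0.0})
    m = toy_base_model()
    with pytest.raises(KeyError):
        compose_whole_body_maintenance(m, WholeBodyObjective({"Liver_": 1.0}))


# ---------------------------------------------------------------------------
# Storage
# ---------------------------------------------------------------------------

def test_add_storage_phases():
    base = tiny_base()
    organs = two_organs()
    meta = replicate_base(base, organs)
    add_storage(meta, organs[0], ["glycogen"], phase="feeding")
    r = meta.get_reaction("Liver_sink_glycogen[c]")
    assert (r.lb, r.ub) == (0.0, DEFAULT_BIG)
    add_storage(meta, organs[0], ["glycogen"], phase="fasting")
    assert (r.lb, r.ub) == (-DEFAULT_BIG, 0.0)
    with pytest.raises(ValueError):
        add_storage(meta, organs[0], ["glycogen"], phase="lunch")
    with pytest.raises(KeyError):
        add_storage(meta, organs[0], ["unobtainium"])


# ---------------------------------------------------------------------------
# Proteomics -> core
# ---------------------------------------------------------------------------

def test_proteomics_to_core_threshold_and_relaxed_complexes():
    expr = pd.DataFrame({"Liver_": [1.0, 0.1, 0.5],
                         "Brain_": [0.1, 0.1, 0.9]},
                        index=["gA", "gB", "gC"])
    gprs = {"R_complex": "gA and gB",  # complex: one subunit suffices
            "R_iso": "gB or gC",
            "R_single": "gB"}
    core = proteomics_to_core(expr, gprs, threshold=0.2)
    assert core["Liver_"] == {"R_complex", "R_iso"}
    assert core["Brain_"] == {"R_iso"}
    with pytest.raises(ValueError):
        proteomics_to_core(expr - 0.5, gprs)


def test_proteomics_to_core_rescales_by_table_maximum():
    expr = pd.DataFrame({"Liver_": [10.0, 1.0]}, index=["gA", "gB"])
    core = proteomics_to_core(expr, {"RA": "gA", "RB": "gB"}, threshold=0.2)
    # scaled: gA = 1.0, gB = 0.1 -> only gA passes
    assert core["Liver_"] == {"RA"}


# ---------------------------------------------------------------------------
# Organ extraction
# ---------------------------------------------------------------------------

def test_extract_organ_model_converts_transports(toy):
    liver = extract_organ_model(toy.wbm, "Liver_")
    # every metabolite is liver-owned; no biofluid metabolites remain
    assert all(m.base_id.startswith("Liver_") for m in liver.metabolites)
    ex = liver.get_reaction("Liver_EX_glc_D[bc]_[e]")
    assert ex.stoichiometry == {"Liver_glc_D[e]": -1.0}
    # flipped: negative flux = uptake (standard exchange convention)
    assert (ex.lb, ex.ub) == (-DEFAULT_BIG, DEFAULT_BIG)
    assert liver.objective  # organ BOF registered
    with pytest.raises(KeyError):
        extract_organ_model(toy.wbm, "Spleen_")


def test_extract_organ_model_drops_pure_fluid_reactions(toy):
    kidney = extract_organ_model(toy.wbm, "Kidney_")
    assert not any(r.id.startswith("Kidney_FILT_") for r in kidney.reactions)
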