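"""model: GPR logic, containers, validation, serialization round-trips."""

import json

import pytest
from hypothesis import given, strategies as st

import wholebody as wb
from wholebody import (DEFAULT_BIG, GprExpression, Metabolite, Reaction,
                       StoichiometricModel, evaluate_gpr,
                       knock_out_genes, reactions_lost_by_gene_deletion,
                       read_json, read_sbml, read_tsv, set_default_bounds,
                       split_met_id, validate_model, write_json, write_sbml,
                       write_tsv)

from _builders import linear_chain, model_from

GENES = [f"g{i}" for i in range(6)]


# ---------------------------------------------------------------------------
# GPR expressions (property test against a reference evaluator)
# ---------------------------------------------------------------------------

def _render(node):
    if isinstance(node, str):
        return node
    op, kids = node
    return "(" + f" {op} ".join(_render(k) for k in kids) + ")"


def _reference_eval(node, present, relax=False):
    if isinstance(node, str):
        return node in present
    op, kids = node
    vals = [_reference_eval(k, present, relax) for k in kids]
    if op == "or" or relax:
        return any(vals)
    return all(vals)


gpr_trees = st.recursive(
    st.sampled_from(GENES),
    lambda children: st.tuples(st.sampled_from(["and", "or"]),
                               st.lists(children, min_size=2, max_size=3)),
    max_leaves=8)


@given(tree=gpr_trees, present=st.sets(st.sampled_from(GENES)),
       relax=st.booleans())
def test_gpr_evaluate_matches_reference(tree, present, relax):
    text = _render(tree)
    parsed = GprExpression.parse(text)
    assert parsed.evaluate(present, relax_and_to_or=relax) == \
        _reference_eval(tree, present, relax)
    # canonical string form parses back to an equivalent tree
    again = GprExpression.parse(str(parsed))
    assert again.evaluate(present, relax_and_to_or=relax) == \
        parsed.evaluate(present, relax_and_to_or=relax)


@given(tree=gpr_trees)
def test_gpr_genes_is_leaf_set(tree):
    def leaves(node):
        if isinstance(node, str):
            return {node}
        out = set()
        for k in node[1]:
            out |= leaves(k)
        return out
    assert GprExpression.parse(_render(tree)).genes() == leaves(tree)


@pytest.mark.parametrize("bad", ["", "and and", "g1 or", "(g1 and g2",
                                 "g1 g2", "g1 and (or g2)"])
def test_gpr_malformed_raises(bad):
    with pytest.raises(ValueError):
        GprExpression.parse(bad)


def test_gpr_case_insensitive_keywords_and_wrapper():
    assert evaluate_gpr("g1 AND g2", {"g1", "g2"})
    assert not evaluate_gpr("g1 AND g2", {"g1"})
    assert evaluate_gpr("g1 AND g2", {"g1"}, relax_and_to_or=True)
    assert evaluate_gpr("g1 OR g2", {"g2"})


# ---------------------------------------------------------------------------
# Identifiers, metabolites, reactions
# ---------------------------------------------------------------------------

def test_split_met_id():
    assert split_met_id("glc_D[bc]") == ("glc_D", "bc")
    assert split_met_id("Liver_glc_D[c]") == ("Liver_glc_D", "c")
    with pytest.raises(ValueError):
        split_met_id("glc_D")


def test_metabolite_base_id_and_compartment_inference():
    m = Metabolite("Liver_atp[c]")
    assert m.compartment == "c"
    assert m.base_id == "Liver_atp"


@pytest.mark.parametrize("rid,organ,kind", [
    ("EX_glc_D[u]", None, "exchange"),
    ("Diet_EX_glc_D[d]", None, "exchange"),
    ("Liver_DM_atp_c_", "Liver_", "demand"),
    ("Liver_sink_glycogen[c]", "Liver_", "sink"),
    ("MAKE_b", None, "exchange"),  # bare single-metabolite reaction
])
def test_boundary_kind(rid, organ, kind):
    r = Reaction(rid, {"a[c]": -1.0}, 0.0, 1.0, organ=organ)
    assert r.is_boundary
    assert r.boundary_kind == kind


def test_non_boundary_reaction_has_no_kind():
    r = Reaction("R1", {"a[c]": -1.0, "b[c]": 1.0})
    assert not r.is_boundary
    assert r.boundary_kind is None


def test_reversibility_is_bounds_only():
    assert Reaction("R", {"a[c]": -1.0}, -1.0, 1.0).reversible
    assert not Reaction("R", {"a[c]": -1.0}, 0.0, 1.0).reversible


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

def test_duplicate_ids_rejected():
    m = StoichiometricModel()
    m.add_metabolite(Metabolite("a[c]"))
    with pytest.raises(ValueError):
        m.add_metabolite(Metabolite("a[c]"))
    m.add_reaction(Reaction("R1", {"a[c]": -1.0}))
    with pytest.raises(ValueError):
        m.add_reaction(Reaction("R1", {"a[c]": 1.0}))


def test_s_matrix_layout():
    m = linear_chain(2)
    S = m.S.toarray()
    assert S.shape == (3, 4)  # A0..A2 x (EX_in, R0, R1, EX_out)
    i = {mid: k for k, mid in enumerate(m.metabolite_ids)}
    j = {rid: k for k, rid in enumerate(m.reaction_ids)}
    assert S[i["A0[c]"], j["EX_in"]] == -1.0
    assert S[i["A0[c]"], j["R0"]] == -1.0
    assert S[i["A1[c]"], j["R0"]] == 1.0
    assert S[i["A2[c]"], j["EX_out"]] == -1.0


def test_remove_reactions_cleans_objective_and_coupling():
    m = linear_chain(2)
    m.objective = {"R0": 1.0}
    m.coupling.append(wb.CouplingConstraint("R1", "R0", 10.0))
    m.remove_reactions(["R0"])
    assert not m.has_reaction("R0")
    assert m.objective == {}
    assert m.coupling == []


def test_copy_is_deep():
    m = linear_chain(2)
    m.annotations["tag"] = {"x": 1}
    c = m.copy("copy")
    c.get_reaction("R0").ub = 5.0
    c.annotations["tag"]["x"] = 2
    assert m.get_reaction("R0").ub == DEFAULT_BIG
    assert m.annotations["tag"]["x"] == 1


def test_genes_union_of_gprs_and_declared():
    m = linear_chain(1)
    m.get_reaction("R0").gpr = "gA and gB"
    m.annotations["genes"] = ["gC"]
    assert m.genes == {"gA", "gB", "gC"}


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def test_validate_clean_model_ok(toy):
    assert validate_model(toy.wbm).ok
    assert validate_model(toy.base).ok


def test_validate_reports_violations():
    m = StoichiometricModel("bad")
    m.add_metabolite(Metabolite("a[c]"))
    m.add_reaction(Reaction("R1", {"a[c]": -1.0, "ghost[c]": 1.0}, 2.0, 1.0,
                            gpr="and and"))
    m.add_reaction(Reaction("R2", {}))
    m.objective = {"missing": 1.0}
    m.coupling.append(wb.CouplingConstraint("nope", "R1", -5.0))
    codes = validate_model(m).codes()
    assert {"bounds inverted", "empty stoichiometry",
            "dangling metabolite reference", "malformed GPR",
            "objective on missing reaction", "dangling coupling reaction",
            "non-positive coupling factor"} <= codes


def test_validate_duplicate_reaction_id():
    m = linear_chain(1)
    m.reactions.append(m.get_reaction("R0").copy())  # bypass add_reaction guard
    assert "duplicate reaction id" in validate_model(m).codes()


def test_set_default_bounds():
    m = model_from({"R1": ({"a[c]": -1.0, "b[c]": 1.0}, -float("inf"), float("inf")),
                    "R2": ({"a[c]": -1.0, "b[c]": 1.0}, 0.0, 2e7),
                    "R3": ({"a[c]": -1.0, "b[c]": 1.0}, 0.0, 5.0)})
    set_default_bounds(m)
    assert (m.get_reaction("R1").lb, m.get_reaction("R1").ub) == (-DEFAULT_BIG, DEFAULT_BIG)
    assert (m.get_reaction("R2").lb, m.get_reaction("R2").ub) == (0.0, DEFAULT_BIG)
    assert m.get_reaction("R3").ub == 5.0
    with pytest.raises(ValueError):
        set_default_bounds(m, big=-1.0)


# ---------------------------------------------------------------------------
# Gene deletion
# ---------------------------------------------------------------------------

def test_gene_deletion_complex_and_isozyme(toy):
    base = toy.base
    # complex: losing one subunit kills the reaction
    assert "GLYCL" in reactions_lost_by_gene_deletion(base, {"TOY_GCK"})
    # isozyme: one of two OR-ed genes is not enough to kill it
    assert "ALCD2if" not in reactions_lost_by_gene_deletion(base, {"TOY_ADH1B"})
    assert "ALCD2if" in reactions_lost_by_gene_deletion(
        base, {"TOY_ADH1B", "TOY_ADH1C"})
    assert reactions_lost_by_gene_deletion(base, set()) == set()


def test_knock_out_genes_closes_reactions(toy):
    m = toy.base.copy()
    lost = knock_out_genes(m, {"TOY_PAH"})
    assert lost == {"PHETHL"}
    r = m.get_reaction("PHETHL")
    assert r.lb == r.ub == 0.0


# ---------------------------------------------------------------------------
# Serialization round-trips
# ---------------------------------------------------------------------------

def test_json_roundtrip_exact(tmp_path, constrained):
    path = tmp_path / "wbm.json"
    write_json(constrained, path)
    back = read_json(path)
    assert back.to_dict() == constrained.to_dict()


def test_tsv_roundtrip(tmp_path, toy):
    rp, mp = tmp_path / "rxns.tsv", tmp_path / "mets.tsv"
    write_tsv(toy.wbm, rp, mp)
    back = read_tsv(rp, mp, model_id=toy.wbm.id)
    assert back.reaction_ids == toy.wbm.reaction_ids
    assert back.metabolite_ids == toy.wbm.metabolite_ids
    for rid in back.reaction_ids:
        a, b = back.get_reaction(rid), toy.wbm.get_reaction(rid)
        assert a.stoichiometry == b.stoichiometry
        assert (a.lb, a.ub, a.gpr, a.organ) == (b.lb, b.ub, b.gpr, b.organ)


def test_sbml_roundtrip_with_sidecar(tmp_path, constrained):
    path = tmp_path / "wbm.xml"
    write_sbml(constrained, path)
    assert (tmp_path / "wbm.xml.sidecar.json").exists()
    back = read_sbml(path)
    assert set(back.reaction_ids) == set(constrained.reaction_ids)
    assert set(back.metabolite_ids) == set(constrained.metabolite_ids)
    for rid in constrained.reaction_ids:
        a, b = back.get_reaction(rid), constrained.get_reaction(rid)
        assert a.stoichiometry == pytest.approx(b.stoichiometry)
        # SBML stores bounds as decimal text; allow print/parse rounding
        assert a.lb == pytest.approx(b.lb, rel=1e-9, abs=1e-9)
        assert a.ub == pytest.approx(b.ub, rel=1e-9, abs=1e-9)
        assert a.organ == b.organ
    # coupling constraints survive via the sidecar
    orig = {(c.coupled_reaction, c.anchor_reaction, c.factor)
            for c in constrained.coupling}
    assert {(c.coupled_reaction, c.anchor_reaction, c.factor)
            for c in back.coupling} == orig
    assert len(orig) > 0
    assert back.objective == constrained.objective


def test_sbml_roundtrip_preserves_gprs(tmp_path, toy):
    path = tmp_path / "base.xml"
    write_sbml(toy.base, path)
    back = read_sbml(path)
    for rid in toy.base.reaction_ids:
        orig = toy.base.get_reaction(rid).gpr
        got = back.get_reaction(rid).gpr
        if orig is None:
            assert got is None
        else:
            genes = GprExpression.parse(orig).genes()
            # logical equivalence over all subsets is overkill; compare on
            # the full set and on each single-gene set
            for present in [genes] + [genes - {g} for g in genes]:
                assert evaluate_gpr(got, present) == evaluate_gpr(orig, present)
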