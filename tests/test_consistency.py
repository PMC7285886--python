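"""consistency: fastcc/fastcore vs FVA oracles, leak test, ATP yield, QC."""

import warnings

import numpy as np
import pytest

from wholebody import (CoreReactionSet, DEFAULT_BIG, Reaction, atp_yield,
                       build_wbm_draft, extract_organ_model, extract_submodel,
                       fastcc, fastcore, leak_test, proteomics_to_core,
                       sanity_suite)
from wholebody.fixtures import toy_expression

from _builders import (fva_consistency_partition, linear_chain, model_from,
                       random_consistent_toy, random_toy,
                       sanity_counterexamples)

EPS = 1e-4


# ---------------------------------------------------------------------------
# fastcc
# ---------------------------------------------------------------------------

def test_fastcc_hand_case_dead_end():
    m = linear_chain(2)
    m.add_metabolite(type(m.metabolites[0])("DEADEND[c]"))
    m.add_reaction(Reaction("DEAD", {"A0[c]": -1.0, "DEADEND[c]": 1.0},
                            0.0, DEFAULT_BIG))
    res = fastcc(m, EPS)
    assert res.removed == {"DEAD"}
    assert res.consistent == set(m.reaction_ids) - {"DEAD"}


def test_fastcc_reversible_only_cycle():
    """An internal reversible loop is flux-consistent even with no exchange."""
    m = model_from({"F": ({"a[c]": -1.0, "b[c]": 1.0}, -10.0, 10.0),
                    "B": ({"b[c]": -1.0, "a[c]": 1.0}, -10.0, 10.0)})
    assert fastcc(m, EPS).removed == set()


def test_fastcc_matches_fva_partition_battery():
    rng = np.random.default_rng(2024)
    for _ in range(30):
        m = random_toy(rng)
        assert fastcc(m, EPS).consistent == \
            fva_consistency_partition(m, tol=0.99 * EPS)


def test_fastcc_epsilon_validation():
    with pytest.raises(ValueError):
        fastcc(linear_chain(1), 0.0)


# ---------------------------------------------------------------------------
# fastcore
# ---------------------------------------------------------------------------

def test_fastcore_contains_core_and_is_consistent():
    rng = np.random.default_rng(7)
    for _ in range(10):
        m = random_consistent_toy(rng)
        cons = sorted(fastcc(m, EPS).consistent)
        core = set(rng.choice(cons, size=2, replace=False))
        out = fastcore(m, core, EPS)
        assert core <= out
        sub = extract_submodel(m, out)
        # the extracted subnetwork keeps every core reaction flux-consistent
        assert core <= fastcc(sub, EPS).consistent


def test_fastcore_idempotent():
    rng = np.random.default_rng(11)
    m = random_consistent_toy(rng)
    core = {"EX_in", "EX_out"}
    out = fastcore(m, core, EPS)
    again = fastcore(extract_submodel(m, out), core, EPS)
    assert again <= out


def test_fastcore_accepts_core_reaction_set_type():
    m = linear_chain(2)
    out = fastcore(m, CoreReactionSet({"R1"}, {"R1": "proteomics"}), EPS)
    assert "R1" in out


def test_fastcore_core_validation():
    m = linear_chain(2)
    with pytest.raises(ValueError):
        fastcore(m, set(), EPS)
    with pytest.raises(KeyError):
        fastcore(m, {"NOPE"}, EPS)


def test_fastcore_inconsistent_core_policies():
    m = linear_chain(2)
    m.add_metabolite(type(m.metabolites[0])("DEADEND[c]"))
    m.add_reaction(Reaction("DEAD", {"A0[c]": -1.0, "DEADEND[c]": 1.0},
                            0.0, DEFAULT_BIG))
    with pytest.raises(ValueError):
        fastcore(m, {"DEAD", "R1"}, EPS, on_inconsistent_core="raise")
    with pytest.warns(UserWarning):
        out = fastcore(m, {"DEAD", "R1"}, EPS, on_inconsistent_core="warn")
    assert "R1" in out and "DEAD" not in out
    out = fastcore(m, {"DEAD", "R1"}, EPS, on_inconsistent_core="drop")
    assert "R1" in out and "DEAD" not in out


def test_extract_submodel_prunes_metabolites():
    m = linear_chain(3)
    sub = extract_submodel(m, {"EX_in", "R0"})
    assert set(sub.reaction_ids) == {"EX_in", "R0"}
    assert set(sub.metabolite_ids) == {"A0[c]", "A1[c]"}


# ---------------------------------------------------------------------------
# Leak test
# ---------------------------------------------------------------------------

def test_leak_test_negative_on_clean_chain():
    assert leak_test(linear_chain(3)) == []


def test_leak_test_positive_and_exclusions():
    ces = sanity_counterexamples()
    assert leak_test(ces[1]) == ["b[c]"]
    assert leak_test(ces[1], exclude=["b"]) == []


def test_leak_test_open_mets_matter():
    ce2 = sanity_counterexamples()[2]
    assert leak_test(ce2) == []                       # closed: no leak
    assert leak_test(ce2, open_mets=["h2o"]) == ["b[c]"]


def test_leak_test_keep_bounds_preserves_reversible_demand():
    ce4 = sanity_counterexamples()[4]
    work = ce4.copy()
    work.get_reaction("DM_atp").lb = -DEFAULT_BIG
    excl = ["atp", "adp", "pi", "h2o", "h", "amp"]
    assert leak_test(work, exclude=excl) == []  # demand clamped: no leak
    assert leak_test(work, exclude=excl, keep_bounds=["DM_atp"]) == ["b[c]"]


# ---------------------------------------------------------------------------
# ATP yield (the toy organs are engineered to 31 aerobic / 2 anaerobic)
# ---------------------------------------------------------------------------

def test_atp_yield_liver(toy):
    liver = extract_organ_model(toy.wbm, "Liver_")
    assert atp_yield(liver, "glc_D", aerobic=True) == pytest.approx(31.0, abs=1e-6)
    assert atp_yield(liver, "glc_D", aerobic=False) == pytest.approx(2.0, abs=1e-6)


def test_atp_yield_rbc_lacks_mitochondria(toy):
    rbc = extract_organ_model(toy.wbm, "RBC_")
    assert atp_yield(rbc, "glc_D", aerobic=True) == pytest.approx(2.0, abs=1e-6)


def test_atp_yield_unknown_source(toy):
    liver = extract_organ_model(toy.wbm, "Liver_")
    with pytest.raises(KeyError):
        atp_yield(liver, "unobtainium")


# ---------------------------------------------------------------------------
# Sanity suite plumbing (full criterion-9 coverage is in test_acceptance)
# ---------------------------------------------------------------------------

def test_sanity_report_shape(toy):
    report = sanity_suite(toy.base.copy())
    assert len(report.results) == 16
    assert [r.number for r in report.results] == list(range(1, 17))
    assert report.failed() == [r for r in report.results if not r.passed]


# ---------------------------------------------------------------------------
# Draft extraction from proteomic core evidence
# ---------------------------------------------------------------------------

def test_build_wbm_draft_from_proteomics(toy):
    core_by_organ = proteomics_to_core(toy_expression(), toy.wbm)
    core_ids = set()
    for organ, rids in core_by_organ.items():
        core_ids |= {rid for rid in rids
                     if rid.startswith(organ) and toy.wbm.has_reaction(rid)}
    assert core_ids
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draft = build_wbm_draft(toy.wbm, CoreReactionSet(core_ids))
    report = draft.annotations["draft_report"]
    assert set(report["scenarios"]) == {"feeding", "fasting"}
    assert report["unserved_biofluid_metabolites"] == []
    assert len(draft.reactions) < len(toy.wbm.reactions)
    assert set(draft.reaction_ids) <= set(toy.wbm.reaction_ids)
    # the draft retains a substantial part of the evidence-backed core
    assert len(core_ids & set(draft.reaction_ids)) > 0.5 * len(core_ids)
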