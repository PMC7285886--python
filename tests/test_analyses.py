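"""analyses: energy arithmetic, IEM predictions, kappa oracles, cycles."""

import numpy as np
import pytest

from wholebody import (EnergyConstants, IemTask, activity_energy_budget,
                       agreement_stats, atp_consumption_by_reaction,
                       atp_grams_to_moles, atp_mmol_to_kcal, cycle_activation,
                       fba, glucose_to_atp_moles, organ_essentiality,
                       predict_bmr, random_removal_robustness, simulate_iem)
from wholebody.fixtures import toy_iem_catalog

from _builders import model_from


def _iem(iem_id):
    return next(t for t in toy_iem_catalog() if t.iem_id == iem_id)


# ---------------------------------------------------------------------------
# Energy arithmetic (pure unit conversions, checked by hand)
# ---------------------------------------------------------------------------

def test_glucose_to_atp_moles_exact():
    # 120 g/day / 180.16 g/mol x 31 ATP/glucose
    assert glucose_to_atp_moles(120.0) == pytest.approx(120.0 / 180.16 * 31.0)
    assert glucose_to_atp_moles(0.0) == 0.0
    with pytest.raises(ValueError):
        glucose_to_atp_moles(-1.0)


def test_atp_grams_to_moles_exact():
    assert atp_grams_to_moles(6000.0) == pytest.approx(6000.0 / 507.18)
    with pytest.raises(ValueError):
        atp_grams_to_moles(-1.0)


def test_atp_mmol_to_kcal_exact():
    # 1000 mmol = 1 mol -> 64 kJ -> 64/4.184 kcal
    assert atp_mmol_to_kcal(1000.0) == pytest.approx(64.0 / 4.184)
    c = EnergyConstants()
    assert c.atp_hydrolysis_kj_per_mol == 64.0
    assert c.atp_per_glucose == 31.0


# ---------------------------------------------------------------------------
# Agreement statistics against statsmodels / sklearn
# ---------------------------------------------------------------------------

def test_agreement_stats_hand_case():
    pred = ["increased", "increased", "decreased", "inconclusive"]
    obs = ["increased", "decreased", "decreased", "inconclusive"]
    out = agreement_stats(pred, obs)
    assert out["n"] == 4
    assert out["percent_agreement"] == pytest.approx(75.0)
    # hand kappa: p_o = 3/4; p_e = (2*1 + 1*2 + 1*1)/16 = 5/16
    p_o, p_e = 0.75, 5.0 / 16.0
    assert out["cohens_kappa"] == pytest.approx((p_o - p_e) / (1 - p_e))
    lo, hi = out["kappa_ci"]
    assert lo <= out["cohens_kappa"] <= hi


def test_agreement_stats_matches_library_oracles():
    from sklearn.metrics import cohen_kappa_score
    from statsmodels.stats.inter_rater import cohens_kappa

    cats = ("increased", "inconclusive", "decreased")
    rng = np.random.default_rng(42)
    for _ in range(5):
        pred = list(rng.choice(cats, size=40))
        obs = list(rng.choice(cats, size=40))
        ours = agreement_stats(pred, obs)
        assert ours["cohens_kappa"] == pytest.approx(
            cohen_kappa_score(pred, obs, labels=list(cats)), abs=1e-12)
        table = np.zeros((3, 3))
        idx = {c: i for i, c in enumerate(cats)}
        for p, o in zip(pred, obs):
            table[idx[p], idx[o]] += 1
        sm = cohens_kappa(table, return_results=True)
        assert ours["cohens_kappa"] == pytest.approx(sm.kappa, abs=1e-12)


def test_agreement_stats_edge_cases():
    with pytest.raises(ValueError):
        agreement_stats([], [])
    with pytest.raises(ValueError):
        agreement_stats(["increased"], [])
    perfect = agreement_stats(["increased"] * 3 + ["decreased"] * 3,
                              ["increased"] * 3 + ["decreased"] * 3)
    assert perfect["cohens_kappa"] == pytest.approx(1.0)
    assert perfect["percent_agreement"] == pytest.approx(100.0)
    # degenerate: everyone says the same thing -> p_e = 1
    same = agreement_stats(["increased"] * 4, ["increased"] * 4)
    assert same["percent_agreement"] == pytest.approx(100.0)
    assert same["cohens_kappa"] in (0.0, 1.0)


# ---------------------------------------------------------------------------
# Organ essentiality
# ---------------------------------------------------------------------------

def test_organ_essentiality(constrained):
    assert organ_essentiality(constrained, "Liver_") == "essential"
    assert organ_essentiality(constrained, "Muscle_") == "non_essential"
    with pytest.raises(KeyError):
        organ_essentiality(constrained, "Spleen_")


def test_fragile_variant_makes_siec_essential(toy_fragile):
    frag = toy_fragile.constrained_model()
    assert organ_essentiality(frag, "sIEC_") == "essential"


# ---------------------------------------------------------------------------
# Inborn errors of metabolism
# ---------------------------------------------------------------------------

def test_simulate_iem_pku(constrained):
    task = _iem("PKU_toy")
    preds = simulate_iem(constrained, task)
    assert len(preds) == len(task.biomarkers)
    calls = {(p.metabolite, p.biofluid): p.call for p in preds}
    assert calls[("phe_L", "bc")] == "increased"
    assert calls[("tyr_L", "bc")] == "decreased"
    for p, (met, fluid, expected) in zip(preds, task.biomarkers):
        assert (p.metabolite, p.biofluid) == (met, fluid)
        assert p.call == expected


def test_simulate_iem_isozyme_control_inconclusive(constrained):
    """Knocking out one of two redundant alcohol dehydrogenase genes leaves
    the reaction intact, so no biomarker should move."""
    task = _iem("ADH_isozyme_control")
    preds = simulate_iem(constrained, task)
    assert all(p.call == "inconclusive" for p in preds)
    assert all(np.isnan(p.disease_max) for p in preds)


def test_simulate_iem_gad_csf(constrained):
    task = _iem("GAD_deficiency_toy")
    preds = simulate_iem(constrained, task)
    assert preds[0].biofluid == "csf"
    assert preds[0].call == "decreased"


def test_simulate_iem_unknown_genes(constrained):
    task = IemTask("bogus", ["NOT_A_GENE"], [("phe_L", "bc", "increased")])
    with pytest.raises(KeyError):
        simulate_iem(constrained, task)


# ---------------------------------------------------------------------------
# Energy budgets
# ---------------------------------------------------------------------------

def test_predict_bmr(constrained):
    bmr = predict_bmr(constrained, "Whole_body_objective_rxn")
    assert bmr == pytest.approx(25.606063, rel=1e-4)
    bmr2, details = predict_bmr(constrained, "Whole_body_objective_rxn",
                                return_details=True)
    assert bmr2 == pytest.approx(bmr)
    assert details["total_atp_mmol_per_day"] == pytest.approx(
        bmr * 4.184 / 64.0 * 1000.0, rel=1e-6)
    assert details["solution"].optimal


def test_activity_energy_budget(constrained):
    out = activity_energy_budget(constrained)
    assert out == pytest.approx(198.71, rel=1e-3)
    with pytest.raises(KeyError):
        activity_energy_budget(constrained,
                               organ_demands={"Spleen_DM_atp_c_": 100.0})


def test_atp_consumption_by_reaction():
    m = model_from({
        "EX_atp": ({"atp[c]": -1.0}, -10.0, 10.0),
        "USE1": ({"atp[c]": -1.0, "adp[c]": 1.0}, 0.0, 10.0),
        "DM_adp": ({"adp[c]": -1.0}, 0.0, 10.0),
    })
    sol = fba(m, {"USE1": 1.0}, "max")
    series = atp_consumption_by_reaction(m, sol.fluxes)
    assert series["USE1"] == pytest.approx(10.0)
    assert "DM_adp" not in series.index


# ---------------------------------------------------------------------------
# Inter-organ cycles
# ---------------------------------------------------------------------------

def test_cori_cycle_activation(constrained):
    out = cycle_activation(constrained, muscle_glucose_uptake=900.0)
    assert out["cori_active"]
    assert out["muscle_lactate_secretion"] > 50.0
    assert out["liver_lactate_uptake"] > 50.0
    assert out["liver_glucose_secretion"] > 50.0
    assert out["liver_gluconeogenesis"] > 0.0
    assert out["solution"].optimal


def test_cahill_cycle_activation(constrained):
    out = cycle_activation(constrained, muscle_glucose_uptake=900.0,
                           liver_alanine_uptake=100.0)
    assert out["cahill_active"]
    assert out["liver_alanine_uptake"] == pytest.approx(100.0, rel=1e-6)
    assert out["muscle_alanine_secretion"] == pytest.approx(100.0, rel=1e-6)
    assert out["liver_urea_synthesis"] > 0.0


# ---------------------------------------------------------------------------
# Robustness to random reaction removal
# ---------------------------------------------------------------------------

def test_robustness_bounds_and_determinism(toy):
    wbm = toy.wbm
    kw = dict(n_trials=20, seed=5,
              maintenance_id="Whole_body_objective_rxn")
    assert random_removal_robustness(wbm, 0.0, **kw) == pytest.approx(1.0)
    assert random_removal_robustness(wbm, 1.0, **kw) == pytest.approx(0.0)
    a = random_removal_robustness(wbm, 0.01, **kw)
    b = random_removal_robustness(wbm, 0.01, **kw)
    assert a == b
    with pytest.raises(ValueError):
        random_removal_robustness(wbm, -0.1, **kw)
    with pytest.raises(ValueError):
        random_removal_robustness(wbm, 1.5, **kw)
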