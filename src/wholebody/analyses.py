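"""Headline whole-body analyses: organ essentiality, inborn-error-of-metabolism
(IEM) biomarker prediction with agreement statistics, basal metabolic rate,
ATP-demand arithmetic, inter-organ cycle activation, and robustness to random
reaction removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .assembly import WHOLE_BODY_OBJECTIVE_ID
from .model import (DEFAULT_BIG, FLUX_ZERO_TOL, Reaction, StoichiometricModel,
                    reactions_lost_by_gene_deletion, split_met_id)
from .simulate import LPData, fba, feasible_at, fva, min_norm_flux

GLUCOSE_MW_G_PER_MOL = 180.16


@dataclass
class EnergyConstants:
    """Energy bookkeeping constants (overridable)."""
    atp_hydrolysis_kj_per_mol: float = 64.0
    kcal_per_kj: float = 1.0 / 4.184
    atp_per_glucose: float = 31.0
    atp_molecular_weight_g_per_mol: float = 507.18


DEFAULT_ENERGY = EnergyConstants()


def glucose_to_atp_moles(grams_per_day: float,
                         constants: EnergyConstants = DEFAULT_ENERGY) -> float:
    """mol ATP/day from a daily glucose consumption in grams (31 ATP/glucose)."""
    if grams_per_day < 0:
        raise ValueError("glucose consumption must be non-negative")
    return grams_per_day / GLUCOSE_MW_G_PER_MOL * constants.atp_per_glucose


def atp_grams_to_moles(grams_per_day: float,
                       constants: EnergyConstants = DEFAULT_ENERGY) -> float:
    """mol ATP/day from grams ATP/day (MW 507.18 g/mol)."""
    if grams_per_day < 0:
        raise ValueError("ATP turnover must be non-negative")
    return grams_per_day / constants.atp_molecular_weight_g_per_mol


def atp_mmol_to_kcal(mmol_per_day: float,
                     constants: EnergyConstants = DEFAULT_ENERGY) -> float:
    return mmol_per_day / 1000.0 * constants.atp_hydrolysis_kj_per_mol * constants.kcal_per_kj


# ---------------------------------------------------------------------------
# Organ essentiality
# ---------------------------------------------------------------------------

def organ_essentiality(wbm: StoichiometricModel, organ_tag: str,
                       maintenance_id: str = WHOLE_BODY_OBJECTIVE_ID,
                       tol: float = FLUX_ZERO_TOL) -> str:
    """'essential' or 'non_essential'.

    The organ's dummy-objective term is removed from the whole-body
    maintenance reaction, every reaction of the organ is closed, and the
    maintenance flux is maximized: the organ is metabolically non-essential
    iff a non-zero maintenance flux remains possible.
    """
    if not any(r.organ == organ_tag or r.id.startswith(organ_tag)
               for r in wbm.reactions):
        raise KeyError(f"unknown organ tag {organ_tag!r}")
    work = wbm.copy(f"{wbm.id}_wo_{organ_tag.rstrip('_')}")
    maint = work.get_reaction(maintenance_id)
    maint.stoichiometry = {m: c for m, c in maint.stoichiometry.items()
                           if not m.startswith(organ_tag)}
    for rxn in work.reactions:
        if rxn.organ == organ_tag or (rxn.id.startswith(organ_tag)
                                      and rxn.id != maintenance_id):
            rxn.lb = rxn.ub = 0.0
    sol = fba(work, {maintenance_id: 1.0}, "max")
    if sol.optimal and sol.objective_value > tol:
        return "non_essential"
    return "essential"


# ---------------------------------------------------------------------------
# IEM biomarker prediction
# ---------------------------------------------------------------------------

@dataclass
class IemTask:
    iem_id: str
    genes: list[str]
    biomarkers: list[tuple[str, str, str]]  # (metabolite base, biofluid, direction)

    def __post_init__(self):
        for met, fluid, direction in self.biomarkers:
            if fluid not in ("bc", "u", "csf"):
                raise ValueError(f"{self.iem_id}: biofluid must be bc/u/csf, got {fluid!r}")
            if direction not in ("increased", "decreased"):
                raise ValueError(f"{self.iem_id}: expected direction must be "
                                 f"increased/decreased, got {direction!r}")


@dataclass
class BiomarkerPrediction:
    metabolite: str
    biofluid: str
    healthy_max: float
    disease_max: float
    call: str  # increased | decreased | inconclusive
    healthy_min: float = 0.0
    disease_min: float = 0.0


def _biomarker_probe(model: StoichiometricModel, met_base: str, fluid: str) -> str:
    """Reaction measuring secretion of a metabolite into a biofluid: the
    urinary exchange for [u], a (possibly temporary) biofluid demand for
    blood and CSF."""
    if fluid == "u":
        rid = f"EX_{met_base}[u]"
        if model.has_reaction(rid):
            return rid
    mid = f"{met_base}[{fluid}]"
    if not model.has_metabolite(mid):
        raise KeyError(f"biomarker metabolite {mid!r} not in model")
    rid = f"__biomarker_DM_{mid}"
    if not model.has_reaction(rid):
        model.add_reaction(Reaction(rid, {mid: -1.0}, 0.0, DEFAULT_BIG))
    return rid


def simulate_iem(wbm: StoichiometricModel, task: IemTask,
                 tau_rel: float = 0.05, healthy_activity: float = 0.9,
                 tol: float = FLUX_ZERO_TOL) -> list[BiomarkerPrediction]:
    """Predict biomarker direction for one inborn error of metabolism.

    The defective genes are mapped through the GPRs to the affected reactions
    in every organ. The healthy model carries flux through each affected
    reaction (at ``healthy_activity`` of its individual maximum — a working
    enzyme is active, not merely present); the disease model has the affected
    reactions closed. For each biomarker the maximal secretion into the
    biofluid is compared: relative change beyond +-tau_rel calls the direction,
    otherwise the prediction is inconclusive. If the gene loss removes no
    reaction (isozyme rescue) every call is inconclusive.
    """
    lost = reactions_lost_by_gene_deletion(wbm, set(task.genes))
    if not any(any(g in (r.gpr or "") for r in wbm.reactions) for g in task.genes):
        raise KeyError(f"{task.iem_id}: none of {task.genes} appears in any GPR")

    predictions = []
    if not lost:
        for met, fluid, _ in task.biomarkers:
            predictions.append(BiomarkerPrediction(met, fluid, math.nan, math.nan,
                                                   "inconclusive"))
        return predictions

    healthy = wbm.copy(f"{wbm.id}_healthy")
    disease = wbm.copy(f"{wbm.id}_{task.iem_id}")
    # healthy: the affected enzymes are active
    for rid in sorted(lost):
        sol = fba(healthy, {rid: 1.0}, "max")
        vmax = sol.objective_value if sol.optimal else 0.0
        if vmax > tol:
            healthy.get_reaction(rid).lb = healthy_activity * vmax
    # disease: the affected reactions are closed in every organ
    for rid in lost:
        r = disease.get_reaction(rid)
        r.lb = r.ub = 0.0

    for met, fluid, _ in task.biomarkers:
        h_rid = _biomarker_probe(healthy, met, fluid)
        d_rid = _biomarker_probe(disease, met, fluid)
        h = fba(healthy, {h_rid: 1.0}, "max")
        d = fba(disease, {d_rid: 1.0}, "max")
        h_max = h.objective_value if h.optimal else 0.0
        d_max = d.objective_value if d.optimal else 0.0
        denom = max(abs(h_max), tol)
        rel = (d_max - h_max) / denom
        if d_max > tol and h_max <= tol:
            call = "increased"
        elif rel > tau_rel:
            call = "increased"
        elif rel < -tau_rel:
            call = "decreased"
        else:
            call = "inconclusive"
        predictions.append(BiomarkerPrediction(met, fluid, h_max, d_max, call))
    return predictions


def agreement_stats(predictions: Iterable[str], observations: Iterable[str],
                    categories: tuple = ("increased", "inconclusive", "decreased"),
                    alpha: float = 0.05) -> dict:
    """Percent agreement and Cohen's kappa (with large-sample CI) between two
    categorical vectors."""
    pred = list(predictions)
    obs = list(observations)
    if len(pred) != len(obs):
        raise ValueError("prediction/observation length mismatch")
    n = len(pred)
    if n == 0:
        raise ValueError("empty vectors")
    idx = {c: i for i, c in enumerate(categories)}
    table = np.zeros((len(categories), len(categories)))
    for p, o in zip(pred, obs):
        table[idx[p], idx[o]] += 1
    p_o = np.trace(table) / n
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    p_e = float(row @ col)
    if p_e >= 1.0:
        kappa = 1.0 if p_o >= 1.0 else 0.0
        se = 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
        se = math.sqrt(max(p_o * (1.0 - p_o), 0.0) / n) / (1.0 - p_e)
    from scipy.stats import norm
    z = norm.ppf(1.0 - alpha / 2.0)
    return {
        "percent_agreement": 100.0 * p_o,
        "cohens_kappa": kappa,
        "kappa_ci": (kappa - z * se, kappa + z * se),
        "n": n,
        "contingency": table,
    }


# ---------------------------------------------------------------------------
# Basal metabolic rate and energy budget
# ---------------------------------------------------------------------------

def _is_atp(met_id: str) -> bool:
    base, comp = split_met_id(met_id)
    if comp not in ("c", "m"):
        return False
    return base == "atp" or base.endswith("_atp")


def atp_consumption_by_reaction(model: StoichiometricModel,
                                fluxes: pd.Series) -> pd.Series:
    """Per-reaction ATP consumption (mmol/day): -sum of ATP stoichiometries
    times flux, restricted to reactions that net-consume ATP."""
    out = {}
    for rxn in model.reactions:
        coeff = sum(c for m, c in rxn.stoichiometry.items() if _is_atp(m))
        if coeff == 0.0:
            continue
        consumption = -coeff * float(fluxes[rxn.id])
        if consumption > 0.0:
            out[rxn.id] = consumption
    return pd.Series(out, dtype=float).sort_values(ascending=False)


def predict_bmr(wbm: StoichiometricModel,
                maintenance_id: str = WHOLE_BODY_OBJECTIVE_ID,
                maintenance_flux: float = 1.0,
                constants: EnergyConstants = DEFAULT_ENERGY,
                return_details: bool = False):
    """Basal metabolic rate, kcal/day.

    The whole-body maintenance flux is fixed (default 1), the Euclidean norm
    of the flux vector is minimized to obtain a unique basal flux state, and
    the rates of ATP consumption of all reactions in all organs are summed;
    BMR = total ATP (mol/day) x 64 kJ/mol / 4.184 kJ/kcal.
    """
    sol = min_norm_flux(wbm, fixed={maintenance_id: maintenance_flux})
    if not sol.optimal:
        raise ValueError("maintenance flux is infeasible under the current constraints")
    per_rxn = atp_consumption_by_reaction(wbm, sol.fluxes)
    total_mmol = float(per_rxn.sum())
    bmr = atp_mmol_to_kcal(total_mmol, constants)
    if return_details:
        maint_share = float(per_rxn.get(maintenance_id, 0.0))
        return bmr, {"total_atp_mmol_per_day": total_mmol,
                     "per_reaction": per_rxn,
                     "maintenance_atp_mmol_per_day": maint_share,
                     "solution": sol}
    return bmr


def activity_energy_budget(wbm: StoichiometricModel, diet_kcal: Optional[float] = None,
                           organ_demands: Optional[Mapping[str, float]] = None,
                           maintenance_id: str = WHOLE_BODY_OBJECTIVE_ID,
                           constants: EnergyConstants = DEFAULT_ENERGY) -> float:
    """Remaining extractable energy (kcal/day) after whole-body maintenance
    and fixed organ activity demands.

    *organ_demands* maps ATP-demand reaction ids to lower bounds in
    mmol/day (defaults: brain 3500 for electrophysiology, heart 6000 for
    pumping). The maximal total surplus flux through all organ ATP demands is
    converted at 64 kJ/mol ATP.
    """
    if organ_demands is None:
        organ_demands = {"Brain_DM_atp_c_": 3500.0, "Heart_DM_atp_c_": 6000.0}
    work = wbm.copy(f"{wbm.id}_budget")
    forced_total = 0.0
    for rid, lb in organ_demands.items():
        if not work.has_reaction(rid):
            raise KeyError(f"ATP demand reaction {rid!r} not in model")
        work.get_reaction(rid).lb = lb
        forced_total += lb
    demands = {r.id: 1.0 for r in work.reactions if "DM_atp" in r.id}
    sol = fba(work, demands, "max", fixed={maintenance_id: 1.0})
    if not sol.optimal:
        raise ValueError("organ ATP demands are infeasible under the current constraints")
    surplus_mmol = max(sol.objective_value - forced_total, 0.0)
    return atp_mmol_to_kcal(surplus_mmol, constants)


# ---------------------------------------------------------------------------
# Inter-organ cycles (Cori / Cahill)
# ---------------------------------------------------------------------------

def cycle_activation(wbm: StoichiometricModel, muscle_glucose_uptake: float,
                     liver_alanine_uptake: Optional[float] = None,
                     maintenance_id: str = WHOLE_BODY_OBJECTIVE_ID,
                     tol: float = FLUX_ZERO_TOL) -> dict:
    """Minimum-norm basal flux with enforced muscle glucose uptake (and
    optionally liver alanine uptake); reports the fluxes diagnostic for the
    Cori cycle (liver secretes glucose, muscle secretes lactate, liver
    consumes lactate) and the Cahill pattern (muscle secretes alanine, liver
    deaminates it and regenerates glucose)."""
    work = wbm.copy(f"{wbm.id}_cycles")
    glc_rid = "Muscle_EX_glc_D[bc]_[e]"
    work.get_reaction(glc_rid).lb = muscle_glucose_uptake
    if liver_alanine_uptake is not None:
        work.get_reaction("Liver_EX_ala_L[bc]_[e]").lb = liver_alanine_uptake
    sol = min_norm_flux(work, fixed={maintenance_id: 1.0})
    if not sol.optimal:
        raise ValueError("enforced uptakes are infeasible")
    v = sol.fluxes

    def get(rid):
        return float(v[rid]) if rid in v.index else 0.0

    fluxes = {
        "muscle_glucose_uptake": get(glc_rid),
        "muscle_lactate_secretion": -min(get("Muscle_EX_lac_L[bc]_[e]"), 0.0),
        "liver_lactate_uptake": max(get("Liver_EX_lac_L[bc]_[e]"), 0.0),
        "liver_glucose_secretion": -min(get("Liver_EX_glc_D[bc]_[e]"), 0.0),
        "liver_gluconeogenesis": get("Liver_GLUCONEO"),
        "muscle_alanine_secretion": -min(get("Muscle_EX_ala_L[bc]_[e]"), 0.0),
        "muscle_alanine_synthesis": get("Muscle_ALASYN"),
        "liver_alanine_uptake": max(get("Liver_EX_ala_L[bc]_[e]"), 0.0),
        "liver_urea_synthesis": get("Liver_UREASYN"),
    }
    fluxes["cori_active"] = (fluxes["muscle_lactate_secretion"] > tol
                             and fluxes["liver_lactate_uptake"] > tol
                             and fluxes["liver_glucose_secretion"] > tol)
    fluxes["cahill_active"] = (fluxes["muscle_alanine_secretion"] > tol
                               and fluxes["liver_alanine_uptake"] > tol
                               and fluxes["liver_gluconeogenesis"] > tol)
    fluxes["solution"] = sol
    return fluxes


# ---------------------------------------------------------------------------
# Robustness to random reaction removal
# ---------------------------------------------------------------------------

def random_removal_robustness(wbm: StoichiometricModel, fraction: float,
                              n_trials: int = 200, seed: int = 0,
                              maintenance_id: str = WHOLE_BODY_OBJECTIVE_ID,
                              required_flux: float = 1.0) -> float:
    """Fraction of trials in which a unit maintenance flux stays feasible
    after removing round(fraction * n) randomly chosen reactions."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lp = LPData(wbm)
    candidates = [rid for rid in lp.rxn_ids if rid != maintenance_id]
    k = round(fraction * len(lp.rxn_ids))
    if k == 0:
        return 1.0 if feasible_at(wbm, maintenance_id, required_flux, lp=lp) else 0.0
    if k >= len(candidates):
        return 0.0
    feasible = 0
    for _ in range(n_trials):
        removed = rng.choice(candidates, size=k, replace=False)
        overrides = {rid: (0.0, 0.0) for rid in removed}
        sol = lp.solve(np.zeros(lp.n), "min", fixed={maintenance_id: required_flux},
                       overrides=overrides)
        feasible += sol.optimal
    return feasible / n_trials
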