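"""Physiologically and stoichiometrically constrained modeling (PSCM).

Turns physiology, quantitative metabolomics and diet tables into reaction
bounds and coupling constraints:

* organ uptake caps: plasma flow (cardiac output x organ blood-flow fraction
  x (1 - hematocrit)) times the maximal plasma concentration;
* glomerular filtration: GFR (20% of renal plasma flow by default) times the
  plasma concentration range, applied as forced lower/upper bounds on the
  kidney filtration reactions — the kidney filters plasma metabolites
  irrespective of their nature;
* CSF return to blood and urinary excretion: flow/volume times concentration
  range;
* diet: uptake lower bounds (uptake is negative by convention), everything
  absent from the diet closed;
* coupling: every organ reaction tied to its organ's biomass objective with a
  factor (default 20,000).

Units are fixed package-wide: concentrations in mmol/L (mM), flows in L/day,
fluxes in mmol/day/person.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .model import (DEFAULT_BIG, DEFAULT_COUPLING_FACTOR, CouplingConstraint,
                    StoichiometricModel)

ML_PER_MIN_TO_L_PER_DAY = 60.0 * 24.0 / 1000.0  # = 1.44


@dataclass
class PhysiologyParameters:
    sex: str = "male"
    body_weight: float = 70.0        # kg
    height: float = 170.0            # cm
    heart_rate: float = 67.0         # 1/min
    stroke_volume: float = 80.0      # ml
    cardiac_output: Optional[float] = None  # ml/min; heart_rate*stroke_volume if None
    organ_blood_flow_fraction: dict[str, float] = field(default_factory=dict)
    hematocrit: float = 0.45
    gfr_fraction: float = 0.20       # fraction of renal plasma flow filtered
    gfr: Optional[float] = None      # L/day; overrides the derived value
    urine_volume: float = 1.4        # L/day
    csf_flow: float = 0.5            # L/day
    organ_weight_fraction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.cardiac_output is None:
            self.cardiac_output = self.heart_rate * self.stroke_volume
        if self.cardiac_output <= 0:
            raise ValueError("cardiac output must be positive")
        for name, frac in [("hematocrit", self.hematocrit),
                           ("gfr_fraction", self.gfr_fraction)]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        total = sum(self.organ_blood_flow_fraction.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"organ blood-flow fractions sum to {total:.3f} > 1")

    @property
    def cardiac_output_l_per_day(self) -> float:
        return self.cardiac_output * ML_PER_MIN_TO_L_PER_DAY

    def plasma_flow(self, organ_tag: str) -> float:
        """Plasma flow through an organ, L/day."""
        frac = self.organ_blood_flow_fraction[organ_tag]
        return self.cardiac_output_l_per_day * frac * (1.0 - self.hematocrit)

    @property
    def gfr_l_per_day(self) -> float:
        """Glomerular filtration rate: gfr_fraction of renal plasma flow
        unless an explicit GFR was supplied."""
        if self.gfr is not None:
            return self.gfr
        kidney = next((t for t in self.organ_blood_flow_fraction
                       if t.lower().startswith("kidney")), None)
        if kidney is None:
            raise KeyError("no kidney entry in organ_blood_flow_fraction")
        return self.gfr_fraction * self.plasma_flow(kidney)


@dataclass
class MetabolitePanel:
    """Concentration ranges (mmol/L) of metabolites in one biofluid."""
    biofluid: str
    concentrations: dict[str, tuple[float, float]]  # base id -> (min, max)

    def __post_init__(self):
        for met, (lo, hi) in self.concentrations.items():
            if not 0.0 <= lo <= hi:
                raise ValueError(f"{met}: invalid concentration range ({lo}, {hi})")

    def items(self):
        return self.concentrations.items()

    @classmethod
    def from_tsv(cls, path, biofluid: str) -> "MetabolitePanel":
        df = pd.read_csv(path, sep="\t")
        return cls(biofluid, {row["metabolite"]: (float(row["conc_min"]),
                                                  float(row["conc_max"]))
                              for _, row in df.iterrows()})


@dataclass
class DietSpec:
    """Daily dietary intake, mmol/day, with optional energy content."""
    intakes: dict[str, float]
    energy_kcal: Optional[float] = None

    def __post_init__(self):
        for met, val in self.intakes.items():
            if val < 0:
                raise ValueError(f"{met}: negative dietary intake")

    @classmethod
    def from_tsv(cls, path, energy_kcal: Optional[float] = None) -> "DietSpec":
        df = pd.read_csv(path, sep="\t")
        return cls({row["metabolite"]: float(row["intake"])
                    for _, row in df.iterrows()}, energy_kcal)


def _mark_constrained(model: StoichiometricModel, rxn_ids: Iterable[str]) -> None:
    touched = set(model.annotations.get("constrained_reactions", ()))
    touched |= set(rxn_ids)
    model.annotations["constrained_reactions"] = sorted(touched)


# ---------------------------------------------------------------------------
# Constraint families
# ---------------------------------------------------------------------------

def organ_uptake_bounds(model: StoichiometricModel, phys: PhysiologyParameters,
                        plasma: MetabolitePanel) -> StoichiometricModel:
    """Cap each organ's uptake of every plasma metabolite at plasma flow times
    the maximal plasma concentration. Transports are written with positive
    flux = uptake, so the cap tightens the upper bound."""
    touched = []
    for organ_tag in sorted(set(r.organ for r in model.reactions if r.organ)):
        if organ_tag not in phys.organ_blood_flow_fraction:
            warnings.warn(f"no blood-flow fraction for {organ_tag!r}; skipped")
            continue
        flow = phys.plasma_flow(organ_tag)
        for base, (_, cmax) in plasma.items():
            rid = f"{organ_tag}EX_{base}[{plasma.biofluid}]_[e]"
            if not model.has_reaction(rid):
                continue
            rxn = model.get_reaction(rid)
            cap = flow * cmax
            rxn.ub = min(rxn.ub, cap)
            rxn.lb = min(rxn.lb, rxn.ub)
            touched.append(rid)
    _mark_constrained(model, touched)
    return model


def kidney_filtration_bounds(model: StoichiometricModel,
                             phys: PhysiologyParameters,
                             plasma: MetabolitePanel,
                             kidney_tag: str = "Kidney_") -> StoichiometricModel:
    """Force glomerular filtration of every plasma metabolite into the
    GFR x concentration range (lb = GFR*cmin, ub = GFR*cmax)."""
    if not any(r.id.startswith(f"{kidney_tag}FILT_") for r in model.reactions):
        raise KeyError(f"model has no {kidney_tag}FILT_* filtration reactions")
    gfr = phys.gfr_l_per_day
    touched = []
    for base, (cmin, cmax) in plasma.items():
        rid = f"{kidney_tag}FILT_{base}"
        if not model.has_reaction(rid):
            continue
        rxn = model.get_reaction(rid)
        rxn.lb, rxn.ub = gfr * cmin, gfr * cmax
        touched.append(rid)
    _mark_constrained(model, touched)
    return model


def csf_return_bounds(model: StoichiometricModel, phys: PhysiologyParameters,
                      csf_panel: MetabolitePanel) -> StoichiometricModel:
    """CSF metabolites are unselectively returned to the bloodstream: the
    csf->blood drain of each panel metabolite is bounded by csf_flow times its
    CSF concentration range."""
    touched = []
    for base, (cmin, cmax) in csf_panel.items():
        rid = f"TR_{base}_csf_bc"
        if not model.has_reaction(rid):
            continue
        rxn = model.get_reaction(rid)
        rxn.lb, rxn.ub = phys.csf_flow * cmin, phys.csf_flow * cmax
        touched.append(rid)
    _mark_constrained(model, touched)
    return model


def urine_excretion_bounds(model: StoichiometricModel, phys: PhysiologyParameters,
                           urine_panel: MetabolitePanel) -> StoichiometricModel:
    """Urinary excretion bounded by daily urine volume times the urine
    concentration range; metabolites absent from the panel are untouched."""
    touched = []
    for base, (cmin, cmax) in urine_panel.items():
        rid = f"EX_{base}[u]"
        if not model.has_reaction(rid):
            continue
        rxn = model.get_reaction(rid)
        rxn.lb = phys.urine_volume * cmin
        rxn.ub = phys.urine_volume * cmax
        touched.append(rid)
    _mark_constrained(model, touched)
    return model


def apply_diet(model: StoichiometricModel, diet: DietSpec) -> StoichiometricModel:
    """Set dietary uptake bounds: lb = -intake (uptake negative), ub = 0;
    dietary exchanges for metabolites absent from the diet are closed."""
    unknown = [met for met in diet.intakes
               if not model.has_reaction(f"Diet_EX_{met}[d]")]
    if unknown:
        warnings.warn(f"diet names metabolites without dietary exchanges: {unknown}")
    touched = []
    for rxn in model.reactions:
        if not rxn.id.startswith("Diet_EX_"):
            continue
        base = rxn.id[len("Diet_EX_"):].rsplit("[", 1)[0]
        intake = diet.intakes.get(base, 0.0)
        rxn.lb, rxn.ub = -intake, 0.0
        touched.append(rxn.id)
    _mark_constrained(model, touched)
    return model


def apply_coupling(model: StoichiometricModel,
                   factor: float = DEFAULT_COUPLING_FACTOR,
                   organs: Optional[Iterable[str]] = None) -> StoichiometricModel:
    """Couple every organ reaction to that organ's biomass objective function:
    |v_i| <= factor * v_BOF. Unprefixed reactions (biofluid flows, boundary
    exchanges, the whole-body objective) are not coupled."""
    tags = sorted(organs) if organs is not None else sorted(
        set(r.organ for r in model.reactions if r.organ))
    existing = {(c.coupled_reaction, c.anchor_reaction) for c in model.coupling}
    for tag in tags:
        bofs = [r.id for r in model.reactions
                if r.organ == tag and r.id.startswith(f"{tag}biomass_")
                and "DEGR" not in r.id]
        if not bofs:
            raise KeyError(f"organ {tag!r} has no biomass objective function")
        bof = bofs[0]
        for rxn in model.reactions:
            if rxn.organ != tag or rxn.id == bof:
                continue
            if (rxn.id, bof) in existing:
                continue
            model.coupling.append(CouplingConstraint(rxn.id, bof, factor))
            existing.add((rxn.id, bof))
    return model


def constraint_coverage(model: StoichiometricModel) -> tuple[int, float]:
    """(count, fraction) of reactions whose bounds differ from the recorded
    defaults (see :func:`wholebody.model.snapshot_default_bounds`)."""
    defaults = model.annotations.get("default_bounds")
    if defaults is None:
        raise ValueError("no default-bound snapshot recorded on this model")
    n = 0
    for rxn in model.reactions:
        d = defaults.get(rxn.id)
        if d is None or rxn.lb != d[0] or rxn.ub != d[1]:
            n += 1
    return n, n / max(len(model.reactions), 1)


def apply_pscm(model: StoichiometricModel, phys: PhysiologyParameters,
               plasma: MetabolitePanel, urine: MetabolitePanel,
               csf: MetabolitePanel, diet: DietSpec,
               coupling_factor: float = DEFAULT_COUPLING_FACTOR,
               couple: bool = True) -> StoichiometricModel:
    """Apply the full constraint stack in the canonical order."""
    organ_uptake_bounds(model, phys, plasma)
    kidney_filtration_bounds(model, phys, plasma)
    csf_return_bounds(model, phys, csf)
    urine_excretion_bounds(model, phys, urine)
    apply_diet(model, diet)
    if couple:
        apply_coupling(model, coupling_factor)
    return model
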