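# wholebody

Organ-resolved, sex-specific whole-body metabolic modeling at the
flux-balance level: assemble a multi-organ stoichiometric model from a base
metabolic reconstruction, constrain it with measured physiology (blood flow,
filtration, diet, biofluid metabolomes), and interrogate it — energy budgets,
inter-organ cycles, inborn errors of metabolism, organ essentiality, and
host–gut-microbiome co-metabolism.

## Science

A whole-body model (WBM) couples organ-specific copies of a metabolic network
through biofluid compartments: diet → gut lumen → feces along the intestinal
axis, blood circulation and portal blood between organs, cerebrospinal fluid
behind a blood–brain barrier, and urine behind glomerular filtration. Each
organ pays a maintenance cost (ATP, amino-acid and lipid turnover) that feeds
a single whole-body maintenance objective weighted by organ mass. The model
operates at steady state (`S v = 0`) with flux bounds in mmol/day.

Two ideas make the model *personalizable*:

1. **Physiological constraints.** Organ uptake of a blood metabolite cannot
   exceed plasma flow times its plasma concentration; plasma flow follows
   from cardiac output (heart rate x stroke volume), the organ's blood-flow
   fraction and the hematocrit. Kidney filtration is pinned to the glomerular
   filtration rate, urine output to measured urine metabolome ranges, and the
   diet sets dietary exchange bounds. Each family only tightens the feasible
   flux space.
2. **Coupling constraints.** Every organ reaction `v` satisfies
   `|v| <= 20000 x v_biomass(organ)`, so flux through an organ requires that
   organ to turn over biomass (microbial strain reactions use factor 400).

The package also implements the flux-consistency toolbox needed to build such
models from data — `fastcc` (maximal consistent subnetwork), `fastcore`
(compact subnetwork covering a proteomics-derived core), leak tests and a
16-point sanity suite — plus a gut-microbiome layer: abundance-weighted
strain communities attached to the large-intestinal lumen.

All algorithms are validated against independent oracles (exhaustive FVA,
subset-enumeration minimal supports, COBRApy, statsmodels/scikit-learn) on a
deterministic synthetic study system: a nine-organ toy body engineered to
yield exactly 31 ATP per glucose aerobically and 2 anaerobically, with
red blood cells lacking mitochondria, a PKU-like inborn error, an isozyme
negative control, and four gut strains including a butyrate producer.
See `docs/methods.md` for the full model description.

## Worked example

```python
from wholebody import (make_toy_body, fba, predict_bmr, organ_essentiality,
                       cycle_activation, simulate_iem, fold_change)
from wholebody.fixtures import toy_iem_catalog

toy = make_toy_body(0)                      # nine-organ synthetic body
wbm = toy.constrained_model()               # physiology + diet + coupling

sol = fba(wbm)                              # maximize whole-body maintenance
print(f"max. whole-body maintenance flux: {sol.objective_value:.4f} /day")
print(f"basal metabolic rate:             "
      f"{predict_bmr(wbm, 'Whole_body_objective_rxn'):.2f} kcal/day")
print(f"liver essentiality:               {organ_essentiality(wbm, 'Liver_')}")

cori = cycle_activation(wbm, muscle_glucose_uptake=900.0)
print(f"Cori cycle active:                {cori['cori_active']} "
      f"(liver glucose secretion {cori['liver_glucose_secretion']:.1f} mmol/day)")

pku = next(t for t in toy_iem_catalog() if t.iem_id == "PKU_toy")
for p in simulate_iem(wbm, pku):
    print(f"PKU biomarker {p.metabolite:>6} [{p.biofluid}]:       {p.call}")

my = toy.with_microbiome({"Faecalibacterium_toyii": 0.4,
                          "Clostridium_toyense": 0.2,
                          "Bacteroides_toyii": 0.3,
                          "Clostridioides_toydifficile": 0.1})
print(f"colonic butyrate activation:      fold change "
      f"{fold_change(wbm, my, 'Colon_BUTCOAL')}")
```

Output:

```
max. whole-body maintenance flux: 12.1648 /day
basal metabolic rate:             25.61 kcal/day
liver essentiality:               essential
Cori cycle active:                True (liver glucose secretion 943.3 mmol/day)
PKU biomarker  phe_L [bc]:       increased
PKU biomarker  tyr_L [bc]:       decreased
colonic butyrate activation:      fold change inf
```

(The numbers are toy-scale, not human-scale: the toy body is a small study
system for validating the methods. The infinite fold change is exact — the
germ-free colon has no luminal butyrate source, so the butyrate-CoA ligase
maximum rises from exactly 0 to a positive value with the microbiome.)

A `wbm` command-line interface wraps the same functionality:

```bash
wbm build --no-constrain --out toy_wbm.json   # unconstrained model
wbm sanity toy_wbm.json                       # 16 quality-control checks
wbm simulate --help                            # FBA / FVA / BMR / robustness
```

Run `wbm sanity` on the *unconstrained* model: physiological constraints
deliberately block routes (e.g. microbial butyrate) that the consistency
check would report as blocked reactions.

## Reproduction

```bash
# full test suite (~5 min, 1 CPU): unit tests, oracle comparisons, and one
# acceptance test per headline claim in tests/test_acceptance.py
python -m pytest -o addopts= -p no:cacheprovider -q tests/

# headline quantities as JSON (deterministic given --seed)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

With seed 1 the acceptance script reports, among others:
`glucose_atp_mol_per_day` 20.648, `atp_turnover_mol_per_day` 11.830,
`bmr_kcal_per_day` 25.606, `cori_active` and `cahill_active` 1.0,
`fastcc_fva_agreement_rate` 1.0 (n=50), `fastcore_within_two_rate` 1.0
(n=20), `iem_percent_agreement` 75.0 with `iem_cohens_kappa` 0.6 (the
isozyme negative control is deliberately inconclusive),
`butyrate_producer_spearman_rho` 1.0 over a 20-member cohort, robustness
0.985/0.89/0.285 at removal fractions 0.001/0.01/0.1 (200 trials each), and
`sanity_checks_passed` 16/16.

## Package layout

| module | contents |
| --- | --- |
| `wholebody.model` | metabolites, reactions, GPR logic, validation, JSON/TSV/SBML I/O |
| `wholebody.assembly` | organ replication, biofluid wiring, blood–brain barrier, biomass composition, proteomics→core mapping |
| `wholebody.consistency` | fastcc, fastcore, leak test, ATP yield, 16-check sanity suite, draft WBM builder |
| `wholebody.pscm` | physiology parameters and the constraint families |
| `wholebody.simulate` | FBA, FVA, minimum-norm flux states, solution checking |
| `wholebody.analyses` | energy budgets, BMR, Cori/Cahill cycles, IEM biomarkers, essentiality, robustness |
| `wholebody.microbiome` | strain communities, host attachment, fold changes, secretion potential |
| `wholebody.fixtures` | the deterministic toy body, cohorts, panels, diets, microbes |
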