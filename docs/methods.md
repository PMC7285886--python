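# Methods

This document records the modeling choices, algorithms, parameter values and
numerical conventions behind the `wholebody` package, together with its known
limitations. All empirical numbers quoted here are computed by the test suite
(`tests/`) or by `scripts/acceptance.py`.

## 1. Model representation

A model is a set of metabolites `met[compartment]` and reactions with sparse
stoichiometries, flux bounds `lb <= v <= ub` (mmol/day for whole-body models)
and optional gene–protein–reaction (GPR) rules, plus a linear objective and a
list of *coupling constraints*. Steady state imposes `S v = 0`. A coupling
constraint ties a reaction to an anchor (a biomass reaction) via two linear
rows,

```
 v_i - c * v_anchor <= 0
-v_i - c * v_anchor <= 0,
```

i.e. `|v_i| <= c * v_anchor`. Host organ reactions use `c = 20000`, microbial
strain reactions `c = 400`. Coupling prevents flux through an organ or strain
whose biomass turnover is zero.

Numerical conventions:

- default "infinite" bound `DEFAULT_BIG = 1e6`,
- fluxes below `FLUX_ZERO_TOL = 1e-6` are treated as zero,
- the flux-consistency threshold is `epsilon = 1e-4`.

GPR rules are parsed into and/or trees by a recursive-descent parser;
`evaluate` supports the relaxation of AND to OR used when mapping noisy
expression evidence (a missing subunit measurement should not delete a
complex).

## 2. Linear and quadratic programs

Flux balance analysis (FBA) and flux variability analysis (FVA) are solved
with `scipy.optimize.linprog(method="highs")`. Coupling rows are appended as
inequality rows of `A_ub`. FVA solves one min and one max LP per reaction and
raises on any non-optimal subproblem rather than returning partial tables.

The minimum-Euclidean-norm flux state (used for basal-state analyses, where
the FBA optimum is degenerate) minimizes `||v||^2` subject to the same
constraints, via OSQP (absolute/relative tolerance `1e-9`, polishing on) with
a `scipy.optimize.minimize(method="trust-constr")` fallback. Uniqueness of
the minimizer makes basal flux maps reproducible to solver precision.

`check_solution` independently verifies mass balance (`max |S v|`), bound and
coupling-row violations of any returned solution at tolerance `1e-5`.

## 3. Flux consistency: fastcc and fastcore

`fastcc` finds the maximal flux-consistent subnetwork by the LP7/LP3 sweep
with column flipping for reversible candidates; support membership uses the
threshold `0.99 * epsilon` so that a flux exactly at `epsilon` counts. The
test suite validates `fastcc` against an exhaustive per-reaction FVA oracle
on hundreds of random networks.

`fastcore` extracts a compact consistent subnetwork containing a core set by
alternating LP7 (maximize the number of core reactions carrying flux) and LP9
(minimize the L1 penalty on non-core flux). It is a heuristic: it guarantees
core coverage and consistency, not minimality. The acceptance criterion
therefore allows a slack of **+2 reactions** over the exhaustive
minimal-support oracle (subset enumeration by increasing size), and the
observed worst case on the random battery is +1.

## 4. Whole-body assembly

Organ submodels are organ-prefixed copies of a base reconstruction
(`Liver_`, `Brain_`, ...), with organ restrictions applied (e.g. the red
blood cell lacks mitochondrial reactions). Thirteen biofluid compartments
connect them: diet `[d]`, gut lumen `[lu]`, small/large-intestinal lumen
`[luSI]`/`[luLI]`, feces `[fe]`, blood circulation `[bc]`, portal blood
`[bp]`, bile duct `[bd]`, cerebrospinal fluid `[csf]`, urine `[u]`, sweat
`[sw]`, milk `[mi]`, air `[a]`. Organ–biofluid transport reactions are named
`<Organ>_EX_<met>[<fluid>]_[e]` with **positive flux = uptake into the
organ**; luminal transit follows the chain `d → lu → luSI → luLI → fe`;
kidney filtration reactions `Kidney_FILT_<met>` move metabolites from blood
to urine. The biofluid topology is validated as a directed graph (every
biofluid must be reachable from the diet or producible, and drain to an
excretion route).

The blood–brain barrier is modeled as list-plus-cutoff: explicitly allowed
metabolites always cross, explicitly blocked ones never do, and otherwise a
molecular-weight cutoff of 500 g/mol applies, permissive when the mass is
unknown.

Organ biomass/maintenance reactions are composed from a reference
coefficient table; variants: full biomass, `noTrTr` (no
transcription/translation precursors, for enucleated cells), and
degradation bookkeeping via `_DEGR` reactions. Each organ's biomass produces
a `dummy_objective` metabolite consumed by the single
`Whole_body_objective_rxn`, whose organ weights come from a reference
coefficient table (e.g. muscle 40, brain 2 per unit whole-body maintenance).

## 5. Physiological constraints (PSCM)

Physiology is parameterized by sex, weight, height, heart rate HR (1/min),
stroke volume SV (ml), hematocrit hct, organ blood-flow fractions f_organ,
glomerular filtration fraction (0.2 of renal plasma flow), urine volume
(L/day) and CSF flow (L/day). Derived quantities:

- cardiac output `CO = HR x SV` ml/min; in L/day: `CO x 1.44`,
- organ plasma flow `Q_organ = CO[L/day] x f_organ x (1 - hct)`,
- GFR `= 0.2 x Q_kidney`.

Constraint families, each only *tightening* bounds (the acceptance test
asserts the maximal whole-body maintenance flux is non-increasing as the
families are applied):

1. **Organ uptake caps**: `ub(Organ_EX_met[bc]_[e]) <= Q_organ x c_max(met)`
   from the plasma concentration panel (mmol/L).
2. **Kidney filtration**: `GFR x c_min <= v(Kidney_FILT_met) <= GFR x c_max`.
3. **CSF return**: CSF drainage into blood bounded by CSF flow times the CSF
   concentration range.
4. **Urine excretion**: urine exchange bounded by urine volume times the
   urine concentration range.
5. **Diet**: `lb(Diet_EX_met[d]) = -intake`, all dietary exchanges for
   metabolites absent from the diet closed.
6. **Coupling**: every organ reaction coupled to its organ's biomass with
   factor 20000.

With the toy defaults (HR 67, SV 75 ml, hct 0.45) the cardiac output is
7236 L/day, liver plasma flow 994.95 L/day (so the liver glucose uptake cap
is 994.95 x 8 = 7959.6 mmol/day) and GFR 151.2324 L/day.

## 6. The toy whole-body fixture

The synthetic study system is a nine-organ body (liver, brain, muscle,
heart, kidney, adipocytes, colon, small-intestinal epithelium, red blood
cells) built from a ~60-reaction base network engineered so that:

- aerobic glucose catabolism yields exactly **31 ATP/glucose** (glycolysis 2,
  then a mitochondrial chain whose proton bookkeeping — lactate shuttle 29 H+,
  ATP synthase 2 H+/ATP — was chosen to reproduce the whole-body literature
  value used in the energy arithmetic),
- anaerobic catabolism yields exactly **2 ATP/glucose**,
- the red blood cell lacks mitochondria (and transcription/translation), so
  its aerobic yield is also 2.

Generator variants: `default`; `fragile` (colon absorption removed, for
essentiality analyses); `redundant` (scaled parallel copies of load-bearing
reactions, for robustness analyses). The defaults are the study conditions;
none of the generator parameters are tuned to test outcomes.

Gene deletions use the GPR rules: a complex (`and`) dies with any subunit, an
isozyme pair (`or`) survives single deletions — the fixture includes a PAH
gene (phenylalanine hydroxylase, complex of one) and an ADH isozyme pair as
positive and negative controls.

## 7. Analyses

**Energy arithmetic.** `glucose_to_atp_moles(g/day) = g / 180.16 x 31`;
`atp_grams_to_moles(g/day) = g / 507.18`; ATP hydrolysis is valued at
64 kJ/mol = 64/4.184 kcal/mol.

**BMR.** The whole-body maintenance flux is fixed to 1/day, the
minimum-norm basal state is computed, and ATP consumption is summed over all
reactions that net-consume cytosolic or mitochondrial ATP; BMR = total ATP
(mol/day) x 64/4.184 kcal/mol. On the toy body this gives 25.61 kcal/day
(1674 mmol ATP/day) — a *toy-scale* number, not a human prediction.

**Activity budget.** Brain and heart ATP demands are fixed (3500 and
6000 mmol/day), the total organ ATP demand is maximized at unit maintenance,
and the surplus over the forced demands is converted to kcal (198.7 kcal/day
on the toy body).

**Inter-organ cycles.** Muscle glucose uptake is forced and the minimum-norm
state inspected: the Cori pattern is muscle lactate secretion + liver lactate
uptake + liver glucose secretion; additionally forcing liver alanine uptake
elicits the Cahill pattern (muscle alanine secretion, liver urea synthesis).

**Inborn errors of metabolism.** Following the healthy/disease flux-forcing
approach: for each reaction lost by the gene defect (via GPRs), the healthy
model forces `lb = 0.9 x` the reaction's maximal flux and the disease model
closes it; each biomarker's maximal biofluid exchange is compared between the
two states, with a relative-change threshold `tau_rel = 0.05` deciding
increased/decreased/inconclusive. If the defect removes no reaction (isozyme
redundancy) all biomarkers are inconclusive by construction. Agreement with
observed directions is summarized by percent agreement and Cohen's kappa
(validated in-suite against statsmodels and scikit-learn).

**Organ essentiality.** An organ is non-essential iff a positive whole-body
maintenance flux survives closing all its reactions (after removing its term
from the maintenance stoichiometry).

**Robustness.** `random_removal_robustness` reports the fraction of seeded
trials in which unit maintenance stays feasible after closing
`round(fraction x n)` randomly chosen reactions.

## 8. Microbiome

Strain models share the host's large-intestinal lumen namespace `[luLI]`.
A community is the abundance-weighted union of strain submodels; the
`communityBiomass` reaction consumes each strain biomass at its normalized
relative abundance and produces pooled microbial biomass, excreted fecally.
Attachment fixes community growth at 1/day and couples every strain reaction
to its strain biomass (factor 400). Microbial luminal metabolites unknown to
the host receive a transit-to-feces route so they cannot accumulate.

**Butyrate readout.** The germ-free colonocyte butyrate-CoA ligase flux
(`Colon_BUTCOAL`) has maximum exactly 0 — the host has no luminal butyrate
source — so the microbiome-associated fold change is **+inf for every cohort
member**; the fold change itself is therefore uninformative as a graded
readout. The graded statistic used instead is the microbiome-associated
maximal flux, which across a 20-member synthetic cohort (Dirichlet(2)
abundances) is a strictly monotone function of the butyrate-producer
abundance (Spearman rho = 1.0 on the seed-1 cohort). An earlier candidate
readout — fold change of the colonocyte ATP demand, which has a finite
germ-free baseline — is essentially flat (≈ 0.997, Spearman ≈ 0.04) because
the community net-consumes luminal glucose; this negative result is reported
here rather than silently replaced.

## 9. Quality control (sanity suite)

Sixteen checks, each validated against a constructed counterexample that
fails exactly that check (and possibly its logical consequences): 1 mass
production from nothing, 2 leaks with only water open, 3 with water+oxygen,
4 energy generation from nothing (reversible ATP demand kept open via
`keep_bounds`), 5–6 proton pumping from nothing, 7 futile-cycle detection,
8 biomass producibility, 9 biomass precursor availability, 10 realistic
maximal ATP yield per glucose, 11 duplicate reactions, 12 orphan declared
genes (unparseable GPRs are deferred to check 15), 13 demand reactions made
reversible, 14 bound/annotation reversibility mismatches, 15 malformed GPRs,
16 flux-inconsistent (blocked) reactions.

The leak test maximizes a temporary demand for each candidate metabolite with
all boundary imports closed except explicitly opened media; opened media
exchanges are excluded from the probe objective (including them cancels leak
signals — a bug found and fixed via counterexample 2).

## 10. Limitations

- The toy body is a study system for the *methods*: absolute fluxes, BMR and
  energy budgets are toy-scale, not human-scale predictions.
- FBA maxima are used for biomarker and butyrate readouts; they bound what is
  achievable rather than predicting realized fluxes.
- `fastcore` minimality is heuristic (+2 slack documented above).
- The SBML writer stores coupling constraints, organ tags and annotations in
  a JSON sidecar; plain-SBML consumers lose them.
- The microbiome module models four synthetic strains with fixed community
  growth; no dynamic abundance or pH/oxygen gradients.
- Physiological parameters enter as static bounds; no circadian or postprandial
  dynamics beyond the feeding/fasting storage phases.
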