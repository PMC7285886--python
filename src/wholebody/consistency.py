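"""Flux-consistency checking, compact core-preserving extraction, and QC.

``fastcc`` finds the flux-consistent part of a network (every reaction can
carry |v| >= epsilon in some steady state) with a blocked-reaction LP sweep
rather than 2n FVA solves. ``fastcore`` extracts a compact flux-consistent
subnetwork containing a set of core reactions, alternating two LPs (maximise
the number of core reactions above epsilon; minimise the L1 support of
non-core reactions). ``sanity_suite`` runs the 16 structural/functional QC
checks used for organ and whole-body models (leak tests with and without
water/oxygen, energy-from-nothing probes, ATP yield, duplicates, demand
bounds, reversibility bookkeeping, gene-deletion smoke test, consistency).

Consistency analysis operates on the reconstruction level and ignores
coupling constraints (coupling belongs to condition-specific models).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model import (DEFAULT_BIG, FLUX_ZERO_TOL, Metabolite, Reaction,
                    StoichiometricModel, reactions_lost_by_gene_deletion,
                    split_met_id)
from .simulate import LPData, fba

DEFAULT_EPSILON = 1e-4


@dataclass
class CoreReactionSet:
    """Reactions required active in an extracted subnetwork, with evidence."""
    reaction_ids: set[str]
    provenance: dict[str, str] = field(default_factory=dict)  # id -> evidence label

    def __post_init__(self):
        self.reaction_ids = set(self.reaction_ids)

    def __iter__(self):
        return iter(self.reaction_ids)

    def __len__(self):
        return len(self.reaction_ids)


@dataclass
class ConsistencyResult:
    consistent: set[str]
    removed: set[str]
    epsilon: float


class _Arrays:
    """Mutable LP arrays for the sweep algorithms (columns may be flipped)."""

    def __init__(self, model: StoichiometricModel):
        self.rxn_ids = model.reaction_ids
        self.pos = {rid: j for j, rid in enumerate(self.rxn_ids)}
        self.n = len(self.rxn_ids)
        self.S = model.S.tolil()
        self.lb = np.array([r.lb for r in model.reactions], dtype=float)
        self.ub = np.array([r.ub for r in model.reactions], dtype=float)
        self.lb = np.clip(self.lb, -DEFAULT_BIG, DEFAULT_BIG)
        self.ub = np.clip(self.ub, -DEFAULT_BIG, DEFAULT_BIG)

    def irreversible(self) -> np.ndarray:
        return np.flatnonzero(self.lb >= 0)

    def flip(self, js: np.ndarray) -> None:
        if len(js) == 0:
            return
        Scsc = self.S.tocsc()
        for j in js:
            Scsc.data[Scsc.indptr[j]:Scsc.indptr[j + 1]] *= -1.0
        self.S = Scsc.tolil()
        lo = self.lb[js].copy()
        self.lb[js] = -self.ub[js]
        self.ub[js] = -lo

    # LP7: maximise the number of reactions in J with flux >= eps
    def lp7(self, J: np.ndarray, eps: float) -> np.ndarray:
        nJ = len(J)
        S = self.S.tocsr()
        A_eq = sp.hstack([S, sp.csr_matrix((S.shape[0], nJ))], format="csr")
        rows = np.arange(nJ)
        A_ub = sp.hstack([
            sp.csr_matrix((np.full(nJ, -1.0), (rows, J)), shape=(nJ, self.n)),
            sp.identity(nJ, format="csr"),
        ], format="csr")  # z_j - v_j <= 0
        c = np.concatenate([np.zeros(self.n), -np.ones(nJ)])
        bounds = np.column_stack([
            np.concatenate([self.lb, np.zeros(nJ)]),
            np.concatenate([self.ub, np.full(nJ, eps)]),
        ])
        res = linprog(c, A_ub=A_ub, b_ub=np.zeros(nJ), A_eq=A_eq,
                      b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
        if res.status != 0:
            raise RuntimeError(f"LP7 failed with status {res.status} "
                               f"({res.message})")
        return res.x[:self.n]

    # LP3: maximise sum of fluxes over J
    def lp3(self, J: np.ndarray) -> np.ndarray:
        c = np.zeros(self.n)
        c[J] = -1.0
        res = linprog(c, A_eq=self.S.tocsr(), b_eq=np.zeros(self.S.shape[0]),
                      bounds=np.column_stack([self.lb, self.ub]), method="highs")
        if res.status != 0:
            raise RuntimeError(f"LP3 failed with status {res.status}")
        return res.x

    # LP9: minimise L1 support over P subject to v_K >= eps
    def lp9(self, K: np.ndarray, P: np.ndarray, eps: float) -> np.ndarray:
        nP = len(P)
        S = self.S.tocsr()
        A_eq = sp.hstack([S, sp.csr_matrix((S.shape[0], nP))], format="csr")
        rows = np.arange(nP)
        ident = sp.identity(nP, format="csr")
        sel = sp.csr_matrix((np.ones(nP), (rows, P)), shape=(nP, self.n))
        A_ub = sp.vstack([
            sp.hstack([sel, -ident]),    # v_i - t_i <= 0
            sp.hstack([-sel, -ident]),   # -v_i - t_i <= 0
        ], format="csr")
        lb = self.lb.copy()
        lb[K] = np.maximum(lb[K], eps)
        tmax = max(np.max(np.abs(self.lb)), np.max(np.abs(self.ub)), eps)
        bounds = np.column_stack([
            np.concatenate([lb, np.zeros(nP)]),
            np.concatenate([self.ub, np.full(nP, tmax)]),
        ])
        c = np.concatenate([np.zeros(self.n), np.ones(nP)])
        res = linprog(c, A_ub=A_ub, b_ub=np.zeros(2 * nP), A_eq=A_eq,
                      b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
        if res.status != 0:
            raise RuntimeError(f"LP9 failed with status {res.status}")
        return res.x[:self.n]


def fastcc(model: StoichiometricModel, epsilon: float = DEFAULT_EPSILON) -> ConsistencyResult:
    """Partition reactions into flux-consistent and blocked at *epsilon*.

    Equivalent to per-reaction FVA consistency (|vmax| >= eps or |vmin| >= eps)
    but implemented as the LP sweep of the original algorithm.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    ar = _Arrays(model)
    N = np.arange(ar.n)
    supp_tol = 0.99 * epsilon

    A: set[int] = set()
    J = ar.irreversible()
    if len(J):
        v = ar.lp7(J, epsilon)
        A |= set(np.flatnonzero(np.abs(v) >= supp_tol))
    inconsistent_irrev = set(J) - A
    J_set = set(N) - A - inconsistent_irrev

    flipped = False
    singleton = False
    irrev = set(ar.irreversible())
    while J_set:
        J_sorted = np.array(sorted(J_set))
        if singleton:
            Ji = J_sorted[:1]
            v = ar.lp3(Ji)
        else:
            Ji = J_sorted
            v = ar.lp7(Ji, epsilon)
        A |= set(np.flatnonzero(np.abs(v) >= supp_tol))
        if J_set & A:
            J_set -= A
            flipped = False
        else:
            Ji_rev = np.array([j for j in Ji if j not in irrev])
            if flipped or len(Ji_rev) == 0:
                flipped = False
                if singleton:
                    J_set.discard(int(Ji[0]))  # inconsistent
                else:
                    singleton = True
            else:
                ar.flip(Ji_rev)
                flipped = True

    consistent = {ar.rxn_ids[j] for j in A}
    removed = set(ar.rxn_ids) - consistent
    return ConsistencyResult(consistent, removed, epsilon)


def fastcore(model: StoichiometricModel, core: CoreReactionSet | Iterable[str],
             epsilon: float = DEFAULT_EPSILON,
             on_inconsistent_core: str = "warn") -> set[str]:
    """Compact flux-consistent subnetwork containing the core reactions.

    The result contains every flux-consistent core reaction plus a small
    (LP-heuristic, not globally minimal) set of supporting reactions. Core
    reactions that are not flux-consistent in the input model are reported
    via ``on_inconsistent_core``: 'raise', 'warn' (drop after warning) or
    'drop'.
    """
    core_ids = set(core.reaction_ids if isinstance(core, CoreReactionSet) else core)
    if not core_ids:
        raise ValueError("empty core reaction set")
    missing = core_ids - set(model.reaction_ids)
    if missing:
        raise KeyError(f"core reactions not in model: {sorted(missing)}")

    cons = fastcc(model, epsilon)
    bad = core_ids & cons.removed
    if bad:
        msg = f"{len(bad)} core reactions are not flux-consistent: {sorted(bad)}"
        if on_inconsistent_core == "raise":
            raise ValueError(msg)
        if on_inconsistent_core == "warn":
            warnings.warn(msg)
        core_ids -= bad

    sub = extract_submodel(model, cons.consistent)
    ar = _Arrays(sub)
    supp_tol = 0.99 * epsilon
    irrev = set(ar.irreversible())
    C = {ar.pos[r] for r in core_ids}
    N = set(range(ar.n))

    def find_sparse_mode(J: set[int], P: set[int], single: bool) -> set[int]:
        if not J:
            return set()
        Jarr = np.array(sorted(J)[:1] if single else sorted(J))
        v = ar.lp7(Jarr, epsilon)
        K = np.array([j for j in Jarr if v[j] >= supp_tol])
        if len(K) == 0:
            return set()
        v = ar.lp9(K, np.array(sorted(P)), epsilon)
        return set(np.flatnonzero(np.abs(v) >= supp_tol))

    flipped = False
    singleton = False
    J = C & irrev
    P = N - C
    A = find_sparse_mode(J, P, singleton)
    if J - A:
        raise ValueError(f"inconsistent irreversible core reactions: "
                         f"{sorted(ar.rxn_ids[j] for j in J - A)}")
    J = C - A
    while J:
        P = P - A
        A |= find_sparse_mode(J, P, singleton)
        if J & A:
            J = J - A
            flipped = False
        else:
            if singleton:
                Ji_rev = set(sorted(J)[:1]) - irrev
            else:
                Ji_rev = J - irrev
            if flipped or not Ji_rev:
                if singleton:
                    raise RuntimeError("fastcore failed to activate core reaction(s): "
                                       f"{sorted(ar.rxn_ids[j] for j in J)}")
                flipped = False
                singleton = True
            else:
                ar.flip(np.array(sorted(Ji_rev)))
                flipped = True
    return {ar.rxn_ids[j] for j in A}


def extract_submodel(model: StoichiometricModel, reaction_ids: Iterable[str],
                     model_id: Optional[str] = None) -> StoichiometricModel:
    """Submodel induced by a set of reactions (unused metabolites pruned)."""
    keep = set(reaction_ids)
    sub = model.copy(model_id or f"{model.id}_sub")
    sub.remove_reactions([rid for rid in sub.reaction_ids if rid not in keep])
    sub.prune_unused_metabolites()
    return sub


# ---------------------------------------------------------------------------
# Leak test
# ---------------------------------------------------------------------------

def _matches_base(met: Metabolite, base: str) -> bool:
    b = met.base_id
    return b == base or b.endswith("_" + base)


def leak_test(model: StoichiometricModel, tol: float = FLUX_ZERO_TOL,
              open_mets: Iterable[str] = (), exclude: Iterable[str] = (),
              demand_cap: float = 1.0,
              keep_bounds: Iterable[str] = ()) -> list[str]:
    """Metabolites producible from nothing.

    All exchange/sink/demand lower bounds are set to 0 (except boundaries of
    metabolites in *open_mets*, opened to -1e6, and reactions listed in
    *keep_bounds*, left untouched); then the maximum flux of every closed
    exchange and of a temporary demand for every metabolite is probed.
    Opened or kept boundaries supply media, so they are not probed — their
    import flux must not offset a leak in the probe objective. Metabolites in
    *exclude* (base ids) are not reported. Returns the sorted list of leaking
    metabolite ids.
    """
    open_bases = set(open_mets)
    excl_bases = set(exclude) | open_bases
    keep = set(keep_bounds)

    work = model.copy(model.id + "_leak")
    work.coupling = []
    exchange_of: dict[str, str] = {}
    for r in work.boundary_reactions():
        met_id = next(iter(r.stoichiometry))
        met = work.get_metabolite(met_id)
        if r.id in keep:
            continue
        if any(_matches_base(met, b) for b in open_bases):
            r.lb = -DEFAULT_BIG
            continue
        r.lb = max(r.lb, 0.0)
        if r.boundary_kind == "exchange":
            exchange_of[r.id] = met_id

    demand_of: dict[str, str] = {}
    for met in list(work.metabolites):
        rid = f"__leak_DM_{met.id}"
        work.add_reaction(Reaction(rid, {met.id: -1.0}, 0.0, demand_cap))
        demand_of[rid] = met.id

    probe = dict(exchange_of)
    probe.update(demand_of)
    leaking: set[str] = set()
    lp = LPData(work)
    closed: dict[str, tuple] = {}
    for _ in range(len(probe) + 1):
        active = [rid for rid in probe if rid not in closed]
        if not active:
            break
        c = lp.objective_vector({rid: 1.0 for rid in active})
        sol = lp.solve(c, "max", overrides=closed)
        if not sol.optimal or sol.objective_value <= tol:
            break
        hit = [rid for rid in active if sol.fluxes[rid] > tol]
        if not hit:
            break
        for rid in hit:
            met = work.get_metabolite(probe[rid])
            if not any(_matches_base(met, b) for b in excl_bases):
                leaking.add(met.id)
            closed[rid] = (max(lp.lb[lp.rxn_pos[rid]], 0.0), 0.0)
    return sorted(leaking)


# ---------------------------------------------------------------------------
# ATP yield
# ---------------------------------------------------------------------------

_COMPARTMENT_PREFERENCE = ("d", "bc", "e", "luSI", "luLI", "lu", "c")


def _candidate_met(model: StoichiometricModel, base: str) -> Optional[str]:
    cands = [m for m in model.metabolites if _matches_base(m, base)]
    if not cands:
        return None
    rank = {c: i for i, c in enumerate(_COMPARTMENT_PREFERENCE)}
    cands.sort(key=lambda m: (rank.get(m.compartment, 99), m.id))
    return cands[0].id


def _atp_demand_ids(model: StoichiometricModel) -> list[str]:
    return [r.id for r in model.reactions if "DM_atp" in r.id]


def atp_yield(organ_model: StoichiometricModel, carbon_source: str,
              aerobic: bool = True,
              media: Iterable[str] = ("h2o", "pi", "h")) -> float:
    """Maximal mol ATP hydrolysed per mol of *carbon_source* taken up.

    All uptakes are closed; one unit of the source plus water/minerals (and
    O2 when aerobic) are allowed; the maximum flux through the ATP demand is
    returned. A source that cannot be metabolised yields 0.
    """
    work = organ_model.copy(organ_model.id + "_atpyield")
    work.coupling = []
    for r in work.boundary_reactions():
        r.lb = max(r.lb, 0.0)

    media = list(media) + (["o2"] if aerobic else [])
    for base in media:
        for r in work.boundary_reactions():
            met = work.get_metabolite(next(iter(r.stoichiometry)))
            if _matches_base(met, base):
                r.lb = -DEFAULT_BIG

    src = _candidate_met(work, carbon_source)
    if src is None:
        raise KeyError(f"carbon source {carbon_source!r} has no metabolite in model")
    work.add_reaction(Reaction("__src_EX", {src: -1.0}, -1.0, 0.0))

    demands = _atp_demand_ids(work)
    if not demands:
        atp = _candidate_met(work, "atp")
        h2o = _candidate_met(work, "h2o")
        adp = _candidate_met(work, "adp")
        pi = _candidate_met(work, "pi")
        if not all([atp, h2o, adp, pi]):
            raise ValueError("model has no ATP demand and no ATP species to build one")
        work.add_reaction(Reaction("__DM_atp", {atp: -1.0, h2o: -1.0,
                                                adp: 1.0, pi: 1.0}, 0.0, DEFAULT_BIG))
        demands = ["__DM_atp"]

    sol = fba(work, {rid: 1.0 for rid in demands}, "max")
    if not sol.optimal:
        return 0.0
    return float(sol.objective_value)


# ---------------------------------------------------------------------------
# Sanity suite (16 QC checks)
# ---------------------------------------------------------------------------

@dataclass
class CheckResult:
    number: int
    name: str
    passed: bool
    detail: str = ""


@dataclass
class SanityReport:
    results: list[CheckResult]

    @property
    def all_passed(self) -> bool:
        return all(r.passed for r in self.results)

    def failed(self) -> list[CheckResult]:
        return [r for r in self.results if not r.passed]

    def __repr__(self) -> str:
        n_ok = sum(r.passed for r in self.results)
        return f"<SanityReport: {n_ok}/{len(self.results)} checks passed>"


def _proton_mets(model: StoichiometricModel, compartment: str) -> list[str]:
    return [m.id for m in model.metabolites
            if m.compartment == compartment and _matches_base(m, "h")]


def _probe_max_demands(model: StoichiometricModel, met_ids: list[str],
                       tol: float) -> list[str]:
    """Max temporary demand for each metabolite with boundaries closed;
    returns those with positive max."""
    if not met_ids:
        return []
    work = model.copy(model.id + "_probe")
    work.coupling = []
    for r in work.boundary_reactions():
        r.lb = max(r.lb, 0.0)
    probes = {}
    for mid in met_ids:
        rid = f"__probe_DM_{mid}"
        work.add_reaction(Reaction(rid, {mid: -1.0}, 0.0, 1.0))
        probes[rid] = mid
    lp = LPData(work)
    hits: set[str] = set()
    closed: dict[str, tuple] = {}
    for _ in range(len(probes) + 1):
        active = {rid: 1.0 for rid in probes if rid not in closed}
        if not active:
            break
        sol = lp.solve(lp.objective_vector(active), "max", overrides=closed)
        if not sol.optimal or sol.objective_value <= tol:
            break
        found = [rid for rid in active if sol.fluxes[rid] > tol]
        if not found:
            break
        for rid in found:
            hits.add(probes[rid])
            closed[rid] = (0.0, 0.0)
    return sorted(hits)


def _objective_reactions(model: StoichiometricModel) -> dict[str, float]:
    if model.objective:
        return dict(model.objective)
    biomass = [r.id for r in model.reactions if "biomass" in r.id.lower()]
    return {rid: 1.0 for rid in biomass}


def sanity_suite(model: StoichiometricModel, tol: float = FLUX_ZERO_TOL,
                 epsilon: float = DEFAULT_EPSILON) -> SanityReport:
    """Run the 16-check QC suite on a reconstruction-level model."""
    results: list[CheckResult] = []

    def add(number, name, passed, detail=""):
        results.append(CheckResult(number, name, bool(passed), detail))

    # 1-3: leak tests (closed; h2o open; h2o+o2 open)
    leaks = leak_test(model, tol)
    add(1, "fastLeakTest", not leaks, f"leaking: {leaks[:5]}" if leaks else "")
    leaks = leak_test(model, tol, open_mets=["h2o"])
    add(2, "no leak with h2o open", not leaks,
        f"leaking: {leaks[:5]}" if leaks else "")
    leaks = leak_test(model, tol, open_mets=["h2o", "o2"])
    add(3, "no leak with h2o and o2 open", not leaks,
        f"leaking: {leaks[:5]}" if leaks else "")

    # 4: closed boundaries with reversible ATP demand must not create mass
    work = model.copy(model.id + "_qc4")
    dm = _atp_demand_ids(work)
    for rid in dm:
        work.get_reaction(rid).lb = -DEFAULT_BIG
    leaks = leak_test(work, tol, exclude=["atp", "adp", "amp", "pi", "h", "h2o"],
                      keep_bounds=dm)
    # biomass dummy-objective metabolites are bookkeeping products of the
    # (legitimately runnable) ATP-hydrolysing biomass reactions, not mass
    leaks = [m for m in leaks if "_dummy_objective" not in m]
    add(4, "no leak with reversible ATP demand", not leaks,
        f"leaking: {leaks[:5]}" if leaks else "")

    # 5-6: no proton production from nothing
    hm = _probe_max_demands(model, _proton_mets(model, "m"), tol)
    add(5, "no h[m] from nothing", not hm, f"producible: {hm[:5]}" if hm else "")
    hc = _probe_max_demands(model, _proton_mets(model, "c"), tol)
    add(6, "no h[c] from nothing", not hc, f"producible: {hc[:5]}" if hc else "")

    # 7: no proton consumption into nothing (EX_h closed, min demand >= 0)
    work = model.copy(model.id + "_qc7")
    work.coupling = []
    for r in work.boundary_reactions():
        r.lb = max(r.lb, 0.0)
        met = work.get_metabolite(next(iter(r.stoichiometry)))
        if _matches_base(met, "h"):
            r.ub = 0.0
    sinks = []
    for mid in _proton_mets(work, "c"):
        rid = f"__probe_rev_DM_{mid}"
        work.add_reaction(Reaction(rid, {mid: -1.0}, -1.0, 0.0))
        sinks.append(rid)
    if sinks:
        sol = fba(work, {rid: 1.0 for rid in sinks}, "min")
        ok = sol.optimal and sol.objective_value >= -tol
        add(7, "no h[c] consumed from nothing", ok,
            "" if ok else f"min total = {sol.objective_value if sol.optimal else sol.status}")
    else:
        add(7, "no h[c] consumed from nothing", True, "no h[c] in model")

    # 8-9: metabolic objectives with open / closed sinks
    obj = _objective_reactions(model)
    if obj:
        for number, mode in ((8, "open"), (9, "closed")):
            work = model.copy(f"{model.id}_qc{number}")
            for r in work.boundary_reactions():
                if r.boundary_kind == "exchange":
                    r.lb = -DEFAULT_BIG
                elif r.boundary_kind == "sink":
                    r.lb = -DEFAULT_BIG if mode == "open" else 0.0
            sol = fba(work, obj, "max")
            ok = sol.optimal and sol.objective_value > tol
            add(number, f"objective feasible with {mode} sinks", ok,
                "" if ok else f"max = {sol.objective_value if sol.optimal else sol.status}")
    else:
        add(8, "objective feasible with open sinks", True, "no objective")
        add(9, "objective feasible with closed sinks", True, "no objective")

    # 10: realistic aerobic glucose ATP yield
    if _candidate_met(model, "glc_D"):
        try:
            y = atp_yield(model, "glc_D", aerobic=True)
            add(10, "aerobic glucose ATP yield realistic", 0 < y <= 40.0,
                f"yield = {y:.3f}")
        except (KeyError, ValueError) as exc:
            add(10, "aerobic glucose ATP yield realistic", False, str(exc))
    else:
        add(10, "aerobic glucose ATP yield realistic", True, "no glucose in model")

    # 11: duplicate reactions
    seen: dict[tuple, str] = {}
    dups = []
    for r in model.reactions:
        key = tuple(sorted((m, round(c, 9)) for m, c in r.stoichiometry.items()))
        if key in seen:
            dups.append((seen[key], r.id))
        else:
            seen[key] = r.id
    add(11, "no duplicate reactions", not dups, f"duplicates: {dups[:5]}" if dups else "")

    # 12: no genes without reactions (empty columns in the rxn-gene matrix)
    gpr_genes = set()
    for r in model.reactions:
        if r.gpr:
            from .model import GprExpression
            try:
                gpr_genes |= GprExpression.parse(r.gpr).genes()
            except ValueError:
                continue  # malformed GPRs are check 15's failure mode
    declared = set(model.annotations.get("genes", ()))
    orphans = sorted(declared - gpr_genes)
    add(12, "no genes without reactions", not orphans,
        f"orphan genes: {orphans[:5]}" if orphans else "")

    # 13: demand reactions have lb >= 0
    bad = [r.id for r in model.boundary_reactions(["demand"]) if r.lb < 0]
    add(13, "demand reactions have lb >= 0", not bad, f"violators: {bad[:5]}" if bad else "")

    # 14: reversibility annotation consistent with lb
    rev_ann = model.annotations.get("rev", {})
    bad = [rid for rid, rev in rev_ann.items()
           if model.has_reaction(rid) and bool(rev) != (model.get_reaction(rid).lb < 0)]
    add(14, "rev flags consistent with lb", not bad, f"violators: {bad[:5]}" if bad else "")

    # 15: single-gene deletion runs smoothly
    try:
        for gene in sorted(model.genes):
            reactions_lost_by_gene_deletion(model, {gene})
        add(15, "single-gene deletion smoke test", True)
    except Exception as exc:  # noqa: BLE001 - a smoke test reports, not raises
        add(15, "single-gene deletion smoke test", False, str(exc))

    # 16: flux consistency
    removed = fastcc(model, epsilon).removed
    add(16, "flux consistency", not removed,
        f"blocked: {sorted(removed)[:5]}" if removed else "")

    return SanityReport(results)


# ---------------------------------------------------------------------------
# Draft extraction with feeding/fasting scenarios
# ---------------------------------------------------------------------------

BIOFLUID_CODES = ("d", "lu", "luSI", "luLI", "fe", "bc", "bp", "bd",
                  "csf", "u", "sw", "mi", "a")


def _scenario_bounds(model: StoichiometricModel, scenario: str) -> None:
    """Apply feeding/fasting bound presets in place.

    feeding: dietary exchanges open (lb=-1e6, ub=0), storage sinks act as
    demands (lb=0, ub=1e6). fasting: dietary exchanges closed, storage sinks
    release only (lb=-1e6, ub=0).
    """
    for r in model.reactions:
        stem = r.id if not r.organ else r.id[len(r.organ):]
        if stem.startswith("Diet_EX_"):
            if scenario == "feeding":
                r.lb, r.ub = -DEFAULT_BIG, 0.0
            else:
                r.lb = r.ub = 0.0
        elif r.boundary_kind == "sink":
            if scenario == "feeding":
                r.lb, r.ub = 0.0, DEFAULT_BIG
            else:
                r.lb, r.ub = -DEFAULT_BIG, 0.0


def build_wbm_draft(meta: StoichiometricModel, core: CoreReactionSet,
                    scenarios: Iterable[str] = ("feeding", "fasting"),
                    epsilon: float = DEFAULT_EPSILON) -> StoichiometricModel:
    """Extract a draft whole-body model as the union of per-scenario
    fastcore subnetworks, with a biofluid-closure second pass.

    Per scenario: apply the scenario bound preset, run fastcore on the core;
    then drop the biofluid demand placeholders, re-core on everything kept and
    re-extract — this forces every biofluid metabolite to be transported,
    excreted, or catabolised rather than served by a placeholder demand.
    The returned model is the union of the scenario subnetworks; placeholder
    demands are removed, and biofluid metabolites left without any producing
    or consuming reaction are flagged in ``annotations['draft_report']``.
    """
    placeholder_demands = {
        r.id for r in meta.boundary_reactions(["demand"])
        if split_met_id(next(iter(r.stoichiometry)))[1] in BIOFLUID_CODES}

    union: set[str] = set()
    feasible_scenarios = []
    for scenario in scenarios:
        work = meta.copy(f"{meta.id}_{scenario}")
        _scenario_bounds(work, scenario)
        core_ids = set(core.reaction_ids) & set(work.reaction_ids)
        try:
            first = fastcore(work, core_ids, epsilon, on_inconsistent_core="warn")
        except ValueError:
            continue
        # second pass: no placeholder demands, everything kept becomes core
        work2 = work.copy()
        work2.remove_reactions(placeholder_demands)
        core2 = (first - placeholder_demands) & set(work2.reaction_ids)
        second = fastcore(work2, core2, epsilon, on_inconsistent_core="warn")
        union |= second
        feasible_scenarios.append(scenario)

    if not feasible_scenarios:
        raise ValueError("core infeasible under every scenario")

    draft = extract_submodel(meta, union, f"{meta.id}_draft")
    unserved = []
    met_use: dict[str, int] = {}
    for r in draft.reactions:
        for mid in r.stoichiometry:
            met_use[mid] = met_use.get(mid, 0) + 1
    for met in meta.metabolites:
        if met.compartment in BIOFLUID_CODES and met_use.get(met.id, 0) == 0:
            # only report metabolites that had a placeholder demand
            if any(meta.has_reaction(rid) and
                   next(iter(meta.get_reaction(rid).stoichiometry)) == met.id
                   for rid in placeholder_demands):
                unserved.append(met.id)
    draft.annotations["draft_report"] = {
        "scenarios": feasible_scenarios,
        "unserved_biofluid_metabolites": sorted(unserved),
    }
    return draft
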