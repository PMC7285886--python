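"""Hand-built and random models used by the unit and acceptance tests:
small networks with known optima, random toys for the fastcc/fastcore
oracle battery, and one constructed counterexample per sanity check."""

import itertools

from wholebody import (DEFAULT_BIG, Metabolite, Reaction, StoichiometricModel,
                       extract_submodel, fva)

BIG = DEFAULT_BIG


def model_from(reactions, model_id="toy", objective=None, annotations=None):
    """Build a model from {rxn_id: (stoich, lb, ub)}; metabolites inferred."""
    m = StoichiometricModel(model_id)
    mets = sorted({mid for stoich, _, _ in reactions.values() for mid in stoich})
    for mid in mets:
        m.add_metabolite(Metabolite(mid))
    for rid, (stoich, lb, ub) in reactions.items():
        m.add_reaction(Reaction(rid, dict(stoich), lb, ub))
    if objective:
        m.objective = dict(objective)
    if annotations:
        m.annotations.update(annotations)
    return m


def linear_chain(n=3):
    """EX_in <-> A0 -> A1 -> ... -> An -> EX_out, all max flux 10."""
    rxns = {"EX_in": ({"A0[c]": -1.0}, -10.0, 0.0)}
    for i in range(n):
        rxns[f"R{i}"] = ({f"A{i}[c]": -1.0, f"A{i+1}[c]": 1.0}, 0.0, BIG)
    rxns["EX_out"] = ({f"A{n}[c]": -1.0}, 0.0, BIG)
    return model_from(rxns, "chain")


# ---------------------------------------------------------------------------
# Random toys for the consistency oracle battery
# ---------------------------------------------------------------------------

def random_toy(rng, max_reactions=30):
    """Random sparse network: internal conversions plus a few exchanges.
    Not guaranteed consistent — that is the point of the fastcc battery."""
    n_mets = int(rng.integers(3, 9))
    n_rxns = int(rng.integers(4, max_reactions + 1))
    mets = [f"M{i}[c]" for i in range(n_mets)]
    rxns = {}
    n_ex = int(rng.integers(1, min(4, n_mets) + 1))
    for k, i in enumerate(rng.choice(n_mets, size=n_ex, replace=False)):
        lb = -10.0 if rng.random() < 0.7 else 0.0
        rxns[f"EX{k}"] = ({mets[int(i)]: -1.0}, lb, 10.0)
    for k in range(n_rxns - n_ex):
        size = int(rng.integers(2, min(4, n_mets) + 1))
        chosen = rng.choice(n_mets, size=size, replace=False)
        stoich = {}
        for j, i in enumerate(chosen):
            coeff = float(rng.choice([-2.0, -1.0, 1.0, 2.0]))
            if j == 0:
                coeff = -abs(coeff)
            elif j == 1:
                coeff = abs(coeff)
            stoich[mets[int(i)]] = coeff
        lb = -10.0 if rng.random() < 0.4 else 0.0
        rxns[f"R{k}"] = (stoich, lb, 10.0)
    return model_from(rxns, "random_toy")


def random_consistent_toy(rng, max_reactions=12):
    """Random branched pathway network, guaranteed flux-consistent after
    trimming: chains with exchanges at both ends plus random shortcuts."""
    n = int(rng.integers(3, max(4, max_reactions - 3)))
    mets = [f"M{i}[c]" for i in range(n + 1)]
    rxns = {"EX_in": ({mets[0]: -1.0}, -10.0, 0.0),
            "EX_out": ({mets[n]: -1.0}, 0.0, 10.0)}
    for i in range(n):
        lb = -10.0 if rng.random() < 0.3 else 0.0
        rxns[f"R{i}"] = ({mets[i]: -1.0, mets[i + 1]: 1.0}, lb, 10.0)
    k = 0
    while len(rxns) < max_reactions and k < 4:
        i, j = sorted(rng.choice(n + 1, size=2, replace=False))
        if j > i:
            rxns[f"S{k}"] = ({mets[int(i)]: -1.0, mets[int(j)]: 1.0}, 0.0, 10.0)
        k += 1
    return model_from(rxns, "random_consistent_toy")


def fva_consistency_partition(model, tol=1e-6):
    """Oracle: a reaction is flux-consistent iff FVA shows |v| can exceed tol."""
    result = fva(model)
    consistent = set()
    for rid in model.reaction_ids:
        if result.vmax(rid) > tol or result.vmin(rid) < -tol:
            consistent.add(rid)
    return consistent


def subnetwork_supports_core(model, subset, core, epsilon):
    """True iff every core reaction can carry |v| >= epsilon inside the
    subnetwork induced by *subset*."""
    sub = extract_submodel(model, subset)
    result = fva(sub, core)
    return all(result.vmax(rid) >= epsilon or result.vmin(rid) <= -epsilon
               for rid in core)


def brute_force_min_support(model, core, epsilon):
    """Size of the smallest reaction subset containing the core in which every
    core reaction stays flux-consistent (exhaustive search by subset size)."""
    core = sorted(core)
    non_core = [rid for rid in model.reaction_ids if rid not in core]
    for extra in range(len(non_core) + 1):
        for combo in itertools.combinations(non_core, extra):
            if subnetwork_supports_core(model, set(core) | set(combo),
                                        core, epsilon):
                return len(core) + extra
    return None


# ---------------------------------------------------------------------------
# One counterexample per sanity check (each fails its targeted check)
# ---------------------------------------------------------------------------

def sanity_counterexamples():
    """{check number: model that must fail that check}."""
    out = {}

    # 1: metabolite producible from nothing with all boundaries closed
    out[1] = model_from({"MAKE_b": ({"b[c]": 1.0}, 0.0, BIG)}, "ce1")

    # 2: leak only when water is open
    out[2] = model_from({
        "EX_h2o": ({"h2o[c]": -1.0}, -BIG, BIG),
        "CONV": ({"h2o[c]": -1.0, "b[c]": 1.0}, 0.0, BIG),
    }, "ce2")

    # 3: leak only when water and oxygen are open
    out[3] = model_from({
        "EX_h2o": ({"h2o[c]": -1.0}, -BIG, BIG),
        "EX_o2": ({"o2[c]": -1.0}, -BIG, BIG),
        "CONV": ({"h2o[c]": -1.0, "o2[c]": -1.0, "b[c]": 1.0}, 0.0, BIG),
    }, "ce3")

    # 4: reversible ATP demand creates non-energy mass
    out[4] = model_from({
        "DM_atp": ({"atp[c]": -1.0}, 0.0, BIG),
        "HYDRO": ({"atp[c]": -1.0, "adp[c]": 1.0, "pi[c]": 1.0, "b[c]": 1.0},
                  0.0, BIG),
    }, "ce4")

    # 5/6: protons from nothing (mitochondrial / cytosolic)
    out[5] = model_from({"PUMP": ({"h[m]": 1.0}, 0.0, BIG)}, "ce5")
    out[6] = model_from({"PUMP": ({"h[c]": 1.0}, 0.0, BIG)}, "ce6")

    # 7: protons consumed into nothing
    out[7] = model_from({
        "R1": ({"h[c]": -1.0, "a[c]": -1.0, "b[c]": 1.0}, 0.0, BIG),
        "R2": ({"b[c]": -1.0, "a[c]": 1.0}, 0.0, BIG),
    }, "ce7")

    # 8: objective cannot carry flux even with open sinks
    out[8] = model_from({"biomass_x": ({"a[c]": -1.0, "obj[c]": 1.0}, 0.0, BIG)},
                        "ce8", objective={"biomass_x": 1.0})

    # 9: objective works on sink supply only (fails when sinks close)
    out[9] = model_from({
        "sink_a": ({"a[c]": -1.0}, -BIG, BIG),
        "biomass_x": ({"a[c]": -1.0, "obj[c]": 1.0}, 0.0, BIG),
        "DM_obj": ({"obj[c]": -1.0}, 0.0, BIG),
    }, "ce9", objective={"biomass_x": 1.0})

    # 10: unrealistic aerobic glucose ATP yield (50 > 40)
    out[10] = model_from({
        "EX_glc_D": ({"glc_D[e]": -1.0}, -BIG, BIG),
        "t_glc": ({"glc_D[e]": -1.0, "glc_D[c]": 1.0}, 0.0, BIG),
        "EX_h2o": ({"h2o[c]": -1.0}, -BIG, BIG),
        "EX_pi": ({"pi[c]": -1.0}, -BIG, BIG),
        "GLYC50": ({"glc_D[c]": -1.0, "adp[c]": -50.0, "pi[c]": -50.0,
                    "atp[c]": 50.0}, 0.0, BIG),
        "DM_atp": ({"atp[c]": -1.0, "h2o[c]": -1.0, "adp[c]": 1.0,
                    "pi[c]": 1.0}, 0.0, BIG),
    }, "ce10")

    # 11: duplicated reaction column
    out[11] = model_from({
        "R1": ({"a[c]": -1.0, "b[c]": 1.0}, 0.0, BIG),
        "R1_copy": ({"a[c]": -1.0, "b[c]": 1.0}, 0.0, BIG),
    }, "ce11")

    # 12: declared gene without any reaction
    out[12] = model_from({"R1": ({"a[c]": -1.0, "b[c]": 1.0}, 0.0, BIG)},
                         "ce12", annotations={"genes": ["ORPHAN_GENE"]})

    # 13: demand reaction with negative lower bound
    out[13] = model_from({"DM_b": ({"b[c]": -1.0}, -1.0, BIG)}, "ce13")

    # 14: reversibility annotation contradicting the bounds
    out[14] = model_from({"R1": ({"a[c]": -1.0, "b[c]": 1.0}, 0.0, BIG)},
                         "ce14", annotations={"rev": {"R1": True}})

    # 15: malformed GPR breaks the gene-deletion smoke test
    ce15 = model_from({"R1": ({"a[c]": -1.0, "b[c]": 1.0}, 0.0, BIG)}, "ce15")
    ce15.get_reaction("R1").gpr = "and and"  # bypasses construction-time checks
    out[15] = ce15

    # 16: dead-end reaction (blocked at any epsilon)
    out[16] = model_from({
        "EX_a": ({"a[c]": -1.0}, -BIG, BIG),
        "DEAD": ({"a[c]": -1.0, "b[c]": 1.0}, 0.0, BIG),
    }, "ce16")
    return out
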