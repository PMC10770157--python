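"""Independent oracles used by the tests.

Deliberately implemented without the package's LP or parser code paths:
routing costs come from exhaustive enumeration of simple substrate→product
paths in the reaction graph, and GPR trees are evaluated by direct
recursion over an explicit nested-list structure.
"""

from __future__ import annotations

import networkx as nx


def enumerate_routings(model, target_metabolite: str, substrate: str = "S"):
    """All simple reaction paths from substrate to target in a unit-stoichiometry network.

    Only valid for networks whose internal reactions consume one metabolite
    and produce one (the toy-generator family). Returns a list of reaction-id
    tuples.
    """
    g = nx.MultiDiGraph()
    for r in model.reactions:
        if r.is_exchange:
            continue
        subs = [m for m, c in r.stoichiometry.items() if c < 0]
        prods = [m for m, c in r.stoichiometry.items() if c > 0]
        assert len(subs) == 1 and len(prods) == 1, "oracle only handles unit chains"
        g.add_edge(subs[0], prods[0], reaction=r.id)
    if target_metabolite not in g or substrate not in g:
        return []
    return [
        tuple(g.edges[e]["reaction"] for e in path)
        for path in nx.all_simple_edge_paths(g, substrate, target_metabolite)
    ]


def best_routing(model, target_metabolite: str, weights: dict, flux: float, tol: float = 1e-9):
    """Cheapest routing under Σ w·v: (min internal weighted cost, active count).

    The cost of pushing ``flux`` through a path is flux · Σ w over its
    reactions; among weight-optimal paths the one with the fewest reactions
    is reported (the canonicalisation rule's secondary total-flux
    minimisation picks exactly that path).
    """
    routings = enumerate_routings(model, target_metabolite)
    assert routings, f"no routing to {target_metabolite}"
    costs = [flux * sum(weights[r] for r in path) for path in routings]
    best = min(costs)
    lengths = [len(p) for p, c in zip(routings, costs) if c <= best + tol]
    return best, min(lengths)


def eval_nested_gpr(node, values):
    """Recursive min/max evaluation of a nested-list GPR: ['and'|'or', child, ...] or gene str."""
    if isinstance(node, str):
        return values.get(node)
    op, *children = node
    vals = [eval_nested_gpr(c, values) for c in children]
    if op == "and":
        return None if any(v is None for v in vals) else min(vals)
    defined = [v for v in vals if v is not None]
    return max(defined) if defined else None


def nested_to_string(node) -> str:
    if isinstance(node, str):
        return node
    op, *children = node
    return "(" + f" {op} ".join(nested_to_string(c) for c in children) + ")"
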