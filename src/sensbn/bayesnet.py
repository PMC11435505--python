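"""Discrete Bayesian networks: structures, parameter learning, exact inference.

Three network structures ship with the package, all sharing a top-down
diagnostic layout inherited from the ITS-3 family of skin-sensitisation
networks: the 4-class potency target PEC3_CLASS is the root; it parents one
latent node per evidence group (CYTOX for KeratinoSens, CYSTEINE for
DPRA/kDPRA, HCLAT for h-CLAT, BIOAV for the physico-chemical block) and the
in silico node; each latent node parents its discretised indicators.  The
in silico branch is what distinguishes the variants:

* ``baseline`` — a five-level TIMES-SS call, no kDPRA nodes;
* ``A``        — a ternary Skin Doctor CP call; kDPRA nodes (KMAX,
                 KDPRA_CLASS) attached to CYSTEINE exactly like DPRA_CYS;
* ``B``        — a latent INSILICO node over Skin Doctor CP and Derek Nexus;
                 kDPRA nodes as in A.

The adjacency lives in editable JSON files under ``sensbn/structures/`` so it
can be revised without code changes.  Parameters are learned by Dirichlet
(K2-style) smoothing with a per-state pseudo-count: families are counted over
rows where the node and all its parents are observed (available-case
analysis), and a never-observed parent configuration falls back to the
uniform distribution implied by the prior.  Inference is exact variable
elimination with a greedy min-size elimination order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np

MODEL_IDS = ("baseline", "A", "B")

#: Continuous-node -> CSV column (all discretised with CAIM before learning).
CONTINUOUS_NODE_COLUMNS: dict[str, str] = {
    "DPRA_CYS": "dpra_cys", "DPRA_LYS": "dpra_lys", "KMAX": "kdpra_kmax",
    "KS_EC15": "ks_ec15", "KS_EC3": "ks_ec3", "KS_IC50": "ks_ic50",
    "HCLAT_EC150": "hclat_ec150", "HCLAT_EC200": "hclat_ec200",
    "HCLAT_CV75": "hclat_cv75",
    "LOG_KOW": "log_kow", "LOG_D": "log_d_ph7", "WS": "ws_ph7",
    "PROTEIN_BINDING": "protein_binding", "F_ION": "f_ion",
}

#: Categorical-node -> CSV column (consumed as supplied, never discretised).
CATEGORICAL_NODE_COLUMNS: dict[str, str] = {
    "KDPRA_CLASS": "kdpra_class", "SKIN_DOCTOR": "skin_doctor_class",
    "DEREK": "derek_class", "TIMES": "times_class",
}


@dataclass
class NetworkSpec:
    """DAG over named discrete nodes with per-node cardinalities."""

    nodes: dict[str, int]
    edges: list[tuple[str, str]]
    target: str = "PEC3_CLASS"
    latent: set[str] = field(default_factory=set)

    def __post_init__(self):
        for a, b in self.edges:
            for x in (a, b):
                if x not in self.nodes:
                    raise ValueError(f"edge endpoint {x!r} not declared")
        if self.target not in self.nodes:
            raise ValueError(f"target node {self.target!r} not declared")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        order = self.topological_order()
        if len(order) != len(self.nodes):
            raise ValueError("network graph contains a cycle")

    def parents(self, node: str) -> list[str]:
        return [a for a, b in self.edges if b == node]

    def children(self, node: str) -> list[str]:
        return [b for a, b in self.edges if a == node]

    def topological_order(self) -> list[str]:
        indeg = {n: 0 for n in self.nodes}
        for _, b in self.edges:
            indeg[b] += 1
        queue = [n for n in self.nodes if indeg[n] == 0]
        order = []
        while queue:
            n = queue.pop(0)
            order.append(n)
            for c in self.children(n):
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        return order

    def with_cardinalities(self, cards: Mapping[str, int]) -> "NetworkSpec":
        nodes = dict(self.nodes)
        for k, v in cards.items():
            if k not in nodes:
                raise ValueError(f"unknown node {k!r}")
            nodes[k] = int(v)
        return NetworkSpec(nodes, list(self.edges), self.target, set(self.latent))

    def to_json(self) -> dict:
        return {"nodes": self.nodes, "edges": [list(e) for e in self.edges],
                "target": self.target, "latent": sorted(self.latent)}

    @classmethod
    def from_json(cls, d: dict) -> "NetworkSpec":
        return cls(nodes={k: (None if v is None else int(v))
                          for k, v in d["nodes"].items()},
                   edges=[tuple(e) for e in d["edges"]],
                   target=d.get("target", "PEC3_CLASS"),
                   latent=set(d.get("latent", [])))


def build_structure(model_id: str, include_kdpra: bool = True) -> NetworkSpec:
    """Load one of the bundled structures (``baseline``, ``A`` or ``B``).

    ``include_kdpra=False`` strips the KMAX and KDPRA_CLASS nodes from models
    A/B, the ablation used to quantify the kDPRA contribution.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")
    fname = {"baseline": "baseline.json", "A": "model_a.json", "B": "model_b.json"}
    text = resources.files("sensbn.structures").joinpath(fname[model_id]).read_text()
    spec = NetworkSpec.from_json(json.loads(text))
    if not include_kdpra:
        drop = {"KMAX", "KDPRA_CLASS"} & set(spec.nodes)
        spec = NetworkSpec(
            nodes={k: v for k, v in spec.nodes.items() if k not in drop},
            edges=[e for e in spec.edges if e[0] not in drop and e[1] not in drop],
            target=spec.target, latent=spec.latent - drop)
    return spec


def latent_member_map(spec: NetworkSpec) -> dict[str, list[str]]:
    """Latent node -> its observable children (the LCA indicator group)."""
    return {ln: [c for c in spec.children(ln) if c not in spec.latent]
            for ln in sorted(spec.latent)}


# ---------------------------------------------------------------------------
# Parameter learning
# ---------------------------------------------------------------------------

@dataclass
class CPTSet:
    """Per-node conditional probability tables.

    ``tables[node]`` has shape ``(*parent_cards, card)``, axes ordered as
    ``parents(node) + [node]``; every distribution along the last axis sums
    to 1.
    """

    parents: dict[str, list[str]]
    tables: dict[str, np.ndarray]

    def to_json(self) -> dict:
        return {"parents": self.parents,
                "tables": {k: v.tolist() for k, v in self.tables.items()}}

    @classmethod
    def from_json(cls, d: dict) -> "CPTSet":
        return cls(parents={k: list(v) for k, v in d["parents"].items()},
                   tables={k: np.asarray(v, dtype=float)
                           for k, v in d["tables"].items()})


def learn_parameters(spec: NetworkSpec, table, pseudo_count: float = 1.0) -> CPTSet:
    """Bayesian (Dirichlet posterior-mean) CPT estimation from incomplete data.

    ``table`` maps node name -> integer state array with missing as -1 (a
    pandas DataFrame of such columns also works).  For each family, counts
    come from the rows where the node and all its parents are observed;
    entries are ``(count + pseudo_count) / (config_total + pseudo_count * card)``.
    """
    if pseudo_count <= 0:
        raise ValueError("pseudo_count must be positive")
    cols = {n: np.asarray(table[n], dtype=np.int64) for n in spec.nodes
            if n in table}
    missing = [n for n in spec.nodes if n not in cols]
    n_rows = len(next(iter(cols.values()))) if cols else 0

    parents = {n: spec.parents(n) for n in spec.nodes}
    tables: dict[str, np.ndarray] = {}
    for node, pars in parents.items():
        card = spec.nodes[node]
        shape = tuple(spec.nodes[p] for p in pars) + (card,)
        counts = np.zeros(shape, dtype=float)
        fam = pars + [node]
        if all(f in cols for f in fam) and n_rows:
            mat = np.stack([cols[f] for f in fam], axis=1)
            ok = (mat >= 0).all(axis=1)
            for f, c in zip(fam, mat.T):
                ok &= c < spec.nodes[f]
            np.add.at(counts, tuple(mat[ok].T), 1.0)
        counts += pseudo_count
        tables[node] = counts / counts.sum(axis=-1, keepdims=True)
    return CPTSet(parents=parents, tables=tables)


# ---------------------------------------------------------------------------
# Exact inference (variable elimination)
# ---------------------------------------------------------------------------

class Factor:
    """A non-negative table over an ordered tuple of variables."""

    __slots__ = ("vars", "values")

    def __init__(self, vars: tuple[str, ...], values: np.ndarray):
        self.vars = tuple(vars)
        self.values = np.asarray(values, dtype=float)

    def multiply(self, other: "Factor") -> "Factor":
        out_vars = self.vars + tuple(v for v in other.vars if v not in self.vars)
        a = self._expand(out_vars)
        b = other._expand(out_vars)
        return Factor(out_vars, a * b)

    def _expand(self, out_vars: tuple[str, ...]) -> np.ndarray:
        # permute own axes to their positions in out_vars, add length-1 axes
        perm = [self.vars.index(v) for v in out_vars if v in self.vars]
        arr = np.transpose(self.values, perm)
        shape = [arr.shape[[v for v in out_vars if v in self.vars].index(v)]
                 if v in self.vars else 1 for v in out_vars]
        return arr.reshape(shape)

    def marginalise(self, var: str) -> "Factor":
        i = self.vars.index(var)
        return Factor(self.vars[:i] + self.vars[i + 1:], self.values.sum(axis=i))

    def reduce(self, var: str, state: int) -> "Factor":
        i = self.vars.index(var)
        return Factor(self.vars[:i] + self.vars[i + 1:],
                      np.take(self.values, state, axis=i))


def _cpt_factors(spec: NetworkSpec, cpts: CPTSet,
                 evidence: Mapping[str, int]) -> list[Factor]:
    for node, state in evidence.items():
        if node not in spec.nodes:
            raise ValueError(f"evidence on unknown node {node!r}")
        if not (0 <= int(state) < spec.nodes[node]):
            raise ValueError(
                f"evidence state {state} out of range for node {node!r} "
                f"(cardinality {spec.nodes[node]})")
    factors = []
    for node, tab in cpts.tables.items():
        f = Factor(tuple(cpts.parents[node]) + (node,), tab)
        for v in list(f.vars):
            if v in evidence:
                f = f.reduce(v, int(evidence[v]))
        factors.append(f)
    return factors


def infer(spec: NetworkSpec, cpts: CPTSet, evidence: Mapping[str, int],
          query: Optional[str] = None) -> np.ndarray:
    """Exact posterior over ``query`` (default: the target) given evidence.

    Unobserved variables are marginalised out by variable elimination; the
    returned vector sums to 1.
    """
    query = query or spec.target
    if query in evidence:
        raise ValueError(f"query node {query!r} must not be in evidence")
    factors = _cpt_factors(spec, cpts, evidence)
    hidden = [n for n in spec.nodes if n != query and n not in evidence]

    while hidden:
        # greedy: eliminate the variable whose product factor is smallest
        best, best_size = None, None
        for h in hidden:
            involved = [f for f in factors if h in f.vars]
            vs = set().union(*(f.vars for f in involved)) if involved else set()
            size = int(np.prod([spec.nodes[v] for v in vs])) if vs else 1
            if best_size is None or size < best_size:
                best, best_size = h, size
        involved = [f for f in factors if best in f.vars]
        factors = [f for f in factors if best not in f.vars]
        if involved:
            prod = involved[0]
            for f in involved[1:]:
                prod = prod.multiply(f)
            factors.append(prod.marginalise(best))
        hidden.remove(best)

    result = Factor((), np.array(1.0))
    for f in factors:
        result = result.multiply(f)
    if result.vars != (query,):
        result_vals = result._expand((query,)).reshape(spec.nodes[query])
    else:
        result_vals = result.values
    total = result_vals.sum()
    if total <= 0:
        raise ValueError("evidence has zero probability under the model")
    return result_vals / total
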