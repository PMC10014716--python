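"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration and direct
formula evaluation — and shares no code path with the package internals it
checks.
"""

import itertools

import numpy as np

from riskbn.preprocess import AnalysisTable, ColumnMeta
from riskbn.tan import CPTSet, TANStructure


def random_tan_model(rng, n_predictors=None, max_levels=2):
    """Random forest-structured TAN with Dirichlet CPTs (for oracle checks)."""
    p = n_predictors or rng.integers(1, 6)
    names = [f"x{i}" for i in range(p)]
    levels = {v: int(rng.integers(2, max_levels + 1)) for v in names}
    parent = {}
    for i, v in enumerate(names):
        # parent chosen among earlier variables (or none): always a forest
        choices = [None] + names[:i]
        parent[v] = choices[rng.integers(len(choices))]
    structure = TANStructure(
        class_node="y", predictors=names, parent=parent,
        roots=[v for v in names if parent[v] is None],
        edge_weights={}, class_mi={v: 0.0 for v in names})
    prior = rng.dirichlet([2.0, 2.0])
    tables = {}
    for v in names:
        lv = levels[v]
        if parent[v] is None:
            tables[v] = rng.dirichlet(np.ones(lv), size=2)
        else:
            lp = levels[parent[v]]
            tables[v] = rng.dirichlet(np.ones(lv), size=(2, lp))
    cpts = CPTSet(class_prior=prior, tables=tables, pseudo_count=1.0)
    return structure, cpts, levels


def enumerate_posterior(structure, cpts, levels, record):
    """P(y=1 | record) by materialising the full joint probability table."""
    names = structure.predictors
    total = {0: 0.0, 1: 0.0}
    for config in itertools.product(*[range(levels[v]) for v in names]):
        assign = dict(zip(names, config))
        if any(assign[v] != record[v] for v in names):
            continue
        for y in (0, 1):
            p = cpts.class_prior[y]
            for v in names:
                pa = structure.parent[v]
                if pa is None:
                    p *= cpts.tables[v][y, assign[v]]
                else:
                    p *= cpts.tables[v][y, assign[pa], assign[v]]
            total[y] += p
    return total[1] / (total[0] + total[1])


def table_from_records(records, y, levels):
    """AnalysisTable from explicit integer-coded rows (test plumbing)."""
    names = list(levels)
    codes = np.array([[r[v] for v in names] for r in records], dtype=np.int64)
    meta = {v: ColumnMeta(v, "categorical",
                          [str(i) for i in range(levels[v])], ordered=True)
            for v in names}
    return AnalysisTable(codes, np.asarray(y), names, meta)


def sample_from_tan(structure, cpts, levels, n, rng):
    """Ancestral sampling from a TAN model (class first, then topological)."""
    names = structure.predictors
    y = (rng.random(n) < cpts.class_prior[1]).astype(np.int64)
    data = {}
    remaining = list(names)
    while remaining:
        progressed = False
        for v in list(remaining):
            pa = structure.parent[v]
            if pa is not None and pa not in data:
                continue
            lv = levels[v]
            u = rng.random(n)
            if pa is None:
                cdf = np.cumsum(cpts.tables[v], axis=1)
                data[v] = (u[:, None] > cdf[y]).sum(axis=1)
            else:
                cdf = np.cumsum(cpts.tables[v], axis=2)
                data[v] = (u[:, None] > cdf[y, data[pa]]).sum(axis=1)
            remaining.remove(v)
            progressed = True
        assert progressed, "cyclic structure"
    codes = np.column_stack([data[v] for v in names])
    meta = {v: ColumnMeta(v, "categorical",
                          [str(i) for i in range(levels[v])], ordered=True)
            for v in names}
    return AnalysisTable(codes, y, names, meta)


def all_spanning_trees(nodes):
    """Every labeled spanning tree of the complete graph (edge-set tuples)."""
    all_edges = list(itertools.combinations(nodes, 2))
    trees = []
    for edges in itertools.combinations(all_edges, len(nodes) - 1):
        parent = {v: v for v in nodes}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for a, b in edges:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if ok:
            trees.append(tuple(sorted(edges)))
    return trees
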