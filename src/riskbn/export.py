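"""Serialisation of fitted networks: JSON model files, DOT and GraphML graphs.

The DAG export carries the class node, one node per retained predictor
(annotated with normalised importance and risk/protective direction), the
class→predictor edges and the augmenting predictor→predictor edges with
their conditional-mutual-information weights (reported in bits).
"""

from __future__ import annotations

import json

import networkx as nx
import numpy as np

from .preprocess import AnalysisTable, ColumnMeta, Discretizer
from .selection import FinalModel
from .tan import CPTSet, TANResults, TANStructure, TreeAugmentedNB

__all__ = ["model_to_json", "model_from_json", "build_dag", "to_dot",
           "to_graphml"]


def model_to_json(model: FinalModel, path=None) -> dict:
    s, c = model.results.structure, model.results.cpts
    d = {
        "country": model.country,
        "variables": model.variables,
        "discretizer": model.discretizer.to_dict(),
        "structure": {
            "class_node": s.class_node,
            "predictors": s.predictors,
            "parent": s.parent,
            "roots": s.roots,
            "edge_weights": {f"{a}|{b}": w for (a, b), w in s.edge_weights.items()},
            "class_mi": s.class_mi,
        },
        "cpts": {
            "class_prior": c.class_prior.tolist(),
            "pseudo_count": c.pseudo_count,
            "tables": {v: t.tolist() for v, t in c.tables.items()},
        },
        "alpha": model.results.model.alpha,
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)
    return d


def model_from_json(source) -> FinalModel:
    if isinstance(source, dict):
        d = source
    else:
        with open(source) as fh:
            d = json.load(fh)
    disc = Discretizer.from_dict(d["discretizer"])
    sd = d["structure"]
    structure = TANStructure(
        class_node=sd["class_node"],
        predictors=list(sd["predictors"]),
        parent=dict(sd["parent"]),
        roots=list(sd["roots"]),
        edge_weights={tuple(k.split("|")): v
                      for k, v in sd["edge_weights"].items()},
        class_mi=dict(sd["class_mi"]),
    )
    cd = d["cpts"]
    cpts = CPTSet(class_prior=np.asarray(cd["class_prior"]),
                  tables={v: np.asarray(t) for v, t in cd["tables"].items()},
                  pseudo_count=cd["pseudo_count"])
    # rebuild a placeholder model handle exposing alpha/pseudo-count; the
    # training table itself is not serialised
    meta = {v: disc.meta[v] for v in structure.predictors}
    empty = AnalysisTable(np.empty((0, len(structure.predictors)), dtype=np.int64),
                          np.empty(0, dtype=np.int64), structure.predictors, meta)
    handle = TreeAugmentedNB(empty, alpha=d["alpha"],
                             pseudo_count=cd["pseudo_count"])
    results = TANResults(handle, structure, cpts)
    return FinalModel(results, disc, list(d["variables"]), country=d["country"])


def build_dag(results: TANResults, importance=None, directions=None
              ) -> nx.DiGraph:
    """Directed acyclic graph of the fitted network as a networkx object."""
    s = results.structure
    g = nx.DiGraph()
    g.add_node(s.class_node, role="class")
    for v in s.predictors:
        attrs = {"role": "predictor"}
        if importance is not None and v in importance.names:
            attrs["importance_pct"] = round(
                float(importance.normalized[importance.names.index(v)]), 3)
        if directions is not None and v in directions:
            attrs["direction"] = directions[v]["label"]
        g.add_node(v, **attrs)
        g.add_edge(s.class_node, v, kind="class")
    for (a, b), w in s.edge_weights.items():
        child = b if s.parent.get(b) == a else a
        parent = a if child == b else b
        g.add_edge(parent, child, kind="augmenting",
                   cmi_bits=round(float(w) / float(np.log(2)), 6))
    return g


_DIR_COLOR = {"risk": "red", "protective": "green", "non-monotone": "gray"}


def to_dot(results: TANResults, importance=None, directions=None,
           path=None) -> str:
    """Emit the DAG in DOT syntax (risk red, protective green)."""
    g = build_dag(results, importance, directions)
    lines = ["digraph tan {", '  rankdir=TB;']
    for node, attrs in sorted(g.nodes(data=True)):
        parts = []
        label = node
        if "importance_pct" in attrs:
            label += f"\\n{attrs['importance_pct']:.1f}%"
        parts.append(f'label="{label}"')
        if attrs.get("role") == "class":
            parts.append("shape=doublecircle")
        color = _DIR_COLOR.get(attrs.get("direction", ""), None)
        if color:
            parts.append(f"color={color}")
        lines.append(f'  "{node}" [{", ".join(parts)}];')
    for a, b, attrs in sorted(g.edges(data=True)):
        extra = ""
        if attrs.get("kind") == "augmenting":
            extra = f' [style=dashed, label="{attrs["cmi_bits"]:.3f}"]'
        lines.append(f'  "{a}" -> "{b}"{extra};')
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def to_graphml(results: TANResults, importance=None, directions=None,
               path=None) -> nx.DiGraph:
    g = build_dag(results, importance, directions)
    if path is not None:
        nx.write_graphml(g, path)
    return g
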