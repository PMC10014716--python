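"""Tree-Augmented Naive Bayes: structure learning, CPTs and inference.

The classifier extends naive Bayes by letting every predictor depend on at
most one other predictor; the augmenting edges form a forest chosen to
maximise conditional mutual information I(Xi; Xj | Y) (the Chow-Liu
criterion applied conditionally on the class).  Candidate edges must first
survive a likelihood-ratio (G²) conditional-independence test at
significance 0.01 with conditioning sets of size at most 5, so weakly
coupled predictor pairs are pruned and the learned structure can fall back
to plain naive Bayes.  Conditional probability tables use additive
("Bayes adjustment") smoothing so sparse strata never yield zero
probabilities, and posterior inference accumulates in log space.

The user-facing surface follows the model/results idiom: build a
:class:`TreeAugmentedNB` from an :class:`~riskbn.preprocess.AnalysisTable`
(or a discrete DataFrame), call :meth:`~TreeAugmentedNB.fit`, and read the
fitted network, probabilities and diagnostics off the returned
:class:`TANResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .preprocess import AnalysisTable, ColumnMeta, OUTCOME_NAME

__all__ = [
    "conditional_mutual_information",
    "mutual_information",
    "g2_test",
    "IndependenceTestResult",
    "learn_structure",
    "TANStructure",
    "fit_cpts",
    "CPTSet",
    "predict_proba",
    "TreeAugmentedNB",
    "TANResults",
]

MAX_CONDITIONING_SET = 5  # pre-specified hyperparameter of the analysis
DEFAULT_ALPHA = 0.01
DEFAULT_PSEUDO_COUNT = 1.0


# ------------------------------------------------------------- information

def _check_lengths(*arrays):
    n = {len(a) for a in arrays}
    if len(n) != 1:
        raise ValueError(f"input vectors differ in length: {sorted(n)}")


def _counts_3d(xi, xj, y, li, lj, ly) -> np.ndarray:
    idx = (np.asarray(xi) * lj + np.asarray(xj)) * ly + np.asarray(y)
    return np.bincount(idx, minlength=li * lj * ly).reshape(li, lj, ly).astype(float)


def _levels(x) -> int:
    return int(np.max(x)) + 1 if len(x) else 0


def conditional_mutual_information(xi, xj, y, levels=None) -> float:
    """Empirical I(Xi; Xj | Y) in nats from integer-coded vectors."""
    _check_lengths(xi, xj, y)
    li, lj, ly = levels or (_levels(xi), _levels(xj), _levels(y))
    if min(li, lj) < 2:
        return 0.0
    n = len(xi)
    c = _counts_3d(xi, xj, y, li, lj, ly)
    p = c / n
    py = p.sum(axis=(0, 1), keepdims=True)
    pi_y = p.sum(axis=1, keepdims=True)
    pj_y = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p * py / (pi_y * pj_y)
        term = p * np.log(ratio)
    return float(np.nansum(term))


def mutual_information(x, y, levels=None) -> float:
    """Empirical I(X; Y) in nats (used to pick forest roots)."""
    _check_lengths(x, y)
    lx, ly = levels or (_levels(x), _levels(y))
    if min(lx, ly) < 2:
        return 0.0
    n = len(x)
    c = np.bincount(np.asarray(x) * ly + np.asarray(y),
                    minlength=lx * ly).reshape(lx, ly).astype(float)
    p = c / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log(p / (px * py))
    return float(np.nansum(term))


# ------------------------------------------------------------- G² test

@dataclass
class IndependenceTestResult:
    statistic: float
    df: int
    p_value: float
    conditioning_size: int
    alpha: float

    @property
    def reject(self) -> bool:
        """True when independence is rejected (the pair is kept as dependent)."""
        return self.p_value < self.alpha


def g2_test(xi, xj, conditioning=(), alpha: float = DEFAULT_ALPHA
            ) -> IndependenceTestResult:
    """Likelihood-ratio test of Xi ⟂ Xj given the conditioning variables.

    G² = 2 Σ O ln(O/E) within each conditioning stratum (zero cells
    contribute nothing); df sums (li−1)(lj−1) over non-empty strata; the
    p-value is the chi-square upper tail.  Conditioning sets are capped at
    5 variables, the pre-specified maximum of the analysis.
    """
    conditioning = list(conditioning)
    if len(conditioning) > MAX_CONDITIONING_SET:
        raise ValueError(
            f"conditioning set of size {len(conditioning)} exceeds the "
            f"maximum of {MAX_CONDITIONING_SET}")
    _check_lengths(xi, xj, *conditioning) if conditioning else _check_lengths(xi, xj)
    xi = np.asarray(xi)
    xj = np.asarray(xj)
    li, lj = _levels(xi), _levels(xj)
    if conditioning:
        strata = np.zeros(len(xi), dtype=np.int64)
        mult = 1
        for c in conditioning:
            c = np.asarray(c)
            strata = strata * _levels(c) + c
            mult *= _levels(c)
        n_strata = mult
    else:
        strata = np.zeros(len(xi), dtype=np.int64)
        n_strata = 1
    counts = np.bincount((strata * li + xi) * lj + xj,
                         minlength=n_strata * li * lj
                         ).reshape(n_strata, li, lj).astype(float)
    totals = counts.sum(axis=(1, 2))
    nonempty = totals > 0
    g2 = 0.0
    for s in np.flatnonzero(nonempty):
        O = counts[s]
        E = O.sum(axis=1, keepdims=True) * O.sum(axis=0, keepdims=True) / totals[s]
        mask = O > 0
        g2 += 2.0 * float((O[mask] * np.log(O[mask] / E[mask])).sum())
    df = int(nonempty.sum()) * (li - 1) * (lj - 1)
    df = max(df, 1)
    g2 = max(g2, 0.0)
    p = float(chi2.sf(g2, df))
    return IndependenceTestResult(g2, df, p, len(conditioning), alpha)


# ------------------------------------------------------------- structure

@dataclass
class TANStructure:
    """Class node plus an augmenting forest over the predictors."""

    class_node: str
    predictors: list[str]
    parent: dict[str, str | None]            # augmenting parent (besides Y)
    roots: list[str]
    edge_weights: dict[tuple[str, str], float] = field(default_factory=dict)
    class_mi: dict[str, float] = field(default_factory=dict)

    @property
    def edges(self) -> list[tuple[str, str]]:
        """Directed augmenting edges (parent, child)."""
        return [(p, c) for c, p in self.parent.items() if p is not None]

    def validate(self) -> None:
        for c, p in self.parent.items():
            if p is not None and p not in self.predictors:
                raise ValueError(f"parent {p!r} of {c!r} not a predictor")
        # forest check: no cycles following parents upward
        for start in self.predictors:
            seen = {start}
            node = self.parent.get(start)
            while node is not None:
                if node in seen:
                    raise ValueError("augmenting edges contain a cycle")
                seen.add(node)
                node = self.parent.get(node)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def learn_structure(table: AnalysisTable, alpha: float = DEFAULT_ALPHA
                    ) -> TANStructure:
    """Learn the augmenting forest by pruned maximum-CMI spanning.

    Pairwise I(Xi; Xj | Y) weights every candidate edge; pairs whose G² test
    conditioned on Y accepts independence at ``alpha`` are discarded; Kruskal
    over the survivors (weights descending, lexicographic tie-break) yields a
    maximum-weight spanning forest, and each tree is directed away from the
    predictor with the highest I(Xi; Y).  With every edge pruned the result
    is plain naive Bayes.
    """
    cols = [c for c in table.columns]
    if len(cols) == 0:
        raise ValueError("table has no predictors")
    y = table.y
    ly = 2
    data = {c: table.column(c) for c in cols}
    lv = {c: table.n_levels(c) for c in cols}
    class_mi = {c: mutual_information(data[c], y, (lv[c], ly)) for c in cols}

    candidate = []
    weights = {}
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            a_, b_ = sorted((a, b))  # canonical pair: column order irrelevant
            w = conditional_mutual_information(data[a_], data[b_], y,
                                               (lv[a_], lv[b_], ly))
            weights[(a_, b_)] = w
            test = g2_test(data[a_], data[b_], conditioning=[y], alpha=alpha)
            if test.reject:
                candidate.append((a_, b_, w))

    # Kruskal, deterministic: weight descending then lexicographic pair
    candidate.sort(key=lambda e: (-e[2], e[0], e[1]))
    uf = _UnionFind(cols)
    forest_edges = []
    for a, b, w in candidate:
        if uf.union(a, b):
            forest_edges.append((a, b, w))

    adj: dict[str, list[str]] = {c: [] for c in cols}
    for a, b, _w in forest_edges:
        adj[a].append(b)
        adj[b].append(a)

    parent: dict[str, str | None] = {c: None for c in cols}
    roots = []
    visited = set()
    # components in deterministic order: best class-MI first, name tie-break
    for start in sorted(cols, key=lambda c: (-class_mi[c], c)):
        if start in visited:
            continue
        roots.append(start)
        stack = [start]
        visited.add(start)
        while stack:
            node = stack.pop()
            for nb in sorted(adj[node]):
                if nb not in visited:
                    visited.add(nb)
                    parent[nb] = node
                    stack.append(nb)

    structure = TANStructure(
        class_node=OUTCOME_NAME,
        predictors=cols,
        parent=parent,
        roots=sorted(r for r in roots if adj[r]),
        edge_weights={(a, b): w for a, b, w in forest_edges},
        class_mi=class_mi,
    )
    structure.validate()
    return structure


# ------------------------------------------------------------- CPTs

@dataclass
class CPTSet:
    """Smoothed class prior and per-predictor conditional tables.

    ``tables[v]`` has shape (2, levels_v) for root/naive predictors and
    (2, levels_parent, levels_v) for augmented ones; the last axis always
    normalises to 1 and all entries are strictly positive.
    """

    class_prior: np.ndarray
    tables: dict[str, np.ndarray]
    pseudo_count: float


def fit_cpts(table: AnalysisTable, structure: TANStructure,
             pseudo_count: float = DEFAULT_PSEUDO_COUNT) -> CPTSet:
    """Estimate CPTs with additive smoothing: (count + a) / (total + a·levels)."""
    y = table.y
    n = table.n
    a = float(pseudo_count)
    cy = np.bincount(y, minlength=2).astype(float)
    prior = (cy + a) / (n + 2 * a) if a > 0 else cy / n
    tables = {}
    for v in structure.predictors:
        if v not in table.columns:
            raise ValueError(f"structure variable {v!r} missing from table")
        xv = table.column(v)
        lv = table.n_levels(v)
        p = structure.parent[v]
        if p is None:
            c = _counts_3d(y, xv, np.zeros(n, dtype=int), 2, lv, 1)[:, :, 0]
            tab = (c + a) / (c.sum(axis=1, keepdims=True) + a * lv)
        else:
            xp = table.column(p)
            lp = table.n_levels(p)
            c = _counts_3d(y * lp + xp, xv, np.zeros(n, dtype=int),
                           2 * lp, lv, 1)[:, :, 0].reshape(2, lp, lv)
            tab = (c + a) / (c.sum(axis=2, keepdims=True) + a * lv)
        if a == 0:
            tab = np.nan_to_num(tab, nan=1.0 / lv)
        tables[v] = tab
    return CPTSet(class_prior=prior, tables=tables, pseudo_count=a)


# ------------------------------------------------------------- inference

def _log_factors(table: AnalysisTable, structure: TANStructure,
                 cpts: CPTSet, columns: list[str] | None = None) -> np.ndarray:
    """Per-row, per-variable, per-class log CPT contributions (n, p, 2)."""
    cols = columns if columns is not None else structure.predictors
    n = table.n
    out = np.empty((n, len(cols), 2))
    for j, v in enumerate(cols):
        xv = table.column(v)
        if len(xv) and xv.max() >= cpts.tables[v].shape[-1]:
            raise ValueError(f"column {v!r} contains unseen level codes")
        tab = np.log(cpts.tables[v])
        p = structure.parent[v]
        if p is None:
            out[:, j, 0] = tab[0, xv]
            out[:, j, 1] = tab[1, xv]
        else:
            xp = table.column(p)
            if len(xp) and xp.max() >= tab.shape[1]:
                raise ValueError(f"column {p!r} contains unseen level codes")
            out[:, j, 0] = tab[0, xp, xv]
            out[:, j, 1] = tab[1, xp, xv]
    return out


def predict_proba(table: AnalysisTable, structure: TANStructure,
                  cpts: CPTSet) -> np.ndarray:
    """Posterior P(Y=1 | x) per row, accumulated in log space."""
    logf = _log_factors(table, structure, cpts)
    logpost = logf.sum(axis=1) + np.log(cpts.class_prior)
    m = logpost.max(axis=1, keepdims=True)
    w = np.exp(logpost - m)
    return w[:, 1] / w.sum(axis=1)


# ------------------------------------------------------------- model facade

class TreeAugmentedNB:
    """Tree-augmented naive Bayes model for a binary outcome.

    Parameters
    ----------
    table:
        Discrete predictor matrix with binary outcome.
    alpha:
        Significance level of the G² edge-pruning test.
    pseudo_count:
        Additive smoothing of the CPT counts.
    """

    def __init__(self, table: AnalysisTable, alpha: float = DEFAULT_ALPHA,
                 pseudo_count: float = DEFAULT_PSEUDO_COUNT):
        if len(table.columns) < 1:
            raise ValueError("need at least one predictor")
        self.table = table
        self.alpha = alpha
        self.pseudo_count = pseudo_count

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str = OUTCOME_NAME,
                       **kwargs) -> "TreeAugmentedNB":
        """Build from a DataFrame whose columns are already discrete.

        Every non-outcome column is encoded on its sorted observed levels.
        """
        y = df[outcome].to_numpy()
        cols = [c for c in df.columns if c != outcome]
        codes = np.empty((len(df), len(cols)), dtype=np.int64)
        meta = {}
        for j, c in enumerate(cols):
            vals = df[c].astype(str)
            levels = sorted(vals.unique().tolist())
            mapping = {lev: i for i, lev in enumerate(levels)}
            codes[:, j] = vals.map(mapping).to_numpy()
            meta[c] = ColumnMeta(c, "categorical", levels, ordered=False)
        return cls(AnalysisTable(codes, y, cols, meta), **kwargs)

    def fit(self) -> "TANResults":
        structure = learn_structure(self.table, alpha=self.alpha)
        cpts = fit_cpts(self.table, structure, pseudo_count=self.pseudo_count)
        return TANResults(self, structure, cpts)


class TANResults:
    """Fitted network: structure, CPTs, prediction and diagnostics."""

    def __init__(self, model: TreeAugmentedNB, structure: TANStructure,
                 cpts: CPTSet):
        self.model = model
        self.structure = structure
        self.cpts = cpts

    def predict_proba(self, table: AnalysisTable | None = None) -> np.ndarray:
        table = table if table is not None else self.model.table
        return predict_proba(table, self.structure, self.cpts)

    def nagelkerke_r2(self, table: AnalysisTable | None = None) -> float:
        from .evaluate import nagelkerke_r2
        table = table if table is not None else self.model.table
        return nagelkerke_r2(self.predict_proba(table), table.y)

    def variable_importance(self, table: AnalysisTable | None = None,
                            n_permutations: int = 10, seed: int = 0):
        from .selection import variable_importance
        table = table if table is not None else self.model.table
        return variable_importance(self, table, n_permutations=n_permutations,
                                   seed=seed)

    def summary(self) -> str:
        s = self.structure
        lines = []
        lines.append("Tree-Augmented Naive Bayes Results")
        lines.append("=" * 64)
        lines.append(f"Outcome: {s.class_node}    n = {self.model.table.n}"
                     f"    predictors = {len(s.predictors)}")
        lines.append(f"Pruning alpha = {self.model.alpha}"
                     f"    pseudo-count = {self.cpts.pseudo_count}")
        lines.append(f"Class prior P(Y=1) = {self.cpts.class_prior[1]:.4f}")
        lines.append("-" * 64)
        lines.append(f"{'predictor':<24}{'levels':>7}  {'augmenting parent':<20}"
                     f"{'I(X;Y) bits':>12}")
        for v in sorted(s.predictors, key=lambda c: (-s.class_mi[c], c)):
            mi_bits = s.class_mi[v] / np.log(2)
            lines.append(f"{v:<24}{self.model.table.n_levels(v):>7}  "
                         f"{s.parent[v] or '-':<20}{mi_bits:>12.4f}")
        lines.append("-" * 64)
        lines.append(f"Augmenting edges: {len(s.edges)}"
                     f" (naive Bayes if 0); roots: {', '.join(s.roots) or '-'}")
        return "\n".join(lines)

    def __repr__(self):
        return (f"<TANResults: {len(self.structure.predictors)} predictors, "
                f"{len(self.structure.edges)} augmenting edges>")
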