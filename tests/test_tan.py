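"""TAN core tests: information measures, G², structure, CPTs, inference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from riskbn.tan import (TreeAugmentedNB, conditional_mutual_information,
                        fit_cpts, g2_test, learn_structure,
                        mutual_information, predict_proba)

from oracles import (all_spanning_trees, enumerate_posterior,
                     random_tan_model, sample_from_tan, table_from_records)


# ------------------------------------------------------- mutual information

def test_cmi_zero_for_conditionally_independent_counts():
    # product-form joint within each class: Xi ⟂ Xj | Y exactly
    xi, xj, y = [], [], []
    for cls, (pi, pj) in enumerate([((2, 2), (2, 2)), ((1, 3), (3, 1))]):
        for a in range(2):
            for b in range(2):
                reps = pi[a] * pj[b]
                xi += [a] * reps
                xj += [b] * reps
                y += [cls] * reps
    cmi = conditional_mutual_information(np.array(xi), np.array(xj), np.array(y))
    assert cmi == pytest.approx(0.0, abs=1e-12)


def test_cmi_equals_ln2_for_xor_construction():
    # Y = Xi XOR Xj with fair independent bits: I(Xi;Xj|Y) = ln 2, I(Xi;Xj) = 0
    xi, xj = [], []
    for a in range(2):
        for b in range(2):
            xi += [a] * 25
            xj += [b] * 25
    xi, xj = np.array(xi), np.array(xj)
    y = xi ^ xj
    assert conditional_mutual_information(xi, xj, y) == pytest.approx(np.log(2), abs=1e-12)
    assert mutual_information(xi, xj) == pytest.approx(0.0, abs=1e-12)


def test_cmi_invariant_to_category_relabeling(rng):
    xi = rng.integers(0, 3, 400)
    xj = rng.integers(0, 4, 400)
    y = rng.integers(0, 2, 400)
    base = conditional_mutual_information(xi, xj, y)
    relabel = np.array([2, 0, 1])
    assert conditional_mutual_information(relabel[xi], xj, y) == pytest.approx(base, abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 10_000))
def test_cmi_nonnegative_and_symmetric_on_fuzz(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 200))
    xi = rng.integers(0, rng.integers(2, 5), n)
    xj = rng.integers(0, rng.integers(2, 5), n)
    y = rng.integers(0, 2, n)
    cmi = conditional_mutual_information(xi, xj, y)
    assert cmi >= -1e-12
    assert conditional_mutual_information(xj, xi, y) == pytest.approx(cmi, abs=1e-12)


def test_cmi_rejects_length_mismatch():
    with pytest.raises(ValueError):
        conditional_mutual_information(np.zeros(3, int), np.zeros(4, int),
                                       np.zeros(3, int))


# ------------------------------------------------------------------ G² test

def _expand(counts_2x2):
    xi, xj = [], []
    for a in range(2):
        for b in range(2):
            xi += [a] * counts_2x2[a][b]
            xj += [b] * counts_2x2[a][b]
    return np.array(xi), np.array(xj)


def test_g2_zero_on_exactly_independent_table():
    xi, xj = _expand([[25, 25], [25, 25]])
    res = g2_test(xi, xj)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)
    assert not res.reject


def test_g2_diagonal_table_value_and_rejection():
    xi, xj = _expand([[10, 0], [0, 10]])
    res = g2_test(xi, xj)
    assert res.statistic == pytest.approx(40 * np.log(2), rel=1e-12)
    assert res.df == 1
    assert res.reject


def test_g2_scales_linearly_with_counts():
    xi, xj = _expand([[8, 3], [4, 9]])
    once = g2_test(xi, xj).statistic
    xi2, xj2 = np.repeat(xi, 2), np.repeat(xj, 2)
    assert g2_test(xi2, xj2).statistic == pytest.approx(2 * once, rel=1e-10)


def test_g2_conditioning_set_capped_at_five():
    x = np.zeros(10, dtype=int)
    with pytest.raises(ValueError, match="maximum of 5"):
        g2_test(x, x, conditioning=[x] * 6)


def test_g2_stratified_df_sums_over_strata(rng):
    xi = rng.integers(0, 3, 600)
    xj = rng.integers(0, 2, 600)
    z = rng.integers(0, 4, 600)
    res = g2_test(xi, xj, conditioning=[z])
    assert res.df == 4 * (3 - 1) * (2 - 1)
    assert res.statistic >= 0


# ---------------------------------------------------------------- structure

def test_independent_predictors_give_naive_bayes(rng):
    n = 2000
    y = rng.integers(0, 2, n)
    records = [{f"x{i}": int(v) for i, v in enumerate(row)}
               for row in rng.integers(0, 3, (n, 4))]
    table = table_from_records(records, y, {f"x{i}": 3 for i in range(4)})
    s = learn_structure(table, alpha=0.01)
    assert s.edges == []
    assert all(p is None for p in s.parent.values())


@pytest.mark.parametrize("seed", range(10))
def test_learned_forest_maximises_weight_over_enumerated_trees(seed):
    # dependent 4-variable data; compare Kruskal's forest weight with the
    # best of all 16 labeled spanning trees of K4 (restricted to kept edges)
    rng = np.random.default_rng(seed)
    n = 800
    y = rng.integers(0, 2, n)
    base = rng.integers(0, 2, n)
    cols = {}
    for i in range(4):
        flip = rng.random(n) < 0.2 + 0.1 * i
        cols[f"x{i}"] = np.where(flip, rng.integers(0, 2, n), base)
    records = [{k: int(cols[k][r]) for k in cols} for r in range(n)]
    table = table_from_records(records, y, {k: 2 for k in cols})
    s = learn_structure(table, alpha=0.01)

    names = list(cols)
    weights = {tuple(sorted((a, b))): conditional_mutual_information(
        cols[a], cols[b], y) for i, a in enumerate(names)
        for b in names[i + 1:]}
    kept = {pair for pair in weights
            if g2_test(cols[pair[0]], cols[pair[1]], conditioning=[y]).reject}
    learned_weight = sum(weights[tuple(sorted(e))] for e in s.edge_weights)
    best = 0.0
    for tree in all_spanning_trees(names):
        if all(tuple(sorted(e)) in kept for e in tree):
            best = max(best, sum(weights[tuple(sorted(e))] for e in tree))
    # the learned forest may beat every full tree when some edges are pruned;
    # it can never be worse than the best admissible full tree
    assert learned_weight >= best - 1e-12


def test_planted_xor_dependency_is_recovered(rng):
    n = 5000
    y = rng.integers(0, 2, n)
    xa = rng.integers(0, 2, n)
    xb = np.where(rng.random(n) < 0.95, xa ^ y, rng.integers(0, 2, n))
    others = {f"z{i}": rng.integers(0, 2, n) for i in range(3)}
    cols = {"xa": xa, "xb": xb, **others}
    records = [{k: int(v[r]) for k, v in cols.items()} for r in range(n)]
    table = table_from_records(records, y, {k: 2 for k in cols})
    s = learn_structure(table, alpha=0.01)
    assert set(map(tuple, map(sorted, s.edge_weights))) == {("xa", "xb")}


def test_lower_alpha_never_adds_edges(rng):
    n = 600
    y = rng.integers(0, 2, n)
    data = rng.integers(0, 3, (n, 5))
    data[:, 1] = np.where(rng.random(n) < 0.6, data[:, 0], data[:, 1])
    records = [{f"x{i}": int(v) for i, v in enumerate(row)} for row in data]
    table = table_from_records(records, y, {f"x{i}": 3 for i in range(5)})
    edges = {}
    for alpha in (0.2, 0.05, 0.01, 0.001):
        s = learn_structure(table, alpha=alpha)
        edges[alpha] = set(s.edge_weights)
    assert edges[0.001] <= edges[0.01] <= edges[0.05] <= edges[0.2]


# --------------------------------------------------------------------- CPTs

def test_cpt_smoothing_arithmetic():
    # stratum counts (3,1) with pseudo-count 1 -> (4/6, 2/6)
    records = [{"x": 0}] * 3 + [{"x": 1}]
    table = table_from_records(records, [1] * 4, {"x": 2})
    from riskbn.tan import TANStructure
    structure = TANStructure("y", ["x"], {"x": None}, [], {}, {"x": 0.0})
    cpts = fit_cpts(table, structure, pseudo_count=1)
    assert cpts.tables["x"][1].tolist() == pytest.approx([4 / 6, 2 / 6])
    # empty stratum (y=0 unobserved) -> uniform under smoothing
    assert cpts.tables["x"][0].tolist() == pytest.approx([0.5, 0.5])


def test_cpt_zero_pseudocount_recovers_mle(rng):
    structure, cpts0, levels = random_tan_model(rng, n_predictors=3)
    table = sample_from_tan(structure, cpts0, levels, 500, rng)
    ml = fit_cpts(table, structure, pseudo_count=0)
    v = structure.predictors[0]
    xv = table.column(v)
    emp = np.array([np.bincount(xv[table.y == y], minlength=levels[v])
                    for y in (0, 1)], dtype=float)
    if structure.parent[v] is None and (emp.sum(axis=1) > 0).all():
        emp = emp / emp.sum(axis=1, keepdims=True)
        assert np.allclose(ml.tables[v], emp)


def test_cpts_strictly_positive_and_normalized(rng):
    structure, cpts0, levels = random_tan_model(rng, n_predictors=4, max_levels=3)
    table = sample_from_tan(structure, cpts0, levels, 60, rng)
    cpts = fit_cpts(table, structure, pseudo_count=1)
    for v, tab in cpts.tables.items():
        assert (tab > 0).all()
        assert np.allclose(tab.sum(axis=-1), 1.0, atol=1e-9)


# ---------------------------------------------------------------- inference

def test_uniform_cpts_return_class_prior(rng):
    structure, cpts, levels = random_tan_model(rng, n_predictors=3)
    for v, tab in cpts.tables.items():
        cpts.tables[v] = np.full_like(tab, 1.0 / tab.shape[-1])
    record = {v: 0 for v in structure.predictors}
    table = table_from_records([record], [1], levels)
    post = predict_proba(table, structure, cpts)
    assert post[0] == pytest.approx(cpts.class_prior[1], abs=1e-12)


@pytest.mark.parametrize("seed", range(15))
def test_posterior_matches_joint_enumeration(seed):
    rng = np.random.default_rng(seed)
    structure, cpts, levels = random_tan_model(rng, max_levels=3)
    record = {v: int(rng.integers(levels[v])) for v in structure.predictors}
    table = table_from_records([record], [1], levels)
    got = predict_proba(table, structure, cpts)[0]
    want = enumerate_posterior(structure, cpts, levels, record)
    assert got == pytest.approx(want, abs=1e-12)
    assert 0.0 < got < 1.0


def test_missing_level_codes_rejected(rng):
    structure, cpts, levels = random_tan_model(rng, n_predictors=2)
    v = structure.predictors[0]
    record = {u: 0 for u in structure.predictors}
    record[v] = levels[v] + 3
    bad_levels = dict(levels)
    bad_levels[v] = levels[v] + 4
    table = table_from_records([record], [1], bad_levels)
    with pytest.raises(ValueError, match="unseen level"):
        predict_proba(table, structure, cpts)


def test_model_results_facade_runs(austria_survey):
    from riskbn.preprocess import Discretizer, build_feature_frame
    frame = build_feature_frame(austria_survey)
    table = Discretizer(k=5).fit_transform(frame)
    res = TreeAugmentedNB(table).fit()
    post = res.predict_proba()
    assert post.shape == (table.n,)
    assert np.all((post > 0) & (post < 1))
    text = res.summary()
    assert "Tree-Augmented Naive Bayes Results" in text
    assert "phq8" in text
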