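"""Diversity estimators, rarefaction, UPGMA, PCoA and ANOVA checks."""

import itertools
import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from cassmicro.community import (
    DistanceMatrix,
    OtuTable,
    alpha_with_ci,
    anova_oneway,
    chao1,
    cut_tree,
    distance_matrix,
    goods_coverage,
    inv_simpson,
    jaccard_distance,
    pcoa,
    rarefy,
    shannon,
    simpson_evenness,
    upgma,
    yue_clayton_distance,
    zone_cut,
)
from cassmicro.errors import InvalidInputError

counts_vectors = st.lists(st.integers(min_value=0, max_value=40), min_size=1, max_size=15).filter(
    lambda v: sum(v) > 0
)


# ---------------------------------------------------------------------------
# alpha diversity


@pytest.mark.parametrize(
    "func,counts,expected",
    [
        (goods_coverage, [4, 3, 1, 1, 1], 0.7),
        (goods_coverage, [1, 1, 1], 0.0),
        (goods_coverage, [5, 5], 1.0),
        (chao1, [4, 3, 1, 1, 1], 8.0),
        (chao1, [2, 1, 1], 3.5),
        (chao1, [5, 4, 3], 3.0),
        (shannon, [5, 3, 2], 1.0296530140645737),
        (shannon, [7], 0.0),
        (shannon, [3, 3, 3, 3], math.log(4)),
        (inv_simpson, [5, 3, 2], 90 / 28),
        (inv_simpson, [9], 1.0),
        (simpson_evenness, [5, 3, 2], (1 / 0.38) / 3),
        (simpson_evenness, [4, 4, 4], 1.0),
        (simpson_evenness, [6], 1.0),
    ],
)
def test_alpha_index_hand_values(func, counts, expected):
    assert func(counts) == pytest.approx(expected, abs=1e-10)


def test_inv_simpson_all_singletons_is_undefined():
    assert math.isnan(inv_simpson([1, 1]))


def test_empty_sample_rejected():
    for func in (goods_coverage, chao1, shannon, inv_simpson, simpson_evenness):
        with pytest.raises(InvalidInputError):
            func([0, 0])


@given(counts=counts_vectors)
@settings(derandomize=True, max_examples=200)
def test_alpha_indices_invariant_under_relabeling(counts):
    perm = np.random.default_rng(0).permutation(len(counts))
    shuffled = list(np.asarray(counts)[perm])
    for func in (goods_coverage, chao1, shannon, simpson_evenness):
        a, b = func(counts), func(shuffled)
        assert a == pytest.approx(b, rel=1e-12)


@given(counts=counts_vectors)
@settings(derandomize=True, max_examples=200)
def test_chao1_bounds_observed_richness(counts):
    s_obs = sum(1 for c in counts if c > 0)
    assert chao1(counts) >= s_obs


@given(
    counts=st.lists(st.integers(min_value=0, max_value=6), min_size=1, max_size=4).filter(
        lambda v: 2 <= sum(v) <= 8
    )
)
@settings(derandomize=True, max_examples=300)
def test_inv_simpson_matches_pair_enumeration(counts):
    """1/D equals the inverse probability that two reads drawn without
    replacement belong to the same OTU, by exhaustive pair enumeration."""
    reads = [otu for otu, c in enumerate(counts) for _ in range(c)]
    pairs = list(itertools.combinations(range(len(reads)), 2))
    same = sum(1 for i, j in pairs if reads[i] == reads[j])
    got = inv_simpson(counts)
    if same == 0:
        assert math.isnan(got)
    else:
        assert got == pytest.approx(len(pairs) / same, rel=1e-12)


# ---------------------------------------------------------------------------
# rarefaction


def _plain_table(counts):
    counts = np.atleast_2d(counts)
    return OtuTable(
        sample_ids=[f"S{i}" for i in range(counts.shape[0])],
        otu_ids=[f"O{j}" for j in range(counts.shape[1])],
        counts=counts,
    )


def test_rarefy_hits_depth_exactly():
    rng = np.random.default_rng(5)
    table = _plain_table(rng.multinomial(5000, np.ones(40) / 40, size=3))
    out = rarefy(table, 1498, seed=1)
    assert (out.totals() == 1498).all()
    assert (out.counts <= table.counts).all()


def test_rarefy_at_depth_returns_sample_unchanged():
    table = _plain_table([[3, 4, 5]])
    out = rarefy(table, 12, seed=0)
    assert (out.counts == table.counts).all()


def test_rarefy_drops_shallow_samples_with_warning(caplog):
    table = _plain_table([[1, 1, 0], [5, 5, 5]])
    with caplog.at_level(logging.WARNING):
        out = rarefy(table, 10, seed=0)
    assert out.sample_ids == ["S1"]
    assert "dropping sample S0" in caplog.text


def test_rarefy_all_below_depth_gives_empty_table(caplog):
    table = _plain_table([[1, 1], [2, 0]])
    with caplog.at_level(logging.WARNING):
        out = rarefy(table, 100, seed=0)
    assert out.n_samples == 0


def test_rarefy_invalid_depth():
    with pytest.raises(InvalidInputError):
        rarefy(_plain_table([[5]]), 0, seed=0)


def test_rarefy_deterministic_for_seed():
    rng = np.random.default_rng(9)
    table = _plain_table(rng.multinomial(3000, np.ones(25) / 25, size=2))
    a = rarefy(table, 1000, seed=42)
    b = rarefy(table, 1000, seed=42)
    assert (a.counts == b.counts).all()


def test_alpha_with_ci_single_iteration_collapses():
    table = _plain_table([[50, 30, 20]])
    (rec,) = alpha_with_ci(table, depth=50, n_iter=1, seed=0)
    lo, hi = rec.ci95["shannon"]
    assert lo == hi == pytest.approx(rec.shannon)


def test_alpha_with_ci_zero_width_at_exact_depth():
    table = _plain_table([[5, 3, 2]])
    (rec,) = alpha_with_ci(table, depth=10, n_iter=20, seed=0)
    assert rec.ci95["inv_simpson"] == (pytest.approx(90 / 28), pytest.approx(90 / 28))
    assert rec.chao1 == pytest.approx(3.0)


def test_alpha_with_ci_stable_across_seeds():
    rng = np.random.default_rng(3)
    table = _plain_table(rng.multinomial(4000, rng.dirichlet(np.ones(60)), size=1))
    (a,) = alpha_with_ci(table, depth=1000, n_iter=100, seed=1)
    (b,) = alpha_with_ci(table, depth=1000, n_iter=100, seed=2)
    for name in ("shannon", "inv_simpson", "chao1"):
        lo_a, hi_a = a.ci95[name]
        lo_b, hi_b = b.ci95[name]
        assert lo_a <= hi_b and lo_b <= hi_a  # intervals overlap
        width = max(hi_a - lo_a, hi_b - lo_b, 1e-9)
        assert abs(getattr(a, name) - getattr(b, name)) <= width


# ---------------------------------------------------------------------------
# beta diversity


def test_jaccard_hand_value():
    a = [1, 2, 3, 0]
    b = [0, 5, 1, 4]
    assert jaccard_distance(a, b) == pytest.approx(0.5)


def test_yue_clayton_hand_value():
    assert yue_clayton_distance([0.5, 0.5, 0.0], [0.5, 0.25, 0.25]) == pytest.approx(0.25)


@pytest.mark.parametrize("func", [jaccard_distance, yue_clayton_distance])
def test_distance_identity_and_disjoint(func):
    assert func([3, 2, 1], [3, 2, 1]) == pytest.approx(0.0)
    assert func([3, 0, 1, 0], [0, 2, 0, 5]) == pytest.approx(1.0)


@given(a=counts_vectors, b=counts_vectors)
@settings(derandomize=True, max_examples=200)
def test_distances_symmetric_and_bounded(a, b):
    n = max(len(a), len(b))
    a = a + [0] * (n - len(a))
    b = b + [0] * (n - len(b))
    for func in (jaccard_distance, yue_clayton_distance):
        d1, d2 = func(a, b), func(b, a)
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert -1e-12 <= d1 <= 1 + 1e-12


@given(
    vecs=st.lists(counts_vectors, min_size=3, max_size=3),
)
@settings(derandomize=True, max_examples=200)
def test_jaccard_triangle_inequality(vecs):
    n = max(map(len, vecs))
    a, b, c = [v + [0] * (n - len(v)) for v in vecs]
    dab, dbc, dac = jaccard_distance(a, b), jaccard_distance(b, c), jaccard_distance(a, c)
    assert dac <= dab + dbc + 1e-12


# ---------------------------------------------------------------------------
# UPGMA


def _random_dm(rng, n):
    d = rng.uniform(0.05, 1.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=[f"L{i}" for i in range(n)], data=d)


def test_upgma_three_leaf_hand_case():
    dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 0.2, 0.6], [0.2, 0, 0.8], [0.6, 0.8, 0]]))
    tree = upgma(dm)
    assert tree.height == pytest.approx(0.35)  # mean(0.6, 0.8) / 2
    (ab,) = [c for c in tree.children if len(c.leaves) == 2]
    assert ab.leaves == ("A", "B")
    assert ab.height == pytest.approx(0.1)


def test_upgma_two_leaves():
    dm = DistanceMatrix(["X", "Y"], np.array([[0, 0.4], [0.4, 0]]))
    tree = upgma(dm)
    assert tree.height == pytest.approx(0.2)
    assert tree.to_newick() == "(X:0.2,Y:0.2);"


def test_upgma_matches_scipy_average_linkage():
    """Cophenetic distances equal scipy's average-linkage on random matrices."""
    rng = np.random.default_rng(12)
    for _ in range(20):
        dm = _random_dm(rng, 6)
        tree = upgma(dm)
        z = average(squareform(dm.data, checks=False))
        scipy_coph = squareform(cophenet(z))
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                if i < j:
                    assert tree.cophenetic(a, b) == pytest.approx(
                        scipy_coph[i, j], abs=1e-10
                    )


def test_upgma_ultrametric_property():
    """For every leaf triple the two largest cophenetic distances are equal."""
    rng = np.random.default_rng(7)
    dm = _random_dm(rng, 7)
    tree = upgma(dm)
    for a, b, c in itertools.combinations(dm.labels, 3):
        ds = sorted([tree.cophenetic(a, b), tree.cophenetic(b, c), tree.cophenetic(a, c)])
        assert ds[1] == pytest.approx(ds[2], abs=1e-10)


def test_upgma_deterministic_under_ties():
    d = np.full((4, 4), 0.5)
    np.fill_diagonal(d, 0.0)
    dm = DistanceMatrix(["D", "C", "B", "A"], d)
    t1 = upgma(dm)
    dm2 = DistanceMatrix(["A", "B", "C", "D"], d)
    t2 = upgma(dm2)
    assert t1.to_newick() == t2.to_newick()


def test_cut_tree_boundaries():
    rng = np.random.default_rng(1)
    dm = _random_dm(rng, 5)
    tree = upgma(dm)
    assert cut_tree(tree, 1) == [tuple(sorted(dm.labels))]
    assert cut_tree(tree, 5) == sorted((lab,) for lab in dm.labels)


def test_zone_cut_orders_by_mean_depth():
    dm = DistanceMatrix(
        ["deep1", "deep2", "shallow1", "shallow2"],
        np.array(
            [
                [0.0, 0.1, 0.9, 0.9],
                [0.1, 0.0, 0.9, 0.9],
                [0.9, 0.9, 0.0, 0.1],
                [0.9, 0.9, 0.1, 0.0],
            ]
        ),
    )
    depths = {"deep1": 15, "deep2": 17, "shallow1": 1, "shallow2": 3}
    zones = zone_cut(upgma(dm), 2, depths)
    assert zones["shallow1"] == zones["shallow2"] == "Zone 1"
    assert zones["deep1"] == zones["deep2"] == "Zone 2"


# ---------------------------------------------------------------------------
# PCoA


def test_pcoa_collinear_points():
    dm = DistanceMatrix(
        ["P0", "P1", "P2"],
        np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float) / 2.0,
    )
    res = pcoa(dm)
    # one dominant axis carries essentially all positive variance
    assert res.proportion_explained[0] == pytest.approx(1.0, abs=1e-8)
    c = res.coordinates.to_numpy()
    for i in range(3):
        for j in range(3):
            got = np.linalg.norm(c[i] - c[j])
            assert got == pytest.approx(dm.data[i, j], abs=1e-8)


def test_pcoa_zero_matrix():
    dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
    res = pcoa(dm)
    assert np.allclose(res.eigenvalues, 0.0, atol=1e-12)


def test_pcoa_reconstructs_euclidean_distances():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(8, 3))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    d /= d.max()  # keep within [0, 1] for the container contract
    dm = DistanceMatrix([f"p{i}" for i in range(8)], d)
    res = pcoa(dm)
    c = res.coordinates.to_numpy()
    rec = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
    assert np.allclose(rec, d, atol=1e-8)


def test_pcoa_eigenvalues_match_skbio():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(13)
    pts = rng.normal(size=(7, 4))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    d /= d.max()
    dm = DistanceMatrix([f"p{i}" for i in range(7)], d)
    ours = pcoa(dm)
    theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d, dm.labels))
    assert np.allclose(
        ours.eigenvalues[:6], theirs.eigvals.to_numpy()[:6], atol=1e-8
    )


# ---------------------------------------------------------------------------
# ANOVA


def test_anova_equal_means():
    f, p = anova_oneway([[1, 2, 3], [1, 2, 3]])
    assert f == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_anova_hand_case():
    f, p = anova_oneway([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert f == pytest.approx(27.0)
    assert p == pytest.approx(stats.f.sf(27.0, 2, 6), rel=1e-10)


def test_anova_two_groups_equals_t_squared():
    rng = np.random.default_rng(2)
    a, b = rng.normal(size=10), rng.normal(loc=0.5, size=12)
    f, p = anova_oneway([list(a), list(b)])
    t, pt = stats.ttest_ind(a, b)
    assert f == pytest.approx(t**2, rel=1e-10)
    assert p == pytest.approx(pt, rel=1e-10)


def test_anova_rejects_degenerate_groups():
    with pytest.raises(InvalidInputError):
        anova_oneway([[1.0, 2.0]])


# ---------------------------------------------------------------------------
# table-level distance matrices


def test_distance_matrix_from_table(toy_table):
    dm = distance_matrix(toy_table, "jaccard")
    assert dm.labels == toy_table.sample_ids
    assert dm.get("A1_0-2", "A1_0-2") == 0.0
    i, j = 0, 1
    expected = jaccard_distance(toy_table.counts[i], toy_table.counts[j])
    assert dm.get("A1_0-2", "A1_2-4") == pytest.approx(expected)


def test_distance_matrix_unknown_metric(toy_table):
    with pytest.raises(InvalidInputError):
        distance_matrix(toy_table, "bray")
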