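"""JC distances, NJ recovery on additive matrices, bootstrap determinism,
and Robinson-Foulds vs an independent library."""

import math

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from plastcomp.alignment import AlignmentMatrix
from plastcomp.trees import (
    DistanceMatrix,
    bootstrap_support,
    jc_distance,
    neighbor_joining,
    parse_newick,
    robinson_foulds,
)


def _dendropy_rf(newick1, newick2):
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick2, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return treecompare.symmetric_difference(t1, t2)


def random_additive_tree(n_leaves, rng):
    """Random topology with random positive branch lengths; returns
    (newick, sorted taxa, exact patristic distance matrix)."""
    subtrees = [f"L{i}" for i in range(n_leaves)]
    groups = [(f"L{i}",) for i in range(n_leaves)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        la, lb = 0.1 + rng.random(), 0.1 + rng.random()
        merged = f"({subtrees[i]}:{la:.4f},{subtrees[j]}:{lb:.4f})"
        merged_group = groups[i] + groups[j]
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)] + [merged]
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] + [merged_group]
    taxa = sorted(groups[0])
    newick = subtrees[0] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    mat = np.zeros((len(taxa), len(taxa)))
    for i, x in enumerate(taxa):
        for j, y in enumerate(taxa):
            if i < j:
                ti = tree.taxon_namespace.get_taxon(x)
                tj = tree.taxon_namespace.get_taxon(y)
                mat[i, j] = mat[j, i] = pdm.patristic_distance(ti, tj)
    return newick, taxa, mat


def test_jc_identical_and_closed_form():
    aln = AlignmentMatrix.from_dict({"a": "ACGT" * 25, "b": "ACGT" * 25})
    assert jc_distance(aln).d[0, 1] == 0.0
    # p = 0.0369 -> d ~ 0.0379 (hand calculator)
    p = 0.0369
    d = -0.75 * math.log(1 - 4 * p / 3)
    assert d == pytest.approx(0.0379, abs=5e-4)


def test_jc_saturation_flagged():
    aln = AlignmentMatrix.from_dict({"a": "A" * 100, "b": "C" * 100})
    dm = jc_distance(aln)
    assert math.isnan(dm.d[0, 1])
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(["a", "b", "c"], np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0.0]])))


def test_jc_simulation_recovery(rng):
    """Estimated distance within 3 SE of the true distance 0.1."""
    n, d_true = 30_000, 0.1
    p_expect = 0.75 * (1 - math.exp(-4 * d_true / 3))
    s1 = rng.choice(list("ACGT"), size=n)
    s2 = s1.copy()
    flip = rng.random(n) < p_expect
    shift = rng.integers(1, 4, size=n)
    codes = {b: i for i, b in enumerate("ACGT")}
    inv = np.array(list("ACGT"))
    s2[flip] = inv[(np.vectorize(codes.get)(s1) + shift) % 4][flip]
    aln = AlignmentMatrix.from_dict({"a": "".join(s1), "b": "".join(s2)})
    d_hat = jc_distance(aln).d[0, 1]
    se = math.sqrt(p_expect * (1 - p_expect) / n) / (1 - 4 * p_expect / 3)
    assert abs(d_hat - d_true) < 3 * se


def test_nj_three_taxa_additive():
    dm = DistanceMatrix(["a", "b", "c"], np.array([[0.0, 3, 4], [3, 0.0, 5], [4, 5, 0.0]]))
    tree = neighbor_joining(dm)
    lengths = {n.name: n.length for n in tree.root.leaves()}
    assert lengths["a"] == pytest.approx(1.0)
    assert lengths["b"] == pytest.approx(2.0)
    assert lengths["c"] == pytest.approx(3.0)


def test_nj_quartet_structure():
    # AB|CD additive matrix: d(A,B)=2, d(C,D)=2, cross distances 6
    taxa = ["A", "B", "C", "D"]
    d = np.array(
        [[0.0, 2, 6, 6], [2, 0.0, 6, 6], [6, 6, 0.0, 2], [6, 6, 2, 0.0]]
    )
    tree = neighbor_joining(DistanceMatrix(taxa, d))
    assert frozenset({"C", "D"}) in tree.bipartitions() or frozenset({"A", "B"}) in tree.bipartitions()


def test_nj_recovers_random_additive_trees(rng):
    """NJ is consistent on additive matrices (trees up to 10 leaves)."""
    for n_leaves in (5, 7, 10):
        for _ in range(5):
            newick, taxa, mat = random_additive_tree(n_leaves, rng)
            est = neighbor_joining(DistanceMatrix(taxa, mat))
            assert _dendropy_rf(newick, est.newick()) == 0


def test_rf_trivial_and_smallest():
    t = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
    assert robinson_foulds(t, t) == 0
    u = parse_newick("((a:1,c:1):1,(b:1,d:1):1);")
    assert robinson_foulds(t, u) == 2


def test_rf_matches_dendropy_on_random_trees(rng):
    for _ in range(10):
        n1, taxa, _ = random_additive_tree(8, rng)
        n2, _, _ = random_additive_tree(8, rng)
        mine = robinson_foulds(parse_newick(n1), parse_newick(n2))
        assert mine == _dendropy_rf(n1, n2)


def test_bootstrap_deterministic_and_confident(rng):
    newick, taxa, mat = random_additive_tree(6, rng)
    # long clean alignment simulated on the tree distances: use JC pair sim
    # via the package simulator is overkill here; resample a planted alignment
    from plastcomp.plan import toy_plan
    from plastcomp.sim import SimConfig, evolve

    cfg = SimConfig(plan=toy_plan(), hotspot_labels={}, seed=99)
    _, truth = evolve(cfg)
    aln = truth.alignment
    t1 = bootstrap_support(aln, n_reps=20, seed=5)
    t2 = bootstrap_support(aln, n_reps=20, seed=5)
    s1 = sorted(n.support for n, _ in t1.edges_with_clades())
    s2 = sorted(n.support for n, _ in t2.edges_with_clades())
    assert s1 == s2
    # clean, long alignment: every true bipartition strongly supported
    true_tree = parse_newick(truth.tree)
    assert robinson_foulds(t1, true_tree) == 0
    assert min(s1) >= 0.95


def test_bootstrap_on_identical_sequences():
    aln = AlignmentMatrix.from_dict({t: "ACGT" * 100 for t in "abcd"})
    tree = bootstrap_support(aln, n_reps=10, seed=1)
    for node, _ in tree.edges_with_clades():
        assert node.support is not None
    # star-like: zero-length internal branches
    assert all(n.length == 0 for n, _ in tree.edges_with_clades())


def test_rf_leafset_mismatch_errors():
    with pytest.raises(ValueError):
        robinson_foulds(parse_newick("((a:1,b:1):1,c:1);"), parse_newick("((a:1,b:1):1,d:1);"))
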