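import math

import numpy as np
import pytest

import genefam as gf
from genefam.io_formats import PhyloTree, TreeNode
from genefam.phylo_classify import MSA, DistanceMatrix


def _msa(*rows):
    return MSA([gf.SequenceRecord(f"s{i}", r) for i, r in enumerate(rows)])


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def test_identical_sequences_align_gap_free():
    msa = gf.align_family([gf.SequenceRecord(f"s{i}", "MKVWEDLYR") for i in range(4)])
    assert all("-" not in r.residues for r in msa.records)
    assert msa.n_columns == 9


def test_three_sequence_hand_alignment():
    msa = gf.align_family([gf.SequenceRecord("a", "MKV"),
                           gf.SequenceRecord("b", "MRV"),
                           gf.SequenceRecord("c", "MKV")])
    assert msa.n_columns == 3
    middle = {r.id: r.residues[1] for r in msa.records}
    assert middle == {"a": "K", "b": "R", "c": "K"}


def test_alignment_width_at_least_longest_input():
    seqs = [gf.SequenceRecord("a", "MKVWEDLYRAGH"),
            gf.SequenceRecord("b", "MKVDLYRAGH"),
            gf.SequenceRecord("c", "MKVWEDLY")]
    msa = gf.align_family(seqs)
    assert msa.n_columns >= 12
    # degapped rows reproduce the inputs
    degapped = {r.id: r.residues.replace("-", "") for r in msa.records}
    assert degapped == {s.id: s.residues for s in seqs}


def test_alignment_needs_three_sequences():
    with pytest.raises(ValueError):
        gf.align_family([gf.SequenceRecord("a", "MK"), gf.SequenceRecord("b", "MK")])


# ---------------------------------------------------------------------------
# Poisson distances
# ---------------------------------------------------------------------------

def test_poisson_distance_identical_and_hand_value():
    msa = _msa("AAAAAAAAAA", "AAAAAAAAAC", "AAAAAAAAAA")
    dm = gf.poisson_distance(msa)
    assert dm.d[0, 2] == 0.0
    assert math.isclose(dm.d[0, 1], -math.log(0.9), rel_tol=1e-12)


def test_poisson_distance_pairwise_deletion_ignores_gap_columns():
    # pair (0,1): 10 shared columns, 1 mismatch; gaps in row 2 don't matter
    msa = _msa("ACDEFGHIKL", "ACDEFGHIKV", "ACDEF-----")
    dm = gf.poisson_distance(msa)
    assert math.isclose(dm.d[0, 1], -math.log(0.9))
    assert dm.d[0, 2] == 0.0   # the 5 shared columns agree


def test_poisson_distance_zero_overlap_is_error():
    msa = _msa("AC----", "--DE--", "ACDEFG")
    with pytest.raises(ValueError, match="shared"):
        gf.poisson_distance(msa)


def test_poisson_distance_saturation_is_error():
    msa = _msa("AAAA", "CCCC", "AAAA")
    with pytest.raises(ValueError, match="saturated"):
        gf.poisson_distance(msa)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def test_nj_three_taxa_closed_form():
    dm = DistanceMatrix(["a", "b", "c"],
                        np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0.0]]))
    tree = gf.nj_tree(dm)
    lengths = {c.name: c.length for c in tree.root.children}
    assert lengths == {"a": 0.0, "b": 2.0, "c": 4.0}


def test_nj_recovers_additive_four_taxon_tree():
    # tree ((a:1,b:2):1,(c:3,d:4)) -> additive distances
    d = np.array([
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0.0],
    ])
    dm = DistanceMatrix(list("abcd"), d)
    tree = gf.nj_tree(dm)
    assert set(map(frozenset, tree.bipartitions())) == {frozenset({"c", "d"})} \
        or list(tree.bipartitions()) == [frozenset({"c", "d"})]
    for i, x in enumerate("abcd"):
        for j, y in enumerate("abcd"):
            if i < j:
                assert math.isclose(tree.patristic(x, y), d[i, j], abs_tol=1e-12)


def test_nj_deterministic_on_ties():
    d = np.ones((4, 4)) - np.eye(4)
    dm = DistanceMatrix(list("abcd"), d)
    t1 = gf.nj_tree(dm)
    t2 = gf.nj_tree(dm)
    from genefam.io_formats import newick_string
    assert newick_string(t1) == newick_string(t2)


def test_distance_matrix_rejects_asymmetry():
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0.0]]))


def _random_additive_tree(rng, n):
    """Random binary unrooted tree with positive lengths + its distance matrix."""
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.1, 2.0)))
             for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        new = TreeNode(children=[b, a], length=float(rng.uniform(0.1, 2.0)))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [new]
    tree = PhyloTree(root=TreeNode(children=nodes))
    labels = sorted(tree.leaf_names())
    d = np.zeros((n, n))
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if i < j:
                d[i, j] = d[j, i] = tree.patristic(x, y)
    return tree, DistanceMatrix(labels, d)


def test_nj_exact_on_random_additive_matrices():
    rng = np.random.default_rng(42)
    for _ in range(25):
        n = int(rng.integers(4, 9))
        true_tree, dm = _random_additive_tree(rng, n)
        est = gf.nj_tree(dm)
        assert set(est.bipartitions()) == set(true_tree.bipartitions())
        for i, x in enumerate(dm.labels):
            for j, y in enumerate(dm.labels):
                if i < j:
                    assert math.isclose(est.patristic(x, y), dm.d[i, j],
                                        abs_tol=1e-9)


def test_nj_topology_matches_scikit_bio():
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj
    rng = np.random.default_rng(8)
    _, dm = _random_additive_tree(rng, 7)
    ours = gf.nj_tree(dm)
    sk_tree = skbio_nj(SkbioDM(dm.d, ids=dm.labels))
    sk_bips = set()
    total = set(dm.labels)
    for node in sk_tree.non_tips():
        below = frozenset(t.name for t in node.tips())
        if 1 < len(below) < len(total) - 1:
            anchor = min(total)
            side = below if anchor not in below else frozenset(total - below)
            sk_bips.add(frozenset(side))
    assert set(ours.bipartitions()) == sk_bips


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_constant_alignment_gives_full_support():
    # zero variable columns: every resample is identical, so the (tie-broken
    # but deterministic) tree recurs in all replicates and supports are 100
    msa = _msa("ACDEFGHIKL", "ACDEFGHIKL", "ACDEFGHIKL", "ACDEFGHIKL",
               "ACDEFGHIKL")
    tree = gf.nj_tree(gf.poisson_distance(msa))
    supports = gf.bootstrap_supports(msa, n_replicates=10, seed=0)
    for bip in tree.bipartitions():
        assert supports.get(bip, 0.0) == 100.0


def test_bootstrap_single_replicate_supports_binary():
    msa = _msa("ACDEFGHIKL", "ACDEFGHIKV", "ACDEWGHIKV", "MCDEWGHIKV")
    supports = gf.bootstrap_supports(msa, n_replicates=1, seed=3)
    assert set(supports.values()) <= {0.0, 100.0}


def test_bootstrap_separated_clades_high_support():
    rng = np.random.default_rng(1)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    core_a = "".join(rng.choice(aa, size=60))
    core_b = list(core_a)
    for k in rng.choice(60, size=20, replace=False):
        core_b[k] = str(rng.choice(aa))
    core_b = "".join(core_b)

    def noisy(core):
        s = list(core)
        for k in rng.choice(60, size=3, replace=False):
            s[k] = str(rng.choice(aa))
        return "".join(s)

    rows = [gf.SequenceRecord(f"a{i}", noisy(core_a)) for i in range(3)] + \
           [gf.SequenceRecord(f"b{i}", noisy(core_b)) for i in range(3)]
    msa = MSA(rows)
    supports = gf.bootstrap_supports(msa, n_replicates=100, seed=1)
    clade = frozenset({"b0", "b1", "b2"})
    assert supports.get(clade, 0.0) >= 95.0


def test_bootstrap_permutation_equivariance():
    msa = _msa("ACDEFGHIKL", "ACDEFGHIKV", "ACDEWGHIKV", "MCDEWGHIKV")
    sup1 = gf.bootstrap_supports(msa, n_replicates=50, seed=5)
    renamed = MSA([gf.SequenceRecord(f"z{r.id}", r.residues) for r in msa.records])
    sup2 = gf.bootstrap_supports(renamed, n_replicates=50, seed=5)
    mapped = {frozenset("z" + x for x in bip): v for bip, v in sup1.items()}
    assert mapped == sup2


# ---------------------------------------------------------------------------
# subgroup assignment
# ---------------------------------------------------------------------------

def _tree(newick):
    return gf.read_newick(newick)


def test_assignment_sister_to_single_reference():
    t = _tree("((q1:1,R3:1):1,(R1:1,R2:1):1,out:3);")
    asn = gf.assign_subgroups(t, {"R1": "A1", "R2": "A1", "R3": "A3", "out": "A5"})
    assert asn.labels["q1"] == "A3"
    assert asn.method["q1"] == "clade"


def test_assignment_mixed_clade_uses_nearest_reference():
    t = _tree("(((RA:1,RB:4):1,q1:0.5):1,(x1:1,x2:1):1,RC:5);")
    asn = gf.assign_subgroups(t, {"RA": "A1", "RB": "A2", "RC": "A4"})
    assert asn.labels["q1"] == "A1"
    assert asn.method["q1"] == "nearest"


def test_assignment_missing_label_error():
    t = _tree("((q1:1,R1:1):1,R2:1,R3:1);")
    with pytest.raises(ValueError, match="A9"):
        gf.assign_subgroups(t, {"R1": "A1", "R2": "A2", "R9": "A9"})


def test_assignment_covers_all_queries(small_sim):
    bundle, truth, refs, _ = small_sim
    fam = sorted(truth.family_members)
    seqs = [bundle.proteins[g] for g in fam] + list(refs)
    msa = gf.align_family(seqs)
    tree = gf.nj_tree(gf.poisson_distance(msa))
    asn = gf.assign_subgroups(tree, {r.id: r.description for r in refs})
    assert set(asn.labels) == set(fam)
    correct = sum(asn.labels[g] == truth.family_members[g] for g in fam)
    assert correct >= 0.95 * len(fam)
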