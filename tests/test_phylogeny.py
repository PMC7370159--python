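"""PCG concatenation, neighbor joining, newick round-trips, monophyly."""
import dendropy
import numpy as np
import pytest

from helpers import random_additive, rf_unrooted
from mitochar import (DistanceMatrix, GeneFeature, MitoRecord, concatenate_pcgs,
                      is_monophyletic, monophyly_report, nj_tree, p_distance_matrix,
                      read_newick, write_newick)
from mitochar.simulate import DEFAULT_GROUPS, DEFAULT_GUIDE_TREE, DEFAULT_OUTGROUP


def test_concatenate_toy_two_genes():
    # two CDS of 2 aa each (ATG + one codon + TAA): stops stripped -> 12 nt
    seq = "ATGGCATAA" + "ATGTGCTAA"
    rec = MitoRecord("t", "t", seq, features=[
        GeneFeature("ND1", "CDS", "H", 1, 9),
        GeneFeature("ND2", "CDS", "H", 10, 18),
    ])
    assert concatenate_pcgs(rec, require_all=False) == "ATGGCA" + "ATGTGC"
    with pytest.raises(ValueError, match="COX1"):
        concatenate_pcgs(rec)


def test_concatenation_length_is_three_times_aa_total(default_record):
    from mitochar import build_feature_table
    rows, _ = build_feature_table(default_record)
    aa_total = sum(r.aa_count for r in rows if r.aa_count)
    assert len(concatenate_pcgs(default_record)) == 3 * aa_total


def test_distance_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError, match="diagonal"):
        DistanceMatrix(("a", "b"), np.array([[1.0, 1.0], [1.0, 0.0]]))


def test_nj_three_taxa_closed_form():
    dm = DistanceMatrix(("a", "b", "c"), np.array([
        [0.0, 3.0, 4.0],
        [3.0, 0.0, 5.0],
        [4.0, 5.0, 0.0],
    ]))
    tree = nj_tree(dm)
    lengths = {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}
    assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})


def test_nj_four_taxa_additive_split():
    # (a,b) vs (c,d), terminal branches 1, internal branch 1
    m = np.array([
        [0.0, 2.0, 3.0, 3.0],
        [2.0, 0.0, 3.0, 3.0],
        [3.0, 3.0, 0.0, 2.0],
        [3.0, 3.0, 2.0, 0.0],
    ])
    tree = nj_tree(DistanceMatrix(("a", "b", "c", "d"), m))
    truth = dendropy.Tree.get(data="((a:1,b:1):1,c:1,d:1);", schema="newick",
                              taxon_namespace=tree.taxon_namespace)
    mine = dendropy.Tree.get(data=write_newick(tree), schema="newick",
                             taxon_namespace=tree.taxon_namespace)
    assert rf_unrooted(mine, truth) == 0


@pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
def test_nj_recovers_random_additive_trees(n):
    for seed in range(3):
        taxa, m, truth, ns = random_additive(n, seed)
        tree = nj_tree(DistanceMatrix(tuple(taxa), m))
        mine = dendropy.Tree.get(data=write_newick(tree), schema="newick", taxon_namespace=ns)
        assert rf_unrooted(mine, truth) == 0


def test_nj_agrees_with_independent_implementation():
    skbio = pytest.importorskip("skbio")
    from skbio.tree import nj as skbio_nj
    for seed in range(3):
        taxa, m, _, ns = random_additive(7, seed + 50)
        rng = np.random.default_rng(seed)
        noise = rng.uniform(0, 0.02, size=m.shape)
        m = m + noise + noise.T  # non-additive perturbation
        np.fill_diagonal(m, 0.0)
        mine = dendropy.Tree.get(data=write_newick(nj_tree(DistanceMatrix(tuple(taxa), m))),
                                 schema="newick", taxon_namespace=ns)
        other = dendropy.Tree.get(data=str(skbio_nj(skbio.DistanceMatrix(m, ids=taxa))),
                                  schema="newick", taxon_namespace=ns)
        assert rf_unrooted(mine, other) == 0


def test_nj_requires_three_taxa():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]])))


def test_newick_round_trip():
    tree = read_newick("(A:1,B:1,(C:1,D:1):1);")
    text = write_newick(tree)
    again = write_newick(read_newick(text))
    assert text == again
    with pytest.raises(ValueError):
        read_newick("A:1;")
    with pytest.raises(ValueError):
        read_newick("((A:1,B:1;")


def test_nj_output_round_trips_with_branch_lengths():
    rng = np.random.default_rng(2)
    for seed in range(3):
        taxa, m, _, _ = random_additive(6, seed + 100)
        tree = nj_tree(DistanceMatrix(tuple(taxa), m))
        text = write_newick(tree)
        assert write_newick(read_newick(text)) == text


def test_monophyly_on_guide_topology():
    tree = read_newick(DEFAULT_GUIDE_TREE)
    out = DEFAULT_OUTGROUP
    report = monophyly_report(tree, DEFAULT_GROUPS, out)
    assert report == {"Caranginae": True, "Naucratinae": True, "Trachinotinae": True}
    car = {t for t, g in DEFAULT_GROUPS.items() if g == "Caranginae"}
    nau = {t for t, g in DEFAULT_GROUPS.items() if g == "Naucratinae"}
    tra = {t for t, g in DEFAULT_GROUPS.items() if g == "Trachinotinae"}
    # nesting (Trachinotinae, (Naucratinae, Caranginae))
    assert is_monophyletic(tree, nau | car, out)
    assert not is_monophyletic(tree, tra | nau, out)
    # singleton and full ingroup are trivially monophyletic
    assert is_monophyletic(tree, {"Alepes_A"}, out)
    assert is_monophyletic(tree, car | nau | tra, out)
    with pytest.raises(ValueError, match="not in tree"):
        is_monophyletic(tree, {"nope"}, out)
    with pytest.raises(ValueError, match="outgroup"):
        is_monophyletic(tree, {out, "Alepes_A"}, out)


def test_monophyly_invariant_to_leaf_order():
    a = read_newick("(Out:1,(A1:1,A2:1):1,(B1:1,B2:1):1);")
    b = read_newick("((B2:1,B1:1):1,(A2:1,A1:1):1,Out:1);")
    for tree in (a, b):
        assert is_monophyletic(tree, {"A1", "A2"}, "Out")
        assert not is_monophyletic(tree, {"A1", "B1"}, "Out")


def test_simulated_tips_recover_guide_tree(sim_tips):
    concat = {label: concatenate_pcgs(rec) for label, rec in sim_tips.items()}
    assert len(next(iter(concat.values()))) > 10_000
    tree = nj_tree(p_distance_matrix(concat))
    guide = dendropy.Tree.get(data=DEFAULT_GUIDE_TREE, schema="newick",
                              taxon_namespace=tree.taxon_namespace,
                              preserve_underscores=True)
    mine = dendropy.Tree.get(data=write_newick(tree), schema="newick",
                             taxon_namespace=tree.taxon_namespace,
                             preserve_underscores=True)
    assert rf_unrooted(mine, guide) == 0
    report = monophyly_report(tree, DEFAULT_GROUPS, DEFAULT_OUTGROUP)
    assert all(report.values())
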