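"""Shared independent oracles for the test suite.

These deliberately re-derive quantities by brute force (recursive pathway
enumeration, path-length matrices from explicit trees) so the tests do not
reuse the code paths they are checking.
"""
from __future__ import annotations

import random

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from mitochar.codes import is_stop, translate_codon


def _aa(codon: str) -> str:
    return "*" if is_stop(codon) else translate_codon(codon)


def pathway_oracle(a: str, b: str) -> tuple[float, float]:
    """Exhaustive recursive enumeration of NG86 mutational pathways.

    Returns pathway-averaged (synonymous, nonsynonymous) difference counts,
    skipping pathways through stop codons unless every pathway is blocked.
    """
    diff = tuple(i for i in range(3) if a[i] != b[i])
    if not diff:
        return 0.0, 0.0

    def walk(cur: str, remaining: tuple[int, ...], blocked: bool):
        if not remaining:
            return [((), blocked)]
        out = []
        for i, pos in enumerate(remaining):
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            step_syn = _aa(cur) == _aa(nxt)
            now_blocked = blocked or (is_stop(nxt) and nxt != b)
            for tail, tb in walk(nxt, remaining[:i] + remaining[i + 1:], now_blocked):
                out.append(((step_syn,) + tail, tb))
        return out

    all_paths = walk(a, diff, False)
    open_paths = [p for p in all_paths if not p[1]]
    use = open_paths or all_paths
    sd = sum(sum(1 for s in steps if s) for steps, _ in use) / len(use)
    nd = sum(sum(1 for s in steps if not s) for steps, _ in use) / len(use)
    return sd, nd


def rf_unrooted(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance between two trees treated as unrooted."""
    for t in (t1, t2):
        t.is_rooted = False
        t.update_bipartitions(suppress_unifurcations=True,
                              collapse_unrooted_basal_bifurcation=True)
    return treecompare.symmetric_difference(t1, t2)


def random_additive(n: int, seed: int):
    """Random binary tree with branch lengths plus its additive path-length matrix.

    Returns (taxa, matrix, tree, taxon_namespace).
    """
    r = random.Random(seed)
    taxa = [f"t{i}" for i in range(n)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        1.0, 0.0, taxon_namespace=ns, num_extant_tips=n, rng=r)
    for e in tree.edges():
        if e.length is not None:
            e.length = 0.05 + r.random()
    pdm = tree.phylogenetic_distance_matrix()
    m = np.zeros((n, n))
    for i, x in enumerate(taxa):
        for j, y in enumerate(taxa):
            if i != j:
                m[i, j] = pdm.distance(ns.get_taxon(x), ns.get_taxon(y))
    return taxa, m, tree, ns
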