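"""PCG concatenation, distance matrices, neighbor joining, and monophyly checks.

The tree-building route here is deliberately simple and fully specified:
p-distance on the concatenation of the 13 protein-coding genes (stop codons
removed), followed by Saitou-Nei neighbor joining.  Saturated model-based
inference (ML / Bayesian) is out of scope; monophyly statements can equally
be checked on externally supplied newick trees.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .codes import PCG_NAMES, normalize_gene_name
from .divergence import p_distance, strip_stop
from .genome import MitoRecord, extract_gene_sequence


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered taxon labels."""

    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} taxa")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix has non-finite entries")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.taxa.index(pair[0]), self.taxa.index(pair[1])
        return float(self.values[i, j])


def concatenate_pcgs(record: MitoRecord, require_all: bool = True) -> str:
    """Coding-sense PCG concatenation in genome order, stop codons removed.

    Both complete stops and incomplete T/TA remnants are stripped, so the
    result length equals 3x the summed amino-acid counts.  With
    ``require_all`` (default) the 13 canonical PCGs must all be present.
    """
    cds = record.by_category("CDS")
    found = {normalize_gene_name(f.name) for f in cds}
    missing = [g for g in PCG_NAMES if g not in found]
    if require_all and missing:
        raise ValueError(f"record {record.record_id} lacks protein-coding genes: {missing}")
    return "".join(strip_stop(extract_gene_sequence(record, f)) for f in cds)


def p_distance_matrix(seqs: dict[str, str], positions: str = "all") -> DistanceMatrix:
    """Pairwise p-distance matrix over aligned sequences keyed by taxon."""
    taxa = tuple(sorted(seqs))
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(seqs[taxa[i]], seqs[taxa[j]], positions)
    return DistanceMatrix(taxa=taxa, values=d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Ties in Q are broken by lexicographic order of the joined pair's labels
    (internal nodes carry synthetic labels); negative branch lengths are
    clamped to zero.  The returned tree is unrooted with a basal trifurcation.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    ns = dendropy.TaxonNamespace(list(dm.taxa))
    nodes: dict[str, dendropy.Node] = {}
    for label in dm.taxa:
        node = dendropy.Node(taxon=ns.get_taxon(label))
        nodes[label] = node
    D: dict[frozenset, float] = {}
    for i, x in enumerate(dm.taxa):
        for j in range(i + 1, n):
            D[frozenset((x, dm.taxa[j]))] = float(dm.values[i, j])
    active = sorted(dm.taxa)
    k = 0
    while len(active) > 3:
        m = len(active)
        r = {x: sum(D[frozenset((x, y))] for y in active if y != x) for x in active}
        best = None
        for i, x in enumerate(active):
            for y in active[i + 1:]:
                q = (m - 2) * D[frozenset((x, y))] - r[x] - r[y]
                key = (q, tuple(sorted((x, y))))
                if best is None or key < best[0]:
                    best = (key, x, y)
        _, x, y = best
        dxy = D[frozenset((x, y))]
        bx = 0.5 * dxy + (r[x] - r[y]) / (2.0 * (m - 2))
        by = dxy - bx
        new_label = f"__nj{k}"
        k += 1
        parent = dendropy.Node()
        parent.add_child(nodes[x])
        parent.add_child(nodes[y])
        nodes[x].edge.length = max(bx, 0.0)
        nodes[y].edge.length = max(by, 0.0)
        nodes[new_label] = parent
        for z in active:
            if z in (x, y):
                continue
            D[frozenset((new_label, z))] = 0.5 * (
                D[frozenset((x, z))] + D[frozenset((y, z))] - dxy
            )
        active = sorted([z for z in active if z not in (x, y)] + [new_label])
    a, b, c = active
    root = dendropy.Node()
    dab, dac, dbc = D[frozenset((a, b))], D[frozenset((a, c))], D[frozenset((b, c))]
    for label, bl in ((a, (dab + dac - dbc) / 2.0),
                      (b, (dab + dbc - dac) / 2.0),
                      (c, (dac + dbc - dab) / 2.0)):
        root.add_child(nodes[label])
        nodes[label].edge.length = max(bl, 0.0)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize to newick with branch lengths at 6 decimals."""
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True,
        real_value_format_specifier=".6f",
    ).strip()


def read_newick(text: str) -> dendropy.Tree:
    """Parse a newick string; requires at least 3 leaves."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"cannot parse newick: {exc}") from exc
    if len(tree.leaf_nodes()) < 3:
        raise ValueError("tree must have at least 3 leaves")
    return tree


def read_newick_file(path: str | Path) -> dendropy.Tree:
    return read_newick(Path(path).read_text())


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def is_monophyletic(tree: dendropy.Tree, taxa: set[str], outgroup: str) -> bool:
    """True iff ``taxa`` form exactly one clade after rooting on ``outgroup``."""
    labels = leaf_labels(tree)
    unknown = (set(taxa) | {outgroup}) - labels
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    if outgroup in taxa:
        raise ValueError("outgroup must not be part of the tested group")
    taxa = set(taxa)
    if len(taxa) == 1:
        return True
    work = tree.clone(depth=1)
    og = next(l for l in work.leaf_node_iter() if l.taxon.label == outgroup)
    work.reroot_at_edge(og.edge, update_bipartitions=False)
    mrca = work.mrca(taxa=[l.taxon for l in work.leaf_node_iter() if l.taxon.label in taxa])
    clade = {l.taxon.label for l in mrca.leaf_iter()}
    return clade == taxa


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a 2-column tab-delimited taxon -> group map."""
    groups = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        taxon, group = line.split("\t")[:2]
        groups[taxon] = group
    return groups


def monophyly_report(tree: dendropy.Tree, groups: dict[str, str],
                     outgroup: str) -> dict[str, bool]:
    """Monophyly verdict for every group in a taxon -> group map."""
    by_group: dict[str, set[str]] = {}
    for taxon, group in groups.items():
        by_group.setdefault(group, set()).add(taxon)
    return {g: is_monophyletic(tree, members, outgroup)
            for g, members in sorted(by_group.items())}
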