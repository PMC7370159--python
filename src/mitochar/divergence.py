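"""Pairwise evolutionary-rate statistics: Nei-Gojobori (1986) Ka/Ks and
p-distances at codon-position resolution.

The NG86 method counts synonymous and nonsynonymous *sites* per codon by
enumerating all single-nucleotide neighbours, and synonymous and
nonsynonymous *differences* per codon pair by averaging over all mutational
pathways between the two codons.  Changes that create a stop codon are
excluded from the site normalization, and pathways passing through a stop
codon are skipped (when every pathway is blocked the average is taken over
all of them).  Proportions are corrected with the Jukes-Cantor formula
d = -(3/4) ln(1 - (4/3) p); Ka/Ks = dN/dS.  All of this is under the
vertebrate mitochondrial code.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import pandas as pd

from .codes import NUCLEOTIDES, PCG_NAMES, is_stop, normalize_gene_name, translate_codon

_POSITION_CHOICES = ("all", "1+2", "full")


@dataclass
class PairwiseDivergence:
    """NG86 counts, corrected rates, and p-distance variants for one pair."""

    gene: str
    taxa: tuple[str, str]
    Sd: float
    Nd: float
    S_sites: float
    N_sites: float
    pS: float
    pN: float
    dS: float | None       # None when the JC correction is undefined (p >= 3/4)
    dN: float | None
    ka_ks: float | None    # None when dS is 0 or undefined
    p12: float
    p_codon: float
    p_full: float
    n_codons: int


def _pairwise_sites(a: str, b: str, positions: str) -> list[int]:
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length ({len(a)} vs {len(b)}); align first")
    if positions not in _POSITION_CHOICES:
        raise ValueError(f"positions must be one of {_POSITION_CHOICES}")
    if positions == "1+2" and len(a) % 3:
        raise ValueError("codon-position filter needs length divisible by 3")
    keep = []
    for i, (x, y) in enumerate(zip(a, b)):
        if x not in NUCLEOTIDES or y not in NUCLEOTIDES:
            continue  # N or gap: site deleted pairwise
        if positions == "1+2" and i % 3 == 2:
            continue
        keep.append(i)
    return keep


def p_distance(a: str, b: str, positions: str = "all") -> float:
    """Proportion of differing sites, with pairwise deletion of N/gap sites.

    ``positions``: "all"/"full" use every site; "1+2" restricts to the first
    and second codon positions (sequences must be codon-aligned).
    """
    a, b = a.upper(), b.upper()
    sites = _pairwise_sites(a, b, positions)
    if not sites:
        raise ValueError("no comparable sites after pairwise deletion")
    diffs = sum(1 for i in sites if a[i] != b[i])
    return diffs / len(sites)


def overall_mean_p(seqs: dict[str, str], positions: str = "all") -> float:
    """Unweighted mean p-distance over all unordered taxon pairs."""
    taxa = sorted(seqs)
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    vals = [p_distance(seqs[x], seqs[y], positions)
            for i, x in enumerate(taxa) for y in taxa[i + 1:]]
    return sum(vals) / len(vals)


@lru_cache(maxsize=None)
def ng86_site_count(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    At each position the synonymous fraction is (# amino-acid-preserving
    changes) / (3 - # stop-creating changes); stop-creating changes are
    excluded from the normalization.  Nonsynonymous sites are 3 minus the
    synonymous sites.
    """
    codon = codon.upper()
    if is_stop(codon):
        raise ValueError(f"stop codon {codon} has no NG86 site decomposition")
    aa = translate_codon(codon)
    syn_sites = 0.0
    for pos in range(3):
        n_syn = n_stop = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1:]
            if is_stop(mutant):
                n_stop += 1
            elif translate_codon(mutant) == aa:
                n_syn += 1
        denom = 3 - n_stop
        if denom:
            syn_sites += n_syn / denom
    return syn_sites, 3.0 - syn_sites


@lru_cache(maxsize=None)
def _pathway_counts(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences for one codon pair."""
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    open_paths, all_paths = [], []
    for order in permutations(diff_pos):
        cur = a
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if translate_codon_or_stop(cur) == translate_codon_or_stop(nxt):
                syn += 1
            else:
                nonsyn += 1
            if is_stop(nxt) and nxt != b:
                blocked = True  # intermediate stop codon
            cur = nxt
        all_paths.append((syn, nonsyn))
        if not blocked:
            open_paths.append((syn, nonsyn))
    paths = open_paths or all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def translate_codon_or_stop(codon: str) -> str:
    return "*" if is_stop(codon) else translate_codon(codon)


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_pair(a: str, b: str, gene: str = "", taxa: tuple[str, str] = ("a", "b"),
              corrected: bool = True) -> PairwiseDivergence:
    """NG86 divergence for a codon-aligned, stop-free sequence pair.

    Codons containing N or gaps in either sequence are deleted pairwise
    (whole codon).  ``corrected=False`` reports the uncorrected proportions
    pN/pS as dN/dS.
    """
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length ({len(a)} vs {len(b)})")
    if len(a) % 3:
        raise ValueError("sequence length must be a codon multiple")
    s1 = s2 = 0.0
    sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if any(x not in NUCLEOTIDES for x in ca + cb):
            continue
        if is_stop(ca) or is_stop(cb):
            raise ValueError(f"stop codon at alignment position {i + 1}; strip stops first")
        n_codons += 1
        s1 += ng86_site_count(ca)[0]
        s2 += ng86_site_count(cb)[0]
        d = _pathway_counts(ca, cb)
        sd += d[0]
        nd += d[1]
    if n_codons == 0:
        raise ValueError("no comparable codons after pairwise deletion")
    S = (s1 + s2) / 2.0
    N = 3.0 * n_codons - S
    pS = sd / S if S else 0.0
    pN = nd / N if N else 0.0
    if corrected:
        dS, dN = _jc(pS), _jc(pN)
    else:
        dS, dN = pS, pN
    ka_ks = dN / dS if (dS not in (None, 0.0) and dN is not None) else None
    return PairwiseDivergence(
        gene=gene, taxa=taxa, Sd=sd, Nd=nd, S_sites=S, N_sites=N, pS=pS, pN=pN,
        dS=dS, dN=dN, ka_ks=ka_ks,
        p12=p_distance(a, b, "1+2"), p_codon=p_distance(a, b, "all"),
        p_full=p_distance(a, b, "full"), n_codons=n_codons,
    )


def strip_stop(cds: str) -> str:
    """Remove a trailing complete stop codon or incomplete T/TA remnant."""
    cds = cds.upper()
    rem = len(cds) % 3
    if rem:
        return cds[:-rem]
    return cds[:-3] if is_stop(cds[-3:]) else cds


def gene_divergence(gene: str, a: str, b: str, taxa: tuple[str, str] = ("a", "b"),
                    corrected: bool = True) -> PairwiseDivergence:
    """Divergence for one gene pair given full coding sequences (stops allowed).

    Ka/Ks and codon p-distances use the stop-stripped alignment; p_full is
    computed over the full input sequences.
    """
    div = ng86_pair(strip_stop(a), strip_stop(b), gene=gene, taxa=taxa, corrected=corrected)
    div.p_full = p_distance(a, b, "full")
    return div


def kaks_gene_table(alignments: dict[str, dict[str, str]],
                    corrected: bool = True) -> pd.DataFrame:
    """Per-gene mean Ka/Ks and mean p-distances over all taxon pairs.

    ``alignments`` maps gene name -> {taxon: aligned full coding sequence}.
    The 13 canonical PCGs must be present; genes are reported in genome
    order.  A gene whose pairs are all undefined gets NaN.
    """
    canon = {normalize_gene_name(g): g for g in alignments}
    missing = [g for g in PCG_NAMES if g not in canon]
    if missing:
        raise ValueError(f"alignments lack canonical protein-coding genes: {missing}")
    rows = []
    for gene in PCG_NAMES:
        seqs = alignments[canon[gene]]
        taxa = sorted(seqs)
        if len(taxa) < 2:
            raise ValueError(f"gene {gene}: need at least two taxa")
        divs = [gene_divergence(gene, seqs[x], seqs[y], taxa=(x, y), corrected=corrected)
                for i, x in enumerate(taxa) for y in taxa[i + 1:]]
        defined = [d.ka_ks for d in divs if d.ka_ks is not None]
        rows.append({
            "gene": gene,
            "mean_ka_ks": sum(defined) / len(defined) if defined else math.nan,
            "n_pairs": len(divs),
            "n_defined": len(defined),
            "mean_p12": sum(d.p12 for d in divs) / len(divs),
            "mean_p_codon": sum(d.p_codon for d in divs) / len(divs),
            "mean_p_full": sum(d.p_full for d in divs) / len(divs),
        })
    return pd.DataFrame(rows).set_index("gene")
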