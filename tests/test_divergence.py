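"""p-distances and Nei-Gojobori Ka/Ks against brute-force oracles."""
import math

import numpy as np
import pytest

from helpers import pathway_oracle
from mitochar import (gene_divergence, kaks_gene_table, ng86_pair, ng86_site_count,
                      overall_mean_p, p_distance)
from mitochar.codes import PCG_NAMES, SENSE_CODONS
from mitochar.divergence import _pathway_counts, strip_stop


@pytest.mark.parametrize("a,b,positions,expected", [
    ("ACGT", "ACGT", "full", 0.0),
    ("ACGT", "ACGA", "full", 0.25),
    ("ATGAAA", "ATGAAG", "1+2", 0.0),
    ("ATGAAA", "ATGAAG", "all", 1 / 6),
])
def test_p_distance_hand_counts(a, b, positions, expected):
    assert p_distance(a, b, positions) == pytest.approx(expected)


def test_p_distance_pairwise_deletion_and_errors():
    assert p_distance("ANGT", "ACGA") == pytest.approx(1 / 3)  # N site dropped
    with pytest.raises(ValueError, match="length"):
        p_distance("ACG", "ACGT")
    with pytest.raises(ValueError):
        p_distance("NNN", "ACG")


def test_overall_mean_p():
    assert overall_mean_p({"x": "ACGT", "y": "ACGA"}) == pytest.approx(0.25)
    assert overall_mean_p({"x": "ACGT", "y": "ACGT", "z": "ACGT"}) == 0.0
    seqs = {"x": "AAAA", "y": "AAAT", "z": "ATTT"}
    hand = (p_distance("AAAA", "AAAT") + p_distance("AAAA", "ATTT")
            + p_distance("AAAT", "ATTT")) / 3
    assert overall_mean_p(seqs) == pytest.approx(hand)


def test_site_counts_enumeration_values():
    # frozen from exhaustive single-neighbour enumeration under transl_table 2
    syn, nonsyn = ng86_site_count("TTT")  # Phe: only 3rd-position T->C is synonymous
    assert syn == pytest.approx(1 / 3) and nonsyn == pytest.approx(8 / 3)
    syn, nonsyn = ng86_site_count("GGG")  # Gly: fully degenerate 3rd position
    assert syn == pytest.approx(1.0) and nonsyn == pytest.approx(2.0)


def test_site_counts_sum_to_three_without_stop_neighbours():
    for codon in ("TTT", "GGG", "CCC", "ATG"):
        assert sum(ng86_site_count(codon)) == pytest.approx(3.0)
    with pytest.raises(ValueError):
        ng86_site_count("TAA")


def test_pathway_counts_match_recursive_oracle_sample():
    rng = np.random.default_rng(3)
    for _ in range(300):
        a, b = rng.choice(SENSE_CODONS, size=2)
        assert _pathway_counts(a, b) == pytest.approx(pathway_oracle(a, b))


def test_pathway_substitution_conservation():
    sd, nd = _pathway_counts("TTT", "TCC")  # two differing positions
    assert sd + nd == pytest.approx(2.0)


def test_ng86_identical_sequences():
    div = ng86_pair("ATGGCA", "ATGGCA")
    assert div.Sd == 0 and div.Nd == 0 and div.ka_ks is None


def test_ng86_toy_pair_matches_oracle():
    # ten codons: one synonymous (GGA->GGG) and one nonsynonymous (TTT->GTT) difference
    a = "ATG" + "GGA" + "TTT" + "GCA" * 7
    b = "ATG" + "GGG" + "GTT" + "GCA" * 7
    div = ng86_pair(a, b)
    sd = nd = s1 = s2 = 0.0
    for i in range(0, len(a), 3):
        d = pathway_oracle(a[i:i + 3], b[i:i + 3])
        sd += d[0]
        nd += d[1]
        s1 += ng86_site_count(a[i:i + 3])[0]
        s2 += ng86_site_count(b[i:i + 3])[0]
    S = (s1 + s2) / 2
    N = 3 * 10 - S
    assert div.Sd == pytest.approx(sd) and div.Nd == pytest.approx(nd)
    assert div.S_sites == pytest.approx(S) and div.N_sites == pytest.approx(N)
    assert div.pS == pytest.approx(sd / S) and div.pN == pytest.approx(nd / N)
    # Jukes-Cantor correction applied to both proportions
    assert div.dS == pytest.approx(-0.75 * math.log(1 - 4 * div.pS / 3))
    assert div.ka_ks == pytest.approx(div.dN / div.dS)


def test_ng86_symmetric_in_arguments():
    rng = np.random.default_rng(5)
    for _ in range(20):
        codons = rng.choice(SENSE_CODONS, size=30)
        a = "".join(codons)
        mutated = list(codons)
        for k in rng.integers(0, 30, size=4):
            mutated[k] = str(rng.choice(SENSE_CODONS))
        b = "".join(mutated)
        d1, d2 = ng86_pair(a, b), ng86_pair(b, a)
        assert d1.Sd == pytest.approx(d2.Sd) and d1.Nd == pytest.approx(d2.Nd)
        assert d1.S_sites == pytest.approx(d2.S_sites)


def test_ng86_rejects_stops_and_bad_lengths():
    with pytest.raises(ValueError, match="stop"):
        ng86_pair("ATGTAA", "ATGTAA")
    with pytest.raises(ValueError, match="codon multiple"):
        ng86_pair("ATGG", "ATGG")


def test_more_synonymous_differences_never_increase_kaks():
    # start with one nonsynonymous difference, then add synonymous ones
    base_a = ["ATG"] + ["GGA"] * 20
    base_b = ["ATG"] + ["GGA"] * 20
    base_b[1] = "CGA"  # Gly -> Arg, nonsynonymous
    prev = math.inf
    for n_syn in range(0, 6):
        b = list(base_b)
        for k in range(n_syn):
            b[2 + k] = "GGG"  # synonymous Gly change
        div = ng86_pair("".join(base_a), "".join(b))
        if div.ka_ks is not None:
            assert div.ka_ks <= prev + 1e-12
            prev = div.ka_ks


def test_gene_divergence_strips_stops():
    a = "ATG" + "GGA" * 3 + "TAA"
    b = "ATG" + "GGA" * 3 + "TAG"
    div = gene_divergence("g", a, b)
    assert div.n_codons == 4  # stop codon removed before NG86
    assert div.p_full == pytest.approx(1 / 15)  # full sequence keeps the stop difference
    assert strip_stop("ATGGCAT") == "ATGGCA"
    assert strip_stop("ATGGCATA") == "ATGGCA"


def test_kaks_gene_table_identical_and_pairwise():
    aln_identical = {g: {"x": "ATGGCAGCA", "y": "ATGGCAGCA", "z": "ATGGCAGCA"}
                     for g in PCG_NAMES}
    table = kaks_gene_table(aln_identical)
    assert list(table.index) == list(PCG_NAMES)
    assert table["mean_ka_ks"].isna().all()

    a = "ATG" + "GGA" + "TTT" + "GCA" * 7
    b = "ATG" + "GGG" + "GTT" + "GCA" * 7
    aln_two = {g: {"x": a, "y": b} for g in PCG_NAMES}
    table2 = kaks_gene_table(aln_two)
    single = ng86_pair(a, b)
    assert table2.loc["ATP8", "mean_ka_ks"] == pytest.approx(single.ka_ks)

    with pytest.raises(ValueError, match="ND5"):
        kaks_gene_table({g: {"x": a, "y": b} for g in PCG_NAMES if g != "ND5"})
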