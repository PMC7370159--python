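"""Codon frequency and relative synonymous codon usage (RSCU) over all PCGs.

RSCU(c) = n * x_c / sum over the synonymous family of c, where n is the
family size under the vertebrate mitochondrial code (transl_table 2).  An
RSCU of 1 means no preference within the family.  Leu and Ser are 6-codon
families spanning two codon boxes; the four mito stop codons (TAA, TAG,
AGA, AGG) form their own family.  Complete terminal stop codons are counted
(they appear in usage reports); incomplete stops contribute no codon.
"""
from __future__ import annotations

import math

import pandas as pd

from .codes import ALL_CODONS, FAMILY_OF, FAMILY_SIZE, STOP_CODONS, translate_codon


def count_codons(cds_list: list[str], strict: bool = False) -> dict[str, int]:
    """Tally codons over coding-sense CDS; trailing incomplete stops dropped.

    With ``strict`` an internal (non-terminal) stop codon raises, naming the
    CDS index and codon position.
    """
    counts = {c: 0 for c in ALL_CODONS}
    for idx, cds in enumerate(cds_list):
        cds = cds.upper()
        trimmed = cds[: len(cds) - len(cds) % 3]
        n_codons = len(trimmed) // 3
        for i in range(n_codons):
            codon = trimmed[3 * i: 3 * i + 3]
            if codon not in counts:
                continue  # ambiguous bases excluded
            if strict and codon in STOP_CODONS and i < n_codons - 1:
                raise ValueError(f"internal stop codon {codon} in CDS {idx} at codon {i}")
            counts[codon] += 1
    return counts


def rscu(counts: dict[str, int], include_stops: bool = True) -> pd.DataFrame:
    """Full 64-codon usage table with frequency and RSCU columns.

    Frequencies are proportions of all counted codons (stops excluded when
    ``include_stops`` is False).  RSCU is NaN for families never observed.
    """
    total = sum(n for c, n in counts.items()
                if include_stops or c not in STOP_CODONS)
    rows = []
    for codon in ALL_CODONS:
        fam = FAMILY_OF[codon]
        fam_total = sum(counts.get(c, 0) for c in fam)
        n = counts.get(codon, 0)
        if not include_stops and codon in STOP_CODONS:
            freq = 0.0
        else:
            freq = n / total if total else 0.0
        rows.append({
            "codon": codon,
            "amino_acid": translate_codon(codon),
            "family_size": FAMILY_SIZE[codon],
            "count": n,
            "frequency": freq,
            "rscu": FAMILY_SIZE[codon] * n / fam_total if fam_total else math.nan,
        })
    return pd.DataFrame(rows).set_index("codon")


def usage_report(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge per-species usage tables into one long-format report.

    Codons are displayed in the RNA alphabet (U for T).
    """
    if not tables:
        raise ValueError("need at least one usage table")
    rows = []
    for species, table in tables.items():
        for codon, row in table.iterrows():
            rows.append({
                "species": species,
                "codon": codon.replace("T", "U"),
                "amino_acid": row["amino_acid"],
                "count": int(row["count"]),
                "frequency": row["frequency"],
                "rscu": row["rscu"],
            })
    return pd.DataFrame(rows)
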