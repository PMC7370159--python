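"""Base composition and strand-asymmetry (AT/GC-skew) statistics.

AT-skew = (A - T) / (A + T) and GC-skew = (G - C) / (G + C), computed at
genome, gene, gene-class, and codon-position resolution.  Per-gene skews are
taken on coding-sense sequences, so L-strand genes (ND6 and eight tRNAs) are
reverse-complemented first — this is what makes ND6 flip sign relative to
the H-strand genes.  A skew with a zero denominator is flagged as undefined
(stored as None), never propagated as NaN.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .codes import PCG_NAMES, normalize_gene_name
from .genome import MitoRecord, extract_gene_sequence


@dataclass
class SkewProfile:
    """Base counts plus AT/GC content and skew for one labelled sequence."""

    label: str
    a: int
    c: int
    g: int
    t: int

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def at_percent(self) -> float:
        return 100.0 * (self.a + self.t) / self.total

    @property
    def gc_percent(self) -> float:
        return 100.0 * (self.g + self.c) / self.total

    @property
    def at_skew(self) -> float | None:
        denom = self.a + self.t
        return (self.a - self.t) / denom if denom else None

    @property
    def gc_skew(self) -> float | None:
        denom = self.g + self.c
        return (self.g - self.c) / denom if denom else None


def skew_profile(seq: str, label: str = "") -> SkewProfile:
    """Count bases (N excluded) and derive skews for a sequence."""
    seq = seq.upper()
    prof = SkewProfile(label=label, a=seq.count("A"), c=seq.count("C"),
                       g=seq.count("G"), t=seq.count("T"))
    if prof.total == 0:
        raise ValueError(f"no unambiguous bases in sequence {label!r}")
    return prof


def _canonical_cds(record: MitoRecord) -> list:
    cds = record.by_category("CDS")
    found = {normalize_gene_name(f.name) for f in cds}
    missing = [n for n in PCG_NAMES if n not in found]
    if missing:
        raise ValueError(f"record {record.record_id} lacks protein-coding genes: {missing}")
    return cds


def pcg_skew_table(record: MitoRecord) -> list[SkewProfile]:
    """Skew profile of each of the 13 PCGs (coding sense) plus their concatenation."""
    cds = _canonical_cds(record)
    profiles = []
    concat = []
    for f in cds:
        seq = extract_gene_sequence(record, f)
        concat.append(seq)
        profiles.append(skew_profile(seq, label=f.name))
    profiles.append(skew_profile("".join(concat), label="PCGs"))
    return profiles


def codon_position_composition(cds_list: list[str]) -> pd.DataFrame:
    """Percent A/C/G/T at each codon position over all codons of all CDS.

    Trailing incomplete stop remnants (length mod 3) are removed before
    tallying; complete stop codons are kept.
    """
    counts = {p: {b: 0 for b in "ACGT"} for p in (1, 2, 3)}
    for cds in cds_list:
        cds = cds.upper()
        if len(cds) < 3:
            raise ValueError("CDS shorter than one codon")
        trimmed = cds[: len(cds) - len(cds) % 3]
        for i in range(0, len(trimmed), 3):
            for p in (1, 2, 3):
                b = trimmed[i + p - 1]
                if b in "ACGT":
                    counts[p][b] += 1
    table = pd.DataFrame(counts).T  # rows = positions 1..3
    table.index.name = "position"
    return table.div(table.sum(axis=1), axis=0) * 100.0


def class_composition(record: MitoRecord) -> dict[str, SkewProfile]:
    """Skew profiles of the whole genome and of each gene class.

    Classes are concatenated in genome order, in coding sense.
    """
    out = {"genome": skew_profile(record.sequence, label="genome")}
    for category, label in (("CDS", "PCGs"), ("tRNA", "tRNAs"), ("rRNA", "rRNAs"),
                            ("control", "control")):
        feats = record.by_category(category)
        if not feats:
            continue
        concat = "".join(extract_gene_sequence(record, f) for f in feats)
        out[label] = skew_profile(concat, label=label)
    return out


def composition_frame(profiles: list[SkewProfile]) -> pd.DataFrame:
    """Tidy long table (label, counts, AT%, skews) for reporting."""
    return pd.DataFrame([
        {
            "label": p.label, "A": p.a, "C": p.c, "G": p.g, "T": p.t,
            "at_percent": p.at_percent, "gc_percent": p.gc_percent,
            "at_skew": p.at_skew, "gc_skew": p.gc_skew,
        }
        for p in profiles
    ])
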