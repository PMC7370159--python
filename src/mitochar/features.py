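"""Per-gene feature tables: sizes, GC%, start/stop codons, amino-acid counts,
and intergenic spacer / overlap accounting on the circular gene chain.

Mitochondrial protein-coding genes frequently end in an incomplete stop
codon ("T" or "TA") that is completed to UAA by post-transcriptional
polyadenylation; such stops are reported verbatim, never auto-extended.

The control region is excluded from the gene-adjacency chain: spacer and
overlap counts are among genes only, and the single chain gap that contains
the control region is reported separately in :class:`SpacerSummary`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .codes import STOP_CODONS, is_stop
from .genome import GeneFeature, MitoRecord, extract_gene_sequence, validate_record

# stop kinds and the number of nucleotides the incomplete remnant occupies
_INCOMPLETE_LEN = {"complete": 0, "TA": 2, "T": 1}


@dataclass
class FeatureRow:
    """One row of a per-gene summary table (Table-1 style)."""

    name: str
    category: str
    strand: str
    size_bp: int
    gc_percent: float
    aa_count: int | None = None
    start_codon: str | None = None
    stop_codon: str | None = None
    one_letter_code: str | None = None
    anticodon: str | None = None
    igs_to_next: int = 0  # signed; negative = overlap with the next gene


@dataclass
class SpacerSummary:
    """Counts and totals of intergenic spacers (IGS > 0) and overlaps (IGS < 0)."""

    n_spacers: int
    total_spacer_bp: int
    n_overlaps: int
    total_overlap_bp: int
    largest_spacer: tuple[tuple[str, str], int] | None
    control_gap: tuple[tuple[str, str], int] | None = None  # chain gap holding the control region


def gc_content(seq: str) -> float:
    """GC percentage of a sequence, N sites excluded."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("cannot compute GC content: no unambiguous bases")
    return 100.0 * (counts["G"] + counts["C"]) / total


def infer_codons(cds: str, strict: bool = False) -> tuple[str, str]:
    """Start codon and (possibly incomplete) stop codon of a coding-sense CDS.

    A CDS whose length is not a codon multiple carries an incomplete
    terminator: the trailing 1 or 2 nt remainder (expected "T" or "TA").
    """
    cds = cds.upper()
    if len(cds) < 6:
        raise ValueError(f"CDS too short to infer codons ({len(cds)} nt)")
    start = cds[:3]
    rem = len(cds) % 3
    if rem:
        stop = cds[-rem:]
        if stop not in ("T", "TA"):
            msg = f"incomplete terminator {stop!r} is not T or TA"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg)
    else:
        stop = cds[-3:]
        if not is_stop(stop):
            msg = f"final codon {stop!r} is not a stop under the vertebrate mito code"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg)
    return start, stop


def stop_kind(stop_codon: str) -> str:
    """Classify a reported stop codon string as complete / TA / T."""
    if len(stop_codon) == 3:
        return "complete"
    if stop_codon in ("TA", "T"):
        return stop_codon
    raise ValueError(f"unrecognized stop codon {stop_codon!r}")


def amino_acid_count(cds_length: int, stop_kind: str) -> int:
    """Number of encoded amino acids for a CDS of ``cds_length`` bp.

    A complete stop occupies a full codon (not translated); incomplete
    stops ("TA", "T") occupy 2 or 1 trailing nucleotides.
    """
    try:
        tail = _INCOMPLETE_LEN[stop_kind]
    except KeyError:
        raise ValueError(f"stop_kind must be one of {list(_INCOMPLETE_LEN)}, got {stop_kind!r}")
    coding = cds_length - tail
    if coding % 3:
        raise ValueError(
            f"CDS length {cds_length} with stop kind {stop_kind!r} is not codon-divisible"
        )
    n = coding // 3
    return n - 1 if stop_kind == "complete" else n


def _check_nested(genes: list[GeneFeature]) -> None:
    linear = [g for g in genes if not g.wraps]
    for i, a in enumerate(linear):
        for b in linear[i + 1:]:
            if (a.start <= b.start and b.end <= a.end and (a.start, a.end) != (b.start, b.end)):
                raise ValueError(f"feature {b.name} is nested inside {a.name}")
            if (b.start <= a.start and a.end <= b.end and (a.start, a.end) != (b.start, b.end)):
                raise ValueError(f"feature {a.name} is nested inside {b.name}")


def intergenic_lengths(record: MitoRecord) -> list[tuple[str, str, int]]:
    """Signed intergenic lengths between adjacent genes on the circle.

    igs = start(next) - end(current) - 1; the last gene pairs with the first
    across the origin.  The control region is not part of the chain.
    """
    genes = record.genes()
    if len(genes) < 2:
        raise ValueError("need at least two gene features for intergenic accounting")
    _check_nested(genes)
    L = record.length
    out = []
    for cur, nxt in zip(genes, genes[1:] + genes[:1]):
        gap = nxt.start - cur.end - 1
        if nxt is genes[0]:  # wrap pair
            gap = (nxt.start + L) - cur.end - 1
        out.append((cur.name, nxt.name, gap))
    return out


def _pair_contains_control(record: MitoRecord, cur_end: int, gap: int) -> bool:
    ctrl = record.control_region()
    if ctrl is None or gap <= 0:
        return False
    # gap interval on the circle, 1-based; contained if either end of the
    # control region falls inside the gap
    first = cur_end % record.length + 1
    for point in (ctrl.start, ctrl.end):
        if (point - first) % record.length < gap:
            return True
    return False


def summarize_spacers(record: MitoRecord,
                      igs: list[tuple[str, str, int]] | None = None) -> SpacerSummary:
    """Spacer/overlap counts over the gene chain, control-region gap set aside."""
    if igs is None:
        igs = intergenic_lengths(record)
    genes = record.genes()  # same order as the igs chain
    control_gap = None
    counted = []
    for cur, (a, b, gap) in zip(genes, igs):
        if _pair_contains_control(record, cur.end, gap):
            control_gap = ((a, b), gap)
        else:
            counted.append((a, b, gap))
    spacers = [(a, b, g) for a, b, g in counted if g > 0]
    overlaps = [(a, b, g) for a, b, g in counted if g < 0]
    largest = max(spacers, key=lambda t: t[2], default=None)
    return SpacerSummary(
        n_spacers=len(spacers),
        total_spacer_bp=sum(g for *_, g in spacers),
        n_overlaps=len(overlaps),
        total_overlap_bp=sum(-g for *_, g in overlaps),
        largest_spacer=((largest[0], largest[1]), largest[2]) if largest else None,
        control_gap=control_gap,
    )


def build_feature_table(record: MitoRecord) -> tuple[list[FeatureRow], SpacerSummary]:
    """One FeatureRow per gene (control region excluded) plus spacer summary."""
    problems = validate_record(record)
    if problems:
        raise ValueError("invalid record: " + "; ".join(problems))
    igs = intergenic_lengths(record)
    rows = []
    for f, (_, _, gap) in zip(record.genes(), igs):
        seq = extract_gene_sequence(record, f)
        row = FeatureRow(
            name=f.name, category=f.category, strand=f.strand,
            size_bp=f.span_length(record.length), gc_percent=gc_content(seq),
            one_letter_code=f.one_letter_code, anticodon=f.anticodon,
            igs_to_next=gap,
        )
        if f.category == "CDS":
            row.start_codon, row.stop_codon = infer_codons(seq)
            row.aa_count = amino_acid_count(len(seq), stop_kind(row.stop_codon))
        rows.append(row)
    return rows, summarize_spacers(record, igs)


def feature_table_frame(rows: list[FeatureRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


def write_feature_table_tsv(rows: list[FeatureRow], path: str | Path) -> None:
    feature_table_frame(rows).to_csv(path, sep="\t", index=False)
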