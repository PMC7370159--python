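"""Data model for annotated circular mitogenomes, plus GenBank / feature-table I/O.

Coordinates are 1-based inclusive throughout (GenBank convention).  A feature
with ``start > end`` wraps across the origin and is legal only on a circular
molecule.  L-strand features are stored by their H-strand footprint; reading
them in coding sense reverse-complements the slice.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .codes import revcomp

CATEGORIES = ("tRNA", "rRNA", "CDS", "control")
STRANDS = ("H", "L")

_TO_GENBANK_TYPE = {"tRNA": "tRNA", "rRNA": "rRNA", "CDS": "CDS", "control": "D-loop"}
_FROM_GENBANK_TYPE = {"tRNA": "tRNA", "rRNA": "rRNA", "CDS": "CDS", "D-loop": "control"}

_TABLE_COLUMNS = ["name", "category", "strand", "start", "end", "anticodon", "one_letter_code"]


@dataclass
class GeneFeature:
    """One annotated gene or control region on a mitogenome."""

    name: str
    category: str  # tRNA | rRNA | CDS | control
    strand: str    # H | L
    start: int     # 1-based inclusive
    end: int       # 1-based inclusive; start > end means wrap across origin
    anticodon: str | None = None
    one_letter_code: str | None = None

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def span_length(self, genome_length: int) -> int:
        if not self.wraps:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end


@dataclass
class MitoRecord:
    """An annotated (usually circular) mitochondrial genome."""

    record_id: str
    organism: str
    sequence: str
    topology: str = "circular"
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.sort_features()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def sort_features(self) -> None:
        self.features.sort(key=lambda f: (f.start, f.end))

    def by_category(self, category: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category == category]

    def genes(self) -> list[GeneFeature]:
        """All features except the control region, in genome order."""
        return [f for f in self.features if f.category != "control"]

    def control_region(self) -> GeneFeature | None:
        ctrl = self.by_category("control")
        return ctrl[0] if ctrl else None

    def copy(self) -> "MitoRecord":
        return MitoRecord(
            record_id=self.record_id,
            organism=self.organism,
            sequence=self.sequence,
            topology=self.topology,
            features=[dataclasses.replace(f) for f in self.features],
        )


def extract_gene_sequence(record: MitoRecord, feature: GeneFeature) -> str:
    """Coding-sense sequence of a feature (L-strand features reverse-complemented)."""
    if feature.wraps:
        if record.topology != "circular":
            raise ValueError(
                f"feature {feature.name} wraps the origin but topology is {record.topology}"
            )
        raw = record.sequence[feature.start - 1:] + record.sequence[: feature.end]
    else:
        raw = record.sequence[feature.start - 1: feature.end]
    return revcomp(raw) if feature.strand == "L" else raw


def validate_record(record: MitoRecord) -> list[str]:
    """Check all model invariants; returns violation messages (empty == valid)."""
    problems: list[str] = []
    if record.length == 0:
        problems.append("sequence is empty")
    bad = set(record.sequence) - set("ACGTN")
    if bad:
        problems.append(f"sequence contains non-ACGTN symbols: {sorted(bad)}")
    n_control = 0
    seen: dict[tuple[str, str | None], str] = {}
    for f in record.features:
        if f.category not in CATEGORIES:
            problems.append(f"{f.name}: unknown category {f.category!r}")
        if f.strand not in STRANDS:
            problems.append(f"{f.name}: unknown strand {f.strand!r}")
        if not (1 <= f.start <= record.length) or not (1 <= f.end <= record.length):
            problems.append(f"{f.name}: coordinates {f.start}..{f.end} outside 1..{record.length}")
        if f.wraps and record.topology != "circular":
            problems.append(f"{f.name}: wraps the origin on a linear molecule")
        if f.category == "tRNA" and not f.anticodon:
            problems.append(f"{f.name}: tRNA without anticodon")
        if f.category != "tRNA" and f.anticodon:
            problems.append(f"{f.name}: anticodon given for non-tRNA feature")
        if f.category == "control":
            n_control += 1
        key = (f.name, f.anticodon)
        if key in seen and f.category != "control":
            problems.append(
                f"{f.name}: duplicate gene not disambiguated by anticodon"
            )
        seen[key] = f.name
    if n_control > 1:
        problems.append(f"{n_control} control regions annotated (at most one allowed)")
    return problems


# ---------------------------------------------------------------------------
# GenBank I/O
# ---------------------------------------------------------------------------

def _to_seqrecord(record: MitoRecord) -> SeqRecord:
    sr = SeqRecord(Seq(record.sequence), id=record.record_id, name=record.record_id[:16],
                   description=record.organism)
    sr.annotations["molecule_type"] = "DNA"
    sr.annotations["topology"] = record.topology
    sr.annotations["organism"] = record.organism
    L = record.length
    for f in record.features:
        strand = 1 if f.strand == "H" else -1
        if f.wraps:
            loc = CompoundLocation(
                [SimpleLocation(f.start - 1, L, strand), SimpleLocation(0, f.end, strand)]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        quals = {"gene": [f.name]}
        if f.anticodon:
            quals["anticodon"] = [f.anticodon]
        if f.one_letter_code:
            quals["one_letter_code"] = [f.one_letter_code]
        sr.features.append(SeqFeature(loc, type=_TO_GENBANK_TYPE[f.category], qualifiers=quals))
    return sr


def _feature_from_seqfeature(sf: SeqFeature, length: int) -> GeneFeature | None:
    if sf.type not in _FROM_GENBANK_TYPE:
        return None
    loc = sf.location
    strand = "L" if loc.strand == -1 else "H"
    parts = getattr(loc, "parts", [loc])
    if len(parts) == 2 and int(parts[0].end) == length and int(parts[1].start) == 0:
        start, end = int(parts[0].start) + 1, int(parts[1].end)  # origin-spanning join
    else:
        start, end = int(loc.start) + 1, int(loc.end)
    quals = sf.qualifiers
    name = (quals.get("gene") or quals.get("product") or [sf.type])[0]
    anticodon = (quals.get("anticodon") or [None])[0]
    one_letter = (quals.get("one_letter_code") or [None])[0]
    if end > length or start > length:
        raise ValueError(f"feature {name}: location {start}..{end} beyond sequence length {length}")
    return GeneFeature(name=name, category=_FROM_GENBANK_TYPE[sf.type], strand=strand,
                       start=start, end=end, anticodon=anticodon, one_letter_code=one_letter)


def read_genbank(path: str | Path) -> list[MitoRecord]:
    """Read all LOCUS entries of a GenBank flat file as MitoRecords."""
    records = []
    try:
        seqrecords = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ValueError(f"malformed GenBank file {path}: {exc}") from exc
    for sr in seqrecords:
        length = len(sr.seq)
        feats = []
        for sf in sr.features:
            gf = _feature_from_seqfeature(sf, length)
            if gf is not None:
                feats.append(gf)
        rec = MitoRecord(
            record_id=sr.id,
            organism=sr.annotations.get("organism", sr.description or ""),
            sequence=str(sr.seq),
            topology=sr.annotations.get("topology", "circular"),
            features=feats,
        )
        records.append(rec)
    return records


def write_genbank(records: MitoRecord | list[MitoRecord], path: str | Path) -> None:
    if isinstance(records, MitoRecord):
        records = [records]
    SeqIO.write([_to_seqrecord(r) for r in records], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA + tab-delimited feature table I/O
# ---------------------------------------------------------------------------

def read_feature_table(fasta: str | Path, table: str | Path) -> MitoRecord:
    """Build a MitoRecord from a FASTA sequence and a tab-delimited feature table.

    Table columns: name, category, strand, start, end, anticodon
    (optionally one_letter_code); coordinates 1-based inclusive.
    """
    seqrecords = list(SeqIO.parse(str(fasta), "fasta"))
    if len(seqrecords) != 1:
        raise ValueError(f"expected exactly one FASTA record in {fasta}, found {len(seqrecords)}")
    sr = seqrecords[0]
    df = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("name", "category", "strand", "start", "end") if c not in df.columns]
    if missing:
        raise ValueError(f"feature table {table} lacks columns: {missing}")
    feats = []
    length = len(sr.seq)
    for _, row in df.iterrows():
        cat = row["category"]
        if cat not in CATEGORIES:
            raise ValueError(f"unknown category token {cat!r} for feature {row['name']!r}")
        start, end = int(row["start"]), int(row["end"])
        if not (1 <= start <= length) or not (1 <= end <= length):
            raise ValueError(
                f"feature {row['name']}: coordinates {start}..{end} out of range 1..{length}"
            )
        feats.append(GeneFeature(
            name=row["name"], category=cat, strand=row["strand"], start=start, end=end,
            anticodon=row.get("anticodon", "") or None,
            one_letter_code=row.get("one_letter_code", "") or None,
        ))
    desc = sr.description.split(None, 1)
    organism = desc[1] if len(desc) == 2 else ""
    return MitoRecord(record_id=sr.id, organism=organism, sequence=str(sr.seq), features=feats)


def write_feature_table(record: MitoRecord, fasta: str | Path, table: str | Path) -> None:
    with open(fasta, "w") as fh:
        fh.write(f">{record.record_id} {record.organism}\n")
        for i in range(0, record.length, 70):
            fh.write(record.sequence[i:i + 70] + "\n")
    rows = [
        {
            "name": f.name, "category": f.category, "strand": f.strand,
            "start": f.start, "end": f.end,
            "anticodon": f.anticodon or "", "one_letter_code": f.one_letter_code or "",
        }
        for f in record.features
    ]
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(table, sep="\t", index=False)
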