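"""Synthetic annotated mitogenomes and codon-aware simulated evolution.

The generator emulates the structure of a typical ~16.5 kb teleost
mitogenome: 37 genes (13 PCGs, 22 tRNAs, 2 rRNAs) plus a control region in
the standard vertebrate order, ND6 and eight tRNAs on the L strand, C/A-rich
base composition, the observed spacer/overlap pattern, and incomplete stop
codons where fish mitogenomes have them.  Evolution along a guide tree is
indel-free and codon-aware: nucleotide changes are proposed under an
HKY-like process and accepted with probability 1 (synonymous) or omega
(nonsynonymous); stop-creating changes are rejected, non-coding regions
evolve neutrally, and the control region carries its own rate multiplier.
Omega-as-acceptance-probability is an approximation to a true codon model,
adequate for rate-ordering and topology-recovery experiments.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .codes import COMPLEMENT, SENSE_CODONS, is_stop, is_transition, normalize_gene_name, translate_codon
from .genome import GeneFeature, MitoRecord, validate_record, write_feature_table, write_genbank

_COMPLETE_STOPS = ("TAA", "TAG")


@dataclass(frozen=True)
class GeneSpec:
    """Layout of one gene in a simulated genome (igs_after may be negative)."""

    name: str
    category: str
    strand: str
    length: int
    start_codon: str | None = None
    stop: str | None = None        # TAA/TAG, or incomplete "TA"/"T" (CDS only)
    anticodon: str | None = None
    one_letter: str | None = None
    igs_after: int = 0


# Standard vertebrate mitochondrial gene order; sizes, strands, codons and
# spacers follow the consensus layout of carangid fish mitogenomes.
DEFAULT_GENE_ORDER: tuple[GeneSpec, ...] = (
    GeneSpec("tRNA-Phe", "tRNA", "H", 68, anticodon="GAA", one_letter="F", igs_after=0),
    GeneSpec("12S-rRNA", "rRNA", "H", 951, igs_after=0),
    GeneSpec("tRNA-Val", "tRNA", "H", 72, anticodon="TAC", one_letter="V", igs_after=0),
    GeneSpec("16S-rRNA", "rRNA", "H", 1725, igs_after=0),
    GeneSpec("tRNA-Leu", "tRNA", "H", 74, anticodon="TAA", one_letter="L", igs_after=0),
    GeneSpec("ND1", "CDS", "H", 975, "ATG", "TAA", igs_after=0),
    GeneSpec("tRNA-Ile", "tRNA", "H", 70, anticodon="GAT", one_letter="I", igs_after=6),
    GeneSpec("tRNA-Gln", "tRNA", "L", 71, anticodon="TTG", one_letter="Q", igs_after=-1),
    GeneSpec("tRNA-Met", "tRNA", "H", 70, anticodon="CAT", one_letter="M", igs_after=-1),
    GeneSpec("ND2", "CDS", "H", 1045, "ATG", "T", igs_after=0),
    GeneSpec("tRNA-Trp", "tRNA", "H", 70, anticodon="TCA", one_letter="W", igs_after=0),
    GeneSpec("tRNA-Ala", "tRNA", "L", 69, anticodon="TGC", one_letter="A", igs_after=1),
    GeneSpec("tRNA-Asn", "tRNA", "L", 73, anticodon="GTT", one_letter="N", igs_after=1),
    GeneSpec("tRNA-Cys", "tRNA", "L", 66, anticodon="GCA", one_letter="C", igs_after=38),
    GeneSpec("tRNA-Tyr", "tRNA", "L", 70, anticodon="GTA", one_letter="Y", igs_after=0),
    GeneSpec("COX1", "CDS", "H", 1551, "GTG", "TAA", igs_after=1),
    GeneSpec("tRNA-Ser", "tRNA", "L", 71, anticodon="TGA", one_letter="S", igs_after=0),
    GeneSpec("tRNA-Asp", "tRNA", "H", 71, anticodon="GTC", one_letter="D", igs_after=3),
    GeneSpec("COX2", "CDS", "H", 691, "ATG", "T", igs_after=6),
    GeneSpec("tRNA-Lys", "tRNA", "H", 74, anticodon="TTT", one_letter="K", igs_after=0),
    GeneSpec("ATP8", "CDS", "H", 168, "ATG", "TAA", igs_after=1),
    GeneSpec("ATP6", "CDS", "H", 678, "ATG", "TAA", igs_after=-10),
    GeneSpec("COX3", "CDS", "H", 785, "ATG", "TA", igs_after=-1),
    GeneSpec("tRNA-Gly", "tRNA", "H", 69, anticodon="TCC", one_letter="G", igs_after=0),
    GeneSpec("ND3", "CDS", "H", 349, "ATG", "T", igs_after=0),
    GeneSpec("tRNA-Arg", "tRNA", "H", 68, anticodon="TCG", one_letter="R", igs_after=0),
    GeneSpec("ND4L", "CDS", "H", 297, "ATG", "TAA", igs_after=1),
    GeneSpec("ND4", "CDS", "H", 1381, "ATG", "T", igs_after=-7),
    GeneSpec("tRNA-His", "tRNA", "H", 71, anticodon="GTG", one_letter="H", igs_after=0),
    GeneSpec("tRNA-Ser", "tRNA", "H", 67, anticodon="GCT", one_letter="S", igs_after=0),
    GeneSpec("tRNA-Leu", "tRNA", "H", 73, anticodon="TAG", one_letter="L", igs_after=4),
    GeneSpec("ND5", "CDS", "H", 1839, "ATG", "TAA", igs_after=0),
    GeneSpec("ND6", "CDS", "L", 522, "ATG", "TAG", igs_after=-4),
    GeneSpec("tRNA-Glu", "tRNA", "L", 69, anticodon="TTC", one_letter="E", igs_after=0),
    GeneSpec("CYTB", "CDS", "H", 1141, "ATG", "T", igs_after=4),
    GeneSpec("tRNA-Thr", "tRNA", "H", 72, anticodon="TGT", one_letter="T", igs_after=0),
    GeneSpec("tRNA-Pro", "tRNA", "L", 71, anticodon="TGG", one_letter="P", igs_after=-1),
)

# average mitogenome base composition of carangid fishes (H-strand sense)
DEFAULT_BASE_WEIGHTS = {"A": 0.2774, "C": 0.2994, "G": 0.1664, "T": 0.2567}

# per-gene Ka/Ks targets under purifying selection: ATP8 fastest, COX1 slowest
DEFAULT_OMEGA = {
    "ND1": 0.04, "ND2": 0.05, "COX1": 0.01, "COX2": 0.012, "ATP8": 0.10,
    "ATP6": 0.05, "COX3": 0.015, "ND3": 0.05, "ND4L": 0.05, "ND4": 0.04,
    "ND5": 0.04, "ND6": 0.08, "CYTB": 0.03,
}

# 8-taxon guide topology with subfamily structure (Trachinotinae,(Naucratinae,Caranginae))
DEFAULT_GUIDE_TREE = (
    "(Larimichthys_crocea:0.20,(Trachinotus_A:0.06,Trachinotus_B:0.06):0.05,"
    "((Seriola_A:0.05,Seriola_B:0.05):0.04,"
    "((Caranx_A:0.04,Caranx_B:0.04):0.03,Alepes_A:0.06):0.04):0.03);"
)

DEFAULT_GROUPS = {
    "Trachinotus_A": "Trachinotinae", "Trachinotus_B": "Trachinotinae",
    "Seriola_A": "Naucratinae", "Seriola_B": "Naucratinae",
    "Caranx_A": "Caranginae", "Caranx_B": "Caranginae", "Alepes_A": "Caranginae",
}

DEFAULT_OUTGROUP = "Larimichthys_crocea"


@dataclass
class SimulationConfig:
    """All knobs of the generator; identical seed implies identical output."""

    genes: tuple[GeneSpec, ...] = DEFAULT_GENE_ORDER
    target_length: int = 16553
    base_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_WEIGHTS))
    guide_tree: str = DEFAULT_GUIDE_TREE
    omega: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OMEGA))
    kappa: float = 2.0
    control_rate_multiplier: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if any(g.length <= 0 for g in self.genes):
            raise ValueError("gene lengths must be positive")
        if any(w < 0 for w in self.base_weights.values()):
            raise ValueError("base weights must be nonnegative")
        if any(om < 0 for om in self.omega.values()):
            raise ValueError("omega values must be nonnegative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


@dataclass
class _CdsInfo:
    name: str
    strand: str
    start: int
    end: int
    length: int
    n_full: int           # number of complete codons (incl. start, incl. complete stop)
    stop_codon_index: int | None  # codon index of a complete stop, else None
    tail: int             # incomplete remnant length (0, 1 or 2)
    omega_key: str


def _layout(cfg: SimulationConfig) -> tuple[list[tuple[GeneSpec, int, int]], tuple[int, int] | None]:
    """Assign 1-based coordinates to genes and the control region."""
    placed = []
    pos = 1
    for spec in cfg.genes:
        start, end = pos, pos + spec.length - 1
        if end > cfg.target_length:
            raise ValueError(f"gene {spec.name} extends past target length {cfg.target_length}")
        placed.append((spec, start, end))
        pos = end + 1 + spec.igs_after
    if pos > cfg.target_length + 1:
        raise ValueError("gene layout exceeds target length; no room for control region")
    control = (pos, cfg.target_length) if pos <= cfg.target_length else None
    return placed, control


def _cds_info(spec: GeneSpec, start: int, end: int) -> _CdsInfo:
    tail = len(spec.stop) if spec.stop in ("TA", "T") else 0
    n_full = (spec.length - tail) // 3
    if (spec.length - tail) % 3:
        raise ValueError(f"CDS {spec.name}: length {spec.length} incompatible with stop {spec.stop!r}")
    return _CdsInfo(
        name=spec.name, strand=spec.strand, start=start, end=end, length=spec.length,
        n_full=n_full, stop_codon_index=(n_full - 1) if tail == 0 else None, tail=tail,
        omega_key=normalize_gene_name(spec.name),
    )


def _coding_to_genome(info: _CdsInfo, idx: int) -> int:
    """0-based genome index of 0-based coding position ``idx``."""
    return (info.start - 1 + idx) if info.strand == "H" else (info.end - 1 - idx)


def _coding_base(info: _CdsInfo, genome_base: str) -> str:
    return genome_base if info.strand == "H" else COMPLEMENT[genome_base]


class _BuildConflict(RuntimeError):
    pass


def _write_codon(genome: list, info: _CdsInfo, codon_index: int, codon: str) -> None:
    for k, base in enumerate(codon):
        g = _coding_to_genome(info, 3 * codon_index + k)
        want = base if info.strand == "H" else COMPLEMENT[base]
        if genome[g] is not None and genome[g] != want:
            raise _BuildConflict(
                f"{info.name}: codon {codon_index} conflicts with previously fixed base"
            )
        genome[g] = want


def _codon_pattern(genome: list, info: _CdsInfo, codon_index: int) -> list[str | None]:
    pat = []
    for k in range(3):
        g = _coding_to_genome(info, 3 * codon_index + k)
        pat.append(None if genome[g] is None else _coding_base(info, genome[g]))
    return pat


def _matches(codon: str, pattern: list[str | None]) -> bool:
    return all(p is None or p == c for p, c in zip(pattern, codon))


def _build_pos_map(infos: list[_CdsInfo]) -> dict[int, list[tuple[int, int]]]:
    pos_map: dict[int, list[tuple[int, int]]] = {}
    for i, info in enumerate(infos):
        for idx in range(info.length):
            pos_map.setdefault(_coding_to_genome(info, idx), []).append((i, idx))
    return pos_map


def _try_build(cfg: SimulationConfig, rng: np.random.Generator) -> MitoRecord:
    placed, control = _layout(cfg)
    genome: list[str | None] = [None] * cfg.target_length
    infos = [_cds_info(spec, s, e) for spec, s, e in placed if spec.category == "CDS"]
    pos_map = _build_pos_map(infos)

    # pin start and stop codons of every CDS first
    for info, spec in zip(infos, [s for s, *_ in placed if s.category == "CDS"]):
        _write_codon(genome, info, 0, spec.start_codon or "ATG")
        if info.tail:
            for k, base in enumerate(spec.stop):
                g = _coding_to_genome(info, 3 * info.n_full + k)
                want = base if info.strand == "H" else COMPLEMENT[base]
                if genome[g] is not None and genome[g] != want:
                    raise _BuildConflict(f"{info.name}: incomplete stop conflicts")
                genome[g] = want
        else:
            pattern = _codon_pattern(genome, info, info.stop_codon_index)
            options = [spec.stop] + [s for s in _COMPLETE_STOPS if s != spec.stop]
            for stop in options:
                if _matches(stop, pattern):
                    _write_codon(genome, info, info.stop_codon_index, stop)
                    break
            else:
                raise _BuildConflict(f"{info.name}: no stop codon fits fixed bases")

    # fill stop-free interiors, checking overlapping reading frames
    for i, info in enumerate(infos):
        last_interior = (info.n_full - 2) if info.tail == 0 else (info.n_full - 1)
        for codon_index in range(1, last_interior + 1):
            pattern = _codon_pattern(genome, info, codon_index)
            candidates = [c for c in SENSE_CODONS if _matches(c, pattern)]
            order = rng.permutation(len(candidates))
            placed_ok = False
            for ci in order:
                codon = candidates[ci]
                writes = {}
                for k, base in enumerate(codon):
                    g = _coding_to_genome(info, 3 * codon_index + k)
                    if genome[g] is None:
                        writes[g] = base if info.strand == "H" else COMPLEMENT[base]
                if _overlap_ok(genome, writes, pos_map, infos, i):
                    genome_update = writes
                    for g, b in genome_update.items():
                        genome[g] = b
                    placed_ok = True
                    break
            if not placed_ok:
                raise _BuildConflict(f"{info.name}: codon {codon_index} unsatisfiable")

    # neutral fill for tRNAs, rRNAs, spacers, control region
    bases = np.array(list("ACGT"))
    w = np.array([cfg.base_weights[b] for b in "ACGT"], dtype=float)
    w = w / w.sum()
    free = [i for i, b in enumerate(genome) if b is None]
    fills = rng.choice(bases, size=len(free), p=w)
    for i, b in zip(free, fills):
        genome[i] = str(b)

    feats = []
    for spec, s, e in placed:
        feats.append(GeneFeature(name=spec.name, category=spec.category, strand=spec.strand,
                                 start=s, end=e, anticodon=spec.anticodon,
                                 one_letter_code=spec.one_letter))
    if control is not None:
        feats.append(GeneFeature(name="D-loop", category="control", strand="H",
                                 start=control[0], end=control[1]))
    return MitoRecord(record_id=f"SYNMITO_{cfg.seed}", organism="synthetic carangid mitogenome",
                      sequence="".join(genome), topology="circular", features=feats)


def _overlap_ok(genome: list, writes: dict[int, str], pos_map, infos, self_index: int) -> bool:
    """Would these writes complete a stop codon in another CDS's frame?"""
    for g, base in writes.items():
        for j, idx in pos_map.get(g, []):
            if j == self_index:
                continue
            other = infos[j]
            codon_index = idx // 3
            if codon_index >= other.n_full:
                continue  # incomplete-tail bases are pinned already
            if codon_index == 0 or codon_index == other.stop_codon_index:
                continue  # pinned start/stop: conflicts already excluded by pattern
            codon = []
            complete = True
            for k in range(3):
                gg = _coding_to_genome(other, 3 * codon_index + k)
                b = writes.get(gg, genome[gg])
                if b is None:
                    complete = False
                    break
                codon.append(_coding_base(other, b))
            if complete and is_stop("".join(codon)):
                return False
    return True


def make_reference_record(cfg: SimulationConfig | None = None) -> MitoRecord:
    """Build the synthetic annotated root genome described by ``cfg``."""
    cfg = cfg or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    last_err = None
    for _ in range(30):
        try:
            record = _try_build(cfg, rng)
            break
        except _BuildConflict as exc:  # resample until the overlap frames agree
            last_err = exc
    else:
        raise RuntimeError(f"could not satisfy overlap constraints: {last_err}")
    problems = validate_record(record)
    if problems:
        raise RuntimeError("generator produced invalid record: " + "; ".join(problems))
    return record


# ---------------------------------------------------------------------------
# evolution along a guide tree
# ---------------------------------------------------------------------------

def _propose_target(cur: str, rng: np.random.Generator, cfg: SimulationConfig) -> str:
    others = [b for b in "ACGT" if b != cur]
    weights = np.array([
        cfg.base_weights[b] * (cfg.kappa if is_transition(cur, b) else 1.0) for b in others
    ])
    weights = weights / weights.sum()
    return others[rng.choice(3, p=weights)]


def _evolve_branch(seq: list, t: float, infos, pos_map, control, cfg: SimulationConfig,
                   rng: np.random.Generator) -> list:
    seq = list(seq)
    L = len(seq)
    n = rng.poisson(t * L)
    positions = list(rng.integers(0, L, size=n))
    if control is not None and cfg.control_rate_multiplier > 1.0:
        cstart, cend = control
        clen = cend - cstart + 1
        n_extra = rng.poisson(t * clen * (cfg.control_rate_multiplier - 1.0))
        positions += list(cstart - 1 + rng.integers(0, clen, size=n_extra))
    for pos in positions:
        cur = seq[pos]
        if cur not in "ACGT":
            continue
        new = _propose_target(cur, rng, cfg)
        accept = 1.0
        for i, idx in pos_map.get(pos, []):
            info = infos[i]
            if idx >= 3 * info.n_full:
                accept = 0.0  # incomplete stop remnant is frozen
                break
            codon_index = idx // 3
            old_codon = []
            new_codon = []
            for k in range(3):
                g = _coding_to_genome(info, 3 * codon_index + k)
                b = seq[g]
                old_codon.append(_coding_base(info, b))
                nb = new if g == pos else b
                new_codon.append(_coding_base(info, nb))
            old_c, new_c = "".join(old_codon), "".join(new_codon)
            if codon_index == info.stop_codon_index:
                if new_c not in _COMPLETE_STOPS:
                    accept = 0.0
                    break
                continue  # stop <-> stop is synonymous
            if is_stop(new_c):
                accept = 0.0
                break
            if translate_codon(new_c) != translate_codon(old_c):
                accept *= cfg.omega[info.omega_key]
        if accept >= 1.0 or (accept > 0.0 and rng.random() < accept):
            seq[pos] = new
    return seq


def evolve_on_tree(root: MitoRecord, cfg: SimulationConfig | None = None
                   ) -> dict[str, MitoRecord]:
    """Evolve a root genome along the guide tree; returns one record per leaf."""
    cfg = cfg or SimulationConfig()
    cfg.validate()
    tree = dendropy.Tree.get(data=cfg.guide_tree, schema="newick", preserve_underscores=True)
    infos = [
        _cds_info(
            GeneSpec(f.name, "CDS", f.strand, f.span_length(root.length),
                     stop=_stop_of(root, f)),
            f.start, f.end,
        )
        for f in root.by_category("CDS")
    ]
    for info in infos:
        if info.omega_key not in cfg.omega:
            raise ValueError(f"omega not defined for CDS {info.name}")
    pos_map = _build_pos_map(infos)
    ctrl = root.control_region()
    control = (ctrl.start, ctrl.end) if ctrl else None
    rng = np.random.default_rng([cfg.seed, 2])
    tips: dict[str, MitoRecord] = {}
    seqs = {id(tree.seed_node): list(root.sequence)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            seq = seqs[id(node)]
        else:
            t = node.edge.length or 0.0
            seq = _evolve_branch(seqs[id(node.parent_node)], t, infos, pos_map,
                                 control, cfg, rng)
            seqs[id(node)] = seq
        if node.is_leaf():
            label = node.taxon.label
            rec = root.copy()
            rec.record_id = label
            rec.organism = label
            rec.sequence = "".join(seq)
            tips[label] = rec
    return tips


def _stop_of(record: MitoRecord, feature: GeneFeature) -> str:
    from .genome import extract_gene_sequence
    seq = extract_gene_sequence(record, feature)
    rem = len(seq) % 3
    return seq[-rem:] if rem else seq[-3:]


def simulate_coding_pair(n_codons: int, omega: float, path_length: float,
                         kappa: float = 2.0, seed: int = 0) -> tuple[str, str]:
    """Two coding sequences separated by ``path_length`` expected proposals/site.

    A single CDS of ``n_codons`` internal codons (plus ATG and TAA) evolves
    from a common ancestor along two branches of ``path_length / 2`` each.
    Returns the full coding sequences (start and stop included).
    """
    length = 3 * (n_codons + 2)
    cfg = SimulationConfig(
        genes=(GeneSpec("CDS1", "CDS", "H", length, "ATG", "TAA"),),
        target_length=length,
        guide_tree=f"(a:{path_length / 2.0},b:{path_length / 2.0});",
        omega={"CDS1": omega},
        kappa=kappa,
        seed=seed,
    )
    root = make_reference_record(cfg)
    tips = evolve_on_tree(root, cfg)
    return tips["a"].sequence, tips["b"].sequence


# ---------------------------------------------------------------------------
# packaged machine-readable gene/element feature table
# ---------------------------------------------------------------------------

def table1_fixture() -> pd.DataFrame:
    """Machine-readable per-gene feature summary of the three carangid
    mitogenomes (sizes, GC ranges, codons, signed intergenic column)."""
    path = resources.files("mitochar").joinpath("data/table1.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", keep_default_na=False)
    for col in ("size_lo", "size_hi", "igs_lo", "igs_hi"):
        df[col] = df[col].astype(int)
    for col in ("gc_lo", "gc_hi"):
        df[col] = df[col].astype(float)
    for col in ("aa_lo", "aa_hi"):
        df[col] = pd.to_numeric(df[col].replace("", pd.NA).replace(" ", pd.NA)).astype("Int64")
    for col in ("start_codons", "stop_codons", "one_letter", "anticodon"):
        df[col] = df[col].astype(str).str.strip()
    return df


def write_simulation_bundle(outdir: str | Path, cfg: SimulationConfig | None = None) -> None:
    """Emit GenBank + FASTA tips, per-gene alignment FASTAs, guide newick, groups.tsv."""
    from .genome import extract_gene_sequence
    cfg = cfg or SimulationConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = make_reference_record(cfg)
    tips = evolve_on_tree(root, cfg)
    write_genbank(list(tips.values()), outdir / "tips.gb")
    for label, rec in tips.items():
        write_feature_table(rec, outdir / f"{label}.fasta", outdir / f"{label}.features.tsv")
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for f in root.by_category("CDS"):
        with open(aln_dir / f"{normalize_gene_name(f.name)}.fasta", "w") as fh:
            for label, rec in tips.items():
                feat = next(x for x in rec.features if (x.name, x.start) == (f.name, f.start))
                fh.write(f">{label}\n{extract_gene_sequence(rec, feat)}\n")
    (outdir / "guide_tree.nwk").write_text(cfg.guide_tree + "\n")
    with open(outdir / "groups.tsv", "w") as fh:
        for taxon, group in DEFAULT_GROUPS.items():
            if taxon in tips:
                fh.write(f"{taxon}\t{group}\n")
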