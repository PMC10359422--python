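"""Shared domain types and I/O for comparative-genomics analyses.

The package-wide coordinate convention is 1-based inclusive (the GFF3
convention). BED input/output is converted at the boundary. Gene order along
a chromosome is expressed as an integer *rank* (0-based), assigned by sorting
on ``(start, end, gene_id)`` so that ties are broken deterministically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Gene",
    "AnnotatedGenome",
    "AssemblyQC",
    "QVResult",
    "FamilyTable",
    "Window",
    "GFFParseError",
    "load_genome",
    "load_repeats",
    "load_family_table",
    "assembly_qv",
    "window_iter",
    "write_genome_gff3",
    "write_cds_fasta",
    "write_repeats_bed",
    "write_family_tsv",
]


class GFFParseError(ValueError):
    """Raised for a malformed GFF3 record, naming the offending line."""


@dataclass
class Gene:
    """A gene model on a chromosome.

    ``rank`` is the 0-based order index along the chromosome; ``labels`` is a
    free-form set of functional categories (e.g. ``{"fattyacid"}``) used by
    retention-bias and enrichment analyses.
    """

    gene_id: str
    species: str
    chrom: str
    start: int
    end: int
    strand: str
    family_id: str
    rank: int = -1
    labels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedGenome:
    """Ordered gene models per chromosome, with optional repeats and CDS.

    ``chromosomes`` is an ordered list of ``(name, length_bp)``;
    ``genes`` maps chromosome name to its rank-ordered gene list;
    ``repeats`` holds ``(chrom, start, end, family)`` 1-based inclusive
    intervals; ``cds`` maps gene_id to its coding nucleotide sequence.
    ``flagged_cds`` collects gene_ids whose CDS length is not a multiple of 3
    (kept for synteny, excluded from Ks).
    """

    species: str
    chromosomes: list[tuple[str, int]] = field(default_factory=list)
    genes: dict[str, list[Gene]] = field(default_factory=dict)
    repeats: list[tuple[str, int, int, str]] = field(default_factory=list)
    cds: dict[str, str] = field(default_factory=dict)
    flagged_cds: set[str] = field(default_factory=set)
    # Simulator bookkeeping: genes inside designated retained runs. Empty for
    # genomes loaded from files.
    retained_genes: set[str] = field(default_factory=set)

    def chrom_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def chrom_length(self, name: str) -> int:
        for cname, clen in self.chromosomes:
            if cname == name:
                return clen
        raise KeyError(name)

    def set_chrom_length(self, name: str, length: int) -> None:
        for i, (cname, _) in enumerate(self.chromosomes):
            if cname == name:
                self.chromosomes[i] = (name, length)
                return
        self.chromosomes.append((name, length))

    def all_genes(self) -> Iterator[Gene]:
        for name in self.chrom_names():
            yield from self.genes.get(name, [])

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.genes.values())

    def gene_index(self) -> dict[str, Gene]:
        return {g.gene_id: g for g in self.all_genes()}

    def families(self) -> dict[str, list[Gene]]:
        fams: dict[str, list[Gene]] = {}
        for g in self.all_genes():
            fams.setdefault(g.family_id, []).append(g)
        return fams

    def recompute_ranks(self) -> None:
        """Re-sort genes by (start, end, gene_id) and reassign ranks."""
        for name in list(self.genes):
            glist = sorted(self.genes[name], key=lambda g: (g.start, g.end, g.gene_id))
            for i, g in enumerate(glist):
                g.rank = i
            self.genes[name] = glist

    def validate(self) -> None:
        lengths = dict(self.chromosomes)
        for g in self.all_genes():
            if g.chrom not in lengths:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > lengths[g.chrom]:
                raise ValueError(
                    f"gene {g.gene_id} extends past end of {g.chrom} "
                    f"({g.end} > {lengths[g.chrom]})"
                )
        for name, glist in self.genes.items():
            ranks = [g.rank for g in glist]
            if ranks != sorted(set(ranks)) or (glist and ranks != list(range(len(glist)))):
                raise ValueError(f"ranks on {name} are not 0..n-1 in order")


@dataclass
class AssemblyQC:
    """Counts underlying the Phred-scaled assembly quality value.

    ``n_variants`` (n) is the number of high-confidence mismatch sites between
    re-aligned reads and the assembly; ``n_covered`` (N) is the number of
    assembly positions with read coverage above the coverage threshold. Both
    thresholds (variant quality, coverage) are recorded for provenance only.
    """

    n_variants: int
    n_covered: int
    min_variant_qual: float = 30.0
    min_coverage: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.n_variants <= self.n_covered:
            raise ValueError("require 0 <= n_variants <= n_covered")


@dataclass(frozen=True)
class QVResult:
    qv: float
    lower_bound: bool  # True when no variants were observed ("at least" QV)


def assembly_qv(qc: AssemblyQC) -> QVResult:
    """Phred-scaled base accuracy of an assembly, ``-10*log10(n/N)``.

    With zero observed variants the value is unbounded; the floor obtained by
    assuming a single variant is returned and flagged as a lower bound.
    """
    if qc.n_covered <= 0:
        raise ValueError("QV undefined for n_covered == 0")
    if qc.n_variants == 0:
        return QVResult(-10.0 * math.log10(1.0 / qc.n_covered), True)
    return QVResult(-10.0 * math.log10(qc.n_variants / qc.n_covered), False)


@dataclass(frozen=True)
class Window:
    """A genomic window, 1-based inclusive bp bounds."""

    chrom: str
    start: int
    end: int
    partial: bool = False

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def window_iter(genome: AnnotatedGenome, width: int, step: int) -> list[Window]:
    """Tile every chromosome with windows of ``width`` bp every ``step`` bp.

    Full windows are emitted while they fit; if the final full window does not
    reach the chromosome end, one trailing partial window is appended and
    flagged.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    out: list[Window] = []
    for chrom, length in genome.chromosomes:
        covered_to = 0
        start = 1
        while start + width - 1 <= length:
            out.append(Window(chrom, start, start + width - 1, False))
            covered_to = start + width - 1
            start += step
        if covered_to < length:
            pstart = start if out and covered_to > 0 and start <= length else max(1, start)
            pstart = min(pstart, length)
            if covered_to == 0:
                pstart = 1
            out.append(Window(chrom, pstart, length, True))
    return out


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def load_genome(gff_path: str | Path, fasta_path: str | Path | None = None,
                species: str | None = None) -> AnnotatedGenome:
    """Load gene models from GFF3 (and optionally CDS from FASTA).

    Chromosome lengths come from ``##sequence-region`` pragmas when present,
    otherwise from the maximum gene end. FASTA records are keyed by gene_id;
    a CDS whose length is not a multiple of 3 triggers a warning and the gene
    is flagged (retained for synteny, excluded from Ks).
    """
    gff_path = Path(gff_path)
    text = gff_path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise GFFParseError(f"{gff_path.name}: malformed GFF3 line {lineno}")

    seq_regions: dict[str, int] = {}
    has_features = any(
        line and not line.startswith("#") for line in text.splitlines()
    )
    if has_features:
        db = gffutils.create_db(text, ":memory:", from_string=True,
                                merge_strategy="create_unique", keep_order=True)
        directives = db.directives
    else:
        directives = [l[2:].strip() for l in text.splitlines() if l.startswith("##")]
    for directive in directives:
        if directive.startswith("sequence-region"):
            parts = directive.split()
            if len(parts) >= 4:
                seq_regions[parts[1]] = int(parts[3])

    genome = AnnotatedGenome(species=species or gff_path.stem)
    by_chrom: dict[str, list[Gene]] = {}
    features = db.features_of_type("gene") if has_features else ()
    for feat in features:
        gid = feat.attributes.get("ID", [feat.id])[0]
        fam = feat.attributes.get("family_id", [gid])[0]
        labels = set(feat.attributes.get("labels", [""])[0].split(","))
        labels.discard("")
        gene = Gene(
            gene_id=gid,
            species=genome.species,
            chrom=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand if feat.strand in {"+", "-"} else "+",
            family_id=fam,
            labels=labels,
        )
        by_chrom.setdefault(feat.seqid, []).append(gene)

    chrom_names = sorted(set(by_chrom) | set(seq_regions))
    for name in chrom_names:
        glist = by_chrom.get(name, [])
        length = seq_regions.get(name, max((g.end for g in glist), default=1))
        genome.chromosomes.append((name, length))
        genome.genes[name] = glist
    genome.recompute_ranks()

    if fasta_path is not None:
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            seq = str(rec.seq).upper()
            genome.cds[rec.id] = seq
            if len(seq) % 3 != 0:
                warnings.warn(
                    f"CDS length of {rec.id} not a multiple of 3; "
                    "gene flagged and excluded from Ks analysis"
                )
                genome.flagged_cds.add(rec.id)
    genome.validate()
    return genome


def load_repeats(bed_path: str | Path) -> list[tuple[str, int, int, str]]:
    """Load BED4 repeat intervals, converting to 1-based inclusive.

    Records with ``end <= start`` (in BED coordinates) are rejected with a
    warning. Overlapping or bookended intervals of the same family are merged.
    """
    raw: list[tuple[str, int, int, str]] = []
    for lineno, line in enumerate(Path(bed_path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"{bed_path}: BED4 requires 4 columns (line {lineno})")
        chrom, s, e, fam = parts[0], int(parts[1]), int(parts[2]), parts[3]
        if e <= s:
            warnings.warn(f"{bed_path}: rejecting interval with end <= start at line {lineno}")
            continue
        raw.append((chrom, s + 1, e, fam))  # BED half-open 0-based -> 1-based inclusive

    merged: list[tuple[str, int, int, str]] = []
    raw.sort(key=lambda r: (r[0], r[3], r[1], r[2]))
    for chrom, s, e, fam in raw:
        if merged and merged[-1][0] == chrom and merged[-1][3] == fam and s <= merged[-1][2] + 1:
            pc, ps, pe, pf = merged[-1]
            merged[-1] = (pc, ps, max(pe, e), pf)
        else:
            merged.append((chrom, s, e, fam))
    merged.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    return merged


class FamilyTable:
    """Gene-family membership rows and the derived species x family counts."""

    def __init__(self, rows: pd.DataFrame):
        required = {"family_id", "species", "gene_id"}
        if not required.issubset(rows.columns):
            raise ValueError(f"family table needs columns {sorted(required)}")
        rows = rows[["family_id", "species", "gene_id"]].drop_duplicates()
        dup = rows.duplicated(subset=["species", "gene_id"], keep=False)
        if dup.any():
            bad = rows[dup].sort_values(["species", "gene_id"]).iloc[0]
            raise ValueError(
                f"gene {bad.gene_id!r} in species {bad.species!r} assigned to "
                "conflicting families"
            )
        self.rows = rows.reset_index(drop=True)

    @classmethod
    def from_genomes(cls, genomes: Iterable[AnnotatedGenome]) -> "FamilyTable":
        recs = [
            {"family_id": g.family_id, "species": g.species, "gene_id": g.gene_id}
            for genome in genomes
            for g in genome.all_genes()
        ]
        return cls(pd.DataFrame(recs, columns=["family_id", "species", "gene_id"]))

    def counts(self, species_subset: Sequence[str] | None = None) -> pd.DataFrame:
        """Species x family count matrix (zero rows for absent species)."""
        if self.rows.empty:
            mat = pd.DataFrame()
        else:
            mat = (
                self.rows.groupby(["species", "family_id"])
                .size()
                .unstack(fill_value=0)
            )
        if species_subset is not None:
            mat = mat.reindex(list(species_subset), fill_value=0)
            mat = mat.fillna(0).astype(int)
        return mat


def load_family_table(tsv_path: str | Path) -> FamilyTable:
    """Read a TSV with columns family_id, species, gene_id."""
    try:
        rows = pd.read_csv(tsv_path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        rows = pd.DataFrame(columns=["family_id", "species", "gene_id"])
    if rows.empty and not set(rows.columns) >= {"family_id", "species", "gene_id"}:
        rows = pd.DataFrame(columns=["family_id", "species", "gene_id"])
    return FamilyTable(rows)


# ---------------------------------------------------------------------------
# Writers (same dialects as the readers)
# ---------------------------------------------------------------------------

def write_genome_gff3(genome: AnnotatedGenome, path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for name, length in genome.chromosomes:
        lines.append(f"##sequence-region {name} 1 {length}")
    for g in genome.all_genes():
        labels = ",".join(sorted(g.labels))
        attrs = f"ID={g.gene_id};family_id={g.family_id}"
        if labels:
            attrs += f";labels={labels}"
        lines.append(
            "\t".join(
                [g.chrom, "paleoretain", "gene", str(g.start), str(g.end),
                 ".", g.strand, ".", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_cds_fasta(genome: AnnotatedGenome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gid, description="")
        for gid, seq in sorted(genome.cds.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def write_repeats_bed(repeats: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    lines = [
        f"{chrom}\t{start - 1}\t{end}\t{fam}"
        for chrom, start, end, fam in repeats
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_family_tsv(table: FamilyTable, path: str | Path) -> None:
    table.rows.to_csv(path, sep="\t", index=False)
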