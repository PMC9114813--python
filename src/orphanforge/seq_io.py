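"""Reading, writing and assembling the standard formats the pipeline touches.

Coordinates are 1-based inclusive (GFF3 convention) everywhere in the
package; any half-open arithmetic is localized to the function that needs
it.  Gene models carry their spliced CDS and translated protein so the
downstream stages never re-derive them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "GeneModel",
    "GenomePackage",
    "ReferenceDB",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "translate",
    "reverse_complement",
]

_CODON_TABLE = standard_dna_table.forward_table
_STOP_CODONS = set(standard_dna_table.stop_codons)
_COMPLEMENT = str.maketrans("ACGTRYKMBDHVNacgtrykmbdhvn",
                            "TGCAYRMKVHDBNtgcayrmkvhdbn")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


@dataclass
class GeneModel:
    """One annotated protein-coding gene.

    ``exons`` are (start, end) pairs on the genomic forward strand, sorted
    by start regardless of transcription direction; ``cds_seq`` is the
    spliced coding sequence in transcription order (minus-strand genes are
    reverse-complemented before translation).
    """

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds_seq: str
    protein_seq: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon start > end")
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def exon_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.exons]

    @property
    def protein_length(self) -> int:
        """Residue count, stop symbol excluded."""
        return len(self.protein_seq.rstrip("*"))


@dataclass
class GenomePackage:
    """Everything known about one species: assembly, gene models, TE library."""

    species_id: str
    genome: dict[str, str]
    genes: list[GeneModel]
    te_library: list[tuple[str, str]] = field(default_factory=list)
    chromosome_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chromosome_lengths:
            self.chromosome_lengths = {c: len(s) for c, s in self.genome.items()}
        for g in self.genes:
            if g.chromosome not in self.genome:
                raise ValueError(f"{g.gene_id}: chromosome {g.chromosome!r} not in genome")
            if g.end > self.chromosome_lengths[g.chromosome]:
                raise ValueError(f"{g.gene_id}: coordinates exceed chromosome length")

    def proteome(self) -> list[tuple[str, str]]:
        return [(g.gene_id, g.protein_seq.rstrip("*")) for g in self.genes]

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class ReferenceDB:
    """One stage of the reference panel: a named set of sequences.

    ``stage_rank`` orders the database within the homology-filter cascade;
    ``kind`` is 'protein' or 'nucleotide'.
    """

    name: str
    kind: str
    records: list[tuple[str, str]]
    stage_rank: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("protein", "nucleotide"):
            raise ValueError("kind must be 'protein' or 'nucleotide'")
        if not self.records:
            raise ValueError(f"ReferenceDB {self.name!r}: records must be non-empty")

    @property
    def total_letters(self) -> int:
        return sum(len(s) for _, s in self.records)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse a FASTA file into an ordered list of (id, sequence) pairs.

    Sequences are uppercased; the record ID is the first whitespace token of
    the header. Duplicate IDs, empty sequences and sequence data before the
    first header are rejected with the offending line number.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    current_id: str | None = None
    chunks: list[str] = []
    header_line = 0

    def _flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(
                f"{path}: empty sequence for record {current_id!r} (header at line {header_line})")
        records.append((current_id, seq.upper()))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                chunks = []
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise FastaParseError(f"{path}: malformed header at line {lineno}")
                if name in seen:
                    raise FastaParseError(f"{path}: duplicate record ID {name!r} at line {lineno}")
                seen.add(name)
                current_id = name
                header_line = lineno
            else:
                if current_id is None:
                    raise FastaParseError(f"{path}: sequence before first header at line {lineno}")
                chunks.append(line)
    _flush()
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write (id, sequence) pairs wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str, complete: bool = False) -> str:
    """Translate a coding sequence with the standard genetic code.

    Translation stops at (and excludes) the first stop codon; a trailing
    partial codon is ignored with a warning; codons containing ambiguity
    codes translate to 'X'.
    """
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    if len(cds) % 3 and complete:
        raise ValueError("complete CDS length must be divisible by 3")
    if len(cds) % 3:
        warnings.warn("CDS length not divisible by 3; trailing bases ignored", stacklevel=2)
    cds = cds.upper()
    residues = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i:i + 3]
        if codon in _STOP_CODONS:
            break
        residues.append(_CODON_TABLE.get(codon, "X"))
    return "".join(residues)


def _attrs(field9: str) -> dict[str, str]:
    out = {}
    for part in field9.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path, genome: dict[str, str]) -> list[GeneModel]:
    """Build GeneModels from a GFF3 annotation against ``genome``.

    Expects gene / mRNA / exon / CDS features linked by ID/Parent. When a
    gene carries several mRNAs the one with the longest summed CDS is kept
    (per-gene statistics need one representative). CDS segments are spliced
    in transcription order and minus-strand CDS reverse-complemented before
    translation; phase is recomputed, not trusted.
    """
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    mrnas: dict[str, dict] = {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 tab-separated columns")
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs_s = cols
            start, end = int(start_s), int(end_s)
            attrs = _attrs(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ValueError(f"{path}: line {lineno}: gene without ID")
                genes[gid] = {"chrom": chrom, "strand": strand, "start": start, "end": end}
            elif ftype == "mRNA":
                mid, parent = attrs.get("ID"), attrs.get("Parent")
                if mid is None or parent is None:
                    raise ValueError(f"{path}: line {lineno}: mRNA without ID/Parent")
                mrna_to_gene[mid] = parent
                mrnas[mid] = {"exons": [], "cds": []}
            elif ftype in ("exon", "CDS"):
                parent = attrs.get("Parent")
                if parent is None:
                    raise ValueError(f"{path}: line {lineno}: {ftype} without Parent")
                for p in parent.split(","):
                    if p not in mrnas:
                        mrnas[p] = {"exons": [], "cds": []}
                        mrna_to_gene.setdefault(p, p)
                    key = "exons" if ftype == "exon" else "cds"
                    mrnas[p][key].append((start, end))

    models: list[GeneModel] = []
    for gid, ginfo in genes.items():
        candidates = [mid for mid, g in mrna_to_gene.items() if g == gid and mrnas[mid]["cds"]]
        if not candidates:
            continue
        # longest-CDS representative
        best = max(candidates,
                   key=lambda m: sum(e - s + 1 for s, e in mrnas[m]["cds"]))
        cds_spans = sorted(mrnas[best]["cds"])
        exon_spans = sorted(mrnas[best]["exons"]) or cds_spans
        chrom = ginfo["chrom"]
        if chrom not in genome:
            raise ValueError(f"{gid}: chromosome {chrom!r} absent from genome")
        chrom_seq = genome[chrom]
        if ginfo["end"] > len(chrom_seq) or any(e > len(chrom_seq) for _, e in cds_spans):
            raise ValueError(f"{gid}: feature extends beyond chromosome {chrom!r}")
        cds = "".join(chrom_seq[s - 1:e] for s, e in cds_spans)
        if ginfo["strand"] == "-":
            cds = reverse_complement(cds)
        protein = translate(cds) if len(cds) >= 3 else ""
        models.append(GeneModel(
            gene_id=gid, chromosome=chrom, strand=ginfo["strand"],
            start=ginfo["start"], end=ginfo["end"], exons=exon_spans,
            cds_seq=cds.upper(), protein_seq=protein))
    models.sort(key=lambda g: (g.chromosome, g.start))
    return models


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/exon/CDS rows for the single-isoform models we build."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            base = f"{g.chromosome}\torphanforge\t"
            tail = f"\t.\t{g.strand}\t"
            fh.write(f"{base}gene\t{g.start}\t{g.end}{tail}.\tID={g.gene_id}\n")
            mid = f"{g.gene_id}.t1"
            fh.write(f"{base}mRNA\t{g.start}\t{g.end}{tail}.\tID={mid};Parent={g.gene_id}\n")
            for s, e in g.exons:
                fh.write(f"{base}exon\t{s}\t{e}{tail}.\tParent={mid}\n")
                fh.write(f"{base}CDS\t{s}\t{e}{tail}0\tParent={mid}\n")
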