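"""Genome, ORF and variant I/O with strand-aware CDS extraction.

All genomic coordinates are 1-based inclusive, matching the convention of
yeast genome annotation and of VCF. Conversion to Python slice indices
happens only inside this module, at the I/O boundary. VCF REF/ALT alleles
are always expressed on the plus strand; complementation onto the coding
strand happens only inside the effect annotator.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

import gffutils
from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from cyvcf2 import VCF

logger = logging.getLogger("iscmscan")

VALID_GENOME_ALPHABET = set("ACGTN")
VALID_BASES = set("ACGT")
REFERENCE_STRAIN = "S288C"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    """Named chromosome sequences; the coordinate frame for everything.

    Sequences are uppercase strings over the alphabet ACGTN.
    """

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome has no chromosomes")
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            bad = set(seq) - VALID_GENOME_ALPHABET
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains illegal characters: {sorted(bad)}"
                )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    def base(self, chrom: str, pos: int) -> str:
        """Plus-strand base at 1-based position ``pos``."""
        return self.chromosomes[chrom][pos - 1]

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Plus-strand sequence for the 1-based inclusive span [start, end]."""
        return self.chromosomes[chrom][start - 1 : end]


@dataclass(frozen=True)
class OrfRecord:
    """A single-interval CDS with strand; the unit of codon mapping.

    ``start``/``end`` are 1-based inclusive genomic coordinates with
    start <= end regardless of strand; ``strand`` is '+' or '-'.
    Intron-containing (multi-interval) ORFs are unsupported.
    """

    orf_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.orf_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.orf_id}: strand must be '+' or '-'")
        if self.span_length % 3 != 0:
            raise ValueError(
                f"{self.orf_id}: CDS length {self.span_length} not divisible by 3"
            )

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_codons(self) -> int:
        return self.span_length // 3

    @property
    def protein_length(self) -> int:
        """Residues in the encoded protein, excluding the terminal stop."""
        return self.n_codons - 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


class GeneticCodeTable:
    """The standard nuclear genetic code: 64 codons, 3 stops (TAA/TAG/TGA).

    Stops translate to ``'*'``.
    """

    STOP = "*"

    def __init__(self) -> None:
        table = unambiguous_dna_by_id[1]  # standard code
        self.codon_to_aa: dict[str, str] = dict(table.forward_table)
        for stop in table.stop_codons:
            self.codon_to_aa[stop] = self.STOP
        self.stop_codons: frozenset[str] = frozenset(table.stop_codons)
        if len(self.codon_to_aa) != 64:
            raise AssertionError("genetic code table must have 64 codons")
        if self.stop_codons != frozenset({"TAA", "TAG", "TGA"}):
            raise AssertionError("standard nuclear code must have stops TAA/TAG/TGA")
        self.aa_to_codons: dict[str, tuple[str, ...]] = {}
        for codon, aa in sorted(self.codon_to_aa.items()):
            self.aa_to_codons.setdefault(aa, ())
            self.aa_to_codons[aa] += (codon,)

    def aa(self, codon: str) -> str:
        """Amino acid for ``codon``; 'X' if the codon contains N."""
        codon = codon.upper()
        if set(codon) - VALID_BASES:
            return "X"
        return self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons


@dataclass(frozen=True, order=True)
class VariantRecord:
    """A single-nucleotide variant of one strain, on the plus strand."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    strain_id: str

    def __post_init__(self) -> None:
        if self.ref_base not in VALID_BASES or self.alt_base not in VALID_BASES:
            raise ValueError(f"{self.key}: bases must be one of ACGT")
        if self.ref_base == self.alt_base:
            raise ValueError(f"{self.key}: ref and alt are identical")

    @property
    def key(self) -> tuple[str, int, str]:
        """Site identity: (chrom, pos, alt). Same site, different alt is a
        different SNP."""
        return (self.chrom, self.pos, self.alt_base)


class StrainVariantTable:
    """One strain's SNP set, keyed by (chrom, pos, alt); one alt per site."""

    def __init__(self, strain_id: str, variants: Iterable[VariantRecord] = ()) -> None:
        self.strain_id = strain_id
        self._by_site: dict[tuple[str, int], VariantRecord] = {}
        for v in variants:
            self.add(v)

    def add(self, variant: VariantRecord) -> None:
        if variant.strain_id != self.strain_id:
            raise ValueError(
                f"variant strain {variant.strain_id!r} != table strain {self.strain_id!r}"
            )
        site = (variant.chrom, variant.pos)
        existing = self._by_site.get(site)
        if existing is not None:
            if existing.alt_base != variant.alt_base:
                raise ValueError(
                    f"{self.strain_id}: conflicting alt alleles at {site}"
                )
            return  # exact duplicate, idempotent
        self._by_site[site] = variant

    def __len__(self) -> int:
        return len(self._by_site)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(sorted(self._by_site.values()))

    @property
    def keys(self) -> frozenset[tuple[str, int, str]]:
        return frozenset(v.key for v in self._by_site.values())


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> Genome:
    """Load a FASTA file into a :class:`Genome`.

    Chromosome names are taken from the header up to the first whitespace;
    lowercase bases are uppercased. Duplicate names, empty files and
    illegal characters raise ``ValueError``.
    """
    chromosomes: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in chromosomes:
            raise ValueError(f"duplicate chromosome name {name!r} in {path}")
        chromosomes[name] = str(record.seq).upper()
    if not chromosomes:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(chromosomes)


def write_fasta(genome: Genome, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_orf_gff(path: str | os.PathLike, genome: Optional[Genome] = None) -> list[OrfRecord]:
    """Parse a GFF3 file holding one single-interval CDS feature per ORF.

    An ID seen on more than one CDS line means a multi-exon ORF, which is
    unsupported: an explicit error is raised. Frame length (divisible by 3)
    is validated on construction. If ``genome`` is given, coordinates are
    checked against chromosome bounds and start/stop codons are validated
    (warn, not fail).
    """
    try:
        db = gffutils.create_db(str(path), ":memory:", merge_strategy="error",
                                keep_order=True)
    except ValueError as exc:
        if "Duplicate ID" in str(exc):
            raise ValueError(
                f"{path}: ORF with multiple CDS intervals: "
                "multi-exon ORFs unsupported"
            ) from exc
        raise
    seen: dict[str, int] = {}
    records: list[OrfRecord] = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        orf_id = feat.attributes.get("ID", [feat.id])[0]
        seen[orf_id] = seen.get(orf_id, 0) + 1
        if seen[orf_id] > 1:
            raise ValueError(
                f"ORF {orf_id!r} has multiple CDS intervals: multi-exon ORFs unsupported"
            )
        gene = feat.attributes.get("gene", [None])[0]
        rec = OrfRecord(
            orf_id=orf_id, chrom=feat.seqid, start=feat.start, end=feat.end,
            strand=feat.strand, gene_name=gene,
        )
        records.append(rec)
    if genome is not None:
        validate_orfs(records, genome)
    return records


def validate_orfs(orfs: Iterable[OrfRecord], genome: Genome,
                  code: Optional[GeneticCodeTable] = None) -> None:
    """Check ORFs against the genome: bounds (fail), start/stop codons and
    internal stops (warn only — real annotations contain exceptions)."""
    code = code or GeneticCodeTable()
    for orf in orfs:
        if orf.chrom not in genome:
            raise ValueError(f"{orf.orf_id}: chromosome {orf.chrom!r} not in genome")
        if orf.end > genome.length(orf.chrom):
            raise ValueError(f"{orf.orf_id}: coordinates exceed chromosome length")
        cds = extract_cds(genome, orf)
        if cds[:3] != "ATG":
            logger.warning("%s: CDS does not begin with ATG (%s)", orf.orf_id, cds[:3])
        if not code.is_stop(cds[-3:]):
            logger.warning("%s: CDS does not end with a stop codon (%s)",
                           orf.orf_id, cds[-3:])


def write_orf_gff(orfs: Iterable[OrfRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for orf in orfs:
            attrs = f"ID={orf.orf_id}"
            if orf.gene_name:
                attrs += f";gene={orf.gene_name}"
            fh.write(
                f"{orf.chrom}\tiscmscan\tCDS\t{orf.start}\t{orf.end}\t.\t"
                f"{orf.strand}\t0\t{attrs}\n"
            )


def read_variants_vcf(path: str | os.PathLike, strain_id: str,
                      genome: Optional[Genome] = None) -> StrainVariantTable:
    """Load the SNVs of one strain from a VCF file.

    Indels and other non-SNV records are skipped with a logged count.
    Multiallelic ALT fields are rejected with an error. If ``genome`` is
    given, REF alleles are cross-checked against it and a mismatch raises.
    """
    table = StrainVariantTable(strain_id)
    n_skipped = 0
    for rec in VCF(str(path)):
        if len(rec.ALT) != 1:
            raise ValueError(
                f"{path}: multiallelic record at {rec.CHROM}:{rec.POS} rejected"
            )
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in VALID_BASES or alt not in VALID_BASES:
            n_skipped += 1
            continue
        if genome is not None and genome.base(rec.CHROM, rec.POS) != ref:
            raise ValueError(
                f"{path}: REF mismatch at {rec.CHROM}:{rec.POS} "
                f"(VCF {ref}, genome {genome.base(rec.CHROM, rec.POS)})"
            )
        table.add(VariantRecord(rec.CHROM, rec.POS, ref, alt, strain_id))
    if n_skipped:
        logger.info("%s: skipped %d non-SNV records", path, n_skipped)
    return table


def write_variants_vcf(table: StrainVariantTable, path: str | os.PathLike,
                       genome: Optional[Genome] = None) -> None:
    """Write a strain's SNVs as a minimal VCF 4.2 file, sorted by site."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=iscmscan\n##strain={table.strain_id}\n")
        if genome is not None:
            for name, seq in genome.chromosomes.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in table:
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref_base}\t{v.alt_base}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# CDS extraction and translation
# ---------------------------------------------------------------------------

def extract_cds(genome: Genome, orf: OrfRecord) -> str:
    """Return the coding sequence of ``orf`` in 5'→3' coding orientation.

    For a minus-strand ORF this is the reverse complement of the genomic
    plus-strand slice.
    """
    if orf.chrom not in genome:
        raise ValueError(f"{orf.orf_id}: chromosome {orf.chrom!r} not in genome")
    if orf.end > genome.length(orf.chrom):
        raise ValueError(f"{orf.orf_id}: ORF extends beyond chromosome end")
    seq = genome.slice(orf.chrom, orf.start, orf.end)
    if orf.strand == "-":
        seq = reverse_complement(seq)
    return seq


def translate(cds: str, code: Optional[GeneticCodeTable] = None) -> str:
    """Translate a CDS codon by codon; stops appear as '*', N-containing
    codons as 'X'. The natural terminal stop is retained as a terminal '*'.
    """
    code = code or GeneticCodeTable()
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return "".join(code.aa(cds[i : i + 3]) for i in range(0, len(cds), 3))
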