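"""Codon-aware SNP consequence annotation.

Maps each SNP onto every ORF it overlaps and classifies the change of the
affected codon: synonymous, missense, nonsense (an ISCM — a sense codon
converted to an internal stop), stop-loss (the natural terminal stop
converted to a sense codon), stop-retained, or start-loss. Nonsense calls
carry a truncation length, defined as protein_length - codon_index: the
number of residues strictly downstream of the mutated codon that are lost
(the mutated residue itself is not counted). Notation strings follow the
community convention for yeast nonsense alleles: one-letter reference
amino acid, protein position, then either the stop codon as a DNA triplet
("W244TGA") or, for missense, the alternate amino acid ("H71L").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genome_io import (
    VALID_BASES,
    GeneticCodeTable,
    Genome,
    OrfRecord,
    StrainVariantTable,
    VariantRecord,
    extract_cds,
)

logger = logging.getLogger("iscmscan")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

NONSYNONYMOUS_EFFECTS = frozenset(
    {"MISSENSE", "NONSENSE", "STOP_LOSS", "START_LOSS"}
)


class SnpEffect(str, Enum):
    """Consequence classes for a (variant, ORF) pair.

    NONSENSE is the ISCM class: a single-nucleotide change converting a
    sense codon inside an ORF to TAA, TAG or TGA.
    """

    INTERGENIC = "INTERGENIC"
    SYNONYMOUS = "SYNONYMOUS"
    MISSENSE = "MISSENSE"
    NONSENSE = "NONSENSE"
    STOP_LOSS = "STOP_LOSS"
    STOP_RETAINED = "STOP_RETAINED"
    START_LOSS = "START_LOSS"
    UNDETERMINED = "UNDETERMINED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def is_nonsynonymous(self) -> bool:
        return self.value in NONSYNONYMOUS_EFFECTS


@dataclass(frozen=True)
class AnnotatedVariant:
    """One SNP's consequence against one ORF (or intergenic)."""

    variant: VariantRecord
    effect: SnpEffect
    orf_id: Optional[str] = None
    gene_name: Optional[str] = None
    codon_index: Optional[int] = None  # 1-based protein position; protein_len+1 is the natural stop
    ref_codon: Optional[str] = None
    alt_codon: Optional[str] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    truncation_len: Optional[int] = None  # NONSENSE only
    notation: Optional[str] = None


# ---------------------------------------------------------------------------
# Codon mapping
# ---------------------------------------------------------------------------

def map_to_codon(orf: OrfRecord, genome: Genome, pos: int) -> tuple[int, int, str]:
    """Locate genomic position ``pos`` within ``orf``'s reading frame.

    Returns ``(codon_index, offset_in_codon, ref_codon)`` with codon_index
    and offset both 1-based and counted from the ORF's own 5' end; the
    ref_codon is given in coding orientation (reverse-complemented for
    minus-strand ORFs).
    """
    if not orf.contains(pos):
        raise ValueError(f"position {pos} outside ORF {orf.orf_id}")
    if orf.strand == "+":
        offset0 = pos - orf.start
    else:
        offset0 = orf.end - pos
    codon_index = offset0 // 3 + 1
    offset_in_codon = offset0 % 3 + 1
    cds = extract_cds(genome, orf)
    ref_codon = cds[(codon_index - 1) * 3 : codon_index * 3]
    return codon_index, offset_in_codon, ref_codon


# ---------------------------------------------------------------------------
# Truncation and notation conventions
# ---------------------------------------------------------------------------

def truncation_length(protein_len: int, codon_index: int) -> int:
    """Residues lost downstream of a premature stop at ``codon_index``.

    Defined as ``protein_len - codon_index``: the count of residues
    strictly after the mutated codon. A nonsense change at the last codon
    of the protein therefore has truncation length 0.
    """
    if not 1 <= codon_index <= protein_len:
        raise ValueError(
            f"codon_index {codon_index} outside protein of length {protein_len}"
        )
    return protein_len - codon_index


def notation(ref_aa: str, codon_index: int, alt: str) -> str:
    """Allele notation string.

    Nonsense: one-letter ref amino acid + position + stop codon triplet,
    e.g. ``W244TGA``. Missense: ref aa + position + alt aa, e.g. ``H71L``.
    ``alt`` is interpreted as a stop codon if it is a 3-letter DNA triplet,
    otherwise as a one-letter amino acid.
    """
    return f"{ref_aa.upper()}{codon_index}{alt.upper()}"


def single_substitution_reachable(aa: str, stop_codon: str,
                                  code: Optional[GeneticCodeTable] = None) -> bool:
    """True iff some codon of ``aa`` differs from ``stop_codon`` at exactly
    one position — i.e. the printed (ref_aa, stop) pair is consistent with
    a single nucleotide change."""
    code = code or GeneticCodeTable()
    stop_codon = stop_codon.upper()
    for codon in code.aa_to_codons.get(aa.upper(), ()):
        if sum(a != b for a, b in zip(codon, stop_codon)) == 1:
            return True
    return False


def codon_one_sub_from(aa: str, target_codon: str,
                       code: Optional[GeneticCodeTable] = None) -> tuple[str, int]:
    """A codon of ``aa`` one substitution away from ``target_codon`` and the
    1-based differing position. Raises if none exists."""
    code = code or GeneticCodeTable()
    target_codon = target_codon.upper()
    for codon in code.aa_to_codons.get(aa.upper(), ()):
        diffs = [i for i in range(3) if codon[i] != target_codon[i]]
        if len(diffs) == 1:
            return codon, diffs[0] + 1
    raise ValueError(f"no codon of {aa} is one substitution from {target_codon}")


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

class OrfIndex:
    """Per-chromosome interval index over ORFs for overlap queries."""

    def __init__(self, orfs: Iterable[OrfRecord]) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self.orfs = list(orfs)
        for orf in self.orfs:
            tree = self._trees.setdefault(orf.chrom, IntervalTree())
            # interval end is exclusive
            tree[orf.start : orf.end + 1] = orf

    def overlapping(self, chrom: str, pos: int) -> list[OrfRecord]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree[pos]]
        return sorted(hits, key=lambda o: (o.start, o.orf_id))


def _classify_codon_change(ref_codon: str, alt_codon: str, codon_index: int,
                           n_codons: int, code: GeneticCodeTable) -> SnpEffect:
    """Effect of one codon substitution given its position in the frame."""
    if set(ref_codon + alt_codon) - VALID_BASES:
        return SnpEffect.UNDETERMINED  # Ns never silently synonymous
    ref_aa = code.aa(ref_codon)
    alt_aa = code.aa(alt_codon)
    at_natural_stop = codon_index == n_codons
    if at_natural_stop:
        if ref_aa != code.STOP:
            # annotation defect: last codon is not a stop; fall through
            pass
        elif alt_aa == code.STOP:
            return SnpEffect.STOP_RETAINED
        else:
            return SnpEffect.STOP_LOSS
    if ref_aa == alt_aa:
        return SnpEffect.SYNONYMOUS
    if codon_index == 1 and ref_codon == "ATG":
        return SnpEffect.START_LOSS
    if alt_aa == code.STOP:
        return SnpEffect.NONSENSE
    if ref_aa == code.STOP:
        return SnpEffect.STOP_LOSS  # internal reference stop mutated to sense
    return SnpEffect.MISSENSE


def annotate_variant(variant: VariantRecord, orfs: OrfIndex | Sequence[OrfRecord],
                     genome: Genome,
                     code: Optional[GeneticCodeTable] = None) -> list[AnnotatedVariant]:
    """Classify one SNP against every ORF it overlaps.

    Returns one record per overlapping ORF, or a single INTERGENIC record
    if none overlap. A REF allele that does not match the genome yields
    UNDETERMINED with a warning. Each SNP is evaluated independently
    against the reference codon; compound changes to one codon are not
    jointly re-evaluated.
    """
    code = code or GeneticCodeTable()
    index = orfs if isinstance(orfs, OrfIndex) else OrfIndex(orfs)

    genome_ref = genome.base(variant.chrom, variant.pos)
    if genome_ref != variant.ref_base:
        logger.warning(
            "REF mismatch at %s:%d (variant %s, genome %s) — effect undetermined",
            variant.chrom, variant.pos, variant.ref_base, genome_ref,
        )
        return [AnnotatedVariant(variant=variant, effect=SnpEffect.UNDETERMINED)]

    hits = index.overlapping(variant.chrom, variant.pos)
    if not hits:
        return [AnnotatedVariant(variant=variant, effect=SnpEffect.INTERGENIC)]

    out: list[AnnotatedVariant] = []
    for orf in hits:
        codon_index, offset, ref_codon = map_to_codon(orf, genome, variant.pos)
        # alt base on the coding strand
        alt_coding = variant.alt_base if orf.strand == "+" else _COMP[variant.alt_base]
        alt_codon = (
            ref_codon[: offset - 1] + alt_coding + ref_codon[offset:]
        )
        effect = _classify_codon_change(ref_codon, alt_codon, codon_index,
                                        orf.n_codons, code)
        ref_aa = code.aa(ref_codon)
        alt_aa = code.aa(alt_codon)
        trunc: Optional[int] = None
        note: Optional[str] = None
        if effect is SnpEffect.NONSENSE:
            if codon_index <= orf.protein_length:
                trunc = truncation_length(orf.protein_length, codon_index)
            note = notation(ref_aa, codon_index, alt_codon)
        elif effect is SnpEffect.MISSENSE:
            note = notation(ref_aa, codon_index, alt_aa)
        out.append(AnnotatedVariant(
            variant=variant, effect=effect, orf_id=orf.orf_id,
            gene_name=orf.gene_name, codon_index=codon_index,
            ref_codon=ref_codon, alt_codon=alt_codon,
            ref_aa=ref_aa, alt_aa=alt_aa,
            truncation_len=trunc, notation=note,
        ))
    return out


def annotate_strain(table: StrainVariantTable, orfs: OrfIndex | Sequence[OrfRecord],
                    genome: Genome,
                    code: Optional[GeneticCodeTable] = None) -> list[AnnotatedVariant]:
    """Annotate every SNP of one strain, flagging compound codons.

    Two SNPs of the same strain landing in one codon of one ORF are each
    annotated independently against the reference codon and logged as a
    "compound codon" — they are not jointly re-evaluated.
    """
    code = code or GeneticCodeTable()
    index = orfs if isinstance(orfs, OrfIndex) else OrfIndex(orfs)
    out: list[AnnotatedVariant] = []
    seen_codons: dict[tuple[str, int], int] = {}
    for variant in table:
        for ann in annotate_variant(variant, index, genome, code):
            if ann.orf_id is not None and ann.codon_index is not None:
                key = (ann.orf_id, ann.codon_index)
                seen_codons[key] = seen_codons.get(key, 0) + 1
                if seen_codons[key] == 2:
                    logger.info("%s: compound codon at %s codon %d",
                                table.strain_id, ann.orf_id, ann.codon_index)
            out.append(ann)
    return out


# ---------------------------------------------------------------------------
# Stop-loss extension scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StopLossReport:
    """C-terminal consequence of a variant hitting the natural stop codon."""

    orf_id: str
    effect: SnpEffect  # STOP_LOSS or STOP_RETAINED
    extension_codons: int  # sense codons read through before the next stop
    terminator_found: bool  # False if the frame runs off the chromosome


def scan_stop_loss(annotation: AnnotatedVariant, genome: Genome, orf: OrfRecord,
                   code: Optional[GeneticCodeTable] = None) -> StopLossReport:
    """Measure the C-terminal extension caused by loss of the natural stop.

    Walks in-frame codons downstream of the ORF in genomic sequence until
    the next stop codon; the extension is the number of sense codons read
    through. If no stop occurs before the chromosome end the report is
    flagged ``terminator_found=False``.
    """
    code = code or GeneticCodeTable()
    if annotation.codon_index != orf.n_codons:
        raise ValueError("variant does not hit the ORF's terminal stop codon")
    if annotation.effect is SnpEffect.STOP_RETAINED:
        return StopLossReport(orf.orf_id, SnpEffect.STOP_RETAINED, 0, True)
    if annotation.effect is not SnpEffect.STOP_LOSS:
        raise ValueError(f"not a stop-codon variant: {annotation.effect}")

    chrom_seq = genome.chromosomes[orf.chrom]
    extension = 0
    if orf.strand == "+":
        i = orf.end  # 0-based index of first downstream base
        while i + 3 <= len(chrom_seq):
            codon = chrom_seq[i : i + 3]
            if code.is_stop(codon):
                return StopLossReport(orf.orf_id, SnpEffect.STOP_LOSS, extension, True)
            extension += 1
            i += 3
    else:
        i = orf.start - 1  # 0-based exclusive end of downstream (reverse) codon
        while i - 3 >= 0:
            from .genome_io import reverse_complement
            codon = reverse_complement(chrom_seq[i - 3 : i])
            if code.is_stop(codon):
                return StopLossReport(orf.orf_id, SnpEffect.STOP_LOSS, extension, True)
            extension += 1
            i -= 3
    return StopLossReport(orf.orf_id, SnpEffect.STOP_LOSS, extension, False)


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "strain", "chrom", "pos", "ref", "alt", "orf_id", "gene", "codon_index",
    "ref_codon", "alt_codon", "effect", "truncation_len", "notation",
]


def annotations_to_frame(annotations: Iterable[AnnotatedVariant]) -> pd.DataFrame:
    """Long-format annotation table, one row per (variant, ORF) record,
    sorted by (chrom, pos, strain, orf_id) for deterministic output."""
    rows = []
    for a in annotations:
        v = a.variant
        rows.append({
            "strain": v.strain_id, "chrom": v.chrom, "pos": v.pos,
            "ref": v.ref_base, "alt": v.alt_base,
            "orf_id": a.orf_id or ".", "gene": a.gene_name or ".",
            "codon_index": a.codon_index if a.codon_index is not None else ".",
            "ref_codon": a.ref_codon or ".", "alt_codon": a.alt_codon or ".",
            "effect": a.effect.value,
            "truncation_len": a.truncation_len if a.truncation_len is not None else ".",
            "notation": a.notation or ".",
        })
    frame = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    if len(frame):
        frame = frame.sort_values(["chrom", "pos", "strain", "orf_id"],
                                  kind="mergesort").reset_index(drop=True)
    return frame


def write_annotations(annotations: Iterable[AnnotatedVariant],
                      path: str) -> pd.DataFrame:
    frame = annotations_to_frame(annotations)
    frame.to_csv(path, sep="\t", index=False)
    return frame
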