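"""Synthetic genomes, ORF sets, strain trees and SNP cohorts with known
ground truth, so every pipeline stage is testable without external data.

Two generators are provided. :func:`simulate_cohort` emulates the
structure of a resequenced yeast strain cohort: a multi-chromosome genome
with non-overlapping single-exon ORFs on both strands, and per-strain SNP
sets drawn along a known strain tree, with controlled fractions of
synonymous / missense / nonsense / stop-loss changes, so planted ISCMs
and branch assignments are recoverable exactly. :func:`build_nonsense_fixture`
materializes a published-style catalogue of 26 internal nonsense alleles
across two laboratory strains (ADE1 W244TGA, TRP1 Q135TAG, ADE2 E64TAA,
AFI1 E887TAA and so on), reconstructing each ORF's length from the
notation arithmetic (protein length = stop position + truncation), which
the annotator must reproduce row for row.

All randomness flows from a single seeded numpy Generator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd
import yaml

from .effect_annotation import OrfIndex, SnpEffect, codon_one_sub_from
from .genome_io import (
    GeneticCodeTable,
    Genome,
    OrfRecord,
    StrainVariantTable,
    VariantRecord,
    reverse_complement,
    write_fasta,
    write_orf_gff,
    write_variants_vcf,
)
from .phylo_attribution import number_branches, write_newick

_CODE = GeneticCodeTable()
_SENSE_CODONS = tuple(sorted(c for c in _CODE.codon_to_aa
                             if c not in _CODE.stop_codons))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class EffectFractions:
    """Fractions of planted SNPs per consequence class; the remainder is
    intergenic. Synonymous/missense/intergenic proportions follow the
    observed genome-wide split for re-sequenced lab strains (about 61% of
    SNPs inside ORFs, about a third of those non-synonymous); the nonsense
    and stop-loss fractions default to 1% and 0.5% so that desk-scale
    cohorts still plant a countable number of ISCMs."""

    synonymous: float = 0.39
    missense: float = 0.20
    nonsense: float = 0.01
    stop_loss: float = 0.005

    def __post_init__(self) -> None:
        vals = (self.synonymous, self.missense, self.nonsense, self.stop_loss)
        if any(v < 0 for v in vals):
            raise ValueError("effect fractions must be non-negative")
        if sum(vals) > 1.0 + 1e-9:
            raise ValueError("effect fractions must sum to <= 1")

    @property
    def intergenic(self) -> float:
        return max(0.0, 1.0 - (self.synonymous + self.missense
                               + self.nonsense + self.stop_loss))


@dataclass
class SimulationConfig:
    """Knobs of the cohort simulator. ``seed`` is mandatory."""

    seed: int
    n_chromosomes: int = 4
    chromosome_length: int = 60_000
    n_orfs: int = 60
    orf_min_codons: int = 80
    orf_max_codons: int = 400
    strand_probability: float = 0.5  # probability an ORF sits on '+'
    tree: Optional[str] = None  # newick over strains; random tree if None
    n_strains: int = 8
    snps_per_branch: int = 30
    fractions: EffectFractions = field(default_factory=EffectFractions)
    homoplasy_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.snps_per_branch < 0 or self.n_orfs < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.homoplasy_rate <= 1.0:
            raise ValueError("homoplasy_rate must be in [0, 1]")
        if isinstance(self.fractions, dict):
            self.fractions = EffectFractions(**self.fractions)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str) -> None:
        data = {k: v for k, v in self.__dict__.items() if k != "fractions"}
        data["fractions"] = self.fractions.__dict__
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Genome and ORF simulation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _random_orf_seq(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + sense internal codons + one stop, in coding orientation."""
    internal = rng.choice(len(_SENSE_CODONS), n_codons - 2)
    stop = sorted(_CODE.stop_codons)[rng.integers(0, 3)]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in internal) + stop


def simulate_genome_and_orfs(config: SimulationConfig,
                             rng: Optional[np.random.Generator] = None,
                             ) -> tuple[Genome, list[OrfRecord]]:
    """Random genome with non-overlapping single-exon ORFs on both strands.

    Every ORF starts with ATG, ends with a stop, and is free of internal
    stop codons, so planted consequence classes stay unambiguous.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1:02d}" for i in range(config.n_chromosomes)]
    chrom_seqs = {name: list(_random_seq(rng, config.chromosome_length))
                  for name in chrom_names}
    orfs: list[OrfRecord] = []
    cursors = {name: 1 for name in chrom_names}
    for i in range(config.n_orfs):
        chrom = chrom_names[i % config.n_chromosomes]
        n_codons = int(rng.integers(config.orf_min_codons,
                                    config.orf_max_codons + 1))
        span = n_codons * 3
        gap = int(rng.integers(20, 200))
        start = cursors[chrom] + gap
        end = start + span - 1
        if end > config.chromosome_length - 20:
            raise ValueError(
                "chromosomes too short for requested ORF count/lengths; "
                "increase chromosome_length or reduce n_orfs"
            )
        strand = "+" if rng.random() < config.strand_probability else "-"
        cds = _random_orf_seq(rng, n_codons)
        genomic = cds if strand == "+" else reverse_complement(cds)
        chrom_seqs[chrom][start - 1 : end] = list(genomic)
        suffix = "W" if strand == "+" else "C"
        orfs.append(OrfRecord(orf_id=f"SYN{i + 1:04d}{suffix}", chrom=chrom,
                              start=start, end=end, strand=strand))
        cursors[chrom] = end + 1
    genome = Genome({name: "".join(seq) for name, seq in chrom_seqs.items()})
    orfs.sort(key=lambda o: (o.chrom, o.start))
    return genome, orfs


def random_strain_tree(n_strains: int, rng: np.random.Generator) -> dendropy.Tree:
    """Random rooted bifurcating tree over strain01..strainNN with
    exponential branch lengths, built by sequential random joins."""
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    labels = [f"strain{i + 1:02d}" for i in range(n_strains)]
    taxa = dendropy.TaxonNamespace(labels)
    nodes = []
    for label in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        node.edge.length = round(float(rng.exponential(1.0)) + 0.05, 4)
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = dendropy.Node()
        parent.edge.length = round(float(rng.exponential(1.0)) + 0.05, 4)
        parent.add_child(a)
        parent.add_child(b)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=nodes[0])
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# SNP planting helpers
# ---------------------------------------------------------------------------

def _coding_to_genomic(orf: OrfRecord, cds_pos: int) -> int:
    """1-based CDS position -> 1-based genomic plus-strand position."""
    if orf.strand == "+":
        return orf.start + cds_pos - 1
    return orf.end - (cds_pos - 1)


def _plus_strand_base(orf: OrfRecord, coding_base: str) -> str:
    return coding_base if orf.strand == "+" else _COMP[coding_base]


def _desired_effect(ref_codon: str, alt_codon: str, codon_index: int,
                    n_codons: int) -> SnpEffect:
    ref_aa, alt_aa = _CODE.aa(ref_codon), _CODE.aa(alt_codon)
    if codon_index == n_codons:
        return (SnpEffect.STOP_RETAINED if alt_aa == _CODE.STOP
                else SnpEffect.STOP_LOSS)
    if ref_aa == alt_aa:
        return SnpEffect.SYNONYMOUS
    if alt_aa == _CODE.STOP:
        return SnpEffect.NONSENSE
    return SnpEffect.MISSENSE


class _SitePlanter:
    """Draws genomic substitutions realizing a requested consequence class,
    avoiding reuse of sites, codon 1 and (except stop-loss) the natural
    stop, so the planted truth stays unambiguous."""

    def __init__(self, genome: Genome, orfs: list[OrfRecord],
                 rng: np.random.Generator) -> None:
        self.genome = genome
        self.orfs = orfs
        self.rng = rng
        self.index = OrfIndex(orfs)
        self.cds = {o.orf_id: None for o in orfs}
        self.used: set[tuple[str, int]] = set()

    def _cds(self, orf: OrfRecord) -> str:
        from .genome_io import extract_cds
        if self.cds[orf.orf_id] is None:
            self.cds[orf.orf_id] = extract_cds(self.genome, orf)
        return self.cds[orf.orf_id]

    def plant_coding(self, effect: SnpEffect, max_tries: int = 2000,
                     ) -> tuple[OrfRecord, int, str, str, str]:
        """Pick (orf, genomic_pos, ref, alt, notation-ready data) realizing
        ``effect``. Returns (orf, pos, ref_plus, alt_plus, ref_codon)."""
        for _ in range(max_tries):
            orf = self.orfs[int(self.rng.integers(0, len(self.orfs)))]
            cds = self._cds(orf)
            n_codons = orf.n_codons
            if effect is SnpEffect.STOP_LOSS:
                ci = n_codons
            else:
                ci = int(self.rng.integers(2, n_codons))  # skip codon 1 & stop
            off = int(self.rng.integers(1, 4))
            cds_pos = (ci - 1) * 3 + off
            pos = _coding_to_genomic(orf, cds_pos)
            if (orf.chrom, pos) in self.used:
                continue
            ref_codon = cds[(ci - 1) * 3 : ci * 3]
            ref_coding = ref_codon[off - 1]
            alts = [b for b in "ACGT" if b != ref_coding]
            self.rng.shuffle(alts)
            for alt_coding in alts:
                alt_codon = ref_codon[: off - 1] + alt_coding + ref_codon[off:]
                if _desired_effect(ref_codon, alt_codon, ci, n_codons) is effect:
                    self.used.add((orf.chrom, pos))
                    return (orf, pos, _plus_strand_base(orf, ref_coding),
                            _plus_strand_base(orf, alt_coding), ref_codon)
        raise RuntimeError(f"could not plant a {effect} site after {max_tries} tries")

    def plant_intergenic(self, max_tries: int = 2000) -> tuple[str, int, str, str]:
        for _ in range(max_tries):
            chrom = sorted(self.genome.chromosomes)[
                int(self.rng.integers(0, len(self.genome.chromosomes)))]
            pos = int(self.rng.integers(1, self.genome.length(chrom) + 1))
            if (chrom, pos) in self.used or self.index.overlapping(chrom, pos):
                continue
            ref = self.genome.base(chrom, pos)
            alts = [b for b in "ACGT" if b != ref]
            alt = alts[int(self.rng.integers(0, 3))]
            self.used.add((chrom, pos))
            return chrom, pos, ref, alt
        raise RuntimeError("could not plant an intergenic site")


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSimulation:
    """A simulated strain cohort plus its planted ground truth."""

    config: SimulationConfig
    genome: Genome
    orfs: list[OrfRecord]
    tree: dendropy.Tree  # rooted tree over the strains (reference excluded)
    tables: dict[str, StrainVariantTable]
    truth: pd.DataFrame  # one row per planted SNP

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fasta")
        write_orf_gff(self.orfs, outdir / "orfs.gff3")
        write_newick(self.tree, str(outdir / "strains.nwk"))
        for strain, table in sorted(self.tables.items()):
            write_variants_vcf(table, outdir / f"{strain}.vcf", self.genome)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.config.to_yaml(str(outdir / "config.yaml"))


TRUTH_COLUMNS = ["chrom", "pos", "ref", "alt", "planted_branch",
                 "planted_clade", "planted_effect", "planted_orf",
                 "planted_truncation", "homoplasious"]


def simulate_cohort(config: SimulationConfig) -> CohortSimulation:
    """Simulate per-strain SNP sets along a known strain tree.

    Each planted SNP is assigned to one branch and inherited by exactly
    that branch's clade of leaf strains; a ``homoplasy_rate`` fraction
    instead receives a carrier set matching no clade. Consequence classes
    are enforced at planting time by choosing a codon position and alt
    base that realize them, so the annotator's output can be compared to
    the truth table exactly.
    """
    rng = np.random.default_rng(config.seed)
    genome, orfs = simulate_genome_and_orfs(config, rng)
    if config.tree is not None:
        tree = dendropy.Tree.get(data=config.tree, schema="newick",
                                 preserve_underscores=True)
        tree.is_rooted = True
    else:
        tree = random_strain_tree(config.n_strains, rng)
    clades = number_branches(tree)
    all_leaves = frozenset().union(*clades.values())
    if all_leaves not in clades.values():
        # the root clade: species-specific SNPs carried by every strain
        clades[max(clades) + 1] = all_leaves
    clade_sets = set(clades.values())

    fr = config.fractions
    classes = [SnpEffect.SYNONYMOUS, SnpEffect.MISSENSE, SnpEffect.NONSENSE,
               SnpEffect.STOP_LOSS, SnpEffect.INTERGENIC]
    probs = np.array([fr.synonymous, fr.missense, fr.nonsense, fr.stop_loss,
                      fr.intergenic])
    probs = probs / probs.sum()

    planter = _SitePlanter(genome, orfs, rng)
    tables = {leaf: StrainVariantTable(leaf) for leaf in sorted(all_leaves)}
    truth_rows = []
    for bid in sorted(clades):
        clade = clades[bid]
        for _ in range(config.snps_per_branch):
            effect = classes[int(rng.choice(len(classes), p=probs))]
            if effect is SnpEffect.INTERGENIC:
                chrom, pos, ref, alt = planter.plant_intergenic()
                orf_id, trunc = ".", "."
            else:
                orf, pos, ref, alt, ref_codon = planter.plant_coding(effect)
                chrom, orf_id = orf.chrom, orf.orf_id
                if effect is SnpEffect.NONSENSE:
                    ci = _codon_index_of(orf, pos)
                    trunc = orf.protein_length - ci
                else:
                    trunc = "."
            carriers, homopl = clade, False
            if config.homoplasy_rate > 0 and rng.random() < config.homoplasy_rate:
                carriers = _corrupt_carriers(clade, all_leaves, clade_sets, rng)
                homopl = True
            for strain in carriers:
                tables[strain].add(VariantRecord(chrom, pos, ref, alt, strain))
            truth_rows.append({
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "planted_branch": "." if homopl else bid,
                "planted_clade": ",".join(sorted(carriers)),
                "planted_effect": effect.value,
                "planted_orf": orf_id, "planted_truncation": trunc,
                "homoplasious": homopl,
            })
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return CohortSimulation(config, genome, orfs, tree, tables, truth)


def _codon_index_of(orf: OrfRecord, pos: int) -> int:
    offset0 = pos - orf.start if orf.strand == "+" else orf.end - pos
    return offset0 // 3 + 1


def _corrupt_carriers(clade: frozenset[str], all_leaves: frozenset[str],
                      clade_sets: set[frozenset[str]],
                      rng: np.random.Generator) -> frozenset[str]:
    """A carrier set near ``clade`` that matches no clade of the tree."""
    for _ in range(100):
        leaves = sorted(all_leaves)
        if clade == all_leaves:
            drop = leaves[int(rng.integers(0, len(leaves)))]
            cand = clade - {drop}
        else:
            outside = sorted(all_leaves - clade)
            add = outside[int(rng.integers(0, len(outside)))]
            cand = clade | {add}
        if cand and frozenset(cand) not in clade_sets:
            return frozenset(cand)
    raise RuntimeError("could not build a homoplasious carrier set")


# ---------------------------------------------------------------------------
# Printed-catalogue fixture: 26 internal nonsense alleles in two strains
# ---------------------------------------------------------------------------

# (systematic name, gene, printed chromosomal position, notation + truncation,
#  strain-unique flag). Strand follows the systematic-name suffix
# (W = Watson/plus, C = Crick/minus). Protein length is reconstructed as
# stop position + truncation.
NONSENSE_CATALOGUE_74D694 = [
    ("YAL056W", "GPB2", 41780, "Q841TAA", 39, True),
    ("YAR015W", "ADE1", 170101, "W244TGA", 62, True),
    ("YAR028W", None, 185308, "W141TGA", 93, False),
    ("YAR031W", "PRM9", 186930, "W34TAG", 264, False),
    ("YBL037W", "APL3", 150039, "L943TAA", 82, True),
    ("YDR007W", "TRP1", 462241, "Q135TAG", 89, True),
    ("YDR147W", "EKI1", 752397, "W257TAG", 277, True),
    ("YFR057W", None, 269422, "Y125TAA", 26, True),
    ("YGR159C", "NSR1", 806553, "E54TAA", 360, True),
    ("YGR249W", "MGA1", 989281, "Q410TAA", 46, False),
    ("YGR281W", "YOR1", 1054483, "K552TAA", 925, True),
    ("YGR283W", None, 1059136, "L304TAG", 37, True),
    ("YHL003C", "LAG1", 101280, "W200TGA", 211, True),
    ("YHR143W", "DSE2", 385718, "L69TAA", 256, False),
    ("YIR028W", "DAL4", 409511, "W349TGA", 286, True),
    ("YKL062W", "MSN4", 323577, "Q236TAA", 394, True),
    ("YKR056W", "TRM2", 549185, "W32TGA", 607, False),
    ("YLR313C", "SPH1", 760398, "Q649TAG", 23, False),
    ("YNL065W", "AQR1", 505411, "Q563TAG", 23, False),
    ("YOL060C", "MAM3", 214535, "K535TAA", 171, True),
    ("YOR183W", "FYV12", 678996, "E42TAA", 87, False),
    ("YPL222W", "FMP40", 130893, "Q245TAA", 443, True),
]

NONSENSE_CATALOGUE_G600 = [
    ("YBR074W", None, 387247, "Q323TAA", 653, True),
    ("YNL106C", "INP52", 422546, "W651TAG", 532, True),
    ("YOR128C", "ADE2", 566003, "E64TAA", 507, False),
    ("YOR129C", "AFI1", 566901, "E887TAA", 6, False),
]

_NOTATION_RE = re.compile(r"^([A-Z])(\d+)(TAA|TAG|TGA)$")

_FILLER_CODONS = ("GCT", "GAA", "TTG", "TCC", "AAC", "GGT", "CCA", "ATC")


def parse_nonsense_notation(s: str) -> tuple[str, int, str]:
    """Split e.g. 'W244TGA' into (ref_aa, codon_index, stop_codon)."""
    m = _NOTATION_RE.match(s)
    if not m:
        raise ValueError(f"bad nonsense notation: {s!r}")
    return m.group(1), int(m.group(2)), m.group(3)


@dataclass
class FixtureResult:
    """Synthetic reconstruction of the printed nonsense-allele catalogue."""

    genome: Genome
    orfs: list[OrfRecord]
    tables: dict[str, StrainVariantTable]
    expected: pd.DataFrame  # one row per catalogue entry

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "fixture_genome.fasta")
        write_orf_gff(self.orfs, outdir / "fixture_orfs.gff3")
        for strain, table in sorted(self.tables.items()):
            write_variants_vcf(table, outdir / f"{strain}.vcf", self.genome)
        self.expected.to_csv(outdir / "fixture_expected.tsv", sep="\t", index=False)


def _fixture_cds(protein_len: int, ref_aa: str, codon_index: int,
                 stop_codon: str) -> tuple[str, str, int]:
    """Deterministic CDS carrying a codon of ``ref_aa`` one substitution
    from ``stop_codon`` at ``codon_index``. Returns (cds, ref_codon, offset)."""
    ref_codon, offset = codon_one_sub_from(ref_aa, stop_codon, _CODE)
    n_codons = protein_len + 1
    codons = ["ATG"]
    for i in range(2, protein_len + 1):
        codons.append(ref_codon if i == codon_index
                      else _FILLER_CODONS[i % len(_FILLER_CODONS)])
    codons.append("TAA")
    if codon_index == 1:
        raise ValueError("catalogue nonsense at codon 1 unsupported")
    assert len(codons) == n_codons
    return "".join(codons), ref_codon, offset


def build_nonsense_fixture(flank: int = 30) -> FixtureResult:
    """Reconstruct the 26-row nonsense-allele catalogue as synthetic data.

    Each catalogue entry becomes a single-exon ORF on its own synthetic
    chromosome (strand from the systematic-name suffix), with protein
    length = stop position + printed truncation, the reference amino
    acid's codon at the stop position, and the single genomic substitution
    converting it to the printed stop codon. A mock aggregate strain
    ("SGRP-mock") carries the variants of every entry not flagged
    strain-unique, so unique-vs-shared classification reproduces the
    printed footnotes. Chromosome coordinates are synthetic; the printed
    genomic positions are kept as metadata in ``expected``.
    """
    chromosomes: dict[str, str] = {}
    orfs: list[OrfRecord] = []
    tables = {
        "74-D694": StrainVariantTable("74-D694"),
        "G600": StrainVariantTable("G600"),
        "SGRP-mock": StrainVariantTable("SGRP-mock"),
    }
    expected_rows = []
    catalogue = ([("74-D694", row) for row in NONSENSE_CATALOGUE_74D694]
                 + [("G600", row) for row in NONSENSE_CATALOGUE_G600])
    for strain, (sys_name, gene, printed_pos, note, trunc, unique) in catalogue:
        ref_aa, codon_index, stop_codon = parse_nonsense_notation(note)
        protein_len = codon_index + trunc
        strand = "+" if sys_name.endswith("W") else "-"
        cds, ref_codon, offset = _fixture_cds(protein_len, ref_aa,
                                              codon_index, stop_codon)
        chrom = f"chr_{sys_name}"
        pad = "T" * flank  # stop-free flank in either frame
        genomic_orf = cds if strand == "+" else reverse_complement(cds)
        chromosomes[chrom] = pad + genomic_orf + pad
        start = flank + 1
        end = flank + len(cds)
        orf = OrfRecord(orf_id=sys_name, chrom=chrom, start=start, end=end,
                        strand=strand, gene_name=gene)
        orfs.append(orf)
        cds_pos = (codon_index - 1) * 3 + offset
        pos = _coding_to_genomic(orf, cds_pos)
        ref_plus = _plus_strand_base(orf, ref_codon[offset - 1])
        alt_plus = _plus_strand_base(orf, stop_codon[offset - 1])
        variant = VariantRecord(chrom, pos, ref_plus, alt_plus, strain)
        tables[strain].add(variant)
        if not unique:
            tables["SGRP-mock"].add(
                VariantRecord(chrom, pos, ref_plus, alt_plus, "SGRP-mock"))
        expected_rows.append({
            "orf_id": sys_name, "gene": gene or ".", "strain": strain,
            "strand": strand, "printed_pos": printed_pos,
            "codon_index": codon_index, "ref_aa": ref_aa,
            "stop_codon": stop_codon, "truncation_len": trunc,
            "notation": note, "protein_len": protein_len,
            "strain_unique": unique,
        })
    genome = Genome(chromosomes)
    expected = pd.DataFrame(expected_rows)
    return FixtureResult(genome, orfs, tables, expected)
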