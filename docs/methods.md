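# Methods

## Coordinate and allele conventions

All genomic coordinates are 1-based inclusive, as in VCF and in yeast
genome annotation; conversion to 0-based slices happens once, at the I/O
boundary. VCF REF/ALT alleles are always expressed on the plus strand;
for a minus-strand ORF the alt base is complemented onto the coding
strand inside the annotator, never in the input records. ORFs are
single-interval CDS features with a strand; intron-containing ORFs are
rejected with an explicit error (the S. cerevisiae ORFs this package
targets are overwhelmingly single-exon, and supporting spliced CDSs
would complicate codon arithmetic for little gain). ORF frame length
must be divisible by 3 (hard error); a missing ATG start or terminal
stop is a warning, not an error, because real annotation sets contain
exceptions.

## Consequence model

For a SNP at genomic position *p* inside an ORF, the codon index is
`(offset // 3) + 1` and the within-codon offset `(offset % 3) + 1`,
where `offset = p − start` on the plus strand and `end − p` on the
minus strand — i.e. codons are always counted from the ORF's own 5'
end. The reference codon is read from the extracted coding sequence and
the alt codon built by substituting the strand-adjusted base. Effects:

- same amino acid → `SYNONYMOUS`;
- sense → different sense amino acid → `MISSENSE`;
- sense → TAA/TAG/TGA inside the ORF → `NONSENSE` (an ISCM);
- natural terminal stop → sense → `STOP_LOSS`; stop → stop →
  `STOP_RETAINED`;
- any change to the ATG start codon → `START_LOSS` (its own class; it
  never counts as an ISCM);
- an N in either codon, or a REF allele disagreeing with the genome →
  `UNDETERMINED` (never silently synonymous), with a logged warning.

The genetic code is the standard nuclear table (64 codons, stops
TAA/TAG/TGA), taken from Biopython; no alternative codes are supported.

Each SNP is classified independently against the *reference* codon. Two
SNPs of one strain in the same codon are each annotated singly and
flagged "compound codon" in the log; the double-mutant codon is not
jointly re-evaluated. A SNP overlapping several ORFs yields one record
per ORF, with no "canonical transcript" selection.

**Truncation length** for a nonsense change at protein position *i* in
a protein of length *L* (stop excluded) is `L − i`: the residues
strictly downstream of the mutated codon. The convention was chosen
because it is the one under which the reconstructed catalogue of
published nonsense alleles is internally consistent (e.g. W244TGA with
a 62-residue truncation implies a 306-residue protein; E64TAA with 507
implies 571). It excludes the mutated residue itself: a nonsense change
at the last sense codon has truncation 0. Equivalently, the mutant
protein has `i − 1` residues, and `(i − 1) + 1 + truncation = L`.

**Notation** follows the community style for yeast alleles: nonsense
changes are written `<ref aa><position><stop codon>` with the stop as a
DNA triplet (`W244TGA`); missense changes as `<ref aa><position><alt aa>`
(`H71L`). Uppercase throughout.

**Stop-loss scanning** walks in-frame codons in genomic sequence
downstream of the ORF until the next stop; the extension is the number
of sense codons read through. If the chromosome ends first, the report
is flagged "no terminator found" rather than given an extension.

## Cross-strain comparison

Tallies operate on distinct SNP keys `(chrom, pos, alt)` — the same
site with a different alt allele is a different SNP. A SNP overlapping
two ORFs counts once toward "SNPs in ORFs" and counts as non-synonymous
if any of its per-ORF records is missense, nonsense, stop-loss or
start-loss; nonsense SNPs are deliberately included in the
non-synonymous tally (the conventional "non-synonymous" column of
strain-summary tables subsumes them).

The ISCM matrix is per-ORF, not per-site: a cell is 1 iff the strain
carries ≥1 nonsense SNP anywhere in that ORF. Distinct nonsense sites
within one ORF stay distinguishable in the long-format listing. An ORF
is *unique* to a strain iff its row is 1 for that strain and 0 for all
others; removing strains from a cohort can therefore only grow the
remaining strains' unique sets. The ISCM frequency statistic is
`round(unique ISCMs / unique non-synonymous SNPs, 3)`, undefined (an
error, not 0) when the denominator is zero.

## Phylogeny and branch attribution

Pairwise strain distances are symmetric-difference counts over SNP
keys; the reference strain is the empty profile, so its distance to any
strain is that strain's SNP count. The tree is built by neighbor
joining (dendropy's implementation, fed taxa in sorted order so ties
resolve deterministically); negative NJ branch lengths are clamped to
zero with a warning. NJ is used deliberately instead of likelihood
methods: the analysis this package performs needs only a reasonable
tree topology over strains, and a user-supplied Newick bypasses tree
building entirely. The tree is rooted on the branch leading to the
reference leaf (bisecting it), making the reference the outgroup.

Branch numbering is deterministic: children are first sorted by their
smallest descendant leaf label, then every non-root node's parent edge
is numbered 1..n in postorder. Attribution is exact clade matching on
the rooted tree: a SNP whose carrier set equals the leaf set subtended
by branch *b* is assigned to *b* — leaf branches collect strain-unique
SNPs, internal branches lineage-specific SNPs, and the branch above the
all-strains clade collects species-specific SNPs (carried by every
non-reference strain). A carrier set matching no clade is homoplasious
under the tree and goes to the `unassigned` set; it is reported, never
forced onto a best-fitting branch, because "unique to a strain or
branch" is defined here *as* exact clade identity. Three per-branch
layers are counted: all SNPs, non-synonymous SNPs, ISCMs.

## Synthetic cohorts

`simulate_cohort` draws a random genome (default 4 chromosomes × 60 kb),
places non-overlapping single-exon ORFs on both strands (default 60
ORFs of 80–400 codons, ATG start, stop end, stop-free internal codons),
takes a strain tree (supplied Newick or a random 8-leaf tree), and
plants a fixed number of SNPs (default 30) on every branch, including
the root clade (species-specific SNPs). Each planted SNP is inherited
by exactly its branch's clade of leaves; with `homoplasy_rate > 0` that
fraction of SNPs instead receives a carrier set verified to match no
clade. Consequence classes are enforced at planting time by choosing a
codon position and alt base that realize them — nonsense sites are
drawn from codons one substitution away from a stop, and codon 1 and
the natural stop are excluded for non-stop-loss classes — so the truth
table can be compared to annotator output exactly.

Default effect fractions are synonymous 0.39, missense 0.20, nonsense
0.01, stop-loss 0.005, remainder intergenic. The synonymous / missense /
intergenic split mirrors the genome-wide proportions observed in
re-sequenced laboratory yeast strains (roughly 61% of SNPs inside ORFs,
roughly a third of those non-synonymous). The raw genome-wide nonsense
rate in such data is far lower (order 10⁻³ of all SNPs); at the
desk-scale cohort sizes the simulator defaults to, that rate would
plant essentially zero ISCMs, so the default nonsense fraction is set
to 1% to keep ISCM-dependent behaviour exercised. Tests that require
exact planted counts pass explicit fractions.

All stochastic choices flow from a single seeded numpy Generator; the
same config reproduces byte-identical cohorts. Strains are haploid SNP
profiles — diploidy (and hence heterozygous ISCMs segregating in
derived haploids) is not modeled. Read-level artifacts (sequencing
error, coverage, caller bias) are outside scope: passing full-loop
recovery tests shows the annotation/attribution logic is exact on clean
variant calls, not that upstream calling is robust.

The fixture builder reconstructs a 26-row catalogue of published-style
nonsense alleles (22 in one strain, 4 in another) purely from each
row's notation arithmetic: protein length = stop position + truncation,
the reference amino acid's codon (the one a single substitution away
from the printed stop) at that position, strand taken from the
systematic name suffix (W = Watson/plus, C = Crick/minus), one
synthetic chromosome per ORF. A mock aggregate strain carries the
variants of the rows not flagged strain-unique, so unique-vs-shared
classification reproduces the printed 14 + 2 unique sets. Chromosome
coordinates are synthetic; the printed genomic positions are carried as
metadata only.

## Numerical and degenerate-input choices

- Output rows are sorted (chrom, pos, strain, orf) with a stable sort;
  re-running the pipeline on identical inputs yields byte-identical files.
- Multiallelic VCF records are rejected outright (one alt per site per
  strain); indels and other non-SNVs are skipped with a logged count.
- An empty variant table is valid everywhere and produces all-zero
  summaries and empty outputs, exit code 0.
- NJ requires ≥3 taxa; the reference profile counts as one, so two
  strains plus the reference suffice.
- Problem sizes throughout tests and the acceptance script (60-ORF
  genomes, 8-strain cohorts, ~100-codon oracle ORFs) were chosen so the
  planted structure is dense enough to exercise every consequence class
  and branch layer while the whole suite runs in seconds.

## Known limitations

- Single-exon CDSs only; no spliced ORFs, no alternative genetic codes.
- No modeling of nonsense-mediated decay, readthrough efficiency, or
  mRNA stability — an ISCM call is a genotypic statement only.
- Attribution assumes a correct tree; under extensive homoplasy or a
  wrong topology, genuinely clade-specific SNPs will surface in the
  unassigned set rather than being re-fit.
- The simulator plants at most one SNP per genomic site per cohort, so
  recurrent mutation at a site is only represented via the explicit
  homoplasy mechanism.
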