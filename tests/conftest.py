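import numpy as np
import pytest

import iscmscan as m


@pytest.fixture(scope="session")
def code():
    return m.GeneticCodeTable()


@pytest.fixture(scope="session")
def toy_genome():
    """Two tiny chromosomes hosting one plus-strand and one minus-strand ORF.

    chrA[11..28] (+): ATG TGG GAA CAA AAA TAA  -> protein "MWEQK"
    chrB[11..22] (-): ATG TGG TAA on the reverse strand -> protein "MW"
    """
    plus_cds = "ATGTGGGAACAAAAATAA"
    minus_cds = "ATGTGGTAA"
    chrA = "T" * 10 + plus_cds + "T" * 10
    chrB = "T" * 10 + m.reverse_complement(minus_cds) + "T" * 10
    genome = m.Genome({"chrA": chrA, "chrB": chrB})
    orfs = [
        m.OrfRecord("ORFP", "chrA", 11, 28, "+", gene_name="PLS1"),
        m.OrfRecord("ORFM", "chrB", 11, 19, "-"),
    ]
    return genome, orfs


@pytest.fixture(scope="session")
def catalogue_fixture():
    return m.build_nonsense_fixture()


@pytest.fixture(scope="session")
def fixture_annotations(catalogue_fixture):
    index = m.OrfIndex(catalogue_fixture.orfs)
    return {
        strain: m.annotate_strain(table, index, catalogue_fixture.genome)
        for strain, table in catalogue_fixture.tables.items()
    }


@pytest.fixture(scope="session")
def cohort():
    """A seeded 8-strain simulated cohort with no homoplasy."""
    return m.simulate_cohort(
        m.SimulationConfig(seed=7, snps_per_branch=12, n_strains=8)
    )


@pytest.fixture(scope="session")
def cohort_annotations(cohort):
    index = m.OrfIndex(cohort.orfs)
    anns = {}
    for strain, table in cohort.tables.items():
        anns[strain] = m.annotate_strain(table, index, cohort.genome)
    return anns


def random_orf_genome(rng, n_codons=100, flank=25, strand="+"):
    """A one-ORF genome with random sense internal codons, for oracle tests."""
    from iscmscan.synthetic_data import _random_orf_seq

    cds = _random_orf_seq(rng, n_codons)
    genomic = cds if strand == "+" else m.reverse_complement(cds)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, flank)])
    seq2 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, flank)])
    chrom = seq + genomic + seq2
    genome = m.Genome({"chr1": chrom})
    orf = m.OrfRecord("ORF1", "chr1", flank + 1, flank + len(cds), strand)
    return genome, orf


def oracle_effect(genome, orf, variant, code):
    """Brute-force consequence call: rebuild the mutant chromosome, extract
    and translate both CDSs, and diff the codons/proteins. Independent of
    the codon-arithmetic path in the annotator."""
    seq = genome.chromosomes[variant.chrom]
    assert seq[variant.pos - 1] == variant.ref_base
    mutant = seq[: variant.pos - 1] + variant.alt_base + seq[variant.pos:]
    genome2 = m.Genome({**genome.chromosomes, variant.chrom: mutant})
    ref_cds = m.extract_cds(genome, orf)
    alt_cds = m.extract_cds(genome2, orf)
    ref_codons = [ref_cds[i : i + 3] for i in range(0, len(ref_cds), 3)]
    alt_codons = [alt_cds[i : i + 3] for i in range(0, len(alt_cds), 3)]
    diff = [i for i, (a, b) in enumerate(zip(ref_codons, alt_codons)) if a != b]
    if not diff:
        return m.SnpEffect.SYNONYMOUS, None
    assert len(diff) == 1
    i = diff[0]
    ref_aa = code.aa(ref_codons[i])
    alt_aa = code.aa(alt_codons[i])
    last = i == len(ref_codons) - 1
    if last and ref_aa == "*":
        eff = (m.SnpEffect.STOP_RETAINED if alt_aa == "*"
               else m.SnpEffect.STOP_LOSS)
    elif ref_aa == alt_aa:
        eff = m.SnpEffect.SYNONYMOUS
    elif i == 0 and ref_codons[0] == "ATG":
        eff = m.SnpEffect.START_LOSS
    elif alt_aa == "*":
        eff = m.SnpEffect.NONSENSE
    else:
        eff = m.SnpEffect.MISSENSE
    return eff, i + 1
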