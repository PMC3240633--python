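"""Cross-strain tallies: per-strain SNP summaries, the ORF-by-strain ISCM
presence/absence matrix, unique-vs-shared classification, and the ISCM
frequency statistic (unique ISCMs per unique non-synonymous SNP).

Counting conventions
--------------------
A SNP is one distinct (chrom, pos, alt) key. A SNP overlapping two ORFs
counts once toward "SNPs in ORFs"; it counts as non-synonymous if its
record against any overlapping ORF is non-synonymous (missense, nonsense,
stop-loss or start-loss — nonsense is included in the non-synonymous
tally). The ISCM matrix is per-ORF, not per-site: a cell is 1 iff the
strain carries at least one nonsense SNP in that ORF; distinct nonsense
sites within one ORF remain distinguishable in the long-format output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .effect_annotation import AnnotatedVariant, SnpEffect


@dataclass(frozen=True)
class StrainSummary:
    """Per-strain tallies of distinct SNPs by consequence."""

    strain_id: str
    n_snps_total: int
    n_snps_in_orfs: int
    n_nonsynonymous: int
    n_iscm: int

    def __post_init__(self) -> None:
        if not (self.n_iscm <= self.n_nonsynonymous
                <= self.n_snps_in_orfs <= self.n_snps_total):
            raise ValueError(f"inconsistent summary for {self.strain_id}: {self}")


def summarize_strain(annotations: Iterable[AnnotatedVariant]) -> StrainSummary:
    """Tally one strain's annotated SNPs.

    ``annotations`` must all belong to one strain (one record per
    overlapping ORF, as produced by the annotator).
    """
    strains = set()
    in_orf: set[tuple] = set()
    nonsyn: set[tuple] = set()
    iscm: set[tuple] = set()
    total: set[tuple] = set()
    for a in annotations:
        strains.add(a.variant.strain_id)
        key = a.variant.key
        total.add(key)
        if a.orf_id is not None:
            in_orf.add(key)
        if a.effect.is_nonsynonymous:
            nonsyn.add(key)
        if a.effect is SnpEffect.NONSENSE:
            iscm.add(key)
    if len(strains) > 1:
        raise ValueError(f"annotations span multiple strains: {sorted(strains)}")
    strain_id = strains.pop() if strains else ""
    return StrainSummary(strain_id, len(total), len(in_orf), len(nonsyn), len(iscm))


def summaries_to_frame(summaries: Iterable[StrainSummary]) -> pd.DataFrame:
    rows = [{
        "strain": s.strain_id,
        "n_snps_total": s.n_snps_total,
        "n_snps_in_orfs": s.n_snps_in_orfs,
        "n_nonsynonymous": s.n_nonsynonymous,
        "n_iscm": s.n_iscm,
    } for s in sorted(summaries, key=lambda s: s.strain_id)]
    return pd.DataFrame(rows, columns=[
        "strain", "n_snps_total", "n_snps_in_orfs", "n_nonsynonymous", "n_iscm",
    ])


# ---------------------------------------------------------------------------
# ISCM presence/absence matrix
# ---------------------------------------------------------------------------

def build_iscm_matrix(
    annotations_by_strain: Mapping[str, Iterable[AnnotatedVariant]],
) -> pd.DataFrame:
    """ORF-by-strain 0/1 matrix of ISCM presence.

    Rows are ORF ids (sorted), columns strain ids (sorted); a cell is 1 iff
    the strain has at least one NONSENSE annotation in that ORF.
    """
    strains = sorted(annotations_by_strain)
    cells: set[tuple[str, str]] = set()
    for strain in strains:
        for a in annotations_by_strain[strain]:
            if a.effect is SnpEffect.NONSENSE and a.orf_id is not None:
                cells.add((a.orf_id, strain))
    orf_ids = sorted({orf for orf, _ in cells})
    matrix = pd.DataFrame(0, index=orf_ids, columns=strains, dtype=int)
    for orf, strain in cells:
        matrix.loc[orf, strain] = 1
    matrix.index.name = "orf_id"
    return matrix


def iscm_long_table(
    annotations_by_strain: Mapping[str, Iterable[AnnotatedVariant]],
) -> pd.DataFrame:
    """Long-format ISCM listing (orf, strain, chrom, pos, notation,
    truncation): keeps multiple nonsense sites in one ORF distinguishable."""
    rows = []
    for strain in sorted(annotations_by_strain):
        for a in annotations_by_strain[strain]:
            if a.effect is SnpEffect.NONSENSE:
                rows.append({
                    "orf_id": a.orf_id, "gene": a.gene_name or ".",
                    "strain": strain, "chrom": a.variant.chrom,
                    "pos": a.variant.pos, "notation": a.notation,
                    "truncation_len": a.truncation_len,
                })
    frame = pd.DataFrame(rows, columns=[
        "orf_id", "gene", "strain", "chrom", "pos", "notation", "truncation_len",
    ])
    if len(frame):
        frame = frame.sort_values(["orf_id", "strain", "pos"],
                                  kind="mergesort").reset_index(drop=True)
    return frame


def classify_sharing(matrix: pd.DataFrame, strain: str) -> dict[str, list[str]]:
    """Partition a strain's ISCM-bearing ORFs into strain-unique vs shared.

    An ORF is unique to ``strain`` iff its matrix row is 1 for this strain
    and 0 for every other strain in the cohort.
    """
    if strain not in matrix.columns:
        raise KeyError(f"strain {strain!r} not in matrix")
    present = matrix[matrix[strain] == 1]
    others = [c for c in matrix.columns if c != strain]
    if others:
        shared_mask = present[others].sum(axis=1) > 0
    else:
        shared_mask = pd.Series(False, index=present.index)
    return {
        "unique_orfs": sorted(present.index[~shared_mask]),
        "shared_orfs": sorted(present.index[shared_mask]),
    }


def iscm_frequency(n_unique_iscm: int, n_unique_nonsyn: int) -> float:
    """Strain-unique ISCMs per strain-unique non-synonymous SNP, rounded to
    three decimals (e.g. 14 unique ISCMs over 680 unique non-synonymous
    SNPs gives 0.021). Undefined for a zero denominator."""
    if n_unique_nonsyn <= 0:
        raise ZeroDivisionError(
            "ISCM frequency undefined: no unique non-synonymous SNPs"
        )
    return round(n_unique_iscm / n_unique_nonsyn, 3)
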