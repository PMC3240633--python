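"""Strain phylogeny from SNP differences and branch attribution of SNPs.

A strain tree is built by neighbor joining from pairwise SNP-difference
counts (or supplied as Newick), rooted on the branch leading to the
reference strain, and each SNP is attributed to the unique branch whose
subtended clade equals the SNP's carrier set exactly. A carrier set of
size one lands on a leaf branch (strain-unique SNP); a carrier set equal
to a deeper clade's leaves marks a lineage-specific SNP; a carrier set
matching no clade (homoplasy under this tree) is reported separately,
never forced onto a best branch. Three layers are counted per branch:
all SNPs, non-synonymous SNPs, and ISCMs (nonsense SNPs).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import pandas as pd

from .effect_annotation import AnnotatedVariant, SnpEffect
from .genome_io import REFERENCE_STRAIN, StrainVariantTable

logger = logging.getLogger("iscmscan")

SnpKey = tuple[str, int, str]  # (chrom, pos, alt)


# ---------------------------------------------------------------------------
# SNP distances
# ---------------------------------------------------------------------------

def snp_distance(a: StrainVariantTable | frozenset, b: StrainVariantTable | frozenset) -> int:
    """Symmetric-difference count over (chrom, pos, alt) SNP keys."""
    ka = a.keys if isinstance(a, StrainVariantTable) else frozenset(a)
    kb = b.keys if isinstance(b, StrainVariantTable) else frozenset(b)
    return len(ka ^ kb)


def build_distance_matrix(tables: Sequence[StrainVariantTable],
                          include_reference: bool = True,
                          reference: str = REFERENCE_STRAIN) -> pd.DataFrame:
    """Pairwise SNP-difference matrix over strains, sorted by strain id.

    The reference strain carries the empty SNP set, so its distance to any
    strain is that strain's SNP count.
    """
    key_sets = {t.strain_id: t.keys for t in tables}
    if len(key_sets) != len(tables):
        raise ValueError("duplicate strain ids in distance matrix input")
    if include_reference:
        if reference in key_sets:
            raise ValueError(f"reference {reference!r} already among strains")
        key_sets[reference] = frozenset()
    names = sorted(key_sets)
    dm = pd.DataFrame(0, index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = snp_distance(key_sets[a], key_sets[b])
            dm.loc[a, b] = dm.loc[b, a] = float(d)
    return dm


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------

def neighbor_joining(distances: pd.DataFrame) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Taxa are processed in sorted order so that agglomeration ties resolve
    deterministically. Negative branch lengths (possible under NJ on
    non-additive matrices) are clamped to zero with a warning.
    """
    if len(distances) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    names = sorted(distances.index)
    dm_sorted = distances.loc[names, names]
    buf = io.StringIO()
    dm_sorted.to_csv(buf)
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=buf, delimiter=",")
    tree = pdm.nj_tree()
    n_clamped = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
            n_clamped += 1
    if n_clamped:
        logger.warning("clamped %d negative NJ branch lengths to 0", n_clamped)
    return tree


def root_at_reference(tree: dendropy.Tree,
                      reference: str = REFERENCE_STRAIN) -> dendropy.Tree:
    """Root the tree on the branch leading to the reference strain leaf."""
    leaf = None
    for node in tree.leaf_node_iter():
        if node.taxon is not None and node.taxon.label == reference:
            leaf = node
            break
    if leaf is None:
        raise ValueError(f"reference leaf {reference!r} not found in tree")
    if leaf.edge.length is not None and leaf.edge.length > 0:
        tree.reroot_at_edge(leaf.edge, length1=leaf.edge.length / 2.0,
                            length2=leaf.edge.length / 2.0,
                            update_bipartitions=False)
    else:
        tree.reroot_at_edge(leaf.edge, update_bipartitions=False)
    tree.is_rooted = True
    return tree


def read_newick(path: str) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


# ---------------------------------------------------------------------------
# Branch numbering and clade enumeration
# ---------------------------------------------------------------------------

def _canonicalize(tree: dendropy.Tree) -> None:
    """Sort children everywhere by their smallest descendant leaf label so
    numbering is invariant to leaf-order rotations of the input tree."""
    min_leaf: dict[dendropy.Node, str] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            min_leaf[node] = node.taxon.label if node.taxon else ""
        else:
            min_leaf[node] = min(min_leaf[c] for c in node.child_nodes())
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            node.set_child_nodes(sorted(node.child_nodes(),
                                        key=lambda c: min_leaf[c]))


def number_branches(tree: dendropy.Tree,
                    reference: str = REFERENCE_STRAIN) -> dict[int, frozenset[str]]:
    """Assign deterministic branch ids on a rooted tree.

    The tree is first canonicalized (children sorted by smallest leaf
    label), then every non-root node's parent edge is numbered 1..n in
    postorder. Returns branch_id -> frozenset of leaf labels subtended,
    and stores the id on each node as ``node.branch_id``. The reference
    leaf's own branch is numbered like any other but carries no SNPs.
    """
    _canonicalize(tree)
    clades: dict[int, frozenset[str]] = {}
    leafsets: dict[dendropy.Node, frozenset[str]] = {}
    next_id = 1
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = frozenset([node.taxon.label])
        else:
            leafsets[node] = frozenset().union(*(leafsets[c] for c in node.child_nodes()))
        if node.parent_node is not None:  # every branch except the root
            node.branch_id = next_id
            clades[next_id] = leafsets[node]
            next_id += 1
    return clades


# ---------------------------------------------------------------------------
# Attribution
# ---------------------------------------------------------------------------

@dataclass
class BranchAssignment:
    """Per-branch counts of uniquely attributed SNPs plus the unassigned set.

    ``counts[branch_id] = (n_snps, n_nonsyn, n_iscm)``; ``clades`` maps each
    branch id to the leaf set of its subtended clade; ``unassigned`` holds
    SNP keys whose carrier set matches no clade of the tree.
    """

    counts: dict[int, tuple[int, int, int]]
    clades: dict[int, frozenset[str]]
    unassigned: set[SnpKey] = field(default_factory=set)

    @property
    def n_assigned(self) -> int:
        return sum(c[0] for c in self.counts.values())


def carrier_sets(tables: Sequence[StrainVariantTable]) -> dict[SnpKey, frozenset[str]]:
    """Map each SNP key to the set of strains carrying it."""
    carriers: dict[SnpKey, set[str]] = {}
    for t in tables:
        for key in t.keys:
            carriers.setdefault(key, set()).add(t.strain_id)
    return {k: frozenset(v) for k, v in carriers.items()}


def effect_layers(annotations: Iterable[AnnotatedVariant]) -> dict[SnpKey, tuple[bool, bool]]:
    """Map each SNP key to (is_nonsynonymous, is_iscm) across all ORFs."""
    layers: dict[SnpKey, list[bool]] = {}
    for a in annotations:
        key = a.variant.key
        flags = layers.setdefault(key, [False, False])
        if a.effect.is_nonsynonymous:
            flags[0] = True
        if a.effect is SnpEffect.NONSENSE:
            flags[1] = True
    return {k: (v[0], v[1]) for k, v in layers.items()}


def attribute_to_branches(
    tree: dendropy.Tree,
    snp_carriers: Mapping[SnpKey, frozenset[str]],
    annotations: Iterable[AnnotatedVariant] = (),
    reference: str = REFERENCE_STRAIN,
) -> BranchAssignment:
    """Attribute each SNP to the branch whose clade equals its carrier set.

    The tree must be rooted (see :func:`root_at_reference`). A SNP whose
    carrier set is a single strain lands on that strain's leaf branch; a
    carrier set equal to an internal clade's leaves lands on that internal
    branch; any other carrier set goes to ``unassigned``.
    """
    clades = number_branches(tree, reference=reference)
    clade_to_branch = {leaves: bid for bid, leaves in clades.items()}
    layers = effect_layers(annotations)
    counts = {bid: [0, 0, 0] for bid in clades}
    unassigned: set[SnpKey] = set()
    for key, carriers in snp_carriers.items():
        bid = clade_to_branch.get(frozenset(carriers))
        if bid is None:
            unassigned.add(key)
            continue
        nonsyn, iscm = layers.get(key, (False, False))
        counts[bid][0] += 1
        if nonsyn:
            counts[bid][1] += 1
        if iscm:
            counts[bid][2] += 1
    return BranchAssignment(
        counts={bid: tuple(c) for bid, c in counts.items()},
        clades=clades,
        unassigned=unassigned,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def branch_table(assignment: BranchAssignment) -> pd.DataFrame:
    rows = []
    for bid in sorted(assignment.counts):
        n_snps, n_nonsyn, n_iscm = assignment.counts[bid]
        rows.append({
            "branch_id": bid,
            "clade_leaves": ",".join(sorted(assignment.clades[bid])),
            "n_snps": n_snps, "n_nonsyn": n_nonsyn, "n_iscm": n_iscm,
        })
    return pd.DataFrame(rows, columns=[
        "branch_id", "clade_leaves", "n_snps", "n_nonsyn", "n_iscm",
    ])


def render_annotated_tree(tree: dendropy.Tree, assignment: BranchAssignment,
                          style: str = "comment") -> str:
    """Newick string with per-branch "nonsyn/ISCM" labels.

    ``style='comment'`` attaches ``[&label]`` square-bracket comments to
    every branch (leaves included); ``style='label'`` writes the label as
    the internal node label (leaf branches then appear only in the TSV).
    """
    if style not in ("comment", "label"):
        raise ValueError("style must be 'comment' or 'label'")
    clone = tree.clone(depth=1)
    number_branches(clone)  # ids identical to assignment's (deterministic)
    for node in clone.postorder_node_iter():
        bid = getattr(node, "branch_id", None)
        if bid is None or bid not in assignment.counts:
            continue
        _, n_nonsyn, n_iscm = assignment.counts[bid]
        label = f"{n_nonsyn}/{n_iscm}"
        if style == "comment":
            node.edge.annotations.add_new("branch", f"{bid}:{label}")
        elif not node.is_leaf():
            node.label = label
    return clone.as_string(
        schema="newick", unquoted_underscores=True,
        suppress_annotations=(style != "comment"),
    )
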