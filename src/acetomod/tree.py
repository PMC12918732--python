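"""Reference-tree pruning and tree-overlay annotation files.

Prunes a reference tree (e.g. the GTDB archaeal tree) to the surveyed
genomes and writes plain-text overlay annotations: one iTOL-style
DATASET_BINARY file per module flag plus a leaf-to-category TSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import dendropy

from .classify import CategoryCall
from .errors import AcetomodError
from .hmmio import strip_accession_prefix
from .modules import GenomeProfile


def prune_to_genomes(tree: dendropy.Tree, genome_ids) -> dendropy.Tree:
    """Smallest topology-preserving tree on leaves ∩ genome_ids.

    Leaf labels are matched on the stripped accession (GTDB ``RS_``/
    ``GB_`` prefixes dropped); unmatched requested genomes are reported
    via the returned tree's ``unmatched_genomes`` attribute, not fatal.
    Internal unary nodes are collapsed with branch lengths summed.
    """
    wanted = {strip_accession_prefix(g) for g in genome_ids}
    clone = tree.clone(depth=1)
    keep = [
        leaf.taxon
        for leaf in clone.leaf_node_iter()
        if leaf.taxon is not None
        and strip_accession_prefix(leaf.taxon.label) in wanted
    ]
    if not keep:
        raise AcetomodError("no tree leaf matches any requested genome")
    found = {strip_accession_prefix(t.label) for t in keep}
    clone.retain_taxa(keep)  # prunes, collapses unary nodes, sums edges
    clone.unmatched_genomes = sorted(wanted - found)
    return clone


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [
        leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon is not None
    ]


_ITOL_COLORS = ("#3b7a57",)


def _itol_binary(field_label: str, rows: list[tuple[str, int]]) -> str:
    lines = [
        "DATASET_BINARY",
        "SEPARATOR TAB",
        f"DATASET_LABEL\t{field_label}",
        f"COLOR\t{_ITOL_COLORS[0]}",
        f"FIELD_SHAPES\t1",
        f"FIELD_LABELS\t{field_label}",
        "DATA",
    ]
    lines += [f"{leaf}\t{value}" for leaf, value in rows]
    return "\n".join(lines) + "\n"


@dataclass
class OverlayResult:
    """Paths written by :func:`emit_overlay` plus the unannotated leaves."""

    binary_datasets: dict[str, str]
    category_table: str
    sidecar: str
    unannotated: list[str]


def emit_overlay(
    profiles: list[GenomeProfile],
    calls: list[CategoryCall],
    tree: dendropy.Tree,
    outdir,
) -> OverlayResult:
    """Write per-module binary overlays and a leaf-to-category TSV.

    Every tree leaf appears exactly once in each overlay; leaves without a
    profile are listed in a sidecar file of unannotated leaves.
    """
    os.makedirs(outdir, exist_ok=True)
    by_genome = {strip_accession_prefix(p.genome_id): p for p in profiles}
    call_by_genome = {strip_accession_prefix(c.genome_id): c for c in calls}
    leaves = leaf_labels(tree)
    annotated = [
        leaf for leaf in leaves if strip_accession_prefix(leaf) in by_genome
    ]
    unannotated = [
        leaf for leaf in leaves if strip_accession_prefix(leaf) not in by_genome
    ]
    binary_paths: dict[str, str] = {}
    for flag in GenomeProfile.FLAG_NAMES:
        rows = [
            (leaf, int(by_genome[strip_accession_prefix(leaf)].flags()[flag]))
            for leaf in annotated
        ]
        path = os.path.join(outdir, f"itol_{flag}.txt")
        with open(path, "w") as fh:
            fh.write(_itol_binary(flag, rows))
        binary_paths[flag] = path
    category_table = os.path.join(outdir, "leaf_categories.tsv")
    with open(category_table, "w") as fh:
        fh.write("leaf_id\tcategory\n")
        for leaf in annotated:
            call = call_by_genome.get(strip_accession_prefix(leaf))
            fh.write(f"{leaf}\t{call.category if call else 'unclassified'}\n")
    sidecar = os.path.join(outdir, "unannotated_leaves.txt")
    with open(sidecar, "w") as fh:
        for leaf in unannotated:
            fh.write(leaf + "\n")
    return OverlayResult(
        binary_datasets=binary_paths,
        category_table=category_table,
        sidecar=sidecar,
        unannotated=unannotated,
    )
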