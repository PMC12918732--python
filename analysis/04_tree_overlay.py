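#!/usr/bin/env python
"""Prune the community tree and emit presence/absence overlay files.

Prunes the reference tree to the surveyed genomes and writes one
iTOL-style DATASET_BINARY file per module flag plus a leaf-to-category
table under results/overlay/.
"""

from __future__ import annotations

import os
import sys

import dendropy

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from acetomod import tree as tree_mod  # noqa: E402
from acetomod.pipeline import run_survey  # noqa: E402

sys.path.insert(0, os.path.dirname(__file__))
from importlib import import_module  # noqa: E402

load_community = import_module("02_survey_modules").load_community

ROOT = os.path.join(os.path.dirname(__file__), "..")
RESULTS = os.path.join(ROOT, "results")


def main() -> None:
    community = load_community()
    result = run_survey(community.proteomes, community.hmms)
    full = dendropy.Tree.get(
        data=community.tree_newick, schema="newick", preserve_underscores=True
    )
    pruned = tree_mod.prune_to_genomes(
        full, [p.genome_id for p in result.profiles]
    )
    outdir = os.path.join(RESULTS, "overlay")
    overlay = tree_mod.emit_overlay(result.profiles, result.calls, pruned, outdir)
    pruned.write(path=os.path.join(outdir, "pruned.nwk"), schema="newick")
    print(
        f"Pruned tree to {len(tree_mod.leaf_labels(pruned))} leaves; "
        f"{len(overlay.binary_datasets)} binary overlay datasets and the "
        f"category table written to {os.path.relpath(outdir, ROOT)}/ "
        f"({len(overlay.unannotated)} unannotated leaves)."
    )


if __name__ == "__main__":
    main()
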