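#!/usr/bin/env python
"""Profile-HMM search and module-presence calling on the community.

Loads the fixtures written by 01 (regenerating them if absent), scores
every protein against every model with the internal Viterbi engine,
applies the survey filters (E < 1e-3 and the per-model noise cutoff), and
writes per-genome module profiles to results/profiles.tsv.
"""

from __future__ import annotations

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from acetomod import modules, search, simulate  # noqa: E402
from acetomod.search import SearchConfig  # noqa: E402

ROOT = os.path.join(os.path.dirname(__file__), "..")
SCRATCH = os.path.join(ROOT, "scratch", "community")
RESULTS = os.path.join(ROOT, "results")


def load_community():
    if os.path.isdir(SCRATCH):
        return simulate.read_community(SCRATCH)
    community = simulate.make_community(
        simulate.CommunitySpec(seed=simulate.DEFAULT_SEED)
    )
    simulate.write_community(community, SCRATCH)
    return community


def main() -> None:
    community = load_community()
    cfg = SearchConfig()
    hits = search.run_search(community.proteomes, community.hmms, cfg)
    kept = search.best_hit_per_protein(
        search.filter_hits(hits, community.hmms, cfg)
    )
    profiles = modules.profile_genomes(kept, sorted(community.proteomes))
    frame = modules.profiles_to_frame(profiles)
    os.makedirs(RESULTS, exist_ok=True)
    frame.to_csv(os.path.join(RESULTS, "profiles.tsv"), sep="\t", index=False)
    n_decoy_kept = sum(1 for h in kept if "decoy" in h.protein_id)
    print(
        f"Scored {len(hits)} (protein, model) pairs across "
        f"{len(community.proteomes)} genomes; {len(kept)} hits pass "
        f"E < {cfg.evalue_max:g} and the NC score cutoff "
        f"({n_decoy_kept} from decoy proteins)."
    )
    module_cols = [c for c in frame.columns if c.endswith("_present")]
    print("Module presence counts across genomes:")
    print(frame[module_cols].sum().rename(lambda c: c[:-8]).to_string())
    print("Profiles written to results/profiles.tsv.")


if __name__ == "__main__":
    main()
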