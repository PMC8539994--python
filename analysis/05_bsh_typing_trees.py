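#!/usr/bin/env python
"""BSH subtype typing and neighbor-joining trees.

Types every gene of every strain against the three BSH subtype references
(best local-alignment hit with e < 3.24e-18), tallies per-strain subtype
patterns, then builds a p-distance NJ tree per subtype rooted on the
reference as outgroup, with distance-threshold clade groups.  Writes
results/bsh_profiles.tsv, per-subtype Newick trees and
results/bsh_tree_groups.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from pantrait import cohort_bsh_summary, cut_groups, neighbor_joining, pairwise_distance, root_with_outgroup, strain_bsh_profile
from pantrait.bsh import read_reference_fasta
from pantrait.pipeline import load_proteomes

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    ap.add_argument("--cut-height", type=float, default=0.15)
    args = ap.parse_args()

    refs = read_reference_fasta(args.cohort / "bsh_references.faa")
    proteomes = load_proteomes(args.cohort / "proteomes")
    profiles = [strain_bsh_profile(p, refs) for p in proteomes]
    table, tallies = cohort_bsh_summary(profiles)
    table.to_csv(args.results / "bsh_profiles.tsv", sep="\t", index=False)
    print("subtype presence patterns:", tallies)

    seq_of = {p.strain_id: dict(p.genes) for p in proteomes}
    rows = []
    for ref in sorted(refs, key=lambda r: r.subtype):
        seqs = {ref.accession: ref.sequence}
        for prof in profiles:
            for gene_id, subtype in prof.assignments.items():
                if subtype == ref.subtype:
                    seqs[gene_id] = seq_of[prof.strain_id][gene_id]
        if len(seqs) < 3:
            print(f"BSH{ref.subtype}: only {len(seqs) - 1} genes, skipping tree")
            continue
        dm = pairwise_distance(seqs, model="p")
        tree = neighbor_joining(dm)
        rooted, newick = root_with_outgroup(tree, ref.accession)
        (args.results / f"bsh_{ref.subtype}_nj.nwk").write_text(newick + "\n")
        groups = cut_groups(rooted, args.cut_height)
        n_groups = len(set(groups.values()))
        print(f"BSH{ref.subtype}: {len(seqs) - 1} genes, {n_groups} groups at cut height {args.cut_height}")
        rows += [{"subtype": ref.subtype, "gene": g, "tree_group": grp} for g, grp in sorted(groups.items())]
    pd.DataFrame(rows).to_csv(args.results / "bsh_tree_groups.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
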