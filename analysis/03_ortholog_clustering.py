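#!/usr/bin/env python
"""Ortholog clustering of the cohort proteomes.

All-vs-all local alignment (k-mer prefiltered Smith-Waterman, BLOSUM62,
Karlin-Altschul e-values), reciprocal-hit similarity graph, Markov clustering
into ortholog groups, and the group x strain copy-number matrix.  Writes
results/hits.tsv, results/ortholog_groups.tsv and
results/copy_number_matrix.tsv.
"""

import argparse
from pathlib import Path

from pantrait import all_vs_all, build_graph, copy_number_matrix, mcl
from pantrait.align import write_hit_table
from pantrait.cluster import partition_to_frame
from pantrait.pipeline import load_proteomes
from pantrait.proteomes import gene_strain_map

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    proteomes = load_proteomes(args.cohort / "proteomes")
    hits = all_vs_all(proteomes)
    args.out.mkdir(parents=True, exist_ok=True)
    write_hit_table(hits, args.out / "hits.tsv")
    print(f"{len(hits)} alignment hits over {sum(len(p) for p in proteomes)} genes")

    graph = build_graph(hits, max_evalue=1e-5)
    clusters = mcl(graph, inflation=1.5)
    partition = partition_to_frame(clusters)
    partition.to_csv(args.out / "ortholog_groups.tsv", sep="\t", index=False)
    matrix = copy_number_matrix(
        partition, [p.strain_id for p in proteomes], gene_strain_map(proteomes)
    )
    matrix.to_csv(args.out / "copy_number_matrix.tsv", sep="\t")
    sizes = partition.groupby("group").size()
    print(f"{len(clusters)} ortholog groups (largest {sizes.max()}, singletons {(sizes == 1).sum()})")
    print(f"copy-number matrix: {matrix.shape[0]} groups x {matrix.shape[1]} strains")


if __name__ == "__main__":
    main()
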