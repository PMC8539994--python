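#!/usr/bin/env python
"""Presence/absence screens for tolerance-associated genes.

Contrasts the tolerant-group core against the non-tolerant strains (variable
genes: core in all tolerant, deleted in >= 2 non-tolerant) and the mirror
screen (redundant genes), then clusters the selected groups' copy-number
vectors (Euclidean, complete linkage) for the heatmap ordering.  Writes
results/screen_report.tsv and results/screen_dendrogram.nwk.
"""

import argparse
from pathlib import Path

import pandas as pd

from pantrait import ScreenConfig, hierarchical_cluster, redundant_genes, screen_report, variable_genes
from pantrait.stats import select_extremes

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    ap.add_argument("--k-deletion", type=int, default=2)
    args = ap.parse_args()

    matrix = pd.read_csv(args.results / "copy_number_matrix.tsv", sep="\t", index_col=0)
    pheno = pd.read_csv(args.cohort / "phenotypes.tsv", sep="\t")
    tolerant, nontolerant = select_extremes(pheno, high_threshold=9.5, low_threshold=0.7)
    cfg = ScreenConfig(tuple(tolerant), tuple(nontolerant), k_deletion=args.k_deletion)

    var = variable_genes(matrix, cfg)
    red = redundant_genes(matrix, cfg)
    report = screen_report(var, red, matrix, cfg)
    report.to_csv(args.results / "screen_report.tsv", sep="\t", index=False)

    print(f"variable genes (tolerant-core, deleted in >= {args.k_deletion} non-tolerant): {len(var)}")
    print(f"redundant genes (non-tolerant-core, deleted in >= {args.k_deletion} tolerant): {len(red)}")
    if len(report) >= 2:
        sub = matrix.loc[var + red, list(cfg.tolerant_strains) + list(cfg.nontolerant_strains)]
        hc = hierarchical_cluster(sub, metric="euclidean", linkage="complete")
        (args.results / "screen_dendrogram.nwk").write_text(hc.newick + "\n")
        print(f"heatmap row order: {' '.join(hc.leaf_order)}")
    print(report[["screen", "group", "mean_copy_tolerant", "mean_copy_nontolerant"]].to_string(index=False))


if __name__ == "__main__":
    main()
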