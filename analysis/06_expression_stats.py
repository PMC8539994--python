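#!/usr/bin/env python
"""Relative expression of candidate genes (2^-ddCt).

Computes fold-changes per strain x gene from the qPCR Ct table (target gene
normalised to the reference gene, bile-treated vs control, replicates
averaged before differencing) and compares them with the generator's
configured true fold-changes.  Writes results/expression_fold_changes.tsv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from pantrait.stats import ddct_expression

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    ct = pd.read_csv(args.cohort / "ct_table.tsv", sep="\t")
    truth = json.loads((args.cohort / "truth.json").read_text())
    configured = truth.get("phenotype_params", {}).get("fold_changes", {})

    rows = []
    for (strain, gene), sub in ct.groupby(["strain", "gene"]):
        fc = ddct_expression(sub)
        rows.append(
            {"strain": strain, "gene": gene, "fold_change": fc,
             "configured": configured.get(gene, float("nan"))}
        )
    out = pd.DataFrame(rows)
    out.to_csv(args.results / "expression_fold_changes.tsv", sep="\t", index=False)
    print(out.to_string(index=False, float_format=lambda x: f"{x:.3f}"))


if __name__ == "__main__":
    main()
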