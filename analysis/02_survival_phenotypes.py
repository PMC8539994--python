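#!/usr/bin/env python
"""Survival rates and the tolerant / non-tolerant split.

Reads the phenotype table from results/cohort/, selects the extreme groups at
the 9.5% / 0.7% survival thresholds, and tests whether survival varies with
isolation region (one-way ANOVA and Kruskal-Wallis, region level and
China-part level).  Writes results/survival_groups.tsv and prints the tests.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from pantrait.stats import region_tests, select_extremes

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    pheno = pd.read_csv(args.cohort / "phenotypes.tsv", sep="\t")
    tolerant, nontolerant = select_extremes(pheno, high_threshold=9.5, low_threshold=0.7)
    pheno["group"] = pheno["strain"].map(
        lambda s: "tolerant" if s in tolerant else ("non-tolerant" if s in nontolerant else "middle")
    )
    args.out.mkdir(parents=True, exist_ok=True)
    pheno.sort_values("survival_rate", ascending=False).to_csv(
        args.out / "survival_groups.tsv", sep="\t", index=False
    )

    print(f"tolerant (> 9.5%): {tolerant}")
    print(f"non-tolerant (<= 0.7%): {nontolerant}")
    print(f"max survival: {pheno.survival_rate.max():.2f}%  min: {pheno.survival_rate.min():.2f}%")
    tests = {
        "region": region_tests(pheno, "region"),
        "china_part": region_tests(pheno, "china_part"),
    }
    (args.out / "region_tests.json").write_text(json.dumps(tests, indent=1))
    for level, res in tests.items():
        print(
            f"{level}: ANOVA F={res['F']:.2f} p={res['anova_p']:.4f}; "
            f"KW H={res['H']:.2f} p={res['kruskal_p']:.4f} (alpha 0.10)"
        )


if __name__ == "__main__":
    main()
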