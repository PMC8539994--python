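"""Seeded synthetic pan-genome cohorts with planted, recoverable signal.

The generator emulates the statistical structure the downstream screens
assume: a cohort of strain proteomes split into a bile-salt *tolerant* and a
*non-tolerant* group (study shape: 8 vs 6), sharing

* a universal single-copy core,
* accessory families scattered independently across strains,
* planted **variable** families: tolerant-core genes deleted in at least
  ``k_deletion`` non-tolerant strains (the tolerance-candidate pattern),
* planted **redundant** families: non-tolerant-core genes at strictly lower
  copy (including 0 in >= ``k_deletion`` strains) in the tolerant group,
* three divergent BSH families seeded from the reference proteins.

Ortholog divergence is substitution-only: every copy of a family is an
independently mutated copy of the family's ancestral sequence, so family
membership is unambiguous in the ground-truth ledger.  Accessory presence is
resampled away from the two planted patterns so that a null cohort stays null
for the screens.

Everything is driven by one integer seed; identical configuration and seed
reproduce byte-identical FASTA, tables and ledger.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from pantrait.bsh import BshReference, SUBTYPES
from pantrait.proteomes import AMINO_ACIDS, StrainProteome, validate_protein, write_proteome_fasta

_AA = np.array(list(AMINO_ACIDS))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA[rng.integers(0, 20, size=length)])


def synthetic_bsh_references(length: int = 316) -> tuple[BshReference, ...]:
    """Three synthetic BSH subtype reference proteins (A, B, C).

    These are constructed stand-ins for the three *L. johnsonii* PF01 BSH
    homologs used as subtype anchors, generated from a fixed internal seed so
    they are stable across runs; they are not database sequences.  Mutual
    identity between subtypes is at the random-background level, so subtype
    assignment by best hit is unambiguous.
    """
    rng = np.random.default_rng(20380927)
    refs = []
    for subtype, acc in zip(SUBTYPES, ("BSHA-REF-SYN", "BSHB-REF-SYN", "BSHC-REF-SYN")):
        refs.append(BshReference(subtype, acc, _random_protein(rng, length)))
    return tuple(refs)


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``rate``.

    A substituted site changes to a uniformly chosen *different* residue, so
    ``rate`` is exactly the expected fraction of changed sites.  Length is
    preserved (no indels).
    """
    seq = validate_protein(seq)
    if not (0 <= rate < 0.5):
        raise ValueError("rate must be in [0, 0.5)")
    if rate == 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        idx = np.nonzero(hit)[0]
        # draw a uniform residue among the 19 alternatives at each hit site
        cur = np.searchsorted(_AA, arr[idx])
        offsets = rng.integers(1, 20, size=len(idx))
        arr[idx] = _AA[(cur + offsets) % 20]
    return "".join(arr)


@dataclass(frozen=True)
class SynthConfig:
    """Cohort shape and evolutionary parameters of the synthetic generator.

    Defaults mirror the study cohort: 8 tolerant / 6 non-tolerant strains,
    15 planted variable families, 7 planted redundant families, deletions
    called at ``k_deletion = 2``.
    """

    n_tolerant: int = 8
    n_nontolerant: int = 6
    n_core: int = 40
    n_accessory: int = 20
    n_variable_planted: int = 15
    n_redundant_planted: int = 7
    k_deletion: int = 2
    mutation_rate: float = 0.05
    protein_length_range: tuple[int, int] = (100, 300)
    accessory_presence_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_tolerant, self.n_nontolerant, self.n_core, self.n_accessory,
            self.n_variable_planted, self.n_redundant_planted,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_tolerant < 1 or self.n_nontolerant < 1:
            raise ValueError("both strain groups must be non-empty")
        if not (0 <= self.mutation_rate < 0.5):
            raise ValueError("mutation_rate must be in [0, 0.5)")
        if not (1 <= self.k_deletion <= self.n_nontolerant):
            raise ValueError("require 1 <= k_deletion <= n_nontolerant")
        if self.n_redundant_planted > 0 and self.k_deletion > self.n_tolerant:
            raise ValueError("k_deletion exceeds n_tolerant: redundant pattern impossible")
        lo, hi = self.protein_length_range
        if not (10 <= lo <= hi):
            raise ValueError("protein_length_range must satisfy 10 <= min <= max")
        if not (0 <= self.accessory_presence_prob <= 1):
            raise ValueError("accessory_presence_prob must be a probability")

    @property
    def strains_tolerant(self) -> tuple[str, ...]:
        return tuple(f"TOL{i + 1:02d}" for i in range(self.n_tolerant))

    @property
    def strains_nontolerant(self) -> tuple[str, ...]:
        return tuple(f"NTL{i + 1:02d}" for i in range(self.n_nontolerant))

    @property
    def strains(self) -> tuple[str, ...]:
        return self.strains_tolerant + self.strains_nontolerant


@dataclass
class PlantedTruth:
    """Ground-truth ledger of what the generator planted, for recovery tests."""

    tolerant_strains: list[str]
    nontolerant_strains: list[str]
    #: family -> strain -> planted copy count, for every family in the cohort
    family_copies: dict[str, dict[str, int]]
    variable_gene_families: list[str]
    redundant_gene_families: list[str]
    #: strain -> subtype -> planted BSH gene count
    bsh_assignments: dict[str, dict[str, int]]
    phenotype_params: dict = field(default_factory=dict)

    @property
    def strains(self) -> list[str]:
        return self.tolerant_strains + self.nontolerant_strains

    def total_genes(self) -> int:
        return sum(sum(row.values()) for row in self.family_copies.values())

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _deconfound_accessory(presence: np.ndarray, n_tol: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Rewrite an accessory presence vector that mimics a planted pattern.

    If the vector happens to be core in one group with >= k absences in the
    other, absences are filled in (presence added) until only k-1 remain; a
    gene present everywhere matches neither screen.  Adding presence can never
    create the mirror pattern, so one pass suffices.
    """
    tol, non = presence[:n_tol], presence[n_tol:]
    if tol.all() and (non == 0).sum() >= k:
        zeros = np.nonzero(non == 0)[0]
        fill = rng.permutation(zeros)[: len(zeros) - (k - 1)]
        non[fill] = 1
    elif non.all() and (tol == 0).sum() >= k:
        zeros = np.nonzero(tol == 0)[0]
        fill = rng.permutation(zeros)[: len(zeros) - (k - 1)]
        tol[fill] = 1
    return np.concatenate([tol, non])


def _bsh_copy_plan(cfg: SynthConfig, rng: np.random.Generator) -> dict[str, dict[str, int]]:
    """Per-strain copy counts of the three BSH families.

    Emulates the cohort pattern of the study: nearly all strains carry BSHA
    and BSHB, a minority carries all three subtypes, an occasional strain has
    a double BSHB gene or lacks BSHB altogether.  Placement is constrained so
    BSH families can never satisfy either screen pattern (each subtype is
    missing in fewer than ``k_deletion`` strains of a group, or missing in
    both groups).
    """
    strains = cfg.strains
    n = len(strains)
    plan = {s: {"A": 1, "B": 1, "C": 0} for s in strains}
    if n >= 4 and cfg.k_deletion >= 2:
        drop_b = strains[rng.integers(0, n)]
        plan[drop_b]["B"] = 0
        candidates = [s for s in strains if s != drop_b]
        for s in rng.choice(candidates, size=min(2, len(candidates)), replace=False):
            plan[s]["B"] = 2
    if cfg.n_tolerant >= 3 and cfg.n_nontolerant >= 2:
        # C carriers leave >= 1 strain of each group without C
        tol_c = rng.choice(cfg.strains_tolerant, size=min(2, cfg.n_tolerant - 1), replace=False)
        non_c = rng.choice(cfg.strains_nontolerant, size=1, replace=False)
        for s in list(tol_c) + list(non_c):
            plan[s]["C"] = 1
    return plan


def generate_pangenome(cfg: SynthConfig) -> tuple[list[StrainProteome], PlantedTruth]:
    """Generate the cohort's strain proteomes and the planted-truth ledger.

    Gene identifiers encode ``strain|family|copy`` for audit purposes only;
    the pipeline never parses them.
    """
    rng = np.random.default_rng(cfg.seed)
    tol, non = cfg.strains_tolerant, cfg.strains_nontolerant
    strains = cfg.strains
    n_tol, n_non = len(tol), len(non)
    lo, hi = cfg.protein_length_range

    families: list[str] = []
    ancestors: dict[str, str] = {}

    def new_family(name: str, seq: str | None = None) -> None:
        families.append(name)
        ancestors[name] = seq if seq is not None else _random_protein(
            rng, int(rng.integers(lo, hi + 1))
        )

    for i in range(cfg.n_core):
        new_family(f"CORE{i + 1:04d}")
    for i in range(cfg.n_accessory):
        new_family(f"ACC{i + 1:04d}")
    for i in range(cfg.n_variable_planted):
        new_family(f"VAR{i + 1:04d}")
    for i in range(cfg.n_redundant_planted):
        new_family(f"RED{i + 1:04d}")
    refs = synthetic_bsh_references()
    for ref in refs:
        new_family(f"BSH{ref.subtype}", ref.sequence)

    copies: dict[str, dict[str, int]] = {}
    for fam in families:
        if fam.startswith("CORE"):
            copies[fam] = {s: 1 for s in strains}
        elif fam.startswith("ACC"):
            presence = (rng.random(len(strains)) < cfg.accessory_presence_prob).astype(int)
            presence = _deconfound_accessory(presence, n_tol, cfg.k_deletion, rng)
            copies[fam] = {s: int(c) for s, c in zip(strains, presence)}
        elif fam.startswith("VAR"):
            n_missing = int(rng.integers(cfg.k_deletion, n_non + 1))
            missing = set(rng.choice(non, size=n_missing, replace=False))
            copies[fam] = {s: 1 for s in tol}
            copies[fam].update({s: 0 if s in missing else 1 for s in non})
        elif fam.startswith("RED"):
            n_missing = int(rng.integers(cfg.k_deletion, n_tol + 1))
            missing = set(rng.choice(tol, size=n_missing, replace=False))
            copies[fam] = {s: 2 for s in non}
            copies[fam].update({s: 0 if s in missing else 1 for s in tol})
        # BSH plan drawn as a block below to keep rng consumption ordered

    bsh_plan = _bsh_copy_plan(cfg, rng)
    for subtype in SUBTYPES:
        copies[f"BSH{subtype}"] = {s: bsh_plan[s][subtype] for s in strains}

    proteomes = []
    for s in strains:
        prot = StrainProteome(s)
        for fam in families:
            for c in range(copies[fam][s]):
                prot.add(f"{s}|{fam}|{c + 1}", mutate_sequence(ancestors[fam], cfg.mutation_rate, rng))
        proteomes.append(prot)

    truth = PlantedTruth(
        tolerant_strains=list(tol),
        nontolerant_strains=list(non),
        family_copies=copies,
        variable_gene_families=[f for f in families if f.startswith("VAR")],
        redundant_gene_families=[f for f in families if f.startswith("RED")],
        bsh_assignments={s: dict(bsh_plan[s]) for s in strains},
    )
    audit_planted(proteomes, truth, cfg)
    return proteomes, truth


def audit_planted(proteomes: Sequence[StrainProteome], truth: PlantedTruth, cfg: SynthConfig) -> None:
    """Verify the ledger invariants against the emitted proteomes.

    Raises AssertionError if conservation or any planted pattern is violated;
    runs automatically at the end of generation.
    """
    total = sum(len(p) for p in proteomes)
    assert total == truth.total_genes(), "gene count does not match ledger copy sums"
    planted = set(truth.variable_gene_families) | set(truth.redundant_gene_families)
    for fam in planted:
        assert sum(truth.family_copies[fam].values()) > 0, f"planted family {fam} never emitted"
    for fam in truth.variable_gene_families:
        row = truth.family_copies[fam]
        assert all(row[s] >= 1 for s in truth.tolerant_strains), f"{fam} not tolerant-core"
        n_missing = sum(row[s] == 0 for s in truth.nontolerant_strains)
        assert n_missing >= cfg.k_deletion, f"{fam} missing in only {n_missing} non-tolerant strains"
    for fam in truth.redundant_gene_families:
        row = truth.family_copies[fam]
        assert all(row[s] >= 1 for s in truth.nontolerant_strains), f"{fam} not non-tolerant-core"
        n_missing = sum(row[s] == 0 for s in truth.tolerant_strains)
        assert n_missing >= cfg.k_deletion, f"{fam} missing in only {n_missing} tolerant strains"
        min_non = min(row[s] for s in truth.nontolerant_strains)
        n_reduced = sum(row[s] < min_non for s in truth.tolerant_strains)
        assert n_reduced >= cfg.k_deletion, f"{fam} not copy-reduced in tolerant strains"


DEFAULT_HIGH_RANGE = (9.6, 17.8)
DEFAULT_LOW_RANGE = (0.02, 0.7)
DEFAULT_FOLD_CHANGES = (4.0, 2.0, 8.0, 0.5)

_REGIONS_HIGH = ("Guangdong", "Gansu", "Anhui", "Jiangsu")
_REGIONS_LOW = ("Fujian", "Chongqing", "Yunnan", "Zhejiang")
_CHINA_PART = {
    "Guangdong": "South", "Gansu": "Northwest", "Anhui": "East", "Jiangsu": "East",
    "Fujian": "East", "Chongqing": "Southwest", "Yunnan": "Southwest", "Zhejiang": "East",
}


def generate_phenotypes(
    truth: PlantedTruth,
    cfg: SynthConfig,
    rng: np.random.Generator | int | None = None,
    high_range: tuple[float, float] = DEFAULT_HIGH_RANGE,
    low_range: tuple[float, float] = DEFAULT_LOW_RANGE,
    fold_changes: dict[str, float] | None = None,
    ct_noise_sd: float = 0.1,
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CFU phenotype table and qPCR Ct table for the synthetic cohort.

    Survival rates are drawn uniformly inside the group ranges (defaults
    bracket the study's observed extremes: tolerant above the 9.5% threshold
    up to ~17.8%, non-tolerant between 0.02% and the 0.7% threshold), so group
    membership is guaranteed by construction.  Ct triplicates are drawn with
    Gaussian noise (sd ``ct_noise_sd`` cycles) around the configured true
    fold-changes for one top tolerant and one bottom non-tolerant strain,
    with a constant-Ct reference gene.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1_000_003)
    elif isinstance(rng, int):
        rng = np.random.default_rng(rng)
    if high_range[0] <= low_range[1]:
        raise ValueError("high survival range must lie strictly above the low range")

    rows = []
    for i, s in enumerate(truth.tolerant_strains):
        rate = rng.uniform(*high_range)
        region = _REGIONS_HIGH[i % len(_REGIONS_HIGH)]
        rows.append((s, region, rate))
    for i, s in enumerate(truth.nontolerant_strains):
        rate = rng.uniform(*low_range)
        region = _REGIONS_LOW[i % len(_REGIONS_LOW)]
        rows.append((s, region, rate))
    pheno = []
    for s, region, rate in rows:
        cfu_before = 10 ** rng.normal(8.0, 0.15)
        cfu_after = cfu_before * rate / 100.0
        pheno.append(
            {
                "strain": s,
                "region": region,
                "china_part": _CHINA_PART[region],
                "cfu_before": cfu_before,
                "cfu_after": cfu_after,
                "survival_rate": 100.0 * cfu_after / cfu_before,
            }
        )
    pheno_df = pd.DataFrame(pheno)

    if fold_changes is None:
        targets = truth.variable_gene_families[: len(DEFAULT_FOLD_CHANGES)]
        fold_changes = {g: fc for g, fc in zip(targets, DEFAULT_FOLD_CHANGES)}
    ct_rows = []
    assay_strains = []
    if truth.tolerant_strains:
        assay_strains.append(truth.tolerant_strains[0])
    if truth.nontolerant_strains:
        assay_strains.append(truth.nontolerant_strains[0])
    for s in assay_strains:
        for gene, fc in fold_changes.items():
            base_target, base_ref = 24.0, 16.0
            for condition, target_mean in (
                ("control", base_target),
                ("treated", base_target - math.log2(fc)),
            ):
                for rep in range(1, n_replicates + 1):
                    ct_rows.append(
                        {
                            "strain": s,
                            "gene": gene,
                            "condition": condition,
                            "replicate": rep,
                            "ct_target": target_mean + rng.normal(0.0, ct_noise_sd),
                            "ct_reference": base_ref + rng.normal(0.0, ct_noise_sd),
                        }
                    )
    ct_df = pd.DataFrame(
        ct_rows,
        columns=["strain", "gene", "condition", "replicate", "ct_target", "ct_reference"],
    )
    truth.phenotype_params = {
        "high_range": list(high_range),
        "low_range": list(low_range),
        "fold_changes": dict(fold_changes),
        "ct_noise_sd": ct_noise_sd,
        "n_replicates": n_replicates,
    }
    return pheno_df, ct_df


def write_cohort(
    out_dir: str | Path,
    proteomes: Sequence[StrainProteome],
    truth: PlantedTruth,
    phenotypes: pd.DataFrame,
    ct_table: pd.DataFrame,
    refs: Sequence[BshReference] | None = None,
) -> dict[str, Path]:
    """Write a full synthetic cohort to disk (FASTAs, TSVs, truth JSON)."""
    out_dir = Path(out_dir)
    proteome_dir = out_dir / "proteomes"
    proteome_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for prot in proteomes:
        p = proteome_dir / f"{prot.strain_id}.faa"
        write_proteome_fasta(prot, p)
        paths[prot.strain_id] = p
    phenotypes.to_csv(out_dir / "phenotypes.tsv", sep="\t", index=False)
    ct_table.to_csv(out_dir / "ct_table.tsv", sep="\t", index=False)
    truth.to_json(out_dir / "truth.json")
    if refs is None:
        refs = synthetic_bsh_references()
    with open(out_dir / "bsh_references.faa", "w") as fh:
        for ref in refs:
            fh.write(f">{ref.accession} subtype={ref.subtype}\n{ref.sequence}\n")
    paths.update(
        phenotypes=out_dir / "phenotypes.tsv",
        ct_table=out_dir / "ct_table.tsv",
        truth=out_dir / "truth.json",
        references=out_dir / "bsh_references.faa",
        proteome_dir=proteome_dir,
    )
    return paths
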