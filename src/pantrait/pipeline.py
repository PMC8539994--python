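"""End-to-end orchestration: proteomes + phenotypes in, screened candidates out.

Stage order mirrors the study design: survival phenotypes split the cohort
into tolerant / non-tolerant extremes; all-vs-all alignment and Markov
clustering build the ortholog copy-number matrix; the presence/absence
screens call variable and redundant genes; BSH typing and NJ trees
characterise the hydrolase families; region and expression statistics close
the loop.  Every stage writes its table under the output directory and the
run report records seeds, parameters and file checksums so a rerun with the
same configuration is byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import pandas as pd
import yaml

from pantrait import align, bsh, cluster, phylo, screen, stats, synth
from pantrait.proteomes import StrainProteome, gene_strain_map, read_proteome_fasta


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    Thresholds default to the study values: survival-rate split at 9.5% /
    0.7%, deletions called at k = 2, BSH typing at e < 3.24e-18, ortholog
    edges at e <= 1e-5, MCL inflation 1.5.
    """

    proteome_dir: str = ""
    phenotype_table: str = ""
    ct_table: str = ""
    reference_fasta: str = ""
    out_dir: str = "pantrait_out"
    scoring: align.ScoringParams = field(default_factory=align.ScoringParams)
    kmer: int = 5
    search_max_evalue: float = 10.0
    edge_max_evalue: float = 1e-5
    edge_min_identity: float = 0.0
    inflation: float = 1.5
    k_deletion: int = 2
    high_threshold: float = 9.5
    low_threshold: float = 0.7
    bsh_e_threshold: float = bsh.DEFAULT_E_THRESHOLD
    tree_cut_height: float = 0.15
    region_alpha: float = 0.10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scoring = align.ScoringParams(**raw.pop("scoring", {}))
        return cls(scoring=scoring, **raw)

    def validate_paths(self) -> None:
        for label, p in (
            ("proteome_dir", self.proteome_dir),
            ("phenotype_table", self.phenotype_table),
            ("reference_fasta", self.reference_fasta),
        ):
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{label} does not exist: {p!r}")
        if self.ct_table and not Path(self.ct_table).exists():
            raise FileNotFoundError(f"ct_table does not exist: {self.ct_table!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_proteomes(proteome_dir: str | Path) -> list[StrainProteome]:
    paths = sorted(Path(proteome_dir).glob("*.faa")) + sorted(Path(proteome_dir).glob("*.fasta"))
    if not paths:
        raise FileNotFoundError(f"no FASTA files under {proteome_dir}")
    return [read_proteome_fasta(p) for p in paths]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns the report dict (also written as report.json)."""
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": [], "files": {}}

    def stage(name):
        def wrap(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                report["stages"].append({"name": name, "status": "failed"})
                (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
                raise PipelineError(name, exc) from exc
            report["stages"].append({"name": name, "status": "ok"})
            return result
        return wrap

    proteomes = stage("load_proteomes")(lambda: load_proteomes(cfg.proteome_dir))
    phenotypes = stage("load_phenotypes")(
        lambda: pd.read_csv(cfg.phenotype_table, sep="\t")
    )

    def split():
        tol, non = stats.select_extremes(
            phenotypes, high_threshold=cfg.high_threshold, low_threshold=cfg.low_threshold
        )
        if not tol or not non:
            raise ValueError("survival thresholds produced an empty extreme group")
        return tol, non

    tolerant, nontolerant = stage("select_extremes")(split)

    def search():
        hits = align.all_vs_all(proteomes, cfg.scoring, kmer=cfg.kmer, max_evalue=cfg.search_max_evalue)
        align.write_hit_table(hits, out / "hits.tsv")
        return hits

    hits = stage("all_vs_all")(search)

    def do_cluster():
        g = cluster.build_graph(hits, cfg.edge_max_evalue, cfg.edge_min_identity)
        clusters = cluster.mcl(g, inflation=cfg.inflation)
        partition = cluster.partition_to_frame(clusters)
        partition.to_csv(out / "ortholog_groups.tsv", sep="\t", index=False)
        matrix = cluster.copy_number_matrix(
            partition, [p.strain_id for p in proteomes], gene_strain_map(proteomes)
        )
        matrix.to_csv(out / "copy_number_matrix.tsv", sep="\t")
        return partition, matrix

    partition, matrix = stage("ortholog_clustering")(do_cluster)

    def do_screen():
        scr_cfg = screen.ScreenConfig(
            tuple(tolerant), tuple(nontolerant),
            k_deletion=cfg.k_deletion,
            high_threshold=cfg.high_threshold, low_threshold=cfg.low_threshold,
        )
        var = screen.variable_genes(matrix, scr_cfg)
        red = screen.redundant_genes(matrix, scr_cfg)
        rep = screen.screen_report(var, red, matrix, scr_cfg)
        rep.to_csv(out / "screen_report.tsv", sep="\t", index=False)
        if len(rep) >= 2:
            sub = matrix.loc[var + red, list(scr_cfg.tolerant_strains) + list(scr_cfg.nontolerant_strains)]
            hc = screen.hierarchical_cluster(sub)
            (out / "screen_dendrogram.nwk").write_text(hc.newick + "\n")
        return var, red

    variable, redundant = stage("trait_screen")(do_screen)

    refs = stage("load_references")(lambda: bsh.read_reference_fasta(cfg.reference_fasta))

    def do_bsh():
        profiles = [
            bsh.strain_bsh_profile(p, refs, cfg.scoring, cfg.bsh_e_threshold) for p in proteomes
        ]
        table, tallies = bsh.cohort_bsh_summary(profiles)
        table.to_csv(out / "bsh_profiles.tsv", sep="\t", index=False)
        return profiles, tallies

    profiles, bsh_tallies = stage("bsh_typing")(do_bsh)

    def do_trees():
        gene_seqs = {p.strain_id: dict(p.genes) for p in proteomes}
        tree_files = {}
        groups_rows = []
        for ref in sorted(refs, key=lambda r: r.subtype):
            seqs = {f"{ref.accession}": ref.sequence}
            for prof in profiles:
                for gene_id, subtype in prof.assignments.items():
                    if subtype == ref.subtype:
                        seqs[gene_id] = gene_seqs[prof.strain_id][gene_id]
            if len(seqs) < 3:
                continue
            dm = phylo.pairwise_distance(seqs, model="p", params=cfg.scoring)
            phylo.write_phylip(dm, out / f"bsh_{ref.subtype}_distances.phy")
            tree = phylo.neighbor_joining(dm)
            rooted, newick = phylo.root_with_outgroup(tree, ref.accession)
            path = out / f"bsh_{ref.subtype}_nj.nwk"
            path.write_text(newick + "\n")
            tree_files[ref.subtype] = str(path)
            for leaf, grp in sorted(phylo.cut_groups(rooted, cfg.tree_cut_height).items()):
                groups_rows.append({"subtype": ref.subtype, "gene": leaf, "tree_group": grp})
        pd.DataFrame(groups_rows).to_csv(out / "bsh_tree_groups.tsv", sep="\t", index=False)
        return tree_files

    tree_files = stage("phylogeny")(do_trees)

    def do_stats():
        res = {"region": stats.region_tests(phenotypes, "region")}
        if "china_part" in phenotypes.columns:
            res["china_part"] = stats.region_tests(phenotypes, "china_part")
        res["region"]["significant"] = bool(res["region"]["anova_p"] < cfg.region_alpha)
        expression = []
        if cfg.ct_table:
            ct = pd.read_csv(cfg.ct_table, sep="\t")
            for (s, gene), sub in ct.groupby(["strain", "gene"]):
                expression.append(
                    {"strain": s, "gene": gene, "fold_change": stats.ddct_expression(sub)}
                )
        expr_df = pd.DataFrame(expression, columns=["strain", "gene", "fold_change"])
        expr_df.to_csv(out / "expression_fold_changes.tsv", sep="\t", index=False)
        return res, expression

    stat_res, expression = stage("phenotype_stats")(do_stats)

    report.update(
        {
            "config": {
                **{k: v for k, v in asdict(cfg).items() if k != "scoring"},
                "scoring": asdict(cfg.scoring),
            },
            "n_strains": len(proteomes),
            "tolerant_strains": tolerant,
            "nontolerant_strains": nontolerant,
            "n_ortholog_groups": int(matrix.shape[0]),
            "variable_genes": list(variable),
            "redundant_genes": list(redundant),
            "bsh_pattern_tallies": bsh_tallies,
            "bsh_trees": tree_files,
            "stats": stat_res,
            "expression": expression,
        }
    )
    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "report.json":
            report["files"][p.name] = _sha256(p)
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str, sort_keys=True))
    return report


def run_synthetic_study(
    synth_cfg: synth.SynthConfig,
    out_dir: str | Path,
    pipeline_cfg: PipelineConfig | None = None,
) -> tuple[dict, synth.PlantedTruth]:
    """Generate a synthetic cohort, run the full pipeline on it, return report + truth."""
    out_dir = Path(out_dir)
    cohort_dir = out_dir / "cohort"
    proteomes, truth = synth.generate_pangenome(synth_cfg)
    phenotypes, ct = synth.generate_phenotypes(truth, synth_cfg)
    paths = synth.write_cohort(cohort_dir, proteomes, truth, phenotypes, ct)
    cfg = pipeline_cfg or PipelineConfig()
    cfg.proteome_dir = str(paths["proteome_dir"])
    cfg.phenotype_table = str(paths["phenotypes"])
    cfg.ct_table = str(paths["ct_table"])
    cfg.reference_fasta = str(paths["references"])
    cfg.out_dir = str(out_dir / "results")
    cfg.k_deletion = synth_cfg.k_deletion
    cfg.seed = synth_cfg.seed
    report = run_pipeline(cfg)
    return report, truth
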