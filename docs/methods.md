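# Methods

`pantrait` implements a comparative pan-genomics screen for genes associated
with a binary strain phenotype — here, survival in 0.3% bile salt — in a
bacterial species cohort, together with the side analyses used to
characterise and verify candidates: bile salt hydrolase (BSH) subtype typing,
distance-based phylogenetics, and qPCR expression statistics. This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic validation does and does not establish.

## The screening model

The screen works on an ortholog-group × strain **copy-number matrix** `M`,
where `M[g, s]` counts how many genes of strain `s` fall in ortholog group
`g`. Given a split of the cohort into a tolerant set `T` and a non-tolerant
set `N` (by survival rate), two mirrored rules are applied:

- **Variable genes** (tolerance candidates): groups with `M[g, s] >= 1` for
  every `s` in `T` (tolerant-core) and `M[g, s] = 0` in at least `k` strains
  of `N`. Default `k = 2`.
- **Redundant genes** (dispensable under tolerance): groups core in `N` with
  copy 0 in at least `k` strains of `T`. Mean per-group copy numbers in each
  class are reported alongside, so reduced-but-nonzero patterns remain
  visible even though the *selection* rule is strict absence. "Deleted"
  means copy number zero, not reduced copy.

Candidates are ordered by the number of strains missing the gene
(descending), then by group id, which makes reports deterministic in the
absence of genome coordinates.

### Cohort split

`select_extremes` supports threshold mode (survival rate ≥ 9.5% vs ≤ 0.7%,
the defaults) and count mode (top `n` / bottom `m`). The returned groups must
be strictly separated in survival rate; ties at a group boundary are an
error rather than silently resolved.

## Ortholog groups

1. **All-vs-all search.** Smith–Waterman local alignment with affine gaps
   under BLOSUM62 (gap open 11, extend 1; a gap of length L costs
   `11 + L`). The DP engine is Biopython's C `PairwiseAligner`; an
   independent brute-force Gotoh implementation exists only in the test
   suite as an oracle. Statistical significance uses the Karlin–Altschul
   formula `E = K·m·n·exp(−λS)` with the standard gapped-BLAST constants
   λ = 0.267, K = 0.041, `m` the query length and `n` the summed database
   length; `bit = (λS − ln K)/ln 2`. An exact k-mer prefilter (default word
   length 5) limits the quadratic search: two sequences are aligned only if
   they share a word. At word length 5 orthologs up to ~20% pairwise
   divergence essentially always share a word (property-tested), while
   unrelated proteins rarely do. Hits are reported up to E ≤ 10 (the
   conventional reporting threshold); pass `max_evalue=None` to keep every
   positive-scoring pair.
2. **Similarity graph.** An edge joins two genes only if hits exist in
   *both* directions, each with E ≤ 1e−5 (and optionally a minimum identity).
   The weight is the mean of the two directions' −log10 E, capped at 300
   (the −log10 of the smallest positive double) for E = 0. Reciprocity makes
   the graph symmetric by construction.
3. **Markov clustering.** Column-normalised adjacency with unit self-loops;
   iterate expansion (matrix square) and inflation (elementwise power
   1.5, renormalise), pruning entries below 1e−6, until stationary
   (max 100 iterations, with a warning on non-convergence). Clusters are the
   connected sets of the converged flow's nonzero structure. Because MCL
   flow cannot cross a connected-component boundary, each component is
   clustered independently — mathematically identical and much cheaper.
   Genes with no edges become singleton groups and still appear in the
   matrix, so column sums always equal proteome sizes.

Inflation 1.5 follows the common ortholog-clustering default. The full
species-pair normalisation of OrthoMCL-style pipelines is deliberately
simplified to reciprocal-hit mean −log10(E) weights: in the regime this
package targets (well-separated families), the partition is the same and the
contract is far easier to state and test.

## BSH subtype typing

Each gene is aligned to three labelled subtype reference proteins (A/B/C);
hits with E **strictly below** 3.24e−18 are kept and the gene takes the
subtype of the smallest-E hit (ties: higher bit score, then subtype order
A < B < C; one subtype per gene). Profiles count copies per subtype, and the
cohort summary tallies presence *patterns* (a strain with two B copies still
counts once under "A+B").

The packaged references are **synthetic stand-ins** generated from a fixed
internal seed (`synthetic_bsh_references`): three mutually unrelated ~316-aa
proteins that anchor the three subtypes. They reproduce the geometry the
typing rule needs (within-subtype similarity far above the threshold,
between-subtype similarity at background) without shipping any database
sequence. Analyses of real proteomes should load the real reference FASTA
(`subtype=` tags in headers) instead.

## Phylogenetics

Pairwise distances come from global (Needleman–Wunsch) alignments under the
same scoring parameters: `p` = mismatches / gap-free aligned columns, with an
optional Poisson correction `−ln(1 − p)` (rejected with a clear error at
p = 1). p-distance is the default model. Trees are built with Saitou–Nei
neighbor joining: join the pair minimising
`Q(i,j) = (r−2)·d(i,j) − R_i − R_j`; branch lengths by the standard formulas;
Q-ties resolved toward the lexicographically smallest pair of subtree
labels; negative branch lengths clamped to zero with the deficit moved to
the sibling edge so path lengths are preserved. Outgroup rooting bisects the
outgroup's pendant edge. `cut_groups` partitions leaves into maximal
monophyletic clades whose within-clade leaf-to-leaf path distance does not
exceed a threshold (default 0.15 for the synthetic BSH families) — a
principled grouping rule chosen because published "evolutionary distance
groups" rarely state their criterion; it is a stand-in, not a reproduction
of any particular figure.

## Phenotype and expression statistics

- **Survival rate** = 100 · CFU_after / CFU_before, replicate counts averaged
  before the ratio (mean-first; per-replicate-ratio averaging is the
  alternative the assay literature sometimes uses).
- **2^−ΔΔCt**: per condition, ΔCt = mean(Ct_target) − mean(Ct_reference)
  over replicates; ΔΔCt = ΔCt_treated − ΔCt_control; fold-change = 2^−ΔΔCt.
  Replicates are averaged before differencing, the reference method's
  convention.
- **One-way ANOVA** by explicit sums of squares with df (k−1, N−k);
  degenerate layouts are resolved explicitly (zero between-group variance →
  F = 0, p = 1; zero within-group with nonzero between → F = ∞, p = 0).
- **Kruskal–Wallis** with tie correction (scipy), all-identical data → H = 0,
  p = 1. Region-level analyses use a configurable significance level
  (default 0.05; the region example runs at 0.10). Post hoc pairwise
  procedures are out of scope.

## The synthetic cohort generator

The generator emits a seeded cohort with exactly the structure the screens
assume, plus a ground-truth ledger (`PlantedTruth`) used by every recovery
test. Defaults mirror the study shape:

| parameter | default | meaning |
|---|---|---|
| n_tolerant / n_nontolerant | 8 / 6 | extreme-group sizes |
| n_core | 40 | universal single-copy families |
| n_accessory | 20 | families present per strain with prob 0.5 |
| n_variable_planted | 15 | tolerant-core, deleted in ≥ k non-tolerant |
| n_redundant_planted | 7 | non-tolerant-core (copy 2), reduced/absent in tolerant |
| k_deletion | 2 | minimum missing strains for either pattern |
| mutation_rate | 0.05 | per-site substitution per gene copy from the family ancestor |
| protein_length_range | 100–300 aa | ancestor lengths (uniform) |

Core and accessory counts and sequence lengths are desk-scale choices: large
enough that the screens run on a realistic 85-family, ~1000-gene matrix,
small enough that a 20-seed recovery experiment completes in minutes on one
CPU. Divergence is substitution-only (no indels), so family membership is
unambiguous in the ledger; the alignment engine's indel handling is tested
separately. Each copy is an independent draw from the family ancestor, giving
~10% pairwise divergence within families at the default rate — far inside
the prefilter's and the graph threshold's safe zone.

Two placement constraints keep the null clean. First, an accessory presence
vector that happens to reproduce a planted pattern (core in one group,
absent in ≥ k of the other — probability ≈ 0.4% per family) is
"de-confounded" by filling absences down to k−1; adding presence cannot
create the mirror pattern, so one pass suffices. Second, the three BSH
families are placed so that each subtype is missing from fewer than k strains
of a group or missing from both groups; BSH content therefore never
correlates with the phenotype split, matching the biological conclusion the
screen design presupposes (most strains carry A and B, a minority all three,
occasional double-B or B-less strains).

Phenotypes are drawn uniformly: tolerant survival in (9.6, 17.8)% and
non-tolerant in (0.02, 0.7)%, bracketing the screen thresholds and observed
extremes, so group membership is guaranteed by construction — the assay
model is deliberately simple because no quantitative phenotype model is
available. CFU_before is log-normal around 1e8/mL. Ct tables use a
constant-mean reference gene (16 cycles), a 24-cycle control target, and
Gaussian noise (default sd 0.1 cycles) on every Ct; the true fold-change
enters as a −log2(fc) shift of the treated target mean.

### What passing tests show — and don't

Recovery tests demonstrate that the pipeline's machinery is correct: exact
family recovery, zero false calls under the null, profiles equal to the
ledger. They do **not** show that the screen finds trait genes in real data,
where orthology is blurred by indels, domain shuffling, paralogy and
horizontal transfer, where phenotype groups are noisy, and where deletion
patterns correlate with population structure. The generator also omits
genome coordinates, operon structure and nucleotide-level evolution
entirely.

## Numerical choices and degenerate inputs

- Local alignments with no positive-scoring pair return score 0 with empty
  spans; identity denominators include gap columns (so a 10-residue deletion
  in an otherwise identical 60-column alignment gives identity 50/60).
- Co-optimal alignment ties are broken toward the smallest query start,
  then subject start (scanning up to 16 co-optimal paths — deterministic).
- E-value 0 maps to edge weight 300 in the similarity graph.
- A constant matrix is a valid clustering input (all merges at height 0);
  hierarchical clustering defaults to Euclidean distance with complete
  linkage (the metric is the analysis's stated choice, the linkage ours).
- Two-taxon "trees" are a single edge of length d split across the root;
  three taxa use the closed-form star lengths, clamped at zero.
- Seeds: every stochastic component takes a `numpy` Generator or integer
  seed; identical configuration + seed reproduces byte-identical FASTA,
  tables and report checksums (tested).

## Known limitations

- Protein-only: no nucleotide layer, no six-frame searches; whether the
  original copy-number analyses ran on nucleotide data is unknowable from
  the text, and this package takes the protein reading.
- No composition-based statistics, masking or HSP chaining in the search;
  e-values use fixed Karlin–Altschul constants rather than per-matrix
  estimation.
- No paralog/in-paralog distinction or synteny in ortholog grouping.
- No bootstrap support on trees; no maximum-likelihood models.
- Functional annotation (NR/CDD/COG/KEGG) requires external databases and is
  out of scope; reports identify candidates by group id and copy pattern.
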