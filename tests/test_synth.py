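import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pantrait import ddct_expression
from pantrait.proteomes import write_proteome_fasta
from pantrait.synth import (
    SynthConfig,
    generate_pangenome,
    generate_phenotypes,
    mutate_sequence,
    synthetic_bsh_references,
)

TINY = dict(n_core=6, n_accessory=4, n_variable_planted=3, n_redundant_planted=2,
            protein_length_range=(60, 120))


class TestMutateSequence:
    def test_zero_rate_is_identity(self, rng):
        seq = "MKTAYIAKQRQISFVKSHFSRQ"
        assert mutate_sequence(seq, 0.0, rng) == seq

    def test_substitution_fraction_is_binomial(self):
        # observed changed-site fraction within 3 binomial SDs of the rate
        n, rate, reps = 1000, 0.1, 30
        seq = "".join(np.random.default_rng(0).choice(list("ACDEFGHIKLMNPQRSTVWY"), n))
        changed = []
        for seed in range(reps):
            out = mutate_sequence(seq, rate, np.random.default_rng(seed))
            changed.append(sum(a != b for a, b in zip(seq, out)) / n)
        sd = (rate * (1 - rate) / n) ** 0.5
        mean_sd = sd / reps**0.5
        assert abs(np.mean(changed) - rate) < 3 * mean_sd

    def test_seeded_determinism(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQ" * 3
        a = mutate_sequence(seq, 0.3, np.random.default_rng(9))
        b = mutate_sequence(seq, 0.3, np.random.default_rng(9))
        assert a == b

    def test_length_preserved_and_alphabet_valid(self, rng):
        seq = "MKTAYIAKQRQISFVKSHFSRQ"
        out = mutate_sequence(seq, 0.4, rng)
        assert len(out) == len(seq)
        assert set(out) <= set("ACDEFGHIKLMNPQRSTVWY")

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            mutate_sequence("MKB1", 0.1, rng)
        with pytest.raises(ValueError):
            mutate_sequence("MKT", 0.6, rng)


class TestConfigValidation:
    def test_impossible_k_deletion_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_nontolerant=3, k_deletion=4)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_core=-1)


class TestGeneratePangenome:
    def test_ledger_counts_match_config(self):
        cfg = SynthConfig(**TINY, seed=1)
        _, truth = generate_pangenome(cfg)
        assert len(truth.variable_gene_families) == 3
        assert len(truth.redundant_gene_families) == 2

    def test_gene_conservation(self):
        cfg = SynthConfig(**TINY, seed=2)
        proteomes, truth = generate_pangenome(cfg)
        assert sum(len(p) for p in proteomes) == truth.total_genes()

    def test_core_present_once_everywhere(self):
        cfg = SynthConfig(**TINY, seed=3)
        _, truth = generate_pangenome(cfg)
        core = [f for f in truth.family_copies if f.startswith("CORE")]
        assert all(
            all(c == 1 for c in truth.family_copies[f].values()) for f in core
        )

    def test_planted_variable_pattern(self):
        cfg = SynthConfig(**TINY, seed=4)
        _, truth = generate_pangenome(cfg)
        for fam in truth.variable_gene_families:
            row = truth.family_copies[fam]
            assert all(row[s] >= 1 for s in truth.tolerant_strains)
            assert sum(row[s] == 0 for s in truth.nontolerant_strains) >= cfg.k_deletion

    def test_planted_redundant_pattern(self):
        cfg = SynthConfig(**TINY, seed=5)
        _, truth = generate_pangenome(cfg)
        for fam in truth.redundant_gene_families:
            row = truth.family_copies[fam]
            assert all(row[s] >= 1 for s in truth.nontolerant_strains)
            assert sum(row[s] == 0 for s in truth.tolerant_strains) >= cfg.k_deletion
            # strictly reduced copy in every tolerant strain
            min_non = min(row[s] for s in truth.nontolerant_strains)
            assert all(row[s] < min_non for s in truth.tolerant_strains)

    def test_seeded_determinism_byte_identical_fasta(self):
        cfg = SynthConfig(**TINY, seed=6)
        outputs = []
        for _ in range(2):
            proteomes, _ = generate_pangenome(cfg)
            buf = io.StringIO()
            for p in proteomes:
                for gid, seq in p:
                    buf.write(f">{gid}\n{seq}\n")
            outputs.append(buf.getvalue())
        assert outputs[0] == outputs[1]

    def test_bsh_never_matches_screen_patterns(self):
        for seed in range(5):
            cfg = SynthConfig(**TINY, seed=seed)
            _, truth = generate_pangenome(cfg)
            for subtype in "ABC":
                row = truth.family_copies[f"BSH{subtype}"]
                tol0 = sum(row[s] == 0 for s in truth.tolerant_strains)
                non0 = sum(row[s] == 0 for s in truth.nontolerant_strains)
                core_tol = tol0 == 0
                core_non = non0 == 0
                assert not (core_tol and non0 >= cfg.k_deletion)
                assert not (core_non and tol0 >= cfg.k_deletion)


class TestReferences:
    def test_three_distinct_stable_references(self):
        refs1 = synthetic_bsh_references()
        refs2 = synthetic_bsh_references()
        assert [r.sequence for r in refs1] == [r.sequence for r in refs2]
        assert len({r.sequence for r in refs1}) == 3
        assert sorted(r.subtype for r in refs1) == ["A", "B", "C"]


class TestGeneratePhenotypes:
    def test_group_rates_respect_thresholds(self):
        cfg = SynthConfig(**TINY, seed=7)
        _, truth = generate_pangenome(cfg)
        pheno, _ = generate_phenotypes(truth, cfg)
        rates = pheno.set_index("strain")["survival_rate"]
        assert (rates[truth.tolerant_strains] > 9.5).all()
        assert (rates[truth.nontolerant_strains] <= 0.7).all()

    def test_noise_free_unit_fold_change(self):
        cfg = SynthConfig(**TINY, seed=8)
        _, truth = generate_pangenome(cfg)
        gene = truth.variable_gene_families[0]
        _, ct = generate_phenotypes(truth, cfg, fold_changes={gene: 1.0}, ct_noise_sd=0.0)
        sub = ct[(ct.strain == truth.tolerant_strains[0]) & (ct.gene == gene)]
        assert ddct_expression(sub) == pytest.approx(1.0)

    def test_fold_change_recovery_under_noise(self):
        # configured 4x change, sd 0.1 cycles, 3 replicates: mean recovery within 20%
        cfg = SynthConfig(**TINY, seed=9)
        _, truth = generate_pangenome(cfg)
        gene = truth.variable_gene_families[0]
        recovered = []
        for seed in range(100):
            _, ct = generate_phenotypes(
                truth, cfg, rng=seed, fold_changes={gene: 4.0}, ct_noise_sd=0.1
            )
            sub = ct[(ct.strain == truth.tolerant_strains[0]) & (ct.gene == gene)]
            recovered.append(ddct_expression(sub))
        assert abs(np.mean(recovered) - 4.0) / 4.0 < 0.2

    def test_determinism(self):
        cfg = SynthConfig(**TINY, seed=10)
        _, truth = generate_pangenome(cfg)
        p1, c1 = generate_phenotypes(truth, cfg)
        p2, c2 = generate_phenotypes(truth, cfg)
        assert p1.equals(p2) and c1.equals(c2)
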