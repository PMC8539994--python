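import numpy as np
import pandas as pd
import pytest

from pantrait import all_vs_all, build_graph, copy_number_matrix, mcl
from pantrait.cluster import partition_to_frame
from pantrait.proteomes import gene_strain_map
from pantrait.synth import SynthConfig, generate_pangenome, generate_phenotypes

#: a quick cohort: small core so alignment-heavy fixtures stay cheap
SMALL_CFG = SynthConfig(
    n_core=12, n_accessory=6, n_variable_planted=4, n_redundant_planted=3,
    protein_length_range=(80, 160), seed=11,
)


@pytest.fixture(scope="session")
def small_cohort():
    proteomes, truth = generate_pangenome(SMALL_CFG)
    phenotypes, ct = generate_phenotypes(truth, SMALL_CFG)
    return SMALL_CFG, proteomes, truth, phenotypes, ct


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    """Copy-number matrix + partition from the full align/cluster path."""
    cfg, proteomes, truth, _, _ = small_cohort
    hits = all_vs_all(proteomes)
    clusters = mcl(build_graph(hits))
    partition = partition_to_frame(clusters)
    matrix = copy_number_matrix(
        partition, [p.strain_id for p in proteomes], gene_strain_map(proteomes)
    )
    return matrix, partition


def families_of_groups(partition: pd.DataFrame) -> dict[str, set[str]]:
    """Audit helper: map each ortholog group to the planted families of its members.

    Synthetic gene ids encode strain|family|copy; only tests exploit this.
    """
    fams = partition["gene"].str.split("|").str[1]
    return {g: set(f) for g, f in fams.groupby(partition["group"])}


def recovered_families(groups: list[str], partition: pd.DataFrame) -> set[str]:
    mapping = families_of_groups(partition)
    out: set[str] = set()
    for g in groups:
        out |= mapping[g]
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
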