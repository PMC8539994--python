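"""Strain proteomes: the per-strain protein sets the whole pipeline consumes.

A :class:`StrainProteome` is an ordered mapping of stable gene identifiers to
amino-acid sequences for one strain.  Gene identifiers are opaque strings;
nothing downstream parses them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


def validate_protein(seq: str) -> str:
    """Return *seq* uppercased, rejecting anything outside the 20-letter alphabet."""
    s = seq.upper()
    if not s:
        raise ValueError("empty protein sequence")
    bad = set(s) - _AA_SET
    if bad:
        raise ValueError(f"invalid amino-acid characters: {sorted(bad)}")
    return s


@dataclass
class StrainProteome:
    """All protein sequences of one strain, keyed by gene identifier."""

    strain_id: str
    genes: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.genes.items())

    def add(self, gene_id: str, seq: str) -> None:
        if gene_id in self.genes:
            raise ValueError(f"duplicate gene id {gene_id!r} in strain {self.strain_id}")
        self.genes[gene_id] = validate_protein(seq)

    @property
    def total_residues(self) -> int:
        return sum(len(s) for s in self.genes.values())


def read_proteome_fasta(path: str | Path, strain_id: str | None = None) -> StrainProteome:
    """Read one strain proteome from a protein FASTA file.

    The strain id defaults to the file stem.
    """
    path = Path(path)
    prot = StrainProteome(strain_id or path.stem)
    for rec in SeqIO.parse(str(path), "fasta"):
        prot.add(rec.id, str(rec.seq))
    return prot


def write_proteome_fasta(prot: StrainProteome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene_id, description="")
        for gene_id, seq in prot.genes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def gene_strain_map(proteomes: list[StrainProteome]) -> dict[str, str]:
    """Map every gene id to its strain; gene ids must be cohort-unique."""
    mapping: dict[str, str] = {}
    for prot in proteomes:
        for gene_id in prot.genes:
            if gene_id in mapping:
                raise ValueError(f"gene id {gene_id!r} appears in more than one strain")
            mapping[gene_id] = prot.strain_id
    return mapping
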