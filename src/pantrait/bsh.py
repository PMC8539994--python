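"""Bile salt hydrolase (BSH) subtype typing by best reference hit.

Each gene is locally aligned to three labelled BSH reference proteins
(subtypes A/B/C, in the study design the three *L. johnsonii* PF01 homologs);
hits with e-value strictly below the threshold (default 3.24e-18) are kept and
the gene takes the subtype of its best (smallest e-value) hit.  A gene gets at
most one subtype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from pantrait.align import ScoringParams, smith_waterman
from pantrait.proteomes import StrainProteome, validate_protein

DEFAULT_E_THRESHOLD = 3.24e-18

SUBTYPES = ("A", "B", "C")


@dataclass(frozen=True)
class BshReference:
    subtype: str
    accession: str
    sequence: str


def validate_reference_set(refs: Sequence[BshReference]) -> tuple[BshReference, ...]:
    refs = tuple(refs)
    if len(refs) != 3 or sorted(r.subtype for r in refs) != list(SUBTYPES):
        raise ValueError("reference set must contain exactly one sequence per subtype A, B, C")
    for r in refs:
        validate_protein(r.sequence)
    return refs


def read_reference_fasta(path: str | Path) -> tuple[BshReference, ...]:
    """Read references from FASTA with ``subtype=X`` tags in the headers."""
    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tags = dict(
            part.split("=", 1) for part in rec.description.split() if "=" in part
        )
        if "subtype" not in tags:
            raise ValueError(f"reference record {rec.id!r} lacks a subtype= tag")
        refs.append(BshReference(tags["subtype"], rec.id, str(rec.seq)))
    return validate_reference_set(refs)


@dataclass
class BshProfile:
    """Per-strain BSH content: copy count per subtype and gene-level assignments."""

    strain_id: str
    counts: dict[str, int] = field(default_factory=lambda: {s: 0 for s in SUBTYPES})
    assignments: dict[str, str] = field(default_factory=dict)

    @property
    def present(self) -> tuple[str, ...]:
        return tuple(s for s in SUBTYPES if self.counts[s] > 0)


def assign_subtype(
    gene: str,
    refs: Sequence[BshReference],
    params: ScoringParams = ScoringParams(),
    e_threshold: float = DEFAULT_E_THRESHOLD,
) -> str | None:
    """Subtype of the best reference hit with e-value < threshold, else None.

    The e-value treats the three references as one search database (n = summed
    reference length).  Ties on e-value break by higher bit score, then by
    subtype order A < B < C.
    """
    if e_threshold <= 0:
        raise ValueError("e_threshold must be positive")
    refs = validate_reference_set(refs)
    db_len = sum(len(r.sequence) for r in refs)
    best: tuple[float, float, str] | None = None  # (evalue, -bit, subtype)
    for ref in sorted(refs, key=lambda r: r.subtype):
        aln = smith_waterman(gene, ref.sequence, params, db_length=db_len)
        if aln.evalue < e_threshold:
            key = (aln.evalue, -aln.bit_score, ref.subtype)
            if best is None or key < best:
                best = key
    return best[2] if best else None


def strain_bsh_profile(
    proteome: StrainProteome,
    refs: Sequence[BshReference],
    params: ScoringParams = ScoringParams(),
    e_threshold: float = DEFAULT_E_THRESHOLD,
) -> BshProfile:
    """Type every gene of a strain; tally copy counts per subtype."""
    profile = BshProfile(proteome.strain_id)
    for gene_id, seq in proteome:
        subtype = assign_subtype(seq, refs, params, e_threshold)
        if subtype is not None:
            profile.assignments[gene_id] = subtype
            profile.counts[subtype] += 1
    return profile


def cohort_bsh_summary(profiles: Iterable[BshProfile]) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-strain subtype presence table plus cohort pattern tallies.

    Tallies count presence patterns (e.g. how many strains carry all three
    subtypes, each two-subtype combination, each single subtype); copy numbers
    above 1 still count as presence.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    rows = []
    tallies: dict[str, int] = {}
    for p in profiles:
        rows.append(
            {"strain": p.strain_id, **{f"n_{s}": p.counts[s] for s in SUBTYPES},
             "pattern": "+".join(p.present) if p.present else "none"}
        )
        key = "+".join(p.present) if p.present else "none"
        tallies[key] = tallies.get(key, 0) + 1
    return pd.DataFrame(rows), tallies
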