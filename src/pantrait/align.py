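"""Local protein alignment and e-value statistics: a desk-scale BLAST stand-in.

Pairwise Smith-Waterman local alignment with affine gaps and
substitution-matrix scoring (the DP engine is Biopython's C
``PairwiseAligner``), Karlin-Altschul e-values, and an all-vs-all search over
strain proteomes with an exact k-mer prefilter.

Gap penalty convention follows BLAST: a gap of length L costs
``gap_open + L * gap_extend``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from pantrait.proteomes import StrainProteome, validate_protein

LN2 = math.log(2.0)

#: outfmt-6 style column order used by hit tables.
HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass(frozen=True)
class ScoringParams:
    """Substitution matrix, affine gap penalties and Karlin-Altschul constants.

    Defaults are the standard gapped protein-BLAST parameterisation:
    BLOSUM62 with gap open 11 / extend 1 and (lambda, K) = (0.267, 0.041).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("require gap_open >= gap_extend > 0")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")


@dataclass(frozen=True)
class Alignment:
    """One best local alignment between a query and a subject gene.

    Spans are 1-based inclusive; a score-0 result (no positive-scoring local
    alignment exists) carries empty spans ``(0, 0)``.
    """

    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    evalue: float
    identity: float
    aligned_length: int
    mismatches: int
    gap_opens: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]


@lru_cache(maxsize=8)
def _aligner(params: ScoringParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode=mode)
    aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
    # Biopython charges open_gap_score for the first gapped position, so the
    # BLAST cost open + L*extend maps to open_gap_score = -(open + extend).
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def evalue(raw_score: float, m: int, n: int, params: ScoringParams) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if m <= 0 or n <= 0:
        raise ValueError("sequence/database lengths must be positive")
    return params.K * m * n * math.exp(-params.lam * raw_score)


def bit_score(raw_score: float, params: ScoringParams) -> float:
    """Normalised score S' = (lambda*S - ln K) / ln 2."""
    return (params.lam * raw_score - math.log(params.K)) / LN2


def _alignment_stats(aln, a: str, b: str) -> tuple[int, int, int, int, tuple[int, int], tuple[int, int]]:
    """identities, mismatches, gap opens, aligned length, spans from a path."""
    qblocks, sblocks = aln.aligned
    ident = mism = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        for ca, cb in zip(a[qs:qe], b[ss:se]):
            if ca == cb:
                ident += 1
            else:
                mism += 1
    gap_res = 0
    gap_opens = 0
    for i in range(1, len(qblocks)):
        qgap = qblocks[i][0] - qblocks[i - 1][1]
        sgap = sblocks[i][0] - sblocks[i - 1][1]
        if qgap > 0:
            gap_res += qgap
            gap_opens += 1
        if sgap > 0:
            gap_res += sgap
            gap_opens += 1
    aligned_length = ident + mism + gap_res
    qspan = (int(qblocks[0][0]) + 1, int(qblocks[-1][1]))
    sspan = (int(sblocks[0][0]) + 1, int(sblocks[-1][1]))
    return ident, mism, gap_opens, aligned_length, qspan, sspan


def _best_path(aligner: Align.PairwiseAligner, a: str, b: str):
    """Deterministic co-optimal tie-break: smallest query start, then subject start."""
    alns = aligner.align(a, b)
    best = None
    key = None
    for i, aln in enumerate(alns):
        if i >= 16:  # co-optimal paths beyond this are ignored deterministically
            break
        qblocks, sblocks = aln.aligned
        k = (int(qblocks[0][0]), int(sblocks[0][0]))
        if key is None or k < key:
            key, best = k, aln
    return best


def smith_waterman(
    a: str,
    b: str,
    params: ScoringParams = ScoringParams(),
    query_id: str = "query",
    subject_id: str = "subject",
    db_length: int | None = None,
) -> Alignment:
    """Optimal local alignment of two protein sequences under affine gaps.

    ``db_length`` is the n of the Karlin-Altschul formula; it defaults to
    ``len(b)`` (single-subject search).
    """
    a = validate_protein(a)
    b = validate_protein(b)
    n = db_length if db_length is not None else len(b)
    aligner = _aligner(params, "local")
    score = float(aligner.score(a, b))
    if score <= 0:
        return Alignment(
            query_id, subject_id, 0.0, bit_score(0.0, params),
            evalue(0.0, len(a), n, params), 0.0, 0, 0, 0, (0, 0), (0, 0),
        )
    aln = _best_path(aligner, a, b)
    ident, mism, gap_opens, length, qspan, sspan = _alignment_stats(aln, a, b)
    return Alignment(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=score,
        bit_score=bit_score(score, params),
        evalue=evalue(score, len(a), n, params),
        identity=ident / length if length else 0.0,
        aligned_length=length,
        mismatches=mism,
        gap_opens=gap_opens,
        query_span=qspan,
        subject_span=sspan,
    )


def _kmer_candidates(genes: list[tuple[str, str]], kmer: int) -> set[tuple[int, int]]:
    """Unordered index pairs of genes sharing at least one exact k-mer."""
    buckets: dict[str, list[int]] = {}
    for idx, (_, seq) in enumerate(genes):
        seen = set()
        for pos in range(len(seq) - kmer + 1):
            word = seq[pos : pos + kmer]
            if word not in seen:
                seen.add(word)
                buckets.setdefault(word, []).append(idx)
    pairs: set[tuple[int, int]] = set()
    for members in buckets.values():
        if len(members) < 2:
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.add((members[i], members[j]))
    return pairs


def all_vs_all(
    proteomes: Iterable[StrainProteome],
    params: ScoringParams = ScoringParams(),
    kmer: int = 5,
    max_evalue: float | None = 10.0,
) -> pd.DataFrame:
    """All-vs-all local-alignment search over a cohort of proteomes.

    For every ordered gene pair that shares at least one exact k-mer and has a
    positive local-alignment score, the table records the best alignment in
    outfmt-6 style columns (plus a ``raw_score`` column).  Every gene gets a
    self-hit.  ``max_evalue`` drops hits above the reporting threshold
    (BLAST's default reporting threshold is E = 10); pass ``None`` to keep
    every positive-scoring pair.
    """
    if kmer < 1:
        raise ValueError("kmer must be >= 1")
    genes: list[tuple[str, str]] = []
    lengths: list[int] = []
    for prot in proteomes:
        if len(prot) == 0:
            warnings.warn(f"strain {prot.strain_id} has an empty proteome", stacklevel=2)
        for gene_id, seq in prot:
            genes.append((gene_id, seq))
            lengths.append(len(seq))
    db_len = sum(lengths)
    aligner = _aligner(params, "local")

    rows: list[tuple] = []

    def emit(qid: str, sid: str, score: float, ev: float, ident: int, mism: int,
             gapo: int, length: int, qspan: tuple[int, int], sspan: tuple[int, int]) -> None:
        rows.append((
            qid, sid, 100.0 * ident / length, length, mism, gapo,
            qspan[0], qspan[1], sspan[0], sspan[1], ev, bit_score(score, params), score,
        ))

    # self-hits
    for (gene_id, seq), m in zip(genes, lengths):
        score = float(aligner.score(seq, seq))
        ev = evalue(score, m, db_len, params)
        emit(gene_id, gene_id, score, ev, m, 0, 0, m, (1, m), (1, m))

    for i, j in sorted(_kmer_candidates(genes, kmer)):
        (qid, a), (sid, b) = genes[i], genes[j]
        score = float(aligner.score(a, b))
        if score <= 0:
            continue
        ev_ab = evalue(score, len(a), db_len, params)
        ev_ba = evalue(score, len(b), db_len, params)
        keep_ab = max_evalue is None or ev_ab <= max_evalue
        keep_ba = max_evalue is None or ev_ba <= max_evalue
        if not (keep_ab or keep_ba):
            continue
        aln = _best_path(aligner, a, b)
        ident, mism, gapo, length, qspan, sspan = _alignment_stats(aln, a, b)
        if keep_ab:
            emit(qid, sid, score, ev_ab, ident, mism, gapo, length, qspan, sspan)
        if keep_ba:
            emit(sid, qid, score, ev_ba, ident, mism, gapo, length, sspan, qspan)

    return pd.DataFrame(rows, columns=HIT_COLUMNS + ["raw_score"])


def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    """Serialize a hit table as 12-column tab-separated outfmt-6 rows."""
    hits[HIT_COLUMNS].to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_hit_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS)
    df["raw_score"] = (df["bitscore"] * LN2 + math.log(ScoringParams().K)) / ScoringParams().lam
    return df
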