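"""Pairwise local protein alignment with database-scale E-values.

The built-in backend is Smith-Waterman with affine gaps (BLOSUM62, gap open
11, extend 1) through Biopython's C aligner.  Scores are converted to bit
scores with the gapped Karlin-Altschul parameters lambda = 0.267, K = 0.041
(the standard blastp defaults for this scoring scheme):

    bitscore = (lambda * raw - ln K) / ln 2
    E        = m * n * 2^(-bitscore)

where m is the query length and n the subject length, or the database residue
count when one is supplied.  Percent identity counts gap columns in the
denominator (the blastp convention).  Precomputed 12-column tabular output
from an external search tool can be imported interchangeably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .records import ProteinRecord, validate_sequence

LN2 = math.log(2.0)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and Karlin-Altschul params."""

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        # A gap of length g costs gap_open + g * gap_extend.
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner

    def bitscore(self, raw_score: float) -> float:
        return (self.karlin_lambda * raw_score - math.log(self.karlin_k)) / LN2

    def evalue(self, raw_score: float, m: int, n: int) -> float:
        return m * n * 2.0 ** (-self.bitscore(raw_score))


DEFAULT_SCORING = ScoringScheme()


@dataclass
class AlignmentHit:
    """One directed pairwise local-alignment result."""

    query: str
    subject: str
    bitscore: float
    evalue: float
    identity_pct: float
    alignment_length: int
    query_span: tuple[int, int]  # 1-based, inclusive
    subject_span: tuple[int, int]
    raw_score: float | None = None
    mismatches: int = 0
    gap_opens: int = 0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError("identity_pct must be within [0, 100]")


def align_pair(
    seq_a: str,
    seq_b: str,
    scoring: ScoringScheme = DEFAULT_SCORING,
    ids: tuple[str, str] = ("query", "subject"),
    db_residues: int | None = None,
) -> AlignmentHit:
    """Smith-Waterman local alignment of two sequences.

    ``db_residues`` replaces the subject length in the E-value when aligning
    against a database; without it the single-pair convention E = m*n*2^-S'
    is used.  The first optimal alignment reported by the aligner is taken,
    which is deterministic for fixed inputs.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    validate_sequence(seq_a, ids[0])
    validate_sequence(seq_b, ids[1])
    aligner = scoring.make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    q_blocks, s_blocks = aln.aligned
    gap_opens = (len(q_blocks) - 1) + (len(s_blocks) - 1)
    raw = float(aln.score)
    n = db_residues if db_residues is not None else len(seq_b)
    return AlignmentHit(
        query=ids[0],
        subject=ids[1],
        raw_score=raw,
        bitscore=scoring.bitscore(raw),
        evalue=scoring.evalue(raw, len(seq_a), n),
        identity_pct=100.0 * counts.identities / length,
        alignment_length=int(length),
        query_span=(int(q_blocks[0][0]) + 1, int(q_blocks[-1][1])),
        subject_span=(int(s_blocks[0][0]) + 1, int(s_blocks[-1][1])),
        mismatches=int(counts.mismatches),
        gap_opens=gap_opens,
    )


def all_vs_all(
    records: Sequence[ProteinRecord],
    scoring: ScoringScheme = DEFAULT_SCORING,
    evalue_cutoff: float = 1e-5,
    db_residues: int | None = None,
) -> list[AlignmentHit]:
    """All-vs-all alignment, reporting passing hits in both directions.

    The database size for E-values defaults to the total residue count of the
    record set (as a search tool indexing the same set would use).  Each
    unordered pair is aligned once; the two directed hits share the alignment
    but carry direction-specific E-values (query length differs).
    """
    if len(records) < 2:
        return []
    n_db = db_residues if db_residues is not None else sum(
        len(r.sequence) for r in records
    )
    hits: list[AlignmentHit] = []
    ordered = sorted(records, key=lambda r: r.id)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            fwd = align_pair(
                a.sequence, b.sequence, scoring, ids=(a.id, b.id), db_residues=n_db
            )
            if fwd.evalue <= evalue_cutoff:
                hits.append(fwd)
            rev_evalue = scoring.evalue(fwd.raw_score, len(b.sequence), n_db)
            if rev_evalue <= evalue_cutoff:
                hits.append(
                    AlignmentHit(
                        query=b.id,
                        subject=a.id,
                        raw_score=fwd.raw_score,
                        bitscore=fwd.bitscore,
                        evalue=rev_evalue,
                        identity_pct=fwd.identity_pct,
                        alignment_length=fwd.alignment_length,
                        query_span=fwd.subject_span,
                        subject_span=fwd.query_span,
                        mismatches=fwd.mismatches,
                        gap_opens=fwd.gap_opens,
                    )
                )
    return hits


def import_alignment_tabular(path: str | Path) -> list[AlignmentHit]:
    """Parse 12-column tabular alignment output (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore).

    Comment lines starting with ``#`` are skipped; a wrong column count raises
    ``ValueError`` with the line number.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            (qid, sid, pident, length, mismatch, gapopen,
             qstart, qend, sstart, send, evalue, bitscore) = fields
            hits.append(
                AlignmentHit(
                    query=qid,
                    subject=sid,
                    bitscore=float(bitscore),
                    evalue=float(evalue),
                    identity_pct=float(pident),
                    alignment_length=int(length),
                    query_span=(int(qstart), int(qend)),
                    subject_span=(int(sstart), int(send)),
                    mismatches=int(mismatch),
                    gap_opens=int(gapopen),
                )
            )
    return hits


def write_alignment_tabular(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits in the 12-column tabular dialect read back by the importer."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query}\t{h.subject}\t{h.identity_pct:.2f}\t{h.alignment_length}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.query_span[0]}\t{h.query_span[1]}\t"
                f"{h.subject_span[0]}\t{h.subject_span[1]}\t{h.evalue:.3g}\t"
                f"{h.bitscore:.1f}\n"
            )
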