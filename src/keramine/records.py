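"""Protein records, FASTA input, and annotation-table handling.

The pipeline operates on three kinds of sequence sets: the proteomes of the
focal strains (category ``query``), a panel of functionally characterized
keratinases (``functional_keratinase``), and a panel of proteases with no
keratinolytic activity (``non_keratinase``).  Every downstream stage consumes
:class:`ProteinRecord` objects produced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

CATEGORY_QUERY = "query"
CATEGORY_KERATINASE = "functional_keratinase"
CATEGORY_NON_KERATINASE = "non_keratinase"
CATEGORIES = (CATEGORY_QUERY, CATEGORY_KERATINASE, CATEGORY_NON_KERATINASE)

# 20 standard residues plus X for ambiguity.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class ProteinRecord:
    """One protein with provenance and a functional category label.

    ``strain`` is either a focal-strain name (category ``query``) or a panel
    name.  ``annotations`` collects (annotator, description) pairs from the
    consolidated annotation tables; it may be empty.
    """

    id: str
    strain: str
    sequence: str
    category: str
    annotations: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r} for {self.id}; "
                f"expected one of {CATEGORIES}"
            )
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for protein {self.id}")
        validate_sequence(self.sequence, self.id)


def validate_sequence(sequence: str, protein_id: str = "?") -> None:
    """Raise ``ValueError`` naming the first invalid residue position."""
    for pos, ch in enumerate(sequence, start=1):
        if ch not in VALID_RESIDUES:
            raise ValueError(
                f"invalid residue {ch!r} at position {pos} in protein {protein_id}"
            )


def read_protein_fasta(
    path: str | Path, strain: str, category: str
) -> list[ProteinRecord]:
    """Read a protein FASTA into records with the given strain and category.

    Ids are the first whitespace-delimited header token.  Sequences are
    upper-cased and terminal stop codons (``*``) are stripped.  Duplicate ids
    and non-amino-acid characters raise ``ValueError``.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"duplicate protein id {pid!r} in {path}")
        seen.add(pid)
        seq = str(rec.seq).upper().rstrip("*")
        records.append(ProteinRecord(id=pid, strain=strain, sequence=seq, category=category))
    return records


def write_protein_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_annotation_table(
    path: str | Path,
    annotator_name: str,
    description_column: int = 1,
) -> dict[str, list[str]]:
    """Read a tab-separated annotation table into ``id -> [descriptions]``.

    The first column holds the protein id; ``description_column`` selects the
    description field (0-based).  Multiple rows for one id are concatenated in
    file order.  Lines starting with ``#`` are skipped.  A row without the
    description column is an error.
    """
    if description_column < 1:
        raise ValueError("description_column must be >= 1 (column 0 is the id)")
    mapping: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) <= description_column:
                raise ValueError(
                    f"{path}:{lineno}: missing description column "
                    f"{description_column} (annotator {annotator_name}, "
                    f"{len(fields)} fields)"
                )
            mapping.setdefault(fields[0], []).append(fields[description_column])
    return mapping


def consolidate_annotations(
    records: Iterable[ProteinRecord],
    tables: Mapping[str, Mapping[str, list[str]]],
) -> None:
    """Attach per-annotator descriptions to records, in place.

    ``tables`` maps annotator name to the output of
    :func:`read_annotation_table`.  Records absent from every table keep an
    empty annotation list; all conflicting descriptions are retained.
    """
    for rec in records:
        pairs: list[tuple[str, str]] = []
        for annotator in sorted(tables):
            for desc in tables[annotator].get(rec.id, []):
                pairs.append((annotator, desc))
        rec.annotations = pairs
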