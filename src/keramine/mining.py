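"""Keyword mining of putative proteases from consolidated annotations.

A protein is selected when any keyword occurs as a case-insensitive substring
of any description from any annotator ("at least one of the predictions").
Multi-word keywords such as "penicillin-binding protein" are matched as whole
phrases, so the generic word "protein" alone never triggers a selection.
Manual curation of hits is replaced by a review flag on proteins supported by
exactly one annotator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .records import ProteinRecord


@dataclass
class MiningResult:
    selected: set[str] = field(default_factory=set)
    #: id -> sorted list of (keyword, annotator) pairs that triggered it.
    matches: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    #: ids whose keyword support comes from exactly one annotator.
    review_flagged: set[str] = field(default_factory=set)

    def annotators_for(self, protein_id: str) -> set[str]:
        return {ann for _, ann in self.matches.get(protein_id, [])}


def mine_proteases(
    records: Iterable[ProteinRecord], keywords: Sequence[str]
) -> MiningResult:
    """Select putative proteases by case-insensitive keyword matching."""
    if not keywords:
        raise ValueError("keywords must be non-empty")
    lowered = [(kw, kw.lower()) for kw in keywords]
    result = MiningResult()
    for rec in records:
        hits: set[tuple[str, str]] = set()
        for annotator, desc in rec.annotations:
            desc_low = desc.lower()
            for kw, kw_low in lowered:
                if kw_low in desc_low:
                    hits.add((kw, annotator))
        if hits:
            result.selected.add(rec.id)
            result.matches[rec.id] = sorted(hits)
            if len({ann for _, ann in hits}) == 1:
                result.review_flagged.add(rec.id)
    return result


def write_mining_table(
    result: MiningResult, records: Iterable[ProteinRecord], path: str | Path
) -> None:
    """Write one row per input protein: selection, keywords, annotators, flag."""
    with open(path, "w") as fh:
        fh.write("id\tselected\tkeywords\tannotators\treview_flag\n")
        for rec in records:
            sel = rec.id in result.selected
            kws = sorted({kw for kw, _ in result.matches.get(rec.id, [])})
            anns = sorted(result.annotators_for(rec.id))
            fh.write(
                f"{rec.id}\t{int(sel)}\t{','.join(kws)}\t{','.join(anns)}\t"
                f"{int(rec.id in result.review_flagged)}\n"
            )
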