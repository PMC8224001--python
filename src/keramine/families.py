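"""Peptidase family assignment and protease-orthogroup clustering.

Family assignment follows the MEROPS convention: family codes are a catalytic
superfamily letter (Aspartic, Cysteine, Glutamic, Metallo, asparagiNe,
Serine, Threonine, mixed (P), Unknown) plus digits, e.g. S08, M04.  A query
receives the family of a reference sequence only by reciprocal best hit at
the configured E-value cutoff.

Protease orthogroups ("p-orthogroups") are connected components of the
thresholded all-vs-all alignment graph over the mined protease set; groups
need at least two members, everything else is "unassigned".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from Bio import SeqIO

from .align import AlignmentHit, DEFAULT_SCORING, ScoringScheme, align_pair
from .records import ProteinRecord, validate_sequence

SUPERFAMILY_LETTERS = frozenset("ACGMNSTPU")


@dataclass(frozen=True)
class FamilyReference:
    id: str
    family: str
    sequence: str


@dataclass
class FamilyAssignment:
    protein_id: str
    family: str
    reference_id: str
    evalue: float

    @property
    def superfamily(self) -> str:
        return self.family[0]


@dataclass
class POrthogroup:
    group_id: int
    members: list[str]
    strains: list[str]
    family: str | None = None
    mixed_family: bool = False

    @property
    def size(self) -> int:
        return len(self.members)


def read_family_reference(path: str | Path) -> list[FamilyReference]:
    """Read a reference FASTA whose headers carry family codes as ``id|FAMILY``."""
    refs: list[FamilyReference] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if "|" not in header:
            raise ValueError(
                f"malformed family reference header {header!r}: expected 'id|FAMILY'"
            )
        ref_id, family = header.rsplit("|", 1)
        if not ref_id or not family or family[0] not in SUPERFAMILY_LETTERS:
            raise ValueError(
                f"malformed family code in reference header {header!r}"
            )
        if ref_id in seen:
            raise ValueError(f"duplicate reference id {ref_id!r} in {path}")
        seen.add(ref_id)
        seq = str(rec.seq).upper().rstrip("*")
        validate_sequence(seq, ref_id)
        refs.append(FamilyReference(id=ref_id, family=family, sequence=seq))
    return refs


def _best(
    candidates: list[tuple[float, float, str]],
) -> tuple[float, float, str] | None:
    """Pick the best hit: lowest E-value, ties to higher bitscore, then id."""
    if not candidates:
        return None
    return min(candidates, key=lambda t: (t[0], -t[1], t[2]))


def assign_families(
    queries: Sequence[ProteinRecord],
    reference_db: Sequence[FamilyReference],
    evalue_cutoff: float = 1e-20,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> list[FamilyAssignment]:
    """Reciprocal-best-hit family assignment of queries against a reference set.

    A query is assigned the family of reference R iff R is the query's best
    hit (E-value cutoff applied, query searched against the whole reference
    database) and the query is in turn R's best hit among all queries.
    """
    ref_residues = sum(len(r.sequence) for r in reference_db)
    query_residues = sum(len(q.sequence) for q in queries)
    # score[qid][rid] = (evalue_q_vs_refdb, bitscore); raw scores are symmetric.
    raw_scores: dict[tuple[str, str], float] = {}
    for q in queries:
        for r in reference_db:
            hit = align_pair(
                q.sequence, r.sequence, scoring, ids=(q.id, r.id),
                db_residues=ref_residues,
            )
            raw_scores[(q.id, r.id)] = hit.raw_score

    by_ref = {r.id: r for r in reference_db}
    assignments: list[FamilyAssignment] = []
    for q in queries:
        fwd = [
            (
                scoring.evalue(raw_scores[(q.id, r.id)], len(q.sequence), ref_residues),
                scoring.bitscore(raw_scores[(q.id, r.id)]),
                r.id,
            )
            for r in reference_db
        ]
        best_fwd = _best([t for t in fwd if t[0] <= evalue_cutoff])
        if best_fwd is None:
            continue
        evalue, _, ref_id = best_fwd
        ref = by_ref[ref_id]
        rev = [
            (
                scoring.evalue(
                    raw_scores[(q2.id, ref_id)], len(ref.sequence), query_residues
                ),
                scoring.bitscore(raw_scores[(q2.id, ref_id)]),
                q2.id,
            )
            for q2 in queries
        ]
        best_rev = _best(rev)
        if best_rev is not None and best_rev[2] == q.id:
            assignments.append(
                FamilyAssignment(
                    protein_id=q.id, family=ref.family, reference_id=ref_id,
                    evalue=evalue,
                )
            )
    return assignments


def cluster_p_orthogroups(
    hits: Iterable[AlignmentHit],
    evalue_cutoff: float = 1e-40,
    ids: Iterable[str] | None = None,
    strains: Mapping[str, str] | None = None,
    families: Mapping[str, str] | None = None,
) -> tuple[list[POrthogroup], set[str]]:
    """Cluster proteases into p-orthogroups by thresholded connected components.

    An undirected edge joins two proteins when either directed hit passes the
    E-value cutoff.  Components of size >= 2 become groups, ordered by
    decreasing size then lexicographically smallest member; singletons are
    returned as the unassigned set.  ``ids`` supplies proteins with no hits at
    all (otherwise the universe is inferred from the hit list).
    """
    graph = nx.Graph()
    if ids is not None:
        graph.add_nodes_from(ids)
    for hit in hits:
        graph.add_node(hit.query)
        graph.add_node(hit.subject)
        if hit.query != hit.subject and hit.evalue <= evalue_cutoff:
            graph.add_edge(hit.query, hit.subject)

    components = [sorted(c) for c in nx.connected_components(graph)]
    grouped = sorted(
        (c for c in components if len(c) >= 2), key=lambda c: (-len(c), c[0])
    )
    unassigned = {c[0] for c in components if len(c) == 1}

    groups: list[POrthogroup] = []
    for gid, members in enumerate(grouped):
        member_strains = sorted(
            {strains[m] for m in members if m in strains}
        ) if strains else []
        fam: str | None = None
        mixed = False
        if families:
            fams = sorted({families[m] for m in members if m in families})
            if len(fams) == 1:
                fam = fams[0]
            elif len(fams) > 1:
                mixed = True
        groups.append(
            POrthogroup(
                group_id=gid, members=members, strains=member_strains,
                family=fam, mixed_family=mixed,
            )
        )
    return groups, unassigned


def strain_overlap(
    groups: Sequence[POrthogroup], strains: Sequence[str]
) -> dict:
    """Count p-orthogroups per region of the strain Venn diagram.

    Returns ``{"regions": {region-key: count}, "totals": {strain: count}}``
    where a region key is the '&'-joined sorted tuple of strains whose groups
    contain members of exactly those strains.
    """
    regions: dict[str, int] = {}
    # all non-empty subsets, keyed deterministically
    n = len(strains)
    for mask in range(1, 2**n):
        subset = tuple(s for i, s in enumerate(sorted(strains)) if mask >> i & 1)
        regions["&".join(subset)] = 0
    totals = {s: 0 for s in strains}
    for g in groups:
        present = tuple(sorted(set(g.strains) & set(strains)))
        if not present:
            continue
        regions["&".join(present)] += 1
        for s in present:
            totals[s] += 1
    return {"regions": regions, "totals": totals}


def write_families_table(
    assignments: Sequence[FamilyAssignment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("id\tfamily\tsuperfamily\treference_id\tevalue\n")
        for a in sorted(assignments, key=lambda a: a.protein_id):
            fh.write(
                f"{a.protein_id}\t{a.family}\t{a.superfamily}\t"
                f"{a.reference_id}\t{a.evalue:.3g}\n"
            )


def write_orthogroups_table(
    groups: Sequence[POrthogroup],
    unassigned: set[str],
    strains: Mapping[str, str],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tmember\tstrain\tfamily\n")
        for g in groups:
            fam = "mixed" if g.mixed_family else (g.family or "unassigned")
            for m in g.members:
                fh.write(f"{g.group_id}\t{m}\t{strains.get(m, '')}\t{fam}\n")
        for m in sorted(unassigned):
            fh.write(f"unassigned\t{m}\t{strains.get(m, '')}\t\n")


def write_venn_json(overlap: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(overlap, fh, indent=2, sort_keys=True)
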