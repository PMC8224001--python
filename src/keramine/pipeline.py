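"""End-to-end orchestration: mining -> families -> orthogroups -> network ->
localization embedding -> phylogeny -> candidate selection.

Each stage writes its artifact as TSV/GraphML/Newick/JSON into the output
directory so stages can also be re-run independently; the final candidate
report has one row per mined query protease.  A single config seed makes the
whole run deterministic.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import align, families, localization, mining, network, phylo
from .config import PipelineConfig
from .records import (
    CATEGORY_KERATINASE,
    CATEGORY_NON_KERATINASE,
    CATEGORY_QUERY,
    ProteinRecord,
    consolidate_annotations,
    read_annotation_table,
    read_protein_fasta,
)


@dataclass
class PipelineInputs:
    """Paths to every stage input.

    ``localization_fused`` is an alternative to the three raw predictor
    files.  ``alignment_tabular`` short-circuits the built-in aligner with a
    precomputed 12-column all-vs-all file.  ``trees`` maps a t-SNE group id
    to an externally inferred Newick file (NJ on p-distances is the
    fallback).
    """

    strain_fastas: dict[str, Path]
    annotation_tables: dict[str, Path]
    keratinase_fasta: Path
    non_keratinase_fasta: Path
    family_reference: Path
    psortb: Path | None = None
    cello: Path | None = None
    signalp: Path | None = None
    localization_fused: Path | None = None
    alignment_tabular: Path | None = None
    trees: dict[int, Path] = field(default_factory=dict)

    @classmethod
    def from_bundle_dir(cls, directory: str | Path) -> "PipelineInputs":
        """Wire up the file layout written by ``FixtureBundle.write``."""
        d = Path(directory)
        strain_fastas = {
            p.stem: p for p in sorted(d.glob("*.faa"))
            if p.name not in ("keratinases.faa", "non_keratinases.faa",
                              "family_reference.faa")
        }
        annotation_tables = {
            p.stem.replace("annotations_", ""): p
            for p in sorted(d.glob("annotations_*.tsv"))
        }
        return cls(
            strain_fastas=strain_fastas,
            annotation_tables=annotation_tables,
            keratinase_fasta=d / "keratinases.faa",
            non_keratinase_fasta=d / "non_keratinases.faa",
            family_reference=d / "family_reference.faa",
            psortb=d / "psortb.tsv",
            cello=d / "cello.tsv",
            signalp=d / "signalp.tsv",
        )


@dataclass
class PipelineResult:
    report: pd.DataFrame
    candidates: list[str]
    mining_result: mining.MiningResult
    family_assignments: list[families.FamilyAssignment]
    orthogroups: list[families.POrthogroup]
    orthogroup_unassigned: set[str]
    network: "network.nx.Graph"
    communities: list[network.Community]
    linkage: network.LinkageResult
    embedding: localization.EmbeddingResult | None
    clade_decisions: dict[int, list[phylo.CladeDecision]]
    occupancy: dict[int, phylo.OccupancyProfile]
    summary: dict


REPORT_COLUMNS = [
    "id", "strain", "family", "p_orthogroup", "community", "keratinase_linked",
    "tsne_group", "predicted_extracellular", "clade_selected", "review_flag",
    "evidence",
]


def _align_group_msa(records: list[ProteinRecord]) -> phylo.Msa:
    """Equal-length sequences are taken as already aligned; otherwise the
    group is aligned with mafft when available."""
    lengths = {len(r.sequence) for r in records}
    if len(lengths) == 1:
        return [(r.id, r.sequence) for r in records]
    mafft = shutil.which("mafft")
    if mafft is None:
        raise RuntimeError(
            "group sequences are unaligned and no aligner is available; "
            "supply per-group MSAs or install mafft"
        )
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "group.faa"
        with open(fasta, "w") as fh:
            for r in records:
                fh.write(f">{r.id}\n{r.sequence}\n")
        proc = subprocess.run(
            [mafft, "--auto", "--quiet", str(fasta)],
            capture_output=True, text=True, check=True,
        )
        aligned = Path(tmp) / "aligned.afa"
        aligned.write_text(proc.stdout)
        return phylo.read_alignment_fasta(aligned)


def _predicted_extracellular(feat: localization.LocalizationFeatures) -> bool:
    """Rule-based extracellular call from the fused scores: the extracellular
    compartment wins either compartment predictor, or a signal peptide is
    likely."""
    psortb_extra = feat.psortb[3] >= max(feat.psortb)
    cello_extra = feat.cello[3] >= max(feat.cello)
    return psortb_extra or cello_extra or feat.signalp[5] > 0.5


def run_pipeline(
    config: PipelineConfig,
    inputs: PipelineInputs,
    outdir: str | Path,
) -> PipelineResult:
    """Execute every stage in order and write per-stage artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        # ---------------- inputs ----------------
        query_records: list[ProteinRecord] = []
        for strain in sorted(inputs.strain_fastas):
            query_records.extend(
                read_protein_fasta(
                    inputs.strain_fastas[strain], strain, CATEGORY_QUERY
                )
            )
        keratinases = read_protein_fasta(
            inputs.keratinase_fasta, "keratinase_panel", CATEGORY_KERATINASE
        )
        non_keratinases = read_protein_fasta(
            inputs.non_keratinase_fasta, "non_keratinase_panel",
            CATEGORY_NON_KERATINASE,
        )
        tables = {
            annotator: read_annotation_table(path, annotator)
            for annotator, path in sorted(inputs.annotation_tables.items())
        }
        consolidate_annotations(query_records, tables)

        # ---------------- mining ----------------
        stage = "mining"
        mined = mining.mine_proteases(query_records, config.mining_keywords)
        mining.write_mining_table(mined, query_records, outdir / "mining.tsv")
        proteases = sorted(
            (r for r in query_records if r.id in mined.selected),
            key=lambda r: r.id,
        )
        strain_of = {r.id: r.strain for r in query_records}
        for r in keratinases + non_keratinases:
            strain_of[r.id] = r.strain

        if not proteases:
            report = pd.DataFrame(columns=REPORT_COLUMNS)
            report.to_csv(outdir / "report.tsv", sep="\t", index=False)
            summary = {"n_query_proteins": len(query_records), "n_mined": 0,
                       "n_candidates": 0}
            (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
            return PipelineResult(
                report=report, candidates=[], mining_result=mined,
                family_assignments=[], orthogroups=[],
                orthogroup_unassigned=set(),
                network=network.nx.Graph(), communities=[],
                linkage=network.LinkageResult(), embedding=None,
                clade_decisions={}, occupancy={}, summary=summary,
            )

        # ---------------- families (RBH) ----------------
        stage = "families"
        reference = families.read_family_reference(inputs.family_reference)
        assignments = families.assign_families(
            proteases, reference, config.family_evalue
        )
        families.write_families_table(assignments, outdir / "families.tsv")
        family_of = {a.protein_id: a.family for a in assignments}

        # ---------------- all-vs-all alignment ----------------
        stage = "alignment"
        panel_records = keratinases + non_keratinases
        network_set = proteases + panel_records
        loose_cutoff = max(config.orthogroup_evalue, config.network_evalue)
        if inputs.alignment_tabular is not None:
            hits = align.import_alignment_tabular(inputs.alignment_tabular)
        else:
            hits = align.all_vs_all(
                network_set, evalue_cutoff=loose_cutoff
            )
        align.write_alignment_tabular(hits, outdir / "all_vs_all.tsv")

        # ---------------- p-orthogroups (queries only) ----------------
        stage = "orthogroups"
        protease_ids = {r.id for r in proteases}
        query_hits = [
            h for h in hits if h.query in protease_ids and h.subject in protease_ids
        ]
        groups, unassigned = families.cluster_p_orthogroups(
            query_hits, config.orthogroup_evalue, ids=protease_ids,
            strains=strain_of, families=family_of,
        )
        families.write_orthogroups_table(
            groups, unassigned, strain_of, outdir / "orthogroups.tsv"
        )
        overlap = families.strain_overlap(groups, sorted(inputs.strain_fastas))
        families.write_venn_json(overlap, outdir / "venn.json")
        group_of = {m: g.group_id for g in groups for m in g.members}

        # ---------------- similarity network ----------------
        stage = "network"
        net = network.build_network(
            hits, threshold=config.network_evalue, records=network_set
        )
        communities, singletons = network.detect_communities(
            net, resolution=config.louvain_resolution, seed=config.random_seed
        )
        linkage = network.link_keratinases(
            communities, net, mode=config.linkage_mode
        )
        network.annotate_network(net, communities, linkage)
        network.write_graphml(net, outdir / "network.graphml")
        network.write_edge_list(net, outdir / "network_edges.tsv")
        network.write_communities_table(
            communities, singletons, outdir / "communities.tsv"
        )
        community_of = {m: c.id for c in communities for m in c.members}

        # ---------------- localization embedding ----------------
        stage = "embedding"
        if inputs.localization_fused is not None:
            feats = localization.read_fused_table(inputs.localization_fused)
        elif inputs.psortb and inputs.cello and inputs.signalp:
            feats = localization.parse_predictor_outputs(
                inputs.psortb, inputs.cello, inputs.signalp
            )
        else:
            raise ValueError(
                "no localization input: supply a fused table or all three "
                "predictor files"
            )
        network_ids = {r.id for r in network_set}
        feats = [f for f in feats if f.id in network_ids]
        missing_feats = network_ids - {f.id for f in feats}
        if missing_feats:
            raise ValueError(
                f"no localization scores for {sorted(missing_feats)}"
            )
        localization.write_fused_table(feats, outdir / "features.tsv")
        extracellular_flag = {
            f.id: _predicted_extracellular(f) for f in feats
        }

        category_of = {r.id: r.category for r in network_set}
        embedding: localization.EmbeddingResult | None = None
        tsne_group_of: dict[str, int] = {}
        if len(feats) >= 5 and config.tsne_perplexity < len(feats):
            embedding = localization.embed(feats, config)
            localization.cluster_tsne(
                embedding, eps=config.dbscan_eps,
                min_samples=config.dbscan_min_samples,
            )
            localization.write_embedding_table(
                embedding, outdir / "embedding.tsv"
            )
            comp = localization.group_composition(
                embedding, category_of, strain_of
            )
            comp.to_csv(outdir / "tsne_group_composition.tsv", sep="\t",
                        index=False)
            tsne_group_of = {
                pid: int(lab)
                for pid, lab in zip(embedding.ids, embedding.dbscan_labels)
            }
        else:
            warnings.warn(
                "too few proteins for embedding; skipping t-SNE and phylogeny",
                stacklevel=2,
            )

        # ---------------- phylogeny + clade selection ----------------
        stage = "phylogeny"
        asr_category_of = {}
        for r in network_set:
            if r.category == CATEGORY_KERATINASE:
                asr_category_of[r.id] = "functional_keratinase"
            elif r.category == CATEGORY_NON_KERATINASE:
                asr_category_of[r.id] = "non_keratinase"
            elif r.id in linkage.linked:
                asr_category_of[r.id] = "keratinase_linked"
            else:
                asr_category_of[r.id] = "three_strain"

        records_by_id = {r.id: r for r in network_set}
        clade_decisions: dict[int, list[phylo.CladeDecision]] = {}
        occupancy: dict[int, phylo.OccupancyProfile] = {}
        candidates: set[str] = set()
        analyzed_groups: list[int] = []
        if embedding is not None:
            group_members: dict[int, list[str]] = {}
            for pid, g in tsne_group_of.items():
                if g >= 0:
                    group_members.setdefault(g, []).append(pid)
            for g in sorted(group_members):
                members = sorted(group_members[g])
                has_keratinase = any(
                    asr_category_of[m] == "functional_keratinase" for m in members
                )
                if not has_keratinase or len(members) < 3:
                    continue
                analyzed_groups.append(g)
                msa = _align_group_msa([records_by_id[m] for m in members])
                compact, profile = phylo.occupancy_filter(
                    msa, config.occupancy_threshold
                )
                occupancy[g] = profile
                phylo.write_alignment_fasta(
                    compact, outdir / f"group{g}_compact.afa"
                )
                phylo.write_occupancy_table(
                    profile, outdir / f"group{g}_occupancy.tsv"
                )
                if g in inputs.trees:
                    tree = phylo.dendropy.Tree.get(
                        path=str(inputs.trees[g]), schema="newick",
                        preserve_underscores=True,
                    )
                else:
                    tree = phylo.nj_tree(compact)
                tree = phylo.midpoint_root(tree)
                kept = {name for name, _ in compact}
                ctree = phylo.asr_er(
                    tree, {m: asr_category_of[m] for m in kept}
                )
                phylo.write_annotated_newick(
                    ctree, outdir / f"group{g}_asr.nwk"
                )
                decisions, group_candidates = phylo.select_clades(
                    ctree, strain_of, config.focal_strain,
                    config.clade_probability_threshold,
                    config.clade_probability_mode,
                )
                clade_decisions[g] = decisions
                phylo.write_clade_table(
                    decisions, outdir / f"group{g}_clades.tsv"
                )
                candidates.update(group_candidates)

        # ---------------- report ----------------
        stage = "report"
        rows = []
        for r in proteases:
            kws = sorted({kw for kw, _ in mined.matches.get(r.id, [])})
            rows.append(
                {
                    "id": r.id,
                    "strain": r.strain,
                    "family": family_of.get(r.id, "unassigned"),
                    "p_orthogroup": group_of.get(r.id, "unassigned"),
                    "community": community_of.get(r.id, "singleton"),
                    "keratinase_linked": r.id in linkage.linked,
                    "tsne_group": tsne_group_of.get(r.id, -1),
                    "predicted_extracellular": extracellular_flag.get(
                        r.id, False
                    ),
                    "clade_selected": r.id in candidates,
                    "review_flag": r.id in mined.review_flagged,
                    "evidence": ",".join(kws),
                }
            )
        report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
        report.to_csv(outdir / "report.tsv", sep="\t", index=False)

        summary = {
            "n_query_proteins": len(query_records),
            "n_mined": len(proteases),
            "n_family_assigned": len(assignments),
            "n_p_orthogroups": len(groups),
            "n_orthogroup_unassigned": len(unassigned),
            "venn_regions": overlap["regions"],
            "n_communities_min2": len(communities),
            "n_keratinase_communities": sum(
                1 for c in communities
                if c.contains_functional_keratinase and c.contains_query
            ),
            "n_keratinase_linked": len(linkage.linked),
            "per_strain_linked": linkage.per_strain_counts,
            "tsne_groups_analyzed": analyzed_groups,
            "n_candidates": len(candidates),
            "candidates": sorted(candidates),
        }
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        return PipelineResult(
            report=report,
            candidates=sorted(candidates),
            mining_result=mined,
            family_assignments=assignments,
            orthogroups=groups,
            orthogroup_unassigned=unassigned,
            network=net,
            communities=communities,
            linkage=linkage,
            embedding=embedding,
            clade_decisions=clade_decisions,
            occupancy=occupancy,
            summary=summary,
        )
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
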