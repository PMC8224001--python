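"""Synthetic fixtures with planted ground truth for every pipeline stage.

The generator emulates the shape of the study data: three focal strains whose
proteomes contain divergent protease families, a functional-keratinase panel
sharing one family ("the keratinase-like family") with the strains, a
non-keratinase panel, localization score tables with an extracellular versus
intracellular cluster structure, pre-aligned MSAs, and trees with
category-labeled tips evolved under a known equal-rates process.  The truth
JSON records planted families, keratinase-linked ids, extracellular ids and
the expected candidate set, so end-to-end recovery is checkable exactly.

Everything is seeded: the same seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .config import PipelineConfig
from .localization import FEATURE_NAMES, LocalizationFeatures, write_fused_table
from .records import (
    CATEGORY_KERATINASE,
    CATEGORY_NON_KERATINASE,
    CATEGORY_QUERY,
    ProteinRecord,
    write_protein_fasta,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

STRAINS = ("G11C", "CHD11", "Vc74B-19")

#: family code -> description templates used by the three mock annotators.
FAMILY_DESCRIPTIONS = {
    "S08": ("subtilisin-like serine peptidase", "peptidase S8 family protein",
            "serine endopeptidase"),
    "S01": ("trypsin-like serine protease", "chymotrypsin family peptidase",
            "serine protease"),
    "M04": ("thermolysin metallopeptidase", "peptidase M4 family protein",
            "neutral metalloproteinase"),
    "S12": ("serine beta-lactamase-like peptidase", "D-alanyl-D-alanine peptidase",
            "peptidase S12 protein"),
    "M50": ("membrane-bound metallopeptidase", "peptidase M50 family protein",
            "site-2 protease"),
    "C02": ("calpain-like cysteine proteinase", "peptidase C2 protein",
            "cysteine protease"),
    "S33": ("prolyl aminopeptidase", "peptidase S33 protein", "proline peptidase"),
    "M28": ("aminopeptidase", "peptidase M28 family protein", "leucyl peptidase"),
    "S15": ("X-prolyl-dipeptidyl aminopeptidase", "peptidase S15 protein",
            "dipeptidyl peptidase"),
    "T01": ("proteasome endopeptidase subunit", "peptidase T1 protein",
            "threonine peptidase"),
    "A01": ("pepsin-like aspartic proteinase", "peptidase A1 protein",
            "aspartic protease"),
    "M17": ("leucyl aminopeptidase", "peptidase M17 protein", "cytosol peptidase"),
}

NON_PROTEASE_DESCRIPTIONS = (
    "hypothetical protein",
    "ABC transporter ATP-binding component",
    "DNA polymerase III subunit beta",
    "50S ribosomal subunit L1",
    "MFS transporter",
    "two-component sensor histidine kinase",
)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def mutate(seq: str, n_substitutions: int, rng: np.random.Generator) -> str:
    """Apply ``n_substitutions`` point substitutions at distinct positions."""
    chars = list(seq)
    n = min(n_substitutions, len(chars))
    positions = rng.choice(len(chars), size=n, replace=False)
    for pos in positions:
        current = chars[pos]
        choices = AMINO_ACIDS[AMINO_ACIDS != current]
        chars[pos] = str(rng.choice(choices))
    return "".join(chars)


def _indel(seq: str, indel_rate: float, rng: np.random.Generator) -> str:
    """Optionally apply short insertions/deletions (for gap-handling tests)."""
    if indel_rate <= 0:
        return seq
    chars = list(seq)
    n_events = rng.poisson(indel_rate * len(chars))
    for _ in range(n_events):
        pos = int(rng.integers(0, max(1, len(chars) - 1)))
        size = int(rng.integers(1, 4))
        if rng.random() < 0.5 and len(chars) > size + 10:
            del chars[pos : pos + size]
        else:
            chars[pos:pos] = list(random_protein(rng, size))
    return "".join(chars)


def gen_families(
    n_families: int,
    size_per_family: int,
    length: int = 240,
    within_divergence: float = 0.05,
    seed: int = 0,
    indel_rate: float = 0.0,
    strains: Sequence[str] = STRAINS,
) -> tuple[list[ProteinRecord], dict[str, list[str]], dict[str, str]]:
    """Generate divergent protein families with planted membership truth.

    Each family grows from an independent random root; members carry
    Poisson(length * within_divergence) substitutions and are assigned
    round-robin to the focal strains.  Returns (records, family -> member
    ids, family -> root sequence).
    """
    if not (0.0 < within_divergence < 0.3):
        raise ValueError("within_divergence must be in (0, 0.3)")
    if n_families < 1 or size_per_family < 1 or length < 10:
        raise ValueError("invalid family generation parameters")
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    truth: dict[str, list[str]] = {}
    roots: dict[str, str] = {}
    counters = {s: 0 for s in strains}
    for fam in range(n_families):
        fam_key = f"fam{fam}"
        root = random_protein(rng, length)
        roots[fam_key] = root
        members: list[str] = []
        for m in range(size_per_family):
            strain = strains[m % len(strains)]
            counters[strain] += 1
            pid = f"{strain}_{counters[strain]:05d}"
            n_sub = int(rng.poisson(length * within_divergence))
            seq = _indel(mutate(root, n_sub, rng), indel_rate, rng)
            records.append(
                ProteinRecord(
                    id=pid, strain=strain, sequence=seq, category=CATEGORY_QUERY
                )
            )
            members.append(pid)
        truth[fam_key] = members
    return records, truth, roots


def gen_er_history(
    tree: dendropy.Tree, q: float, k: int = 4, seed: int = 0
) -> tuple[dict[str, int], dict[str, int]]:
    """Evolve a k-state equal-rates character down a tree.

    The root state is uniform; along a branch of length t the child state is
    drawn from the ER transition row.  Returns (tip states, internal node
    states) with nodes keyed by label (internal nodes are labeled in preorder
    if unlabeled).
    """
    from .phylo import _label_nodes, er_transition_matrix

    rng = np.random.default_rng(seed)
    _label_nodes(tree)
    states: dict[int, int] = {}
    tips: dict[str, int] = {}
    internal: dict[str, int] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            state = int(rng.integers(0, k))
        else:
            t = node.edge.length or 0.0
            row = er_transition_matrix(q, t, k)[states[id(node.parent_node)]]
            state = int(rng.choice(k, p=row))
        states[id(node)] = state
        if node.is_leaf():
            tips[node.label] = state
        else:
            internal[node.label] = state
    return tips, internal


def gen_random_tree(
    n_tips: int, seed: int = 0, mean_branch: float = 0.1,
    prefix: str = "t",
) -> dendropy.Tree:
    """Random binary tree built by sequential pair joins, exponential branch
    lengths with the given mean."""
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_tips):
        taxon = taxa.new_taxon(f"{prefix}{i}")
        node = dendropy.Node(taxon=taxon)
        node.edge.length = float(rng.exponential(mean_branch))
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.exponential(mean_branch))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = None
    return tree


# ---------------------------------------------------------------------------
# full scenario

@dataclass
class FixtureBundle:
    """In-memory scenario plus writers for every on-disk input format."""

    config: PipelineConfig
    seed: int
    strain_records: dict[str, list[ProteinRecord]]
    keratinase_panel: list[ProteinRecord]
    non_keratinase_panel: list[ProteinRecord]
    annotations: dict[str, dict[str, list[str]]]  # annotator -> id -> descs
    family_reference: list[tuple[str, str, str]]  # (ref id, family, sequence)
    features: list[LocalizationFeatures]
    truth: dict = field(default_factory=dict)

    def all_query_records(self) -> list[ProteinRecord]:
        out: list[ProteinRecord] = []
        for strain in sorted(self.strain_records):
            out.extend(self.strain_records[strain])
        return out

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every input file the pipeline consumes; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for strain, records in sorted(self.strain_records.items()):
            p = outdir / f"{strain}.faa"
            write_protein_fasta(records, p)
            paths[f"fasta_{strain}"] = p
        paths["keratinase_panel"] = outdir / "keratinases.faa"
        write_protein_fasta(self.keratinase_panel, paths["keratinase_panel"])
        paths["non_keratinase_panel"] = outdir / "non_keratinases.faa"
        write_protein_fasta(self.non_keratinase_panel, paths["non_keratinase_panel"])

        for annotator, table in sorted(self.annotations.items()):
            p = outdir / f"annotations_{annotator}.tsv"
            with open(p, "w") as fh:
                for pid in sorted(table):
                    for desc in table[pid]:
                        fh.write(f"{pid}\t{desc}\n")
            paths[f"annotations_{annotator}"] = p

        paths["family_reference"] = outdir / "family_reference.faa"
        with open(paths["family_reference"], "w") as fh:
            for ref_id, family, seq in self.family_reference:
                fh.write(f">{ref_id}|{family}\n{seq}\n")

        self._write_localization(outdir, paths)

        paths["truth"] = outdir / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
        return paths

    def _write_localization(self, outdir: Path, paths: dict[str, Path]) -> None:
        paths["psortb"] = outdir / "psortb.tsv"
        with open(paths["psortb"], "w") as fh:
            fh.write(
                "SeqID\tCytoplasmic_Score\tCytoplasmicMembrane_Score\t"
                "Cellwall_Score\tExtracellular_Score\n"
            )
            for f in self.features:
                fh.write(f.id + "\t" + "\t".join(f"{x:.3f}" for x in f.psortb) + "\n")
        paths["cello"] = outdir / "cello.tsv"
        with open(paths["cello"], "w") as fh:
            fh.write("id\tcytoplasmic\tcytoplasmic_membrane\tcell_wall\textracellular\n")
            for f in self.features:
                fh.write(f.id + "\t" + "\t".join(f"{x:.3f}" for x in f.cello) + "\n")
        paths["signalp"] = outdir / "signalp.tsv"
        with open(paths["signalp"], "w") as fh:
            fh.write("# SignalP-5.0\tOrganism: gram+\n")
            fh.write(
                "# ID\tPrediction\tSP(Sec/SPI)\tTAT(Tat/SPI)\tLIPO(Sec/SPII)\t"
                "OTHER\tCS Position\n"
            )
            for f in self.features:
                sp, tat, lipo, other = f.signalp[:4]
                pred = "SP(Sec/SPI)" if sp > 0.5 else "OTHER"
                fh.write(
                    f"{f.id}\t{pred}\t{sp:.4f}\t{tat:.4f}\t{lipo:.4f}\t{other:.4f}\t\n"
                )
        paths["fused"] = outdir / "localization_fused.tsv"
        write_fused_table(self.features, paths["fused"])


def _localization_vector(
    rng: np.random.Generator, extracellular: bool
) -> LocalizationFeatures:
    """Draw one localization profile: clear extracellular vs intracellular."""

    def noisy(mu: float, sd: float, lo: float = 0.0, hi: float = 10.0) -> float:
        return float(np.clip(rng.normal(mu, sd), lo, hi))

    if extracellular:
        psortb = (noisy(0.5, 0.15), noisy(0.5, 0.15), noisy(0.8, 0.2), noisy(8.2, 0.4))
        cello = (noisy(0.3, 0.1, 0, 5), noisy(0.4, 0.1, 0, 5),
                 noisy(0.5, 0.15, 0, 5), noisy(3.8, 0.3, 0, 5))
        sp = noisy(0.85, 0.05, 0.0, 0.98)
        tat = noisy(0.05, 0.02, 0.0, 0.2)
        lipo = noisy(0.04, 0.02, 0.0, 0.2)
    else:
        psortb = (noisy(8.6, 0.4), noisy(0.6, 0.2), noisy(0.3, 0.1), noisy(0.2, 0.1))
        cello = (noisy(3.9, 0.3, 0, 5), noisy(0.5, 0.15, 0, 5),
                 noisy(0.2, 0.1, 0, 5), noisy(0.2, 0.1, 0, 5))
        sp = noisy(0.01, 0.005, 0.0, 0.05)
        tat = noisy(0.005, 0.003, 0.0, 0.05)
        lipo = noisy(0.005, 0.003, 0.0, 0.05)
    other = max(0.0, 1.0 - sp - tat - lipo)
    possibility = sp + tat + lipo
    return LocalizationFeatures(
        id="", psortb=psortb, cello=cello,
        signalp=(sp, tat, lipo, other, 1.0 - possibility, possibility),
    )


#: scenario presets: (query families, members per family, keratinase panel
#: size, non-keratinase panel size, sequence length)
SCENARIO_PRESETS = {
    "minimal": dict(n_families=12, size_per_family=6, n_keratinases=10,
                    n_non_keratinases=8, length=240),
    "paper-shaped": dict(n_families=32, size_per_family=18, n_keratinases=61,
                         n_non_keratinases=50, length=300),
}

#: family codes assigned cyclically to planted query families; the first
#: (linked) family is keratinase-like S08, then S01 and M04 for the
#: extracellular decoys, mirroring the families where bacterial keratinases
#: concentrate.
_FAMILY_CODE_CYCLE = tuple(FAMILY_DESCRIPTIONS)


def gen_keratinase_scenario(
    seed: int = 0,
    preset: str = "minimal",
    config: PipelineConfig | None = None,
    within_divergence: float = 0.04,
) -> FixtureBundle:
    """Build a full planted scenario for end-to-end pipeline testing.

    Family 0 is the keratinase-like family: it contains the functional
    keratinase panel plus focal-strain members, which therefore become
    keratinase-linked in the similarity network.  Family 0 and the next two
    families (plus a few non-keratinases) carry extracellular localization
    profiles; everything else is intracellular.  The truth records planted
    families, linked ids, extracellular ids, and the expected candidates:
    the focal-strain members of family 0.
    """
    if preset not in SCENARIO_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose {sorted(SCENARIO_PRESETS)}")
    params = SCENARIO_PRESETS[preset]
    if config is None:
        config = PipelineConfig(random_seed=seed)
    rng = np.random.default_rng(seed)

    records, fam_truth, roots = gen_families(
        n_families=params["n_families"],
        size_per_family=params["size_per_family"],
        length=params["length"],
        within_divergence=within_divergence,
        seed=int(rng.integers(2**31)),
    )
    by_id = {r.id: r for r in records}
    fam_codes = {
        f"fam{i}": _FAMILY_CODE_CYCLE[i % len(_FAMILY_CODE_CYCLE)]
        for i in range(params["n_families"])
    }

    # keratinase panel: same lineage as family 0
    keratinase_panel = []
    for i in range(params["n_keratinases"]):
        n_sub = int(rng.poisson(params["length"] * within_divergence))
        keratinase_panel.append(
            ProteinRecord(
                id=f"KER_{i:03d}", strain="keratinase_panel",
                sequence=mutate(roots["fam0"], n_sub, rng),
                category=CATEGORY_KERATINASE,
            )
        )
    # non-keratinase panel: two independent families (trypsin/papain-like)
    non_roots = [random_protein(rng, params["length"]) for _ in range(2)]
    non_keratinase_panel = []
    for i in range(params["n_non_keratinases"]):
        n_sub = int(rng.poisson(params["length"] * within_divergence))
        non_keratinase_panel.append(
            ProteinRecord(
                id=f"NONKER_{i:03d}", strain="non_keratinase_panel",
                sequence=mutate(non_roots[i % 2], n_sub, rng),
                category=CATEGORY_NON_KERATINASE,
            )
        )

    # non-protease decoy proteins per strain (mining must skip them)
    strain_records: dict[str, list[ProteinRecord]] = {s: [] for s in STRAINS}
    for rec in records:
        strain_records[rec.strain].append(rec)
    decoys: list[str] = []
    for strain in STRAINS:
        for i in range(4):
            pid = f"{strain}_{90000 + i:05d}"
            strain_records[strain].append(
                ProteinRecord(
                    id=pid, strain=strain,
                    sequence=random_protein(rng, params["length"]),
                    category=CATEGORY_QUERY,
                )
            )
            decoys.append(pid)

    # annotations from three mock annotators; a few proteins get single-
    # annotator support and should come out review-flagged
    annotators = ("prokka", "pannzer2", "eggnog")
    annotations: dict[str, dict[str, list[str]]] = {a: {} for a in annotators}
    protease_ids = sorted(by_id)
    single_annotator = set(protease_ids[::17][:3])
    for fam_key, members in fam_truth.items():
        descs = FAMILY_DESCRIPTIONS[fam_codes[fam_key]]
        for pid in members:
            if pid in single_annotator:
                annotations["prokka"].setdefault(pid, []).append(descs[0])
            else:
                for annotator, desc in zip(annotators, descs):
                    annotations[annotator].setdefault(pid, []).append(desc)
    for i, pid in enumerate(decoys):
        desc = NON_PROTEASE_DESCRIPTIONS[i % len(NON_PROTEASE_DESCRIPTIONS)]
        for annotator in annotators[: 1 + i % 3]:
            annotations[annotator].setdefault(pid, []).append(desc)

    # family reference: several slightly diverged references per family so
    # reciprocal best hits resolve cleanly
    family_reference: list[tuple[str, str, str]] = []
    ref_i = 0
    for fam_key in sorted(fam_truth, key=lambda f: int(f[3:])):
        for _ in range(3):
            n_sub = int(rng.poisson(params["length"] * 0.03))
            family_reference.append(
                (f"MER{ref_i:04d}", fam_codes[fam_key],
                 mutate(roots[fam_key], n_sub, rng))
            )
            ref_i += 1

    # localization: family 0 (linked), the two decoy families 1-2, the
    # keratinase panel and a few non-keratinases are extracellular
    extracellular = set(fam_truth["fam0"]) | set(fam_truth["fam1"]) | set(
        fam_truth["fam2"]
    )
    extracellular |= {r.id for r in keratinase_panel}
    extracellular |= {r.id for r in non_keratinase_panel[:3]}
    features: list[LocalizationFeatures] = []
    all_embedded = (
        protease_ids
        + [r.id for r in keratinase_panel]
        + [r.id for r in non_keratinase_panel]
    )
    for pid in all_embedded:
        vec = _localization_vector(rng, pid in extracellular)
        vec.id = pid
        features.append(vec)

    linked_ids = sorted(fam_truth["fam0"])
    candidates = sorted(
        pid for pid in fam_truth["fam0"] if by_id[pid].strain == config.focal_strain
    )
    truth = {
        "seed": seed,
        "preset": preset,
        "params": params,
        "within_divergence": within_divergence,
        "families": {k: sorted(v) for k, v in fam_truth.items()},
        "family_codes": fam_codes,
        "planted_protease_ids": protease_ids,
        "non_protease_ids": sorted(decoys),
        "review_flagged_ids": sorted(single_annotator),
        "keratinase_linked_ids": linked_ids,
        "extracellular_ids": sorted(extracellular),
        "candidate_ids": candidates,
    }
    return FixtureBundle(
        config=config,
        seed=seed,
        strain_records=strain_records,
        keratinase_panel=keratinase_panel,
        non_keratinase_panel=non_keratinase_panel,
        annotations=annotations,
        family_reference=family_reference,
        features=features,
        truth=truth,
    )


def gen_localization_panel(
    n_extracellular: int = 200,
    n_intracellular: int = 495,
    seed: int = 0,
) -> tuple[list[LocalizationFeatures], dict[str, bool]]:
    """A study-scale localization fixture: fused score vectors with a planted
    extracellular/intracellular split.

    The default sizes mirror the scale of the embedded set in the study
    design (584 query proteases plus 61 + 50 panel sequences); the fixed
    t-SNE perplexity and the DBSCAN radius are calibrated to that scale, so
    separability properties are assessed on it.  Returns the feature list
    and ``id -> is_extracellular`` truth.
    """
    rng = np.random.default_rng(seed)
    feats: list[LocalizationFeatures] = []
    truth: dict[str, bool] = {}
    for i in range(n_extracellular + n_intracellular):
        extr = i < n_extracellular
        vec = _localization_vector(rng, extr)
        vec.id = f"prot{i:04d}"
        feats.append(vec)
        truth[vec.id] = extr
    return feats, truth


def gen_gappy_msa(
    n_seqs: int, length: int, gap_fraction: float, seed: int = 0
) -> list[tuple[str, str]]:
    """A synthetic MSA with a controlled fraction of gappy columns.

    A ``gap_fraction`` of columns receive gaps in a random majority of rows
    (driving their occupancy below typical thresholds); the remaining columns
    stay fully occupied.
    """
    rng = np.random.default_rng(seed)
    base = [random_protein(rng, length) for _ in range(n_seqs)]
    n_gappy = int(round(gap_fraction * length))
    gappy_cols = set(rng.choice(length, size=n_gappy, replace=False).tolist())
    rows = [list(s) for s in base]
    for col in gappy_cols:
        n_gaps = int(rng.integers(int(0.6 * n_seqs) + 1, n_seqs + 1))
        for row in rng.choice(n_seqs, size=n_gaps, replace=False):
            rows[row][col] = "-"
    return [(f"s{i}", "".join(rows[i])) for i in range(n_seqs)]
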