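"""Occupancy-filtered phylogenetics and rule-based candidate selection.

For each extracellular t-SNE group, the multiple sequence alignment is
compacted by removing columns whose occupancy (fraction of sequences with a
residue) falls below a threshold, a tree is obtained (externally inferred
Newick, or a neighbor-joining fallback on p-distances), midpoint rooted, and
ancestral category states are reconstructed under the k-state equal-rates
(ER) Mk model.  Under ER with rate q the transition probabilities are

    P_same(t) = 1/k + (k-1)/k * exp(-k q t)
    P_diff(t) = 1/k * (1 - exp(-k q t))

q is fitted by maximizing the Felsenstein pruning likelihood with a flat root
prior, and marginal posteriors at every node are computed exactly with an
inside-outside pass.  Candidate proteins are the focal-strain tips of maximal
clades passing three filters: ancestral probability of the keratinase or
keratinase-linked categories above the threshold, at least one functional
keratinase tip, and at least one focal-strain tip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

#: Discrete categories used for ancestral state reconstruction.
ASR_CATEGORIES = (
    "functional_keratinase",
    "keratinase_linked",
    "three_strain",
    "non_keratinase",
)

GAP_CHARS = frozenset("-.")

#: An MSA is a list of (id, aligned sequence) with equal row lengths.
Msa = list[tuple[str, str]]


# ---------------------------------------------------------------------------
# MSA I/O and occupancy filtering

def read_alignment_fasta(path: str | Path) -> Msa:
    msa: Msa = []
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    msa.append((name, "".join(chunks)))
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.strip())
    if name is not None:
        msa.append((name, "".join(chunks)))
    _check_equal_rows(msa)
    return msa


def write_alignment_fasta(msa: Msa, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in msa:
            fh.write(f">{name}\n{seq}\n")


def _check_equal_rows(msa: Msa) -> None:
    lengths = {len(seq) for _, seq in msa}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")


@dataclass
class OccupancyProfile:
    column_occupancy: np.ndarray
    average_pct: float               # mean occupancy of the original columns
    kept_columns: list[int]
    filtered_average_pct: float      # mean occupancy of the kept columns
    dropped_rows: list[str] = field(default_factory=list)


def occupancy_filter(msa: Msa, threshold: float = 0.70) -> tuple[Msa, OccupancyProfile]:
    """Remove alignment columns with occupancy below ``threshold``.

    Rows that become all-gap after filtering are dropped with a warning.
    """
    if not msa:
        raise ValueError("empty alignment")
    _check_equal_rows(msa)
    rows = np.array([[ch not in GAP_CHARS for ch in seq] for _, seq in msa])
    occupancy = rows.mean(axis=0)
    kept = [i for i in range(rows.shape[1]) if occupancy[i] >= threshold]
    compact: Msa = []
    dropped: list[str] = []
    for name, seq in msa:
        new_seq = "".join(seq[i] for i in kept)
        if new_seq and all(ch in GAP_CHARS for ch in new_seq):
            dropped.append(name)
        else:
            compact.append((name, new_seq))
    if dropped:
        warnings.warn(
            f"dropping all-gap rows after occupancy filtering: {dropped}",
            stacklevel=2,
        )
    profile = OccupancyProfile(
        column_occupancy=occupancy,
        average_pct=100.0 * float(occupancy.mean()),
        kept_columns=kept,
        filtered_average_pct=(
            100.0 * float(occupancy[kept].mean()) if kept else 0.0
        ),
        dropped_rows=dropped,
    )
    return compact, profile


# ---------------------------------------------------------------------------
# trees

def p_distance_matrix(msa: Msa) -> tuple[list[str], np.ndarray]:
    """Pairwise p-distances over columns where both rows have residues.

    Pairs with no overlapping residue columns get the maximal distance 1.
    """
    names = [name for name, _ in msa]
    seqs = [seq for _, seq in msa]
    n = len(msa)
    arr = np.array([list(s) for s in seqs])
    is_res = ~np.isin(arr, list(GAP_CHARS))
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = is_res[i] & is_res[j]
            total = int(both.sum())
            if total == 0:
                d = 1.0
            else:
                d = float((arr[i, both] != arr[j, both]).sum()) / total
            dist[i, j] = dist[j, i] = d
    return names, dist


def nj_tree(msa: Msa) -> dendropy.Tree:
    """Neighbor-joining tree on p-distances (fallback when no tree is given).

    Negative branch lengths are clamped to zero.
    """
    if len(msa) < 3:
        raise ValueError("neighbor joining needs at least 3 sequences")
    from skbio import DistanceMatrix
    from skbio.tree import nj

    names, dist = p_distance_matrix(msa)
    newick = str(nj(DistanceMatrix(dist, ids=names)))
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


def _edge_length(node: dendropy.Node) -> float:
    return node.edge.length or 0.0


def _path_between(
    a: dendropy.Node, b: dendropy.Node
) -> list[tuple[dendropy.Node, str]]:
    """Edges on the tip-to-tip path as (edge-owning child node, side) pairs.

    ``side`` is "up" while climbing from ``a`` to the MRCA and "down" while
    descending to ``b``; each entry's edge is the one above its node.
    """
    a_anc = [a] + list(a.ancestor_iter())
    b_anc = [b] + list(b.ancestor_iter())
    b_set = {id(n): i for i, n in enumerate(b_anc)}
    for i, n in enumerate(a_anc):
        if id(n) in b_set:
            mrca_a, mrca_b = i, b_set[id(n)]
            break
    path = [(n, "up") for n in a_anc[:mrca_a]]
    path += [(n, "down") for n in reversed(b_anc[:mrca_b])]
    return path


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root the tree at the midpoint of the longest tip-to-tip path.

    Ties between equally long paths break toward the lexicographically
    smallest (sorted) tip-label pair.  A tree whose branch lengths are all
    zero is rooted at the first internal node in preorder, with a warning.
    """
    tree = tree.clone(depth=1)
    leaves = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    if len(leaves) < 2:
        return tree
    best: tuple[float, tuple[str, str]] | None = None
    best_pair: tuple[dendropy.Node, dendropy.Node] | None = None
    for i, la in enumerate(leaves):
        for lb in leaves[i + 1 :]:
            d = sum(_edge_length(n) for n, _ in _path_between(la, lb))
            key = tuple(sorted((la.taxon.label, lb.taxon.label)))
            if best is None or d > best[0] + 1e-15 or (
                abs(d - best[0]) <= 1e-15 and key < best[1]
            ):
                best = (d, key)
                best_pair = (la, lb)
    assert best is not None and best_pair is not None
    total, _ = best
    if total <= 0.0:
        warnings.warn(
            "all branch lengths are zero; rooting at the first internal node",
            stacklevel=2,
        )
        node = next(
            nd for nd in tree.preorder_node_iter() if not nd.is_leaf()
        )
        tree.reroot_at_node(node, update_bipartitions=False)
        return tree
    la, lb = best_pair
    if la.taxon.label > lb.taxon.label:
        la, lb = lb, la
    half = total / 2.0
    acc = 0.0
    for node, side in _path_between(la, lb):
        length = _edge_length(node)
        if acc + length >= half - 1e-15:
            remain = half - acc  # distance from the end of the edge nearer la
            if side == "up":
                # moving from child (head) toward parent (tail)
                dist_from_head = remain
            else:
                dist_from_head = length - remain
            if dist_from_head <= 1e-12:
                tree.reroot_at_node(node, update_bipartitions=False)
            elif length - dist_from_head <= 1e-12 and node.parent_node is not None:
                tree.reroot_at_node(node.parent_node, update_bipartitions=False)
            else:
                tree.reroot_at_edge(
                    node.edge,
                    length1=length - dist_from_head,
                    length2=dist_from_head,
                    update_bipartitions=False,
                )
            break
        acc += length
    return tree


# ---------------------------------------------------------------------------
# equal-rates Mk ancestral state reconstruction

def er_transition_matrix(q: float, t: float, k: int) -> np.ndarray:
    """ER transition matrix: rows sum to 1, identity at t = 0, -> 1/k as
    t -> infinity."""
    decay = np.exp(-k * q * t)
    p_same = 1.0 / k + (k - 1.0) / k * decay
    p_diff = (1.0 - decay) / k
    mat = np.full((k, k), p_diff)
    np.fill_diagonal(mat, p_same)
    return mat


def _label_nodes(tree: dendropy.Tree) -> None:
    """Give every node a stable label: tips keep taxon labels, internal nodes
    get n0, n1, ... in preorder."""
    idx = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label
        else:
            node.label = f"n{idx}"
            idx += 1


def _inside_pass(
    tree: dendropy.Tree,
    tip_index: Mapping[str, int],
    q: float,
    k: int,
) -> tuple[dict, float]:
    """Scaled Felsenstein pruning; returns per-node partials and log scale."""
    partial: dict[int, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            vec = np.zeros(k)
            vec[tip_index[node.taxon.label]] = 1.0
        else:
            vec = np.ones(k)
            for child in node.child_nodes():
                mat = er_transition_matrix(q, _edge_length(child), k)
                vec = vec * (mat @ partial[id(child)])
        scale = vec.max()
        if scale <= 0.0:
            raise ValueError("zero likelihood during pruning")
        partial[id(node)] = vec / scale
        log_scale += np.log(scale)
    return partial, log_scale


@dataclass
class CategorizedTree:
    """Rooted tree with tip categories and per-node ancestral posteriors."""

    tree: dendropy.Tree
    categories: tuple[str, ...]
    tip_categories: dict[str, str]
    rate: float
    log_likelihood: float
    #: node label -> posterior probability vector over categories.
    node_probs: dict[str, np.ndarray]


def asr_er(
    tree: dendropy.Tree,
    tip_categories: Mapping[str, str],
    categories: Sequence[str] = ASR_CATEGORIES,
    rate: float | None = None,
) -> CategorizedTree:
    """Fit the ER Mk rate (unless given) and compute exact marginal ancestral
    posteriors at every node with a flat root prior."""
    k = len(categories)
    cat_index = {c: i for i, c in enumerate(categories)}
    tips = [nd.taxon.label for nd in tree.leaf_node_iter()]
    missing = [t for t in tips if t not in tip_categories]
    if missing:
        raise ValueError(f"uncategorized tips: {sorted(missing)}")
    bad = sorted(
        {c for t, c in tip_categories.items() if t in set(tips) and c not in cat_index}
    )
    if bad:
        raise ValueError(f"unknown categories {bad}; expected {tuple(categories)}")
    tip_index = {t: cat_index[tip_categories[t]] for t in tips}
    prior = np.full(k, 1.0 / k)

    def neg_loglik(log10_q: float) -> float:
        partial, log_scale = _inside_pass(tree, tip_index, 10.0**log10_q, k)
        root = partial[id(tree.seed_node)]
        return -(log_scale + np.log(prior @ root))

    if rate is None:
        opt = minimize_scalar(
            neg_loglik, bounds=(-8.0, 3.0), method="bounded",
            options={"xatol": 1e-10},
        )
        if not opt.success:
            raise RuntimeError(f"ER rate optimization failed: {opt}")
        rate = float(10.0**opt.x)
        loglik = -float(opt.fun)
    else:
        loglik = -neg_loglik(np.log10(rate))

    partial, _ = _inside_pass(tree, tip_index, rate, k)

    # outside pass: O[v](s) proportional to P(data outside v, state(v) = s)
    outside: dict[int, np.ndarray] = {id(tree.seed_node): prior.copy()}
    messages: dict[int, np.ndarray] = {}  # upward message from each child
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        for child in children:
            mat = er_transition_matrix(rate, _edge_length(child), k)
            messages[id(child)] = mat @ partial[id(child)]
        for child in children:
            sib_prod = outside[id(node)].copy()
            for sib in children:
                if sib is not child:
                    sib_prod = sib_prod * messages[id(sib)]
            mat = er_transition_matrix(rate, _edge_length(child), k)
            vec = mat.T @ sib_prod
            scale = vec.max()
            outside[id(child)] = vec / scale if scale > 0 else vec

    _label_nodes(tree)
    node_probs: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        marg = partial[id(node)] * outside[id(node)]
        node_probs[node.label] = marg / marg.sum()
    return CategorizedTree(
        tree=tree,
        categories=tuple(categories),
        tip_categories={t: tip_categories[t] for t in tips},
        rate=rate,
        log_likelihood=float(loglik),
        node_probs=node_probs,
    )


def er_log_likelihood(
    tree: dendropy.Tree,
    tip_categories: Mapping[str, str],
    q: float,
    categories: Sequence[str] = ASR_CATEGORIES,
) -> float:
    """Pruning log-likelihood of tip categories under the ER model at rate q."""
    k = len(categories)
    cat_index = {c: i for i, c in enumerate(categories)}
    tip_index = {
        nd.taxon.label: cat_index[tip_categories[nd.taxon.label]]
        for nd in tree.leaf_node_iter()
    }
    partial, log_scale = _inside_pass(tree, tip_index, q, k)
    root = partial[id(tree.seed_node)]
    return float(log_scale + np.log(root.mean()))


def stochastic_map(
    ctree: CategorizedTree, n_draws: int = 1000, seed: int = 0
) -> dict[str, np.ndarray]:
    """Stochastic character mapping: draw seeded joint ancestral histories and
    report empirical per-node category frequencies.

    Node states are sampled exactly from the joint posterior (root from its
    marginal given the subtree likelihoods, then children conditionally on
    the parent), so frequencies converge to the exact marginals.
    """
    rng = np.random.default_rng(seed)
    k = len(ctree.categories)
    cat_index = {c: i for i, c in enumerate(ctree.categories)}
    tree = ctree.tree
    tip_index = {
        nd.taxon.label: cat_index[ctree.tip_categories[nd.taxon.label]]
        for nd in tree.leaf_node_iter()
    }
    partial, _ = _inside_pass(tree, tip_index, ctree.rate, k)
    counts: dict[str, np.ndarray] = {
        node.label: np.zeros(k) for node in tree.preorder_node_iter()
    }
    nodes = list(tree.preorder_node_iter())
    root = tree.seed_node
    root_post = partial[id(root)] / partial[id(root)].sum()
    for _ in range(n_draws):
        states: dict[int, int] = {id(root): int(rng.choice(k, p=root_post))}
        for node in nodes:
            if node is root:
                continue
            mat = er_transition_matrix(ctree.rate, _edge_length(node), k)
            parent_state = states[id(node.parent_node)]
            cond = mat[parent_state] * partial[id(node)]
            cond = cond / cond.sum()
            states[id(node)] = int(rng.choice(k, p=cond))
        for node in nodes:
            counts[node.label][states[id(node)]] += 1
    return {label: c / n_draws for label, c in counts.items()}


# ---------------------------------------------------------------------------
# clade selection

@dataclass
class CladeDecision:
    node_label: str
    tips: list[str]
    keratinase_probability: float  # P(keratinase) + P(keratinase-linked)
    prob_pass: bool
    has_keratinase: bool
    has_focal: bool
    selected: bool
    maximal: bool = False


def select_clades(
    ctree: CategorizedTree,
    tip_strains: Mapping[str, str],
    focal_strain: str,
    prob_threshold: float = 0.5,
    prob_mode: str = "sum",
) -> tuple[list[CladeDecision], list[str]]:
    """Apply the three clade-selection filters and emit candidate proteins.

    For every internal node: (1) the ancestral probability of the functional
    keratinase or keratinase-linked categories exceeds ``prob_threshold``
    (their sum by default, either category alone with ``prob_mode="either"``);
    (2) the subtree holds at least one functional-keratinase tip; (3) at
    least one focal-strain tip.  A selected node nested in another selected
    node is subsumed; candidates are the focal-strain tips of the maximal
    selected clades.
    """
    if prob_mode not in ("sum", "either"):
        raise ValueError("prob_mode must be 'sum' or 'either'")
    idx_k = ctree.categories.index("functional_keratinase")
    idx_l = ctree.categories.index("keratinase_linked")
    decisions: list[CladeDecision] = []
    selected_nodes = set()
    for node in ctree.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        probs = ctree.node_probs[node.label]
        summed = float(probs[idx_k] + probs[idx_l])
        if prob_mode == "sum":
            prob_pass = summed > prob_threshold
        else:
            prob_pass = probs[idx_k] > prob_threshold or probs[idx_l] > prob_threshold
        tips = sorted(lf.taxon.label for lf in node.leaf_iter())
        has_ker = any(
            ctree.tip_categories[t] == "functional_keratinase" for t in tips
        )
        has_focal = any(tip_strains.get(t) == focal_strain for t in tips)
        selected = prob_pass and has_ker and has_focal
        if selected:
            selected_nodes.add(node.label)
        maximal = selected and not any(
            anc.label in selected_nodes for anc in node.ancestor_iter()
        )
        decisions.append(
            CladeDecision(
                node_label=node.label,
                tips=tips,
                keratinase_probability=summed,
                prob_pass=prob_pass,
                has_keratinase=has_ker,
                has_focal=has_focal,
                selected=selected,
                maximal=maximal,
            )
        )
    candidates = sorted(
        {
            t
            for d in decisions
            if d.maximal
            for t in d.tips
            if tip_strains.get(t) == focal_strain
        }
    )
    return decisions, candidates


# ---------------------------------------------------------------------------
# output

def write_occupancy_table(profile: OccupancyProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# average_occupancy_pct\t{profile.average_pct:.2f}\n")
        fh.write(f"# filtered_average_pct\t{profile.filtered_average_pct:.2f}\n")
        fh.write("column\toccupancy\tkept\n")
        kept = set(profile.kept_columns)
        for i, occ in enumerate(profile.column_occupancy):
            fh.write(f"{i}\t{occ:.4f}\t{int(i in kept)}\n")


def write_annotated_newick(ctree: CategorizedTree, path: str | Path) -> None:
    """Write the rooted tree with per-node posterior comments (NHX-style)."""
    tree = ctree.tree.clone(depth=1)
    for node in tree.preorder_node_iter():
        probs = ctree.node_probs.get(node.label)
        if probs is not None:
            node.annotations.add_new(
                "asr", "|".join(f"{p:.4f}" for p in probs)
            )
    tree.write(
        path=str(path), schema="newick", suppress_annotations=False,
        unquoted_underscores=True,
    )


def write_clade_table(decisions: Sequence[CladeDecision], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "node\tker_prob\tprob_pass\thas_keratinase\thas_focal\tselected\t"
            "maximal\tn_tips\ttips\n"
        )
        for d in decisions:
            fh.write(
                f"{d.node_label}\t{d.keratinase_probability:.4f}\t{int(d.prob_pass)}\t"
                f"{int(d.has_keratinase)}\t{int(d.has_focal)}\t{int(d.selected)}\t"
                f"{int(d.maximal)}\t{len(d.tips)}\t{','.join(d.tips)}\n"
            )
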