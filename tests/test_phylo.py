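import itertools

import dendropy
import numpy as np
import pytest

from keramine.phylo import (
    asr_er,
    er_log_likelihood,
    er_transition_matrix,
    midpoint_root,
    nj_tree,
    occupancy_filter,
    p_distance_matrix,
    read_alignment_fasta,
    select_clades,
    stochastic_map,
)
from keramine.simulate import gen_random_tree, mutate, random_protein


# ---------------------------------------------------------------------------
# occupancy

def test_gapless_msa_is_untouched():
    msa = [("a", "MKVL"), ("b", "MKIL")]
    compact, profile = occupancy_filter(msa, 0.70)
    assert compact == msa
    assert profile.average_pct == 100.0
    assert profile.kept_columns == [0, 1, 2, 3]


def test_hand_computed_two_row_case():
    msa = [("a", "AC-"), ("b", "A--")]
    compact, profile = occupancy_filter(msa, 0.70)
    np.testing.assert_allclose(profile.column_occupancy, [1.0, 0.5, 0.0])
    assert profile.average_pct == pytest.approx(50.0)
    assert profile.kept_columns == [0]
    assert compact == [("a", "A"), ("b", "A")]
    assert profile.filtered_average_pct == pytest.approx(100.0)


def test_threshold_zero_is_identity():
    msa = [("a", "A-C"), ("b", "-AC")]
    compact, profile = occupancy_filter(msa, 0.0)
    assert compact == msa
    assert profile.kept_columns == [0, 1, 2]


def test_all_gap_rows_dropped_with_warning():
    msa = [("a", "AC"), ("b", "AC"), ("c", "--")]
    with pytest.warns(UserWarning, match="all-gap"):
        compact, profile = occupancy_filter(msa, 0.5)
    assert [name for name, _ in compact] == ["a", "b"]
    assert profile.dropped_rows == ["c"]


def test_ragged_alignment_is_an_error(tmp_path):
    p = tmp_path / "bad.afa"
    p.write_text(">a\nACD\n>b\nAC\n")
    with pytest.raises(ValueError, match="ragged"):
        read_alignment_fasta(p)


def test_filtering_never_lowers_average_occupancy():
    rng = np.random.default_rng(0)
    for seed in range(5):
        from keramine.simulate import gen_gappy_msa
        msa = gen_gappy_msa(8, 60, gap_fraction=0.4, seed=seed)
        _, profile = occupancy_filter(msa, 0.70)
        if len(profile.kept_columns) < len(profile.column_occupancy):
            assert profile.filtered_average_pct >= profile.average_pct


# ---------------------------------------------------------------------------
# trees

def test_three_taxon_nj_branch_lengths_are_additive():
    rng = np.random.default_rng(1)
    root = random_protein(rng, 100)
    msa = [("A", root), ("B", mutate(root, 6, rng)), ("C", mutate(root, 12, rng))]
    names, d = p_distance_matrix(msa)
    tree = nj_tree(msa)
    # closed form: branch to A = (dAB + dAC - dBC) / 2
    i = {n: k for k, n in enumerate(names)}
    expected_a = (d[i["A"], i["B"]] + d[i["A"], i["C"]] - d[i["B"], i["C"]]) / 2
    leaf_a = next(lf for lf in tree.leaf_node_iter() if lf.taxon.label == "A")
    assert leaf_a.edge.length == pytest.approx(expected_a, abs=1e-9)


def test_nj_recovers_additive_four_taxon_topology():
    rng = np.random.default_rng(2)
    root = random_protein(rng, 300)
    a = mutate(root, 3, rng)
    b = mutate(a, 4, rng)
    other = random_protein(rng, 300)
    c = mutate(other, 3, rng)
    d = mutate(c, 4, rng)
    tree = nj_tree([("A", a), ("B", b), ("C", c), ("D", d)])
    # the A|B vs C|D split must be present
    tree.encode_bipartitions()
    splits = {
        frozenset(lf.taxon.label for lf in edge.head_node.leaf_iter())
        for edge in tree.preorder_edge_iter()
        if edge.head_node is not None and not edge.head_node.is_leaf()
    }
    assert frozenset("AB") in splits or frozenset("CD") in splits


def test_nj_requires_three_sequences():
    with pytest.raises(ValueError):
        nj_tree([("a", "ACD"), ("b", "ACD")])


def test_two_tip_midpoint_splits_path_evenly():
    tree = dendropy.Tree.get(data="(A:1,B:3);", schema="newick")
    rooted = midpoint_root(tree)
    depths = {
        lf.taxon.label: sum(
            (n.edge.length or 0.0) for n in [lf] + list(lf.ancestor_iter())
        )
        for lf in rooted.leaf_node_iter()
    }
    assert depths["A"] == pytest.approx(2.0)
    assert depths["B"] == pytest.approx(2.0)


def test_balanced_tree_midpoint_is_stable():
    tree = dendropy.Tree.get(
        data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick"
    )
    rooted = midpoint_root(tree)
    depths = [
        sum((n.edge.length or 0.0) for n in [lf] + list(lf.ancestor_iter()))
        for lf in rooted.leaf_node_iter()
    ]
    assert all(d == pytest.approx(2.0) for d in depths)


def test_caterpillar_midpoint_matches_brute_force():
    newick = "((((A:5,B:1):1,C:1):1,D:1):1,E:2);"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    # brute-force longest path: A-E = 5+1+1+1+2 = 10 -> midpoint at 5 from A,
    # i.e. at the node joining (A,B) clade? A's own edge is 5 -> exactly at
    # A's parent node.
    rooted = midpoint_root(tree)
    depth = {}
    for lf in rooted.leaf_node_iter():
        depth[lf.taxon.label] = sum(
            (n.edge.length or 0.0) for n in [lf] + list(lf.ancestor_iter())
        )
    assert depth["A"] == pytest.approx(5.0)
    assert depth["E"] == pytest.approx(5.0)


def test_zero_length_tree_warns_and_roots_deterministically():
    tree = dendropy.Tree.get(data="((A:0,B:0):0,C:0);", schema="newick")
    with pytest.warns(UserWarning, match="zero"):
        rooted = midpoint_root(tree)
    assert rooted.seed_node is not None


# ---------------------------------------------------------------------------
# ER model

@pytest.mark.parametrize("q,t,k", [(0.5, 0.3, 4), (2.0, 1.5, 3), (0.01, 10.0, 5)])
def test_er_matrix_rows_sum_to_one(q, t, k):
    mat = er_transition_matrix(q, t, k)
    np.testing.assert_allclose(mat.sum(axis=1), np.ones(k), atol=1e-12)


def test_er_matrix_limits():
    np.testing.assert_allclose(
        er_transition_matrix(0.7, 0.0, 4), np.eye(4), atol=1e-12
    )
    np.testing.assert_allclose(
        er_transition_matrix(0.7, 1e6, 4), np.full((4, 4), 0.25), atol=1e-9
    )


def _brute_force(tree, tip_categories, q, categories):
    k = len(categories)
    ci = {c: i for i, c in enumerate(categories)}
    nodes = list(tree.preorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    total = 0.0
    marg = {id(nd): np.zeros(k) for nd in internal}
    for assign in itertools.product(range(k), repeat=len(internal)):
        state = {id(nd): s for nd, s in zip(internal, assign)}
        for nd in nodes:
            if nd.is_leaf():
                state[id(nd)] = ci[tip_categories[nd.taxon.label]]
        prob = 1.0 / k
        for nd in nodes:
            if nd.parent_node is not None:
                mat = er_transition_matrix(q, nd.edge.length or 0.0, k)
                prob *= mat[state[id(nd.parent_node)], state[id(nd)]]
        total += prob
        for nd in internal:
            marg[id(nd)][state[id(nd)]] += prob
    return np.log(total), {key: v / total for key, v in marg.items()}


def test_asr_matches_exhaustive_enumeration():
    cats = ("functional_keratinase", "keratinase_linked", "three_strain",
            "non_keratinase")
    rng = np.random.default_rng(4)
    for seed in range(5):
        tree = gen_random_tree(int(rng.integers(4, 7)), seed=seed, mean_branch=0.4)
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
        tip_cats = {t: cats[int(rng.integers(4))] for t in tips}
        q = float(rng.uniform(0.1, 2.0))
        log_bf, marg_bf = _brute_force(tree, tip_cats, q, cats)
        assert er_log_likelihood(tree, tip_cats, q, cats) == pytest.approx(
            log_bf, abs=1e-8
        )
        ct = asr_er(tree, tip_cats, categories=cats, rate=q)
        internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        for nd in internal:
            np.testing.assert_allclose(
                ct.node_probs[nd.label], marg_bf[id(nd)], atol=1e-8
            )


def test_two_tips_in_different_categories_are_exchangeable():
    tree = dendropy.Tree.get(data="(A:0.5,B:0.5);", schema="newick")
    ct = asr_er(tree, {"A": "functional_keratinase", "B": "three_strain"})
    root = ct.node_probs["n0"]
    assert root[0] == pytest.approx(root[2], abs=1e-9)
    assert root[0] > root[1]
    assert root[1] == pytest.approx(root[3], abs=1e-9)
    assert root.sum() == pytest.approx(1.0, abs=1e-9)


def test_uniform_tips_make_that_category_modal_everywhere():
    tree = gen_random_tree(8, seed=5, mean_branch=0.3)
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    ct = asr_er(tree, {t: "non_keratinase" for t in tips})
    for probs in ct.node_probs.values():
        assert np.argmax(probs) == 3


def test_uncategorized_tip_is_an_error():
    tree = dendropy.Tree.get(data="(A:1,B:1);", schema="newick")
    with pytest.raises(ValueError, match="uncategorized"):
        asr_er(tree, {"A": "three_strain"})


def test_stochastic_mapping_converges_to_marginals():
    cats = ("functional_keratinase", "keratinase_linked", "three_strain",
            "non_keratinase")
    tree = gen_random_tree(6, seed=6, mean_branch=0.5)
    rng = np.random.default_rng(7)
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    ct = asr_er(tree, {t: cats[int(rng.integers(4))] for t in tips})
    freqs = stochastic_map(ct, n_draws=1000, seed=11)
    worst = max(
        np.abs(freqs[label] - ct.node_probs[label]).max()
        for label in ct.node_probs
    )
    assert worst < 0.05


# ---------------------------------------------------------------------------
# clade selection

def _selection_fixture():
    # clade (K1,K2,G1) is keratinase-rich and contains a focal tip;
    # clade (T1,T2,G2) is a decoy without keratinases.
    newick = "(((K1:0.05,K2:0.05):0.05,G1:0.05):0.8,((T1:0.05,T2:0.05):0.05,G2:0.05):0.8);"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    cats = {
        "K1": "functional_keratinase", "K2": "functional_keratinase",
        "G1": "keratinase_linked", "T1": "three_strain", "T2": "three_strain",
        "G2": "three_strain",
    }
    strains = {"G1": "G11C", "G2": "G11C", "T1": "CHD11", "T2": "Vc74B-19"}
    ct = asr_er(tree, cats)
    return ct, strains


def test_three_filters_select_only_the_keratinase_clade():
    ct, strains = _selection_fixture()
    decisions, candidates = select_clades(ct, strains, "G11C", 0.5)
    assert candidates == ["G1"]
    by_node = {d.node_label: d for d in decisions}
    decoy = next(
        d for d in decisions if set(d.tips) == {"T1", "T2", "G2"}
    )
    assert not decoy.has_keratinase and not decoy.selected
    selected = [d for d in decisions if d.selected]
    assert all(d.has_keratinase and d.has_focal and d.prob_pass for d in selected)
    assert by_node  # decisions exist for every internal node


def test_high_probability_without_keratinase_tip_is_rejected():
    ct, strains = _selection_fixture()
    # decoy clade ancestors can have any probability; without a keratinase
    # tip the second filter must reject them
    for d, _ in [(d, None) for d in select_clades(ct, strains, "G11C", 0.0)[0]]:
        if not d.has_keratinase:
            assert not d.selected


def test_nested_selected_clades_are_subsumed():
    ct, strains = _selection_fixture()
    decisions, candidates = select_clades(ct, strains, "G11C", 0.5)
    maximal = [d for d in decisions if d.maximal]
    selected = [d for d in decisions if d.selected]
    # every selected clade is contained in some maximal one
    for d in selected:
        assert any(set(d.tips) <= set(m.tips) for m in maximal)
    # maximal clades are mutually non-nested
    for a, b in itertools.combinations(maximal, 2):
        assert not (set(a.tips) <= set(b.tips) or set(b.tips) <= set(a.tips))
    assert candidates == ["G1"]


def test_candidates_invariant_to_tip_order():
    rng = np.random.default_rng(8)
    root = random_protein(rng, 150)
    msa = [
        ("KER_A", mutate(root, 5, rng)),
        ("KER_B", mutate(root, 5, rng)),
        ("G11C_1", mutate(root, 5, rng)),
        ("CHD11_1", mutate(root, 6, rng)),
        ("FAR_1", random_protein(rng, 150)),
        ("FAR_2", random_protein(rng, 150)),
    ]
    cats = {
        "KER_A": "functional_keratinase", "KER_B": "functional_keratinase",
        "G11C_1": "keratinase_linked", "CHD11_1": "keratinase_linked",
        "FAR_1": "three_strain", "FAR_2": "three_strain",
    }
    strains = {"G11C_1": "G11C", "CHD11_1": "CHD11", "FAR_1": "G11C",
               "FAR_2": "CHD11"}

    def run(order):
        tree = midpoint_root(nj_tree([msa[i] for i in order]))
        ct = asr_er(tree, cats)
        return select_clades(ct, strains, "G11C", 0.5)[1]

    base = run(range(6))
    for _ in range(3):
        perm = rng.permutation(6)
        assert run(perm) == base
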