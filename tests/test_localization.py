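import warnings

import numpy as np
import pytest

from keramine.config import PipelineConfig
from keramine.localization import (
    EmbeddingResult,
    LocalizationFeatures,
    cluster_tsne,
    embed,
    group_composition,
    parse_cello,
    parse_predictor_outputs,
    parse_psortb,
    parse_signalp,
    read_fused_table,
    write_fused_table,
)


def _write_trio(tmp_path, ids, extracellular=()):
    psortb = tmp_path / "psortb.tsv"
    cello = tmp_path / "cello.tsv"
    signalp = tmp_path / "signalp.tsv"
    with open(psortb, "w") as fh:
        fh.write("SeqID\tCytoplasmic_Score\tCytoplasmicMembrane_Score\t"
                 "Cellwall_Score\tExtracellular_Score\n")
        for pid in ids:
            row = (0.2, 0.3, 0.5, 9.0) if pid in extracellular else (9.0, 0.5, 0.3, 0.2)
            fh.write(pid + "\t" + "\t".join(map(str, row)) + "\n")
    with open(cello, "w") as fh:
        fh.write("id\tcytoplasmic\tcytoplasmic_membrane\tcell_wall\textracellular\n")
        for pid in ids:
            row = (0.2, 0.3, 0.5, 4.0) if pid in extracellular else (4.0, 0.5, 0.3, 0.2)
            fh.write(pid + "\t" + "\t".join(map(str, row)) + "\n")
    with open(signalp, "w") as fh:
        fh.write("# ID\tPrediction\tSP(Sec/SPI)\tTAT(Tat/SPI)\tLIPO(Sec/SPII)\t"
                 "OTHER\tCS Position\n")
        for pid in ids:
            row = (0.9, 0.03, 0.02, 0.05) if pid in extracellular else (0.0, 0.0, 0.0, 1.0)
            fh.write(pid + "\tX\t" + "\t".join(map(str, row)) + "\t\n")
    return psortb, cello, signalp


def test_fusion_yields_14_feature_vectors(tmp_path):
    ids = [f"p{i}" for i in range(5)]
    paths = _write_trio(tmp_path, ids, extracellular={"p0"})
    feats = parse_predictor_outputs(*paths)
    assert [f.id for f in feats] == ids
    for f in feats:
        assert f.vector().shape == (14,)


def test_signalp_other_only_row(tmp_path):
    # OTHER=1 means no signal peptide: possibility 0, intracellular 1
    p = tmp_path / "sp.tsv"
    p.write_text("# header\nA\tOTHER\t0.0\t0.0\t0.0\t1.0\t\n")
    assert parse_signalp(p)["A"] == (0.0, 0.0, 0.0, 1.0, 1.0, 0.0)


def test_missing_protein_in_one_predictor_is_an_error(tmp_path):
    ids = ["p0", "p1", "p2"]
    psortb, cello, signalp = _write_trio(tmp_path, ids)
    # rewrite cello without p1
    lines = cello.read_text().splitlines()
    cello.write_text("\n".join(ln for ln in lines if not ln.startswith("p1")) + "\n")
    with pytest.raises(ValueError, match="p1"):
        parse_predictor_outputs(psortb, cello, signalp)


def test_psortb_long_format(tmp_path):
    p = tmp_path / "psortb.txt"
    p.write_text(
        "SeqID: proteinA description here\n"
        "  Localization Scores:\n"
        "    Cytoplasmic      8.96\n"
        "    CytoplasmicMembrane  0.50\n"
        "    Cellwall         0.30\n"
        "    Extracellular    0.24\n"
        "  Final Prediction:\n"
        "    Cytoplasmic      8.96\n"
    )
    assert parse_psortb(p)["proteinA"] == (8.96, 0.50, 0.30, 0.24)


def test_cello_flexible_headers(tmp_path):
    p = tmp_path / "cello.tsv"
    p.write_text("seq\tcytoplasmic\tmembrane\twall\textracellular\nA\t1\t2\t3\t4\n")
    assert parse_cello(p)["A"] == (1.0, 2.0, 3.0, 4.0)


def test_fused_table_roundtrip(tmp_path):
    feats = [
        LocalizationFeatures(
            id=f"p{i}", psortb=(1.0, 2.0, 3.0, 4.0), cello=(0.1, 0.2, 0.3, 0.4),
            signalp=(0.5, 0.1, 0.1, 0.3, 0.3, 0.7),
        )
        for i in range(3)
    ]
    path = tmp_path / "fused.tsv"
    write_fused_table(feats, path)
    back = read_fused_table(path)
    assert [f.id for f in back] == ["p0", "p1", "p2"]
    np.testing.assert_allclose(back[0].vector(), feats[0].vector(), atol=1e-6)


def _features_from_matrix(X):
    return [
        LocalizationFeatures(
            id=f"p{i:03d}", psortb=tuple(row[:4]), cello=tuple(row[4:8]),
            signalp=tuple(row[8:14]),
        )
        for i, row in enumerate(X)
    ]


def test_collinear_points_put_all_variance_on_pc1():
    t = np.linspace(0, 1, 8)
    direction = np.arange(1, 15, dtype=float)
    X = np.outer(t, direction) + 5.0
    cfg = PipelineConfig(tsne_perplexity=2.0, tsne_iterations=250, random_seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = embed(_features_from_matrix(X), cfg)
    assert result.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(result.explained_variance_ratio) <= 1e-12)
    assert result.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)


def test_embedding_is_deterministic_for_a_seed():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 14))
    cfg = PipelineConfig(tsne_perplexity=10.0, tsne_iterations=300, random_seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = embed(_features_from_matrix(X), cfg)
        b = embed(_features_from_matrix(X), cfg)
    np.testing.assert_array_equal(a.tsne_coords, b.tsne_coords)
    np.testing.assert_array_equal(a.pca_coords, b.pca_coords)


def test_too_few_proteins_is_an_error():
    X = np.random.default_rng(0).normal(size=(4, 14))
    with pytest.raises(ValueError, match="at least 5"):
        embed(_features_from_matrix(X), PipelineConfig())


def test_perplexity_must_be_below_n():
    X = np.random.default_rng(0).normal(size=(10, 14))
    with pytest.raises(ValueError, match="perplexity"):
        embed(_features_from_matrix(X), PipelineConfig(tsne_perplexity=30.0))


def test_separated_blobs_stay_separated_in_tsne():
    rng = np.random.default_rng(1)
    blob_a = rng.normal(0.0, 0.3, size=(100, 14))
    blob_b = rng.normal(0.0, 0.3, size=(100, 14)) + 6.0
    X = np.vstack([blob_a, blob_b])
    cfg = PipelineConfig(random_seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = embed(_features_from_matrix(X), cfg)
    pts = result.tsne_coords
    ca, cb = pts[:100].mean(axis=0), pts[100:].mean(axis=0)
    gap = np.linalg.norm(ca - cb)
    radius_a = np.quantile(np.linalg.norm(pts[:100] - ca, axis=1), 0.95)
    radius_b = np.quantile(np.linalg.norm(pts[100:] - cb, axis=1), 0.95)
    assert gap > max(radius_a, radius_b)


def _embedding_from_coords(coords, ids=None):
    n = len(coords)
    ids = ids or [f"p{i:03d}" for i in range(n)]
    return EmbeddingResult(
        ids=ids, pca_coords=np.zeros((n, 2)),
        explained_variance_ratio=np.array([1.0]),
        loadings=np.zeros((14, 2)), feature_names=[], tsne_coords=np.asarray(coords),
    )


def test_dbscan_two_far_blobs_and_noise_point():
    rng = np.random.default_rng(2)
    blob_a = rng.uniform(0.0, 0.04, size=(50, 2))
    blob_b = rng.uniform(0.96, 1.0, size=(50, 2))
    lone = np.array([[0.5, 0.5]])
    emb = cluster_tsne(
        _embedding_from_coords(np.vstack([blob_a, blob_b, lone])),
        eps=0.05, min_samples=4,
    )
    labels = emb.dbscan_labels
    assert set(labels[:50]) == {0} or set(labels[:50]) == {1}
    assert len(set(labels[:100])) == 2
    assert labels[100] == -1


def test_all_identical_points_form_single_group():
    emb = cluster_tsne(
        _embedding_from_coords(np.full((10, 2), 0.5)), eps=0.05, min_samples=4
    )
    assert set(emb.dbscan_labels) == {0}


def test_group_renumbering_is_order_invariant():
    rng = np.random.default_rng(3)
    coords = np.vstack([
        rng.uniform(0.0, 0.03, size=(30, 2)),     # larger -> group 0
        rng.uniform(0.97, 1.0, size=(10, 2)),     # smaller -> group 1
    ])
    ids = [f"p{i:03d}" for i in range(40)]
    base = cluster_tsne(_embedding_from_coords(coords, ids), 0.05, 4)
    mapping = dict(zip(base.ids, base.dbscan_labels))
    perm = rng.permutation(40)
    shuffled = cluster_tsne(
        _embedding_from_coords(coords[perm], [ids[i] for i in perm]), 0.05, 4
    )
    assert dict(zip(shuffled.ids, shuffled.dbscan_labels)) == mapping
    assert mapping["p000"] == 0 and mapping["p035"] == 1


def test_group_composition_table():
    coords = np.vstack([np.full((4, 2), 0.1), np.full((4, 2), 0.9)])
    ids = [f"p{i}" for i in range(8)]
    emb = cluster_tsne(_embedding_from_coords(coords, ids), 0.05, 4)
    cats = {i: ("functional_keratinase" if int(i[1]) < 4 else "query") for i in ids}
    strains = {i: "G11C" for i in ids}
    table = group_composition(emb, cats, strains)
    assert set(table.columns) == {"tsne_group", "category", "strain", "count"}
    assert table["count"].sum() == 8
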