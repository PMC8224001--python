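"""Subcellular-localization feature fusion, embedding, and t-SNE groups.

Three predictors contribute a fused 14-feature score vector per protein:

* PSORTb: cytoplasmic, cytoplasmic-membrane, cell-wall, extracellular scores;
* CELLO:  the same four compartments on CELLO's own scale;
* SignalP (gram-positive): SP(Sec/SPI), TAT(Tat/SPI), LIPO(Sec/SPII), OTHER
  probabilities, plus two derived features — signal-peptide possibility
  = SP + TAT + LIPO, and intracellular = 1 - that sum.

The matrix is z-scored per feature, embedded with PCA (loadings reported) and
t-SNE at a fixed seed, both coordinate sets min-max normalized to [0, 1]^2,
and the t-SNE plane clustered with DBSCAN into "t-SNE groups".
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

COMPARTMENTS = ("cytoplasmic", "cytoplasmic_membrane", "cell_wall", "extracellular")
SIGNALP_RAW = ("SP(Sec/SPI)", "TAT(Tat/SPI)", "LIPO(Sec/SPII)", "OTHER")

FEATURE_NAMES = tuple(
    [f"psortb_{c}" for c in COMPARTMENTS]
    + [f"cello_{c}" for c in COMPARTMENTS]
    + ["signalp_sp", "signalp_tat", "signalp_lipo", "signalp_other",
       "signalp_intracellular", "signalp_possibility"]
)


@dataclass
class LocalizationFeatures:
    """The fused 14-dimensional localization score vector for one protein."""

    id: str
    psortb: tuple[float, float, float, float]
    cello: tuple[float, float, float, float]
    signalp: tuple[float, float, float, float, float, float]

    def vector(self) -> np.ndarray:
        v = np.array(self.psortb + self.cello + self.signalp, dtype=float)
        if v.shape != (14,) or not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite or malformed feature vector for {self.id}")
        return v


# ---------------------------------------------------------------------------
# predictor output parsers

_PSORTB_ALIASES = {
    "cytoplasmic": "cytoplasmic",
    "cytoplasmicmembrane": "cytoplasmic_membrane",
    "cellwall": "cell_wall",
    "extracellular": "extracellular",
}


def parse_psortb(path: str | Path) -> dict[str, tuple[float, float, float, float]]:
    """Parse PSORTb output: either the tab summary (header with *_Score
    columns) or the long-format report (``SeqID:`` blocks with a
    ``Localization Scores:`` section)."""
    with open(path) as fh:
        content = fh.read()
    stripped = content.lstrip()
    if stripped.startswith("SeqID:"):
        return _parse_psortb_long(content)
    return _parse_psortb_summary(content, path)


def _parse_psortb_summary(content, path) -> dict:
    lines = [ln for ln in content.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    col_of: dict[str, int] = {}
    for i, name in enumerate(header):
        key = re.sub(r"[ _]?score$", "", name.strip().lower()).replace("_", "").replace(" ", "")
        if key in _PSORTB_ALIASES:
            col_of[_PSORTB_ALIASES[key]] = i
    missing = [c for c in COMPARTMENTS if c not in col_of]
    if missing:
        raise ValueError(f"{path}: PSORTb summary lacks score columns {missing}")
    scores = {}
    for ln in lines[1:]:
        fields = ln.split("\t")
        pid = fields[0].split()[0]
        scores[pid] = tuple(float(fields[col_of[c]]) for c in COMPARTMENTS)
    return scores


def _parse_psortb_long(content: str) -> dict:
    scores: dict[str, tuple[float, float, float, float]] = {}
    current: str | None = None
    in_scores = False
    acc: dict[str, float] = {}
    for ln in content.splitlines() + ["SeqID: _end"]:
        if ln.startswith("SeqID:"):
            if current is not None:
                try:
                    scores[current] = tuple(acc[c] for c in COMPARTMENTS)
                except KeyError as err:
                    raise ValueError(
                        f"PSORTb long report for {current} lacks compartment {err}"
                    ) from None
            current = ln.split(":", 1)[1].strip().split()[0]
            in_scores = False
            acc = {}
        elif "Localization Scores:" in ln:
            in_scores = True
        elif in_scores:
            m = re.match(r"\s+(\w+)\s+([\d.]+)", ln)
            if m:
                key = m.group(1).strip().lower()
                if key in _PSORTB_ALIASES:
                    acc[_PSORTB_ALIASES[key]] = float(m.group(2))
            else:
                in_scores = False
    return scores


def parse_cello(path: str | Path) -> dict[str, tuple[float, float, float, float]]:
    """Parse a CELLO per-compartment score table (TSV with a header row)."""
    df = pd.read_csv(path, sep="\t")
    col_of = {}
    for col in df.columns[1:]:
        key = col.strip().lower().replace("membrane", "cytoplasmic_membrane") \
            if col.strip().lower() == "membrane" else col.strip().lower()
        key = {"wall": "cell_wall"}.get(key, key)
        if key in COMPARTMENTS:
            col_of[key] = col
    missing = [c for c in COMPARTMENTS if c not in col_of]
    if missing:
        raise ValueError(f"{path}: CELLO table lacks columns {missing}")
    id_col = df.columns[0]
    return {
        str(row[id_col]).split()[0]: tuple(float(row[col_of[c]]) for c in COMPARTMENTS)
        for _, row in df.iterrows()
    }


def parse_signalp(path: str | Path) -> dict[str, tuple[float, ...]]:
    """Parse SignalP 5 tabular output (gram-positive; four probability
    columns) and derive the intracellular and signal-possibility features."""
    scores: dict[str, tuple[float, ...]] = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            fields = ln.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: SignalP row with fewer than 6 columns: {ln!r}"
                )
            pid = fields[0].split()[0]
            sp, tat, lipo, other = (float(x) for x in fields[2:6])
            possibility = sp + tat + lipo
            scores[pid] = (sp, tat, lipo, other, 1.0 - possibility, possibility)
    return scores


def parse_predictor_outputs(
    psortb_path: str | Path, cello_path: str | Path, signalp_path: str | Path
) -> list[LocalizationFeatures]:
    """Fuse the three predictor outputs into 14-feature vectors.

    Every protein must be present in all three files; missing proteins are an
    error (no imputation).
    """
    psortb = parse_psortb(psortb_path)
    cello = parse_cello(cello_path)
    signalp = parse_signalp(signalp_path)
    union = sorted(set(psortb) | set(cello) | set(signalp))
    missing: dict[str, list[str]] = {}
    for name, table in (("psortb", psortb), ("cello", cello), ("signalp", signalp)):
        absent = [pid for pid in union if pid not in table]
        if absent:
            missing[name] = absent
    if missing:
        detail = "; ".join(f"{k}: {', '.join(v)}" for k, v in sorted(missing.items()))
        raise ValueError(f"proteins missing from predictor files ({detail})")
    return [
        LocalizationFeatures(
            id=pid, psortb=psortb[pid], cello=cello[pid], signalp=signalp[pid]
        )
        for pid in union
    ]


def read_fused_table(path: str | Path) -> list[LocalizationFeatures]:
    """Read a pre-fused TSV: id column plus the 14 named feature columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: fused table lacks feature columns {missing}")
    feats = []
    for _, row in df.iterrows():
        v = [float(row[c]) for c in FEATURE_NAMES]
        feats.append(
            LocalizationFeatures(
                id=str(row[df.columns[0]]),
                psortb=tuple(v[0:4]), cello=tuple(v[4:8]), signalp=tuple(v[8:14]),
            )
        )
    return feats


def write_fused_table(
    features: Sequence[LocalizationFeatures], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(FEATURE_NAMES) + "\n")
        for f in features:
            fh.write(f.id + "\t" + "\t".join(f"{x:.6g}" for x in f.vector()) + "\n")


# ---------------------------------------------------------------------------
# embedding

@dataclass
class EmbeddingResult:
    ids: list[str]
    pca_coords: np.ndarray            # (n, 2), min-max normalized
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray              # (n_features, 2)
    feature_names: list[str]
    tsne_coords: np.ndarray           # (n, 2), min-max normalized to [0,1]^2
    dbscan_labels: np.ndarray | None = None  # group int, -1 = noise


def _minmax(coords: np.ndarray) -> np.ndarray:
    lo = coords.min(axis=0)
    span = coords.max(axis=0) - lo
    span[span == 0.0] = 1.0
    return (coords - lo) / span


def embed(features: Sequence[LocalizationFeatures], config) -> EmbeddingResult:
    """Z-score, PCA (with loadings) and seeded t-SNE of the feature matrix.

    Zero-variance feature columns are dropped with a warning.  PCA loadings
    are eigenvectors scaled by the square root of their eigenvalues.  Both
    coordinate sets are min-max normalized.
    """
    n = len(features)
    if n < 5:
        raise ValueError(f"embedding needs at least 5 proteins, got {n}")
    if config.tsne_perplexity >= n:
        raise ValueError(
            f"tsne_perplexity ({config.tsne_perplexity}) must be smaller than "
            f"the number of embedded sequences ({n})"
        )
    if n < 4 * config.tsne_perplexity:
        warnings.warn(
            f"only {n} sequences for perplexity {config.tsne_perplexity}; "
            "t-SNE neighborhoods may be unstable", stacklevel=2,
        )
    ids = [f.id for f in features]
    X = np.vstack([f.vector() for f in features])
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0.0
    if not np.all(keep):
        dropped = [FEATURE_NAMES[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    names = [FEATURE_NAMES[i] for i in np.flatnonzero(keep)]

    pca = PCA(n_components=min(Z.shape), random_state=config.random_seed)
    scores = pca.fit_transform(Z)
    loadings = (
        pca.components_[:2].T * np.sqrt(pca.explained_variance_[:2])
    )
    tsne = TSNE(
        n_components=2,
        perplexity=config.tsne_perplexity,
        max_iter=config.tsne_iterations,
        init="random",
        random_state=config.random_seed,
    )
    tsne_coords = tsne.fit_transform(Z)
    return EmbeddingResult(
        ids=ids,
        pca_coords=_minmax(scores[:, :2]),
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=loadings,
        feature_names=names,
        tsne_coords=_minmax(tsne_coords),
    )


def cluster_tsne(
    embedding: EmbeddingResult, eps: float = 0.05, min_samples: int = 4
) -> EmbeddingResult:
    """DBSCAN on the normalized t-SNE plane; groups renumbered by size.

    Cluster labels are renumbered 0..k-1 by decreasing size (ties to the
    lexicographically smallest member id) so the labeling is invariant to
    input order; noise keeps -1.  Returns the embedding with labels set.
    """
    raw = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(
        embedding.tsne_coords
    )
    clusters: dict[int, list[str]] = {}
    for pid, lab in zip(embedding.ids, raw):
        if lab != -1:
            clusters.setdefault(int(lab), []).append(pid)
    order = sorted(
        clusters, key=lambda lab: (-len(clusters[lab]), min(clusters[lab]))
    )
    renumber = {old: new for new, old in enumerate(order)}
    embedding.dbscan_labels = np.array(
        [renumber.get(int(lab), -1) for lab in raw], dtype=int
    )
    return embedding


def group_composition(
    embedding: EmbeddingResult,
    categories: Mapping[str, str],
    strains: Mapping[str, str],
) -> pd.DataFrame:
    """Per-t-SNE-group composition by category and strain (long layout)."""
    if embedding.dbscan_labels is None:
        raise ValueError("run cluster_tsne before group_composition")
    df = pd.DataFrame(
        {
            "id": embedding.ids,
            "tsne_group": embedding.dbscan_labels,
            "category": [categories.get(i, "") for i in embedding.ids],
            "strain": [strains.get(i, "") for i in embedding.ids],
        }
    )
    table = (
        df.groupby(["tsne_group", "category", "strain"], sort=True)
        .size()
        .reset_index(name="count")
    )
    return table


def write_embedding_table(embedding: EmbeddingResult, path: str | Path) -> None:
    labels = (
        embedding.dbscan_labels
        if embedding.dbscan_labels is not None
        else np.full(len(embedding.ids), -1, dtype=int)
    )
    with open(path, "w") as fh:
        fh.write("id\tpca1\tpca2\ttsne1\ttsne2\ttsne_group\n")
        for i, pid in enumerate(embedding.ids):
            fh.write(
                f"{pid}\t{embedding.pca_coords[i,0]:.6f}\t{embedding.pca_coords[i,1]:.6f}"
                f"\t{embedding.tsne_coords[i,0]:.6f}\t{embedding.tsne_coords[i,1]:.6f}"
                f"\t{labels[i]}\n"
            )
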