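"""Genotype summaries, identity analysis and cultivar discrimination.

Operates on a wide genotype matrix (one row per sample: ``sample_id``,
``variety``, ``category``, then one column per marker holding ``a1/a2``
allele labels or missing). Provides allele counts and observed
heterozygosity, 0-mismatch identity analysis, the variety-discrimination
rule (two varieties are distinguishable only if *every* cross-variety plant
pair differs), PCA on allele dosages and UPGMA clustering on the leading
principal components, with nearest-centroid mislabel flagging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

__all__ = [
    "summarize", "identity_analysis", "variety_discrimination",
    "pca", "upgma", "flag_mislabels", "genotype_matrix_from_calls",
    "META_COLUMNS",
]

META_COLUMNS = ("sample_id", "variety", "category")


def genotype_matrix_from_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Pivot a genotype-call table into the wide sample x marker matrix.

    Heterozygote and homozygote calls become ``a1/a2`` cells; loci with no
    called allele (dropouts, null alleles) are left missing.
    """
    rows = calls[calls["allele1"].notna()].copy()
    rows["cell"] = rows["allele1"].astype(str) + "/" + \
        rows["allele2"].astype(str)
    index_cols = ["sample_id"]
    for c in ("variety", "category"):
        if c in rows.columns:
            index_cols.append(c)
    wide = rows.pivot_table(index=index_cols, columns="marker",
                            values="cell", aggfunc="first").reset_index()
    wide.columns.name = None
    if "variety" not in wide.columns:
        wide.insert(1, "variety", "")
    if "category" not in wide.columns:
        wide.insert(2, "category", "")
    return wide


def _marker_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c not in META_COLUMNS]


def _split_cell(cell) -> tuple[str, str] | None:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    a1, a2 = str(cell).split("/")
    return (a1, a2) if a1 <= a2 else (a2, a1)


def summarize(matrix: pd.DataFrame) -> dict:
    """Per-marker allele counts (N_al), allele frequencies and observed
    heterozygosity, plus overall means.

    H_Obs is the fraction of heterozygous samples among non-missing samples
    at the marker; frequencies are allele-dosage proportions over non-missing
    samples.
    """
    rows = []
    freqs: dict[str, dict[str, float]] = {}
    for marker in _marker_columns(matrix):
        cells = [_split_cell(c) for c in matrix[marker]]
        typed = [c for c in cells if c is not None]
        if not typed:
            raise ValueError(f"marker {marker} has no typed sample")
        counts: dict[str, int] = {}
        het = 0
        for a1, a2 in typed:
            counts[a1] = counts.get(a1, 0) + 1
            counts[a2] = counts.get(a2, 0) + 1
            het += a1 != a2
        total = 2 * len(typed)
        freqs[marker] = {a: c / total for a, c in sorted(counts.items())}
        rows.append({"marker": marker, "n_typed": len(typed),
                     "N_al": len(counts), "H_obs": het / len(typed)})
    per_marker = pd.DataFrame(rows).set_index("marker")
    return {"per_marker": per_marker, "frequencies": freqs,
            "mean_N_al": float(per_marker["N_al"].mean()),
            "median_N_al": float(per_marker["N_al"].median()),
            "mean_H_obs": float(per_marker["H_obs"].mean())}


def identity_analysis(matrix: pd.DataFrame,
                      min_overlap: int = 20) -> pd.DataFrame:
    """All-pairs 0-mismatch comparison.

    A pair is reported when every co-typed marker carries an identical
    unordered allele pair. Markers missing in either sample are skipped (a
    pair cannot mismatch on missing data) but counted: pairs with fewer than
    ``min_overlap`` co-typed markers are flagged low-confidence.
    """
    markers = _marker_columns(matrix)
    ids = matrix["sample_id"].tolist()
    varieties = matrix["variety"].tolist() if "variety" in matrix else \
        [""] * len(ids)
    profiles = [[_split_cell(matrix.iloc[i][m]) for m in markers]
                for i in range(len(matrix))]
    out = []
    n = len(ids)
    for i in range(n):
        pi = profiles[i]
        for j in range(i + 1, n):
            pj = profiles[j]
            overlap = 0
            match = True
            for gi, gj in zip(pi, pj):
                if gi is None or gj is None:
                    continue
                overlap += 1
                if gi != gj:
                    match = False
                    break
            if match:
                out.append({"sample_a": ids[i], "sample_b": ids[j],
                            "variety_a": varieties[i],
                            "variety_b": varieties[j],
                            "co_typed": overlap,
                            "low_confidence": overlap < min_overlap})
    return pd.DataFrame(out, columns=["sample_a", "sample_b", "variety_a",
                                      "variety_b", "co_typed",
                                      "low_confidence"])


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def variety_discrimination(matrix: pd.DataFrame,
                           identity_pairs: pd.DataFrame) -> dict:
    """Variety distinguishability under the all-plants rule.

    Two varieties are indistinguishable iff at least one cross-variety
    0-mismatch pair exists (one variety differs from another only if *all*
    its plants differ from all of the other's). Indistinguishable varieties
    are grouped as connected components of the indistinguishability graph;
    the number of distinguishable units is the number of components.
    """
    varieties = sorted(matrix["variety"].unique())
    dist = pd.DataFrame(True, index=varieties, columns=varieties)
    uf = _UnionFind(varieties)
    for p in identity_pairs.itertuples(index=False):
        if p.variety_a != p.variety_b:
            dist.loc[p.variety_a, p.variety_b] = False
            dist.loc[p.variety_b, p.variety_a] = False
            uf.union(p.variety_a, p.variety_b)
    components: dict[str, list[str]] = {}
    for v in varieties:
        components.setdefault(uf.find(v), []).append(v)
    groups = sorted((sorted(g) for g in components.values() if len(g) > 1),
                    key=len, reverse=True)
    return {"distinguishable": dist,
            "groups": groups,
            "n_units": len(components),
            "n_varieties": len(varieties)}


def _dosage_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Allele-indicator expansion: one column per (marker, allele) holding
    the allele dosage 0/1/2; missing genotypes become the marker's mean
    dosage after centering (i.e. zeros)."""
    cols = {}
    for marker in _marker_columns(matrix):
        cells = [_split_cell(c) for c in matrix[marker]]
        alleles = sorted({a for cell in cells if cell for a in cell})
        for a in alleles:
            cols[f"{marker}:{a}"] = [
                (0 if cell is None else (cell[0] == a) + (cell[1] == a))
                for cell in cells]
    return pd.DataFrame(cols, index=matrix["sample_id"])


def pca(matrix: pd.DataFrame, n_components: int | None = None,
        scale: bool = False) -> dict:
    """PCA on centered allele-dosage columns.

    Columns are 0/1/2 allele dosages, column-centered (unscaled by default;
    binary dosage columns have comparable variance). The sign of each
    component is fixed so its largest-|loading| entry is positive, making
    scores reproducible across runs. All-identical input has zero variance
    and yields no components.
    """
    dosage = _dosage_matrix(matrix)
    X = dosage.to_numpy(float)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = X / sd
    if not np.any(X):
        return {"scores": pd.DataFrame(index=dosage.index),
                "explained_variance_ratio": np.array([]),
                "loadings": pd.DataFrame(index=dosage.columns)}
    k = min(n_components or min(X.shape), min(X.shape))
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_
    for c in range(loadings.shape[0]):
        imax = int(np.argmax(np.abs(loadings[c])))
        if loadings[c, imax] < 0:
            loadings[c] *= -1
            scores[:, c] *= -1
    nz = model.explained_variance_ > 1e-12
    scores = scores[:, nz]
    loadings = loadings[nz]
    names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return {"scores": pd.DataFrame(scores, index=dosage.index,
                                   columns=names),
            "explained_variance_ratio":
                model.explained_variance_ratio_[nz],
            "loadings": pd.DataFrame(loadings, columns=dosage.columns,
                                     index=names)}


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class _Node:
    members: tuple[str, ...]
    height: float
    children: tuple | None = None  # (left, right) or None for a leaf
    label: str = ""

    def newick(self) -> str:
        if self.children is None:
            return self.label
        l, r = self.children
        return (f"({l.newick()}:{self.height - l.height:.6g},"
                f"{r.newick()}:{self.height - r.height:.6g})")


def upgma(scores: pd.DataFrame, n_axes: int = 3,
          n_clusters: int = 4) -> dict:
    """UPGMA (average linkage) on Euclidean distances over the first
    ``n_axes`` score columns.

    Ties are broken deterministically by merging the pair whose (sorted)
    member-label tuples are lexicographically smallest. Returns the newick
    string, the merge history, cophenetic distances and flat clusters from
    cutting the tree into ``n_clusters`` groups.
    """
    if len(scores) < 2:
        raise ValueError("UPGMA needs at least 2 samples")
    labels = [str(i) for i in scores.index]
    X = scores.iloc[:, :n_axes].to_numpy(float)
    D = squareform(pdist(X))
    nodes: dict[int, _Node] = {
        i: _Node(members=(labels[i],), height=0.0, label=labels[i])
        for i in range(len(labels))}
    sizes = {i: 1 for i in nodes}
    dist = {(i, j): D[i, j] for i in nodes for j in nodes if i < j}
    merges = []
    next_id = len(labels)
    while len(nodes) > 1:
        best_key = min(
            dist,
            key=lambda k: (dist[k],
                           min(nodes[k[0]].members + nodes[k[1]].members),
                           sorted(nodes[k[0]].members + nodes[k[1]].members)))
        i, j = best_key
        d = dist[best_key]
        new = _Node(members=tuple(sorted(nodes[i].members
                                         + nodes[j].members)),
                    height=d / 2.0, children=(nodes[i], nodes[j]))
        merges.append((nodes[i].members, nodes[j].members, d))
        ni, nj = sizes[i], sizes[j]
        for k in list(nodes):
            if k in (i, j):
                continue
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            dik, djk = dist.pop(a), dist.pop(b)
            dist[(min(k, next_id), max(k, next_id))] = \
                (ni * dik + nj * djk) / (ni + nj)
        del dist[best_key]
        del nodes[i], nodes[j], sizes[i], sizes[j]
        nodes[next_id] = new
        sizes[next_id] = ni + nj
        next_id += 1
    root = next(iter(nodes.values()))
    # flat clusters: cut the merge sequence after (n - n_clusters) merges
    n = len(labels)
    uf = _UnionFind(labels)
    for a, b, _ in merges[:max(0, n - n_clusters)]:
        uf.union(a[0], b[0])
    flat = {lab: uf.find(lab) for lab in labels}
    roots = {r: c + 1 for c, r in enumerate(sorted(set(flat.values())))}
    clusters = {lab: roots[r] for lab, r in flat.items()}
    # cophenetic distances from merge heights
    coph = pd.DataFrame(0.0, index=labels, columns=labels)
    for a, b, d in merges:
        for x in a:
            for y in b:
                coph.loc[x, y] = coph.loc[y, x] = d
    return {"newick": root.newick() + ";", "merges": merges,
            "clusters": clusters, "cophenetic": coph}


def flag_mislabels(scores: pd.DataFrame, varieties: pd.Series,
                   margin: float = 0.0, atol: float = 1e-8) -> pd.DataFrame:
    """Nearest-centroid mislabel screen in score space.

    A sample is flagged when its distance to its own variety's centroid
    (computed excluding the sample itself) exceeds the distance to some
    other variety's centroid by more than ``margin``. Varieties with fewer
    than 2 samples cannot provide a leave-one-out centroid and are skipped.
    """
    X = scores.to_numpy(float)
    labels = list(scores.index)
    var = varieties.reindex(scores.index)
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for i, v in enumerate(var):
        sums[v] = sums.get(v, 0) + X[i]
        counts[v] = counts.get(v, 0) + 1
    rows = []
    for i, sid in enumerate(labels):
        v = var.iloc[i]
        if counts[v] < 2:
            continue
        own_centroid = (sums[v] - X[i]) / (counts[v] - 1)
        d_own = float(np.linalg.norm(X[i] - own_centroid))
        best_other, d_other = None, np.inf
        for w in counts:
            if w == v:
                continue
            c = sums[w] / counts[w]
            d = float(np.linalg.norm(X[i] - c))
            if d < d_other:
                best_other, d_other = w, d
        if best_other is not None and d_own > d_other + margin + atol:
            rows.append({"sample_id": sid, "labelled_variety": v,
                         "nearest_variety": best_other,
                         "d_own": d_own, "d_nearest": d_other})
    return pd.DataFrame(rows, columns=["sample_id", "labelled_variety",
                                       "nearest_variety", "d_own",
                                       "d_nearest"])
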