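"""Two-profile partition of the reference map and v-test characterization.

The reference evaluations' map coordinates are clustered by Ward-linkage
agglomeration cut at two clusters, then consolidated by k-means initialized
at the Ward centroids (the usual hierarchical-clustering-on-principal-
components recipe).  Each cluster is described by the categories
significantly over-represented among its evaluations relative to a random
draw: a category's two-tailed hypergeometric p-value is mapped to the
standard-normal scale (the *v-test*), and values above 1.96 flag
characterizing categories.  The cluster in which the positive categories
emerge is labelled *green* ("positively accepted" profile), the other *red*
("negatively accepted").  Any point of the map is then classified by its
nearest consolidated centroid, ties resolved to red (worst case).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom, norm
from sklearn.cluster import KMeans

from .imputation import IndicatorMatrix

__all__ = [
    "ClusterModel",
    "PolarityError",
    "cluster_reference",
    "vtest_categories",
    "assign_polarity",
    "classify_point",
    "vtest",
]

VTEST_THRESHOLD = 1.96


class PolarityError(RuntimeError):
    """The two clusters cannot be told apart as green/red."""


@dataclass
class ClusterModel:
    assignments: np.ndarray                      # (n_ref,) values in {1, 2}
    centroids: np.ndarray                        # (2, ndim), row k-1 is cluster k
    vtests: pd.DataFrame | None = None           # columns: cluster, category, n_kj, n_k, n_j, N, v
    polarity: dict[int, str] | None = None       # {1: "green"/"red", 2: ...}
    vtest_threshold: float = VTEST_THRESHOLD
    map_fingerprint: str | None = None

    def centroid_of(self, label: str) -> np.ndarray:
        if self.polarity is None:
            raise PolarityError("polarity not assigned yet")
        for k, lab in self.polarity.items():
            if lab == label:
                return self.centroids[k - 1]
        raise KeyError(label)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "assignments": self.assignments.tolist(),
            "centroids": self.centroids.tolist(),
            "vtests": None if self.vtests is None else self.vtests.to_dict(orient="list"),
            "polarity": None if self.polarity is None
            else {str(k): v for k, v in self.polarity.items()},
            "vtest_threshold": self.vtest_threshold,
            "map_fingerprint": self.map_fingerprint,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        d = json.loads(Path(path).read_text())
        return cls(
            assignments=np.asarray(d["assignments"], dtype=int),
            centroids=np.asarray(d["centroids"]),
            vtests=None if d["vtests"] is None else pd.DataFrame(d["vtests"]),
            polarity=None if d["polarity"] is None
            else {int(k): v for k, v in d["polarity"].items()},
            vtest_threshold=float(d["vtest_threshold"]),
            map_fingerprint=d.get("map_fingerprint"),
        )


def cluster_reference(amap, k: int = 2) -> ClusterModel:
    """Ward clustering of the reference row coordinates with k-means consolidation.

    The k-means step is deterministically initialized at the Ward-cut
    centroids (no random restarts), so consolidation can only reduce the
    within-cluster sum of squares.
    """
    X = np.asarray(amap.row_coords, dtype=float)
    if np.allclose(X, X[0]):
        raise ValueError("all reference rows identical: no partition exists")
    tree = linkage(X, method="ward")
    cut = fcluster(tree, t=k, criterion="maxclust")
    if len(np.unique(cut)) < k:
        raise ValueError(f"Ward cut produced fewer than {k} clusters")
    init = np.vstack([X[cut == g].mean(axis=0) for g in range(1, k + 1)])
    km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=300).fit(X)
    assignments = km.labels_ + 1
    if len(np.unique(assignments)) < k:
        raise ValueError("consolidation emptied a cluster")
    centroids = np.vstack([X[assignments == g].mean(axis=0) for g in range(1, k + 1)])
    return ClusterModel(
        assignments=assignments,
        centroids=centroids,
        map_fingerprint=amap.fingerprint() if hasattr(amap, "fingerprint") else None,
    )


def vtest(N: int, n_j: int, n_k: int, n_kj: int) -> float:
    """Signed v-test of category over-representation in a cluster.

    Two-tailed exact p-value from the hypergeometric law of the in-cluster
    count ``n_kj`` given cluster size ``n_k``, overall category count ``n_j``
    and corpus size ``N`` (summing the probabilities of all outcomes no more
    likely than the observed one), mapped through the standard-normal
    quantile and signed by the direction of the deviation.
    """
    if n_j <= 0 or n_j > N:
        return float("nan")
    rv = hypergeom(N, n_j, n_k)
    lo = max(0, n_k + n_j - N)
    hi = min(n_k, n_j)
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(n_kj)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = min(p, 1.0)
    direction = n_kj / n_k - n_j / N
    if direction == 0 or p >= 1.0:
        return 0.0
    v = float(np.sign(direction) * norm.isf(p / 2))
    return 0.0 if abs(v) < 1e-12 else v


def vtest_categories(model: ClusterModel, indicator: IndicatorMatrix) -> pd.DataFrame:
    """v-tests of every category in every cluster (crisp counts by argmax)."""
    cb = indicator.codebook
    Z = indicator.values
    N = indicator.n_rows
    if N != len(model.assignments):
        raise ValueError("indicator rows do not align with cluster assignments")
    rows = []
    slices = cb.block_slices()
    # crisp category per (row, variable): argmax within the block
    crisp = np.zeros_like(Z, dtype=bool)
    for var, sl in slices.items():
        block = Z[:, sl]
        crisp[np.arange(N), sl.start + block.argmax(axis=1)] = True
    labels = cb.column_labels()
    counts_total = crisp.sum(axis=0)
    for k in sorted(np.unique(model.assignments)):
        members = model.assignments == k
        n_k = int(members.sum())
        counts_k = crisp[members].sum(axis=0)
        for j, lab in enumerate(labels):
            n_j = int(counts_total[j])
            if n_j == 0:
                continue  # v undefined: category absent from the corpus
            rows.append({
                "cluster": int(k), "category": lab,
                "n_kj": int(counts_k[j]), "n_k": n_k, "n_j": n_j, "N": N,
                "v": vtest(N, n_j, n_k, int(counts_k[j])),
            })
    table = pd.DataFrame(rows)
    model.vtests = table
    return table


def assign_polarity(
    model: ClusterModel,
    vtests: pd.DataFrame | None = None,
    positive_category_set: set[str] | None = None,
) -> ClusterModel:
    """Label the cluster where the positive categories emerge as green.

    ``positive_category_set`` holds ``variable:category`` labels; by default
    the nine trouble-free categories of the standard codebook.  The cluster
    with the greater number of positive categories at v above the threshold
    is green, the other red; a tie (including none passing) is an error, as
    the reference corpus then does not support an acceptability reading.
    """
    if vtests is None:
        vtests = model.vtests
    if vtests is None:
        raise ValueError("v-tests not computed")
    if positive_category_set is None:
        from .schema import DEFAULT_CODEBOOK

        positive_category_set = {
            f"{v}:{c}" for v, c in DEFAULT_CODEBOOK.positive_categories()
        }
    counts: dict[int, int] = {}
    for k in sorted(vtests["cluster"].unique()):
        sub = vtests[(vtests["cluster"] == k) & (vtests["v"] > model.vtest_threshold)]
        counts[int(k)] = int(sub["category"].isin(positive_category_set).sum())
    if len(counts) != 2:
        raise PolarityError("polarity needs exactly two clusters")
    (k1, c1), (k2, c2) = counts.items()
    if c1 == c2:
        raise PolarityError(
            f"clusters tied at {c1} positive characterizing categories; "
            "reference corpus unusable for polarity"
        )
    green = k1 if c1 > c2 else k2
    model.polarity = {k: ("green" if k == green else "red") for k in counts}
    return model


def classify_point(model: ClusterModel, coordinate: np.ndarray) -> str:
    """Green/red label of a map point by nearest consolidated centroid.

    An exact tie goes to red: the worst case for acceptability.
    """
    if model.polarity is None:
        raise PolarityError("polarity not assigned yet")
    x = np.asarray(coordinate, dtype=float)
    d = np.linalg.norm(model.centroids - x, axis=1)
    labels = [model.polarity[k] for k in (1, 2)]
    if d[0] == d[1]:
        return "red"
    return labels[int(np.argmin(d))]


def classify_points(model: ClusterModel, coords: np.ndarray) -> np.ndarray:
    """Vectorized :func:`classify_point` over an (m, ndim) array."""
    if model.polarity is None:
        raise PolarityError("polarity not assigned yet")
    X = np.atleast_2d(np.asarray(coords, dtype=float))
    d = np.linalg.norm(X[:, None, :] - model.centroids[None, :, :], axis=2)
    labels = np.array([model.polarity[1], model.polarity[2]])
    out = labels[(d[:, 1] < d[:, 0]).astype(int)]
    out[d[:, 0] == d[:, 1]] = "red"
    return out
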