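"""The acceptability reference framework: an MCA map with supplementary projection.

A reference corpus of intake evaluations, disjunctively coded, is summarized
by multiple correspondence analysis — performed as a correspondence analysis
of the indicator matrix itself — into a low-dimensional Euclidean map (three
dimensions by default).  Proximity on the map expresses similarity: category
points that are often ticked together lie close, and evaluations completed
in a comparable manner converge.  Evaluations of a medicine under study are
then *projected* onto the fitted map as supplementary rows, with no
influence on the factorial solution, via the correspondence-analysis
transition formula.

Conventions.  Let Z be the n x J indicator (rows may be fuzzy but each
variable block sums to 1, so every row sums to Q = 9).  With P = Z/(nQ),
row masses r_i = 1/n and column masses c_j, the standardized residuals
S = D_r^{-1/2} (P - r c^T) D_c^{-1/2} are SVD-decomposed; eigenvalues are
the squared singular values, and rows/categories get principal coordinates
F = D_r^{-1/2} U Sigma and G = D_c^{-1/2} V Sigma.  The total inertia of a
complete indicator matrix is J/Q - 1.  Each axis is oriented so that the
"fully taken" category lies on the non-positive side: the negative side of
every dimension is the *positive*-acceptability side.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .schema import Codebook, DEFAULT_CODEBOOK
from .imputation import IndicatorMatrix

__all__ = ["AcceptabilityMap", "fit_mca", "project_rows"]


@dataclass
class AcceptabilityMap:
    """A fitted MCA basis: eigenvalues, coordinates and a projection operator."""

    eigenvalues: np.ndarray              # (ndim,) retained eigenvalues, descending
    category_coords: np.ndarray          # (J_kept, ndim) principal coordinates
    category_masses: np.ndarray          # (J_kept,) column masses c_j
    row_coords: np.ndarray               # (n_ref, ndim) reference principal coordinates
    column_labels: list[str]             # labels of kept columns
    kept_columns: np.ndarray             # indices into the codebook's J columns
    ndim: int
    n_ref: int
    total_inertia: float
    codebook: Codebook = field(default_factory=lambda: DEFAULT_CODEBOOK)

    @property
    def n_variables(self) -> int:
        return len(self.codebook.variables)

    def fingerprint(self) -> str:
        """A stable identity token used to refuse cross-map comparisons."""
        h = np.concatenate([self.eigenvalues, [self.n_ref, self.total_inertia]])
        return np.array2string(np.round(h, 10), separator=",")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "eigenvalues": self.eigenvalues.tolist(),
            "category_coords": self.category_coords.tolist(),
            "category_masses": self.category_masses.tolist(),
            "row_coords": self.row_coords.tolist(),
            "column_labels": self.column_labels,
            "kept_columns": self.kept_columns.tolist(),
            "ndim": self.ndim,
            "n_ref": self.n_ref,
            "total_inertia": self.total_inertia,
            "codebook": self.codebook.to_dict(),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "AcceptabilityMap":
        d = json.loads(Path(path).read_text())
        return cls(
            eigenvalues=np.asarray(d["eigenvalues"]),
            category_coords=np.asarray(d["category_coords"]),
            category_masses=np.asarray(d["category_masses"]),
            row_coords=np.asarray(d["row_coords"]),
            column_labels=list(d["column_labels"]),
            kept_columns=np.asarray(d["kept_columns"], dtype=int),
            ndim=int(d["ndim"]),
            n_ref=int(d["n_ref"]),
            total_inertia=float(d["total_inertia"]),
            codebook=Codebook.from_dict(d["codebook"]),
        )


def fit_mca(indicator: IndicatorMatrix, ndim: int = 3) -> AcceptabilityMap:
    """Fit the correspondence analysis of an indicator matrix.

    Categories with zero total mass are dropped with a warning (their
    coordinates are undefined).  Raises if fewer than ``ndim`` positive
    eigenvalues remain.
    """
    cb = indicator.codebook
    Z = np.asarray(indicator.values, dtype=float)
    n, J = Z.shape
    if n < ndim + 1:
        raise ValueError(f"need at least ndim+1={ndim + 1} rows, got {n}")
    indicator.check_normalized()

    col_sums = Z.sum(axis=0)
    kept = np.flatnonzero(col_sums > 0)
    if kept.size < J:
        dropped = [cb.column_labels()[j] for j in np.flatnonzero(col_sums == 0)]
        warnings.warn(f"dropping zero-mass categories: {dropped}", stacklevel=2)
    Zk = Z[:, kept]

    total = Zk.sum()
    P = Zk / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    sr, sc = np.sqrt(r), np.sqrt(c)
    S = (P - np.outer(r, c)) / np.outer(sr, sc)
    U, sig, Vt = np.linalg.svd(S, full_matrices=False)
    lam = sig**2
    if int((lam > 1e-12).sum()) < ndim:
        raise ValueError(f"indicator matrix has rank < {ndim}")

    F = (U * sig) / sr[:, None]          # row principal coordinates
    G = (Vt.T * sig) / sc[:, None]       # category principal coordinates

    # orient: "fully taken" on the non-positive side of every dimension
    labels = [cb.column_labels()[j] for j in kept]
    try:
        anchor = labels.index("result_intake:fully_taken")
    except ValueError:
        anchor = None
    for s in range(ndim):
        if anchor is not None and G[anchor, s] > 0:
            F[:, s] *= -1.0
            G[:, s] *= -1.0

    return AcceptabilityMap(
        eigenvalues=lam[:ndim].copy(),
        category_coords=G[:, :ndim].copy(),
        category_masses=c.copy(),
        row_coords=F[:, :ndim].copy(),
        column_labels=labels,
        kept_columns=kept,
        ndim=ndim,
        n_ref=n,
        total_inertia=float(lam.sum()),
        codebook=cb,
    )


def project_rows(amap: AcceptabilityMap, indicator_rows: np.ndarray) -> np.ndarray:
    """Project supplementary indicator rows onto a fitted map.

    Applies the transition formula: the supplementary row profile (its
    indicator entries over the kept columns, normalized to sum one) is
    combined with the category principal coordinates and rescaled by
    1/sqrt(eigenvalue) per dimension, yielding principal coordinates
    directly comparable to the reference rows' (projecting a reference row
    reproduces its fitted coordinates).
    """
    rows = np.atleast_2d(np.asarray(indicator_rows, dtype=float))
    if rows.shape[1] == len(amap.codebook.column_labels()):
        dropped_mass = rows.sum(axis=1) - rows[:, amap.kept_columns].sum(axis=1)
        if (dropped_mass > 0).any():
            warnings.warn(
                "supplementary rows carry mass on categories dropped at fit time; "
                "that mass is ignored",
                stacklevel=2,
            )
        rows = rows[:, amap.kept_columns]
    elif rows.shape[1] != len(amap.column_labels):
        raise ValueError(
            f"supplementary rows have {rows.shape[1]} columns, "
            f"expected {len(amap.codebook.column_labels())}"
        )
    sums = rows.sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        raise ValueError("supplementary row with no mass")
    profiles = rows / sums
    return (profiles @ amap.category_coords) / np.sqrt(amap.eigenvalues)
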