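"""Missing-category imputation by regularized iterative MCA.

Evaluations are coded as a disjunctive (indicator) matrix: one 0/1 column
per category, grouped in blocks of its nine variables, each block summing
to one per row.  Missing cells are initialized at the observed column
proportions of their variable and then refined by alternating a truncated
(optionally regularized) multiple correspondence analysis of the current
matrix with reconstruction of the missing cells only, until the filled
values stabilise.  The procedure exploits both similarities between
evaluations and associations between variables; the fitted memberships are
kept (fuzzy indicator) and each missing cell is also resolved to its most
plausible category (per-variable argmax, worst-for-acceptability on ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .schema import Codebook, DEFAULT_CODEBOOK, Evaluation

__all__ = ["IndicatorMatrix", "ImputationResult", "build_indicator", "impute_iterative_mca"]


@dataclass
class IndicatorMatrix:
    """Evaluations x categories membership matrix with a missingness mask.

    ``values[i, j]`` is the membership of evaluation ``i`` in category column
    ``j``; within each variable's block of columns the memberships of a row
    sum to one.  ``missing_mask`` records the (row index, variable) cells
    that were originally unobserved.
    """

    values: np.ndarray
    row_ids: list[tuple[str, str]]
    codebook: Codebook
    missing_mask: set[tuple[int, str]]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def column_labels(self) -> list[str]:
        return self.codebook.column_labels()

    def check_normalized(self, atol: float = 1e-10) -> None:
        for var, sl in self.codebook.block_slices().items():
            sums = self.values[:, sl].sum(axis=1)
            if not np.allclose(sums, 1.0, atol=atol):
                raise ValueError(f"memberships for {var!r} do not sum to 1")


@dataclass
class ImputationResult:
    fuzzy: IndicatorMatrix
    completed: list[Evaluation]
    n_imputed: int
    iterations_used: int
    converged: bool


def build_indicator(
    evaluations: Sequence[Evaluation], codebook: Codebook = DEFAULT_CODEBOOK
) -> IndicatorMatrix:
    """Disjunctive coding of evaluations, with proportion-filled missing cells.

    Observed cells are one-hot over their variable's categories; a missing
    cell starts at the observed column proportions of that variable (uniform
    when the variable is never observed), which is also the deterministic
    initialization of the iterative imputation.
    """
    n = len(evaluations)
    J = codebook.n_categories
    Z = np.zeros((n, J))
    mask: set[tuple[int, str]] = set()
    slices = codebook.block_slices()
    for i, ev in enumerate(evaluations):
        for var in codebook.variables:
            cat = ev.measures.get(var)
            if cat is None:
                mask.add((i, var))
            else:
                codebook.validate_category(var, cat)
                Z[i, codebook.column_index(var, cat)] = 1.0
    for var, sl in slices.items():
        rows = [i for (i, v) in mask if v == var]
        if not rows:
            continue
        observed = np.ones(n, dtype=bool)
        observed[rows] = False
        if observed.any():
            props = Z[observed, sl].sum(axis=0)
            props = props / props.sum() if props.sum() > 0 else None
        else:
            props = None
        if props is None:
            props = np.full(sl.stop - sl.start, 1.0 / (sl.stop - sl.start))
        Z[rows, sl] = props
    return IndicatorMatrix(values=Z, row_ids=[(e.patient_id, e.day) for e in evaluations],
                           codebook=codebook, missing_mask=mask)


def _mca_reconstruct(Z: np.ndarray, Q: int, ncp: int, regularized: bool) -> np.ndarray:
    """Rank-``ncp`` CA reconstruction of an indicator matrix.

    Standardized residuals of the correspondence matrix are truncated by SVD
    (singular values shrunk toward the mean residual eigenvalue when
    ``regularized``) and mapped back to the indicator scale.
    """
    n, J = Z.shape
    total = Z.sum()
    P = Z / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    sr = np.sqrt(r)
    sc = np.sqrt(np.where(c > 0, c, 1.0))
    S = (P - np.outer(r, c)) / np.outer(sr, sc)
    S[:, c == 0] = 0.0
    U, sig, Vt = np.linalg.svd(S, full_matrices=False)
    ncp = min(ncp, len(sig))
    if regularized:
        lam = sig**2
        # rank bound of indicator-matrix CA residuals: J - Q (one constraint per variable)
        rank = max(int((lam > 1e-12).sum()), ncp)
        resid = lam[ncp:rank]
        mean_resid = resid.mean() if resid.size else 0.0
        shrunk = np.where(sig[:ncp] > 0, (lam[:ncp] - mean_resid) / np.where(sig[:ncp] > 0, sig[:ncp], 1.0), 0.0)
        shrunk = np.clip(shrunk, 0.0, None)
    else:
        shrunk = sig[:ncp]
    low = (U[:, :ncp] * shrunk) @ Vt[:ncp]
    P_hat = np.outer(r, c) + np.outer(sr, sc) * low
    return P_hat * total


def impute_iterative_mca(
    indicator: IndicatorMatrix,
    ncp: int = 3,
    tol: float = 1e-6,
    max_iter: int = 1000,
    regularized: bool = True,
) -> ImputationResult:
    """Iteratively impute missing cells of a disjunctive matrix.

    Alternates (a) MCA of the current matrix at rank ``ncp``, (b) low-rank
    reconstruction of the indicator, and (c) overwriting of the missing cells
    with the reconstruction, clipped at zero and renormalized per variable,
    until the summed squared change on missing cells drops below ``tol`` or
    ``max_iter`` is reached.  Observed cells are never altered.
    """
    cb = indicator.codebook
    Q = len(cb.variables)
    n = indicator.n_rows
    if ncp < 1 or ncp >= min(n - 1, cb.n_categories - Q):
        raise ValueError(f"ncp={ncp} outside [1, min(n-1, J-Q)) for n={n}")
    if tol <= 0:
        raise ValueError("tol must be positive")

    Z = indicator.values.copy()
    slices = cb.block_slices()
    mask = np.zeros_like(Z, dtype=bool)
    for i, var in indicator.missing_mask:
        mask[i, slices[var]] = True

    iterations = 0
    converged = True
    if mask.any():
        converged = False
        for iterations in range(1, max_iter + 1):
            Z_hat = _mca_reconstruct(Z, Q, ncp, regularized)
            Z_new = Z.copy()
            Z_new[mask] = np.clip(Z_hat[mask], 0.0, None)
            for i, var in indicator.missing_mask:
                sl = slices[var]
                s = Z_new[i, sl].sum()
                if s > 0:
                    Z_new[i, sl] /= s
                else:  # degenerate reconstruction: fall back to uniform
                    Z_new[i, sl] = 1.0 / (sl.stop - sl.start)
            delta = float(((Z_new - Z)[mask] ** 2).sum())
            Z = Z_new
            if delta < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"iterative MCA imputation did not converge in {max_iter} iterations",
                stacklevel=2,
            )

    fuzzy = IndicatorMatrix(
        values=Z, row_ids=list(indicator.row_ids), codebook=cb,
        missing_mask=set(indicator.missing_mask),
    )
    completed: list[Evaluation] = []
    for i, (pid, day) in enumerate(indicator.row_ids):
        measures: dict[str, str | None] = {}
        for var in cb.variables:
            sl = slices[var]
            if (i, var) in indicator.missing_mask:
                block = Z[i, sl]
                best = block.max()
                candidates = [
                    cb.categories[var][k] for k in range(len(block))
                    if block[k] >= best - 1e-12
                ]
                measures[var] = cb.worst_of(var, candidates)
            else:
                k = int(np.argmax(indicator.values[i, sl]))
                measures[var] = cb.categories[var][k]
        completed.append(Evaluation(pid, day, measures))

    return ImputationResult(
        fuzzy=fuzzy,
        completed=completed,
        n_imputed=len(indicator.missing_mask),
        iterations_used=iterations,
        converged=converged,
    )
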