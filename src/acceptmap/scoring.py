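"""Acceptability scoring: barycenter, confidence ellipses and classification.

A medicine (or a subgroup of its evaluations) is positioned at the
*barycenter* of its evaluations' supplementary coordinates on the reference
map.  For every pair of map dimensions, a confidence ellipse around the
barycenter delimits the area containing its true position with the chosen
probability (90% by default) if the experiment were repeated: the sample
covariance of the two coordinate columns divided by the number of
evaluations, inflated by the chi-square(2) quantile — the standard
normal-theory confidence region for a mean.  Each ellipse is traced by
``n_points`` boundary points (1000 by default).  The barycenter and every
ellipse point are assigned to the green or red profile; the medicine is
classified *positively accepted* only if the barycenter and the entire set
of ellipse points lie in the green area.  Two scores differ significantly
when their confidence ellipses are disjoint in at least one plane of the
map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2
from shapely.geometry import Polygon

from .framework import AcceptabilityMap, project_rows
from .imputation import build_indicator
from .profiling import ClusterModel, classify_point, classify_points
from .schema import Evaluation, PatientRecord

__all__ = [
    "AcceptabilityScore",
    "ComparisonResult",
    "SubgroupReport",
    "SampleSizeError",
    "MIN_EVALUATIONS",
    "confidence_ellipses",
    "score_medicine",
    "compare_scores",
    "score_subgroups",
]

#: minimum number of evaluations for a reliable acceptability score
MIN_EVALUATIONS = 30

SUBGROUP_KEYS = ("day", "sex", "age", "exposure")


class SampleSizeError(ValueError):
    """Fewer evaluations than the reliability floor, without an override."""


@dataclass
class AcceptabilityScore:
    label: str
    n_evals: int
    barycenter: np.ndarray                              # (ndim,)
    ellipses: dict[tuple[int, int], np.ndarray]         # plane -> (n_points, ndim)
    membership: dict[str, float]                        # ellipse-point share per polarity
    classification: str                                 # positively_accepted | not_classified_accepted
    barycenter_label: str
    map_fingerprint: str | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_evals": self.n_evals,
            "barycenter": self.barycenter.tolist(),
            "ellipses": {f"{a}-{b}": e.tolist() for (a, b), e in self.ellipses.items()},
            "membership": self.membership,
            "classification": self.classification,
            "barycenter_label": self.barycenter_label,
            "map_fingerprint": self.map_fingerprint,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AcceptabilityScore":
        ellipses = {}
        for key, pts in d["ellipses"].items():
            a, b = key.split("-")
            ellipses[(int(a), int(b))] = np.asarray(pts)
        return cls(
            label=d["label"], n_evals=int(d["n_evals"]),
            barycenter=np.asarray(d["barycenter"]), ellipses=ellipses,
            membership=dict(d["membership"]), classification=d["classification"],
            barycenter_label=d["barycenter_label"],
            map_fingerprint=d.get("map_fingerprint"),
        )


@dataclass
class ComparisonResult:
    labels: tuple[str, str]
    overlap_by_plane: dict[tuple[int, int], bool]
    significantly_different: bool


@dataclass
class SubgroupReport:
    by: str
    scores: list[AcceptabilityScore]
    comparisons: list[ComparisonResult]
    confounding: list  # TestResult-bearing tuples, see score_subgroups


def _ellipse_boundary(
    mean2: np.ndarray, cov2: np.ndarray, level: float, n_points: int
) -> np.ndarray:
    """Boundary of the level-set ellipse of a 2-D normal confidence region."""
    try:
        L = np.linalg.cholesky(cov2)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(cov2)
        if w.min() <= 0 and w.max() <= 0:
            raise ValueError("singular covariance: cannot build a confidence ellipse")
        w = np.clip(w, 0.0, None)
        L = V * np.sqrt(w)
    radius = float(np.sqrt(chi2.ppf(level, df=2)))
    theta = 2 * np.pi * np.arange(n_points) / n_points
    circle = np.vstack([np.cos(theta), np.sin(theta)])
    return mean2 + radius * (L @ circle).T


def confidence_ellipses(
    coords: np.ndarray,
    level: float = 0.90,
    n_points: int = 1000,
) -> dict[tuple[int, int], np.ndarray]:
    """Barycentric confidence ellipses for every pair of map dimensions.

    ``coords`` is the (m, ndim) matrix of supplementary coordinates, m >= 3.
    For a pair (a, b) the ellipse is centred at the barycenter's (a, b)
    coordinates with shape matrix ``sample_cov / m`` scaled by
    ``sqrt(chi2_2(level))``; its 2-D boundary points are completed to ndim
    with the barycenter's remaining coordinates, so they can be classified
    on the full map.
    """
    X = np.asarray(coords, dtype=float)
    if X.ndim != 2:
        raise ValueError("coords must be a 2-D array")
    m, ndim = X.shape
    if m < 3:
        raise ValueError(f"need at least 3 evaluations for a confidence ellipse, got {m}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    bary = X.mean(axis=0)
    out: dict[tuple[int, int], np.ndarray] = {}
    for a, b in combinations(range(ndim), 2):
        S = np.cov(X[:, [a, b]].T, ddof=1)
        if not np.all(np.isfinite(S)) or np.linalg.det(S) <= 0:
            raise ValueError(f"singular covariance in plane ({a}, {b})")
        boundary2 = _ellipse_boundary(bary[[a, b]], S / m, level, n_points)
        pts = np.tile(bary, (n_points, 1))
        pts[:, a] = boundary2[:, 0]
        pts[:, b] = boundary2[:, 1]
        out[(a, b)] = pts
    return out


def score_medicine(
    amap: AcceptabilityMap,
    model: ClusterModel,
    evaluations: Sequence[Evaluation],
    label: str,
    level: float = 0.90,
    n_points: int = 1000,
    min_evaluations: int = MIN_EVALUATIONS,
    allow_below_minimum: bool = False,
) -> AcceptabilityScore:
    """Score a set of completed evaluations on the reference framework.

    Evaluations are projected as supplementary rows; the barycenter, the
    per-plane confidence ellipses and the share of ellipse points per
    profile are recorded.  The score is ``positively_accepted`` only when
    the barycenter and 100% of the ellipse points are green.
    """
    evaluations = list(evaluations)
    n = len(evaluations)
    if n < min_evaluations and not allow_below_minimum:
        raise SampleSizeError(
            f"{n} evaluations < required minimum of {min_evaluations} "
            "for a reliable acceptability score"
        )
    incomplete = [e for e in evaluations if not e.is_complete()]
    if incomplete:
        raise ValueError(
            f"{len(incomplete)} evaluations still have missing cells; impute first"
        )
    indicator = build_indicator(evaluations, amap.codebook)
    coords = project_rows(amap, indicator.values)
    bary = coords.mean(axis=0)
    ellipses = confidence_ellipses(coords, level=level, n_points=n_points)

    bary_label = classify_point(model, bary)
    all_points = np.vstack(list(ellipses.values()))
    point_labels = classify_points(model, all_points)
    total = len(point_labels)
    membership = {
        lab: float((point_labels == lab).sum()) / total for lab in ("green", "red")
    }
    accepted = bary_label == "green" and membership["green"] == 1.0
    return AcceptabilityScore(
        label=label,
        n_evals=n,
        barycenter=bary,
        ellipses=ellipses,
        membership=membership,
        classification="positively_accepted" if accepted else "not_classified_accepted",
        barycenter_label=bary_label,
        map_fingerprint=model.map_fingerprint,
    )


def compare_scores(score_a: AcceptabilityScore, score_b: AcceptabilityScore) -> ComparisonResult:
    """Significance of a score difference by ellipse overlap.

    Two scores differ significantly when, in at least one plane, the two
    closed confidence-ellipse regions are disjoint (boundary polygons
    neither intersect nor contain one another).
    """
    if (
        score_a.map_fingerprint is not None
        and score_b.map_fingerprint is not None
        and score_a.map_fingerprint != score_b.map_fingerprint
    ):
        raise ValueError("scores were computed on different reference maps")
    if set(score_a.ellipses) != set(score_b.ellipses):
        raise ValueError("scores have different dimension pairs")
    overlap: dict[tuple[int, int], bool] = {}
    for plane in sorted(score_a.ellipses):
        a, b = plane
        pa = Polygon(score_a.ellipses[plane][:, [a, b]])
        pb = Polygon(score_b.ellipses[plane][:, [a, b]])
        overlap[plane] = bool(pa.intersects(pb))
    return ComparisonResult(
        labels=(score_a.label, score_b.label),
        overlap_by_plane=overlap,
        significantly_different=not all(overlap.values()),
    )


_LEVEL_ORDERS = {
    "day": None,  # codebook order
    "sex": ("girl", "boy"),
    "age": (3, 4, 5),
    "exposure": ("previous", "first"),
}


def _subgroup_key(by: str, evaluation: Evaluation, patient: PatientRecord | None):
    if by == "day":
        return evaluation.day
    if patient is None:
        return None
    return {"sex": patient.sex, "age": patient.age_years, "exposure": patient.prior_exposure}[by]


def score_subgroups(
    amap: AcceptabilityMap,
    model: ClusterModel,
    evaluations: Sequence[Evaluation],
    patients: Sequence[PatientRecord],
    by: str,
    level: float = 0.90,
    n_points: int = 1000,
) -> SubgroupReport:
    """One acceptability score per subgroup level, plus pairwise comparisons.

    ``by`` is one of day, sex, age, exposure.  Subgroups below the
    30-evaluation floor are scored with a warning (subgroup scores are
    descriptive); empty subgroups are skipped with a warning.  The report
    also carries the patient-characteristic confounding checks: sex x age,
    exposure x age and sex x exposure contingency tables run through the
    test-selection rule.
    """
    from . import stats as summary_stats

    if by not in SUBGROUP_KEYS:
        raise ValueError(f"unknown subgroup key {by!r}; expected one of {SUBGROUP_KEYS}")
    pat = {p.patient_id: p for p in patients}
    levels = _LEVEL_ORDERS[by] or amap.codebook.days
    groups: dict = {lvl: [] for lvl in levels}
    for e in evaluations:
        key = _subgroup_key(by, e, pat.get(e.patient_id))
        if key is None:
            continue  # missing characteristic: excluded from this partition
        groups.setdefault(key, []).append(e)

    scores: list[AcceptabilityScore] = []
    for lvl in levels:
        evs = groups.get(lvl, [])
        if not evs:
            warnings.warn(f"subgroup {by}={lvl!r} is empty; skipped", stacklevel=2)
            continue
        if len(evs) < MIN_EVALUATIONS:
            warnings.warn(
                f"subgroup {by}={lvl!r} has only {len(evs)} evaluations "
                f"(reliability floor is {MIN_EVALUATIONS})",
                stacklevel=2,
            )
        scores.append(
            score_medicine(
                amap, model, evs, label=f"{by}={lvl}", level=level,
                n_points=n_points, allow_below_minimum=True,
            )
        )
    comparisons = [
        compare_scores(sa, sb) for sa, sb in combinations(scores, 2)
    ]

    confounding = []
    for var, strat in (("sex", "age"), ("exposure", "age"), ("sex", "exposure")):
        table = summary_stats.crosstab(patients, var, strat)
        try:
            chosen = summary_stats.choose_test(table)
            result = (
                summary_stats.pearson_chi2(table)
                if chosen == "pearson_chi2"
                else summary_stats.fisher_exact(table)
            )
        except ValueError as err:
            warnings.warn(f"confounding check {var} x {strat} failed: {err}", stacklevel=2)
            continue
        confounding.append((f"{var} x {strat}", table, result))

    return SubgroupReport(by=by, scores=scores, comparisons=comparisons, confounding=confounding)


def write_scores(scores: Sequence[AcceptabilityScore], path: str | Path) -> None:
    Path(path).write_text(json.dumps([s.to_dict() for s in scores]))


def read_scores(path: str | Path) -> list[AcceptabilityScore]:
    return [AcceptabilityScore.from_dict(d) for d in json.loads(Path(path).read_text())]
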