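"""Observer-reported evaluation schema: codebook, I/O and worst-case recoding.

An *evaluation* is one observed medicine intake by one patient on one visit
day, coded on nine categorical observational variables: the result of the
intake, the patient's reaction on a three-point facial hedonic scale, the
preparation/administration time band, and six binary "method" variables
recording whether the observer used a divided dose, food or drink, an
alteration of the intended form of use, a device not provided with the
medicine, a reward, or restraint.

Raw observer reports additionally carry objective fields (whether a
sublingual tablet was still under the tongue at 30 s and 1 min, the
administration time in seconds, free-text method notes).  Before scoring,
these raw fields are resolved against the ticked categories using the worst
case for acceptability: an ambiguous report is always recoded in the
direction least favourable to the medicine, and every change is logged.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Codebook",
    "DEFAULT_CODEBOOK",
    "DEFAULT_KEYWORD_MAP",
    "RawObservation",
    "Evaluation",
    "PatientRecord",
    "RecodeEntry",
    "RecodeLog",
    "DaySummary",
    "SchemaError",
    "IntegrityError",
    "read_study",
    "write_study",
    "read_evaluations",
    "write_evaluations",
    "apply_worst_case_recoding",
    "summarize_by_day",
]

DAYS = ("D1", "D2", "D10")

#: categories of the six binary method variables
METHOD_VARIABLES = (
    "divided_dose",
    "food_drink",
    "alteration",
    "extra_device",
    "reward",
    "restraint",
)


class SchemaError(ValueError):
    """A value that does not belong to the declared codebook."""


class IntegrityError(ValueError):
    """A structural defect of the dataset (e.g. duplicated patient-visit)."""


@dataclass(frozen=True)
class Codebook:
    """Ordered variables and category labels of an evaluation.

    ``categories`` lists each variable's labels in serialization order;
    ``acceptability_order`` lists them from best to worst for acceptability
    and drives every worst-case tie-break in the pipeline.
    """

    variables: tuple[str, ...]
    categories: Mapping[str, tuple[str, ...]]
    acceptability_order: Mapping[str, tuple[str, ...]]
    days: tuple[str, ...] = DAYS

    def __post_init__(self) -> None:
        if len(self.variables) != 9:
            raise SchemaError(f"expected 9 observational variables, got {len(self.variables)}")
        for var in self.variables:
            cats = self.categories[var]
            if len(set(cats)) != len(cats):
                raise SchemaError(f"duplicate category labels for {var!r}")
            if set(self.acceptability_order[var]) != set(cats):
                raise SchemaError(f"acceptability order for {var!r} does not match categories")

    @property
    def n_categories(self) -> int:
        """Total category count J over all variables (21 for the default)."""
        return sum(len(self.categories[v]) for v in self.variables)

    def column_labels(self) -> list[str]:
        """Indicator-matrix column labels, ``variable:category``, in codebook order."""
        return [f"{v}:{c}" for v in self.variables for c in self.categories[v]]

    def column_index(self, variable: str, category: str) -> int:
        idx = 0
        for v in self.variables:
            if v == variable:
                return idx + self.categories[v].index(category)
            idx += len(self.categories[v])
        raise SchemaError(f"unknown variable {variable!r}")

    def block_slices(self) -> dict[str, slice]:
        """Column slice of each variable's category block."""
        out, start = {}, 0
        for v in self.variables:
            stop = start + len(self.categories[v])
            out[v] = slice(start, stop)
            start = stop
        return out

    def worst_of(self, variable: str, candidates: Sequence[str]) -> str:
        """The candidate least favourable to acceptability."""
        order = self.acceptability_order[variable]
        return max(candidates, key=order.index)

    def positive_categories(self) -> set[tuple[str, str]]:
        """The nine categories that express trouble-free, positive acceptability."""
        out = {
            ("result_intake", "fully_taken"),
            ("reaction", "positive"),
            ("prep_admin_time", "short"),
        }
        out.update((m, "not_used") for m in METHOD_VARIABLES)
        return out

    def validate_category(self, variable: str, category: str | None) -> None:
        if variable not in self.categories:
            raise SchemaError(f"unknown variable {variable!r}")
        if category is not None and category not in self.categories[variable]:
            raise SchemaError(f"unknown category {category!r} for variable {variable!r}")

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "categories": {v: list(c) for v, c in self.categories.items()},
            "acceptability_order": {v: list(c) for v, c in self.acceptability_order.items()},
            "days": list(self.days),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Codebook":
        return cls(
            variables=tuple(d["variables"]),
            categories={v: tuple(c) for v, c in d["categories"].items()},
            acceptability_order={v: tuple(c) for v, c in d["acceptability_order"].items()},
            days=tuple(d.get("days", DAYS)),
        )


def _default_codebook() -> Codebook:
    categories = {
        "result_intake": ("fully_taken", "partly_taken", "not_taken"),
        "reaction": ("positive", "neutral", "negative"),
        "prep_admin_time": ("short", "medium", "long"),
    }
    order = dict(categories)
    for m in METHOD_VARIABLES:
        categories[m] = ("used", "not_used")
        order[m] = ("not_used", "used")  # not using a coping method is the better state
    return Codebook(
        variables=("result_intake", "reaction", "prep_admin_time") + METHOD_VARIABLES,
        categories=categories,
        acceptability_order=order,
    )


DEFAULT_CODEBOOK = _default_codebook()

#: free-text tokens mapped to the method variable they imply (case-insensitive
#: substring match); covers the drink/food mentions typically found in reports
DEFAULT_KEYWORD_MAP: dict[str, str] = {
    "water": "food_drink",
    "hot chocolate": "food_drink",
    "fruit juice": "food_drink",
    "juice": "food_drink",
    "candy": "food_drink",
}


@dataclass
class RawObservation:
    """One observer report before worst-case recoding."""

    patient_id: str
    day: str
    reported: dict[str, str | None]
    under_tongue_30s: bool | None = None
    under_tongue_1min: bool | None = None
    admin_time_seconds: float | None = None
    method_texts: dict[str, str] = field(default_factory=dict)


@dataclass
class Evaluation:
    """One intake evaluation after recoding: a total map variable -> category/None."""

    patient_id: str
    day: str
    measures: dict[str, str | None]

    def is_complete(self) -> bool:
        return all(v is not None for v in self.measures.values())


@dataclass
class PatientRecord:
    patient_id: str
    sex: str | None = None            # girl | boy | None
    age_years: int | None = None      # 3..5
    prior_exposure: str | None = None  # previous | first | None

    def __post_init__(self) -> None:
        if self.sex not in (None, "girl", "boy"):
            raise SchemaError(f"unknown sex {self.sex!r}")
        if self.age_years is not None and not (3 <= self.age_years <= 5):
            raise SchemaError(f"age {self.age_years} outside 3-5")
        if self.prior_exposure not in (None, "previous", "first"):
            raise SchemaError(f"unknown exposure {self.prior_exposure!r}")


@dataclass(frozen=True)
class RecodeEntry:
    patient_id: str
    day: str
    variable: str
    old_value: str | None
    new_value: str
    rule_id: str


@dataclass
class RecodeLog:
    entries: list[RecodeEntry]
    n_cells_total: int

    @property
    def recoded_fraction(self) -> float:
        return len(self.entries) / self.n_cells_total if self.n_cells_total else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.patient_id, e.day, e.variable, e.old_value, e.new_value, e.rule_id)
                for e in self.entries
            ],
            columns=["patient_id", "day", "variable", "old_value", "new_value", "rule_id"],
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# reading and writing


_BOOL = {"true": True, "false": False, "yes": True, "no": False, "1": True, "0": False}

_PATIENT_COLS = ("sex", "age_years", "prior_exposure")
_RAW_COLS = ("under_tongue_30s", "under_tongue_1min", "admin_time_seconds")


def _parse_bool(value: str, where: str) -> bool:
    try:
        return _BOOL[value.strip().lower()]
    except KeyError:
        raise SchemaError(f"cannot parse boolean {value!r} at {where}") from None


def read_study(
    path: str | Path,
    codebook: Codebook = DEFAULT_CODEBOOK,
    delimiter: str | None = None,
) -> tuple[list[RawObservation], list[PatientRecord]]:
    """Read a raw study table (one row per patient-visit) from CSV/TSV.

    Unknown variables or category labels raise :class:`SchemaError` naming the
    offending row and column; a duplicated (patient, day) pair raises
    :class:`IntegrityError`.  Empty cells are preserved as missing.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    observations: list[RawObservation] = []
    patients: dict[str, PatientRecord] = {}
    seen: set[tuple[str, str]] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            return [], []
        for lineno, row in enumerate(reader, start=2):
            pid = (row.get("patient_id") or "").strip()
            day = (row.get("day") or "").strip()
            if not pid:
                raise SchemaError(f"row {lineno}: missing patient_id")
            if day not in codebook.days:
                raise SchemaError(f"row {lineno}: unknown day label {day!r}")
            if (pid, day) in seen:
                raise IntegrityError(f"row {lineno}: duplicate evaluation for ({pid}, {day})")
            seen.add((pid, day))

            reported: dict[str, str | None] = {}
            for var in codebook.variables:
                cell = (row.get(var) or "").strip()
                if not cell:
                    reported[var] = None
                    continue
                if cell not in codebook.categories[var]:
                    raise SchemaError(
                        f"row {lineno}, column {var!r}: unknown category {cell!r}"
                    )
                reported[var] = cell

            def _opt(col: str):
                cell = (row.get(col) or "").strip()
                return cell or None

            ut30 = _opt("under_tongue_30s")
            ut60 = _opt("under_tongue_1min")
            secs = _opt("admin_time_seconds")
            if secs is not None:
                try:
                    secs = float(secs)
                except ValueError:
                    raise SchemaError(
                        f"row {lineno}: admin_time_seconds {secs!r} is not a number"
                    ) from None
                if secs < 0:
                    raise SchemaError(f"row {lineno}: negative admin_time_seconds")
            texts = {
                col[len("method_text_"):]: row[col].strip()
                for col in reader.fieldnames
                if col.startswith("method_text_") and (row.get(col) or "").strip()
            }
            observations.append(
                RawObservation(
                    patient_id=pid,
                    day=day,
                    reported=reported,
                    under_tongue_30s=None if ut30 is None else _parse_bool(ut30, f"row {lineno}"),
                    under_tongue_1min=None if ut60 is None else _parse_bool(ut60, f"row {lineno}"),
                    admin_time_seconds=secs,
                    method_texts=texts,
                )
            )

            if pid not in patients and any(_opt(c) for c in _PATIENT_COLS):
                age = _opt("age_years")
                patients[pid] = PatientRecord(
                    patient_id=pid,
                    sex=_opt("sex"),
                    age_years=None if age is None else int(float(age)),
                    prior_exposure=_opt("prior_exposure"),
                )
    for pid in {o.patient_id for o in observations}:
        patients.setdefault(pid, PatientRecord(patient_id=pid))
    order: dict[str, int] = {}
    for o in observations:
        order.setdefault(o.patient_id, len(order))
    return observations, sorted(patients.values(), key=lambda p: order[p.patient_id])


def write_study(
    observations: Iterable[RawObservation],
    patients: Iterable[PatientRecord],
    path: str | Path,
    codebook: Codebook = DEFAULT_CODEBOOK,
    delimiter: str | None = None,
) -> None:
    """Write raw observations (plus patient characteristics) to CSV/TSV."""
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    observations = list(observations)
    pat = {p.patient_id: p for p in patients}
    slots = sorted({s for o in observations for s in o.method_texts})
    cols = (
        ["patient_id", "day", *codebook.variables, *_RAW_COLS]
        + [f"method_text_{s}" for s in slots]
        + list(_PATIENT_COLS)
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(cols)
        for o in observations:
            p = pat.get(o.patient_id)
            row = [o.patient_id, o.day]
            row += [o.reported.get(v) or "" for v in codebook.variables]
            row += [
                "" if o.under_tongue_30s is None else str(o.under_tongue_30s).lower(),
                "" if o.under_tongue_1min is None else str(o.under_tongue_1min).lower(),
                "" if o.admin_time_seconds is None else repr(o.admin_time_seconds),
            ]
            row += [o.method_texts.get(s, "") for s in slots]
            row += [
                "" if p is None or p.sex is None else p.sex,
                "" if p is None or p.age_years is None else str(p.age_years),
                "" if p is None or p.prior_exposure is None else p.prior_exposure,
            ]
            writer.writerow(row)


def write_evaluations(
    evaluations: Iterable[Evaluation],
    path: str | Path,
    codebook: Codebook = DEFAULT_CODEBOOK,
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "day", *codebook.variables])
        for e in evaluations:
            writer.writerow(
                [e.patient_id, e.day] + [e.measures.get(v) or "" for v in codebook.variables]
            )


def read_evaluations(
    path: str | Path, codebook: Codebook = DEFAULT_CODEBOOK
) -> list[Evaluation]:
    out: list[Evaluation] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            measures: dict[str, str | None] = {}
            for var in codebook.variables:
                cell = (row.get(var) or "").strip()
                if cell and cell not in codebook.categories[var]:
                    raise SchemaError(f"row {lineno}, column {var!r}: unknown category {cell!r}")
                measures[var] = cell or None
            day = (row.get("day") or "").strip()
            if day not in codebook.days:
                raise SchemaError(f"row {lineno}: unknown day label {day!r}")
            out.append(Evaluation(row["patient_id"].strip(), day, measures))
    return out


# ---------------------------------------------------------------------------
# worst-case recoding

#: time band from an administration time in seconds; left-closed on the
#: better band (60 s is still "short", 150 s still "medium")
def time_band(seconds: float) -> str:
    if seconds <= 60:
        return "short"
    if seconds <= 150:
        return "medium"
    return "long"


def apply_worst_case_recoding(
    observations: Iterable[RawObservation],
    keyword_map: Mapping[str, str] | None = None,
    codebook: Codebook = DEFAULT_CODEBOOK,
) -> tuple[list[Evaluation], RecodeLog]:
    """Resolve raw fields against the ticked categories, worst case first.

    The cascade is applied in a fixed order, each rule seeing the previous
    rules' output:

    R1
        tablet not under the tongue at 1 min and result "fully taken"
        -> "partly taken" (the dose was not kept at the absorption site).
    R2
        tablet not under the tongue at 30 s -> alteration "used" (the child
        plausibly swallowed the tablet, i.e. another route was used).
    R3
        administration time < 60 s with result "fully taken" -> "partly
        taken" (a sublingual tablet cannot fully dissolve that fast).
    R4
        administration time < 30 s with result "partly taken" -> alteration
        "used" (swallowed or spat out before sufficient absorption).
    R5
        a free-text method note matching ``keyword_map`` -> the mapped
        method variable "used".
    R6
        a reported administration time in seconds overrides a reported time
        category that disagrees with it (missing time categories are left to
        imputation).

    Every change is appended to the :class:`RecodeLog`.  Recoding of the
    result and method variables only ever moves toward the worse state.
    """
    if keyword_map is None:
        keyword_map = DEFAULT_KEYWORD_MAP
    evaluations: list[Evaluation] = []
    entries: list[RecodeEntry] = []
    n_obs = 0

    for obs in observations:
        n_obs += 1
        m = {v: obs.reported.get(v) for v in codebook.variables}

        def recode(variable: str, new: str, rule: str) -> None:
            old = m[variable]
            if old == new:
                return
            entries.append(RecodeEntry(obs.patient_id, obs.day, variable, old, new, rule))
            m[variable] = new

        secs = obs.admin_time_seconds
        if obs.under_tongue_1min is True and secs is not None and secs < 30:
            warnings.warn(
                f"({obs.patient_id}, {obs.day}): tablet reported under the tongue at 1 min "
                f"but administration time {secs:g} s < 30 s; applying the worst case",
                stacklevel=2,
            )
        # R1
        if obs.under_tongue_1min is False and m["result_intake"] == "fully_taken":
            recode("result_intake", "partly_taken", "R1")
        # R2
        if obs.under_tongue_30s is False and m["alteration"] != "used":
            recode("alteration", "used", "R2")
        # R3
        if secs is not None and secs < 60 and m["result_intake"] == "fully_taken":
            recode("result_intake", "partly_taken", "R3")
        # R4
        if secs is not None and secs < 30 and m["result_intake"] == "partly_taken":
            recode("alteration", "used", "R4")
        # R5
        for text in obs.method_texts.values():
            low = text.lower()
            for token, variable in keyword_map.items():
                if token.lower() in low and m[variable] != "used":
                    recode(variable, "used", "R5")
        # R6
        if secs is not None and m["prep_admin_time"] is not None:
            band = time_band(secs)
            if band != m["prep_admin_time"]:
                recode("prep_admin_time", band, "R6")

        evaluations.append(Evaluation(obs.patient_id, obs.day, m))

    return evaluations, RecodeLog(entries=entries, n_cells_total=9 * n_obs)


# ---------------------------------------------------------------------------
# descriptive summaries


@dataclass
class DaySummary:
    """Per-variable category counts by day, with non-missing percentages.

    ``counts`` is indexed by (variable, category); ``missing`` by variable;
    ``percent`` uses the non-missing count of each (variable, day) as the
    denominator, so missing cells never dilute the reported percentages.
    """

    counts: pd.DataFrame
    missing: pd.DataFrame
    percent: pd.DataFrame

    def n_by_day(self) -> pd.Series:
        """Number of evaluations per day (non-missing + missing, any variable)."""
        per_var = self.counts.groupby(level="variable").sum() + self.missing
        return per_var.iloc[0]


def summarize_by_day(
    evaluations: Sequence[Evaluation], codebook: Codebook = DEFAULT_CODEBOOK
) -> DaySummary:
    if not evaluations:
        raise ValueError("no evaluations to summarize")
    days = [d for d in codebook.days if any(e.day == d for e in evaluations)]
    index = pd.MultiIndex.from_tuples(
        [(v, c) for v in codebook.variables for c in codebook.categories[v]],
        names=["variable", "category"],
    )
    counts = pd.DataFrame(0, index=index, columns=days)
    missing = pd.DataFrame(0, index=list(codebook.variables), columns=days)
    for e in evaluations:
        for var in codebook.variables:
            cat = e.measures.get(var)
            if cat is None:
                missing.loc[var, e.day] += 1
            else:
                codebook.validate_category(var, cat)
                counts.loc[(var, cat), e.day] += 1
    nonmissing = counts.groupby(level="variable").sum()
    denom = nonmissing.reindex(counts.index, level="variable")
    percent = 100.0 * counts / denom.where(denom > 0)
    return DaySummary(counts=counts, missing=missing, percent=percent)


def write_codebook(codebook: Codebook, path: str | Path) -> None:
    Path(path).write_text(json.dumps(codebook.to_dict(), indent=2))


def load_codebook(path: str | Path) -> Codebook:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        return Codebook.from_dict(yaml.safe_load(text))
    return Codebook.from_dict(json.loads(text))
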