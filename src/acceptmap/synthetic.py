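"""Synthetic reference corpora and study datasets.

The real reference corpus behind the acceptability framework (1562 intake
evaluations of many oral/buccal medicines) and the study's raw reports are
not public.  This module generates stand-ins with the statistical structure
the analysis assumes, so every stage of the pipeline is testable end to
end.

The reference generator draws each evaluation's latent profile — positive
or negative acceptability — from a Bernoulli mixing proportion, then draws
the nine observational variables conditionally independently from
per-profile emission tables in which every trouble-free category is
strictly more likely under the positive profile.  The study generator
emulates a 37-patient, three-visit design: demographics matched to the
study population, two patients lost to follow-up (one after the first
visit, one after the second), per-variable missingness concentrated on the
result/reaction/time variables, and raw fields (under-tongue checks,
administration seconds, free-text method notes) that trigger the worst-case
recoding rules at a configurable rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .schema import (
    Codebook,
    DEFAULT_CODEBOOK,
    Evaluation,
    METHOD_VARIABLES,
    PatientRecord,
    RawObservation,
)

__all__ = [
    "GeneratorParams",
    "LabeledDataset",
    "generate_reference",
    "generate_study",
    "sample_profile",
]


def _default_emissions() -> dict[str, dict[str, tuple[float, ...]]]:
    positive = {
        "result_intake": (0.90, 0.08, 0.02),     # fully, partly, not
        "reaction": (0.80, 0.15, 0.05),          # positive, neutral, negative
        "prep_admin_time": (0.60, 0.30, 0.10),   # short, medium, long
    }
    negative = {
        "result_intake": (0.20, 0.50, 0.30),
        "reaction": (0.10, 0.30, 0.60),
        "prep_admin_time": (0.10, 0.30, 0.60),
    }
    for m in METHOD_VARIABLES:
        positive[m] = (0.05, 0.95)               # used, not_used
        negative[m] = (0.60, 0.40)
    return {"positive": positive, "negative": negative}


@dataclass
class GeneratorParams:
    """All knobs of the synthetic generators, with study-sized defaults."""

    n_reference: int = 1562
    mixing: float = 0.7                      # P(positive profile), reference corpus
    emissions: Mapping[str, Mapping[str, tuple[float, ...]]] = field(
        default_factory=_default_emissions
    )
    # study design
    n_patients: int = 37
    days: tuple[str, ...] = ("D1", "D2", "D10")
    dropout_after_first: int = 1             # patients with only the first visit
    dropout_after_second: int = 1            # patients with only the first two visits
    study_mixing: float = 0.85               # P(positive profile) per study evaluation
    missingness: Mapping[str, float] = field(
        default_factory=lambda: {
            # targets ~13 missing cells over 108 evaluations:
            # 2 results, 4 reactions, 7 times
            "result_intake": 2 / 108,
            "reaction": 4 / 108,
            "prep_admin_time": 7 / 108,
        }
    )
    recode_trigger_rate: float = 0.12        # per-evaluation rate of each raw-field quirk
    seconds_report_rate: float = 0.8         # fraction of evaluations with admin seconds
    seed: int = 0
    codebook: Codebook = field(default_factory=lambda: DEFAULT_CODEBOOK)

    def __post_init__(self) -> None:
        if not 0 < self.mixing < 1:
            raise ValueError("mixing must be in (0, 1); degenerate corpora have no profile")
        for profile, tables in self.emissions.items():
            for var in self.codebook.variables:
                if var not in tables:
                    raise ValueError(f"emission table for {profile!r} misses {var!r}")
                probs = np.asarray(tables[var], dtype=float)
                if len(probs) != len(self.codebook.categories[var]):
                    raise ValueError(f"emission for {profile}/{var} has wrong length")
                if not np.isclose(probs.sum(), 1.0):
                    raise ValueError(f"emission for {profile}/{var} does not sum to 1")
        for rate in self.missingness.values():
            if not 0 <= rate <= 1:
                raise ValueError("missingness rates must be in [0, 1]")
        if self.dropout_after_first + self.dropout_after_second > self.n_patients:
            raise ValueError("dropout exceeds the number of patients")


@dataclass
class LabeledDataset:
    """Generated data plus the latent truth that produced it."""

    evaluations: list[Evaluation]            # complete, pre-missingness ground truth
    latent_labels: list[str]                 # per evaluation: positive | negative
    patients: list[PatientRecord]
    params: GeneratorParams
    raw_observations: list[RawObservation] | None = None  # study variant only


def _draw_measures(rng: np.random.Generator, params: GeneratorParams, profile: str) -> dict:
    cb = params.codebook
    table = params.emissions[profile]
    return {
        var: cb.categories[var][rng.choice(len(cb.categories[var]), p=np.asarray(table[var]))]
        for var in cb.variables
    }


def generate_reference(params: GeneratorParams | None = None, seed: int | None = None) -> LabeledDataset:
    """A reference corpus with a latent two-profile structure."""
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    evaluations, labels = [], []
    for i in range(params.n_reference):
        profile = "positive" if rng.random() < params.mixing else "negative"
        labels.append(profile)
        evaluations.append(
            Evaluation(f"R{i:04d}", "D1", _draw_measures(rng, params, profile))
        )
    return LabeledDataset(evaluations=evaluations, latent_labels=labels,
                          patients=[], params=params)


def sample_profile(
    profile: str,
    n: int,
    params: GeneratorParams | None = None,
    seed: int | None = None,
) -> list[Evaluation]:
    """Draw ``n`` evaluations from a single emission profile (no mixing)."""
    params = params or GeneratorParams()
    if profile not in params.emissions:
        raise ValueError(f"unknown profile {profile!r}")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    return [
        Evaluation(f"S{i:04d}", "D1", _draw_measures(rng, params, profile))
        for i in range(n)
    ]


#: demographics of the 36 patients with known characteristics, proportionally
#: completing the study population's printed age distribution; one further
#: patient has all demographics missing
_SEX_COUNTS = {"girl": 12, "boy": 24}
_AGE_COUNTS = {3: 12, 4: 18, 5: 6}
_EXPOSURE_COUNTS = {"previous": 12, "first": 24}


def _study_patients(rng: np.random.Generator, params: GeneratorParams) -> list[PatientRecord]:
    n = params.n_patients
    n_known = n - 1
    def expand(counts: Mapping, total: int) -> list:
        vals = [v for v, k in counts.items() for _ in range(k)]
        # rescale the template to the requested cohort size
        while len(vals) < total:
            vals.append(rng.permutation(list(counts)).tolist()[0])
        vals = vals[:total]
        rng.shuffle(vals)
        return vals
    sexes = expand(_SEX_COUNTS, n_known)
    ages = expand(_AGE_COUNTS, n_known)
    expo = expand(_EXPOSURE_COUNTS, n_known)
    patients = [
        PatientRecord(f"P{i + 1:02d}", sex=sexes[i], age_years=int(ages[i]),
                      prior_exposure=expo[i])
        for i in range(n_known)
    ]
    patients.append(PatientRecord(f"P{n:02d}"))  # demographics missing
    return patients


def _seconds_for_band(rng: np.random.Generator, band: str, result: str) -> float:
    # a fully/partly taken sublingual dose is incompatible with <60 s / <30 s
    # administration, so consistent draws respect those floors
    lo, hi = {"short": (20.0, 60.0), "medium": (61.0, 150.0), "long": (151.0, 300.0)}[band]
    if band == "short":
        if result == "fully_taken":
            return 60.0
        if result == "partly_taken":
            lo = 30.0
    return float(np.round(rng.uniform(lo, hi)))


def generate_study(params: GeneratorParams | None = None, seed: int | None = None) -> LabeledDataset:
    """A study dataset: raw observations with missingness and recodable fields."""
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    cb = params.codebook
    patients = _study_patients(rng, params)

    # dropout: last-visit index per patient
    ids = [p.patient_id for p in patients]
    dropped = rng.choice(len(ids), size=params.dropout_after_first + params.dropout_after_second,
                         replace=False)
    last_day = {pid: len(params.days) - 1 for pid in ids}
    for j, idx in enumerate(dropped):
        last_day[ids[idx]] = 0 if j < params.dropout_after_first else 1

    evaluations: list[Evaluation] = []
    labels: list[str] = []
    raw: list[RawObservation] = []
    r = params.recode_trigger_rate
    for pid in ids:
        for d, day in enumerate(params.days):
            if d > last_day[pid]:
                continue
            profile = "positive" if rng.random() < params.study_mixing else "negative"
            truth = _draw_measures(rng, params, profile)
            evaluations.append(Evaluation(pid, day, dict(truth)))
            labels.append(profile)

            reported: dict[str, str | None] = dict(truth)
            secs = (
                _seconds_for_band(rng, truth["prep_admin_time"], truth["result_intake"])
                if rng.random() < params.seconds_report_rate
                else None
            )
            # under-tongue checks are only meaningful when a dose was taken
            not_taken = truth["result_intake"] == "not_taken"
            ut30: bool | None = None if not_taken else True
            ut60: bool | None = None if not_taken else True
            texts: dict[str, str] = {}
            # raw-field quirks that the worst-case cascade must resolve
            if rng.random() < r and reported["result_intake"] == "fully_taken":
                ut60 = False                                      # triggers R1
            if rng.random() < r:
                ut30 = False                                      # triggers R2
                ut60 = False
            if rng.random() < r and reported["result_intake"] == "fully_taken":
                secs = float(rng.integers(30, 60))                # triggers R3 (and R6)
            if rng.random() < r and reported["result_intake"] == "partly_taken":
                secs = float(rng.integers(5, 30))                 # triggers R4
                ut30 = ut60 = None                                # checks not performed
            if rng.random() < r and reported["food_drink"] == "not_used":
                texts["other"] = "drank water after intake"       # triggers R5
            # missingness injection
            for var, rate in params.missingness.items():
                if rng.random() < rate:
                    reported[var] = None
            raw.append(
                RawObservation(
                    patient_id=pid, day=day, reported=reported,
                    under_tongue_30s=ut30, under_tongue_1min=ut60,
                    admin_time_seconds=secs, method_texts=texts,
                )
            )
    return LabeledDataset(
        evaluations=evaluations, latent_labels=labels, patients=patients,
        params=params, raw_observations=raw,
    )
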