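"""Shared fixtures: the published per-day outcome counts and a fitted pipeline."""

from __future__ import annotations

import numpy as np
import pytest

import acceptmap as am

# Per-day category counts of the study's observer-reported outcomes
# (categories in codebook order; `missing` counted separately).
TABLE2_COUNTS = {
    "result_intake": {"D1": [21, 14, 2], "D2": [24, 11, 1], "D10": [19, 13, 1]},
    "reaction": {"D1": [14, 12, 11], "D2": [15, 14, 6], "D10": [15, 15, 2]},
    "prep_admin_time": {"D1": [5, 15, 15], "D2": [5, 11, 17], "D10": [4, 18, 11]},
    "divided_dose": {"D1": [2, 35], "D2": [0, 36], "D10": [1, 34]},
    "food_drink": {"D1": [11, 26], "D2": [12, 24], "D10": [9, 26]},
    "alteration": {"D1": [10, 27], "D2": [7, 29], "D10": [8, 27]},
    "extra_device": {"D1": [1, 36], "D2": [1, 35], "D10": [1, 34]},
    "reward": {"D1": [5, 32], "D2": [4, 32], "D10": [5, 30]},
    "restraint": {"D1": [1, 36], "D2": [0, 36], "D10": [1, 34]},
}
TABLE2_N = {"D1": 37, "D2": 36, "D10": 35}


@pytest.fixture(scope="session")
def codebook() -> am.Codebook:
    return am.DEFAULT_CODEBOOK


@pytest.fixture(scope="session")
def table2_evaluations(codebook) -> list[am.Evaluation]:
    """Evaluations whose per-variable marginal counts equal the published table.

    Variables are filled independently (only marginals matter for per-day
    summaries and variable-by-day contingency tables); the remainder up to
    the day's n is missing.
    """
    evaluations = []
    for day, n in TABLE2_N.items():
        per_var = {}
        for var, by_day in TABLE2_COUNTS.items():
            cats: list[str | None] = []
            for cat, k in zip(codebook.categories[var], by_day[day]):
                cats.extend([cat] * k)
            cats.extend([None] * (n - len(cats)))
            per_var[var] = cats
        for i in range(n):
            evaluations.append(
                am.Evaluation(f"P{i + 1:02d}", day, {v: per_var[v][i] for v in codebook.variables})
            )
    return evaluations


@pytest.fixture(scope="session")
def reference_dataset() -> am.LabeledDataset:
    return am.generate_reference(am.GeneratorParams(seed=11))


@pytest.fixture(scope="session")
def fitted_pipeline(reference_dataset):
    """(indicator, map, polarized cluster model) on the default reference corpus."""
    indicator = am.build_indicator(reference_dataset.evaluations)
    amap = am.fit_mca(indicator, ndim=3)
    model = am.cluster_reference(amap)
    am.vtest_categories(model, indicator)
    am.assign_polarity(model)
    return indicator, amap, model


@pytest.fixture(scope="session")
def study_dataset() -> am.LabeledDataset:
    return am.generate_study(am.GeneratorParams(seed=7))
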