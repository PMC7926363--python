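"""Barycentric confidence ellipses, classification and subgroup scoring."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import chi2
from shapely.geometry import Point, Polygon

import acceptmap as am
from acceptmap.scoring import MIN_EVALUATIONS, SampleSizeError


class TestConfidenceEllipses:
    def test_isotropic_coords_give_circular_boundary(self):
        rng = np.random.default_rng(0)
        sigma = 0.7
        X = rng.normal(0, sigma, size=(2000, 2))
        ellipses = am.confidence_ellipses(X, level=0.90, n_points=360)
        pts = ellipses[(0, 1)]
        assert pts.shape == (360, 2)
        radii = np.linalg.norm(pts - X.mean(axis=0), axis=1)
        # sample covariance ~ sigma^2 I, so the boundary is nearly a circle of
        # radius sqrt(chi2_2(0.9) * sigma^2 / m)
        expected = np.sqrt(chi2.ppf(0.90, 2) * sigma**2 / len(X))
        assert radii.mean() == pytest.approx(expected, rel=0.1)
        assert radii.std() / radii.mean() < 0.1

    def test_three_planes_lifted_with_barycenter_coordinate(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        ellipses = am.confidence_ellipses(X)
        assert set(ellipses) == {(0, 1), (0, 2), (1, 2)}
        bary = X.mean(axis=0)
        for (a, b), pts in ellipses.items():
            assert pts.shape == (1000, 3)
            other = ({0, 1, 2} - {a, b}).pop()
            assert np.allclose(pts[:, other], bary[other])

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            am.confidence_ellipses(np.zeros((36, 2)))  # zero variance
        with pytest.raises(ValueError):
            am.confidence_ellipses(np.random.default_rng(0).normal(size=(2, 2)))
        with pytest.raises(ValueError):
            am.confidence_ellipses(np.random.default_rng(0).normal(size=(10, 2)), level=1.2)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(36, 3))
        shift = np.array([5.0, -3.0, 2.0])
        e0 = am.confidence_ellipses(X)
        e1 = am.confidence_ellipses(X + shift)
        for plane in e0:
            assert np.allclose(e1[plane], e0[plane] + shift, atol=1e-10)

    def test_area_shrinks_inversely_with_sample_size(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(50, 2))
        # same covariance, doubled sample: duplicate rows
        doubled = np.vstack([base, base])

        def area(pts):
            return Polygon(pts).area

        a1 = area(am.confidence_ellipses(base)[(0, 1)][:, :2])
        a2 = area(am.confidence_ellipses(doubled)[(0, 1)][:, :2])
        # duplicating halves S/m up to the ddof=1 correction:
        # S_2m = 2(m-1)/(2m-1) * S_m, so areas scale by (m-1)/(2m-1)
        m = len(base)
        expected_ratio = (m - 1) / (2 * m - 1)
        assert a2 / a1 == pytest.approx(expected_ratio, rel=1e-6)

    def test_monte_carlo_coverage_near_nominal(self):
        # smoke-level check; the full 500-replicate calibration lives in the
        # acceptance suite
        rng = np.random.default_rng(4)
        mean = np.array([1.0, -2.0])
        cov = np.array([[1.0, 0.4], [0.4, 2.0]])
        hits = 0
        n_rep = 150
        for _ in range(n_rep):
            X = rng.multivariate_normal(mean, cov, size=36)
            pts = am.confidence_ellipses(X, level=0.90, n_points=200)[(0, 1)]
            hits += Polygon(pts).contains(Point(mean))
        assert 0.82 <= hits / n_rep <= 0.97


@pytest.fixture(scope="module")
def scored(fitted_pipeline):
    _, amap, model = fitted_pipeline
    positive = am.sample_profile("positive", 40, seed=21)
    negative = am.sample_profile("negative", 40, seed=22)
    pos_score = am.score_medicine(amap, model, positive, "positive sample")
    neg_score = am.score_medicine(amap, model, negative, "negative sample")
    return amap, model, pos_score, neg_score


class TestScoreMedicine:
    def test_positive_profile_sample_positively_accepted(self, scored):
        _, _, pos, _ = scored
        assert pos.classification == "positively_accepted"
        assert pos.membership["green"] == 1.0
        assert pos.barycenter_label == "green"

    def test_negative_profile_sample_not_accepted(self, scored):
        _, _, _, neg = scored
        assert neg.classification == "not_classified_accepted"

    def test_barycenter_is_mean_of_projected_rows(self, scored, fitted_pipeline):
        indicator, amap, model = fitted_pipeline
        positive = am.sample_profile("positive", 40, seed=21)
        coords = am.project_rows(amap, am.build_indicator(positive).values)
        _, _, pos, _ = scored
        assert np.allclose(pos.barycenter, coords.mean(axis=0), atol=1e-12)

    def test_membership_proportions_sum_to_one(self, scored):
        _, _, pos, neg = scored
        for s in (pos, neg):
            assert sum(s.membership.values()) == pytest.approx(1.0)
            assert all(len(e) == 1000 for e in s.ellipses.values())

    def test_below_minimum_refused_without_override(self, fitted_pipeline):
        _, amap, model = fitted_pipeline
        sample = am.sample_profile("positive", MIN_EVALUATIONS - 1, seed=5)
        with pytest.raises(SampleSizeError, match="30"):
            am.score_medicine(amap, model, sample, "too few")
        score = am.score_medicine(amap, model, sample, "ok", allow_below_minimum=True)
        assert score.n_evals == MIN_EVALUATIONS - 1

    def test_incomplete_evaluations_rejected(self, fitted_pipeline):
        _, amap, model = fitted_pipeline
        sample = am.sample_profile("positive", 35, seed=6)
        sample[0].measures["reaction"] = None
        with pytest.raises(ValueError, match="missing"):
            am.score_medicine(amap, model, sample, "incomplete")

    def test_added_green_evaluation_never_flips_barycenter(self, scored, fitted_pipeline):
        _, amap, model = fitted_pipeline
        _, _, pos, _ = scored
        deep_green = am.sample_profile("positive", 41, seed=21)  # superset draw
        score2 = am.score_medicine(amap, model, deep_green, "augmented")
        assert score2.barycenter_label == "green"


class TestCompareScores:
    def test_score_overlaps_itself(self, scored):
        _, _, pos, _ = scored
        cmp = am.compare_scores(pos, pos)
        assert all(cmp.overlap_by_plane.values())
        assert not cmp.significantly_different

    def test_distant_ellipses_significantly_different(self, scored):
        _, _, pos, neg = scored
        shifted = am.AcceptabilityScore.from_dict(neg.to_dict())
        for plane in shifted.ellipses:
            shifted.ellipses[plane] = shifted.ellipses[plane] + 100.0
        cmp = am.compare_scores(pos, shifted)
        assert cmp.significantly_different
        assert not any(cmp.overlap_by_plane.values())

    def test_agrees_with_grid_membership_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(8):
            a = rng.normal(size=(40, 2))
            b = rng.normal(size=(40, 2)) + rng.uniform(0, 1.5, size=2)
            ea = am.confidence_ellipses(a, n_points=400)[(0, 1)]
            eb = am.confidence_ellipses(b, n_points=400)[(0, 1)]
            pa, pb = Polygon(ea), Polygon(eb)
            # grid oracle over the joint bounding box
            xmin, ymin = np.minimum(ea.min(axis=0), eb.min(axis=0)) - 1e-3
            xmax, ymax = np.maximum(ea.max(axis=0), eb.max(axis=0)) + 1e-3
            xs = np.arange(xmin, xmax, 1e-3)[:, None]
            grid_hit = False
            for y in np.arange(ymin, ymax, 5e-3):
                pts = np.hstack([xs, np.full_like(xs, y)])
                ina = np.array([pa.contains(Point(p)) for p in pts[:: 20]])
                inb = np.array([pb.contains(Point(p)) for p in pts[:: 20]])
                if (ina & inb).any():
                    grid_hit = True
                    break
            assert pa.intersects(pb) == grid_hit or pa.touches(pb)

    def test_cross_map_comparison_rejected(self, scored):
        _, _, pos, _ = scored
        other = am.AcceptabilityScore.from_dict(pos.to_dict())
        other.map_fingerprint = "some other map"
        with pytest.raises(ValueError, match="different reference maps"):
            am.compare_scores(pos, other)


@pytest.fixture(scope="module")
def completed_study(study_dataset):
    evaluations, _ = am.apply_worst_case_recoding(study_dataset.raw_observations)
    return am.impute_iterative_mca(am.build_indicator(evaluations)).completed


class TestScoreSubgroups:
    def test_partition_by_day_gives_three_scores(self, fitted_pipeline, completed_study,
                                                 study_dataset):
        _, amap, model = fitted_pipeline
        report = am.score_subgroups(amap, model, completed_study, study_dataset.patients, "day")
        assert [s.n_evals for s in report.scores] == [37, 36, 35]
        assert [s.label for s in report.scores] == ["day=D1", "day=D2", "day=D10"]
        assert len(report.comparisons) == 3

    def test_partition_by_sex_reports_comparison_and_confounding(
        self, fitted_pipeline, completed_study, study_dataset
    ):
        _, amap, model = fitted_pipeline
        report = am.score_subgroups(amap, model, completed_study, study_dataset.patients, "sex")
        assert {s.label for s in report.scores} == {"sex=girl", "sex=boy"}
        assert len(report.comparisons) == 1
        names = [name for name, _, _ in report.confounding]
        assert names == ["sex x age", "exposure x age", "sex x exposure"]
        for _, _, result in report.confounding:
            assert 0 <= result.p_value <= 1

    def test_unknown_partition_key_rejected(self, fitted_pipeline, completed_study,
                                            study_dataset):
        _, amap, model = fitted_pipeline
        with pytest.raises(ValueError, match="height"):
            am.score_subgroups(amap, model, completed_study, study_dataset.patients, "height")

    def test_small_subgroup_warns_but_scores(self, fitted_pipeline, completed_study,
                                             study_dataset):
        _, amap, model = fitted_pipeline
        with pytest.warns(UserWarning, match="reliability floor"):
            report = am.score_subgroups(
                amap, model, completed_study, study_dataset.patients, "age"
            )
        assert {s.label for s in report.scores} == {"age=3", "age=4", "age=5"}
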