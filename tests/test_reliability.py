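"""MEAD, RMSE, and inter-rater ICC validation metrics."""

import math

import numpy as np
import pytest

from facegest import FrameObservation, icc, mead, rmse
from facegest.reliability import icc2_single
from facegest.synthetic import eight_class_scenario, generate, make_two_raters


def frames_at(coords_list, clip_id="c", likelihood=None, scheme_size=13):
    out = []
    for i, coords in enumerate(coords_list):
        lik = np.ones(scheme_size) if likelihood is None else np.asarray(likelihood[i])
        out.append(FrameObservation(clip_id, i, np.asarray(coords, float), lik))
    return out


def grid_coords(rng, n_frames, scheme_size=13):
    return [rng.uniform(0, 500, size=(scheme_size, 2)) for _ in range(n_frames)]


class TestMead:
    def test_identical_sets_have_zero_error_and_full_detections(self, scheme):
        rng = np.random.default_rng(0)
        manual = frames_at(grid_coords(rng, 6))
        predicted = frames_at([m.coords.copy() for m in manual])
        report = mead(manual, predicted, scheme)
        assert report.overall_mean == 0.0
        assert (report.per_landmark["n_detections"] == 6).all()

    def test_three_four_five_offset_gives_error_five(self, scheme):
        rng = np.random.default_rng(1)
        manual = frames_at(grid_coords(rng, 4))
        predicted = frames_at([m.coords + np.array([3.0, 4.0]) for m in manual])
        report = mead(manual, predicted, scheme)
        assert report.overall_mean == pytest.approx(5.0)
        assert report.per_landmark["mead"].to_numpy() == pytest.approx(5.0)

    def test_cutoff_exclusion_is_strict_at_the_boundary(self, scheme):
        rng = np.random.default_rng(2)
        manual = frames_at(grid_coords(rng, 5))
        lik = np.ones((5, 13))
        j = scheme.index("Mouth_Left")
        lik[:, j] = 0.6  # exactly at the cutoff: "higher than" excludes it
        predicted = frames_at([m.coords.copy() for m in manual], likelihood=lik)
        report = mead(manual, predicted, scheme, cutoff=0.6)
        assert report.per_landmark.loc["Mouth_Left", "n_detections"] == 0
        assert np.isnan(report.per_landmark.loc["Mouth_Left", "mead"])

    def test_landmark_below_cutoff_everywhere_reported_absent(self, scheme):
        rng = np.random.default_rng(3)
        manual = frames_at(grid_coords(rng, 5))
        lik = np.ones((5, 13))
        lik[:, scheme.index("Nosetip")] = 0.5
        predicted = frames_at([m.coords.copy() for m in manual], likelihood=lik)
        report = mead(manual, predicted, scheme, cutoff=0.6)
        assert report.per_landmark.loc["Nosetip", "n_detections"] == 0

    def test_missing_manual_point_excluded_despite_high_likelihood(self, scheme):
        rng = np.random.default_rng(4)
        manual = frames_at(grid_coords(rng, 3))
        j = scheme.index("Mouth_Top")
        manual[0].coords[j] = np.nan
        manual[0].likelihood[j] = 0.0
        predicted = frames_at([np.nan_to_num(m.coords, nan=1.0) for m in manual])
        report = mead(manual, predicted, scheme)
        assert report.per_landmark.loc["Mouth_Top", "n_detections"] == 2

    def test_disjoint_frames_error(self, scheme):
        rng = np.random.default_rng(5)
        manual = frames_at(grid_coords(rng, 2), clip_id="a")
        predicted = frames_at(grid_coords(rng, 2), clip_id="b")
        with pytest.raises(ValueError, match="overlap"):
            mead(manual, predicted, scheme)

    def test_rigid_transform_of_both_sets_is_invariant(self, scheme):
        rng = np.random.default_rng(6)
        manual = frames_at(grid_coords(rng, 5))
        predicted = frames_at(
            [m.coords + rng.normal(0, 3, size=(13, 2)) for m in manual]
        )
        theta = 0.6
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        shift = np.array([40.0, -17.0])
        manual2 = frames_at([m.coords @ rot.T + shift for m in manual])
        predicted2 = frames_at([p.coords @ rot.T + shift for p in predicted])
        a = mead(manual, predicted, scheme)
        b = mead(manual2, predicted2, scheme)
        assert b.overall_mean == pytest.approx(a.overall_mean, rel=1e-9)

    def test_uniform_scaling_is_equivariant(self, scheme):
        rng = np.random.default_rng(7)
        manual = frames_at(grid_coords(rng, 5))
        predicted = frames_at(
            [m.coords + rng.normal(0, 3, size=(13, 2)) for m in manual]
        )
        manual3 = frames_at([3.0 * m.coords for m in manual])
        predicted3 = frames_at([3.0 * p.coords for p in predicted])
        a = mead(manual, predicted, scheme)
        b = mead(manual3, predicted3, scheme)
        assert b.overall_mean == pytest.approx(3.0 * a.overall_mean, rel=1e-9)


class TestRmse:
    def test_identical_sets_give_zero(self, scheme):
        rng = np.random.default_rng(8)
        labeled = frames_at(grid_coords(rng, 4))
        predicted = frames_at([m.coords.copy() for m in labeled])
        per_landmark, pooled = rmse(labeled, predicted, scheme)
        assert pooled == 0.0
        assert (per_landmark == 0.0).all()

    def test_constant_offset_zero_three_gives_three(self, scheme):
        rng = np.random.default_rng(9)
        labeled = frames_at(grid_coords(rng, 4))
        predicted = frames_at([m.coords + np.array([0.0, 3.0]) for m in labeled])
        per_landmark, pooled = rmse(labeled, predicted, scheme)
        assert pooled == pytest.approx(3.0)
        assert per_landmark.to_numpy() == pytest.approx(3.0)

    def test_random_errors_match_accumulation_oracle(self, scheme):
        rng = np.random.default_rng(10)
        labeled = frames_at(grid_coords(rng, 6))
        predicted = frames_at(
            [m.coords + rng.normal(0, 2, size=(13, 2)) for m in labeled]
        )
        per_landmark, pooled = rmse(labeled, predicted, scheme)
        sq_sum, count = 0.0, 0
        for m, p in zip(labeled, predicted):
            for j in range(13):
                sq_sum += math.dist(m.coords[j], p.coords[j]) ** 2
                count += 1
        assert pooled == pytest.approx(math.sqrt(sq_sum / count), rel=1e-12)


@pytest.fixture(scope="module")
def truth_dataset():
    return generate(eight_class_scenario(clips_per_class=2, seed=13))


class TestIcc:
    def test_identical_raters_give_one(self, scheme, truth_dataset):
        a, _ = make_two_raters(truth_dataset, 0.0, seed=1)
        report = icc(a, a, scheme)
        assert report.estimate == 1.0

    def test_small_rater_noise_gives_high_agreement(self, scheme, truth_dataset):
        # rater noise far below the between-subject coordinate spread
        a, b = make_two_raters(truth_dataset, 3.0, seed=2)
        report = icc(a, b, scheme)
        assert report.estimate > 0.95
        assert report.ci_lower <= report.estimate <= report.ci_upper
        assert set(report.per_axis) == {"x", "y"}

    def test_unrelated_relabeling_gives_near_zero(self, scheme, truth_dataset):
        rng = np.random.default_rng(3)
        a, _ = make_two_raters(truth_dataset, 0.0, seed=3)
        b = [
            FrameObservation(
                o.clip_id, o.frame_index,
                rng.uniform(0, 900, size=o.coords.shape), np.ones(13),
            )
            for o in a
        ]
        report = icc(a, b, scheme)
        assert abs(report.estimate) < 0.1

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(4)
        truth = rng.normal(0, 10, 40)
        ratings = np.column_stack(
            [truth + rng.normal(0, 1, 40), truth + rng.normal(0, 1, 40)]
        )
        est, lo, hi = icc2_single(ratings)
        long = pd.DataFrame(
            {
                "s": np.tile(np.arange(40), 2),
                "r": np.repeat(["A", "B"], 40),
                "v": np.r_[ratings[:, 0], ratings[:, 1]],
            }
        )
        ref = pg.intraclass_corr(long, targets="s", raters="r", ratings="v")
        ref_row = ref.loc[ref["Type"] == "ICC(A,1)"].iloc[0]
        assert est == pytest.approx(float(ref_row["ICC"]), abs=1e-10)
        # pingouin rounds its CI to 2 decimals
        assert lo == pytest.approx(ref_row["CI95"][0], abs=0.005)
        assert hi == pytest.approx(ref_row["CI95"][1], abs=0.005)

    def test_variance_component_recovery(self):
        # closed form: ICC = sigma_b^2 / (sigma_b^2 + sigma_r^2); over
        # replicates the 95% CI covers it at the nominal rate and the mean
        # estimate sits on the population value
        rng = np.random.default_rng(5)
        sigma_b, sigma_r, n, reps = 10.0, 2.0, 300, 40
        population = sigma_b**2 / (sigma_b**2 + sigma_r**2)
        covered, estimates = 0, []
        for _ in range(reps):
            truth = rng.normal(0, sigma_b, n)
            ratings = np.column_stack(
                [truth + rng.normal(0, sigma_r, n), truth + rng.normal(0, sigma_r, n)]
            )
            est, lo, hi = icc2_single(ratings)
            covered += lo <= population <= hi
            estimates.append(est)
        assert covered >= 33  # ~4 SD below the nominal 38/40
        se = np.std(estimates, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(estimates) - population) < 4 * se + 1e-3

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            icc2_single(np.array([[1.0, 2.0]]))
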