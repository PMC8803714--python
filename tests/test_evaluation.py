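"""Agreement statistics: Dice, matching, sensitivity, Pearson, ICC(2,1), SD."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from promisequant.evaluation import (
    AgreementReport,
    MatchResult,
    dice,
    icc2,
    make_report,
    match_lesions,
    pearson,
    reference_sd,
    sensitivity,
)
from promisequant.grid import VoxelGrid
from promisequant.phantom import LesionTruth
from promisequant.segmentation import quantify


class TestDice:
    def test_identical_masks(self):
        m = np.random.default_rng(0).random((6, 6, 6)) > 0.5
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[1, 1, 1] = True
        assert dice(a, b) == 0.0

    def test_printed_formula_case(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = a[0, 0, 1] = True
        b[0, 0, 1] = b[0, 0, 2] = True
        assert dice(a, b) == 0.5

    def test_both_empty_defined_as_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert dice(np.zeros((3, 3, 3), bool), np.zeros((3, 3, 3), bool)) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((3, 3, 3), bool), np.zeros((4, 4, 4), bool))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=arrays(bool, (5, 5, 5), elements=st.booleans()),
        b=arrays(bool, (5, 5, 5), elements=st.booleans()),
    )
    def test_symmetry_bounds_and_subset_identity(self, a, b):
        if not (a.any() or b.any()):
            return
        d = dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dice(b, a)
        both = a | b
        if a.any():
            # a vs a-union-b: forced value 2|A| / (|A| + |A∪B|)
            assert dice(a, both) == 2 * a.sum() / (a.sum() + both.sum())

    def test_symmetry_and_set_counting_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a = rng.random((8, 8, 8)) > rng.uniform(0.3, 0.9)
            b = rng.random((8, 8, 8)) > rng.uniform(0.3, 0.9)
            if not a.any() and not b.any():
                continue
            inter = sum(
                1 for i in zip(*np.nonzero(a)) if b[i]
            )
            expected = 2 * inter / (a.sum() + b.sum())
            assert dice(a, b) == expected
            assert dice(a, b) == dice(b, a)


def _truth_lesion(center_mm, diameter_mm=12.0, shape=(20, 20, 20), spacing=3.0):
    x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = ((x * spacing - center_mm[0]) ** 2 + (y * spacing - center_mm[1]) ** 2
          + (z * spacing - center_mm[2]) ** 2)
    return LesionTruth(
        mask=d2 <= (diameter_mm / 2) ** 2, center_mm=center_mm,
        diameter_mm=diameter_mm, peak_suv=5.0, realized_suvmax=4.0, compartment="lymph",
    )


def _detection(center_mm, response=1.0, shape=(20, 20, 20), spacing=3.0):
    g = VoxelGrid(data=np.full(shape, 2.0), spacing=(spacing,) * 3)
    x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = ((x * spacing - center_mm[0]) ** 2 + (y * spacing - center_mm[1]) ** 2
          + (z * spacing - center_mm[2]) ** 2)
    mask = d2 <= 36.0
    from promisequant.detection import LesionCandidate

    cand = LesionCandidate(
        seed_index=tuple(int(round(c / spacing)) for c in center_mm),
        position_mm=center_mm, scale_mm=12.0, response=response, compartment="lymph",
    )
    return quantify(g, mask, cand)


class TestMatching:
    def test_perfect_detections_all_matched(self):
        truths = [_truth_lesion((15, 15, 15)), _truth_lesion((45, 45, 45))]
        dets = [_detection((15, 15, 15)), _detection((45, 45, 45))]
        m = match_lesions(truths, dets)
        assert m.n_matched == 2 and m.false_positives == []

    def test_no_detections_all_missed(self):
        truths = [_truth_lesion((15, 15, 15))]
        m = match_lesions(truths, [])
        assert m.pairs == [] and m.missed_truth == [0]

    def test_one_to_one_second_detection_is_fp(self):
        truths = [_truth_lesion((15, 15, 15))]
        dets = [_detection((15, 15, 15), response=2.0), _detection((18, 15, 15), response=1.0)]
        m = match_lesions(truths, dets)
        assert m.n_matched == 1 and len(m.false_positives) == 1
        # the higher-response detection wins the match
        assert m.pairs == [(0, 0)]


class TestSensitivity:
    def test_9_of_10(self):
        m = MatchResult(pairs=[(i, i) for i in range(9)], missed_truth=[9],
                        false_positives=[])
        pct, (lo, hi) = sensitivity(m)
        assert pct == 90.0
        assert lo < 90.0 < hi <= 100.0

    def test_all_matched(self):
        m = MatchResult(pairs=[(0, 0)], missed_truth=[], false_positives=[])
        assert sensitivity(m)[0] == 100.0

    def test_table_scale_arithmetic(self):
        m = MatchResult(pairs=[(i, i) for i in range(172)],
                        missed_truth=list(range(172, 188)), false_positives=[])
        assert sensitivity(m)[0] == pytest.approx(91.489, abs=0.001)

    def test_sensitivity_plus_miss_rate_is_100(self):
        m = MatchResult(pairs=[(0, 0), (1, 1)], missed_truth=[2, 3, 4],
                        false_positives=[9])
        pct, _ = sensitivity(m)
        miss = 100.0 * len(m.missed_truth) / m.n_truth
        assert pct + miss == 100.0

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            sensitivity(MatchResult(pairs=[], missed_truth=[], false_positives=[]))


class TestPearson:
    def test_perfect_correlation(self):
        r, _ = pearson([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        r, _ = pearson([1, 2, 3, 4], [-1, -2, -3, -4])
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 4.0])
        expected = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        r, (lo, hi) = pearson(x, y)
        assert r == pytest.approx(expected, abs=1e-12)
        assert lo <= r <= hi

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])


class TestICC2:
    def test_identical_columns_give_one(self):
        m = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        assert abs(icc2(m) - 1.0) <= 1e-12

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(0)
        subjects = np.full(200, 3.0)  # no subject variance
        m = subjects[:, None] + rng.normal(0, 2.0, (200, 3))
        assert abs(icc2(m)) < 0.15

    def test_matches_anova_oracle_and_pingouin(self):
        # Shrout–Fleiss-style 6 subjects x 4 raters matrix
        m = np.array(
            [[9, 2, 5, 8], [6, 1, 3, 2], [8, 4, 6, 8],
             [7, 1, 2, 6], [10, 5, 6, 9], [6, 2, 4, 7]], dtype=float
        )
        got = icc2(m)
        # independent oracle: explicit two-way ANOVA mean squares
        n, k = m.shape
        grand = m.mean()
        msr = k * ((m.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((m.mean(0) - grand) ** 2).sum() / (k - 1)
        sse = ((m - m.mean(1, keepdims=True) - m.mean(0, keepdims=True) + grand) ** 2).sum()
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert got == pytest.approx(expected, abs=1e-12)
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        df = pd.DataFrame(
            {"subject": np.repeat(np.arange(n), k),
             "rater": np.tile(np.arange(k), n),
             "score": m.ravel()}
        )
        ref = pingouin.intraclass_corr(
            data=df, targets="subject", raters="rater", ratings="score"
        )
        # two-way random, absolute agreement, single rater: labelled ICC2 or ICC(A,1)
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])]
        assert got == pytest.approx(float(row["ICC"].iloc[0]), abs=1e-9)

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, np.nan], [2.0, 2.0]])
        with pytest.raises(ValueError):
            icc2(m)


class TestReferenceSD:
    def test_constant_values(self):
        assert reference_sd({"m": np.array([2.0, 2.0, 2.0])})["m"] == 0.0

    def test_closed_form(self):
        assert reference_sd({"m": np.array([1.0, 2.0, 3.0])})["m"] == pytest.approx(1.0)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            reference_sd({"m": np.array([1.0])})


class TestReport:
    def test_empty_report_valid(self):
        report = make_report()
        doc = json.loads(report.to_json())
        assert doc["schema_version"] == 1

    def test_json_round_trip(self, tmp_path):
        report = make_report(
            dice_per_region={"femur": 0.95},
            icc_matrices={"SUVmax": np.array([[1.0, 1.0], [2.0, 2.0]])},
        )
        report.to_json(tmp_path / "r.json")
        back = AgreementReport.from_json(tmp_path / "r.json")
        assert back == report

    def test_csv_row_count(self, tmp_path):
        import pandas as pd

        report = make_report(
            dice_per_region={"femur": 0.95, "thorax": 0.88},
            pearson_pairs={"a_vs_b": (np.array([1.0, 2, 3]), np.array([1.1, 2, 3.2]))},
        )
        report.to_csv(tmp_path / "r.csv")
        assert len(pd.read_csv(tmp_path / "r.csv")) == 3

    def test_out_of_range_sensitivity_rejected(self):
        with pytest.raises(ValueError):
            AgreementReport(sensitivity_pct=120.0)
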