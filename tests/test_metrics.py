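"""Scoring metrics, selection rules, robustness machinery, statistics."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from ecgrecon.grid import ElectrodeCombination, GridLayout, enumerate_triangles
from ecgrecon.metrics import (
    LeadScores,
    bland_altman,
    compare_orientations,
    compare_shapes,
    icc_2_1,
    pearson_cc,
    r_square,
    rmse,
    robustness_map,
    score_combination,
    select_best,
)
from ecgrecon.metrics import _rowwise_icc2
from ecgrecon.preprocess import LEAD_NAMES


class TestPearson:
    def test_identity_and_affine(self):
        x = np.array([0.3, 1.2, -0.7, 2.0, 0.1])
        assert pearson_cc(x, x) == pytest.approx(1.0)
        assert pearson_cc(x, -2 * x + 3) == pytest.approx(-1.0)

    def test_matches_sum_formula_oracle(self):
        """Direct computation from the raw-sums formula."""
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 5.0])
        n = len(x)
        num = n * np.sum(x * y) - x.sum() * y.sum()
        den = math.sqrt(n * np.sum(x**2) - x.sum() ** 2) * math.sqrt(
            n * np.sum(y**2) - y.sum() ** 2
        )
        assert pearson_cc(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_cc(np.ones(5), np.arange(5.0))


class TestErrorMetrics:
    def test_identical_signals(self):
        x = np.sin(np.linspace(0, 9, 120))
        assert rmse(x, x) == 0.0
        assert r_square(x, x) == pytest.approx(1.0)
        assert icc_2_1(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_mean_predictor_gives_zero_r2(self):
        x = np.array([1.0, 2.0, 3.0, 6.0])
        pred = np.full_like(x, x.mean())
        assert r_square(x, pred) == pytest.approx(0.0, abs=1e-12)

    def test_rmse_formula(self):
        assert rmse([0, 0, 0, 0], [1, -1, 1, -1]) == pytest.approx(1.0)

    def test_icc_matches_mean_squares_oracle(self):
        """4-target x 2-rater toy table against the hand-computed two-way
        ANOVA mean-squares formula."""
        table = np.array([[9.0, 2.0], [1.0, 10.0], [8.0, 8.0], [2.0, 6.0]])
        n, k = table.shape
        grand = table.mean()
        msr = k * np.sum((table.mean(axis=1) - grand) ** 2) / (n - 1)
        msc = n * np.sum((table.mean(axis=0) - grand) ** 2) / (k - 1)
        sse = (
            np.sum((table - grand) ** 2)
            - k * np.sum((table.mean(axis=1) - grand) ** 2)
            - n * np.sum((table.mean(axis=0) - grand) ** 2)
        )
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_2_1(table) == pytest.approx(expected, abs=1e-12)

    def test_icc_matches_pingouin(self):
        """Independent library oracle for ICC(2,1)."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        base = rng.normal(size=12)
        table = np.column_stack([base, base + 0.4 * rng.normal(size=12)])
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 2),
                "raters": np.tile(["a", "b"], 12),
                "scores": table.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="targets", raters="raters", ratings="scores"
        )
        # two-way random, absolute agreement, single measures
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_2_1(table) == pytest.approx(icc2, abs=1e-10)

    def test_vectorized_icc_matches_scalar(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(size=(5, 300))
        pred = ref + 0.3 * rng.normal(size=(5, 300))
        vec = _rowwise_icc2(ref, pred)
        for i in range(5):
            assert vec[i] == pytest.approx(
                icc_2_1(np.column_stack([ref[i], pred[i]])), abs=1e-10
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rmse([], [])


class TestBlandAltman:
    def test_limits_symmetric_about_bias(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=500)
        pred = ref + 0.2 + 0.1 * rng.normal(size=500)
        ba = bland_altman(ref, pred)
        assert ba.loa_high - ba.bias == pytest.approx(ba.bias - ba.loa_low)

    def test_limits_cover_about_95_percent_of_gaussian_differences(self):
        rng = np.random.default_rng(6)
        n = 5000
        ref = rng.normal(size=n)
        pred = ref + 0.05 + 0.3 * rng.normal(size=n)
        ba = bland_altman(ref, pred)
        d = pred - ref
        coverage = np.mean((d >= ba.loa_low) & (d <= ba.loa_high))
        assert coverage == pytest.approx(0.95, abs=0.02)


def _scores_from_lead_ccs(ccs: dict[str, float]) -> LeadScores:
    per_lead = pd.DataFrame(
        {
            "lead": list(ccs),
            "mean_cc": list(ccs.values()),
            "median_cc": list(ccs.values()),
            "mean_rmse_uV": [10.0] * len(ccs),
            "mean_r2": [0.9] * len(ccs),
            "icc": [0.9] * len(ccs),
        }
    )
    per_subject = per_lead.rename(columns={"mean_cc": "cc"}).assign(
        subject_id="S01", rmse_uV=10.0, r2=0.9
    )
    return LeadScores(per_subject=per_subject, per_lead=per_lead)


class TestSelection:
    def test_single_combination_wins_both_approaches(self):
        combo = ElectrodeCombination((1, 2, 6, 7))
        scores = _scores_from_lead_ccs({l: 0.9 for l in LEAD_NAMES})
        for approach in ("meanCC", "minCC"):
            sel = select_best([(combo, scores)], approach)
            assert sel.combination is combo
            assert sel.score == pytest.approx(0.9)

    def test_mean_and_min_can_disagree(self):
        a = ElectrodeCombination((1, 2, 6, 7))
        b = ElectrodeCombination((3, 4, 8, 9))
        cc_a = {l: 0.95 for l in LEAD_NAMES} | {"aVL": 0.40}
        cc_b = {l: 0.85 for l in LEAD_NAMES} | {"aVL": 0.80}
        scored = [
            (a, _scores_from_lead_ccs(cc_a)),
            (b, _scores_from_lead_ccs(cc_b)),
        ]
        assert select_best(scored, "meanCC").combination is a
        assert select_best(scored, "minCC").combination is b

    def test_min_score_never_exceeds_mean_score(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            ccs = dict(zip(LEAD_NAMES, rng.uniform(-1, 1, size=12)))
            s = _scores_from_lead_ccs(ccs)
            assert s.min_cc_score <= s.mean_cc_score + 1e-12

    def test_tie_breaks_toward_lowest_id_tuple(self):
        a = ElectrodeCombination((2, 3, 7, 8))
        b = ElectrodeCombination((1, 2, 6, 7))
        scores = _scores_from_lead_ccs({l: 0.9 for l in LEAD_NAMES})
        sel = select_best([(a, scores), (b, scores)], "meanCC")
        assert sel.combination is b

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_best([], "meanCC")


class TestScoreCombination:
    class _StubModel:
        """Predicts the reference exactly, except an optional corrupted lead."""

        def __init__(self, ref_matrix, corrupt_lead=None, seed=0):
            self.ref = ref_matrix
            self.corrupt = corrupt_lead
            self.rng = np.random.default_rng(seed)

        def predict(self, X):
            out = self.ref.T.copy()
            if self.corrupt is not None:
                j = LEAD_NAMES.index(self.corrupt)
                out[:, j] = self.rng.normal(size=out.shape[0])
            return out

    def _merged(self):
        from ecgrecon.preprocess import MergedRecording, SegmentInfo

        rng = np.random.default_rng(8)
        n = 600
        rec = MergedRecording(
            fs=100.0,
            chest=rng.normal(size=(35, n)),
            limb_electrodes={k: rng.normal(size=n) for k in ("LA", "RA", "LL")},
            precordial_electrodes={f"V{i}": rng.normal(size=n) for i in range(1, 7)},
            segments=[
                SegmentInfo("S01", 2, 0.0, 0, 300),
                SegmentInfo("S02", 2, 0.0, 300, 600),
            ],
        )
        return rec

    def test_perfect_reconstruction_scores_one(self):
        from ecgrecon.preprocess import derive_12lead

        merged = self._merged()
        ref = derive_12lead(merged).matrix()
        scores = score_combination(
            self._StubModel(ref), merged, ElectrodeCombination((1, 2, 6, 7))
        )
        assert scores.mean_cc_score == pytest.approx(1.0)
        assert float(scores.per_lead["mean_rmse_uV"].max()) == pytest.approx(0.0)
        assert float(scores.per_lead["icc"].min()) == pytest.approx(1.0)

    def test_corrupted_lead_scores_near_zero_others_unchanged(self):
        from ecgrecon.preprocess import derive_12lead

        merged = self._merged()
        ref = derive_12lead(merged).matrix()
        scores = score_combination(
            self._StubModel(ref, corrupt_lead="V3"),
            merged,
            ElectrodeCombination((1, 2, 6, 7)),
        )
        per_lead = scores.per_lead.set_index("lead")["mean_cc"]
        assert abs(per_lead["V3"]) < 0.25
        for lead in LEAD_NAMES:
            if lead != "V3":
                assert per_lead[lead] == pytest.approx(1.0)


class TestRobustnessMap:
    def _uniform_scores(self, triangles, value=0.8):
        return {t.key(): value for t in triangles}

    def test_interior_triangle_averages_four_shifts(self, grid):
        triangles = enumerate_triangles(grid)
        frame = robustness_map(self._uniform_scores(triangles), triangles, grid)
        # interior placements: squares at columns 2..4, rows 2 (of 1..3)
        interior = frame[frame["n_shifts"] == 4]
        assert len(interior) > 0
        boundary = frame[frame["n_shifts"] < 4]
        assert len(boundary) > 0
        # a triangle whose 10x10 square sits at the grid corner shifts
        # in exactly two directions
        corner = frame[frame["ids"].map(lambda t: set(t) <= {1, 3, 7, 11, 13})]
        assert (corner["n_shifts"] == 2).all()

    def test_uniform_scores_give_constant_map(self, grid):
        triangles = enumerate_triangles(grid)
        frame = robustness_map(self._uniform_scores(triangles, 0.7), triangles, grid)
        assert np.allclose(frame["robust_score"], 0.7)

    def test_unshifted_position_optionally_included(self, grid):
        triangles = enumerate_triangles(grid)
        frame = robustness_map(
            self._uniform_scores(triangles), triangles, grid, include_unshifted=True
        )
        assert (frame["n_shifts"] == frame["n_shifts"].clip(3, 5)).all()
        assert frame["directions"].str.startswith("center").all()


class TestStatisticalComparisons:
    def test_wilcoxon_all_positive_differences_gives_zero_statistic(self):
        a = np.array([1.0, 2, 3, 4, 5, 6])
        b = np.array([2.0, 3, 4, 6, 7, 9])
        w, p = compare_shapes(a, b)
        assert w == 0.0
        assert 0 < p < 0.1

    def test_wilcoxon_degenerate_rejected(self):
        x = np.arange(6.0)
        with pytest.raises(ValueError):
            compare_shapes(x, x)

    def test_wilcoxon_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=168)
        b = a + 0.1 + 0.2 * rng.normal(size=168)
        w, p = compare_shapes(a, b)
        assert 0 <= p <= 1

    def test_anova_matches_mean_squares_oracle(self):
        """3-group toy table against hand-computed between/within MS ratio."""
        groups = [
            np.array([1.0, 2.0, 3.0]),
            np.array([2.0, 4.0, 6.0]),
            np.array([5.0, 6.0, 10.0]),
        ]
        allv = np.concatenate(groups)
        grand = allv.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_expected = (ss_between / 2) / (ss_within / (len(allv) - 3))
        table = compare_orientations({"I": groups})
        assert float(table.loc[0, "F"]) == pytest.approx(f_expected, abs=1e-10)

    def test_anova_requires_replicates(self):
        with pytest.raises(ValueError):
            compare_orientations({"I": [np.array([1.0]), np.array([2.0, 3.0])]})
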