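"""Reconstruction scoring, combination selection, robustness, statistics.

Per (subject, lead) the reconstructed signal is compared with the reference
on that subject's test segment via Pearson CC, RMSE (uV), R^2 about the
reference mean, and ICC(2,1) (two-way random effects, absolute agreement,
single measures). Per-lead aggregates (mean/median CC, mean RMSE, mean ICC)
feed two selection rules over the 12 leads:

* meanCC — score a combination by the mean of its 12 per-lead mean CCs;
* minCC  — score it by the minimum of the same 12 values, which guards the
  worst-reconstructed lead. The minimum is taken lead-wise after averaging
  over subjects (per-lead minima are the quantity of clinical interest:
  a single poorly reconstructed lead, typically aVL or III, dominates).

min over 12 values never exceeds their mean, so minCC score <= meanCC score
for every combination.

Positional robustness: each right-angled-triangle patch is re-scored as the
average of its one-lattice-step shifted variants (up/down/left/right, only
those that stay on the grid), emulating a misplaced patch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grid import ElectrodeCombination, GridLayout, compute_chest_leads, shift_combination
from .models import predict
from .preprocess import LEAD_NAMES, MergedRecording, derive_12lead

__all__ = [
    "pearson_cc",
    "rmse",
    "r_square",
    "icc_2_1",
    "bland_altman",
    "BlandAltmanStats",
    "LeadScores",
    "SelectionResult",
    "score_combination",
    "select_best",
    "robustness_map",
    "compare_shapes",
    "compare_orientations",
]

APPROACHES = ("meanCC", "minCC")


def _paired(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size == 0:
        raise ValueError("inputs are empty")
    return x, y


def pearson_cc(x, y) -> float:
    """Pearson correlation coefficient between two equal-length signals."""
    x, y = _paired(x, y)
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt((xd**2).sum())
    sy = np.sqrt((yd**2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for constant input")
    return float((xd @ yd) / (sx * sy))


def rmse(x, y) -> float:
    """Root-mean-square error, in the units of the inputs."""
    x, y = _paired(x, y)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def r_square(ref, pred) -> float:
    """R^2 = 1 - SS_res / SS_tot about the reference mean."""
    ref, pred = _paired(ref, pred)
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant reference")
    ss_res = float(np.sum((ref - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def icc_2_1(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``ratings`` is (n_targets, k_raters); here the raters are the reference
    and the reconstruction, and targets are time samples. Computed from the
    two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[0] < 2 or ratings.shape[1] < 2:
        raise ValueError("ratings must be (n >= 2 targets, k >= 2 raters)")
    n, k = ratings.shape
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((ratings - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ValueError("ICC undefined: zero variance in ratings")
    return float((msr - mse) / denom)


@dataclass(frozen=True)
class BlandAltmanStats:
    """Agreement summary: bias, +/-1.96 SD limits, and difference-vs-mean slope."""

    bias: float
    loa_low: float
    loa_high: float
    slope: float
    sd_diff: float

    @property
    def half_width(self) -> float:
        return 1.96 * self.sd_diff


def bland_altman(ref, pred) -> BlandAltmanStats:
    """Bland–Altman agreement between paired measurements (caller's units)."""
    ref, pred = _paired(ref, pred)
    diff = pred - ref
    mean = (pred + ref) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    if np.ptp(mean) > 0:
        slope = float(stats.linregress(mean, diff).slope)
    else:
        slope = 0.0
    return BlandAltmanStats(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        slope=slope, sd_diff=sd,
    )


# ---------------------------------------------------------------------------
# Combination scoring and selection.


@dataclass
class LeadScores:
    """Per-(subject, lead) and per-lead reconstruction scores.

    ``per_subject`` columns: subject_id, lead, cc, rmse_uV, r2, icc.
    ``per_lead`` columns: lead, mean_cc, median_cc, mean_rmse_uV, mean_r2, icc.
    """

    per_subject: pd.DataFrame
    per_lead: pd.DataFrame

    @property
    def mean_cc_score(self) -> float:
        """meanCC selection score: mean over the 12 per-lead mean CCs."""
        return float(self.per_lead["mean_cc"].mean())

    @property
    def min_cc_score(self) -> float:
        """minCC selection score: minimum over the 12 per-lead mean CCs."""
        return float(self.per_lead["mean_cc"].min())

    def score(self, approach: str) -> float:
        if approach == "meanCC":
            return self.mean_cc_score
        if approach == "minCC":
            return self.min_cc_score
        raise ValueError(f"unknown approach {approach!r} (use meanCC or minCC)")


def _rowwise_cc(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    num = (A * B).sum(axis=1)
    den = np.sqrt((A**2).sum(axis=1) * (B**2).sum(axis=1))
    if np.any(den == 0):
        raise ValueError("correlation undefined for constant channel")
    return num / den


def _rowwise_icc2(ref: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Vectorized ICC(2,1) with k = 2 raters per row of (n_rows, T)."""
    n = ref.shape[1]
    grand = (ref + pred).mean(axis=1, keepdims=True) / 2.0
    row_means = (ref + pred) / 2.0  # per-target means, (n_rows, T)
    c_ref = ref.mean(axis=1, keepdims=True)
    c_pred = pred.mean(axis=1, keepdims=True)
    ssr = 2.0 * ((row_means - grand) ** 2).sum(axis=1)
    ssc = n * ((c_ref - grand) ** 2 + (c_pred - grand) ** 2).ravel()
    sst = ((ref - grand) ** 2).sum(axis=1) + ((pred - grand) ** 2).sum(axis=1)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc  # / (k - 1) with k = 2
    mse = sse / (n - 1)
    denom = msr + mse + (2.0 / n) * (msc - mse)
    return (msr - mse) / denom


def score_combination(
    model,
    test_merged: MergedRecording,
    combination: ElectrodeCombination,
    reference_leads=None,
) -> LeadScores:
    """Score a fitted model for one combination on the merged test signal.

    CC/RMSE/R^2/ICC are computed per subject segment and per lead; the
    per-lead table aggregates over subjects. ``reference_leads`` (a
    :class:`LeadSet12`) can be passed to avoid re-deriving the reference.
    """
    leads = reference_leads if reference_leads is not None else derive_12lead(test_merged)
    ref = leads.matrix()  # (12, N)
    cl = compute_chest_leads(test_merged.chest, combination)
    recon = predict(model, cl.cl)  # (12, N)
    if not test_merged.segments:
        raise ValueError("merged test signal carries no segment boundaries")
    rows = []
    for seg in test_merged.segments:
        sl = slice(seg.start_idx, seg.stop_idx)
        r = ref[:, sl]
        p = recon[:, sl]
        cc = _rowwise_cc(r, p)
        rm = np.sqrt(((r - p) ** 2).mean(axis=1))
        ss_tot = ((r - r.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        r2 = 1.0 - ((r - p) ** 2).sum(axis=1) / ss_tot
        icc = _rowwise_icc2(r, p)
        for j, lead in enumerate(LEAD_NAMES):
            rows.append(
                {
                    "subject_id": seg.subject_id,
                    "lead": lead,
                    "cc": cc[j],
                    "rmse_uV": rm[j],
                    "r2": r2[j],
                    "icc": icc[j],
                }
            )
    per_subject = pd.DataFrame(rows)
    g = per_subject.groupby("lead", sort=False)
    per_lead = pd.DataFrame(
        {
            "lead": list(g.groups),
            "mean_cc": g["cc"].mean().to_numpy(),
            "median_cc": g["cc"].median().to_numpy(),
            "mean_rmse_uV": g["rmse_uV"].mean().to_numpy(),
            "mean_r2": g["r2"].mean().to_numpy(),
            "icc": g["icc"].mean().to_numpy(),
        }
    )
    return LeadScores(per_subject=per_subject, per_lead=per_lead)


@dataclass
class SelectionResult:
    """Winning combination under one selection approach."""

    combination: ElectrodeCombination
    approach: str
    score: float
    scores: LeadScores


def select_best(
    scored: Sequence[tuple[ElectrodeCombination, LeadScores]],
    approach: str,
) -> SelectionResult:
    """Argmax of the selection score; ties break toward the lowest id tuple."""
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}")
    if not scored:
        raise ValueError("no scored combinations to select from")
    best = max(scored, key=lambda cs: (cs[1].score(approach), tuple(-i for i in cs[0].ids)))
    return SelectionResult(
        combination=best[0],
        approach=approach,
        score=best[1].score(approach),
        scores=best[1],
    )


def robustness_map(
    triangle_scores: Mapping[tuple[int, int, int, int], float]
    | Sequence[tuple[ElectrodeCombination, float]],
    triangles: Sequence[ElectrodeCombination],
    grid: GridLayout | None = None,
    include_unshifted: bool = False,
) -> pd.DataFrame:
    """Average each triangle's score over its valid one-step shifted variants.

    ``triangle_scores`` maps sorted id 4-tuples (or combinations) to the
    selection-metric value of that triangle; every shifted variant that stays
    on the grid is itself a triangle in the family and is looked up there.
    """
    grid = grid or GridLayout()
    if not isinstance(triangle_scores, Mapping):
        triangle_scores = {c.key(): s for c, s in triangle_scores}
    rows = []
    for tri in triangles:
        values = []
        directions = []
        if include_unshifted:
            values.append(triangle_scores[tri.key()])
            directions.append("center")
        for direction in ("up", "down", "left", "right"):
            shifted = shift_combination(tri, direction, grid)
            if shifted is None:
                continue
            if shifted.key() not in triangle_scores:
                raise KeyError(
                    f"shifted variant {shifted.key()} of {tri.key()} not scored"
                )
            values.append(triangle_scores[shifted.key()])
            directions.append(direction)
        rows.append(
            {
                "ids": tri.key(),
                "orientation": tri.orientation,
                "n_shifts": len(values),
                "directions": ",".join(directions),
                "robust_score": float(np.mean(values)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Statistical comparisons.


def compare_shapes(scores_a, scores_b):
    """Wilcoxon signed-rank test on paired (subject x lead) scores.

    Uses the exact null distribution for n <= 25 pairs (no ties, no zeros),
    otherwise the normal approximation with continuity correction. Returns
    ``(W, p)`` two-sided.
    """
    a, b = _paired(scores_a, scores_b)
    d = a - b
    if np.all(d == 0):
        raise ValueError("degenerate comparison: all paired differences are zero")
    nz = d[d != 0]
    exact_ok = nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size
    if exact_ok:
        res = stats.wilcoxon(a, b, method="exact")
    else:
        res = stats.wilcoxon(a, b, method="approx", correction=True)
    return float(res.statistic), float(res.pvalue)


def compare_orientations(per_lead_groups: Mapping[str, Sequence[np.ndarray]]):
    """Per-lead one-way ANOVA across triangle orientations.

    ``per_lead_groups`` maps each lead name to a list of >= 2 groups (one per
    orientation) of per-subject scores. Returns a DataFrame with F and p per
    lead.
    """
    rows = []
    for lead, groups in per_lead_groups.items():
        groups = [np.asarray(g, dtype=float) for g in groups]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            raise ValueError("ANOVA needs >= 2 groups with >= 2 replicates each")
        f, p = stats.f_oneway(*groups)
        rows.append({"lead": lead, "F": float(f), "p": float(p)})
    return pd.DataFrame(rows)
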