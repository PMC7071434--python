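"""End-to-end study: simulate -> preprocess -> enumerate -> fit -> score
-> select -> robustness -> report.

The study design mirrors a universal-coefficient electrode-placement
experiment: a cohort of subjects is recorded twice; one randomly placed 20 s
segment per subject and session is band-pass filtered and the segments are
pooled (session 1 -> training merge, session 2 -> test merge). For every
candidate 4-electrode combination, three chest leads are formed, a universal
MLR and/or 5-seed ANN ensemble is fitted on the pooled training merge, and
the reconstruction is scored per subject and lead on the pooled test merge.
Shape families are then ranked under the meanCC and minCC selection rules,
shapes are compared by Wilcoxon signed-rank on paired (subject x lead)
scores, triangle orientations by per-lead one-way ANOVA, and positional
robustness by averaging each triangle's score over its one-step shifted
variants.

All randomness flows from explicit seeds in :class:`StudyConfig`, so a rerun
with the same configuration reproduces every output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .grid import (
    ElectrodeCombination,
    GridLayout,
    compute_chest_leads,
    enumerate_all,
    enumerate_family,
)
from .metrics import (
    LeadScores,
    SelectionResult,
    bland_altman,
    compare_orientations,
    compare_shapes,
    robustness_map,
    score_combination,
    select_best,
)
from .models import EnsembleReconstructor, MLRReconstructor, predict
from .preprocess import (
    LEAD_NAMES,
    LeadSet12,
    MergedRecording,
    bandpass_recording,
    derive_12lead,
    extract_and_merge,
)
from .simulate import CohortConfig, MultichannelRecording, simulate_cohort

__all__ = [
    "StudyConfig",
    "PreparedData",
    "StudyResults",
    "RunManifest",
    "prepare_data",
    "fit_combination",
    "run_shape_study",
    "scan_all_mlr",
    "run_study",
    "report",
]

SHAPE_FAMILIES = ("square5", "square10", "triangle")


@dataclass(frozen=True)
class StudyConfig:
    """Complete, explicit-seeded configuration of one study run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    filter_low_hz: float = 0.5
    filter_high_hz: float = 35.0
    filter_order: int = 2
    segment_length_s: float = 20.0
    edge_guard_s: float = 2.0
    train_segment_seed: int = 11
    test_segment_seed: int = 22
    families: tuple[str, ...] = SHAPE_FAMILIES
    include_all_combinations: bool = False
    models: tuple[str, ...] = ("mlr", "ann")
    ann_hidden_units: int = 6
    ann_output_activation: str = "linear"
    ann_max_iter: int = 200
    ann_tol: float = 1e-10
    ann_train_stride: int = 8
    ensemble_seeds: tuple[int, ...] = (101, 102, 103, 104, 105)
    robustness_include_unshifted: bool = False

    def __post_init__(self) -> None:
        if self.cohort.n_sessions < 2:
            raise ValueError("the study design needs 2 sessions (train/test)")
        unknown = set(self.models) - {"mlr", "ann"}
        if unknown:
            raise ValueError(f"unknown model type(s): {sorted(unknown)}")
        if self.ann_train_stride < 1:
            raise ValueError("ann_train_stride must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class PreparedData:
    """Filtered, segmented, merged train/test signals with reference leads."""

    train: MergedRecording
    test: MergedRecording
    train_leads: LeadSet12
    test_leads: LeadSet12
    grid: GridLayout


def prepare_data(
    config: StudyConfig,
    recordings: Sequence[MultichannelRecording] | None = None,
) -> PreparedData:
    """Simulate (unless given), filter, segment, and merge the cohort."""
    if recordings is None:
        recordings = simulate_cohort(config.cohort)
    filtered = [
        bandpass_recording(
            r, config.filter_low_hz, config.filter_high_hz, config.filter_order
        )
        for r in recordings
    ]
    train_recs = [r for r in filtered if r.session_id == 1]
    test_recs = [r for r in filtered if r.session_id == 2]
    if not train_recs or not test_recs:
        raise ValueError("need session 1 (train) and session 2 (test) recordings")
    train = extract_and_merge(
        train_recs, config.train_segment_seed, config.segment_length_s,
        config.edge_guard_s,
    )
    test = extract_and_merge(
        test_recs, config.test_segment_seed, config.segment_length_s,
        config.edge_guard_s,
    )
    return PreparedData(
        train=train,
        test=test,
        train_leads=derive_12lead(train),
        test_leads=derive_12lead(test),
        grid=GridLayout(),
    )


def fit_combination(
    config: StudyConfig,
    data: PreparedData,
    combination: ElectrodeCombination,
    model_type: str,
):
    """Fit a universal transformation for one combination on the train merge."""
    cl = compute_chest_leads(data.train.chest, combination)
    X = cl.as_features()
    Y = data.train_leads.matrix().T
    if model_type == "mlr":
        return MLRReconstructor().fit(X, Y)
    if model_type == "ann":
        stride = config.ann_train_stride
        return EnsembleReconstructor(
            seeds=config.ensemble_seeds,
            hidden_units=config.ann_hidden_units,
            output_activation=config.ann_output_activation,
            max_iter=config.ann_max_iter,
            tol=config.ann_tol,
        ).fit(X[::stride], Y[::stride])
    raise ValueError(f"unknown model type {model_type!r}")


def _ensemble_convexity_margin(
    model: EnsembleReconstructor, X_test: np.ndarray, Y_test: np.ndarray
) -> float:
    """Ensemble test MSE minus the mean of member test MSEs (<= 0 always)."""
    preds = np.stack([m.predict(X_test) for m in model.members_])
    member_mse = np.mean((preds - Y_test[None]) ** 2, axis=(1, 2))
    ens_mse = np.mean((preds.mean(axis=0) - Y_test) ** 2)
    return float(ens_mse - member_mse.mean())


@dataclass
class StudyResults:
    """Everything the report stage needs, in memory."""

    config: StudyConfig
    combos: list[ElectrodeCombination]
    combo_table: pd.DataFrame
    lead_scores: dict[tuple[str, tuple[int, int, int, int]], LeadScores]
    models: dict[tuple[str, tuple[int, int, int, int]], object]
    selections: dict[tuple[str, str, str], SelectionResult]
    selection_table: pd.DataFrame
    wilcoxon_table: pd.DataFrame
    anova_table: pd.DataFrame
    robustness: dict[str, pd.DataFrame]
    bland_altman_table: pd.DataFrame
    ensemble_convexity_margin: float | None
    all_combinations_table: pd.DataFrame | None = None


def run_shape_study(
    config: StudyConfig,
    data: PreparedData | None = None,
    progress: bool = False,
    keep_models: bool = True,
) -> StudyResults:
    """Fit and score every combination in the configured shape families."""
    data = data or prepare_data(config)
    combos: list[ElectrodeCombination] = []
    for family in config.families:
        combos.extend(enumerate_family(family, data.grid))

    test_leads = data.test_leads
    Y_test = test_leads.matrix().T
    rows = []
    lead_scores: dict[tuple[str, tuple[int, int, int, int]], LeadScores] = {}
    fitted: dict[tuple[str, tuple[int, int, int, int]], object] = {}
    worst_margin: float | None = None
    for idx, combo in enumerate(combos):
        if progress and idx % 10 == 0:
            print(f"  combination {idx + 1}/{len(combos)}", flush=True)
        for model_type in config.models:
            model = fit_combination(config, data, combo, model_type)
            scores = score_combination(model, data.test, combo, test_leads)
            lead_scores[(model_type, combo.key())] = scores
            if keep_models:
                fitted[(model_type, combo.key())] = model
            if model_type == "ann":
                X_test = compute_chest_leads(data.test.chest, combo).as_features()
                margin = _ensemble_convexity_margin(model, X_test, Y_test)
                worst_margin = (
                    margin if worst_margin is None else max(worst_margin, margin)
                )
            rows.append(
                {
                    "model": model_type,
                    "shape_tag": combo.shape_tag,
                    "orientation": combo.orientation,
                    "ids": combo.key(),
                    "mean_cc_score": scores.mean_cc_score,
                    "min_cc_score": scores.min_cc_score,
                    "mean_rmse_uV": float(scores.per_lead["mean_rmse_uV"].mean()),
                    "median_cc": float(scores.per_subject["cc"].median()),
                    "mean_r2": float(scores.per_lead["mean_r2"].mean()),
                    "mean_icc": float(scores.per_lead["icc"].mean()),
                }
            )
    combo_table = pd.DataFrame(rows)

    selections: dict[tuple[str, str, str], SelectionResult] = {}
    sel_rows = []
    for model_type in config.models:
        for family in config.families:
            group = [
                (c, lead_scores[(model_type, c.key())])
                for c in combos
                if c.shape_tag == family
            ]
            if not group:  # e.g. a family that is empty on a reduced grid
                continue
            for approach in ("meanCC", "minCC"):
                sel = select_best(group, approach)
                selections[(model_type, approach, family)] = sel
                sel_rows.append(
                    {
                        "model": model_type,
                        "approach": approach,
                        "shape_tag": family,
                        "ids": sel.combination.key(),
                        "score": sel.score,
                        "mean_cc": float(sel.scores.per_subject["cc"].mean()),
                        "cc_sd": float(sel.scores.per_subject["cc"].std(ddof=1)),
                        "median_cc": float(sel.scores.per_subject["cc"].median()),
                        "mean_rmse_uV": float(
                            sel.scores.per_lead["mean_rmse_uV"].mean()
                        ),
                        "mean_r2": float(sel.scores.per_lead["mean_r2"].mean()),
                        "mean_icc": float(sel.scores.per_lead["icc"].mean()),
                    }
                )
    selection_table = pd.DataFrame(sel_rows)

    wilcoxon_table = _shape_comparisons(config, selections)
    anova_table = _orientation_anova(config, data.grid, combos, lead_scores)
    robustness = _robustness_maps(config, data.grid, combos, combo_table)
    ba_table = _bland_altman_tables(config, data, selections, fitted)

    return StudyResults(
        config=config,
        combos=combos,
        combo_table=combo_table,
        lead_scores=lead_scores,
        models=fitted,
        selections=selections,
        selection_table=selection_table,
        wilcoxon_table=wilcoxon_table,
        anova_table=anova_table,
        robustness=robustness,
        bland_altman_table=ba_table,
        ensemble_convexity_margin=worst_margin,
    )


def _shape_comparisons(config, selections) -> pd.DataFrame:
    """Pairwise Wilcoxon signed-rank between shape families.

    Pairs are (subject x lead) CC and RMSE values at each family's best
    combination under the given approach, for each model type.
    """
    rows = []
    fams = list(config.families)
    for model_type in config.models:
        for approach in ("meanCC", "minCC"):
            for i in range(len(fams)):
                for j in range(i + 1, len(fams)):
                    a = selections[(model_type, approach, fams[i])].scores
                    b = selections[(model_type, approach, fams[j])].scores
                    for metric in ("cc", "rmse_uV"):
                        va = a.per_subject.sort_values(["subject_id", "lead"])[
                            metric
                        ].to_numpy()
                        vb = b.per_subject.sort_values(["subject_id", "lead"])[
                            metric
                        ].to_numpy()
                        try:
                            w, p = compare_shapes(va, vb)
                        except ValueError:
                            w, p = np.nan, np.nan
                        rows.append(
                            {
                                "model": model_type,
                                "approach": approach,
                                "metric": metric,
                                "shape_a": fams[i],
                                "shape_b": fams[j],
                                "W": w,
                                "p": p,
                            }
                        )
    return pd.DataFrame(rows)


def _orientation_anova(config, grid, combos, lead_scores) -> pd.DataFrame:
    """Per-lead one-way ANOVA of CC across the 4 triangle orientations of
    each 10x10 square placement, per model. Replicates are per-subject CCs."""
    triangles = [c for c in combos if c.shape_tag == "triangle"]
    if not triangles:
        return pd.DataFrame(columns=["model", "square_center", "lead", "F", "p"])
    placements: dict[tuple[int, int], list[ElectrodeCombination]] = {}
    for tri in triangles:
        cols_rows = [grid.position(i) for i in tri.ids]
        c0 = min(c for c, _ in cols_rows)
        r0 = min(r for _, r in cols_rows)
        placements.setdefault((c0, r0), []).append(tri)
    rows = []
    for model_type in config.models:
        for (c0, r0), tris in sorted(placements.items()):
            if len(tris) < 2:
                continue
            groups_per_lead = {lead: [] for lead in LEAD_NAMES}
            for tri in sorted(tris, key=lambda t: t.orientation):
                ps = lead_scores[(model_type, tri.key())].per_subject
                for lead in LEAD_NAMES:
                    groups_per_lead[lead].append(
                        ps.loc[ps["lead"] == lead, "cc"].to_numpy()
                    )
            table = compare_orientations(groups_per_lead)
            center = grid.electrode_id(c0 + 1, r0 + 1)
            for _, r in table.iterrows():
                rows.append(
                    {
                        "model": model_type,
                        "square_center": center,
                        "lead": r["lead"],
                        "F": r["F"],
                        "p": r["p"],
                    }
                )
    return pd.DataFrame(rows)


def _robustness_maps(config, grid, combos, combo_table) -> dict[str, pd.DataFrame]:
    triangles = [c for c in combos if c.shape_tag == "triangle"]
    out: dict[str, pd.DataFrame] = {}
    if not triangles:
        return out
    for model_type in config.models:
        sub = combo_table[
            (combo_table["model"] == model_type)
            & (combo_table["shape_tag"] == "triangle")
        ]
        for approach, col in (("meanCC", "mean_cc_score"), ("minCC", "min_cc_score")):
            scores = {ids: s for ids, s in zip(sub["ids"], sub[col])}
            out[f"{model_type}_{approach}"] = robustness_map(
                scores,
                triangles,
                grid,
                include_unshifted=config.robustness_include_unshifted,
            )
    return out


def _bland_altman_tables(config, data, selections, fitted) -> pd.DataFrame:
    """Agreement statistics (mV) at each selected combination, pooled over
    the test merge and all 12 leads."""
    rows = []
    ref_mv = data.test_leads.matrix().ravel() / 1000.0
    for (model_type, approach, family), sel in selections.items():
        key = (model_type, sel.combination.key())
        model = fitted.get(key)
        if model is None:
            model = fit_combination(config, data, sel.combination, model_type)
        recon_mv = (
            predict(
                model, compute_chest_leads(data.test.chest, sel.combination).cl
            ).ravel()
            / 1000.0
        )
        stats_ = bland_altman(ref_mv, recon_mv)
        rows.append(
            {
                "model": model_type,
                "approach": approach,
                "shape_tag": family,
                "ids": sel.combination.key(),
                "bias_mV": stats_.bias,
                "loa_low_mV": stats_.loa_low,
                "loa_high_mV": stats_.loa_high,
                "half_width_mV": stats_.half_width,
                "slope": stats_.slope,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Exhaustive MLR scan over all C(35,4) combinations via sufficient statistics.


def scan_all_mlr(data: PreparedData) -> pd.DataFrame:
    """Score an MLR reconstruction for every 4-electrode combination.

    Uses pooled second-moment (Gram) matrices so each combination costs a
    4x4 solve plus per-subject moment algebra rather than a pass over the
    signal. Fitting raw chest leads with a bias spans the same affine space
    as standardized leads, so predictions match :class:`MLRReconstructor`.

    Returns per-combination meanCC/minCC scores and mean RMSE sorted by
    meanCC score.
    """
    train, test = data.train, data.test
    U = train.chest  # (35, N)
    Rtr = data.train_leads.matrix()  # (12, N)
    n_tr = U.shape[1]
    Su = U.sum(axis=1)
    Sr = Rtr.sum(axis=1)
    Guu = U @ U.T
    Gur = U @ Rtr.T

    Rte = data.test_leads.matrix()
    subjects = []
    for seg in test.segments:
        sl = slice(seg.start_idx, seg.stop_idx)
        u = test.chest[:, sl]
        r = Rte[:, sl]
        n = u.shape[1]
        subjects.append(
            {
                "n": n,
                "Su": u.sum(axis=1),
                "Sr": r.sum(axis=1),
                "Guu": u @ u.T,
                "Gur": u @ r.T,
                "r_mean": r.mean(axis=1),
                "r_var": r.var(axis=1),
                "r2mean": (r**2).mean(axis=1),
            }
        )

    def cl_moments(Gu, Su_, idx, rdx):
        s_cl = Su_[idx] - Su_[rdx]
        g_cc = (
            Gu[np.ix_(idx, idx)]
            - Gu[np.ix_(idx, [rdx] * 3)]
            - Gu[np.ix_([rdx] * 3, idx)]
            + Gu[rdx, rdx]
        )
        return s_cl, g_cc

    rows = []
    for combo in enumerate_all(data.grid):
        ref, a, b, c = combo.ids
        idx = [a - 1, b - 1, c - 1]
        rdx = ref - 1
        s_cl, g_cc = cl_moments(Guu, Su, idx, rdx)
        g_cr = Gur[idx] - Gur[rdx]
        XtX = np.empty((4, 4))
        XtX[0, 0] = n_tr
        XtX[0, 1:] = s_cl
        XtX[1:, 0] = s_cl
        XtX[1:, 1:] = g_cc
        XtY = np.vstack([Sr, g_cr])
        try:
            B = np.linalg.solve(XtX, XtY)  # (4, 12)
        except np.linalg.LinAlgError:
            continue
        cc_subj, rmse_subj = [], []
        for s in subjects:
            n = s["n"]
            s_cl_t, g_cc_t = cl_moments(s["Guu"], s["Su"], idx, rdx)
            s_cl_t = s_cl_t / n
            g_cc_t = g_cc_t / n
            g_cr_t = (s["Gur"][idx] - s["Gur"][rdx]) / n
            m1 = np.concatenate([[1.0], s_cl_t])
            M2 = np.empty((4, 4))
            M2[0, 0] = 1.0
            M2[0, 1:] = s_cl_t
            M2[1:, 0] = s_cl_t
            M2[1:, 1:] = g_cc_t
            cross = np.vstack([s["Sr"] / n, g_cr_t])  # (4, 12)
            e_p = m1 @ B
            e_p2 = np.einsum("ij,ik,kj->j", B, M2, B)
            e_pr = np.sum(B * cross, axis=0)
            var_p = np.maximum(e_p2 - e_p**2, 0.0)
            cov = e_pr - e_p * s["r_mean"]
            denom = np.sqrt(var_p * s["r_var"])
            cc = np.where(denom > 0, cov / denom, 0.0)
            mse = np.maximum(e_p2 - 2 * e_pr + s["r2mean"], 0.0)
            cc_subj.append(cc)
            rmse_subj.append(np.sqrt(mse))
        lead_mean_cc = np.mean(cc_subj, axis=0)
        rows.append(
            {
                "ids": combo.key(),
                "mean_cc_score": float(lead_mean_cc.mean()),
                "min_cc_score": float(lead_mean_cc.min()),
                "mean_rmse_uV": float(np.mean(rmse_subj)),
            }
        )
    return pd.DataFrame(rows).sort_values(
        "mean_cc_score", ascending=False, ignore_index=True
    )


# ---------------------------------------------------------------------------
# Reporting and the run manifest.


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    stage_timings_s: dict[str, float]
    files: dict[str, str]  # relative path -> sha256

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _frame_for_csv(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    if "ids" in out.columns:
        out["ids"] = out["ids"].map(lambda t: "-".join(map(str, t)))
    return out


def report(results: StudyResults, outdir: str | Path) -> list[Path]:
    """Write the study's tables (CSV) and summary (JSON); returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def write_csv(frame: pd.DataFrame, name: str):
        p = outdir / name
        _frame_for_csv(frame).to_csv(p, index=False, float_format="%.6g")
        written.append(p)

    write_csv(results.combo_table, "combinations_scored.csv")
    write_csv(results.selection_table, "selection_summary.csv")
    if len(results.wilcoxon_table):
        write_csv(results.wilcoxon_table, "shape_wilcoxon.csv")
    if len(results.anova_table):
        write_csv(results.anova_table, "orientation_anova.csv")
    if len(results.bland_altman_table):
        write_csv(results.bland_altman_table, "bland_altman.csv")

    grid = GridLayout()
    for key, frame in results.robustness.items():
        write_csv(frame, f"robustness_{key}.csv")
        # grid-aligned map: average over orientations per square placement,
        # indexed by the placement's centre electrode cell
        mat = np.full((grid.n_rows, grid.n_cols), np.nan)
        agg: dict[int, list[float]] = {}
        for _, row in frame.iterrows():
            cols_rows = [grid.position(i) for i in row["ids"]]
            c0 = min(c for c, _ in cols_rows)
            r0 = min(r for _, r in cols_rows)
            agg.setdefault(grid.electrode_id(c0 + 1, r0 + 1), []).append(
                row["robust_score"]
            )
        for center, vals in agg.items():
            c, r = grid.position(center)
            mat[r - 1, c - 1] = float(np.mean(vals))
        p = outdir / f"robustness_map_{key}.csv"
        pd.DataFrame(
            mat,
            index=[f"row{r}" for r in range(1, grid.n_rows + 1)],
            columns=[f"col{c}" for c in range(1, grid.n_cols + 1)],
        ).to_csv(p, float_format="%.6g")
        written.append(p)

    for (model_type, approach, family), sel in results.selections.items():
        p = outdir / f"per_lead_{model_type}_{approach}_{family}.csv"
        sel.scores.per_lead.to_csv(p, index=False, float_format="%.6g")
        written.append(p)

    if results.all_combinations_table is not None:
        write_csv(
            results.all_combinations_table.head(1000), "all_combinations_top.csv"
        )

    summary = {
        "config_hash": results.config.content_hash(),
        "n_combinations_scored": int(len({c.key() for c in results.combos})),
        "ensemble_convexity_margin": results.ensemble_convexity_margin,
        "selections": _frame_for_csv(results.selection_table).to_dict("records"),
    }
    p = outdir / "summary.json"
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    written.append(p)
    return written


def run_study(
    config: StudyConfig, outdir: str | Path, progress: bool = False
) -> RunManifest:
    """Execute the full pipeline and write reports plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    data = prepare_data(config)
    timings["simulate_preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    results = run_shape_study(config, data, progress=progress)
    timings["fit_score_select"] = time.perf_counter() - t0

    if config.include_all_combinations:
        t0 = time.perf_counter()
        results.all_combinations_table = scan_all_mlr(data)
        timings["all_combinations_scan"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    written = report(results, outdir)
    timings["report"] = time.perf_counter() - t0

    files = {str(p.relative_to(outdir)): _sha256(p) for p in written}
    manifest = RunManifest(
        config_hash=config.content_hash(),
        package_version=__version__,
        stage_timings_s=timings,
        files=files,
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2)
    return manifest
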