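"""Two-step feature-selection pipeline orchestration.

Stage 1 — per-gap filtering: for each gap value g (default 0..9), encode
the training sequences as 400 g-gap dipeptide frequencies, rank the
features by one-way ANOVA F, and sweep nested prefixes with a
cross-validated RBF-SVM; keep the prefix at the accuracy peak as that g's
optimal subset.

Stage 2 — fusion and redundancy removal: concatenate the ten optimal
subsets into one fused matrix, discretize, re-order the fused features by
greedy mRMR, sweep prefixes of the mRMR order the same way, and train the
final SVM on all data at the peak prefix with its tuned (C, gamma). The
final report carries Sn, Sp, Acc, Mcc and auROC from pooled
cross-validation, plus the Z-scored mRMR ranking.

Every stage is a pure function of (sequences, config, seed); rerunning
with identical inputs reproduces the reports bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd

from . import anova, ggap, ifs, metrics, mrmr
from .sequence_io import ProteinSequence, labels_of

logger = logging.getLogger(__name__)

BUNDLE_FORMAT_VERSION = 1


@dataclass
class PipelineConfig:
    """Settings shared by both pipeline stages."""

    g_values: Sequence[int] = field(default_factory=lambda: list(range(10)))
    n_folds: int = 5
    seed: int = 0
    criterion: str = "mid"          # mRMR variant: 'mid' or 'miq'
    n_bins: int = 3
    bin_multiplier: float = 1.0
    grid_c: Sequence[float] = field(default_factory=lambda: list(ifs.DEFAULT_GRID_C))
    grid_gamma: Sequence[float] = field(
        default_factory=lambda: list(ifs.DEFAULT_GRID_GAMMA)
    )
    stage1_max_k: int | None = None          # None = all 400
    stage1_k_values: Sequence[int] | None = None
    stage2_max_k: int | None = None
    stage2_k_values: Sequence[int] | None = None
    tune: str = "per_k"             # 'per_k' (honest, costly) or 'once' (fast)

    def model_config(self) -> ifs.ModelConfig:
        return ifs.ModelConfig(
            n_folds=self.n_folds,
            seed=self.seed,
            grid_c=list(self.grid_c),
            grid_gamma=list(self.grid_gamma),
        )


@dataclass
class Stage1Result:
    """Per-g rankings, IFS curves and the selected optimal subsets."""

    g_values: list[int]
    matrices: dict[int, ggap.FeatureMatrix]
    rankings: dict[int, anova.RankedFeatures]
    curves: dict[int, ifs.IFSCurve]
    selections: dict[int, list[int]]  # ranked original column indices per g

    @property
    def fused_width(self) -> int:
        return sum(len(s) for s in self.selections.values())


@dataclass
class Stage2Result:
    """Fused-feature mRMR re-ranking, final IFS curve, model and report."""

    fused: ggap.FeatureMatrix
    mrmr_ranking: anova.RankedFeatures
    zscores: mrmr.ZScores
    curve: ifs.IFSCurve
    model: object          # sklearn SVC trained on all data at the peak
    selected_descriptors: list[ggap.GGapDescriptor]
    report: metrics.MetricsReport


def _labeled(seqs: Sequence[ProteinSequence]) -> np.ndarray:
    return np.asarray(labels_of(seqs), dtype=int)


def run_stage1(
    seqs: Sequence[ProteinSequence], config: PipelineConfig
) -> Stage1Result:
    """ANOVA ranking + IFS sweep for every gap value."""
    y = _labeled(seqs)
    mc = config.model_config()
    matrices, rankings, curves, selections = {}, {}, {}, {}
    for g in config.g_values:
        X = ggap.build_matrix(seqs, g)
        result = anova.anova_f_scores(X, y)
        ranking = anova.rank_by_score(result.f_scores, descriptors=X.descriptors)
        ranked = X.select_columns(ranking.order)
        curve = ifs.ifs_sweep(
            ranked, y, mc,
            max_k=config.stage1_max_k,
            k_values=config.stage1_k_values,
            tune=config.tune,
        )
        sel = [int(i) for i in ranking.order[: curve.peak_k]]
        logger.info(
            "stage1 g=%d: peak k=%d acc=%.4f", g, curve.peak_k,
            max(curve.accuracies),
        )
        matrices[g], rankings[g], curves[g], selections[g] = X, ranking, curve, sel
    return Stage1Result(
        g_values=list(config.g_values),
        matrices=matrices,
        rankings=rankings,
        curves=curves,
        selections=selections,
    )


def run_stage2(
    seqs: Sequence[ProteinSequence],
    stage1: Stage1Result,
    config: PipelineConfig,
) -> Stage2Result:
    """Fuse the per-g optimal subsets, mRMR-reorder, sweep, fit final model."""
    y = _labeled(seqs)
    mc = config.model_config()

    fused = ggap.fuse(
        [stage1.matrices[g] for g in stage1.g_values],
        [stage1.selections[g] for g in stage1.g_values],
    )
    logger.info("stage2: fused width = %d", fused.n_features)

    disc = mrmr.discretize(
        fused, n_bins=config.n_bins, scheme="mean_sd",
        multiplier=config.bin_multiplier,
    )
    ranking = mrmr.mrmr_order(disc, y, criterion=config.criterion)
    z = mrmr.zscore(ranking.scores)

    reordered = fused.select_columns(ranking.order)
    curve = ifs.ifs_sweep(
        reordered, y, mc,
        max_k=config.stage2_max_k,
        k_values=config.stage2_k_values,
        tune=config.tune,
    )
    peak_cols = list(range(curve.peak_k))
    X_final = reordered.select_columns(peak_cols)
    C, gamma = curve.peak_params
    model = ifs.fit_final_svm(X_final, y, C=C, gamma=gamma)
    logger.info(
        "stage2: peak k=%d acc=%.4f C=%g gamma=%g",
        curve.peak_k, max(curve.accuracies), C, gamma,
    )
    return Stage2Result(
        fused=fused,
        mrmr_ranking=ranking,
        zscores=z,
        curve=curve,
        model=model,
        selected_descriptors=list(X_final.descriptors),
        report=curve.peak_metrics,
    )


def run_pipeline(
    seqs: Sequence[ProteinSequence], config: PipelineConfig
) -> tuple[Stage1Result, Stage2Result]:
    """Full two-step protocol on labeled sequences."""
    s1 = run_stage1(seqs, config)
    s2 = run_stage2(seqs, s1, config)
    return s1, s2


# ---------------------------------------------------------------------------
# model bundle persistence and prediction


def save_model(stage2: Stage2Result, config: PipelineConfig, path: str | Path) -> None:
    """Persist the final model with its descriptors and tuning metadata."""
    C, gamma = stage2.curve.peak_params
    joblib.dump(
        {
            "format_version": BUNDLE_FORMAT_VERSION,
            "model": stage2.model,
            "descriptors": [d.name for d in stage2.selected_descriptors],
            "C": C,
            "gamma": gamma,
            "n_folds": config.n_folds,
            "seed": config.seed,
            "criterion": config.criterion,
            "cv_acc": stage2.report.acc,
        },
        path,
    )


def load_model(path: str | Path) -> dict:
    bundle = joblib.load(path)
    if bundle.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise ValueError(f"unsupported model bundle version in {path}")
    return bundle


def encode_for_model(
    seqs: Sequence[ProteinSequence], descriptor_names: Sequence[str]
) -> np.ndarray:
    """Encode only the model's selected descriptors for new sequences.

    Sequences too short for any required gap are reported per record in a
    single error.
    """
    descs = [ggap.GGapDescriptor.from_name(n) for n in descriptor_names]
    gaps = sorted({d.g for d in descs})
    too_short = [
        (s.id, g) for s in seqs for g in gaps if len(s) < g + 2
    ]
    if too_short:
        detail = "; ".join(f"{sid} (needs L >= {g + 2} for g={g})" for sid, g in too_short)
        raise ggap.DegenerateSequenceError(f"sequence(s) too short: {detail}")
    per_gap = {g: np.stack([ggap.ggap_vector(s, g) for s in seqs]) for g in gaps}
    cols = [per_gap[d.g][:, d.index] for d in descs]
    return np.column_stack(cols) if cols else np.empty((len(seqs), 0))


def predict(
    bundle: dict, seqs: Sequence[ProteinSequence]
) -> pd.DataFrame:
    """Score sequences with a saved model.

    Returns a DataFrame with columns id, score (SVM decision value, positive
    means virion) and label (predicted class).
    """
    if not seqs:
        return pd.DataFrame(columns=["id", "score", "label"])
    X = encode_for_model(seqs, bundle["descriptors"])
    scores = bundle["model"].decision_function(X)
    return pd.DataFrame(
        {
            "id": [s.id for s in seqs],
            "score": scores,
            "label": (scores > 0).astype(int),
        }
    )


def evaluate_on(
    bundle: dict, seqs: Sequence[ProteinSequence]
) -> metrics.MetricsReport:
    """Evaluate a saved model on labeled sequences (e.g. an independent set
    never touched during selection)."""
    y = _labeled(seqs)
    df = predict(bundle, seqs)
    return metrics.evaluate_predictions(y, df["label"].to_numpy(), df["score"].to_numpy())


def export_stage1(stage1: Stage1Result, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = []
    for g in stage1.g_values:
        stage1.rankings[g].to_tsv(out / f"ranking_g{g}.tsv", score_name="anova_f")
        stage1.curves[g].to_tsv(out / f"ifs_curve_g{g}.tsv")
        summary.append(
            {
                "g": g,
                "n_selected": len(stage1.selections[g]),
                "peak_acc": max(stage1.curves[g].accuracies),
            }
        )
    pd.DataFrame(summary).to_csv(out / "stage1_summary.tsv", sep="\t", index=False)
    sel = {str(g): stage1.selections[g] for g in stage1.g_values}
    (out / "selections.json").write_text(json.dumps(sel, indent=2) + "\n")


def export_stage2(stage2: Stage2Result, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage2.mrmr_ranking.to_tsv(
        out / "mrmr_ranking.tsv", score_name="mrmr_score",
        extra={"z_score": stage2.zscores.z},
    )
    stage2.curve.to_tsv(out / "ifs_curve_fused.tsv")
    stage2.report.to_tsv(out / "final_metrics.tsv")
    if stage2.report.roc_points is not None:
        metrics.roc_to_tsv(stage2.report.roc_points, out / "roc.tsv")
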