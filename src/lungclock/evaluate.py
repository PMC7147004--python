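"""Clock evaluation and delta-age inference.

Two cross-validation designs mirror how the clock is validated: repeated
random 75/25 holdout splits (stratified by study) and leave-one-study-out
rounds, both reporting mean absolute error (MAE) in months. Delta age
(predicted minus chronological age) is summarized per exposure group and
compared against the sham reference with Welch two-sample t-tests plus a
classical one-way ANOVA across all groups; p-values map onto the usual
star codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

from .clock import PredictionResult, fit_clock, predict_age
from .io import ExpressionMatrix, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "CvReport",
    "GroupComparison",
    "mae",
    "random_holdout_cv",
    "leave_one_study_out_cv",
    "delta_age_table",
    "group_inference",
    "star_code",
]

STAR_THRESHOLDS = (
    (1e-4, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (5e-2, "*"),
    (1e-1, "."),
)


def star_code(p: float) -> str:
    """Map a p-value onto the conventional significance stars."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value out of range: {p}")
    for cut, code in STAR_THRESHOLDS:
        if p < cut:
            return code
    return "ns"


def mae(predicted, actual) -> float:
    """Mean absolute error, in the units of its inputs (months here)."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape or predicted.size == 0:
        raise ValueError("predicted and actual must be equal-length, nonempty")
    return float(np.mean(np.abs(predicted - actual)))


@dataclass
class CvReport:
    scheme: str  # "random_holdout" | "leave_one_study_out"
    runs: list[dict]  # per-run rows: run, train_mae, validation_mae, ...
    pooled_validation_mae: float
    per_study_mae: dict[str, float] = field(default_factory=dict)
    skipped_runs: list[int] = field(default_factory=list)
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.runs)


def _mae_of(
    model, matrix: ExpressionMatrix, records: list[SampleMetadata]
) -> float:
    ids = [r.sample_id for r in records]
    preds = predict_age(model, matrix.subset_samples(ids), records)
    return mae(
        [p.predicted_age_months for p in preds],
        [p.chronological_age_months for p in preds],
    )


def random_holdout_cv(
    matrix: ExpressionMatrix,
    records: list[SampleMetadata],
    runs: int = 100,
    train_frac: float = 0.75,
    seed: int = 0,
    excluded_genes: tuple[str, ...] = (),
    **fit_kwargs,
) -> CvReport:
    """Repeated random train/validation splits, stratified by study.

    Each run refits the clock on the training part and evaluates MAE on
    both partitions; the pooled validation MAE is the mean of per-run
    validation MAEs. Runs whose training part has fewer than two distinct
    ages are skipped and recorded, never silently dropped.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must leave both partitions nonempty")
    if len(records) < 8:
        raise ValueError("need >= 8 samples for holdout cross-validation")
    studies = [r.study_id for r in records]
    rows, skipped = [], []
    rng = np.random.default_rng(seed)
    for run in range(runs):
        split_seed = int(rng.integers(0, 2**31 - 1))
        train, val = train_test_split(
            records,
            train_size=train_frac,
            random_state=split_seed,
            stratify=studies,
        )
        if len({r.age_months for r in train}) < 2:
            logger.warning("run %d skipped: <2 distinct training ages", run)
            skipped.append(run)
            continue
        model = fit_clock(
            matrix, list(train), excluded_genes=excluded_genes,
            seed=split_seed, **fit_kwargs,
        )
        rows.append(
            {
                "run": run,
                "n_train": len(train),
                "n_validation": len(val),
                "train_mae": _mae_of(model, matrix, list(train)),
                "validation_mae": _mae_of(model, matrix, list(val)),
                "n_genes_selected": len(model.coefficients),
            }
        )
    if not rows:
        raise ValueError("all holdout runs were skipped")
    pooled = float(np.mean([r["validation_mae"] for r in rows]))
    return CvReport(
        scheme="random_holdout",
        runs=rows,
        pooled_validation_mae=pooled,
        skipped_runs=skipped,
        seed=seed,
    )


def leave_one_study_out_cv(
    matrix: ExpressionMatrix,
    records: list[SampleMetadata],
    seed: int = 0,
    excluded_genes: tuple[str, ...] = (),
    **fit_kwargs,
) -> CvReport:
    """One round per study: train on the others, validate on the held-out one."""
    studies = sorted({r.study_id for r in records})
    if len(studies) < 2:
        raise ValueError("leave-one-study-out needs >= 2 studies")
    rows = []
    per_study = {}
    for i, study in enumerate(studies):
        train = [r for r in records if r.study_id != study]
        val = [r for r in records if r.study_id == study]
        model = fit_clock(
            matrix, train, excluded_genes=excluded_genes, seed=seed, **fit_kwargs
        )
        v_mae = _mae_of(model, matrix, val)
        per_study[study] = v_mae
        rows.append(
            {
                "run": i,
                "held_out_study": study,
                "n_train": len(train),
                "n_validation": len(val),
                "train_mae": _mae_of(model, matrix, train),
                "validation_mae": v_mae,
                "n_genes_selected": len(model.coefficients),
            }
        )
    pooled = float(np.mean([r["validation_mae"] for r in rows]))
    return CvReport(
        scheme="leave_one_study_out",
        runs=rows,
        pooled_validation_mae=pooled,
        per_study_mae=per_study,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Delta age


def delta_age_table(
    predictions: list[PredictionResult],
    records: list[SampleMetadata],
    by_time_point: bool = False,
) -> pd.DataFrame:
    """Per-group (optionally per-time-point) delta-age summaries."""
    meta = {r.sample_id: r for r in records}
    rows = []
    for p in predictions:
        if p.chronological_age_months is None:
            raise ValueError(f"prediction for {p.sample_id} lacks an age")
        r = meta[p.sample_id]
        rows.append(
            {
                "sample_id": p.sample_id,
                "study_id": r.study_id,
                "group": r.exposure_group.value,
                "exposure_months": r.exposure_months,
                "delta_age_months": p.delta_age_months,
            }
        )
    df = pd.DataFrame(rows)
    keys = ["group", "exposure_months"] if by_time_point else ["group"]
    out = (
        df.groupby(keys, sort=True)["delta_age_months"]
        .agg(mean_delta="mean", sd_delta="std", n="count")
        .reset_index()
    )
    return out


@dataclass
class GroupComparison:
    reference_group: str
    summaries: pd.DataFrame  # group, mean, sd, n
    tests: pd.DataFrame  # group, t, df, p, stars (Welch vs reference)
    anova_f: float
    anova_df: tuple[float, float]
    anova_p: float
    anova_stars: str


def group_inference(
    deltas_by_group: dict[str, np.ndarray],
    reference_group: str = "sham",
) -> GroupComparison:
    """Welch t-tests of each group vs the reference plus one-way ANOVA.

    Star codes follow the usual thresholds (**** <1e-4 ... '.' <0.1, else
    ns). No multiplicity correction is applied across the per-group
    comparisons; each is reported as-is.
    """
    if reference_group not in deltas_by_group:
        raise ValueError(f"reference group {reference_group!r} absent")
    groups = {g: np.asarray(v, dtype=float) for g, v in deltas_by_group.items()}
    if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    ref = groups[reference_group]
    srows, trows = [], []
    for g in sorted(groups):
        v = groups[g]
        srows.append(
            {"group": g, "mean_delta": float(v.mean()),
             "sd_delta": float(v.std(ddof=1)), "n": int(v.size)}
        )
        if g == reference_group:
            continue
        if v.std(ddof=1) == 0 and ref.std(ddof=1) == 0:
            # degenerate: both groups constant; keep the report total
            df = float(v.size + ref.size - 2)
            t, p = (0.0, 1.0) if v.mean() == ref.mean() else (np.inf, 0.0)
        else:
            res = stats.ttest_ind(v, ref, equal_var=False)
            t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        trows.append({"group": g, "t": t, "df": df, "p": p, "stars": star_code(p)})
    f, p_anova = stats.f_oneway(*[groups[g] for g in sorted(groups)])
    k, n = len(groups), sum(v.size for v in groups.values())
    return GroupComparison(
        reference_group=reference_group,
        summaries=pd.DataFrame(srows),
        tests=pd.DataFrame(trows),
        anova_f=float(f),
        anova_df=(float(k - 1), float(n - k)),
        anova_p=float(p_anova),
        anova_stars=star_code(float(p_anova)),
    )
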