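"""End-to-end orchestration of the analysis stages.

Each stage reads/writes the standard artifact files inside an output
directory so stages can run alone or chained; every artifact carries a
header comment recording the root seed and a hash of the configuration
that produced it. All randomness flows from one root seed, split per
stage with :func:`stage_seed`.

Artifact tree (under ``out_dir``)::

    expression.tsv, metadata.csv, truth.json          simulate
    contrasts_age.tsv, contrasts_exposure.tsv,
    regulated_age.json, regulated_exposure.json       deg
    venn.tsv, mfc.tsv, pc1_loadings.tsv               overlap
    model.json, selected_genes.tsv                    train
    cv_holdout.tsv, cv_loso.tsv                       validate
    predictions.tsv                                   predict
    delta_age_groups.tsv, group_inference.tsv         delta
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clock, degenes, evaluate, io, overlap, simulate
from .io import ExposureGroup

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "STAGES"]

STAGES = ("simulate", "deg", "overlap", "train", "validate", "predict", "delta")


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    seed: int = 0
    matrix_path: str | None = None  # defaults to the simulate artifact
    metadata_path: str | None = None
    fdr_cutoff: float = degenes.DEFAULT_FDR_CUTOFF
    fc_cutoff: float = degenes.DEFAULT_FC_CUTOFF
    excluded_genes: tuple[str, ...] = ()
    clock_folds: int = 5
    holdout_runs: int = 20
    train_frac: float = 0.75
    missing_policy: str = "impute_training_mean"
    moderation: str = "eb"
    simulation: dict = field(default_factory=dict)  # overrides for the preset

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(**doc)
        cfg.excluded_genes = tuple(cfg.excluded_genes)
        return cfg

    def config_hash(self) -> str:
        doc = asdict(self)
        doc.pop("out_dir")  # hash the scientific config, not the destination
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def header(self) -> str:
        return f"config_hash={self.config_hash()} seed={self.seed}"


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed split from the root seed (< 2**31)."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the `{producer}` stage first"
        )
    return path


def _load_inputs(cfg: PipelineConfig):
    out = Path(cfg.out_dir)
    mpath = Path(cfg.matrix_path) if cfg.matrix_path else out / "expression.tsv"
    dpath = Path(cfg.metadata_path) if cfg.metadata_path else out / "metadata.csv"
    _require(mpath, "simulate")
    _require(dpath, "simulate")
    return io.read_expression_matrix(mpath), io.read_metadata(dpath)


def _stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    seed = stage_seed(cfg.seed, "simulate")
    matrix, records, truth = simulate.scenario_three_study(seed, **cfg.simulation)
    io.write_expression_matrix(matrix, out / "expression.tsv",
                               header_comment=cfg.header())
    io.write_metadata(records, out / "metadata.csv", header_comment=cfg.header())
    doc = truth.to_dict()
    doc["provenance"] = cfg.header()
    with open(out / "truth.json", "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("simulate: %d genes x %d samples", *matrix.shape)


def _stage_deg(cfg: PipelineConfig, out: Path) -> None:
    matrix, records = _load_inputs(cfg)
    for kind, build in (
        ("age", degenes.build_age_contrasts),
        ("exposure", degenes.build_exposure_contrasts),
    ):
        specs = build(records)
        results = degenes.run_contrasts(matrix, specs, moderation=cfg.moderation)
        _write_tsv(results, out / f"contrasts_{kind}.tsv", cfg.header())
        regulated = degenes.identify_regulated(
            results, cfg.fc_cutoff, cfg.fdr_cutoff, cfg.excluded_genes
        )
        with open(out / f"regulated_{kind}.json", "w") as fh:
            json.dump(
                {
                    "provenance": cfg.header(),
                    "gene_ids": regulated.gene_ids,
                    "fc_cutoff": regulated.fc_cutoff,
                    "fdr_cutoff": regulated.fdr_cutoff,
                    "contributing": regulated.contributing,
                    "excluded_genes": regulated.excluded_genes,
                },
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")
        logger.info("deg[%s]: %d contrasts, %d regulated genes",
                    kind, len(specs), len(regulated))


def _load_regulated(path: Path) -> degenes.RegulatedGeneSet:
    with open(path) as fh:
        doc = json.load(fh)
    return degenes.RegulatedGeneSet(
        gene_ids=doc["gene_ids"],
        fc_cutoff=doc["fc_cutoff"],
        fdr_cutoff=doc["fdr_cutoff"],
        contributing=doc["contributing"],
        excluded_genes=doc["excluded_genes"],
    )


def _stage_overlap(cfg: PipelineConfig, out: Path) -> None:
    res_age = _read_tsv(_require(out / "contrasts_age.tsv", "deg"))
    res_exp = _read_tsv(_require(out / "contrasts_exposure.tsv", "deg"))
    set_age = _load_regulated(_require(out / "regulated_age.json", "deg"))
    set_exp = _load_regulated(_require(out / "regulated_exposure.json", "deg"))

    a_only, b_only, inter, pct = overlap.venn_overlap(set_age, set_exp)
    venn = pd.DataFrame(
        [{"age_only": a_only, "exposure_only": b_only,
          "shared": inter, "pct_age_in_exposure": pct}]
    )
    _write_tsv(venn, out / "venn.tsv", cfg.header())

    prof_age = overlap.fold_change_profile(res_age, "age")
    prof_exp = overlap.fold_change_profile(res_exp, "exposure")
    mfc = pd.concat(
        [overlap.signed_max_fold_change(prof_age),
         overlap.signed_max_fold_change(prof_exp)],
        axis=1,
    ).reset_index(names="gene_id")
    _write_tsv(mfc, out / "mfc.tsv", cfg.header())

    pc_age = overlap.pc1_loadings(prof_age)
    pc_exp = overlap.pc1_loadings(prof_exp)
    r, p, table = overlap.compare_loadings(pc_age, pc_exp)
    table.attrs["pearson_r"] = r
    header = (
        f"{cfg.header()} inertia_age={pc_age.inertia:.4f} "
        f"inertia_exposure={pc_exp.inertia:.4f} pearson_r={r:.6f} p={p:.3e}"
    )
    _write_tsv(table, out / "pc1_loadings.tsv", header)
    logger.info("overlap: %d shared genes, pct=%.1f%%, PC1 r=%.3f", inter, pct, r)


def _sham(records: list[io.SampleMetadata]) -> list[io.SampleMetadata]:
    return [r for r in records if r.exposure_group == ExposureGroup.SHAM]


def _stage_train(cfg: PipelineConfig, out: Path) -> None:
    matrix, records = _load_inputs(cfg)
    model = clock.fit_clock(
        matrix, _sham(records), excluded_genes=cfg.excluded_genes,
        k=cfg.clock_folds, seed=stage_seed(cfg.seed, "train"),
    )
    io.save_model(model, out / "model.json", provenance=cfg.header())
    genes = pd.DataFrame(
        sorted(model.coefficients.items()),
        columns=["gene_id", "coefficient_months_per_log2"],
    )
    _write_tsv(genes, out / "selected_genes.tsv", cfg.header())
    logger.info("train: %d predictor genes, lambda=%.4g",
                len(model.coefficients), model.lambda_selected)


def _stage_validate(cfg: PipelineConfig, out: Path) -> None:
    matrix, records = _load_inputs(cfg)
    sham = _sham(records)
    rep = evaluate.random_holdout_cv(
        matrix, sham, runs=cfg.holdout_runs, train_frac=cfg.train_frac,
        seed=stage_seed(cfg.seed, "validate"),
        excluded_genes=cfg.excluded_genes, k=cfg.clock_folds,
    )
    _write_tsv(
        rep.to_frame(), out / "cv_holdout.tsv",
        f"{cfg.header()} pooled_validation_mae={rep.pooled_validation_mae:.6f}",
    )
    loso = evaluate.leave_one_study_out_cv(
        matrix, sham, seed=stage_seed(cfg.seed, "validate"),
        excluded_genes=cfg.excluded_genes, k=cfg.clock_folds,
    )
    _write_tsv(
        loso.to_frame(), out / "cv_loso.tsv",
        f"{cfg.header()} pooled_validation_mae={loso.pooled_validation_mae:.6f}",
    )
    logger.info("validate: holdout MAE=%.3f, LOSO MAE=%.3f",
                rep.pooled_validation_mae, loso.pooled_validation_mae)


def _stage_predict(cfg: PipelineConfig, out: Path) -> None:
    matrix, records = _load_inputs(cfg)
    model = io.load_model(_require(out / "model.json", "train"))
    preds = clock.predict_age(model, matrix, records,
                              missing_policy=cfg.missing_policy)
    df = pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in preds],
            "predicted_age_months": [p.predicted_age_months for p in preds],
            "chronological_age_months": [p.chronological_age_months for p in preds],
            "delta_age_months": [p.delta_age_months for p in preds],
        }
    )
    _write_tsv(df, out / "predictions.tsv", cfg.header())


def _stage_delta(cfg: PipelineConfig, out: Path) -> None:
    _, records = _load_inputs(cfg)
    preds_df = _read_tsv(_require(out / "predictions.tsv", "predict"))
    preds = [
        clock.PredictionResult(
            sample_id=str(row.sample_id),
            predicted_age_months=float(row.predicted_age_months),
            chronological_age_months=float(row.chronological_age_months),
            genes_missing_count=0,
        )
        for row in preds_df.itertuples(index=False)
    ]
    table = evaluate.delta_age_table(preds, records)
    _write_tsv(table, out / "delta_age_groups.tsv", cfg.header())

    meta = {r.sample_id: r for r in records}
    by_group: dict[str, list[float]] = {}
    for p in preds:
        by_group.setdefault(meta[p.sample_id].exposure_group.value, []).append(
            p.delta_age_months
        )
    comp = evaluate.group_inference(
        {g: np.array(v) for g, v in by_group.items()}
    )
    tests = comp.tests.copy()
    header = (
        f"{cfg.header()} anova_f={comp.anova_f:.6f} anova_p={comp.anova_p:.3e} "
        f"anova_stars={comp.anova_stars}"
    )
    _write_tsv(tests, out / "group_inference.tsv", header)
    logger.info("delta: ANOVA F=%.2f p=%.2e", comp.anova_f, comp.anova_p)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "deg": _stage_deg,
    "overlap": _stage_overlap,
    "train": _stage_train,
    "validate": _stage_validate,
    "predict": _stage_predict,
    "delta": _stage_delta,
}


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Run the requested stages in canonical order; returns the output dir."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        fh.write(f"# {cfg.header()}\n")
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    for stage in STAGES:
        if stage in stages:
            logger.info("stage: %s", stage)
            _STAGE_FUNCS[stage](cfg, out)
    return out
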