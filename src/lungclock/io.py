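"""Domain types and file I/O shared by every analysis stage.

Expression data travel as a genes-in-rows log2 matrix (TSV, first column
``gene_id``, remaining columns one per sample); sample annotations as a CSV
with study, chronological age in months, exposure group and exposure
duration; fitted clock models as versioned JSON documents.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = "lungclock-model-1"

__all__ = [
    "ExposureGroup",
    "ExpressionMatrix",
    "SampleMetadata",
    "ClockModel",
    "ContrastResult",
    "LoadError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_metadata",
    "write_metadata",
    "save_model",
    "load_model",
]


class LoadError(ValueError):
    """Raised when an input file violates the format contract."""


class ExposureGroup(str, Enum):
    """Experimental arm of a sample.

    ``sham`` animals breathe fresh air and define the natural-aging
    reference; ``cs`` is cigarette-smoke exposure; ``htp`` heated-tobacco
    aerosol; ``cessation`` smoke exposure stopped mid-study; ``switch``
    smoke exposure replaced by HTP mid-study.
    """

    SHAM = "sham"
    CS = "cs"
    HTP = "htp"
    CESSATION = "cessation"
    SWITCH = "switch"
    OTHER = "other"

    @classmethod
    def parse(cls, label: str, strict: bool = True) -> "ExposureGroup":
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            if strict:
                raise LoadError(f"unknown exposure group label: {label!r}")
            return cls.OTHER


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotation.

    Ages are real-valued months; chronological age is baseline age at
    exposure start (2 months for all studies emulated here) plus the
    exposure duration.
    """

    sample_id: str
    study_id: str
    age_months: float
    exposure_group: ExposureGroup
    exposure_months: float

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise LoadError("empty sample_id")
        if not (self.age_months > 0) or not math.isfinite(self.age_months):
            raise LoadError(
                f"sample {self.sample_id}: age_months must be positive, "
                f"got {self.age_months}"
            )
        if self.exposure_months < 0 or not math.isfinite(self.exposure_months):
            raise LoadError(
                f"sample {self.sample_id}: exposure_months must be >= 0, "
                f"got {self.exposure_months}"
            )


class ExpressionMatrix:
    """Validated log2 expression values, genes in rows, samples in columns."""

    def __init__(
        self,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
    ) -> None:
        gene_ids = [str(g) for g in gene_ids]
        sample_ids = [str(s) for s in sample_ids]
        values = np.asarray(values, dtype=float)
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise LoadError(
                f"value matrix shape {values.shape} does not match "
                f"{len(gene_ids)} genes x {len(sample_ids)} samples"
            )
        _reject_duplicates(gene_ids, "gene")
        _reject_duplicates(sample_ids, "sample")
        if not np.all(np.isfinite(values)):
            g, s = np.argwhere(~np.isfinite(values))[0]
            raise LoadError(
                f"non-finite expression value at gene {gene_ids[g]!r}, "
                f"sample {sample_ids[s]!r}"
            )
        self.gene_ids = gene_ids
        self.sample_ids = sample_ids
        self.values = values
        self._gene_index = {g: i for i, g in enumerate(gene_ids)}
        self._sample_index = {s: i for i, s in enumerate(sample_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_row(self, gene_id: str) -> np.ndarray:
        return self.values[self._gene_index[gene_id]]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._sample_index[s] for s in sample_ids]
        return ExpressionMatrix(self.gene_ids, list(sample_ids), self.values[:, idx])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._gene_index[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), self.sample_ids, self.values[idx, :])

    def drop_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        drop = set(gene_ids)
        keep = [g for g in self.gene_ids if g not in drop]
        return self.subset_genes(keep)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class ClockModel:
    """Sparse linear age predictor: age = intercept + sum coef_g * x_g.

    Coefficients are in months per log2 expression unit (the OLS refit is
    done on the raw log2 scale). ``standardization_params`` records the
    per-gene mean/sd used during LASSO selection; ``training_means`` of the
    coefficient genes support the impute-training-mean policy when the model
    is applied to a platform missing some predictor genes.
    """

    intercept: float
    coefficients: dict[str, float]
    lambda_selected: float
    training_gene_universe: list[str]
    training_sample_count: int
    standardization_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    lambda_grid: list[float] = field(default_factory=list)
    schema_version: str = MODEL_SCHEMA_VERSION

    def __post_init__(self) -> None:
        universe = set(self.training_gene_universe)
        for g, c in self.coefficients.items():
            if g not in universe:
                raise ValueError(f"coefficient gene {g!r} not in training universe")
            if c == 0.0:
                raise ValueError(f"coefficient gene {g!r} carries zero weight")
        if self.lambda_selected < 0:
            raise ValueError("lambda_selected must be >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.coefficients)

    def training_mean(self, gene_id: str) -> float:
        return self.standardization_params[gene_id][0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClockModel):
            return NotImplemented
        return (
            self.intercept == other.intercept
            and self.coefficients == other.coefficients
            and self.lambda_selected == other.lambda_selected
            and self.training_gene_universe == other.training_gene_universe
            and self.training_sample_count == other.training_sample_count
            and {k: tuple(v) for k, v in self.standardization_params.items()}
            == {k: tuple(v) for k, v in other.standardization_params.items()}
            and self.lambda_grid == other.lambda_grid
        )


@dataclass(frozen=True)
class ContrastResult:
    """One gene's statistics for one two-group contrast."""

    contrast_id: str
    gene_id: str
    log2fc: float
    t_stat: float
    p_value: float
    fdr: float


def _reject_duplicates(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise LoadError(f"duplicate {what} id: {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# Expression matrix TSV


def read_expression_matrix(
    path: str | Path, *, missing_policy: str = "strict"
) -> ExpressionMatrix:
    """Read a genes x samples log2 expression TSV.

    Row 1 must be ``gene_id`` followed by sample ids. ``missing_policy``
    is ``"strict"`` (reject missing cells, the default) or ``"drop"``
    (drop genes with any missing value, with a logged count). Values are
    never silently imputed.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
        while header_line.startswith("#"):
            header_line = fh.readline()
    header = header_line.rstrip("\n").split("\t")
    if len(header) < 2:
        raise LoadError(f"{path}: expected gene_id column plus >=1 sample column")
    if header[0].lower() != "gene_id":
        raise LoadError(
            f"{path}: first header cell must be 'gene_id', got {header[0]!r}"
        )
    sample_ids = header[1:]
    _reject_duplicates(sample_ids, "sample")
    df = pd.read_csv(
        path, sep="\t", header=0, dtype={0: str}, comment="#",
        float_precision="round_trip",
    )
    gene_ids = df.iloc[:, 0].astype(str).tolist()
    body = df.iloc[:, 1:]
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & body.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise LoadError(
            f"{path}: non-numeric value {body.iat[r, c]!r} at gene "
            f"{gene_ids[r]!r}, sample {sample_ids[c]!r}"
        )
    missing = numeric.isna()
    if missing.to_numpy().any():
        if missing_policy == "drop":
            keep = ~missing.any(axis=1).to_numpy()
            logger.warning(
                "%s: dropping %d genes with missing values", path, int((~keep).sum())
            )
            gene_ids = [g for g, k in zip(gene_ids, keep) if k]
            numeric = numeric.iloc[keep]
        else:
            r, c = np.argwhere(missing.to_numpy())[0]
            raise LoadError(
                f"{path}: missing value at gene {gene_ids[r]!r}, "
                f"sample {sample_ids[c]!r}"
            )
    return ExpressionMatrix(gene_ids, sample_ids, numeric.to_numpy(dtype=float))


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, *, header_comment: str | None = None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Sample metadata CSV

_METADATA_COLUMNS = [
    "sample_id",
    "study_id",
    "age_months",
    "exposure_group",
    "exposure_months",
]


def read_metadata(path: str | Path, *, strict: bool = True) -> list[SampleMetadata]:
    """Read per-sample annotations from CSV.

    Exposure group labels are parsed case-insensitively into the
    :class:`ExposureGroup` enum; unknown labels raise under ``strict``
    and map to ``other`` otherwise.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing required columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SampleMetadata(
                sample_id=str(row.sample_id),
                study_id=str(row.study_id),
                age_months=float(row.age_months),
                exposure_group=ExposureGroup.parse(row.exposure_group, strict=strict),
                exposure_months=float(row.exposure_months),
            )
        )
    _reject_duplicates([r.sample_id for r in records], "sample")
    return records


def metadata_frame(records: Sequence[SampleMetadata]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "study_id": [r.study_id for r in records],
            "age_months": [r.age_months for r in records],
            "exposure_group": [r.exposure_group.value for r in records],
            "exposure_months": [r.exposure_months for r in records],
        }
    )


def write_metadata(
    records: Sequence[SampleMetadata],
    path: str | Path,
    *,
    header_comment: str | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        metadata_frame(records).to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Clock model JSON


def save_model(
    model: ClockModel, path: str | Path, provenance: str | None = None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "schema_version": model.schema_version,
        "provenance": provenance,
        "intercept": model.intercept,
        "coefficients": model.coefficients,
        "lambda_selected": model.lambda_selected,
        "training_gene_universe": model.training_gene_universe,
        "training_sample_count": model.training_sample_count,
        "standardization_params": {
            g: [m, s] for g, (m, s) in model.standardization_params.items()
        },
        "lambda_grid": model.lambda_grid,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_model(path: str | Path) -> ClockModel:
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise LoadError(
            f"{path}: model schema version {version!r} does not match "
            f"{MODEL_SCHEMA_VERSION!r}"
        )
    known = {
        "schema_version",
        "provenance",
        "intercept",
        "coefficients",
        "lambda_selected",
        "training_gene_universe",
        "training_sample_count",
        "standardization_params",
        "lambda_grid",
    }
    unknown = set(doc) - known
    if unknown:
        logger.warning("%s: ignoring unknown model fields %s", path, sorted(unknown))
    return ClockModel(
        intercept=float(doc["intercept"]),
        coefficients={str(g): float(c) for g, c in doc["coefficients"].items()},
        lambda_selected=float(doc["lambda_selected"]),
        training_gene_universe=[str(g) for g in doc["training_gene_universe"]],
        training_sample_count=int(doc["training_sample_count"]),
        standardization_params={
            str(g): (float(m), float(s))
            for g, (m, s) in doc.get("standardization_params", {}).items()
        },
        lambda_grid=[float(v) for v in doc.get("lambda_grid", [])],
    )
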