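"""Multi-study expression simulator with planted aging and exposure signal.

The generative model for gene g in sample s is

    x_gs = b_g + m_g * f(effective_age_gs) + step_g * a_s + u_{study(s),g} + eps_gs

where ``b_g`` is a baseline log2 level, ``m_g`` a per-month slope carried
only by age-trending genes, ``u`` a per-study per-gene batch offset,
``eps ~ N(0, sigma^2)`` i.i.d. noise, and ``f`` a linear or saturating
trend of effective age.

Exposure acts through two disjoint mechanisms:

* overlap genes (exposure-responsive genes drawn from the age set) read a
  shifted *effective age*: ``age + delta * a_s``, i.e. the acceleration
  ``delta`` moves each such gene along its own aging slope — this is the
  signal a transcriptomic clock trained on controls can translate back
  into months of premature aging;
* exposure-only genes carry a step effect ``step_g`` with no age trend.

``a_s`` is the per-sample acceleration factor: 1 for continuous smoke
exposure, 0 for sham and HTP aerosol arms, and an exponential decay with
configurable half-life after the switch time for cessation/switch arms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import ExposureGroup, ExpressionMatrix, SampleMetadata

__all__ = [
    "GroupSpec",
    "StudyDesign",
    "SimulationConfig",
    "SimulationTruth",
    "generate_dataset",
    "simulate_samples",
    "scenario_three_study",
    "three_study_config",
]


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group: arm x exposure duration x group size."""

    arm: ExposureGroup
    exposure_months: float
    n: int
    switch_month: float | None = None  # when cessation/switch arms left CS


@dataclass(frozen=True)
class StudyDesign:
    study_id: str
    groups: tuple[GroupSpec, ...]


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2000
    n_age_genes: int = 150
    n_exposure_genes: int = 220
    overlap_fraction: float = 0.62
    slope_range: tuple[float, float] = (0.1, 0.4)  # log2 units per month
    step_effect_range: tuple[float, float] = (0.6, 1.5)  # log2 units
    exposure_shift_months: float = 2.0  # delta: months of extra effective age
    cessation_half_life_months: float = 1.0
    study_designs: tuple[StudyDesign, ...] = ()
    batch_sd: float = 0.3
    noise_sd: float = 0.25
    baseline_age_months: float = 2.0
    trend_shape: str = "linear"  # or "saturating"
    saturation_scale_months: float = 8.0
    fraction_up: float = 0.6  # fraction of age slopes / step effects positive
    seed: int = 0

    def __post_init__(self) -> None:
        n_overlap = round(self.overlap_fraction * self.n_exposure_genes)
        if self.n_age_genes + self.n_exposure_genes - n_overlap > self.n_genes:
            raise ValueError("gene counts exceed gene universe")
        if n_overlap > self.n_age_genes:
            raise ValueError("overlap larger than the age gene set")
        if min(self.batch_sd, self.noise_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.exposure_shift_months < 0:
            raise ValueError("exposure_shift_months must be >= 0")
        if self.trend_shape not in ("linear", "saturating"):
            raise ValueError(f"unknown trend_shape {self.trend_shape!r}")


@dataclass
class SimulationTruth:
    """Planted parameters, kept for parameter-recovery checks."""

    config: SimulationConfig
    gene_ids: list[str]
    baselines: np.ndarray  # (n_genes,)
    slopes: np.ndarray  # (n_genes,) zero outside age genes
    step_effects: np.ndarray  # (n_genes,) zero outside exposure-only genes
    age_gene_ids: list[str]
    exposure_gene_ids: list[str]
    overlap_gene_ids: list[str]
    batch_offsets: dict[str, np.ndarray]  # study_id -> (n_genes,)
    effective_age_months: dict[str, float] = field(default_factory=dict)

    def acceleration_factor(self, record: SampleMetadata) -> float:
        """Per-sample multiplier on the planted age shift (and step effects)."""
        return _acceleration_factor(
            record.exposure_group,
            record.exposure_months,
            self._switch_months.get(record.sample_id),
            self.config.cessation_half_life_months,
        )

    _switch_months: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "age_genes": {
                g: float(self.slopes[self.gene_ids.index(g)])
                for g in self.age_gene_ids
            },
            "exposure_genes": self.exposure_gene_ids,
            "overlap_genes": self.overlap_gene_ids,
            "step_effects": {
                g: float(self.step_effects[self.gene_ids.index(g)])
                for g in self.exposure_gene_ids
                if g not in set(self.overlap_gene_ids)
            },
            "effective_age_months": self.effective_age_months,
            "exposure_shift_months": self.config.exposure_shift_months,
        }


def _acceleration_factor(
    arm: ExposureGroup,
    exposure_months: float,
    switch_month: float | None,
    half_life: float,
) -> float:
    if arm == ExposureGroup.CS:
        return 1.0
    if arm in (ExposureGroup.CESSATION, ExposureGroup.SWITCH):
        if switch_month is None:
            raise ValueError(f"{arm.value} group requires switch_month")
        dt = exposure_months - switch_month
        if dt <= 0:
            return 1.0
        return math.exp(-math.log(2.0) * dt / half_life)
    return 0.0  # sham, htp, other


def _trend(ages: np.ndarray, config: SimulationConfig) -> np.ndarray:
    if config.trend_shape == "linear":
        return ages
    tau = config.saturation_scale_months
    return tau * (1.0 - np.exp(-np.asarray(ages) / tau))


def _plant_genes(config: SimulationConfig, rng: np.random.Generator):
    n = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    baselines = rng.uniform(4.0, 12.0, size=n)

    n_overlap = round(config.overlap_fraction * config.n_exposure_genes)
    perm = rng.permutation(n)
    age_idx = perm[: config.n_age_genes]
    overlap_idx = age_idx[: n_overlap] if n_overlap else age_idx[:0]
    n_only = config.n_exposure_genes - n_overlap
    only_idx = perm[config.n_age_genes : config.n_age_genes + n_only]

    lo, hi = config.slope_range
    signs = np.where(rng.random(config.n_age_genes) < config.fraction_up, 1.0, -1.0)
    slopes = np.zeros(n)
    slopes[age_idx] = signs * rng.uniform(lo, hi, size=config.n_age_genes)

    slo, shi = config.step_effect_range
    ssigns = np.where(rng.random(n_only) < config.fraction_up, 1.0, -1.0)
    steps = np.zeros(n)
    steps[only_idx] = ssigns * rng.uniform(slo, shi, size=n_only)

    return gene_ids, baselines, slopes, steps, age_idx, overlap_idx, only_idx


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, list[SampleMetadata], SimulationTruth]:
    """Simulate a full multi-study dataset; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    gene_ids, baselines, slopes, steps, age_idx, overlap_idx, only_idx = _plant_genes(
        config, rng
    )

    batch_offsets = {
        d.study_id: rng.normal(0.0, config.batch_sd, size=config.n_genes)
        for d in config.study_designs
    }

    truth = SimulationTruth(
        config=config,
        gene_ids=gene_ids,
        baselines=baselines,
        slopes=slopes,
        step_effects=steps,
        age_gene_ids=[gene_ids[i] for i in age_idx],
        exposure_gene_ids=[gene_ids[i] for i in np.concatenate([overlap_idx, only_idx])],
        overlap_gene_ids=[gene_ids[i] for i in overlap_idx],
        batch_offsets=batch_offsets,
    )

    records: list[SampleMetadata] = []
    for design in config.study_designs:
        for group in design.groups:
            for i in range(group.n):
                sid = (
                    f"{design.study_id}_{group.arm.value}_"
                    f"{group.exposure_months:g}m_{i + 1}"
                )
                rec = SampleMetadata(
                    sample_id=sid,
                    study_id=design.study_id,
                    age_months=config.baseline_age_months + group.exposure_months,
                    exposure_group=group.arm,
                    exposure_months=group.exposure_months,
                )
                records.append(rec)
                if group.switch_month is not None:
                    truth._switch_months[sid] = group.switch_month

    values = simulate_sample_values(truth, records, rng)
    matrix = ExpressionMatrix(gene_ids, [r.sample_id for r in records], values)
    return matrix, records, truth


def simulate_sample_values(
    truth: SimulationTruth,
    records: list[SampleMetadata],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw expression values for ``records`` from the planted model.

    Reuses the planted gene effects and batch offsets in ``truth`` so that
    fresh replicate groups are exchangeable with the original dataset.
    Studies unseen at planting time get a fresh batch offset (drawn from
    ``rng``) that is then cached in ``truth``.
    """
    config = truth.config
    n_genes = config.n_genes
    overlap_mask = np.zeros(n_genes, dtype=bool)
    idx = {g: i for i, g in enumerate(truth.gene_ids)}
    overlap_mask[[idx[g] for g in truth.overlap_gene_ids]] = True

    values = np.empty((n_genes, len(records)))
    for j, rec in enumerate(records):
        a = truth.acceleration_factor(rec)
        eff_age = rec.age_months + config.exposure_shift_months * a
        truth.effective_age_months[rec.sample_id] = eff_age
        if rec.study_id not in truth.batch_offsets:
            truth.batch_offsets[rec.study_id] = rng.normal(
                0.0, config.batch_sd, size=n_genes
            )
        # overlap genes follow the shifted effective age; other age genes
        # follow chronological age
        f_eff = _trend(np.array([eff_age]), config)[0]
        f_chrono = _trend(np.array([rec.age_months]), config)[0]
        trend = np.where(overlap_mask, f_eff, f_chrono)
        col = (
            truth.baselines
            + truth.slopes * trend
            + truth.step_effects * a
            + truth.batch_offsets[rec.study_id]
        )
        values[:, j] = col
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=values.shape)
    return values


def simulate_samples(
    truth: SimulationTruth,
    records: list[SampleMetadata],
    seed: int,
    switch_months: dict[str, float] | None = None,
) -> ExpressionMatrix:
    """Generate a fresh replicate matrix for new sample records."""
    if switch_months:
        truth._switch_months.update(switch_months)
    rng = np.random.default_rng(seed)
    values = simulate_sample_values(truth, records, rng)
    return ExpressionMatrix(truth.gene_ids, [r.sample_id for r in records], values)


# ---------------------------------------------------------------------------
# Default preset: 3 chronic-exposure inhalation studies


def _study_designs() -> tuple[StudyDesign, ...]:
    """Three studies emulating chronic CS/HTP inhalation designs.

    Sham and CS arms share time points within each study; one study adds
    an HTP arm, one adds HTP plus cessation and switch arms (animals leave
    CS after 2 months of exposure). Sham group sizes total 111 across the
    three studies; the within-study sham time-point pairs number
    C(6,2)+C(5,2)+C(3,2) = 28 and the per-time-point CS-vs-sham pairs
    6+5+3 = 14.
    """
    sham, cs, htp = ExposureGroup.SHAM, ExposureGroup.CS, ExposureGroup.HTP
    cess, switch = ExposureGroup.CESSATION, ExposureGroup.SWITCH

    s1_tps = [1.0, 2.0, 3.0, 4.0, 6.0, 8.0]
    s2_tps = [1.0, 2.0, 3.0, 4.0, 6.0]
    s3_tps = [1.0, 3.0, 6.0]

    study1 = StudyDesign(
        "study1",
        tuple(
            GroupSpec(arm, t, 8) for t in s1_tps for arm in (sham, cs)
        ),
    )
    study2 = StudyDesign(
        "study2",
        tuple(
            GroupSpec(arm, t, 8) for t in s2_tps for arm in (sham, cs, htp)
        ),
    )
    s3_groups = [
        GroupSpec(sham, 1.0, 8),
        GroupSpec(sham, 3.0, 8),
        GroupSpec(sham, 6.0, 7),
    ]
    s3_groups += [GroupSpec(cs, t, 8) for t in s3_tps]
    s3_groups += [GroupSpec(htp, t, 8) for t in s3_tps]
    s3_groups += [GroupSpec(cess, t, 8, switch_month=2.0) for t in (3.0, 6.0)]
    s3_groups += [GroupSpec(switch, t, 8, switch_month=2.0) for t in (3.0, 6.0)]
    study3 = StudyDesign("study3", tuple(s3_groups))
    return (study1, study2, study3)


def three_study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default multi-study scenario used throughout the analyses."""
    base = SimulationConfig(study_designs=_study_designs(), seed=seed)
    return replace(base, **overrides) if overrides else base


def scenario_three_study(
    seed: int = 0, **overrides
) -> tuple[ExpressionMatrix, list[SampleMetadata], SimulationTruth]:
    return generate_dataset(three_study_config(seed, **overrides))
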