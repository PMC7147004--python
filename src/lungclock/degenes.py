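"""Two-group differential expression with variance-moderated t-statistics.

Each contrast compares two disjoint sample groups gene by gene on the log2
scale; the fold change is the difference of group means with a fixed
orientation (older minus younger for age contrasts, treated minus control
for exposure contrasts). Per-gene variances may be moderated by an
empirical-Bayes shrinkage toward a common prior variance: the pooled
sample variance s_g^2 with d_g degrees of freedom is replaced by

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the t-statistic gains d0 extra degrees of freedom. The prior (d0,
s0^2) is estimated by the method of moments on the log sample variances,
using the exact moments of the log of a scaled chi-square variable.

Multiplicity within a contrast is handled by the Benjamini-Hochberg
step-up adjustment, implemented here directly from its definition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExposureGroup, ExpressionMatrix, SampleMetadata

logger = logging.getLogger(__name__)

DEFAULT_FC_CUTOFF = math.log2(1.5)
DEFAULT_FDR_CUTOFF = 0.05

__all__ = [
    "ContrastSpec",
    "RegulatedGeneSet",
    "contrast_test",
    "bh_adjust",
    "build_age_contrasts",
    "build_exposure_contrasts",
    "identify_regulated",
    "estimate_variance_prior",
    "DEFAULT_FC_CUTOFF",
    "DEFAULT_FDR_CUTOFF",
]


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group comparison, oriented group_a minus group_b.

    ``group_a`` is the older (age contrasts) or treated (exposure
    contrasts) group; the orientation is fixed by construction, never
    auto-detected.
    """

    contrast_id: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    kind: str  # "age" | "exposure"

    def __post_init__(self) -> None:
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError(
                f"{self.contrast_id}: each group needs >= 2 samples "
                f"(got {len(self.group_a)} vs {len(self.group_b)})"
            )
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"{self.contrast_id}: groups overlap")
        if self.kind not in ("age", "exposure"):
            raise ValueError(f"unknown contrast kind {self.kind!r}")


@dataclass
class RegulatedGeneSet:
    """Genes passing fold-change and FDR cutoffs in at least one contrast."""

    gene_ids: list[str]
    fc_cutoff: float
    fdr_cutoff: float
    contributing: dict[str, list[str]] = field(default_factory=dict)
    excluded_genes: list[str] = field(default_factory=list)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.gene_ids)

    def __len__(self) -> int:
        return len(self.gene_ids)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * n / j, capped at 1, returned in the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-d vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(n)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Variance moderation


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments prior (d0, s0^2) from per-gene pooled variances.

    Uses log variances: for s^2 ~ s0^2 * F(d, d0), E[log s^2] and
    Var[log s^2] involve digamma/trigamma terms of d/2 and d0/2. Genes
    with zero sample variance are left out of the moment estimation.
    Returns d0 = inf when the observed spread of log variances is no
    larger than expected from chi-square sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 2:
        return 0.0, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    evar = np.var(e, ddof=1) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return math.inf, float(np.exp(np.mean(e)))
    d0 = 2.0 * _trigamma_inverse(evar)
    # E[e] = log s0^2 - digamma(d0/2) + log(d0/2)
    s0_sq = float(
        np.exp(np.mean(e) + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    )
    return d0, s0_sq


def contrast_test(
    matrix: ExpressionMatrix,
    spec: ContrastSpec,
    moderation: str = "eb",
    prior: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-gene two-group test for one contrast.

    Returns a frame with columns ``contrast_id, gene_id, log2fc, t, p,
    fdr`` (FDR adjusted within the contrast). ``moderation`` is ``"eb"``
    (empirical-Bayes shrinkage, the default) or ``"ordinary"``; ``prior``
    optionally fixes (d0, s0^2) instead of estimating them — d0 = 0
    recovers the ordinary pooled t, d0 = inf uses s0^2 for every gene.
    """
    if moderation not in ("eb", "ordinary"):
        raise ValueError(f"unknown moderation {moderation!r}")
    a = matrix.subset_samples(list(spec.group_a)).values
    b = matrix.subset_samples(list(spec.group_b)).values
    na, nb = a.shape[1], b.shape[1]
    df_resid = na + nb - 2

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = mean_a - mean_b
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + (
        (b - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid

    if moderation == "ordinary":
        d0, s0_sq = 0.0, 0.0
    elif prior is not None:
        d0, s0_sq = prior
    else:
        d0, s0_sq = estimate_variance_prior(s2, df_resid)

    if math.isinf(d0):
        s2_mod = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0.0:
        s2_mod = s2
        df_total = float(df_resid)
    else:
        s2_mod = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = float(df_resid + d0)

    se = np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    # genes with zero variance in both groups are reported flat by policy,
    # even when shrinkage would lend them a positive moderated variance
    degenerate = s2 == 0.0
    t = np.where(degenerate, 0.0, t)
    if degenerate.any():
        logger.warning(
            "%s: %d genes with zero variance in both groups set to t=0, p=1",
            spec.contrast_id,
            int(degenerate.sum()),
        )
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {
            "contrast_id": spec.contrast_id,
            "gene_id": matrix.gene_ids,
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "fdr": bh_adjust(p),
        }
    )


# ---------------------------------------------------------------------------
# Contrast enumeration


def _group_samples(
    records: list[SampleMetadata],
) -> dict[tuple[str, ExposureGroup, float], list[str]]:
    groups: dict[tuple[str, ExposureGroup, float], list[str]] = {}
    for r in records:
        groups.setdefault(
            (r.study_id, r.exposure_group, r.exposure_months), []
        ).append(r.sample_id)
    return groups


def build_age_contrasts(records: list[SampleMetadata]) -> list[ContrastSpec]:
    """All within-study sham time-point pairs, oriented oldest minus youngest."""
    groups = _group_samples(records)
    sham_by_study: dict[str, list[tuple[float, list[str]]]] = {}
    for (study, arm, t), ids in groups.items():
        if arm == ExposureGroup.SHAM:
            sham_by_study.setdefault(study, []).append((t, ids))
    specs: list[ContrastSpec] = []
    for study in sorted(sham_by_study):
        tps = sorted(sham_by_study[study])
        for i, (t_young, young) in enumerate(tps):
            for t_old, old in tps[i + 1 :]:
                specs.append(
                    ContrastSpec(
                        contrast_id=(
                            f"{study}:sham_{t_old:g}m-sham_{t_young:g}m"
                        ),
                        group_a=tuple(old),
                        group_b=tuple(young),
                        kind="age",
                    )
                )
    if not specs:
        logger.warning("no sham time-point pairs found; no age contrasts")
    return specs


def build_exposure_contrasts(
    records: list[SampleMetadata],
    arm: ExposureGroup = ExposureGroup.CS,
) -> list[ContrastSpec]:
    """Treated-vs-sham contrasts at matched time points within each study."""
    groups = _group_samples(records)
    specs: list[ContrastSpec] = []
    for study in sorted({s for s, _, _ in groups}):
        tps = sorted(
            t
            for (s, a, t) in groups
            if s == study and a == arm and (s, ExposureGroup.SHAM, t) in groups
        )
        for t in tps:
            specs.append(
                ContrastSpec(
                    contrast_id=f"{study}:{arm.value}_{t:g}m-sham_{t:g}m",
                    group_a=tuple(groups[(study, arm, t)]),
                    group_b=tuple(groups[(study, ExposureGroup.SHAM, t)]),
                    kind="exposure",
                )
            )
    return specs


# ---------------------------------------------------------------------------
# Regulated-set definition


def identify_regulated(
    results: pd.DataFrame,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
    excluded_genes: tuple[str, ...] = (),
) -> RegulatedGeneSet:
    """Genes with |log2fc| > fc_cutoff and FDR < fdr_cutoff in >= 1 contrast.

    ``results`` is the concatenation of per-contrast frames from
    :func:`contrast_test`. The fold-change criterion is applied two-sided.
    ``excluded_genes`` are removed from the set regardless of statistics
    (e.g. a gene knocked out in some of the underlying strains).
    """
    if not 0 < fdr_cutoff <= 1:
        raise ValueError("fdr_cutoff must be in (0, 1]")
    if fc_cutoff < 0:
        raise ValueError("fc_cutoff must be >= 0")
    hits = results[
        (results["log2fc"].abs() > fc_cutoff) & (results["fdr"] < fdr_cutoff)
    ]
    excluded = set(excluded_genes)
    contributing: dict[str, list[str]] = {}
    for gene, sub in hits.groupby("gene_id", sort=True):
        if gene in excluded:
            continue
        contributing[str(gene)] = sorted(sub["contrast_id"].unique())
    return RegulatedGeneSet(
        gene_ids=sorted(contributing),
        fc_cutoff=fc_cutoff,
        fdr_cutoff=fdr_cutoff,
        contributing=contributing,
        excluded_genes=sorted(excluded),
    )


def run_contrasts(
    matrix: ExpressionMatrix,
    specs: list[ContrastSpec],
    moderation: str = "eb",
) -> pd.DataFrame:
    """Run a batch of contrasts and concatenate the per-gene results."""
    if not specs:
        return pd.DataFrame(
            columns=["contrast_id", "gene_id", "log2fc", "t", "p", "fdr"]
        )
    return pd.concat(
        [contrast_test(matrix, s, moderation=moderation) for s in specs],
        ignore_index=True,
    )
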