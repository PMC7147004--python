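"""Age x exposure transcriptional overlap: Venn counts, signed maximum
fold change across contrasts, and first-principal-component loadings of
fold-change profiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .degenes import RegulatedGeneSet

__all__ = [
    "FoldChangeProfile",
    "Pc1Result",
    "fold_change_profile",
    "venn_overlap",
    "signed_max_fold_change",
    "pc1_loadings",
    "compare_loadings",
]


@dataclass
class FoldChangeProfile:
    """Complete genes x contrasts matrix of log2 fold changes."""

    gene_ids: list[str]
    contrast_ids: list[str]
    values: np.ndarray  # (n_genes, n_contrasts)
    kind: str  # "age" | "exposure"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.contrast_ids)):
            raise ValueError("profile shape does not match ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile contains missing or non-finite cells")


@dataclass
class Pc1Result:
    """First principal component of a fold-change profile.

    ``loadings`` are the unit-norm per-gene weights of component 1;
    ``inertia`` is the percentage of total variance it captures. The sign
    is oriented so the loadings correlate non-negatively with the
    gene-wise mean fold change.
    """

    gene_ids: list[str]
    loadings: np.ndarray
    inertia: float
    orientation_sign: int


def fold_change_profile(results: pd.DataFrame, kind: str) -> FoldChangeProfile:
    """Pivot concatenated contrast results into a genes x contrasts matrix."""
    wide = results.pivot(index="gene_id", columns="contrast_id", values="log2fc")
    if wide.isna().to_numpy().any():
        raise ValueError("fold-change profile is incomplete across contrasts")
    wide = wide.sort_index(axis=0).sort_index(axis=1)
    return FoldChangeProfile(
        gene_ids=[str(g) for g in wide.index],
        contrast_ids=[str(c) for c in wide.columns],
        values=wide.to_numpy(),
        kind=kind,
    )


def venn_overlap(
    set_a: RegulatedGeneSet, set_b: RegulatedGeneSet, ndigits: int | None = 1
) -> tuple[int, int, int, float]:
    """(|a only|, |b only|, |a and b|, percent of a that is also in b)."""
    a, b = set(set_a.gene_ids), set(set_b.gene_ids)
    inter = len(a & b)
    pct = 100.0 * inter / len(a) if a else 0.0
    if ndigits is not None:
        pct = round(pct, ndigits)
    return len(a) - inter, len(b) - inter, inter, pct


def signed_max_fold_change(profile: FoldChangeProfile) -> pd.Series:
    """Per gene, the log2 fold change of largest magnitude across contrasts.

    The sign is retained; ties in magnitude resolve to the
    lexicographically earliest contrast id.
    """
    if not profile.contrast_ids:
        raise ValueError("profile has no contrasts")
    order = np.argsort(np.array(profile.contrast_ids), kind="stable")
    vals = profile.values[:, order]
    pick = np.argmax(np.abs(vals), axis=1)  # first max wins the tie
    mfc = vals[np.arange(vals.shape[0]), pick]
    return pd.Series(mfc, index=profile.gene_ids, name=f"mfc_{profile.kind}")


def pc1_loadings(
    profile: FoldChangeProfile, scale_columns: bool = False
) -> Pc1Result:
    """PCA of the column-centered profile; returns component-1 gene loadings.

    Centering is per contrast (column) so the loadings live on the gene
    axis. ``scale_columns`` additionally divides each centered column by
    its standard deviation. Inertia is 100 * lambda_1 / sum(lambda).
    """
    if len(profile.contrast_ids) < 2 or len(profile.gene_ids) < 2:
        raise ValueError("PCA needs >= 2 genes and >= 2 contrasts")
    x = profile.values - profile.values.mean(axis=0, keepdims=True)
    if scale_columns:
        sd = x.std(axis=0, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("cannot scale a zero-variance contrast column")
        x = x / sd
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    if not np.any(s > 0):
        raise ValueError("profile has rank 0 after centering")
    inertia = 100.0 * float(s[0] ** 2 / np.sum(s**2))
    loadings = u[:, 0]
    mean_profile = profile.values.mean(axis=1)
    sign = 1
    corr = float(np.dot(loadings, mean_profile - mean_profile.mean()))
    if corr < 0:
        sign = -1
    return Pc1Result(
        gene_ids=list(profile.gene_ids),
        loadings=sign * loadings,
        inertia=inertia,
        orientation_sign=sign,
    )


def compare_loadings(age: Pc1Result, exposure: Pc1Result):
    """Pearson correlation of PC1 loadings over the shared gene universe.

    Returns ``(r, p, table)`` where ``table`` pairs the loadings per gene
    for export or plotting.
    """
    shared = sorted(set(age.gene_ids) & set(exposure.gene_ids))
    if len(shared) < 3:
        raise ValueError("need >= 3 shared genes to correlate loadings")
    ia = {g: i for i, g in enumerate(age.gene_ids)}
    ib = {g: i for i, g in enumerate(exposure.gene_ids)}
    la = np.array([age.loadings[ia[g]] for g in shared])
    lb = np.array([exposure.loadings[ib[g]] for g in shared])
    r, p = stats.pearsonr(la, lb)
    table = pd.DataFrame(
        {"gene_id": shared, "loading_age": la, "loading_exposure": lb}
    )
    return float(r), float(p), table
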