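"""Normalization, dispersion estimation and NB Wald differential expression.

A transparent re-implementation of the standard count-based DE workflow:
median-of-ratios size factors, method-of-moments gene-wise dispersions
with optional shrinkage toward the central tendency, per-contrast
negative-binomial Wald tests with size factors as offsets, and
Benjamini-Hochberg adjustment.  No fold-change shrinkage prior is
applied: the reported log2 fold changes are maximum-likelihood
estimates, which keeps them directly usable for dose-ratio regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from paracomp.simdata import CountDataset, Genotype

DISPERSION_FLOOR = 1e-8


@dataclass
class NormalizationModel:
    """Per-sample size factors and per-gene NB dispersions."""

    size_factors: pd.Series  # indexed by sample_id, all > 0
    dispersions: pd.Series  # indexed by gene_id, all >= DISPERSION_FLOOR
    pseudo_reference: bool = False  # True if the GM fallback was used


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group comparison between sets of genotypes.

    ``log2FC`` is reported as B over A, so ``group_a`` is the reference
    (e.g. wild type) and ``group_b`` the condition of interest.
    """

    name: str
    group_a: frozenset[Genotype]
    group_b: frozenset[Genotype]
    stage: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError(f"contrast {self.name!r}: empty group")
        if self.group_a & self.group_b:
            raise ValueError(f"contrast {self.name!r}: groups overlap")

    @staticmethod
    def of(name: str, a: Iterable[Genotype], b: Iterable[Genotype], stage=None):
        return ContrastSpec(name, frozenset(a), frozenset(b), stage)


@dataclass
class DEResult:
    """Per-gene Wald test results for one contrast.

    ``table`` columns: baseMean, mean_a, mean_b (normalized), log2FC,
    se, stat, pvalue, padj, tested, zero_substituted.  Untested genes
    carry NaN statistics.
    """

    contrast: ContrastSpec
    table: pd.DataFrame

    def significant(self, q_max: float = 0.05) -> set[str]:
        t = self.table
        return set(t.index[(t["tested"]) & (t["padj"] < q_max)])


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over genes of K_ij / GM_i where GM_i is the geometric
    mean of gene i across samples; genes with any zero are excluded from
    the reference.  If no gene is positive in every sample a
    pseudo-reference (geometric mean over positive samples only) is
    used and the caller is warned via ValueError advice.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    k = counts.to_numpy(dtype=float)
    all_pos = (k > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has positive counts in every sample; use "
            "size_factors_pseudo_reference instead"
        )
    with np.errstate(divide="ignore"):
        log_gm = np.log(k[all_pos]).mean(axis=1)
    ratios = np.log(k[all_pos]) - log_gm[:, None]
    s = np.exp(np.median(ratios, axis=0))
    return pd.Series(s, index=counts.columns, name="size_factor")


def size_factors_pseudo_reference(counts: pd.DataFrame) -> pd.Series:
    """Fallback size factors using geometric means over positive samples."""
    k = counts.to_numpy(dtype=float)
    pos = k > 0
    usable = pos.sum(axis=1) >= 2
    if not usable.any():
        raise ValueError("no gene observed in at least two samples")
    logk = np.where(pos, np.log(np.where(pos, k, 1.0)), np.nan)
    log_gm = np.nanmean(logk[usable], axis=1)
    ratios = logk[usable] - log_gm[:, None]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s = np.exp(np.nanmedian(ratios, axis=0))
    s = np.where(np.isfinite(s), s, 1.0)  # samples with no usable ratio
    return pd.Series(s, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    groups: Sequence[Sequence[str]],
    shrinkage_weight: float = 0.3,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Method-of-moments NB dispersion per gene, pooled within groups.

    For each gene, the within-group mean/variance of normalized counts
    are pooled across all replicate groups and alpha = (v - m) / m^2 is
    floored at ``floor``.  Dispersions are then shrunk on the log scale
    toward the 20%-trimmed mean of log alpha with weight
    ``shrinkage_weight`` (0 disables shrinkage); genes at the floor stay
    at the floor.
    """
    s = size_factors.loc[counts.columns].to_numpy()
    y = counts.to_numpy(dtype=float) / s[None, :]
    n_genes = y.shape[0]
    ss_within = np.zeros(n_genes)
    df_total = 0
    mean_total = np.zeros(n_genes)
    n_total = 0
    for grp in groups:
        idx = [counts.columns.get_loc(c) for c in grp]
        if len(idx) < 2:
            continue
        sub = y[:, idx]
        m = sub.mean(axis=1)
        ss_within += ((sub - m[:, None]) ** 2).sum(axis=1)
        df_total += len(idx) - 1
        mean_total += sub.sum(axis=1)
        n_total += len(idx)
    if df_total == 0:
        raise ValueError("need at least one group with >= 2 replicates")
    v = ss_within / df_total
    m = mean_total / n_total
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - m) / m**2
    alpha = np.where(m > 0, alpha, np.nan)
    alpha = np.maximum(alpha, floor)

    finite = np.isfinite(alpha)
    if shrinkage_weight > 0 and finite.sum() >= 3:
        log_a = np.log(alpha[finite])
        centre = stats.trim_mean(log_a, 0.2)
        shrunk = np.exp(
            (1 - shrinkage_weight) * np.log(alpha[finite]) + shrinkage_weight * centre
        )
        out = alpha.copy()
        out[finite] = np.maximum(shrunk, floor)
        alpha = out
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _fit_nb_group(
    k: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised NB MLE of the normalized group mean, offsets fixed.

    Model: K_j ~ NB(mean = s_j * mu, var = m + alpha m^2), one mu per
    gene.  Newton-Raphson on eta = log mu; returns (mu_hat, info) where
    info is the observed Fisher information in eta (so var(eta_hat) =
    1/info).  Genes must have at least one positive count.
    """
    k = np.asarray(k, dtype=float)
    alpha = np.asarray(alpha, dtype=float)[:, None]
    mu0 = (k / s[None, :]).mean(axis=1)
    eta = np.log(np.maximum(mu0, 1e-8))
    for _ in range(n_iter):
        m = s[None, :] * np.exp(eta)[:, None]
        denom = 1.0 + alpha * m
        score = ((k - m) / denom).sum(axis=1)
        info = (m * (1.0 + alpha * k) / denom**2).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        eta = eta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = np.exp(eta)
    m = s[None, :] * mu[:, None]
    denom = 1.0 + alpha * m
    info = (m * (1.0 + alpha * k) / denom**2).sum(axis=1)
    return mu, info


def nb_wald_test(
    dataset: CountDataset,
    norm: NormalizationModel,
    contrast: ContrastSpec,
    min_base_mean: float = 1.0,
) -> DEResult:
    """Two-group negative-binomial Wald test for one contrast.

    Group means are fitted independently by NB maximum likelihood with
    the shared gene-wise dispersion and size-factor offsets;
    log2FC = log2(mu_b / mu_a), its standard error comes from the
    observed Fisher information, and p-values are two-sided normal.
    Genes with base mean below ``min_base_mean`` (or all-zero in both
    groups) are flagged untested.  If one group has an all-zero fit,
    0.5 / mean(s) is substituted for reporting and the gene is flagged
    ``zero_substituted``.
    """
    cols_a = _contrast_samples(dataset, contrast.group_a, contrast.stage)
    cols_b = _contrast_samples(dataset, contrast.group_b, contrast.stage)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"contrast {contrast.name!r}: both groups need >= 2 samples "
            f"(got {len(cols_a)} vs {len(cols_b)})"
        )
    ka = dataset.counts[cols_a].to_numpy(dtype=float)
    kb = dataset.counts[cols_b].to_numpy(dtype=float)
    sa = norm.size_factors.loc[cols_a].to_numpy()
    sb = norm.size_factors.loc[cols_b].to_numpy()
    alpha = norm.dispersions.loc[dataset.counts.index].to_numpy()
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)

    norm_all = np.concatenate([ka / sa[None, :], kb / sb[None, :]], axis=1)
    base_mean = norm_all.mean(axis=1)
    tested = base_mean >= min_base_mean

    mu_a, info_a = _fit_nb_group(ka, sa, alpha)
    mu_b, info_b = _fit_nb_group(kb, sb, alpha)

    zero_a = ka.sum(axis=1) == 0
    zero_b = kb.sum(axis=1) == 0
    pseudo = 0.5 / float(np.mean(np.concatenate([sa, sb])))
    substituted = (zero_a ^ zero_b) & tested
    mu_a = np.where(zero_a, pseudo, mu_a)
    mu_b = np.where(zero_b, pseudo, mu_b)
    # information at the substituted mean so the Wald se stays finite
    info_a = np.where(zero_a, _info_at(pseudo, sa, alpha), info_a)
    info_b = np.where(zero_b, _info_at(pseudo, sb, alpha), info_b)

    log2fc = np.log2(mu_b / mu_a)
    ln2 = np.log(2.0)
    se = np.sqrt(1.0 / np.maximum(info_a, 1e-12) + 1.0 / np.maximum(info_b, 1e-12)) / ln2
    z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    tested &= ~(zero_a & zero_b)
    p = np.where(tested, p, np.nan)
    q = bh_adjust(p)

    table = pd.DataFrame(
        {
            "baseMean": base_mean,
            "mean_a": mu_a,
            "mean_b": mu_b,
            "log2FC": np.where(tested, log2fc, np.nan),
            "se": np.where(tested, se, np.nan),
            "stat": np.where(tested, z, np.nan),
            "pvalue": p,
            "padj": q,
            "tested": tested,
            "zero_substituted": substituted,
        },
        index=dataset.counts.index,
    )
    return DEResult(contrast=contrast, table=table)


def _info_at(mu: float, s: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    m = s[None, :] * mu
    return (m / (1.0 + alpha[:, None] * m) ** 2 * 1.0).sum(axis=1)


def _contrast_samples(
    dataset: CountDataset, group: frozenset[Genotype], stage: Optional[str]
) -> list[str]:
    cols: list[str] = []
    for g in sorted(group):
        cols.extend(dataset.samples_for(g, stage))
    if not cols:
        raise ValueError(f"no samples for genotypes {sorted(group)} (stage={stage})")
    return cols


def fit_normalization(
    dataset: CountDataset,
    shrinkage_weight: float = 0.3,
    stage: Optional[str] = None,
) -> NormalizationModel:
    """Convenience: size factors + dispersions grouped by genotype."""
    counts = dataset.counts
    samples = dataset.samples
    if stage is not None:
        keep = samples["stage"] == stage
        samples = samples[keep]
        counts = counts[samples["sample_id"]]
    try:
        s = size_factors(counts)
        pseudo = False
    except ValueError:
        s = size_factors_pseudo_reference(counts)
        pseudo = True
    groups = [
        list(sub["sample_id"])
        for _, sub in samples.groupby(["genotype_a", "genotype_c", "stage"])
    ]
    disp = estimate_dispersion(counts, s, groups, shrinkage_weight=shrinkage_weight)
    return NormalizationModel(size_factors=s, dispersions=disp, pseudo_reference=pseudo)


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN entries are ignored in m."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if not ok.any():
        return q
    ps = p[ok]
    m = ps.size
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def de_count_grid(
    dataset: CountDataset,
    contrasts: Sequence[ContrastSpec],
    stages: Optional[Sequence[str]] = None,
    q_threshold: float = 0.05,
    shrinkage_weight: float = 0.3,
) -> pd.DataFrame:
    """Significant-gene counts for every (contrast, stage) cell."""
    if stages is None:
        stages = sorted(dataset.samples["stage"].unique())
    grid = pd.DataFrame(index=[c.name for c in contrasts], columns=list(stages), dtype=float)
    for stage in stages:
        norm = fit_normalization(dataset, shrinkage_weight=shrinkage_weight, stage=stage)
        for c in contrasts:
            spec = ContrastSpec(c.name, c.group_a, c.group_b, stage)
            res = nb_wald_test(dataset, norm, spec)
            grid.loc[c.name, stage] = len(res.significant(q_threshold))
    return grid.astype(int)


def pca_samples(log_expr: pd.DataFrame, n_components: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples from a gene x sample log-expression matrix.

    Genes are centred; SVD coordinates for the top components are
    returned with the fraction of variance each explains.
    """
    if log_expr.shape[1] < 3:
        raise ValueError("need at least three samples")
    x = log_expr.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    if np.allclose(x, 0):
        raise ValueError("constant expression matrix")
    u, sv, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(sv))
    coords = (vt[:k].T * sv[:k])
    var_frac = sv**2 / (sv**2).sum()
    cols = [f"PC{i+1}" for i in range(k)]
    return pd.DataFrame(coords, index=log_expr.columns, columns=cols), var_frac[:k]


def compare_experiments(
    de_a: DEResult, de_b: DEResult, q_max: float = 0.01
) -> tuple[float, int]:
    """Pearson r of log2FC over genes significant in both experiments."""
    shared = sorted(
        (de_a.significant(q_max) & de_b.significant(q_max))
        & set(de_a.table.index)
        & set(de_b.table.index)
    )
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared significant genes")
    x = de_a.table.loc[shared, "log2FC"]
    y = de_b.table.loc[shared, "log2FC"]
    r = float(np.corrcoef(x, y)[0, 1])
    return r, len(shared)


def normalized_counts(dataset: CountDataset, norm: NormalizationModel) -> pd.DataFrame:
    """Counts divided by per-sample size factors."""
    s = norm.size_factors.loc[dataset.counts.columns]
    return dataset.counts / s


def log_normalized(dataset: CountDataset, norm: NormalizationModel) -> pd.DataFrame:
    """log2(normalized counts + 1), the default expression transform."""
    return np.log2(normalized_counts(dataset, norm) + 1.0)
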