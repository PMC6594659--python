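"""Core dosage-compensation inference.

Four canonical contrasts over the allelic series, a per-gene rescue
classification from their joint significance pattern, the dose-ratio
regression (log2 fold change in the het-C double mutant against the
double knockout, expected slope 1:2 under linear dosage response), the
compensation index (upregulation of the intact paralogue transcript in
locus-A knockouts), and per-gene genotype profiles.

Contrast directions: group A is always the reference, so a negative
log2FC means lower expression in the mutant condition.

- L1: double knockout (0,0) vs wild type
- L2: (0,1) vs wild type
- L3: (0,0) vs (0,2)
- L4: (0,0) vs (0,1)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from paracomp.denorm import (
    ContrastSpec,
    DEResult,
    NormalizationModel,
    bh_adjust,
    fit_normalization,
    nb_wald_test,
    normalized_counts,
)
from paracomp.simdata import DOUBLE_KO, GENOTYPES, WILD_TYPE, CountDataset, Genotype

CANONICAL_CONTRASTS: tuple[ContrastSpec, ...] = (
    ContrastSpec.of("L1_dko_vs_wt", [WILD_TYPE], [DOUBLE_KO]),
    ContrastSpec.of("L2_hetC_vs_wt", [WILD_TYPE], [(0, 1)]),
    ContrastSpec.of("L3_dko_vs_homC", [(0, 2)], [DOUBLE_KO]),
    ContrastSpec.of("L4_dko_vs_hetC", [(0, 1)], [DOUBLE_KO]),
)

#: Named significance patterns over (L1, L2, L3, L4).  The four named
#: patterns correspond to the qualitative rescue behaviours the allelic
#: series distinguishes; all other non-zero patterns get a canonical
#: ``pattern_bXXXX`` label.
PATTERN_LABELS: dict[tuple[int, int, int, int], str] = {
    (1, 0, 1, 1): "full_rescue",
    (1, 1, 1, 1): "partial_rescue",
    (1, 1, 1, 0): "two_allele_rescue",
    (1, 0, 0, 0): "dko_only_mild",
}


@dataclass
class RescueTable:
    """Per-gene significance bits and rescue class for the four contrasts.

    ``table`` columns: b1..b4 (0/1), lfc_L1..lfc_L4, rescue_class; one
    row per gene significant in at least one contrast.
    """

    table: pd.DataFrame
    q_threshold: float
    results: dict[str, DEResult]

    def genes_in_class(self, label: str) -> list[str]:
        return list(self.table.index[self.table["rescue_class"] == label])


def rescue_classify(bits: Sequence[int]) -> str:
    """Map a 4-bit significance pattern over (L1..L4) to a class label.

    Full rescue (significant in L1, L3, L4 but not L2) means one
    functional allele of the compensating paralogue restores wild-type
    expression; partial rescue (all four significant) means expression
    moves toward but never reaches wild type; two-allele rescue
    (L1, L2, L3) means only the full paralogue dose rescues; a mild
    double-knockout-only change is significant in L1 alone.  Unnamed
    patterns are returned as ``pattern_b<bits>``.
    """
    bits = tuple(int(b) for b in bits)
    if len(bits) != 4 or any(b not in (0, 1) for b in bits):
        raise ValueError(f"need four 0/1 bits, got {bits!r}")
    if bits == (0, 0, 0, 0):
        raise ValueError("all-zero pattern: gene is not significant anywhere")
    if bits in PATTERN_LABELS:
        return PATTERN_LABELS[bits]
    return "pattern_b" + "".join(map(str, bits))


def build_rescue_table(
    dataset: CountDataset,
    stage: Optional[str] = None,
    q_threshold: float = 0.05,
    norm: Optional[NormalizationModel] = None,
) -> RescueTable:
    """Run the four canonical contrasts and classify every DE gene."""
    for contrast in CANONICAL_CONTRASTS:
        for g in contrast.group_a | contrast.group_b:
            if not dataset.samples_for(g, stage):
                raise ValueError(
                    f"missing genotype {g} required by contrast {contrast.name!r}"
                )
    if norm is None:
        norm = fit_normalization(dataset, stage=stage)
    results: dict[str, DEResult] = {}
    for contrast in CANONICAL_CONTRASTS:
        spec = ContrastSpec(contrast.name, contrast.group_a, contrast.group_b, stage)
        results[contrast.name] = nb_wald_test(dataset, norm, spec)

    names = [c.name for c in CANONICAL_CONTRASTS]
    sig = {n: results[n].significant(q_threshold) for n in names}
    union = sorted(set().union(*sig.values()))
    rows = []
    for gene in union:
        bits = tuple(int(gene in sig[n]) for n in names)
        lfcs = [float(results[n].table.loc[gene, "log2FC"]) for n in names]
        rows.append((gene, *bits, *lfcs, rescue_classify(bits)))
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "b1",
            "b2",
            "b3",
            "b4",
            "lfc_L1",
            "lfc_L2",
            "lfc_L3",
            "lfc_L4",
            "rescue_class",
        ],
    ).set_index("gene_id")
    return RescueTable(table=table, q_threshold=q_threshold, results=results)


@dataclass
class DoseSlope:
    slope: float
    ci_low: float
    ci_high: float
    n_genes: int


def _debias_selected(
    lfc: np.ndarray, se: np.ndarray, z_threshold: float
) -> np.ndarray:
    """Winner's-curse correction for significance-selected estimates.

    Each log2FC was observed conditional on |lfc/se| exceeding the
    selection threshold, which biases the naive estimate away from
    zero.  The conditional MLE under the two-sided truncated-normal
    likelihood overcorrects for borderline genes, so the returned value
    is the average of the naive and conditional estimates (the
    compromise estimator of the selection-bias literature).
    """
    from scipy import optimize

    out = np.empty_like(lfc)
    for i, (yi, sei) in enumerate(zip(lfc, se)):
        z = yi / sei
        bound = abs(z) + 5.0

        def nll(mu: float) -> float:
            sel = stats.norm.sf(z_threshold - mu) + stats.norm.cdf(-z_threshold - mu)
            return -(stats.norm.logpdf(z - mu) - np.log(max(sel, 1e-300)))

        res = optimize.minimize_scalar(nll, bounds=(-bound, bound), method="bounded")
        out[i] = res.x * sei
    return 0.5 * (out + lfc)


def dose_slope(
    rescue: RescueTable,
    include: str = "L2-significant",
    through_origin: bool = True,
    debias: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
) -> DoseSlope:
    """Regression of the het-C double-mutant log2FC on the DKO log2FC.

    Under a linear dosage response the het-C condition loses half the
    paralogue dose, so the expected slope is 0.5 (the 1:2 ratio).  The
    fit is least squares through the origin over genes significant in
    L2 by default (``include='union'`` uses all genes in the rescue
    table); the confidence interval is a seeded percentile bootstrap
    over genes.

    Because the default inclusion rule selects genes on the
    significance of the very estimate being regressed, the naive fit
    inherits a winner's-curse bias; with ``debias=True`` the selected
    L2 estimates are first shrunk by a truncated-normal conditional
    likelihood at the realised significance threshold (no-op for
    ``include='union'``, where the response is not the selection
    variable).
    """
    t = rescue.table
    if include == "L2-significant":
        t = t[t["b2"] == 1]
    elif include != "union":
        raise ValueError(f"unknown inclusion rule {include!r}")
    x = t["lfc_L1"].to_numpy(dtype=float)
    y = t["lfc_L2"].to_numpy(dtype=float)
    if debias and include == "L2-significant" and len(t):
        l2 = rescue.results["L2_hetC_vs_wt"].table
        sig_p = l2["pvalue"][(l2["tested"]) & (l2["padj"] < rescue.q_threshold)]
        if len(sig_p):
            z_threshold = float(stats.norm.isf(sig_p.max() / 2.0))
            se = l2.loc[t.index, "se"].to_numpy(dtype=float)
            y = _debias_selected(y, se, z_threshold)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 10:
        raise ValueError(f"only {x.size} genes available for the dose regression")

    def fit(xv: np.ndarray, yv: np.ndarray) -> float:
        if through_origin:
            return float(xv @ yv / (xv @ xv))
        xc, yc = xv - xv.mean(), yv - yv.mean()
        return float(xc @ yc / (xc @ xc))

    slope = fit(x, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = x.size
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        boots[b] = fit(x[idx], y[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return DoseSlope(slope=slope, ci_low=float(lo), ci_high=float(hi), n_genes=n)


def compensation_index(
    dataset: CountDataset,
    gene: str = "locus_c",
    background: tuple[Genotype, Genotype] = ((0, 2), WILD_TYPE),
    stage: Optional[str] = None,
    norm: Optional[NormalizationModel] = None,
) -> tuple[float, float]:
    """Fold change of one gene between two genotypes, with a Wald p.

    The default measures the compensatory upregulation of the intact
    paralogue's transcript in locus-A knockouts: normalized mean in
    genotype (0, 2) over wild type.  Returns (fold_change, p_value).
    """
    if gene not in dataset.counts.index:
        raise KeyError(f"unknown gene {gene!r}")
    condition, reference = background
    if norm is None:
        norm = fit_normalization(dataset, stage=stage)
    spec = ContrastSpec.of("compensation", [reference], [condition], stage)
    res = nb_wald_test(dataset, norm, spec)
    row = res.table.loc[gene]
    fold = float(row["mean_b"] / row["mean_a"])
    return fold, float(row["pvalue"])


@dataclass
class GeneProfile:
    gene: str
    normalized: dict[Genotype, np.ndarray]
    significant_vs_reference: dict[Genotype, bool]
    q_values: dict[Genotype, float]


def gene_profile(
    dataset: CountDataset,
    gene: str,
    reference: Genotype = WILD_TYPE,
    stage: Optional[str] = None,
    q_threshold: float = 0.05,
    norm: Optional[NormalizationModel] = None,
) -> GeneProfile:
    """Per-genotype normalized counts with significance vs a reference.

    Each non-reference genotype is Wald-tested against the reference for
    this gene; the eight p-values are BH-adjusted together and starred
    at ``q_threshold`` — the data behind a violin-plot genotype profile.
    """
    if gene not in dataset.counts.index:
        raise KeyError(f"unknown gene {gene!r}")
    if norm is None:
        norm = fit_normalization(dataset, stage=stage)
    normed = normalized_counts(dataset, norm)
    profile: dict[Genotype, np.ndarray] = {}
    for g in GENOTYPES:
        cols = dataset.samples_for(g, stage)
        profile[g] = normed.loc[gene, cols].to_numpy(dtype=float)

    others = [g for g in GENOTYPES if g != reference]
    pvals = []
    for g in others:
        spec = ContrastSpec.of(f"profile_{g}", [reference], [g], stage)
        res = nb_wald_test(dataset, norm, spec)
        pvals.append(float(res.table.loc[gene, "pvalue"]))
    qvals = bh_adjust(np.array(pvals))
    sig = {g: bool(np.isfinite(q) and q < q_threshold) for g, q in zip(others, qvals)}
    qmap = {g: float(q) for g, q in zip(others, qvals)}
    return GeneProfile(
        gene=gene, normalized=profile, significant_vs_reference=sig, q_values=qmap
    )
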