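"""Synthetic allelic-series count data with known truth.

The generator emulates a single-embryo RNA-seq experiment over the nine
genotypes of a two-locus allelic series (0, 1 or 2 functional alleles at
a mutated transcription-factor locus A and its compensating paralogue,
locus C).  Counts are negative binomial around class-specific expected
means; the generative model encodes three claims that the downstream
analyses are designed to recover:

1. mutant-allele transcripts are degraded by nonsense-mediated decay, so
   a non-functional allele contributes only a residual fraction
   ``nmd_lambda`` of its normal output;
2. when locus A is fully knocked out, the locus-C transcript is
   upregulated by a compensatory factor ``1 + comp_kappa`` (~50% with the
   default kappa of 0.5);
3. target genes respond linearly (in log2) to the remaining "tfap2 dose",
   so the log2 fold change of a heterozygous-C double mutant is exactly
   half that of the double knockout — a 1:2 ratio.

Every simulated gene belongs to one of eight classes (see
:func:`expected_mean`) and the truth — class, effect size, genomic
position and expected mean per genotype — is returned alongside the
counts so that recovery tests can score the analysis modules.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

#: Functional-allele counts (locus A, locus C).  (2, 2) is wild type,
#: (0, 0) the double knockout.
Genotype = tuple[int, int]

GENOTYPES: tuple[Genotype, ...] = tuple(
    (a, c) for a in (2, 1, 0) for c in (2, 1, 0)
)
WILD_TYPE: Genotype = (2, 2)
DOUBLE_KO: Genotype = (0, 0)

GENE_CLASSES = (
    "null",
    "dosage_linear",
    "full_rescue",
    "partial_rescue",
    "two_allele_rescue",
    "epidermal",
    "neural_up",
    "cis_block",
)

#: Special per-locus transcript classes (always simulated, never part of
#: the class mixture).
LOCUS_CLASSES = ("locus_a", "locus_c")


def _default_proportions() -> dict[str, float]:
    return {
        "null": 0.70,
        "dosage_linear": 0.08,
        "full_rescue": 0.04,
        "partial_rescue": 0.04,
        "two_allele_rescue": 0.04,
        "epidermal": 0.04,
        "neural_up": 0.03,
        "cis_block": 0.03,
    }


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic allelic-series experiment.

    Attributes
    ----------
    n_genes:
        Number of mixture genes; the two locus transcripts are added on
        top, so the dataset has ``n_genes + 2`` rows.
    n_per_genotype:
        Single-embryo replicates per genotype (the study design used up
        to 10).
    baseline_log_mean_mu, baseline_log_mean_sd:
        Natural-log location/scale of the per-gene baseline means.
    dispersion_alpha:
        NB dispersion: variance = mu + alpha * mu**2.
    nmd_lambda:
        Residual transcript output of a non-functional allele after
        nonsense-mediated decay (0 = complete decay, 1 = none).
    comp_kappa:
        Compensatory upregulation of the locus-C transcript in locus-A
        knockouts; the locus-C mean is multiplied by ``1 + comp_kappa``.
    class_proportions:
        Mixture over the eight gene classes; must sum to 1.
    beta_sd:
        Scale of the per-gene log2 effect sizes (half-normal draw).
    beta_fixed:
        If set, every non-null gene gets |beta| = beta_fixed (random
        sign); used by recovery tests that plant a known effect size.
    depth_sd:
        Log-normal sd of per-sample depth factors (0 disables).
    cis_block_chrom, cis_block_size:
        Chromosome carrying locus A and the genomic span (bp) of the
        linked haplotype block.
    recombinant_sample:
        If True, one locus-A-homozygous embryo carries a recombined
        (wild-type) haplotype across the cis block.
    n_chromosomes:
        Size of the karyotype over which genes are scattered (25 for
        zebrafish).
    stage:
        Stage label attached to every sample.
    seed:
        Seed for the single NumPy generator driving the simulation.
    """

    n_genes: int = 2000
    n_per_genotype: int = 10
    baseline_log_mean_mu: float = 5.5
    baseline_log_mean_sd: float = 1.0
    dispersion_alpha: float = 0.05
    nmd_lambda: float = 0.3
    comp_kappa: float = 0.5
    class_proportions: dict[str, float] = field(default_factory=_default_proportions)
    beta_sd: float = 1.5
    beta_fixed: Optional[float] = None
    depth_sd: float = 0.2
    cis_block_chrom: str = "24"
    cis_block_size: int = 10_000_000
    recombinant_sample: bool = False
    n_chromosomes: int = 25
    stage: str = "15s"
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class_proportions must sum to 1, got {total}")
        unknown = set(self.class_proportions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        if self.dispersion_alpha < 0:
            raise ValueError("dispersion_alpha must be >= 0")
        if not 0.0 <= self.nmd_lambda <= 1.0:
            raise ValueError("nmd_lambda must lie in [0, 1]")

    def replace(self, **kwargs) -> "SimParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment.

    ``table`` has one row per gene: gene_id, gene_class, beta (log2
    effect), chrom, start, baseline, and an ``mean_<a>_<c>`` column with
    the expected (depth-1) mean for each of the nine genotypes.
    """

    table: pd.DataFrame
    params: SimParams

    def genes_of_class(self, gene_class: str) -> list[str]:
        sub = self.table[self.table["gene_class"] == gene_class]
        return list(sub["gene_id"])

    def expected_mean(self, gene_id: str, genotype: Genotype) -> float:
        row = self.table.set_index("gene_id").loc[gene_id]
        return float(row[f"mean_{genotype[0]}_{genotype[1]}"])


@dataclass
class CountDataset:
    """Gene x sample integer counts plus sample and gene metadata.

    ``counts``: DataFrame indexed by gene_id with sample-id columns.
    ``samples``: DataFrame with sample_id, genotype_a, genotype_c, stage.
    ``genes``: DataFrame with gene_id, chrom, start, end, name
    (1-based inclusive coordinates).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples["sample_id"]):
            raise ValueError("count columns do not match sample metadata")
        if list(self.counts.index) != list(self.genes["gene_id"]):
            raise ValueError("count rows do not match gene annotation")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)

    @property
    def genotypes(self) -> list[Genotype]:
        return [
            (int(a), int(c))
            for a, c in zip(self.samples["genotype_a"], self.samples["genotype_c"])
        ]

    def samples_for(self, genotype: Genotype, stage: Optional[str] = None) -> list[str]:
        sel = (self.samples["genotype_a"] == genotype[0]) & (
            self.samples["genotype_c"] == genotype[1]
        )
        if stage is not None:
            sel &= self.samples["stage"] == stage
        return list(self.samples.loc[sel, "sample_id"])


def genotype_activity(genotype: Genotype, params: SimParams) -> float:
    """Total regulatory activity of the two paralogues, wild type = 1.

    Each locus contributes half of the wild-type activity in proportion
    to its functional alleles; the locus-C contribution is boosted by
    ``1 + comp_kappa`` when locus A is fully knocked out (the
    compensation trigger).
    """
    a, c = genotype
    if a not in (0, 1, 2) or c not in (0, 1, 2):
        raise ValueError(f"invalid genotype {genotype!r}")
    boost = 1.0 + params.comp_kappa if a == 0 else 1.0
    return 0.5 * (a / 2.0) + 0.5 * (c / 2.0) * boost


def _lost_dose(genotype: Genotype) -> float:
    """Fraction of the combined tfap2 dose lost, by total allele count.

    Defined so the heterozygous-C double mutant (0, 1) has exactly half
    the lost dose of the double knockout — the generative source of the
    1:2 fold-change ratio.
    """
    a, c = genotype
    return max(0.0, 1.0 - (a + c) / 2.0)


def expected_mean(
    gene_class: str,
    baseline: float,
    beta: float,
    genotype: Genotype,
    params: SimParams,
) -> float:
    """Expected (depth-1) mean of a gene in one genotype.

    Classes
    -------
    null
        Baseline in every genotype.
    dosage_linear
        ``baseline * 2**(beta * d)`` with d the lost-dose fraction
        (d = 1 for the double knockout, 1/2 for (0, 1)).
    full_rescue
        Shifted by 2**beta only when activity is zero (double knockout);
        a single functional C allele restores baseline.
    partial_rescue
        ``baseline * 2**(beta * (1 - activity))`` — graded, never fully
        restored while activity < 1.
    two_allele_rescue
        Shifted whenever locus A is knocked out and locus C has fewer
        than two functional alleles; only the full C dose rescues.
    epidermal / neural_up
        Down- (epidermal) or up-regulated (neural_up) by |beta| in the
        zero-activity genotype only.
    cis_block
        Baseline here; the haplotype factor is applied per sample in
        :func:`simulate_experiment`.
    locus_a / locus_c
        The locus transcripts themselves: functional alleles emit fully,
        non-functional alleles emit the NMD residual ``nmd_lambda``;
        locus C additionally carries the compensation boost.
    """
    a, c = genotype
    act = genotype_activity(genotype, params)
    if gene_class in ("null", "cis_block"):
        return baseline
    if gene_class == "dosage_linear":
        return baseline * 2.0 ** (beta * _lost_dose(genotype))
    if gene_class == "full_rescue":
        return baseline * 2.0**beta if act == 0.0 else baseline
    if gene_class == "partial_rescue":
        return baseline * 2.0 ** (beta * (1.0 - act))
    if gene_class == "two_allele_rescue":
        return baseline * 2.0**beta if (a == 0 and c < 2) else baseline
    if gene_class == "epidermal":
        return baseline * 2.0 ** (-abs(beta)) if act == 0.0 else baseline
    if gene_class == "neural_up":
        return baseline * 2.0 ** (abs(beta)) if act == 0.0 else baseline
    if gene_class == "locus_a":
        return baseline * (a + params.nmd_lambda * (2 - a)) / 2.0
    if gene_class == "locus_c":
        boost = 1.0 + params.comp_kappa if a == 0 else 1.0
        return baseline * (c + params.nmd_lambda * (2 - c)) / 2.0 * boost
    raise ValueError(f"unknown gene class {gene_class!r}")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, variance = mean + alpha*mean^2); Poisson when alpha = 0."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0.0:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_experiment(params: SimParams) -> tuple[CountDataset, SimTruth]:
    """Simulate one allelic-series experiment and its truth table.

    Returns a :class:`CountDataset` of ``n_genes + 2`` genes (the two
    locus transcripts first) over ``9 * n_per_genotype`` single-embryo
    samples, and the matching :class:`SimTruth`.  Fully reproducible
    from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_genes

    classes = list(params.class_proportions)
    probs = np.array([params.class_proportions[c] for c in classes])
    gene_class = list(rng.choice(classes, size=n, p=probs))
    gene_class = ["locus_a", "locus_c"] + gene_class

    n_total = n + 2
    baseline = np.exp(
        rng.normal(params.baseline_log_mean_mu, params.baseline_log_mean_sd, n_total)
    )

    if params.beta_fixed is not None:
        mag = np.full(n_total, float(params.beta_fixed))
    else:
        mag = np.abs(rng.normal(0.0, params.beta_sd, n_total))
    sign = rng.choice([-1.0, 1.0], size=n_total)
    beta = mag * sign
    beta[np.array(gene_class) == "null"] = 0.0

    # Genomic placement: cis-block genes in one window around locus A;
    # everything else scattered uniformly over the karyotype.
    locus_a_pos = 20_000_000
    chroms = np.array(
        [str(k) for k in rng.integers(1, params.n_chromosomes + 1, n_total)],
        dtype=object,
    )
    starts = rng.integers(1, 60_000_000, n_total)
    cls_arr = np.array(gene_class, dtype=object)
    is_cis = cls_arr == "cis_block"
    chroms[is_cis] = params.cis_block_chrom
    starts[is_cis] = rng.integers(
        max(1, locus_a_pos - params.cis_block_size // 2),
        locus_a_pos + params.cis_block_size // 2,
        int(is_cis.sum()),
    )
    chroms[0] = params.cis_block_chrom  # locus A sits inside its own block
    starts[0] = locus_a_pos
    gene_ids = ["locus_a", "locus_c"] + [f"g{i:05d}" for i in range(n)]
    names = ["tfap2a", "tfap2c"] + [f"gene{i:05d}" for i in range(n)]

    samples = []
    for g in GENOTYPES:
        for r in range(params.n_per_genotype):
            samples.append(
                {
                    "sample_id": f"s_a{g[0]}c{g[1]}_r{r:02d}",
                    "genotype_a": g[0],
                    "genotype_c": g[1],
                    "stage": params.stage,
                }
            )
    sample_df = pd.DataFrame(samples)
    n_samples = len(sample_df)

    depth = (
        np.exp(rng.normal(0.0, params.depth_sd, n_samples))
        if params.depth_sd > 0
        else np.ones(n_samples)
    )

    # Expected mean per gene per genotype (depth 1).
    mean_by_geno = np.empty((n_total, len(GENOTYPES)))
    for j, g in enumerate(GENOTYPES):
        for i in range(n_total):
            mean_by_geno[i, j] = expected_mean(
                gene_class[i], baseline[i], beta[i], g, params
            )

    geno_index = {g: j for j, g in enumerate(GENOTYPES)}
    sample_geno = [
        geno_index[(int(a), int(c))]
        for a, c in zip(sample_df["genotype_a"], sample_df["genotype_c"])
    ]
    mu = mean_by_geno[:, sample_geno] * depth[None, :]

    # Cis-haplotype block: apparent expression tracks the inherited
    # chromosome segment around locus A, i.e. the locus-A genotype.
    if is_cis.any():
        hap_dose = sample_df["genotype_a"].to_numpy() / 2.0  # 1 wt, .5 het, 0 hom
        if params.recombinant_sample:
            hom = np.flatnonzero(sample_df["genotype_a"] == 0)
            if hom.size:
                hap_dose = hap_dose.copy()
                hap_dose[hom[0]] = 1.0  # one embryo recombined back to wt haplotype
        factor = 2.0 ** (beta[is_cis, None] * (1.0 - hap_dose[None, :]))
        mu[is_cis, :] = mu[is_cis, :] * factor

    counts = _nb_draw(rng, mu, params.dispersion_alpha)

    gene_df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": chroms,
            "start": starts,
            "end": starts + 999,
            "name": names,
        }
    )
    counts_df = pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_df["sample_id"]
    )

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "gene_class": gene_class,
            "beta": beta,
            "chrom": chroms,
            "start": starts,
            "baseline": baseline,
        }
    )
    for j, g in enumerate(GENOTYPES):
        truth[f"mean_{g[0]}_{g[1]}"] = mean_by_geno[:, j]

    dataset = CountDataset(counts=counts_df, samples=sample_df, genes=gene_df)
    return dataset, SimTruth(table=truth, params=params)


def make_toy_ontology(
    n_terms: int,
    depth: int = 2,
    n_genes: int = 20,
    seed: int = 0,
    flat: bool = False,
    annotations_per_gene: int = 2,
) -> tuple["nx.DiGraph", dict[str, set[str]]]:
    """Random rooted is_a DAG plus direct gene annotations.

    With ``flat=True`` every non-root term is a child of the root, which
    makes the parent-child-union enrichment statistic coincide with the
    plain hypergeometric test (an oracle-equivalence fixture).  Edges
    point child -> parent.
    """
    if n_terms < 2:
        raise ValueError("need at least a root and one term")
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    terms = [f"T:{i:04d}" for i in range(n_terms)]
    root = terms[0]
    for t in terms:
        g.add_node(t, name=f"term {t}")
    levels: dict[str, int] = {root: 0}
    for i, t in enumerate(terms[1:], start=1):
        if flat:
            parents = [root]
        else:
            # attach below an existing shallower term; allow a second
            # parent occasionally to exercise the DAG (not tree) case
            candidates = [u for u in terms[:i] if levels[u] < depth]
            if not candidates:
                candidates = [root]
            parents = [candidates[rng.integers(len(candidates))]]
            if len(candidates) > 1 and rng.random() < 0.2:
                other = candidates[rng.integers(len(candidates))]
                if other not in parents:
                    parents.append(other)
        for p in parents:
            g.add_edge(t, p)
        levels[t] = min(levels[p] for p in parents) + 1
    g.graph["root"] = root

    genes = [f"gene{i:03d}" for i in range(n_genes)]
    non_root = terms[1:]
    annot: dict[str, set[str]] = {}
    for gene in genes:
        k = min(annotations_per_gene, len(non_root))
        chosen = rng.choice(non_root, size=k, replace=False)
        annot[gene] = set(str(t) for t in chosen)
    return g, annot
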