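"""Correlation network, Markov clustering and haplotype diagnostics.

Simulates a dataset with a planted cis-haplotype block, clusters the
r >= 0.7 co-expression graph with MCL, and shows how the chromosome
test and colocation score expose the haplotype artifact.
"""

from paracomp import (
    CANONICAL_CONTRASTS,
    SimParams,
    chromosome_enrichment,
    colocation_score,
    correlation_graph,
    mcl,
    nb_wald_test,
    simulate_experiment,
)
from paracomp.denorm import fit_normalization, log_normalized

proportions = {
    "null": 0.80, "dosage_linear": 0.08, "cis_block": 0.12,
    "full_rescue": 0.0, "partial_rescue": 0.0, "two_allele_rescue": 0.0,
    "epidermal": 0.0, "neural_up": 0.0,
}
dataset, truth = simulate_experiment(
    SimParams(n_genes=600, seed=6, beta_fixed=2.0, class_proportions=proportions)
)
norm = fit_normalization(dataset)
expr = log_normalized(dataset, norm)

graph = correlation_graph(expr, r_min=0.7, min_mean=1.0, min_var=0.05)
clusters = mcl(graph, inflation=2.2, min_cluster=3)
print(f"{len(clusters.clusters)} clusters from {graph.number_of_nodes()} genes")

de = nb_wald_test(dataset, norm, CANONICAL_CONTRASTS[0])
chrom = chromosome_enrichment(sorted(de.significant(0.05)), dataset.genes,
                              list(dataset.counts.index))
flagged = chrom[chrom["flagged"]]
print("\nchromosome enrichment of the DKO-vs-WT list:")
print(flagged[["chrom_genes", "de_genes", "padj"]].to_string())

for label, genes in list(clusters.clusters.items())[:3]:
    modal, within = colocation_score(genes, dataset.genes)
    print(f"cluster {label}: {len(genes)} genes, modal-chromosome fraction {modal:.2f}")
print(
    "\nA cluster whose genes all sit on the flagged chromosome is a\n"
    "cis-haplotype block - linkage, not regulation, drives its signal."
)
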