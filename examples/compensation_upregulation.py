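"""Measure the compensatory upregulation of the intact paralogue.

Under the generative model the locus-C transcript rises by the factor
1 + kappa (default 1.5x) in locus-A knockouts; compensation_index
estimates this from normalized counts with a Wald p-value.
"""

from paracomp import SimParams, compensation_index, simulate_experiment

dataset, _ = simulate_experiment(SimParams(n_genes=300, seed=4, comp_kappa=0.5))
fold, p = compensation_index(dataset)  # genotype (0,2) vs wild type, locus_c
print(f"locus-C fold change in locus-A knockouts: {fold:.2f} (Wald p = {p:.2e})")
print(f"percent increase: {(fold - 1) * 100:.1f}%")
print(
    "A value near +50% reproduces the compensatory upregulation the allelic\n"
    "series is designed to expose; with kappa = 0 the fold change sits at 1."
)
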