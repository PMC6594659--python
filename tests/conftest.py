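import numpy as np
import pandas as pd
import pytest

from paracomp.denorm import fit_normalization
from paracomp.simdata import CountDataset, SimParams, simulate_experiment


def class_props(**overrides) -> dict[str, float]:
    """All-null proportions with selected classes overridden."""
    props = {
        "null": 1.0,
        "dosage_linear": 0.0,
        "full_rescue": 0.0,
        "partial_rescue": 0.0,
        "two_allele_rescue": 0.0,
        "epidermal": 0.0,
        "neural_up": 0.0,
        "cis_block": 0.0,
    }
    props.update(overrides)
    props["null"] = 1.0 - sum(v for k, v in props.items() if k != "null")
    return props


def redraw_counts(dataset: CountDataset, truth, seed: int) -> CountDataset:
    """New NB counts from the same truth table (an independent replicate)."""
    params = truth.params
    rng = np.random.default_rng(seed)
    # build the gene x sample mean matrix from the truth table
    cols = []
    for a, c in zip(dataset.samples["genotype_a"], dataset.samples["genotype_c"]):
        cols.append(truth.table[f"mean_{a}_{c}"].to_numpy())
    mu = np.column_stack(cols)
    alpha = params.dispersion_alpha
    if alpha == 0:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / alpha
        counts = rng.negative_binomial(size, size / (size + mu))
    counts_df = pd.DataFrame(
        counts, index=dataset.counts.index, columns=dataset.counts.columns
    )
    return CountDataset(counts=counts_df, samples=dataset.samples.copy(), genes=dataset.genes.copy())


@pytest.fixture(scope="session")
def small_sim():
    """Default-mixture simulation, 300 genes, 9 x 10 embryos."""
    params = SimParams(n_genes=300, seed=1)
    dataset, truth = simulate_experiment(params)
    return dataset, truth, params


@pytest.fixture(scope="session")
def small_norm(small_sim):
    dataset, _, _ = small_sim
    return fit_normalization(dataset)


@pytest.fixture(scope="session")
def planted_sim():
    """Strong planted effects (|beta| = 2) across all rescue classes."""
    params = SimParams(
        n_genes=800,
        seed=2,
        beta_fixed=2.0,
        class_proportions=class_props(
            dosage_linear=0.08,
            full_rescue=0.08,
            partial_rescue=0.08,
            two_allele_rescue=0.08,
            epidermal=0.04,
            neural_up=0.04,
            cis_block=0.05,
        ),
    )
    dataset, truth = simulate_experiment(params)
    return dataset, truth, params
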