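"""Reading and writing the pipeline's plain-text formats.

Counts travel as a gene x sample TSV (header row = sample ids, first
column = gene_id) or as a MatrixMarket triplet with ``.rows`` /
``.cols`` index files; sample metadata, gene annotation, DE results and
truth tables are TSVs.  Gene coordinates are 1-based inclusive.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from paracomp.simdata import CountDataset

GENOTYPE_ALIASES = {"+/+": 2, "+/-": 1, "-/+": 1, "-/-": 0}


def _parse_genotype(value) -> int:
    if isinstance(value, str) and value in GENOTYPE_ALIASES:
        return GENOTYPE_ALIASES[value]
    iv = int(value)
    if iv not in (0, 1, 2):
        raise ValueError(f"functional-allele count must be 0, 1 or 2, got {value!r}")
    return iv


def read_counts_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated gene ids: {dupes[:5]}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("non-numeric entries in count matrix")
    if not np.allclose(values, np.round(values)):
        raise ValueError("count matrix contains non-integer entries")
    df.index.name = "gene_id"
    return df.astype(np.int64)


def write_counts_tsv(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_mtx(path: str) -> pd.DataFrame:
    """MatrixMarket counts with ``<path>.rows`` and ``<path>.cols`` ids."""
    mat = spio.mmread(path)
    rows = pd.read_csv(path + ".rows", header=None)[0].astype(str).tolist()
    cols = pd.read_csv(path + ".cols", header=None)[0].astype(str).tolist()
    dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    if dense.shape != (len(rows), len(cols)):
        raise ValueError(
            f"matrix shape {dense.shape} does not match index files "
            f"({len(rows)} rows, {len(cols)} cols)"
        )
    if not np.allclose(dense, np.round(dense)):
        raise ValueError("count matrix contains non-integer entries")
    df = pd.DataFrame(dense.astype(np.int64), index=rows, columns=cols)
    df.index.name = "gene_id"
    return df


def write_counts_mtx(counts: pd.DataFrame, path: str) -> None:
    spio.mmwrite(path, sparse.csr_matrix(counts.to_numpy()))
    if not path.endswith(".mtx"):
        path = path + ".mtx"
    pd.Series(counts.index).to_csv(path + ".rows", index=False, header=False)
    pd.Series(counts.columns).to_csv(path + ".cols", index=False, header=False)


def read_samples_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "genotype_a", "genotype_c", "stage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    df["genotype_a"] = df["genotype_a"].map(_parse_genotype)
    df["genotype_c"] = df["genotype_c"].map(_parse_genotype)
    return df


def read_genes_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "start", "end", "name"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
    return df


def read_dataset(
    counts_path: str, samples_path: str, genes_path: str
) -> CountDataset:
    """Assemble a CountDataset from TSV/MTX files, aligning orders."""
    if counts_path.endswith(".mtx"):
        counts = read_counts_mtx(counts_path)
    else:
        counts = read_counts_tsv(counts_path)
    samples = read_samples_tsv(samples_path)
    genes = read_genes_tsv(genes_path)
    counts = counts.loc[genes["gene_id"], samples["sample_id"]]
    return CountDataset(counts=counts, samples=samples, genes=genes)


def write_dataset(dataset: CountDataset, outdir: str, fmt: str = "tsv") -> dict[str, str]:
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "samples": os.path.join(outdir, "samples.tsv"),
        "genes": os.path.join(outdir, "genes.tsv"),
    }
    dataset.samples.to_csv(paths["samples"], sep="\t", index=False)
    dataset.genes.to_csv(paths["genes"], sep="\t", index=False)
    if fmt == "tsv":
        paths["counts"] = os.path.join(outdir, "counts.tsv")
        write_counts_tsv(dataset.counts, paths["counts"])
    elif fmt == "mtx":
        paths["counts"] = os.path.join(outdir, "counts.mtx")
        write_counts_mtx(dataset.counts, paths["counts"])
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return paths


def read_gene_list(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def write_gene_list(genes, path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_de_table(result, path: str) -> None:
    result.table.to_csv(path, sep="\t", index_label="gene_id")
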