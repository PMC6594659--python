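"""Co-expression networks, Markov clustering and genomic diagnostics.

Genes are connected when their expression profiles across samples have
Pearson correlation at or above a threshold (0.7 by default, positive
correlations only); the resulting weighted graph is partitioned with
the Markov Cluster algorithm (alternating random-walk expansion and
entrywise inflation of a column-stochastic matrix).  Cluster expression
summaries, hierarchical gene clustering, and two haplotype-artifact
diagnostics — per-chromosome enrichment of a DE list and a cluster
colocation score — complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from paracomp.denorm import bh_adjust
from paracomp.simdata import CountDataset


def correlation_graph(
    log_expr: pd.DataFrame,
    r_min: float = 0.7,
    min_mean: float = 0.0,
    min_var: float = 1e-12,
) -> nx.Graph:
    """Positive Pearson correlation graph over genes.

    ``log_expr`` is gene x sample on a log scale (the pipeline uses
    log2(normalized counts + 1)).  Genes failing the mean or variance
    floors (constant rows in particular) are excluded; edges connect
    pairs with r >= r_min.  Node set = retained genes; edge weight = r.
    """
    if log_expr.shape[1] < 3:
        raise ValueError("need at least three samples")
    x = log_expr.to_numpy(dtype=float)
    mean = x.mean(axis=1)
    var = x.var(axis=1)
    keep = (mean >= min_mean) & (var > min_var)
    genes = list(log_expr.index[keep])
    g = nx.Graph(r_min=r_min)
    g.add_nodes_from(genes)
    if len(genes) < 2:
        return g
    r = np.corrcoef(x[keep])
    iu, ju = np.triu_indices(len(genes), k=1)
    hits = r[iu, ju] >= r_min
    for i, j, w in zip(iu[hits], ju[hits], r[iu, ju][hits]):
        g.add_edge(genes[i], genes[j], weight=float(w))
    return g


@dataclass
class ClusterSet:
    """Disjoint gene clusters labelled 1..k in decreasing size order."""

    clusters: dict[int, list[str]]
    small: list[list[str]] = field(default_factory=list)  # below min_cluster
    converged: bool = True

    def labels(self) -> pd.Series:
        rows = {}
        for label, genes in self.clusters.items():
            for gene in genes:
                rows[gene] = label
        return pd.Series(rows, name="cluster")


def mcl(
    graph: nx.Graph,
    inflation: float = 2.2,
    expansion: int = 2,
    self_loops: bool = True,
    prune: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-6,
    min_cluster: int = 3,
) -> ClusterSet:
    """Markov clustering of a weighted undirected graph.

    The adjacency matrix (self-loop weight = maximum incident edge
    weight) is column-normalized and iterated: expansion (matrix power)
    followed by inflation (entrywise power and renormalization), with
    entries below ``prune`` zeroed, until the matrix changes by less
    than ``tol`` or ``max_iter`` is reached.  Clusters are the
    connected components of the non-zero structure of the attractor
    matrix; clusters smaller than ``min_cluster`` are reported
    separately.
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("empty graph")
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        a[index[u], index[v]] = w
        a[index[v], index[u]] = w
    if self_loops:
        loop = a.max(axis=0)
        loop[loop == 0] = 1.0  # isolated nodes keep a unit loop
        np.fill_diagonal(a, loop)

    m = a / a.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        m_new = np.linalg.matrix_power(m, expansion)
        m_new = m_new**inflation
        m_new[m_new < prune] = 0.0
        colsum = m_new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m_new = m_new / colsum
        delta = np.abs(m_new - m).max()
        m = m_new
        if delta < tol:
            converged = True
            break

    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m)
    for i, j in zip(rows, cols):
        if i != j:
            support.add_edge(i, j)
    components = [sorted(nodes[i] for i in comp) for comp in nx.connected_components(support)]
    components.sort(key=lambda c: (-len(c), c[0]))
    clusters = {}
    small = []
    label = 0
    for comp in components:
        if len(comp) >= min_cluster:
            label += 1
            clusters[label] = comp
        else:
            small.append(comp)
    return ClusterSet(clusters=clusters, small=small, converged=converged)


def cluster_profiles(
    clusters: ClusterSet,
    log_expr: pd.DataFrame,
    sample_order: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cluster per-sample summaries of gene z-scores.

    Each gene is mean-centred and variance-scaled across samples; the
    returned long-format frame has one row per (cluster, sample) with
    the median and quartiles of the member-gene z-scores — the data
    behind per-cluster genotype-ordered boxplots.
    """
    if sample_order is None:
        sample_order = list(log_expr.columns)
    x = log_expr[sample_order].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    zdf = pd.DataFrame(z, index=log_expr.index, columns=sample_order)
    rows = []
    for label, genes in clusters.clusters.items():
        sub = zdf.loc[[g for g in genes if g in zdf.index]]
        q1, med, q3 = np.percentile(sub.to_numpy(), [25, 50, 75], axis=0)
        for s, a, b, c in zip(sample_order, q1, med, q3):
            rows.append(
                {"cluster": label, "sample_id": s, "q1": a, "median": b, "q3": c}
            )
    return pd.DataFrame(rows)


def hcluster_genes(
    z_expr: pd.DataFrame, linkage: str = "complete", metric: str = "euclidean"
) -> tuple[list[str], np.ndarray]:
    """Agglomerative clustering of genes; returns (leaf order, merge tree).

    Genes are sorted by id before linkage so ties break deterministically.
    """
    if z_expr.shape[0] < 2:
        raise ValueError("need at least two genes")
    order = sorted(z_expr.index)
    x = z_expr.loc[order].to_numpy(dtype=float)
    tree = hierarchy.linkage(pdist(x, metric=metric), method=linkage)
    leaves = hierarchy.leaves_list(tree)
    return [order[i] for i in leaves], tree


def chromosome_enrichment(
    de_genes: list[str],
    gene_annotation: pd.DataFrame,
    universe: list[str],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-chromosome hypergeometric enrichment of a DE gene list.

    A strong excess of DE genes on the mutation-bearing chromosome is
    the signature of a cis-haplotype artifact.  Genes missing from the
    annotation are dropped (and counted in ``n_unannotated`` on
    ``DataFrame.attrs``).  Returns one row per chromosome with counts,
    the upper-tail p, BH-adjusted q, and a ``flagged`` column marking
    the minimum-p chromosome when its q is below ``q_threshold``.
    """
    ann = gene_annotation.set_index("gene_id")["chrom"].astype(str)
    universe_set = [g for g in dict.fromkeys(universe) if g in ann.index]
    de_set = set(g for g in de_genes if g in ann.index)
    n_unannotated = len(set(de_genes)) - len(de_set)
    n_pop = len(universe_set)
    n_study = len(de_set & set(universe_set))
    rows = []
    chrom_of = ann.loc[universe_set]
    for chrom, members in chrom_of.groupby(chrom_of).groups.items():
        big_k = len(members)
        k = len(de_set & set(members))
        p = float(stats.hypergeom.sf(k - 1, n_pop, big_k, n_study)) if n_study else np.nan
        rows.append({"chrom": str(chrom), "chrom_genes": big_k, "de_genes": k, "pvalue": p})
    result = pd.DataFrame(rows).set_index("chrom")
    if result.empty or n_study == 0:
        result["padj"] = np.nan
        result["flagged"] = False
        result.attrs["n_unannotated"] = n_unannotated
        return result.iloc[0:0] if n_study == 0 else result
    result["padj"] = bh_adjust(result["pvalue"].to_numpy())
    result["flagged"] = False
    best = result["pvalue"].idxmin()
    if result.loc[best, "padj"] < q_threshold:
        result.loc[best, "flagged"] = True
    result.attrs["n_unannotated"] = n_unannotated
    return result


def colocation_score(
    cluster_genes: list[str],
    gene_annotation: pd.DataFrame,
    window: int = 10_000_000,
) -> tuple[float, float]:
    """How genomically concentrated a co-expression cluster is.

    Returns (modal-chromosome fraction, within-window fraction): the
    fraction of annotated cluster genes on the most common chromosome,
    and the fraction of those lying within ``window`` bp of their
    median position.  High values indicate a cis-haplotype block rather
    than a regulatory cluster.
    """
    ann = gene_annotation.set_index("gene_id")
    genes = [g for g in cluster_genes if g in ann.index]
    if len(genes) < 2:
        raise ValueError("need at least two annotated genes")
    chroms = ann.loc[genes, "chrom"].astype(str)
    modal = chroms.mode().iloc[0]
    on_modal = chroms == modal
    modal_frac = float(on_modal.mean())
    pos = ann.loc[chroms.index[on_modal], "start"].to_numpy(dtype=float)
    centre = np.median(pos)
    within = np.abs(pos - centre) <= window / 2.0
    return modal_frac, float(within.mean())
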