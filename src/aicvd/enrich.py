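"""Gene mapping and hypergeometric gene-set over-representation per cluster.

Each genetic pattern's SNPs map to their nearest genes (from the annotation
table); the overlap of that gene list with each named gene set is tested
one-sided with the hypergeometric distribution, and Benjamini-Hochberg FDR
is applied across all set x cluster tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)


def map_snps_to_genes(
    assignments: pd.Series, annotation: pd.DataFrame
) -> dict[int, list[str]]:
    """Nearest-gene list per cluster, duplicates collapsed.

    SNPs absent from the annotation are skipped (count logged); a cluster
    whose SNPs all lack annotation is excluded with a warning.
    """
    gene_of = dict(zip(annotation["rsid"], annotation["gene"]))
    out: dict[int, list[str]] = {}
    n_missing = 0
    for c in sorted(assignments.unique()):
        members = assignments.index[assignments == c]
        genes: list[str] = []
        for rsid in members:
            g = gene_of.get(rsid)
            if g is None:
                n_missing += 1
                continue
            if g not in genes:
                genes.append(g)
        if genes:
            out[int(c)] = genes
        else:
            logger.warning("cluster %s has no annotated SNPs; excluded", c)
    if n_missing:
        logger.info("%d SNPs absent from annotation; skipped", n_missing)
    return out


def hypergeom_enrich(
    cluster_genes: dict[int, list[str]],
    sets: GeneSetCollection,
    universe: list[str] | set[str],
) -> pd.DataFrame:
    """One-sided over-representation of each gene set in each cluster.

    With N = |universe|, K = |set ∩ universe|, n = |cluster genes| and
    x = overlap, p_hyper = P(X >= x) for X ~ Hypergeometric(N, K, n).
    q_fdr is Benjamini-Hochberg across all set x cluster tests.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    restricted = sets.restrict_to(universe)
    N = len(universe)
    rows = []
    for c, genes in cluster_genes.items():
        in_uni = [g for g in genes if g in universe]
        dropped = len(genes) - len(in_uni)
        if dropped:
            logger.warning("cluster %s: %d genes outside universe dropped", c, dropped)
        n = len(in_uni)
        gset = set(in_uni)
        for name, members in restricted.sets.items():
            K = len(members)
            x = len(gset & set(members))
            p = float(hypergeom.sf(x - 1, N, K, n))
            rows.append({
                "cluster": c, "gene_set": name, "K": K, "n": n, "x": x,
                "N": N, "p_hyper": min(max(p, np.finfo(float).tiny), 1.0),
            })
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(q_fdr=[])
    df["q_fdr"] = false_discovery_control(df["p_hyper"].to_numpy(), method="bh")
    return df
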