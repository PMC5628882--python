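"""Cross-phenotype meta-analysis (CPMA) pleiotropy scoring and LD pruning.

Under the global null, a SNP's association P-values across the six diseases
are Uniform(0,1), so x = -ln(p) is Exponential(rate 1).  Pleiotropy bends the
observed decay rate away from 1: an excess of small P-values gives rate < 1.
CPMA is the likelihood-ratio test of rate = 1 against the MLE rate

    lambda_hat = k / sum(x_i),
    statistic  = -2[l(1) - l(lambda_hat)] = 2*sum(x) + 2k*ln(lambda_hat) - 2k,

referred to chi-square with 1 df (two-sided in lambda; a one-sided variant
counting only excess association is available).  Significant SNPs are then
reduced to independent signals by greedy r^2 pruning of dosage correlations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io_formats import DISEASES, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class CpmaResult:
    rsid: str
    p_vector: np.ndarray
    n_nominal: int
    lambda_hat: float
    statistic: float
    p_cpma: float


def cpma_statistic(
    p_vector: np.ndarray, rsid: str = "", one_sided: bool = False,
    p_nominal: float = 0.05,
) -> CpmaResult:
    """CPMA likelihood-ratio statistic for one SNP's per-disease P-values.

    P-values must lie in (0, 1]; a value of exactly 1 is clamped to
    1 - 1e-16 with a warning (log of 1 carries no evidence either way but
    breaks the rate MLE at the boundary).
    """
    p = np.asarray(p_vector, dtype=float)
    if p.ndim != 1 or len(p) < 2:
        raise ValueError("p_vector must be 1-D with at least 2 phenotypes")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("P-values must lie in (0, 1]")
    if np.any(p == 1.0):
        warnings.warn("P-value exactly 1 clamped to 1-1e-16", stacklevel=2)
        p = np.where(p == 1.0, 1.0 - 1e-16, p)
    x = -np.log(p)
    k = len(x)
    lam = k / x.sum()
    stat = 2.0 * x.sum() + 2.0 * k * np.log(lam) - 2.0 * k
    stat = max(stat, 0.0)
    p_two = float(chi2.sf(stat, df=1))
    if one_sided:
        p_out = p_two / 2.0 if lam < 1.0 else 1.0 - p_two / 2.0
    else:
        p_out = p_two
    return CpmaResult(
        rsid=rsid,
        p_vector=p,
        n_nominal=int((p < p_nominal).sum()),
        lambda_hat=float(lam),
        statistic=float(stat),
        p_cpma=float(max(p_out, np.finfo(float).tiny)),
    )


def pvalue_matrix(assoc: pd.DataFrame, diseases: tuple[str, ...] = DISEASES) -> pd.DataFrame:
    """Pivot an association table to SNPs x diseases P-values."""
    mat = assoc.pivot_table(index="rsid", columns="disease", values="p", sort=False)
    return mat.reindex(columns=list(diseases))


def select_pleiotropic(
    assoc: pd.DataFrame,
    p_nominal: float = 0.05,
    p_cpma_max: float = 0.01,
    min_nominal: int = 1,
    one_sided: bool = False,
) -> list[CpmaResult]:
    """Score nominally associated SNPs and keep the pleiotropic ones.

    A SNP enters CPMA scoring when at least ``min_nominal`` diseases show
    P < ``p_nominal``; it is retained when P_CPMA < ``p_cpma_max``.  SNPs
    with a missing disease P-value (non-converged fit) are skipped with a
    warning count.
    """
    mat = pvalue_matrix(assoc)
    n_skipped = int(mat.isna().any(axis=1).sum())
    if n_skipped:
        logger.warning("%d SNPs skipped: missing per-disease P-values", n_skipped)
    mat = mat.dropna()
    out: list[CpmaResult] = []
    for rsid, row in mat.iterrows():
        p = row.to_numpy(dtype=float)
        if (p < p_nominal).sum() < min_nominal:
            continue
        res = cpma_statistic(p, rsid=str(rsid), one_sided=one_sided,
                             p_nominal=p_nominal)
        if res.p_cpma < p_cpma_max:
            out.append(res)
    logger.info("CPMA: %d SNPs retained at P_CPMA<%g", len(out), p_cpma_max)
    return out


def ld_prune(
    candidates: list[CpmaResult],
    g: GenotypeMatrix,
    r2_max: float = 0.2,
    window_kb: float = 1000.0,
) -> list[CpmaResult]:
    """Greedy LD pruning of pleiotropic SNPs by dosage-correlation r^2.

    Candidates are ranked by ascending P_CPMA (ties broken by genomic
    position); the best is kept and any same-chromosome SNP within the
    window whose squared Pearson dosage correlation with a kept SNP exceeds
    ``r2_max`` is dropped.
    """
    if not candidates:
        return []
    meta = g.snp_meta.set_index("rsid")

    def sort_key(c: CpmaResult):
        m = meta.loc[c.rsid]
        return (c.p_cpma, str(m["chromosome"]), int(m["position"]))

    ranked = sorted(candidates, key=sort_key)
    kept: list[CpmaResult] = []
    kept_info: list[tuple[str, int, np.ndarray]] = []
    window = window_kb * 1000.0
    for cand in ranked:
        m = meta.loc[cand.rsid]
        chrom, pos = str(m["chromosome"]), int(m["position"])
        d = g.dosage_for(cand.rsid)
        redundant = False
        for kchrom, kpos, kdos in kept_info:
            if kchrom != chrom or abs(kpos - pos) > window:
                continue
            ok = ~np.isnan(d) & ~np.isnan(kdos)
            if ok.sum() < 3:
                continue
            a, b = d[ok], kdos[ok]
            if a.std() == 0 or b.std() == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            if r * r > r2_max:
                redundant = True
                break
        if not redundant:
            kept.append(cand)
            kept_info.append((chrom, pos, d))
    logger.info("LD pruning: %d -> %d independent SNPs", len(candidates), len(kept))
    return kept


def cpma_table(results: list[CpmaResult], kept: list[CpmaResult] | None = None) -> pd.DataFrame:
    """Flatten CPMA results to the output table layout."""
    kept_ids = {c.rsid for c in (kept if kept is not None else results)}
    rows = []
    for r in results:
        row = {"rsid": r.rsid}
        for d, p in zip(DISEASES, r.p_vector):
            row[f"p_{d}"] = p
        row.update(
            n_nominal=r.n_nominal, lambda_hat=r.lambda_hat,
            statistic=r.statistic, p_cpma=r.p_cpma,
            kept_after_prune=r.rsid in kept_ids,
        )
        rows.append(row)
    return pd.DataFrame(rows)
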