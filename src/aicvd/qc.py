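"""Sample and variant quality control.

The cascade mirrors standard GWAS practice for a case-only multi-cohort
design: variant filters (MAF, missingness, imputation info score), an exact
Hardy-Weinberg test evaluated in an external healthy-control cohort, iterative
PCA-based ancestry-outlier removal, and exclusion of samples whose
cardiovascular event predates their autoimmune-disease diagnosis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse.linalg
import scipy.special

from .io_formats import GenotypeMatrix, flag_pre_diagnosis_events

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Bookkeeping of what each filter removed."""

    n_snps_in: int = 0
    n_snps_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    pca_outliers_per_iter: list[list[str]] = field(default_factory=list)

    def check(self) -> None:
        snp_removed = sum(
            v for k, v in self.removed.items() if k in ("maf", "missingness", "hwe", "info")
        )
        sample_removed = sum(
            v
            for k, v in self.removed.items()
            if k in ("pca_outliers", "pre_diagnosis_event")
        )
        if self.n_snps_in:
            assert self.n_snps_in == self.n_snps_out + snp_removed
        if self.n_samples_in:
            assert self.n_samples_in == self.n_samples_out + sample_removed
        assert all(v >= 0 for v in self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"axis": "snp", "stage": "in", "count": self.n_snps_in},
            {"axis": "snp", "stage": "out", "count": self.n_snps_out},
            {"axis": "sample", "stage": "in", "count": self.n_samples_in},
            {"axis": "sample", "stage": "out", "count": self.n_samples_out},
        ]
        for k, v in sorted(self.removed.items()):
            rows.append({"axis": "removed", "stage": k, "count": v})
        return pd.DataFrame(rows)

    def merge(self, other: "QCReport") -> None:
        for k, v in other.removed.items():
            self.removed[k] = self.removed.get(k, 0) + v
        self.pca_outliers_per_iter.extend(other.pca_outliers_per_iter)


# ---------------------------------------------------------------------------
# Variant filters
# ---------------------------------------------------------------------------


def filter_variants(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    miss_max: float = 0.05,
    info_min: float = 0.8,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove variants failing MAF, missingness or imputation-info thresholds.

    MAF is min(p, 1-p) with p the mean dosage / 2 over non-missing samples.
    The info filter applies only to variants carrying an info score (directly
    genotyped variants have none).  A variant failing several filters is
    counted once, under the first failing filter in the order MAF ->
    missingness -> info.
    """
    if g.n_snps == 0:
        raise ValueError("empty genotype matrix")
    maf = g.maf()
    miss = g.missing_rate()
    info = g.snp_meta["info_score"].to_numpy(dtype=float)

    fail_maf = maf < maf_min
    fail_miss = miss > miss_max
    fail_info = (~np.isnan(info)) & (info <= info_min)

    report = QCReport(n_snps_in=g.n_snps)
    report.removed["maf"] = int(fail_maf.sum())
    report.removed["missingness"] = int((fail_miss & ~fail_maf).sum())
    report.removed["info"] = int((fail_info & ~fail_maf & ~fail_miss).sum())

    keep = ~(fail_maf | fail_miss | fail_info)
    if not keep.any():
        raise ValueError(
            "all variants removed by QC filters; review maf_min/miss_max/info_min"
        )
    out = g.subset_snps(np.flatnonzero(keep))
    report.n_snps_out = out.n_snps
    report.check()
    logger.info(
        "variant QC: %d -> %d (maf %d, missingness %d, info %d)",
        g.n_snps,
        out.n_snps,
        report.removed["maf"],
        report.removed["missingness"],
        report.removed["info"],
    )
    return out, report


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_pvalue(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Exact conditional Hardy-Weinberg test P-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count (same parity as the minor-allele count) whose
    conditional probability does not exceed that of the observed count.
    Returns a value in (0, 1]; monomorphic tables give 1 (single possible
    configuration).
    """
    for name, v in (("n_AA", n_AA), ("n_AB", n_AB), ("n_BB", n_BB)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    n_AA, n_AB, n_BB = int(n_AA), int(n_AB), int(n_BB)
    n = n_AA + n_AB + n_BB
    if n == 0:
        raise ValueError("at least one genotype count must be positive")
    n_a = 2 * n_AA + n_AB  # copies of allele A
    n_b = 2 * n_BB + n_AB
    n_minor = min(n_a, n_b)
    if n_minor == 0:
        return 1.0

    # log-probability of each admissible heterozygote count n_ab
    # P(n_ab | n, n_minor) proportional to n! / (n_hom_min! n_ab! n_hom_maj!) * 2^n_ab
    lg = math.lgamma
    het_counts = np.arange(n_minor % 2, n_minor + 1, 2)
    logp = np.empty(len(het_counts))
    for i, h in enumerate(het_counts):
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        logp[i] = (
            h * math.log(2.0)
            - lg(hom_min + 1)
            - lg(h + 1)
            - lg(hom_maj + 1)
        )
    logp -= scipy.special.logsumexp(logp)
    probs = np.exp(logp)
    obs = min(n_AB, n_minor)  # observed heterozygote count
    idx = np.flatnonzero(het_counts == n_AB)
    if len(idx) == 0:  # parity violation cannot happen with consistent counts
        raise ValueError("inconsistent genotype counts")
    p_obs = probs[idx[0]]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def hwe_filter(
    controls: GenotypeMatrix, threshold: float = 1e-4
) -> tuple[list[str], pd.Series]:
    """rsIDs deviating from Hardy-Weinberg equilibrium in the control cohort.

    Evaluated on hard-called genotypes of the external healthy controls, as
    is conventional: HWE deviation in cases may be a true association signal,
    in controls it flags genotyping artefacts.
    """
    calls = controls.hard_calls()
    pvals = np.ones(controls.n_snps)
    for j in range(controls.n_snps):
        col = calls[:, j]
        col = col[~np.isnan(col)]
        if len(col) == 0:
            continue
        n_bb = int((col == 2).sum())
        n_ab = int((col == 1).sum())
        n_aa = int((col == 0).sum())
        pvals[j] = hwe_exact_pvalue(n_aa, n_ab, n_bb)
    series = pd.Series(pvals, index=controls.snp_meta["rsid"].values, name="p_hwe")
    failing = series.index[series < threshold].tolist()
    logger.info("HWE filter: %d/%d variants fail P<%g", len(failing), len(series), threshold)
    return failing, series


# ---------------------------------------------------------------------------
# PCA outlier removal
# ---------------------------------------------------------------------------


def _standardize_genotypes(calls: np.ndarray) -> np.ndarray:
    """Centre at 2p and scale by sqrt(2p(1-p)); missing -> 0 after centring."""
    p = np.nanmean(calls, axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    x = calls[:, keep]
    p = p[keep]
    x = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return np.nan_to_num(x, nan=0.0)


def pca_outlier_removal(
    g: GenotypeMatrix,
    n_pcs: int = 10,
    n_iter: int = 10,
    sigma: float = 6.0,
) -> tuple[list[str], pd.DataFrame, QCReport]:
    """Iterative PCA ancestry-outlier removal on hard-called genotypes.

    Each iteration standardizes every variant, takes the top ``n_pcs``
    principal components by truncated SVD, and drops any sample whose score
    on any PC lies more than ``sigma`` standard deviations from that PC's
    mean.  Stops early once an iteration removes nobody.  Returns the
    retained sample IDs, their final PC scores (the first two feed the
    association model as ancestry covariates), and a report.
    """
    if g.n_samples <= n_pcs:
        raise ValueError(f"need more than n_pcs={n_pcs} samples, have {g.n_samples}")
    calls = g.hard_calls()
    active = np.arange(g.n_samples)
    report = QCReport(n_samples_in=g.n_samples)
    scores = None
    for _ in range(max(0, n_iter)):
        x = _standardize_genotypes(calls[active, :])
        if x.shape[1] == 0 or not np.isfinite(x).all():
            raise ValueError("degenerate genotype matrix (no polymorphic variants)")
        k = min(n_pcs, min(x.shape) - 1)
        v0 = np.ones(min(x.shape))
        u, s, _ = scipy.sparse.linalg.svds(x, k=k, v0=v0)
        order = np.argsort(s)[::-1]
        scores = (u * s)[:, order]
        mean = scores.mean(axis=0)
        sd = scores.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        outlier = (np.abs(scores - mean) > sigma * sd).any(axis=1)
        removed_ids = [g.sample_ids[i] for i in active[outlier]]
        report.pca_outliers_per_iter.append(removed_ids)
        if not outlier.any():
            break
        active = active[~outlier]
        if len(active) <= n_pcs:
            raise ValueError("PCA outlier removal exhausted the sample set")
    retained = [g.sample_ids[i] for i in active]
    n_removed = g.n_samples - len(retained)
    report.removed["pca_outliers"] = n_removed
    report.n_samples_out = len(retained)
    report.check()
    if scores is None:  # n_iter == 0: identity
        x = _standardize_genotypes(calls)
        k = min(n_pcs, min(x.shape) - 1)
        u, s, _ = scipy.sparse.linalg.svds(x, k=k, v0=np.ones(min(x.shape)))
        scores = (u * s)[:, np.argsort(s)[::-1]]
    pc_cols = {f"pc{i + 1}": scores[:, i] for i in range(scores.shape[1])}
    pc_df = pd.DataFrame({"sample_id": retained, **pc_cols})
    logger.info("PCA outlier removal: %d samples removed over %d iteration(s)",
                n_removed, len(report.pca_outliers_per_iter))
    return retained, pc_df, report


# ---------------------------------------------------------------------------
# Pre-diagnosis event exclusion
# ---------------------------------------------------------------------------


def exclude_pre_diagnosis_events(
    samples: pd.DataFrame,
) -> tuple[pd.DataFrame, QCReport]:
    """Drop samples whose cardiovascular event predates their diagnosis.

    Samples with equal event and diagnosis dates are retained (the criterion
    is strictly 'before').  CVD cases lacking dates are retained with a
    warning.
    """
    report = QCReport(n_samples_in=len(samples))
    if "cvd_status" in samples.columns and "event_date" in samples.columns:
        undated = samples["cvd_status"] & samples["event_date"].isna()
        if undated.any():
            logger.warning(
                "%d CVD cases lack an event date; retained", int(undated.sum())
            )
    flag = flag_pre_diagnosis_events(samples)
    out = samples.loc[~flag].reset_index(drop=True)
    report.removed["pre_diagnosis_event"] = int(flag.sum())
    report.n_samples_out = len(out)
    report.check()
    logger.info("pre-diagnosis event exclusion: %d samples removed", int(flag.sum()))
    return out, report


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------


def run_qc(
    g: GenotypeMatrix,
    samples: pd.DataFrame,
    controls: GenotypeMatrix | None = None,
    maf_min: float = 0.05,
    miss_max: float = 0.05,
    info_min: float = 0.8,
    hwe_threshold: float = 1e-4,
    n_pcs: int = 10,
    n_iter: int = 10,
    sigma: float = 6.0,
) -> tuple[GenotypeMatrix, pd.DataFrame, QCReport]:
    """Full QC cascade; returns filtered genotypes, samples with PC scores, report."""
    report = QCReport(n_snps_in=g.n_snps, n_samples_in=len(samples))

    samples, rep_date = exclude_pre_diagnosis_events(samples)
    g = g.subset_samples(samples["sample_id"])

    g, rep_var = filter_variants(g, maf_min=maf_min, miss_max=miss_max, info_min=info_min)

    if controls is not None:
        failing, _ = hwe_filter(
            controls.subset_snps(
                [controls.index_of(r) for r in g.rsids if r in set(controls.rsids)]
            ),
            threshold=hwe_threshold,
        )
        failing_set = set(failing)
        keep = [j for j, r in enumerate(g.rsids) if r not in failing_set]
        report.removed["hwe"] = g.n_snps - len(keep)
        g = g.subset_snps(keep)
    else:
        report.removed["hwe"] = 0

    retained, pc_df, rep_pca = pca_outlier_removal(
        g, n_pcs=n_pcs, n_iter=n_iter, sigma=sigma
    )
    g = g.subset_samples(retained)
    samples = samples[samples["sample_id"].isin(set(retained))].reset_index(drop=True)
    samples = samples.drop(columns=[c for c in samples.columns if c.startswith("pc")],
                           errors="ignore").merge(pc_df, on="sample_id", how="left")

    report.merge(rep_date)
    report.merge(rep_var)
    report.merge(rep_pca)
    report.n_snps_out = g.n_snps
    report.n_samples_out = len(samples)
    report.check()
    return g, samples, report
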