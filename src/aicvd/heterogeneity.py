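"""Breslow-Day homogeneity of the odds ratio across disease strata.

Each disease contributes a 2x2 allele-count table (rows: CVD cases vs
event-free; columns: risk-allele copies vs other-allele copies, each sample
contributing round(dosage) and 2-round(dosage) copies respectively).  The
test asks whether a single common odds ratio — the Mantel-Haenszel estimate —
is compatible with every stratum; the optional Tarone term corrects the
statistic for the MH estimator not being conditional-MLE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io_formats import DISEASES, PAIRED_DISEASES, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class StratifiedTables:
    """Per-disease 2x2 allele-count tables for one SNP.

    Each stratum is (disease, a, b, c, d): a = risk-allele copies among CVD
    cases, b = other-allele copies among cases, c/d likewise among
    event-free samples.
    """

    rsid: str
    strata: list[tuple[str, float, float, float, float]]

    def __post_init__(self) -> None:
        if len(self.strata) < 2:
            raise ValueError("need at least 2 strata")
        for s in self.strata:
            if any(v < 0 for v in s[1:]):
                raise ValueError(f"negative cell count in stratum {s[0]}")
            if sum(s[1:]) <= 0:
                raise ValueError(f"empty stratum {s[0]}")


@dataclass
class HomogeneityResult:
    rsid: str
    comparison: str
    statistic: float
    df: int
    p_bd: float
    or_mh: float


def build_strata(
    g: GenotypeMatrix,
    samples: pd.DataFrame,
    rsid: str,
    diseases: tuple[str, ...] = DISEASES,
) -> StratifiedTables:
    """Allele-count 2x2 tables per disease for one SNP.

    Samples contribute hard-called allele copies (dosage rounded
    ties-to-even); missing dosages are skipped.  Empty strata are dropped
    with a warning; fewer than two remaining is an error.
    """
    unknown = set(diseases) - set(DISEASES)
    if unknown:
        raise ValueError(f"unknown disease labels: {sorted(unknown)}")
    j = g.index_of(rsid)
    calls = np.rint(g.dosages[:, j])
    id_to_row = {s: i for i, s in enumerate(g.sample_ids)}
    strata = []
    for d in diseases:
        sub = samples[samples["disease"] == d]
        a = b = c = dd = 0.0
        for sid, case in zip(sub["sample_id"], sub["cvd_status"]):
            row = id_to_row.get(sid)
            if row is None:
                continue
            cnt = calls[row]
            if np.isnan(cnt):
                continue
            if case:
                a += cnt
                b += 2 - cnt
            else:
                c += cnt
                dd += 2 - cnt
        if a + b + c + dd <= 0:
            logger.warning("stratum %s empty for %s; dropped", d, rsid)
            continue
        strata.append((d, a, b, c, dd))
    if len(strata) < 2:
        raise ValueError(f"fewer than 2 non-empty strata for {rsid}")
    return StratifiedTables(rsid=rsid, strata=strata)


def mantel_haenszel_or(strata: list[tuple[str, float, float, float, float]]) -> float:
    num = sum(a * d / (a + b + c + d) for _, a, b, c, d in strata)
    den = sum(b * c / (a + b + c + d) for _, a, b, c, d in strata)
    if den == 0 or num == 0:
        raise ValueError("Mantel-Haenszel common odds ratio undefined (zero margin)")
    return num / den


def _expected_a(a, b, c, d, psi) -> float:
    """Expected case/risk-allele cell under common OR psi, margins fixed.

    Solves psi (r1-x)(c1-x) = x (n-r1-c1+x) for the root inside
    [max(0, r1+c1-n), min(r1, c1)].
    """
    r1 = a + b
    c1 = a + c
    n = a + b + c + d
    lo, hi = max(0.0, r1 + c1 - n), min(r1, c1)
    if abs(psi - 1.0) < 1e-12:
        x = r1 * c1 / n
    else:
        A = psi - 1.0
        B = -(psi * (r1 + c1) + (n - r1 - c1))
        C = psi * r1 * c1
        disc = B * B - 4 * A * C
        disc = max(disc, 0.0)
        roots = [(-B + np.sqrt(disc)) / (2 * A), (-B - np.sqrt(disc)) / (2 * A)]
        inside = [r for r in roots if lo - 1e-9 <= r <= hi + 1e-9]
        if not inside:
            raise ValueError("no admissible root for expected cell count")
        x = min(inside, key=lambda r: abs(r - a))
        if len(inside) == 2 and not np.isclose(inside[0], inside[1]):
            # exactly one root is admissible for psi>0; prefer strict interior
            strict = [r for r in inside if lo <= r <= hi]
            if strict:
                x = strict[0]
    return float(np.clip(x, lo, hi))


def breslow_day(
    tables: StratifiedTables, tarone: bool = False, comparison: str = "ALL"
) -> HomogeneityResult:
    """Breslow-Day homogeneity test against the Mantel-Haenszel common OR.

    Zero-margin strata (no information on the odds ratio) are dropped; the
    statistic is referred to chi-square with (number of strata - 1) df.
    """
    usable = [
        s for s in tables.strata
        if (s[1] + s[2]) > 0 and (s[3] + s[4]) > 0 and (s[1] + s[3]) > 0 and (s[2] + s[4]) > 0
    ]
    n_dropped = len(tables.strata) - len(usable)
    if n_dropped:
        logger.warning("%s: %d zero-margin strata dropped", tables.rsid, n_dropped)
    if len(usable) < 2:
        raise ValueError("fewer than 2 informative strata")
    psi = mantel_haenszel_or(usable)
    if not np.isfinite(psi) or psi <= 0:
        raise ValueError("common odds ratio undefined")
    stat = 0.0
    sum_dev = 0.0
    sum_var = 0.0
    for _, a, b, c, d in usable:
        a_t = _expected_a(a, b, c, d, psi)
        r1, c1, n = a + b, a + c, a + b + c + d
        b_t, c_t, d_t = r1 - a_t, c1 - a_t, n - r1 - c1 + a_t
        cells = np.array([a_t, b_t, c_t, d_t])
        cells = np.maximum(cells, 1e-12)
        var = 1.0 / np.sum(1.0 / cells)
        stat += (a - a_t) ** 2 / var
        sum_dev += a - a_t
        sum_var += var
    if tarone:
        stat -= sum_dev**2 / sum_var
    stat = max(stat, 0.0)
    df = len(usable) - 1
    return HomogeneityResult(
        rsid=tables.rsid,
        comparison=comparison,
        statistic=float(stat),
        df=df,
        p_bd=float(max(chi2.sf(stat, df), np.finfo(float).tiny)),
        or_mh=float(psi),
    )


def homogeneity_scan(
    g: GenotypeMatrix,
    samples: pd.DataFrame,
    rsids: list[str],
    tarone: bool = False,
) -> pd.DataFrame:
    """All-disease plus clinically-paired Breslow-Day tests for each SNP.

    Comparisons: ALL (six diseases) and the clinically closest pairs PS-PA,
    CD-UC, RA-SLE.
    """
    rows = []
    for rsid in rsids:
        comparisons = [("ALL", DISEASES)] + [
            (f"{a}-{b}", (a, b)) for a, b in PAIRED_DISEASES
        ]
        for name, diseases in comparisons:
            try:
                t = build_strata(g, samples, rsid, diseases)
                res = breslow_day(t, tarone=tarone, comparison=name)
            except ValueError as exc:
                logger.warning("%s %s: %s", rsid, name, exc)
                continue
            rows.append({
                "rsid": res.rsid, "comparison": res.comparison,
                "statistic": res.statistic, "df": res.df,
                "p_bd": res.p_bd, "or_mh": res.or_mh,
            })
    return pd.DataFrame(rows, columns=["rsid", "comparison", "statistic", "df", "p_bd", "or_mh"])
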