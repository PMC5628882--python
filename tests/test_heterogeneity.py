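"""Breslow-Day homogeneity: formula oracle, invariances, type-I calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import chi2
from statsmodels.stats.contingency_tables import StratifiedTable

from aicvd.heterogeneity import (
    StratifiedTables,
    breslow_day,
    build_strata,
    mantel_haenszel_or,
)

from .conftest import make_genotype_matrix


def direct_formula_oracle(strata, tarone=False):
    """Independent Breslow-Day: numeric root-finding instead of the quadratic."""
    psi_num = sum(a * d / (a + b + c + d) for a, b, c, d in strata)
    psi_den = sum(b * c / (a + b + c + d) for a, b, c, d in strata)
    psi = psi_num / psi_den
    stat, sdev, svar = 0.0, 0.0, 0.0
    for a, b, c, d in strata:
        r1, c1, n = a + b, a + c, a + b + c + d
        lo, hi = max(0.0, r1 + c1 - n), min(r1, c1)

        def f(x):
            return x * (n - r1 - c1 + x) - psi * (r1 - x) * (c1 - x)

        a_t = brentq(f, lo + 1e-12, hi - 1e-12)
        var = 1.0 / (1 / a_t + 1 / (r1 - a_t) + 1 / (c1 - a_t)
                     + 1 / (n - r1 - c1 + a_t))
        stat += (a - a_t) ** 2 / var
        sdev += a - a_t
        svar += var
    if tarone:
        stat -= sdev**2 / svar
    return stat


def random_strata(rng, k=4, scale=80):
    return [
        tuple(float(v) for v in rng.integers(5, scale, 4))
        for _ in range(k)
    ]


class TestBreslowDay:
    def test_identical_strata_statistic_zero(self):
        t = StratifiedTables("rs1", [("RA", 20, 30, 15, 35), ("CD", 20, 30, 15, 35)])
        res = breslow_day(t)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_bd == pytest.approx(1.0)
        assert res.df == 1

    def test_worked_two_strata(self):
        strata = [("RA", 10.0, 10, 10, 10), ("CD", 40.0, 10, 10, 40)]
        res = breslow_day(StratifiedTables("rs1", strata))
        want = direct_formula_oracle([s[1:] for s in strata])
        assert res.statistic == pytest.approx(want, abs=1e-8)

    def test_matches_independent_oracles(self, rng):
        """Quadratic-root statistic equals numeric root-finding and statsmodels."""
        for _ in range(60):
            strata = random_strata(rng, k=int(rng.integers(2, 7)))
            t = StratifiedTables("rsX", [("S%d" % i, *s) for i, s in enumerate(strata)])
            res = breslow_day(t)
            want = direct_formula_oracle(strata)
            assert res.statistic == pytest.approx(want, abs=1e-8)
            # statsmodels expects 2x2xK
            tables = np.stack(
                [np.array([[a, b], [c, d]]) for a, b, c, d in strata], axis=-1
            )
            sm_res = StratifiedTable(tables.astype(float)).test_equal_odds(adjust=False)
            assert res.statistic == pytest.approx(sm_res.statistic, rel=1e-6)

    def test_tarone_adjustment_matches_statsmodels(self, rng):
        for _ in range(20):
            strata = random_strata(rng, k=3)
            t = StratifiedTables("rsX", [("S%d" % i, *s) for i, s in enumerate(strata)])
            res = breslow_day(t, tarone=True)
            tables = np.stack(
                [np.array([[a, b], [c, d]]) for a, b, c, d in strata], axis=-1
            )
            sm_res = StratifiedTable(tables.astype(float)).test_equal_odds(adjust=True)
            assert res.statistic == pytest.approx(sm_res.statistic, rel=1e-6)
            assert res.statistic <= breslow_day(t, tarone=False).statistic + 1e-9

    def test_stratum_order_invariance(self, rng):
        strata = [("A", 12.0, 20, 25, 40), ("B", 30.0, 12, 14, 22), ("C", 8.0, 9, 30, 13)]
        res1 = breslow_day(StratifiedTables("rs1", strata))
        res2 = breslow_day(StratifiedTables("rs1", strata[::-1]))
        assert res1.statistic == pytest.approx(res2.statistic, rel=1e-12)

    def test_expected_cell_reproduces_common_or(self, rng):
        from aicvd.heterogeneity import _expected_a

        for _ in range(50):
            a, b, c, d = (float(v) for v in rng.integers(3, 60, 4))
            psi = float(rng.uniform(0.2, 5.0))
            a_t = _expected_a(a, b, c, d, psi)
            r1, c1, n = a + b, a + c, a + b + c + d
            b_t, c_t, d_t = r1 - a_t, c1 - a_t, n - r1 - c1 + a_t
            assert max(0.0, r1 + c1 - n) - 1e-9 <= a_t <= min(r1, c1) + 1e-9
            assert a_t * d_t / (b_t * c_t) == pytest.approx(psi, abs=1e-8)

    def test_type_one_error_under_homogeneity(self, rng):
        """Homogeneous-OR simulations reject near the nominal 5% level."""
        n_sims, hits, used = 800, 0, 0
        for _ in range(n_sims):
            strata = []
            for _k in range(3):
                n1, n0 = 120, 400
                p0 = rng.uniform(0.2, 0.4)
                odds1 = 1.8 * p0 / (1 - p0)  # common OR 1.8 in every stratum
                p1 = odds1 / (1 + odds1)
                a = rng.binomial(n1, p1)
                c = rng.binomial(n0, p0)
                strata.append(("S", float(a), float(n1 - a), float(c), float(n0 - c)))
            try:
                res = breslow_day(StratifiedTables("rs", strata))
            except ValueError:
                continue
            used += 1
            hits += res.p_bd < 0.05
        assert used > 0.95 * n_sims
        assert 0.03 <= hits / used <= 0.07

    def test_zero_margin_stratum_dropped(self):
        t = StratifiedTables("rs1", [
            ("A", 10.0, 12, 9, 15), ("B", 20.0, 10, 12, 18), ("C", 0.0, 0.0, 12, 18),
        ])
        res = breslow_day(t)
        assert res.df == 1  # third stratum uninformative


class TestBuildStrata:
    def test_allele_counting(self):
        g = make_genotype_matrix(np.array([[2.0], [0.0], [1.0], [2.0]]))
        samples = pd.DataFrame({
            "sample_id": g.sample_ids,
            "disease": ["RA", "RA", "CD", "CD"],
            "cvd_status": [True, False, True, False],
        })
        t = build_strata(g, samples, "rs1", ("RA", "CD"))
        # RA: case dosage 2 -> a=2,b=0; control dosage 0 -> c=0,d=2
        assert t.strata[0] == ("RA", 2.0, 0.0, 0.0, 2.0)
        assert t.strata[1] == ("CD", 1.0, 1.0, 2.0, 0.0)

    def test_missing_dosage_skipped(self):
        g = make_genotype_matrix(np.array([[2.0], [np.nan], [1.0], [1.0]]))
        samples = pd.DataFrame({
            "sample_id": g.sample_ids,
            "disease": ["RA", "RA", "CD", "CD"],
            "cvd_status": [True, True, True, False],
        })
        t = build_strata(g, samples, "rs1", ("RA", "CD"))
        assert t.strata[0] == ("RA", 2.0, 0.0, 0.0, 0.0)

    def test_six_strata(self, small_study):
        t = build_strata(small_study.genotypes, small_study.samples,
                         small_study.genotypes.rsids[0])
        assert len(t.strata) == 6

    def test_single_stratum_rejected(self):
        g = make_genotype_matrix(np.array([[2.0], [0.0]]))
        samples = pd.DataFrame({
            "sample_id": g.sample_ids, "disease": ["RA", "RA"],
            "cvd_status": [True, False],
        })
        with pytest.raises(ValueError, match="2 non-empty"):
            build_strata(g, samples, "rs1", ("RA", "CD"))


def test_mantel_haenszel_known_value():
    # single stratum: MH OR reduces to the plain odds ratio ad/bc
    assert mantel_haenszel_or([("S", 10, 5, 4, 20)]) == pytest.approx(10 * 20 / (5 * 4))
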