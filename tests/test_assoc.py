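"""Dosage logistic regression: oracle agreement, calibration, replication calls."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import chi2, kstest, norm

from aicvd.assoc import (
    _align_risk_allele,
    call_replication,
    fit_dosage_logistic,
    run_disease_scan,
)

from .conftest import make_genotype_matrix


def simulate_logistic(rng, n=800, beta=0.0, maf=0.3, case_frac=0.2, n_cov=2):
    dosage = rng.binomial(2, maf, n).astype(float)
    C = rng.standard_normal((n, n_cov))
    alpha = np.log(case_frac / (1 - case_frac)) - beta * 2 * maf
    lp = alpha + beta * dosage + 0.3 * C[:, 0]
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
    if y.sum() in (0, n):  # pathological draw; reshuffle one label
        y[0] = 1 - y[0]
    return dosage, y, C


class TestFitDosageLogistic:
    def test_matches_statsmodels(self, rng):
        """Point estimates and Wald SEs agree with the reference MLE fitter."""
        for _ in range(5):
            d, y, C = simulate_logistic(rng, beta=0.5)
            res = fit_dosage_logistic(d, y, C)
            X = np.column_stack([np.ones(len(y)), d, C])
            ref = sm.Logit(y, X).fit(disp=0)
            assert res.beta == pytest.approx(ref.params[1], abs=1e-6)
            assert res.se == pytest.approx(ref.bse[1], rel=1e-5)
            assert res.p == pytest.approx(ref.pvalues[1], rel=1e-4)

    def test_wald_p_equals_two_sided_normal(self, rng):
        d, y, C = simulate_logistic(rng, beta=0.4)
        res = fit_dosage_logistic(d, y, C)
        z = res.beta / res.se
        assert res.p == pytest.approx(2 * norm.sf(abs(z)), rel=1e-10)
        assert chi2.sf(z * z, 1) == pytest.approx(res.p, rel=1e-10)

    def test_or_and_ci_consistency(self, rng):
        d, y, C = simulate_logistic(rng, beta=0.6)
        res = fit_dosage_logistic(d, y, C)
        assert res.or_ == pytest.approx(np.exp(res.beta))
        lo, hi = res.ci95
        assert lo == pytest.approx(np.exp(res.beta - 1.96 * res.se))
        assert hi == pytest.approx(np.exp(res.beta + 1.96 * res.se))
        assert lo <= res.or_ <= hi

    def test_covariate_rescaling_invariance(self, rng):
        d, y, C = simulate_logistic(rng, beta=0.5, n_cov=3)
        res1 = fit_dosage_logistic(d, y, C)
        C2 = C * np.array([10.0, 0.01, 3.0]) + np.array([5.0, -2.0, 100.0])
        res2 = fit_dosage_logistic(d, y, C2)
        assert res2.beta == pytest.approx(res1.beta, abs=1e-6)
        assert res2.se == pytest.approx(res1.se, rel=1e-6)

    def test_constant_dosage_rejected(self, rng):
        _, y, C = simulate_logistic(rng)
        with pytest.raises(ValueError, match="constant"):
            fit_dosage_logistic(np.ones(len(y)), y, C)

    def test_single_class_outcome_rejected(self, rng):
        d, y, C = simulate_logistic(rng)
        with pytest.raises(ValueError, match="single class"):
            fit_dosage_logistic(d, np.zeros_like(y), C)

    def test_separation_surfaced_not_significant(self):
        # dosage perfectly predicts outcome -> must not report a finite P
        d = np.array([0.0, 0, 0, 0, 2, 2, 2, 2])
        y = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        res = fit_dosage_logistic(d, y, None)
        assert not res.converged
        assert np.isinf(res.se)
        assert np.isnan(res.p)

    def test_type_one_error_calibrated(self, rng):
        """Null rejections at alpha=0.05 stay near nominal (reduced replicate count)."""
        n_sims, hits = 600, 0
        for _ in range(n_sims):
            d, y, C = simulate_logistic(rng, n=400, beta=0.0, n_cov=1)
            try:
                res = fit_dosage_logistic(d, y, C)
            except ValueError:
                continue
            if res.converged and res.p < 0.05:
                hits += 1
        assert 0.03 <= hits / n_sims <= 0.07

    def test_parameter_recovery(self, rng):
        """Planted log-OR 0.8 recovered without bias (reduced replicate count)."""
        betas = []
        for _ in range(150):
            d, y, C = simulate_logistic(rng, n=1000, beta=0.8, case_frac=0.2)
            res = fit_dosage_logistic(d, y, C)
            if res.converged:
                betas.append(res.beta)
        assert abs(np.mean(betas) - 0.8) < 0.1


class TestDiseaseScan:
    def _study(self, rng, n=300, m=25):
        d = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
        g = make_genotype_matrix(d)
        samples = pd.DataFrame({
            "sample_id": g.sample_ids,
            "disease": "RA",
            "cvd_status": rng.random(n) < 0.25,
            "age": rng.normal(50, 10, n),
            "sex": rng.integers(0, 2, n),
            "bmi": rng.normal(26, 4, n),
        })
        return g, samples

    def test_scan_complete_and_deterministic(self, rng):
        g, samples = self._study(rng)
        t1 = run_disease_scan(g, samples, "RA")
        t2 = run_disease_scan(g, samples, "RA")
        assert len(t1) == g.n_snps
        pd.testing.assert_frame_equal(t1, t2)

    def test_absent_disease_rejected(self, rng):
        g, samples = self._study(rng)
        with pytest.raises(ValueError, match="absent"):
            run_disease_scan(g, samples, "UC")

    def test_no_cases_rejected(self, rng):
        g, samples = self._study(rng)
        samples["cvd_status"] = False
        with pytest.raises(ValueError, match="cases"):
            run_disease_scan(g, samples, "RA")

    def test_null_scan_uniform_pvalues(self, rng):
        g, samples = self._study(rng, n=900, m=300)
        t = run_disease_scan(g, samples, "RA")
        p = t.loc[t["converged"], "p"]
        assert kstest(p, "uniform").pvalue > 0.01


class TestReplication:
    def _assoc_row(self, rsid, p, beta, disease="RA"):
        return {
            "rsid": rsid, "chr": 1, "pos": 100, "disease": disease,
            "coded_allele": "G", "beta": beta, "se": 0.1, "or": np.exp(beta),
            "ci_low": 1.0, "ci_high": 2.0, "p": p, "n_cases": 30,
            "n_controls": 300, "converged": True,
        }

    def _meta(self, rsid="rs1", a="A", b="G"):
        return pd.DataFrame([{
            "snp_id": "1:100", "rsid": rsid, "chromosome": 1, "position": 100,
            "allele_A": a, "allele_B": b, "info_score": np.nan, "genotyped": True,
        }])

    def _call(self, p, beta, risk, a="A", b="G"):
        assoc = pd.DataFrame([self._assoc_row("rs1", p, beta)])
        cands = pd.DataFrame([{
            "rsid": "rs1", "risk_allele": risk,
            "source_trait": "CHD", "source_class": "CVD",
        }])
        return call_replication(assoc, cands, self._meta(a=a, b=b)).iloc[0]

    def test_significant_same_allele_replicates(self):
        row = self._call(p=0.041, beta=0.5, risk="G")
        assert row["replicated"] and row["direction_consistent"]

    def test_opposite_direction_fails(self):
        assert not self._call(p=0.02, beta=-0.5, risk="G")["replicated"]

    def test_nonsignificant_fails(self):
        row = self._call(p=0.06, beta=0.5, risk="G")
        assert row["direction_consistent"] and not row["replicated"]

    def test_risk_allele_is_allele_A_flips_sign(self):
        assert self._call(p=0.01, beta=-0.5, risk="A")["replicated"]

    def test_complement_matching(self):
        # risk allele C, assay alleles A/G: complement of C is G = coded
        row = self._call(p=0.01, beta=0.5, risk="C")
        assert row["status"] == "complement" and row["replicated"]

    def test_palindromic_flagged_ambiguous(self):
        assert _align_risk_allele("A", "A", "T") == (None, "ambiguous")
        assert _align_risk_allele("C", "G", "C") == (None, "ambiguous")

    def test_unresolvable(self):
        # for non-palindromic SNPs every ACGT base matches an allele or its
        # complement, so only a non-base risk label is unresolvable
        sign, status = _align_risk_allele("C", "A", "G")
        assert status == "complement"  # sanity: C complements G
        sign, status = _align_risk_allele("I", "A", "G")
        assert sign is None and status == "unresolvable"

    def test_missing_candidate_reported(self):
        assoc = pd.DataFrame([self._assoc_row("rs1", 0.01, 0.5)])
        cands = pd.DataFrame([{
            "rsid": "rs99", "risk_allele": "G",
            "source_trait": "CHD", "source_class": "CVD",
        }])
        calls = call_replication(assoc, cands, self._meta())
        assert calls.iloc[0]["status"] == "missing"
        assert not calls.iloc[0]["replicated"]
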