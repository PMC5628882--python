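"""Generator contracts: determinism, allele frequencies, LD structure,
phenotype calibration, planted-effect recovery and resource construction."""

import numpy as np
import pytest

from aicvd.assoc import fit_dosage_logistic
from aicvd.io_formats import flag_pre_diagnosis_events, validate_sample_table
from aicvd.simulate import (
    PlantedEffect,
    SimulationSpec,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_resources,
)


def small_spec(**over):
    base = dict(
        n_per_disease={"RA": 300, "CD": 300},
        n_controls=100, n_snps=60, ld_block_size=10, ld_rho=0.6,
        missing_rate=0.0, seed=42,
    )
    base.update(over)
    return SimulationSpec(**base)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "field, value, match",
        [
            ("n_snps", 0, "n_snps"),
            ("maf_range", (0.0, 0.5), "maf_range"),
            ("maf_range", (0.1, 0.6), "maf_range"),
            ("ld_rho", 1.0, "ld_rho"),
            ("cvd_base_prevalence", 0.0, "cvd_base_prevalence"),
            ("n_per_disease", {"XX": 10}, "unknown diseases"),
        ],
    )
    def test_invalid_field_named(self, field, value, match):
        with pytest.raises(ValueError, match=match):
            small_spec(**{field: value}).validate()

    def test_planted_effect_validation(self):
        with pytest.raises(ValueError, match="duplicate"):
            small_spec(planted_effects=[
                PlantedEffect([1, 1], {"RA": 0.5}, "A")
            ]).validate()
        with pytest.raises(ValueError, match="nonzero"):
            small_spec(planted_effects=[
                PlantedEffect([1], {"RA": 0.0}, "A")
            ]).validate()


class TestGenotypes:
    def test_deterministic_under_seed(self):
        g1, c1 = simulate_genotypes(small_spec())
        g2, c2 = simulate_genotypes(small_spec())
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        np.testing.assert_array_equal(c1.dosages, c2.dosages)

    def test_seed_changes_output(self):
        g1, _ = simulate_genotypes(small_spec())
        g2, _ = simulate_genotypes(small_spec(seed=43))
        assert not np.array_equal(g1.dosages, g2.dosages)

    def test_allele_frequency_matches_drawn_maf(self):
        spec = small_spec(n_per_disease={"RA": 5000}, maf_range=(0.3, 0.3),
                          n_snps=40, ld_rho=0.0)
        g, _ = simulate_genotypes(spec)
        freq = g.allele_b_freq()
        # 3-sigma binomial bound at n=5000: 3*sqrt(0.3*0.7/(2*5000)) ~ 0.014
        assert np.all(np.abs(freq - 0.3) < 0.02)

    def test_rho_zero_independent(self):
        spec = small_spec(n_per_disease={"RA": 2000}, ld_rho=0.0, n_snps=40)
        g, _ = simulate_genotypes(spec)
        c = np.corrcoef(g.dosages.T)
        off = np.abs(c[np.triu_indices(40, 1)])
        assert off.mean() < 3 / np.sqrt(2000)

    def test_block_structure(self):
        spec = small_spec(n_per_disease={"RA": 1500}, ld_rho=0.9,
                          maf_range=(0.2, 0.4))
        g, _ = simulate_genotypes(spec)
        c = np.corrcoef(g.dosages.T) ** 2
        within = [c[i, j] for b in range(6) for i in range(b * 10, b * 10 + 10)
                  for j in range(i + 1, b * 10 + 10)]
        between = [c[i, j] for i in range(10) for j in range(10, 20)]
        assert np.mean(within) > 0.3
        assert np.mean(between) < 0.01

    def test_hwe_holds_marginally(self):
        spec = small_spec(n_per_disease={"RA": 4000}, maf_range=(0.3, 0.3),
                          n_snps=20, ld_rho=0.8)
        g, _ = simulate_genotypes(spec)
        from aicvd.qc import hwe_exact_pvalue

        pvals = []
        for j in range(20):
            col = g.dosages[:, j]
            pvals.append(hwe_exact_pvalue(
                int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
            ))
        assert min(pvals) > 1e-4  # no wholesale HWE violation


class TestPhenotypes:
    def test_case_fraction_calibrated(self):
        spec = small_spec(
            n_per_disease={"RA": 3000, "CD": 3000},
            cvd_base_prevalence=0.025, pre_diagnosis_event_fraction=0.001,
        )
        g, _ = simulate_genotypes(spec)
        samples = simulate_phenotypes(g, spec)
        clean = samples[~flag_pre_diagnosis_events(samples)]
        frac = clean["cvd_status"].mean()
        sd = np.sqrt(0.025 * 0.975 / len(clean))
        assert abs(frac - 0.025) < 3 * sd + 1e-3

    def test_pre_diagnosis_fraction(self):
        spec = small_spec(n_per_disease={"RA": 3300, "CD": 3185},
                          pre_diagnosis_event_fraction=0.02)
        g, _ = simulate_genotypes(spec)
        samples = simulate_phenotypes(g, spec)
        flagged = flag_pre_diagnosis_events(samples).sum()
        # binomial expectation ~130 of 6485
        assert 90 <= flagged <= 170

    def test_sample_table_valid_and_composite_consistent(self):
        spec = small_spec()
        g, _ = simulate_genotypes(spec)
        samples = validate_sample_table(simulate_phenotypes(g, spec))
        assert (samples["cvd_status"] == (samples["chd"] | samples["cva"]
                                          | samples["pad"])).all()
        assert set(samples["disease"]) == {"RA", "CD"}

    def test_unknown_cohort_rejected(self):
        spec = small_spec()
        g, _ = simulate_genotypes(spec)
        spec2 = small_spec(n_per_disease={"RA": 300})
        with pytest.raises(ValueError, match="absent"):
            simulate_phenotypes(g, spec2)

    def test_planted_effect_recovered_by_regression(self):
        """Planted per-dosage log-OR 1.0 in RA is estimated without gross bias.

        Reduced replicate count; each replicate simulates an RA cohort at the
        emulated size and refits the planted SNP.
        """
        betas = []
        for rep in range(20):
            spec = SimulationSpec(
                n_per_disease={"RA": 1281}, n_controls=10, n_snps=30,
                ld_block_size=10, ld_rho=0.0, maf_range=(0.3, 0.4),
                cvd_base_prevalence=0.08, missing_rate=0.0,
                pre_diagnosis_event_fraction=1e-6, seed=100 + rep,
                planted_effects=[PlantedEffect([0], {"RA": 1.0}, "A")],
            )
            g, _ = simulate_genotypes(spec)
            samples = simulate_phenotypes(g, spec)
            covs = samples[["age", "sex", "bmi", "dyslipidemia", "hypertension",
                            "t2d", "physical_inactivity", "smoking"]].to_numpy(float)
            res = fit_dosage_logistic(
                g.dosages[:, 0], samples["cvd_status"].to_numpy(float), covs
            )
            if res.converged:
                betas.append(res.beta)
        mean_beta = np.mean(betas)
        assert 0.7 < mean_beta < 1.3


class TestResources:
    def test_candidate_counts_and_risk_alleles(self):
        spec = small_spec(n_candidate_cvd=30, n_candidate_aid=20)
        g, _ = simulate_genotypes(spec)
        cands, annotation, gmt = simulate_resources(g, spec)
        cvd = cands[cands["source_class"] == "CVD"]
        assert len(cvd) == 30
        assert cvd["risk_allele"].isin(list("ACGT")).all()
        assert cands["rsid"].isin(g.rsids).all()

    def test_annotation_one_gene_per_snp(self):
        spec = small_spec()
        g, _ = simulate_genotypes(spec)
        _, annotation, _ = simulate_resources(g, spec)
        assert len(annotation) == g.n_snps
        assert annotation["gene"].notna().all()
        # positional nearest-gene: SNPs of one LD block share their gene,
        # distinct blocks (>= 2 Mb apart) map to distinct genes
        block = annotation.iloc[: spec.ld_block_size]
        assert block["gene"].nunique() == 1
        assert annotation.groupby("gene")["chr"].nunique().eq(1).all()

    def test_planted_genes_inside_their_set(self):
        spec = small_spec(planted_effects=[
            PlantedEffect([0, 10, 20], {"RA": 0.8, "CD": 0.8}, "A")
        ])
        g, _ = simulate_genotypes(spec)
        _, annotation, gmt = simulate_resources(g, spec)
        planted_genes = set(annotation.iloc[[0, 10, 20]]["gene"])
        assert planted_genes <= set(gmt["SET_A"])
        assert len(gmt["SET_A"]) > 3  # padded with non-planted genes

    def test_no_planted_effects_still_emits_sets(self):
        spec = small_spec()
        g, _ = simulate_genotypes(spec)
        _, _, gmt = simulate_resources(g, spec)
        assert len(gmt) > 0
        assert all(name.startswith("DECOY") for name in gmt)
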