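"""QC cascade and per-disease dosage association on synthetic cohorts.

Shows the filter bookkeeping (MAF / missingness / info / HWE-in-controls /
PCA outliers / pre-diagnosis exclusions) and a covariate-adjusted logistic
scan for one disease.
"""

from aicvd import SimulationSpec, simulate_study
from aicvd.assoc import run_disease_scan
from aicvd.qc import run_qc

spec = SimulationSpec(
    n_per_disease={"RA": 600, "CD": 600}, n_controls=400,
    n_snps=300, ld_block_size=10, seed=21,
)
study = simulate_study(spec)

g_qc, samples_qc, report = run_qc(study.genotypes, study.samples,
                                  controls=study.controls)
print(report.to_frame().to_string(index=False))
# 'removed maf' counts variants under the 5% MAF floor; 'hwe' the ones whose
# control-cohort genotypes fail the exact test at P<1e-4.

scan = run_disease_scan(g_qc, samples_qc, "RA")
top = scan.nsmallest(5, "p")[["rsid", "beta", "or", "ci_low", "ci_high", "p"]]
print(top.to_string(index=False))
print("Each row: per-allele log-odds for CVD in RA, adjusted for the eight "
      "clinical covariates and two ancestry PCs; under this null simulation "
      "the smallest P-values are what uniform noise produces.")
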