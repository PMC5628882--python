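"""End-to-end run: planted pleiotropic patterns recovered as enriched gene sets.

Simulates the six cohorts with three planted cross-disease risk patterns
(RA+SLE, CD+UC, PS+PA), runs QC -> association -> CPMA -> pruning ->
clustering -> enrichment, and prints which gene sets come out enriched.
"""

import tempfile

from aicvd import PipelineConfig, run_all
from aicvd.simulate import planted_scenario

with tempfile.TemporaryDirectory() as tmp:
    cfg = PipelineConfig(out_dir=tmp, seed=1, simulation=planted_scenario(seed=1))
    state = run_all(cfg)["state"]

    print(f"SNPs after QC: {state['qc_report'].n_snps_out}; "
          f"samples: {state['qc_report'].n_samples_out}")
    print(f"CPMA-significant SNPs: {len(state['cpma_selected'])}; "
          f"independent after r^2>0.2 pruning: {len(state['cpma_kept'])}")
    print(f"genetic clusters: {state['cluster_model'].k}")

    enr = state["enrichment"]
    hits = enr[enr["q_fdr"] < 0.05].sort_values("q_fdr")
    print(hits[["cluster", "gene_set", "K", "n", "x", "p_hyper", "q_fdr"]]
          .to_string(index=False))
    print("The three SET_* collections hold the planted patterns' genes; "
          "recovering exactly those at q<0.05, with every DECOY_* set null, "
          "is the end-to-end correctness check.")
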