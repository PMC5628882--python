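"""End-to-end orchestration: simulate/load -> QC -> association ->
replication -> homogeneity -> CPMA -> clustering -> enrichment.

Every stage writes its outputs (TSV) before the next begins; a JSON manifest
records a SHA-256 content hash per artifact, so re-running an identical
configuration reproduces identical hashes.  When the output directory holds
a manifest produced under the same configuration hash and a stage's files
are all present, that stage is not recomputed — its outputs are reloaded
from disk (content-hash-keyed resumability).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import assoc, cluster, cpma, enrich, heterogeneity, qc
from .io_formats import (
    DISEASES,
    read_annotation,
    read_candidate_list,
    read_dosage_tsv,
    read_gmt,
    read_sample_table,
    write_annotation,
    write_candidate_list,
    write_dosage_tsv,
    write_gmt,
    write_sample_table,
)
from .simulate import SimulationSpec, control_sample_table, simulate_study

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "assoc", "replicate", "breslow_day", "cpma",
          "cluster", "enrich")


@dataclass
class PipelineConfig:
    """All thresholds and paths of one pipeline run.

    Thresholds default to the analysis design: MAF >= 0.05, missingness <=
    0.05, HWE exact P >= 1e-4 in controls, imputation info > 0.8, nominal
    association gate P < 0.05, pleiotropy gate P_CPMA < 0.01, LD pruning at
    r^2 > 0.2, four P-value categories, silhouette-chosen cluster count,
    Bonferroni over cluster x disease tests, enrichment FDR 0.05.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    simulation: SimulationSpec | None = None
    # optional external inputs (dosage TSV + meta, sample TSV, ...)
    input_dosages: str | None = None
    input_snp_meta: str | None = None
    input_samples: str | None = None
    input_control_dosages: str | None = None
    input_control_meta: str | None = None
    input_candidates: str | None = None
    input_annotation: str | None = None
    input_gmt: str | None = None

    maf_min: float = 0.05
    miss_max: float = 0.05
    hwe_threshold: float = 1e-4
    info_min: float = 0.8
    n_pcs: int = 10
    pca_iterations: int = 10
    pca_sigma: float = 6.0
    p_nominal: float = 0.05
    p_cpma_max: float = 0.01
    min_nominal: int = 1
    r2_max: float = 0.2
    prune_window_kb: float = 1000.0
    k_clusters: int | str = "auto"
    linkage_method: str = "ward.D"
    n_tests: int | None = None
    fdr_threshold: float = 0.05
    replication_p: float = 0.05

    def validate(self) -> None:
        for name, v, lo, hi in (
            ("maf_min", self.maf_min, 0, 0.5),
            ("miss_max", self.miss_max, 0, 1),
            ("hwe_threshold", self.hwe_threshold, 0, 1),
            ("info_min", self.info_min, 0, 1),
            ("p_nominal", self.p_nominal, 0, 1),
            ("p_cpma_max", self.p_cpma_max, 0, 1),
            ("r2_max", self.r2_max, 0, 1),
            ("fdr_threshold", self.fdr_threshold, 0, 1),
            ("replication_p", self.replication_p, 0, 1),
        ):
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.simulation is None and self.input_dosages is None:
            raise ValueError("config needs either a simulation spec or input paths")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), default=str, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            from .simulate import PlantedEffect

            effects = [PlantedEffect(**e) for e in sim.pop("planted_effects", [])]
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            cfg.simulation = SimulationSpec(planted_effects=effects, **sim)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for the operator."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause} (see log for details)")
        self.stage = stage


# Output files per stage (for resume checks).
_STAGE_FILES = {
    "simulate": ("dosages.tsv", "snp_meta.tsv", "control_dosages.tsv",
                 "control_meta.tsv", "samples.tsv", "control_samples.tsv",
                 "candidates.tsv", "annotation.tsv", "gene_sets.gmt"),
    "qc": ("qc_report.tsv", "samples_qc.tsv", "retained_samples.txt",
           "retained_snps.txt"),
    "assoc": ("association.tsv",),
    "replicate": ("replication.tsv",),
    "breslow_day": ("homogeneity.tsv",),
    "cpma": ("cpma.tsv",),
    "cluster": ("cluster_assignments.tsv", "cluster_association.tsv",
                "cluster_tree.nwk"),
    "enrich": ("enrichment.tsv",),
}


def run_all(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run (or resume) the pipeline; returns the manifest and in-memory state."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.simulation is not None:
        config.simulation.seed = config.seed
    cfg_hash = config.config_hash()

    manifest_path = out / "manifest.json"
    resumable: set[str] = set()
    if manifest_path.exists():
        with open(manifest_path) as fh:
            prev = json.load(fh)
        if prev.get("config_hash") == cfg_hash:
            done = {a["stage"] for a in prev.get("artifacts", {}).values()}
            resumable = {
                s for s in done
                if all((out / f).exists() for f in _STAGE_FILES.get(s, ()))
            }

    manifest: dict = {"config_hash": cfg_hash, "artifacts": {}}
    state: dict = {}

    def record(stage: str) -> None:
        for name in _STAGE_FILES[stage]:
            p = out / name
            if p.exists():
                manifest["artifacts"][name] = {"stage": stage, "sha256": _sha256(p)}
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    # ----- stage bodies ----------------------------------------------------

    def compute_simulate():
        if config.simulation is not None:
            study = simulate_study(config.simulation)
            state.update(
                genotypes=study.genotypes, controls=study.controls,
                samples=study.samples, candidates=study.candidates,
                annotation=study.annotation, gene_sets=study.gene_sets,
            )
            write_dosage_tsv(study.genotypes, out / "dosages.tsv", out / "snp_meta.tsv")
            write_dosage_tsv(study.controls, out / "control_dosages.tsv",
                             out / "control_meta.tsv")
            write_sample_table(study.samples, out / "samples.tsv")
            write_sample_table(control_sample_table(study.controls),
                               out / "control_samples.tsv")
            write_candidate_list(study.candidates, out / "candidates.tsv")
            write_annotation(study.annotation, out / "annotation.tsv")
            write_gmt(study.gene_sets, out / "gene_sets.gmt")
            record("simulate")
        else:
            state["genotypes"] = read_dosage_tsv(config.input_dosages, config.input_snp_meta)
            state["samples"] = read_sample_table(config.input_samples)
            state["controls"] = (
                read_dosage_tsv(config.input_control_dosages, config.input_control_meta)
                if config.input_control_dosages else None
            )
            state["candidates"] = (
                read_candidate_list(config.input_candidates)
                if config.input_candidates else None
            )
            state["annotation"] = (
                read_annotation(config.input_annotation) if config.input_annotation else None
            )
            state["gene_sets"] = read_gmt(config.input_gmt) if config.input_gmt else None

    def load_simulate():
        state["genotypes"] = read_dosage_tsv(out / "dosages.tsv", out / "snp_meta.tsv")
        state["controls"] = read_dosage_tsv(out / "control_dosages.tsv",
                                            out / "control_meta.tsv")
        state["samples"] = read_sample_table(out / "samples.tsv")
        state["candidates"] = read_candidate_list(out / "candidates.tsv")
        state["annotation"] = read_annotation(out / "annotation.tsv")
        state["gene_sets"] = read_gmt(out / "gene_sets.gmt")

    def compute_qc():
        g, samples, report = qc.run_qc(
            state["genotypes"], state["samples"], controls=state.get("controls"),
            maf_min=config.maf_min, miss_max=config.miss_max,
            info_min=config.info_min, hwe_threshold=config.hwe_threshold,
            n_pcs=config.n_pcs, n_iter=config.pca_iterations, sigma=config.pca_sigma,
        )
        state["genotypes_qc"] = g
        state["samples_qc"] = samples
        state["qc_report"] = report
        _write_tsv(report.to_frame(), out / "qc_report.tsv")
        write_sample_table(samples, out / "samples_qc.tsv")
        (out / "retained_samples.txt").write_text("\n".join(g.sample_ids) + "\n")
        (out / "retained_snps.txt").write_text("\n".join(g.rsids) + "\n")
        record("qc")

    def load_qc():
        g = state["genotypes"]
        keep_samples = (out / "retained_samples.txt").read_text().split()
        keep_snps = set((out / "retained_snps.txt").read_text().split())
        g = g.subset_samples(keep_samples)
        g = g.subset_snps([j for j, r in enumerate(g.rsids) if r in keep_snps])
        state["genotypes_qc"] = g
        state["samples_qc"] = read_sample_table(out / "samples_qc.tsv")

    def compute_assoc():
        diseases = tuple(d for d in DISEASES if d in set(state["samples_qc"]["disease"]))
        table = assoc.run_all_diseases(state["genotypes_qc"], state["samples_qc"], diseases)
        state["assoc"] = table
        _write_tsv(table, out / "association.tsv")
        record("assoc")

    def load_assoc():
        state["assoc"] = pd.read_csv(out / "association.tsv", sep="\t")

    def compute_replicate():
        if state.get("candidates") is None:
            logger.info("no candidate list; replication skipped")
            return
        present = state["candidates"][
            state["candidates"]["rsid"].isin(set(state["genotypes_qc"].rsids))
        ]
        calls = assoc.call_replication(
            state["assoc"], present, state["genotypes_qc"].snp_meta,
            p_threshold=config.replication_p,
        )
        state["replication"] = calls
        _write_tsv(calls, out / "replication.tsv")
        record("replicate")

    def load_replicate():
        path = out / "replication.tsv"
        if path.exists():
            state["replication"] = pd.read_csv(path, sep="\t")

    def compute_bd():
        calls = state.get("replication")
        if calls is None or calls.empty:
            logger.info("no replication calls; homogeneity skipped")
            return
        rsids = sorted(calls.loc[calls["replicated"], "rsid"].unique())
        table = heterogeneity.homogeneity_scan(
            state["genotypes_qc"], state["samples_qc"], rsids
        )
        state["homogeneity"] = table
        _write_tsv(table, out / "homogeneity.tsv")
        record("breslow_day")

    def load_bd():
        path = out / "homogeneity.tsv"
        if path.exists():
            state["homogeneity"] = pd.read_csv(path, sep="\t")

    def compute_cpma():
        selected = cpma.select_pleiotropic(
            state["assoc"], p_nominal=config.p_nominal,
            p_cpma_max=config.p_cpma_max, min_nominal=config.min_nominal,
        )
        kept = cpma.ld_prune(selected, state["genotypes_qc"],
                             r2_max=config.r2_max, window_kb=config.prune_window_kb)
        state["cpma_selected"] = selected
        state["cpma_kept"] = kept
        _write_tsv(cpma.cpma_table(selected, kept), out / "cpma.tsv")
        record("cpma")

    def load_cpma():
        table = pd.read_csv(out / "cpma.tsv", sep="\t")
        results = []
        kept = []
        pcols = [f"p_{d}" for d in DISEASES if f"p_{d}" in table.columns]
        for _, row in table.iterrows():
            res = cpma.CpmaResult(
                rsid=row["rsid"], p_vector=row[pcols].to_numpy(dtype=float),
                n_nominal=int(row["n_nominal"]), lambda_hat=row["lambda_hat"],
                statistic=row["statistic"], p_cpma=row["p_cpma"],
            )
            results.append(res)
            if row["kept_after_prune"]:
                kept.append(res)
        state["cpma_selected"] = results
        state["cpma_kept"] = kept

    def compute_cluster():
        kept = state.get("cpma_kept", [])
        if len(kept) < 3:
            raise ValueError(
                f"only {len(kept)} pleiotropic SNPs after pruning; "
                "clustering needs at least 3 (relax p_cpma_max or plant effects)"
            )
        rsids = [c.rsid for c in kept]
        pmat = cpma.pvalue_matrix(state["assoc"]).loc[rsids]
        cats = cluster.discretize(pmat)
        dist = cluster.gower_distance(cats)
        model = cluster.ward_cluster(dist, rsids, cats, k=config.k_clusters,
                                     method=config.linkage_method)
        model.cluster_assoc = cluster.fisher_combine(
            model.assignments, pmat, n_tests=config.n_tests
        )
        state["cluster_model"] = model
        _write_tsv(model.assignments.rename_axis("rsid").reset_index(),
                   out / "cluster_assignments.tsv")
        _write_tsv(model.cluster_assoc, out / "cluster_association.tsv")
        (out / "cluster_tree.nwk").write_text(
            cluster.linkage_to_newick(model.linkage_matrix, rsids) + "\n"
        )
        record("cluster")

    def load_cluster():
        df = pd.read_csv(out / "cluster_assignments.tsv", sep="\t")
        state["cluster_assignments"] = pd.Series(
            df["cluster"].to_numpy(), index=df["rsid"], name="cluster"
        )

    def compute_enrich():
        model = state.get("cluster_model")
        assignments = (model.assignments if model is not None
                       else state.get("cluster_assignments"))
        if assignments is None or state.get("annotation") is None \
                or state.get("gene_sets") is None:
            logger.info("missing clustering/annotation/gene sets; enrichment skipped")
            return
        cluster_genes = enrich.map_snps_to_genes(assignments, state["annotation"])
        universe = state["annotation"]["gene"].unique().tolist()
        table = enrich.hypergeom_enrich(cluster_genes, state["gene_sets"], universe)
        state["enrichment"] = table
        _write_tsv(table, out / "enrichment.tsv")
        record("enrich")

    bodies = {
        "simulate": (compute_simulate, load_simulate),
        "qc": (compute_qc, load_qc),
        "assoc": (compute_assoc, load_assoc),
        "replicate": (compute_replicate, load_replicate),
        "breslow_day": (compute_bd, load_bd),
        "cpma": (compute_cpma, load_cpma),
        "cluster": (compute_cluster, load_cluster),
        "enrich": (compute_enrich, None),
    }

    last = max(STAGES.index(s) for s in stages)
    for name in STAGES[: last + 1]:
        compute, load = bodies[name]
        try:
            if name in resumable and name in stages and load is not None:
                logger.info("stage %s: outputs up to date, reloading", name)
                load()
                # carry hashes forward so downstream resumes still validate
                for fname in _STAGE_FILES[name]:
                    p = out / fname
                    if p.exists():
                        manifest["artifacts"][fname] = {
                            "stage": name, "sha256": _sha256(p)
                        }
            elif name in stages:
                compute()
            elif load is not None and all(
                (out / f).exists() for f in _STAGE_FILES.get(name, ())
            ):
                load()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - surface the failing stage
            logger.exception("stage %s failed", name)
            raise PipelineError(name, exc) from exc
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return {"manifest": manifest, "state": state}
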