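"""Synthetic multi-cohort genotype/phenotype/resource generator.

Emulates the statistical structure the downstream analysis assumes: six
autoimmune-disease cohorts (plus an external healthy-control cohort for the
Hardy-Weinberg filter), Hardy-Weinberg genotypes with blockwise linkage
disequilibrium, a rare composite cardiovascular endpoint driven by a logistic
model over clinical covariates and planted SNP effects, plus candidate-SNP
lists, a SNP->gene annotation and a GMT gene-set collection in which planted
pleiotropic patterns are recoverable.

Linkage disequilibrium uses a blockwise Gaussian copula: per haplotype, a
latent multivariate normal vector with exchangeable within-block correlation
``ld_rho`` is thresholded at the allele-frequency quantile, and the genotype
is the sum of two independent haplotypes — Hardy-Weinberg holds marginally
and within-block dosage correlation rises with ``ld_rho`` (attenuated
relative to the latent correlation by the thresholding).  Blocks are placed
>1 Mb apart so between-block signals are independent for LD pruning.

Randomness: one master seed; every component draws from its own child stream
of a ``numpy.random.SeedSequence`` (genotypes per cohort, phenotypes,
resources), so cohorts are independent and each stage is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .io_formats import (
    CONTROL_LABEL,
    DISEASES,
    GeneSetCollection,
    GenotypeMatrix,
)

#: Cohort sizes of the study design being emulated.
DEFAULT_COHORTS = {"RA": 1281, "PS": 1123, "PA": 989, "SLE": 907, "CD": 1358, "UC": 827}

#: Aggregate CVD prevalence after QC in the emulated design (140 / 5317).
DEFAULT_PREVALENCE = 140 / 5317

#: Plausible log-odds for the clinical risk factors (per unit; age and BMI per
#: year / kg/m^2).
DEFAULT_COVARIATE_EFFECTS = {
    "age": 0.05,
    "sex": 0.6,
    "dyslipidemia": 0.5,
    "hypertension": 0.6,
    "t2d": 0.5,
    "bmi": 0.03,
    "physical_inactivity": 0.3,
    "smoking": 0.5,
}

_AGE_MEAN = {"RA": 58, "PS": 46, "PA": 51, "SLE": 43, "CD": 40, "UC": 45}
_FEMALE_FRACTION = {"RA": 0.75, "PS": 0.45, "PA": 0.5, "SLE": 0.9, "CD": 0.5, "UC": 0.5}
_BINARY_RATES = {
    "dyslipidemia": 0.25,
    "hypertension": 0.25,
    "t2d": 0.07,
    "physical_inactivity": 0.4,
    "smoking": 0.25,
}


@dataclass
class PlantedEffect:
    """A group of SNPs sharing one cross-disease effect profile.

    ``per_disease_log_or`` gives the additive per-dosage log-odds each member
    SNP contributes within each disease; the label names the genetic pattern
    the clustering stage should recover.
    """

    snp_indices: list[int]
    per_disease_log_or: dict[str, float]
    cluster_label: str

    def validate(self, n_snps: int) -> None:
        if len(set(self.snp_indices)) != len(self.snp_indices):
            raise ValueError(f"planted_effects[{self.cluster_label}]: duplicate snp_indices")
        if any(i < 0 or i >= n_snps for i in self.snp_indices):
            raise ValueError(f"planted_effects[{self.cluster_label}]: snp index out of range")
        if not all(np.isfinite(v) for v in self.per_disease_log_or.values()):
            raise ValueError(f"planted_effects[{self.cluster_label}]: non-finite log-odds")
        if not any(v != 0 for v in self.per_disease_log_or.values()):
            raise ValueError(
                f"planted_effects[{self.cluster_label}]: needs a nonzero effect"
            )
        unknown = set(self.per_disease_log_or) - set(DISEASES)
        if unknown:
            raise ValueError(
                f"planted_effects[{self.cluster_label}]: unknown diseases {sorted(unknown)}"
            )


@dataclass
class SimulationSpec:
    """All knobs of the synthetic study, with defaults matching the emulated design."""

    n_per_disease: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COHORTS))
    n_controls: int = 1558
    n_snps: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 20
    ld_rho: float = 0.8
    cvd_base_prevalence: float = DEFAULT_PREVALENCE
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    pre_diagnosis_event_fraction: float = 0.02
    missing_rate: float = 0.001
    imputed_fraction: float = 0.3
    n_candidate_cvd: int = 103
    n_candidate_aid: int = 315
    seed: int = 0

    def validate(self) -> None:
        for name, value in (
            ("n_controls", self.n_controls),
            ("n_snps", self.n_snps),
            ("ld_block_size", self.ld_block_size),
            ("n_candidate_cvd", self.n_candidate_cvd),
            ("n_candidate_aid", self.n_candidate_aid),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if not self.n_per_disease:
            raise ValueError("n_per_disease must not be empty")
        unknown = set(self.n_per_disease) - set(DISEASES)
        if unknown:
            raise ValueError(f"n_per_disease: unknown diseases {sorted(unknown)}")
        if any(n <= 0 for n in self.n_per_disease.values()):
            raise ValueError("n_per_disease counts must be > 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if not 0 <= self.ld_rho < 1:
            raise ValueError(f"ld_rho must lie in [0, 1), got {self.ld_rho}")
        for name, p in (
            ("cvd_base_prevalence", self.cvd_base_prevalence),
            ("pre_diagnosis_event_fraction", self.pre_diagnosis_event_fraction),
        ):
            if not 0 < p < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {p}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"missing_rate must lie in [0, 1), got {self.missing_rate}")
        for eff in self.planted_effects:
            eff.validate(self.n_snps)

    # Child seed-stream indices (documented master-seed layout).
    _STREAMS = {"maf": 0, "patients": 1, "controls": 2, "phenotypes": 3, "resources": 4}

    def child_rng(self, stream: str) -> np.random.Generator:
        seqs = np.random.SeedSequence(self.seed).spawn(len(self._STREAMS))
        return np.random.default_rng(seqs[self._STREAMS[stream]])


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def _snp_metadata(spec: SimulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = spec.maf_range
    maf = rng.uniform(lo, hi, spec.n_snps)
    n_blocks = int(np.ceil(spec.n_snps / spec.ld_block_size))
    block_of = np.repeat(np.arange(n_blocks), spec.ld_block_size)[: spec.n_snps]
    chrom = 1 + (block_of % 22)
    # 5 kb spacing within a block, >2 Mb between blocks on the same chromosome
    pos = np.empty(spec.n_snps, dtype=int)
    within = np.concatenate([np.arange((block_of == b).sum()) for b in range(n_blocks)])
    block_rank = block_of // 22  # per-chromosome serial number of the block
    pos = 1_000_000 + block_rank * 2_500_000 + within * 5_000 + 1
    alleles = np.array(["A", "C", "G", "T"])
    a_idx = rng.integers(0, 4, spec.n_snps)
    # allele_B differs from allele_A and avoids palindromic pairs
    b_idx = np.empty_like(a_idx)
    compl = {0: 3, 1: 2, 2: 1, 3: 0}
    for i, a in enumerate(a_idx):
        choices = [j for j in range(4) if j != a and j != compl[a]]
        b_idx[i] = choices[rng.integers(0, len(choices))]
    genotyped = rng.random(spec.n_snps) >= spec.imputed_fraction
    info = np.where(genotyped, np.nan, rng.uniform(0.75, 1.0, spec.n_snps))
    meta = pd.DataFrame({
        "snp_id": [f"{c}:{p}" for c, p in zip(chrom, pos)],
        "rsid": [f"rs{i + 1:06d}" for i in range(spec.n_snps)],
        "chromosome": chrom,
        "position": pos,
        "allele_A": alleles[a_idx],
        "allele_B": alleles[b_idx],
        "info_score": info,
        "genotyped": genotyped,
    })
    meta.attrs["maf"] = maf
    meta.attrs["block_of"] = block_of
    return meta


def _draw_genotypes(
    n: int,
    maf: np.ndarray,
    block_of: np.ndarray,
    rho: float,
    missing_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Genotypes via a thresholded blockwise-exchangeable Gaussian copula."""
    m = len(maf)
    thresh = norm.ppf(maf)
    geno = np.zeros((n, m))
    for _ in range(2):  # two independent haplotypes -> HWE marginally
        z = np.empty((n, m))
        if rho > 0:
            shared = {b: rng.standard_normal(n) for b in np.unique(block_of)}
            for b in np.unique(block_of):
                cols = np.flatnonzero(block_of == b)
                eps = rng.standard_normal((n, len(cols)))
                z[:, cols] = np.sqrt(rho) * shared[b][:, None] + np.sqrt(1 - rho) * eps
        else:
            z = rng.standard_normal((n, m))
        geno += (z < thresh[None, :]).astype(float)
    if missing_rate > 0:
        mask = rng.random((n, m)) < missing_rate
        geno[mask] = np.nan
    return geno


def simulate_genotypes(spec: SimulationSpec) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Draw patient and control genotype matrices sharing SNP metadata.

    Sample IDs encode the disease (``RA_0001`` ...); controls are an
    independent cohort from the same allele-frequency distribution, used
    only by the Hardy-Weinberg QC filter.
    """
    spec.validate()
    meta = _snp_metadata(spec, spec.child_rng("maf"))
    maf = meta.attrs["maf"]
    block_of = meta.attrs["block_of"]

    rng_p = spec.child_rng("patients")
    sample_ids = []
    chunks = []
    for d in DISEASES:
        n = spec.n_per_disease.get(d, 0)
        if n == 0:
            continue
        sample_ids += [f"{d}_{i + 1:05d}" for i in range(n)]
        chunks.append(
            _draw_genotypes(n, maf, block_of, spec.ld_rho, spec.missing_rate, rng_p)
        )
    patients = GenotypeMatrix(
        sample_ids=sample_ids, snp_meta=meta.copy(), dosages=np.vstack(chunks)
    )

    rng_c = spec.child_rng("controls")
    controls = GenotypeMatrix(
        sample_ids=[f"{CONTROL_LABEL}_{i + 1:05d}" for i in range(spec.n_controls)],
        snp_meta=meta.copy(),
        dosages=_draw_genotypes(
            spec.n_controls, maf, block_of, spec.ld_rho, spec.missing_rate, rng_c
        ),
    )
    patients.snp_meta.attrs.update(meta.attrs)
    controls.snp_meta.attrs.update(meta.attrs)
    return patients, controls


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def _calibrate_intercept(lp: np.ndarray, target: float) -> float:
    """Intercept alpha with mean(expit(alpha + lp)) == target."""

    def mean_prev(alpha: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + lp))))) - target

    return brentq(mean_prev, -40, 10)


def disease_of_sample(sample_id: str) -> str:
    return sample_id.split("_")[0]


def simulate_phenotypes(genotypes: GenotypeMatrix, spec: SimulationSpec) -> pd.DataFrame:
    """Covariates, composite CVD endpoint and dates for the patient cohort.

    CVD status follows a logistic model: per-disease intercept calibrated so
    the overall case fraction matches ``cvd_base_prevalence``, plus clinical
    covariate effects, plus each planted SNP's per-disease log-odds times its
    centred dosage.  A further ``pre_diagnosis_event_fraction`` of all
    samples is converted to cases whose event predates diagnosis, to
    exercise the exclusion rule.
    """
    spec.validate()
    diseases = [disease_of_sample(s) for s in genotypes.sample_ids]
    missing = set(diseases) - set(spec.n_per_disease)
    if missing:
        raise ValueError(f"disease labels absent from spec.n_per_disease: {sorted(missing)}")
    rng = spec.child_rng("phenotypes")
    n = genotypes.n_samples
    disease_arr = np.array(diseases)

    age = np.empty(n)
    sex = np.empty(n)
    present = [d for d in DISEASES if d in set(diseases)]
    for d in present:
        idx = disease_arr == d
        age[idx] = np.clip(rng.normal(_AGE_MEAN[d], 12.0, idx.sum()), 18, 90)
        sex[idx] = rng.random(idx.sum()) >= _FEMALE_FRACTION[d]  # 1 = male
    bmi = np.clip(rng.normal(26.0, 4.0, n), 15, 50)
    binaries = {k: (rng.random(n) < v).astype(float) for k, v in _BINARY_RATES.items()}

    eff = spec.covariate_effects
    lp = (
        eff.get("age", 0.0) * (age - age.mean())
        + eff.get("sex", 0.0) * sex
        + eff.get("bmi", 0.0) * (bmi - bmi.mean())
        + sum(eff.get(k, 0.0) * v for k, v in binaries.items())
    )

    # planted genetic effects: centred dosage x per-disease log-odds
    maf = genotypes.snp_meta.attrs.get("maf")
    for planted in spec.planted_effects:
        for j in planted.snp_indices:
            d_j = np.nan_to_num(genotypes.dosages[:, j], nan=0.0)
            centre = 2 * maf[j] if maf is not None else np.nanmean(d_j)
            centred = d_j - centre
            for dis, logor in planted.per_disease_log_or.items():
                if logor:
                    lp[disease_arr == dis] += logor * centred[disease_arr == dis]

    # per-disease intercepts: each cohort is calibrated to the base
    # prevalence, so differing covariate profiles (age, sex mix) do not
    # starve any cohort of events
    prob = np.empty(n)
    for d in present:
        idx = disease_arr == d
        alpha = _calibrate_intercept(lp[idx], spec.cvd_base_prevalence)
        prob[idx] = 1.0 / (1.0 + np.exp(-(alpha + lp[idx])))
    cvd = rng.random(n) < prob

    # composite endpoint components; every case has >= 1 of CHD/CVA/PAD
    chd = cvd & (rng.random(n) < 0.55)
    cva = cvd & (rng.random(n) < 0.30)
    pad = cvd & (rng.random(n) < 0.25)
    none = cvd & ~(chd | cva | pad)
    chd = chd | none

    diagnosis = pd.Timestamp("2008-01-01") + pd.to_timedelta(
        rng.integers(-2000, 0, n), unit="D"
    )
    event = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    case_idx = np.flatnonzero(cvd)
    event.iloc[case_idx] = diagnosis[case_idx] + pd.to_timedelta(
        rng.integers(30, 2500, len(case_idx)), unit="D"
    )

    # convert a fraction of all samples into pre-diagnosis-event cases
    pre = rng.random(n) < spec.pre_diagnosis_event_fraction
    pre_idx = np.flatnonzero(pre)
    cvd[pre_idx] = True
    chd[pre_idx] = True
    event.iloc[pre_idx] = diagnosis[pre_idx] - pd.to_timedelta(
        rng.integers(30, 2000, len(pre_idx)), unit="D"
    )

    df = pd.DataFrame({
        "sample_id": genotypes.sample_ids,
        "disease": diseases,
        "chd": chd.astype(bool),
        "cva": cva.astype(bool),
        "pad": pad.astype(bool),
        "cvd_status": cvd.astype(bool),
        "event_date": event.values,
        "diagnosis_date": diagnosis,
        "age": age,
        "sex": sex.astype(int),
        "dyslipidemia": binaries["dyslipidemia"].astype(int),
        "hypertension": binaries["hypertension"].astype(int),
        "t2d": binaries["t2d"].astype(int),
        "bmi": bmi,
        "physical_inactivity": binaries["physical_inactivity"].astype(int),
        "smoking": binaries["smoking"].astype(int),
        "is_control": False,
    })
    # keep component flags consistent with the composite
    df.loc[df["cvd_status"] & ~(df["chd"] | df["cva"] | df["pad"]), "chd"] = True
    df.loc[~df["cvd_status"], ["chd", "cva", "pad"]] = False
    return df


def control_sample_table(controls: GenotypeMatrix) -> pd.DataFrame:
    return pd.DataFrame({
        "sample_id": controls.sample_ids,
        "disease": CONTROL_LABEL,
        "is_control": True,
    })


# ---------------------------------------------------------------------------
# Resources: candidates, annotation, gene sets
# ---------------------------------------------------------------------------


def simulate_resources(
    genotypes: GenotypeMatrix,
    spec: SimulationSpec,
    n_decoy_sets: int = 40,
    decoy_set_size: int = 15,
    planted_set_padding: int = 3,
    gene_window_bp: int = 500_000,
) -> tuple[pd.DataFrame, pd.DataFrame, GeneSetCollection]:
    """Candidate-SNP lists, SNP->gene annotation and a GMT collection.

    Nearest-gene annotation is positional: every SNP maps to the single
    gene of its ``gene_window_bp`` genomic window, so variants of one LD
    block share a gene — as nearest-gene mapping does in real data, where a
    pruned proxy tags the same locus as the variant it replaced.  For each
    planted pattern a gene set containing all of the pattern's genes (padded
    with a few random others) is emitted, alongside decoy sets of random
    non-planted genes, so enrichment recovery is testable end to end.
    """
    spec.validate()
    rng = spec.child_rng("resources")
    meta = genotypes.snp_meta
    genes = [
        f"GENE_{c}_{int(p) // gene_window_bp}"
        for c, p in zip(meta["chromosome"], meta["position"])
    ]
    annotation = pd.DataFrame({
        "rsid": meta["rsid"],
        "chr": meta["chromosome"],
        "pos": meta["position"],
        "gene": genes,
    })

    planted_idx = sorted({i for e in spec.planted_effects for i in e.snp_indices})
    planted_genes_set = {genes[i] for i in planted_idx}
    pool = [i for i in range(len(meta)) if genes[i] not in planted_genes_set]

    def make_candidates(n: int, source_class: str, traits: list[str], prefer: list[int]):
        chosen = list(prefer)[:n]
        remaining = min(n - len(chosen), len(pool))  # capped by available SNPs
        if remaining > 0:
            extra = rng.choice(pool, size=remaining, replace=False)
            chosen += [int(i) for i in extra]
        rows = []
        for i in chosen:
            m = meta.iloc[i]
            # declared risk allele: the allele that increases risk if planted,
            # else a random one of the two assay alleles
            logor = 0.0
            for e in spec.planted_effects:
                if i in e.snp_indices:
                    logor = next((v for v in e.per_disease_log_or.values() if v), 0.0)
                    break
            if logor > 0:
                risk = m["allele_B"]
            elif logor < 0:
                risk = m["allele_A"]
            else:
                risk = m["allele_B"] if rng.random() < 0.5 else m["allele_A"]
            rows.append({
                "rsid": m["rsid"],
                "risk_allele": risk,
                "source_trait": traits[rng.integers(0, len(traits))],
                "source_class": source_class,
            })
        return pd.DataFrame(rows)

    cvd_list = make_candidates(
        spec.n_candidate_cvd, "CVD", ["CHD", "CVA", "PAD"], planted_idx
    )
    used = set(cvd_list["rsid"])
    aid_pool = [i for i in pool if meta.iloc[i]["rsid"] not in used]
    aid_rows = rng.choice(aid_pool, size=min(spec.n_candidate_aid, len(aid_pool)), replace=False)
    aid_list = make_candidates(
        len(aid_rows), "autoimmune", list(DISEASES), [int(i) for i in aid_rows]
    )
    candidates = pd.concat([cvd_list, aid_list], ignore_index=True)

    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    gene_arr = np.array(genes)
    non_planted_genes = np.array(sorted({genes[i] for i in pool}))
    planted_set_padding = min(planted_set_padding, len(non_planted_genes))
    decoy_set_size = min(decoy_set_size, len(non_planted_genes))
    for e in spec.planted_effects:
        members = list(gene_arr[e.snp_indices])
        pad = rng.choice(non_planted_genes, size=planted_set_padding, replace=False)
        sets[f"SET_{e.cluster_label}"] = members + [str(g) for g in pad]
        desc[f"SET_{e.cluster_label}"] = f"planted pattern {e.cluster_label}"
    for i in range(n_decoy_sets):
        pick = rng.choice(non_planted_genes, size=decoy_set_size, replace=False)
        sets[f"DECOY_{i + 1:02d}"] = [str(g) for g in pick]
        desc[f"DECOY_{i + 1:02d}"] = "random decoy set"
    gmt = GeneSetCollection(sets=sets, descriptions=desc)
    return candidates, annotation, gmt


# ---------------------------------------------------------------------------
# Bundled study
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    spec: SimulationSpec
    genotypes: GenotypeMatrix
    controls: GenotypeMatrix
    samples: pd.DataFrame
    candidates: pd.DataFrame
    annotation: pd.DataFrame
    gene_sets: GeneSetCollection


def simulate_study(spec: SimulationSpec | None = None) -> SimulatedStudy:
    """Generate the full synthetic study (genotypes, phenotypes, resources)."""
    spec = spec or SimulationSpec()
    patients, controls = simulate_genotypes(spec)
    samples = simulate_phenotypes(patients, spec)
    candidates, annotation, gmt = simulate_resources(patients, spec)
    return SimulatedStudy(
        spec=spec, genotypes=patients, controls=controls, samples=samples,
        candidates=candidates, annotation=annotation, gene_sets=gmt,
    )


def planted_scenario(
    seed: int = 0,
    n_snps: int = 1200,
    snps_per_cluster: int = 12,
    log_or: float = 1.4,
    cohort_scale: float = 1.0,
) -> SimulationSpec:
    """Three planted pleiotropic patterns with distinct cross-disease profiles.

    Pattern A drives CVD risk in RA+SLE, B in CD+UC, C in PS+PA — disjoint
    profiles matching the clinically paired diseases, so the clustering
    stage can separate them.  Planted SNPs are placed in distinct LD blocks
    (one per block) so LD pruning keeps them all.  The planted per-dosage
    log-odds defaults to 1.4 (OR ~ 4) on common variants (MAF >= 0.1):
    replicated risk loci for a rare composite endpoint of this kind carry
    odds ratios of roughly 2-7 (median near 4), and the rare-event cohorts
    (~25-35 cases each) only resolve effects of that order.
    """
    cohorts = {d: max(40, int(round(n * cohort_scale))) for d, n in DEFAULT_COHORTS.items()}
    block = 10
    profiles = {
        "A": {"RA": log_or, "SLE": log_or},
        "B": {"CD": log_or, "UC": log_or},
        "C": {"PS": log_or, "PA": log_or},
    }
    n_blocks_needed = len(profiles) * snps_per_cluster
    if n_blocks_needed * block > n_snps:
        raise ValueError(
            f"n_snps={n_snps} too small for {n_blocks_needed} planted blocks of {block}"
        )
    effects = []
    next_block = 0
    for label, prof in profiles.items():
        idx = []
        for _ in range(snps_per_cluster):
            idx.append(next_block * block)  # first SNP of its own block
            next_block += 1
        effects.append(PlantedEffect(snp_indices=idx, per_disease_log_or=prof,
                                     cluster_label=label))
    return SimulationSpec(
        n_per_disease=cohorts,
        n_controls=max(60, int(round(1558 * cohort_scale))),
        n_snps=n_snps,
        ld_block_size=block,
        maf_range=(0.1, 0.5),
        planted_effects=effects,
        seed=seed,
    )
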