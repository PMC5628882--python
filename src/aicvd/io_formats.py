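"""Readers/writers for the genotype and tabular formats the pipeline touches.

The canonical in-memory genotype representation is the expected allele dosage
(0..2 copies of allele_B), not hard calls: association uses the expected
genotype counts directly, and hard calls are derived only where a contingency
table is needed.  Supported formats:

* Oxford GEN + SAMPLE (SNPTEST v2 dialect, 5 metadata columns)
* dosage TSV (SNPs x samples) with a SNP-metadata TSV
* sample table TSV, candidate-SNP TSV, SNP->gene annotation TSV
* GMT gene-set collections (MSigDB dialect)
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The six autoimmune disease labels used throughout.
DISEASES = ("RA", "PS", "PA", "SLE", "CD", "UC")

#: Disease label reserved for the external healthy-control cohort (HWE QC only).
CONTROL_LABEL = "CTRL"

#: Clinical covariates entering the logistic model, in canonical order.
COVARIATES = (
    "age",
    "sex",
    "dyslipidemia",
    "hypertension",
    "t2d",
    "bmi",
    "physical_inactivity",
    "smoking",
)

#: Clinically paired diseases for the focused odds-ratio homogeneity tests.
PAIRED_DISEASES = (("PS", "PA"), ("CD", "UC"), ("RA", "SLE"))

SNP_META_COLUMNS = (
    "snp_id",
    "rsid",
    "chromosome",
    "position",
    "allele_A",
    "allele_B",
    "info_score",
    "genotyped",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset(_COMPLEMENT)


class FormatError(ValueError):
    """A file violated its format contract."""


def complement_allele(allele: str) -> str:
    return _COMPLEMENT[allele]


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x SNPs expected-dosage matrix with per-SNP metadata.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per dosage row.
    snp_meta
        One row per SNP with columns ``snp_id, rsid, chromosome, position,
        allele_A, allele_B, info_score, genotyped``.  ``info_score`` may be
        NaN (directly genotyped variants carry no imputation quality).
    dosages
        float array of shape (n_samples, n_snps); values in [0, 2] count
        copies of ``allele_B``; NaN marks a missing genotype.
    """

    sample_ids: list[str]
    snp_meta: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample IDs must be unique")
        missing_cols = [c for c in SNP_META_COLUMNS if c not in self.snp_meta.columns]
        if missing_cols:
            raise ValueError(f"snp_meta missing columns: {missing_cols}")
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        if self.snp_meta["rsid"].duplicated().any():
            dup = self.snp_meta.loc[self.snp_meta["rsid"].duplicated(), "rsid"].iloc[0]
            raise ValueError(f"duplicate rsid: {dup}")
        pos = self.snp_meta["position"]
        if (pos <= 0).any():
            raise ValueError("positions must be positive 1-based integers")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_meta)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_meta)} SNPs"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise ValueError("dosages must lie in [0, 2] or be NaN")
        info = self.snp_meta["info_score"]
        ok = info.isna() | ((info >= 0) & (info <= 1))
        if not ok.all():
            raise ValueError("info_score must lie in [0, 1] or be absent")

    # -- basic geometry ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_meta)

    @property
    def rsids(self) -> list[str]:
        return self.snp_meta["rsid"].tolist()

    def index_of(self, rsid: str) -> int:
        idx = self.snp_meta.index[self.snp_meta["rsid"] == rsid]
        if len(idx) == 0:
            raise KeyError(f"rsid not present: {rsid}")
        return int(idx[0])

    def dosage_for(self, rsid: str) -> np.ndarray:
        return self.dosages[:, self.index_of(rsid)]

    # -- derived views -----------------------------------------------------

    def hard_calls(self) -> np.ndarray:
        """Round dosages to genotype counts, ties-to-even; NaN preserved."""
        return np.rint(self.dosages)

    def allele_b_freq(self) -> np.ndarray:
        """Mean dosage / 2 over non-missing samples, per SNP."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_b_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def subset_snps(self, indices: Sequence[int]) -> "GenotypeMatrix":
        indices = list(indices)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snp_meta=self.snp_meta.iloc[indices].reset_index(drop=True),
            dosages=self.dosages[:, indices].copy(),
        )

    def subset_samples(self, keep_ids: Iterable[str]) -> "GenotypeMatrix":
        keep = set(keep_ids)
        mask = [i for i, s in enumerate(self.sample_ids) if s in keep]
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in mask],
            snp_meta=self.snp_meta.copy(),
            dosages=self.dosages[mask, :].copy(),
        )


# ---------------------------------------------------------------------------
# Sample table
# ---------------------------------------------------------------------------

SAMPLE_REQUIRED = ("sample_id", "disease")
SAMPLE_FLAGS = ("chd", "cva", "pad")


def validate_sample_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a sample table.

    Derives ``cvd_status`` from the CHD/CVA/PAD component flags (composite
    endpoint: at least one of the three) and checks consistency when a
    cvd_status column is already present.  Control-cohort rows (``is_control``
    true) may use the reserved disease label; patient rows must use one of
    the six disease labels.
    """
    df = df.copy()
    for col in SAMPLE_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"sample table missing mandatory column: {col}")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in sample table")
    if "is_control" not in df.columns:
        df["is_control"] = False
    df["is_control"] = df["is_control"].astype(bool)
    allowed = set(DISEASES)
    bad = ~df["disease"].isin(allowed) & ~df["is_control"]
    if bad.any():
        raise FormatError(
            f"unknown disease label(s): {sorted(df.loc[bad, 'disease'].unique())}"
        )
    have_flags = all(c in df.columns for c in SAMPLE_FLAGS)
    if have_flags:
        for c in SAMPLE_FLAGS:
            df[c] = df[c].fillna(0).astype(int).astype(bool)
        composite = df["chd"] | df["cva"] | df["pad"]
        if "cvd_status" in df.columns:
            declared = df["cvd_status"].fillna(0).astype(int).astype(bool)
            if not (declared == composite).all():
                raise FormatError(
                    "cvd_status inconsistent with CHD/CVA/PAD component flags"
                )
        df["cvd_status"] = composite
    elif "cvd_status" in df.columns:
        df["cvd_status"] = df["cvd_status"].fillna(0).astype(int).astype(bool)
    for col in ("event_date", "diagnosis_date"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], format="ISO8601", errors="raise")
    return df.reset_index(drop=True)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "disease": str})
    return validate_sample_table(df)


def write_sample_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in ("event_date", "diagnosis_date"):
        if col in out.columns:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def flag_pre_diagnosis_events(df: pd.DataFrame) -> pd.Series:
    """True where a cardiovascular event strictly precedes disease diagnosis.

    Equal dates are not flagged (the exclusion criterion is an event *before*
    diagnosis).  Rows lacking either date are never flagged.
    """
    if "event_date" not in df.columns or "diagnosis_date" not in df.columns:
        return pd.Series(False, index=df.index)
    # NaT comparisons are False, so undated rows are never flagged
    return (df["event_date"] < df["diagnosis_date"]).astype(bool)


# ---------------------------------------------------------------------------
# Candidate lists and annotation
# ---------------------------------------------------------------------------


def validate_candidate_list(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("rsid", "risk_allele", "source_trait", "source_class"):
        if col not in df.columns:
            raise FormatError(f"candidate list missing column: {col}")
    if df["rsid"].duplicated().any():
        raise FormatError("duplicate rsid in candidate list")
    bad = ~df["risk_allele"].isin(_VALID_ALLELES)
    if bad.any():
        raise FormatError(
            f"invalid risk allele(s): {sorted(df.loc[bad, 'risk_allele'].unique())}"
        )
    bad_class = ~df["source_class"].isin(("CVD", "autoimmune"))
    if bad_class.any():
        raise FormatError("source_class must be 'CVD' or 'autoimmune'")
    return df.reset_index(drop=True)


def read_candidate_list(path: str | Path) -> pd.DataFrame:
    return validate_candidate_list(pd.read_csv(path, sep="\t", dtype=str))


def write_candidate_list(df: pd.DataFrame, path: str | Path) -> None:
    validate_candidate_list(df).to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """SNP->gene annotation: columns rsid, chr, pos, gene."""
    df = pd.read_csv(path, sep="\t")
    for col in ("rsid", "chr", "pos", "gene"):
        if col not in df.columns:
            raise FormatError(f"annotation table missing column: {col}")
    return df


def write_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, order-preserving."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if any(not g for g in genes):
                raise ValueError(f"gene set {name!r} contains an empty symbol")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out.update(genes)
        return out

    def restrict_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        uni = set(universe)
        sets = {}
        desc = {}
        for name, genes in self.sets.items():
            kept = [g for g in genes if g in uni]
            if kept:
                sets[name] = kept
                desc[name] = self.descriptions.get(name, "")
        return GeneSetCollection(sets=sets, descriptions=desc)


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, need >=3"
                )
            name, description = fields[0], fields[1]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} empty")
            sets[name] = genes
            desc[name] = description
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Dosage TSV
# ---------------------------------------------------------------------------


def write_dosage_tsv(
    g: GenotypeMatrix, dosage_path: str | Path, meta_path: str | Path
) -> None:
    """SNPs x samples dosage TSV (rsid first column) + SNP-metadata TSV."""
    df = pd.DataFrame(
        g.dosages.T, index=g.snp_meta["rsid"].values, columns=g.sample_ids
    )
    df.index.name = "rsid"
    df.to_csv(dosage_path, sep="\t", float_format="%.6g", na_rep="NA")
    g.snp_meta.to_csv(meta_path, sep="\t", index=False, float_format="%.6g")


def read_dosage_tsv(dosage_path: str | Path, meta_path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(dosage_path, sep="\t", index_col=0, na_values="NA")
    meta = pd.read_csv(meta_path, sep="\t")
    if list(df.index) != list(meta["rsid"]):
        raise FormatError("dosage TSV rsid order does not match metadata table")
    return GenotypeMatrix(
        sample_ids=[str(c) for c in df.columns],
        snp_meta=meta,
        dosages=df.to_numpy(dtype=float).T,
    )


# ---------------------------------------------------------------------------
# Oxford GEN / SAMPLE
# ---------------------------------------------------------------------------

_PROB_SUM_TOL = 0.02  # residual probability mass tolerance
_SNPID_RE = re.compile(r"^(\w+):(\d+)$")


def dosage_from_probs(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Expected allele_B count from a genotype probability triple.

    Triples summing within [0.98, 1.02] are renormalised; anything further
    from 1 is treated as a missing genotype.
    """
    total = p0 + p1 + p2
    ok = np.abs(total - 1.0) <= _PROB_SUM_TOL
    with np.errstate(invalid="ignore", divide="ignore"):
        dos = (p1 + 2.0 * p2) / total
    dos = np.where(ok, dos, np.nan)
    return dos


def write_gen_sample(
    g: GenotypeMatrix,
    samples: pd.DataFrame,
    gen_path: str | Path,
    sample_path: str | Path,
) -> None:
    """Write Oxford GEN (5 metadata columns) + SAMPLE files.

    Dosages are expanded to the probability triple supported on the two
    adjacent genotypes, which reproduces the dosage exactly on re-read.
    The chromosome is encoded in the snp_id field as ``chr:pos``.
    """
    order = [s for s in g.sample_ids]
    tab = samples.set_index("sample_id").loc[order].reset_index()
    with open(gen_path, "w") as fh:
        for j in range(g.n_snps):
            m = g.snp_meta.iloc[j]
            fields = [
                f"{m['chromosome']}:{m['position']}",
                str(m["rsid"]),
                str(int(m["position"])),
                str(m["allele_A"]),
                str(m["allele_B"]),
            ]
            d = g.dosages[:, j]
            for x in d:
                if np.isnan(x):
                    fields += ["0", "0", "0"]
                else:
                    lo = int(np.floor(x))
                    frac = x - lo
                    probs = [0.0, 0.0, 0.0]
                    if lo == 2:
                        probs[2] = 1.0
                    else:
                        probs[lo] = 1.0 - frac
                        probs[lo + 1] = frac
                    fields += [f"{p:.6g}" for p in probs]
            fh.write(" ".join(fields) + "\n")

    cols = [c for c in tab.columns if c != "sample_id"]
    type_codes = []
    out_cols = {}
    for c in cols:
        col = tab[c]
        if c in ("event_date", "diagnosis_date"):
            out_cols[c] = pd.to_datetime(col).dt.strftime("%Y-%m-%d").fillna("NA")
            type_codes.append("D")
        elif pd.api.types.is_bool_dtype(col):
            out_cols[c] = col.astype(int).astype(str)
            type_codes.append("B")
        elif pd.api.types.is_numeric_dtype(col):
            out_cols[c] = col.map(lambda v: "NA" if pd.isna(v) else f"{v:.6g}")
            type_codes.append("C")
        else:
            out_cols[c] = col.astype(str).fillna("NA")
            type_codes.append("D")
    with open(sample_path, "w") as fh:
        fh.write(" ".join(["ID_1", "ID_2", "missing", *cols]) + "\n")
        fh.write(" ".join(["0", "0", "0", *type_codes]) + "\n")
        for i, sid in enumerate(order):
            row = [sid, sid, "0"] + [str(out_cols[c].iloc[i]) for c in cols]
            fh.write(" ".join(row) + "\n")


def read_gen_sample(
    gen_path: str | Path, sample_path: str | Path
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read Oxford GEN + SAMPLE into a GenotypeMatrix and sample table."""
    sample_ids: list[str] = []
    with open(sample_path) as fh:
        header = fh.readline().split()
        types = fh.readline().split()
        if len(header) < 3 or header[:3] != ["ID_1", "ID_2", "missing"]:
            raise FormatError(f"{sample_path}: not a SAMPLE file header")
        cols = header[3:]
        codes = types[3:]
        rows = []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3 + len(cols):
                raise FormatError(
                    f"{sample_path}: sample row has {len(parts)} fields, "
                    f"expected {3 + len(cols)}"
                )
            sample_ids.append(parts[0])
            rows.append(parts[3:])
    samples = pd.DataFrame(rows, columns=cols)
    samples.insert(0, "sample_id", sample_ids)
    samples = samples.replace("NA", np.nan)
    for c, code in zip(cols, codes):
        if code == "C":
            samples[c] = pd.to_numeric(samples[c])
        elif code == "B":
            samples[c] = pd.to_numeric(samples[c]).astype(bool)
    n = len(sample_ids)

    meta_rows = []
    dosage_rows = []
    with open(gen_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 5 + 3 * n:
                raise FormatError(
                    f"{gen_path}: line {lineno} has {len(parts)} fields, "
                    f"expected {5 + 3 * n} for {n} samples"
                )
            snp_id, rsid, pos, a, b = parts[:5]
            match = _SNPID_RE.match(snp_id)
            chrom = match.group(1) if match else "NA"
            probs = np.asarray(parts[5:], dtype=float).reshape(n, 3)
            dosage_rows.append(dosage_from_probs(probs[:, 0], probs[:, 1], probs[:, 2]))
            meta_rows.append(
                {
                    "snp_id": snp_id,
                    "rsid": rsid,
                    "chromosome": chrom,
                    "position": int(pos),
                    "allele_A": a,
                    "allele_B": b,
                    "info_score": np.nan,
                    "genotyped": True,
                }
            )
    if not meta_rows:
        raise FormatError(f"{gen_path}: no variant rows")
    g = GenotypeMatrix(
        sample_ids=sample_ids,
        snp_meta=pd.DataFrame(meta_rows),
        dosages=np.vstack(dosage_rows).T,
    )
    if "disease" in samples.columns:
        samples = validate_sample_table(samples)
    return g, samples
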