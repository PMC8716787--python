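"""Data containers, file I/O and quality control for case-control genotype data.

Genotypes are coded as minor-allele counts in {0, 1, 2} (PLINK additive
coding). A dedicated sentinel (:data:`MISSING`) marks missing calls so that a
genuine homozygous-major genotype of 0 is never confused with missingness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: out-of-band sentinel for a missing genotype call
MISSING: int = -1

__all__ = [
    "MISSING",
    "SnpInfo",
    "GenotypeMatrix",
    "PhenotypeVector",
    "GenePartition",
    "QcReport",
    "GenotypeDataError",
    "GeneDepletedError",
    "read_genotypes",
    "qc_filter",
    "impute_missing",
    "hwe_pvalue",
    "hwe_chi2_pvalue",
    "hwe_exact_pvalue",
    "minor_allele_freq",
    "write_tsv",
    "write_gene_map",
    "write_plink_raw",
]


class GenotypeDataError(ValueError):
    """Raised on malformed genotype input or violated preconditions."""


class GeneDepletedError(GenotypeDataError):
    """Raised when quality control removes every SNP of a gene."""


@dataclass(frozen=True)
class SnpInfo:
    """Metadata for one SNP: identity, gene assignment and optional map info."""

    snp_id: str
    gene_id: str
    chromosome: str | None = None
    position: int | None = None
    minor_allele_freq: float | None = None

    def __post_init__(self) -> None:
        if self.minor_allele_freq is not None and not (
            0.0 <= self.minor_allele_freq <= 0.5
        ):
            raise GenotypeDataError(
                f"MAF of {self.snp_id} must lie in [0, 0.5], got "
                f"{self.minor_allele_freq}"
            )


@dataclass
class GenotypeMatrix:
    """n x d matrix of minor-allele counts with per-column SNP metadata.

    Attributes
    ----------
    values
        Integer matrix with entries in {0, 1, 2} or :data:`MISSING`.
    snps
        Ordered SNP metadata, one entry per column.
    sample_ids
        Unique sample identifiers, one per row.
    """

    values: np.ndarray
    snps: list[SnpInfo]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise GenotypeDataError("genotype values must be a 2-D matrix")
        valid = np.isin(self.values, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.values[~valid])
            raise GenotypeDataError(
                f"genotype entries must be in {{0,1,2}} or missing; found {bad}"
            )
        if self.values.shape[1] != len(self.snps):
            raise GenotypeDataError(
                f"{self.values.shape[1]} columns but {len(self.snps)} SNP records"
            )
        if self.values.shape[0] != len(self.sample_ids):
            raise GenotypeDataError(
                f"{self.values.shape[0]} rows but {len(self.sample_ids)} sample ids"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GenotypeDataError("sample ids must be unique")
        if len({s.snp_id for s in self.snps}) != len(self.snps):
            raise GenotypeDataError("SNP ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def gene_ids(self) -> list[str]:
        return [s.gene_id for s in self.snps]

    def has_missing(self) -> bool:
        return bool((self.values == MISSING).any())

    def subset_snps(self, columns: Sequence[int]) -> "GenotypeMatrix":
        cols = list(columns)
        return GenotypeMatrix(
            values=self.values[:, cols].copy(),
            snps=[self.snps[c] for c in cols],
            sample_ids=list(self.sample_ids),
        )

    def subset_samples(self, rows: Sequence[int]) -> "GenotypeMatrix":
        idx = list(rows)
        return GenotypeMatrix(
            values=self.values[idx, :].copy(),
            snps=list(self.snps),
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass
class PhenotypeVector:
    """Binary case/control labels: 0 = control, 1 = case."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not np.isin(self.labels, (0, 1)).all():
            raise GenotypeDataError("phenotype labels must be 0 (control) or 1 (case)")

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return self.n - self.n_cases

    def subset(self, rows: Sequence[int]) -> "PhenotypeVector":
        return PhenotypeVector(self.labels[list(rows)])


@dataclass(frozen=True)
class GenePartition:
    """Disjoint column-index sets assigning each SNP to one of two genes.

    ``s1`` holds the p column indices of gene 1, ``s2`` the q indices of
    gene 2; together they must cover exactly the columns submitted to a test.
    """

    gene1_name: str
    gene2_name: str
    s1: tuple[int, ...]
    s2: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "s1", tuple(int(i) for i in self.s1))
        object.__setattr__(self, "s2", tuple(int(i) for i in self.s2))
        if len(self.s1) < 1 or len(self.s2) < 1:
            raise GenotypeDataError("each gene needs at least one SNP")
        if set(self.s1) & set(self.s2):
            raise GenotypeDataError(
                f"gene index sets overlap: {sorted(set(self.s1) & set(self.s2))}"
            )

    @property
    def p(self) -> int:
        return len(self.s1)

    @property
    def q(self) -> int:
        return len(self.s2)

    @property
    def n_features(self) -> int:
        return self.p + self.q

    def validate_against(self, n_columns: int) -> None:
        cover = sorted(self.s1 + self.s2)
        if cover != list(range(n_columns)):
            raise GenotypeDataError(
                "partition must cover every genotype column exactly once"
            )


@dataclass
class QcReport:
    """Outcome of SNP quality control: which SNPs were dropped and why."""

    n_input: int
    n_kept: int
    dropped: list[tuple[str, str]] = field(default_factory=list)
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def dropped_ids(self) -> list[str]:
        return [snp for snp, _ in self.dropped]

    def reasons(self) -> dict[str, str]:
        return dict(self.dropped)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_PLINK_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _read_gene_map(gene_map_path: str | Path) -> pd.DataFrame:
    gm = pd.read_csv(gene_map_path, sep="\t", dtype=str)
    required = {"snp_id", "gene_id"}
    if not required.issubset(gm.columns):
        raise GenotypeDataError(
            f"gene map must have columns {sorted(required)}; got {list(gm.columns)}"
        )
    if gm["snp_id"].duplicated().any():
        dup = gm.loc[gm["snp_id"].duplicated(), "snp_id"].tolist()
        raise GenotypeDataError(f"gene map assigns SNPs more than once: {dup}")
    return gm


def _strip_allele_suffix(name: str) -> str:
    """PLINK .raw appends the counted allele to the SNP name (rs123_A)."""
    if "_" in name:
        return name.rsplit("_", 1)[0]
    return name


def _snp_records(
    snp_ids: Sequence[str], gene_map: pd.DataFrame, values: np.ndarray
) -> list[SnpInfo]:
    gm = gene_map.set_index("snp_id")
    missing = [s for s in snp_ids if s not in gm.index]
    if missing:
        raise GenotypeDataError(f"SNPs absent from gene map: {missing}")
    records = []
    for j, sid in enumerate(snp_ids):
        row = gm.loc[sid]
        chrom = row.get("chromosome")
        pos = row.get("position")
        records.append(
            SnpInfo(
                snp_id=sid,
                gene_id=str(row["gene_id"]),
                chromosome=None if pd.isna(chrom) else str(chrom),
                position=None if pd.isna(pos) else int(pos),
                minor_allele_freq=minor_allele_freq(values[:, j]),
            )
        )
    return records


def _partition_from_snps(snps: Sequence[SnpInfo]) -> GenePartition:
    genes: dict[str, list[int]] = {}
    for j, s in enumerate(snps):
        genes.setdefault(s.gene_id, []).append(j)
    if len(genes) != 2:
        raise GenotypeDataError(
            f"expected exactly 2 genes for a pair test, got {len(genes)}: "
            f"{sorted(genes)}"
        )
    (g1, s1), (g2, s2) = genes.items()
    return GenePartition(gene1_name=g1, gene2_name=g2, s1=tuple(s1), s2=tuple(s2))


def read_genotypes(
    geno_path: str | Path,
    format: str,
    gene_map_path: str | Path,
    label_column: str = "label",
    require_pair: bool = True,
) -> tuple[GenotypeMatrix, PhenotypeVector, GenePartition | None]:
    """Load genotypes, phenotype and the two-gene partition from disk.

    Parameters
    ----------
    geno_path
        Genotype file. ``plink_raw`` expects the PLINK ``--recode A`` layout
        (header ``FID IID PAT MAT SEX PHENOTYPE`` then one column per SNP,
        additive 0/1/2 coding, ``NA`` for missing, phenotype coded 1/2).
        ``tsv`` expects a ``sample_id`` column, one column per SNP and a
        binary ``label`` column.
    format
        ``"plink_raw"`` or ``"tsv"``.
    gene_map_path
        TSV with columns ``snp_id``, ``gene_id`` (optionally ``chromosome``,
        ``position``) assigning every genotype column to exactly one gene.
    require_pair
        When true (default) the gene map must define exactly two genes and
        the two-gene partition is returned; screening workflows covering
        more genes pass ``False`` and receive ``None`` in its place.
    """
    gene_map = _read_gene_map(gene_map_path)
    if format == "plink_raw":
        df = pd.read_csv(geno_path, sep=r"\s+")
        missing_meta = [c for c in _PLINK_META_COLS if c not in df.columns]
        if missing_meta:
            raise GenotypeDataError(
                f"PLINK .raw file lacks columns {missing_meta}"
            )
        snp_cols = [c for c in df.columns if c not in _PLINK_META_COLS]
        sample_ids = df["IID"].astype(str).tolist()
        pheno_raw = df["PHENOTYPE"].to_numpy()
        if not np.isin(pheno_raw, (1, 2)).all():
            raise GenotypeDataError("PLINK PHENOTYPE must be coded 1 (control)/2 (case)")
        labels = (pheno_raw == 2).astype(np.int64)
        values = df[snp_cols].to_numpy(dtype=float)
        snp_ids = [_strip_allele_suffix(c) for c in snp_cols]
    elif format == "tsv":
        df = pd.read_csv(geno_path, sep="\t")
        if "sample_id" not in df.columns:
            raise GenotypeDataError("TSV genotype file needs a sample_id column")
        if label_column not in df.columns:
            raise GenotypeDataError(f"TSV genotype file needs a {label_column!r} column")
        sample_ids = df["sample_id"].astype(str).tolist()
        labels = df[label_column].to_numpy()
        snp_ids = [c for c in df.columns if c not in ("sample_id", label_column)]
        values = df[snp_ids].to_numpy(dtype=float)
    else:
        raise GenotypeDataError(f"unknown genotype format {format!r}")

    ivals = np.full(values.shape, MISSING, dtype=np.int8)
    finite = ~np.isnan(values)
    ivals[finite] = values[finite].astype(np.int8)
    geno = GenotypeMatrix(values=ivals, snps=_snp_records(snp_ids, gene_map, ivals),
                          sample_ids=sample_ids)
    pheno = PhenotypeVector(labels)
    partition = _partition_from_snps(geno.snps) if require_pair else None
    return geno, pheno, partition


def write_tsv(
    geno: GenotypeMatrix,
    pheno: PhenotypeVector,
    path: str | Path,
    label_column: str = "label",
) -> None:
    """Write the plain TSV genotype dialect (inverse of ``read_genotypes``)."""
    df = pd.DataFrame(geno.values.astype(float), columns=geno.snp_ids)
    df = df.mask(df == MISSING)
    df = df.astype("Int64")
    df.insert(0, "sample_id", geno.sample_ids)
    df[label_column] = pheno.labels
    df.to_csv(path, sep="\t", index=False)


def write_gene_map(snps: Sequence[SnpInfo], path: str | Path) -> None:
    rows = [
        {
            "snp_id": s.snp_id,
            "gene_id": s.gene_id,
            "chromosome": s.chromosome,
            "position": s.position,
        }
        for s in snps
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_plink_raw(
    geno: GenotypeMatrix, pheno: PhenotypeVector, path: str | Path
) -> None:
    """Write PLINK ``--recode A`` style .raw output (phenotype coded 1/2).

    Column names carry the counted-allele suffix (``snp_A``) as PLINK does;
    ``read_genotypes`` strips it back off.
    """
    df = pd.DataFrame(
        geno.values.astype(float), columns=[f"{s}_A" for s in geno.snp_ids]
    )
    df = df.mask(df == MISSING).astype("Int64")
    out = pd.DataFrame(
        {
            "FID": geno.sample_ids,
            "IID": geno.sample_ids,
            "PAT": 0,
            "MAT": 0,
            "SEX": 0,
            "PHENOTYPE": pheno.labels + 1,
        }
    )
    out = pd.concat([out, df], axis=1)
    out.to_csv(path, sep=" ", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def minor_allele_freq(column: np.ndarray) -> float | None:
    """Minor-allele frequency over non-missing entries of one genotype column."""
    obs = column[column != MISSING]
    if obs.size == 0:
        return None
    f = float(obs.mean()) / 2.0
    return min(f, 1.0 - f)


def _genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    obs = column[column != MISSING]
    return (
        int((obs == 0).sum()),
        int((obs == 1).sum()),
        int((obs == 2).sum()),
    )


def hwe_chi2_pvalue(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Asymptotic 1-df chi-square test of Hardy-Weinberg equilibrium."""
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        return 1.0
    f = (n_het + 2 * n_hom_minor) / (2 * n)
    expected = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2]) * n
    observed = np.array([n_hom_major, n_het, n_hom_minor], dtype=float)
    if np.any(expected == 0):
        # monomorphic: trivially in equilibrium
        return 1.0
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_exact_pvalue(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact Hardy-Weinberg test conditional on the observed allele counts.

    Sums the probabilities of all heterozygote counts compatible with the
    observed minor-allele total whose conditional probability does not exceed
    that of the observed configuration (the standard SNP-HWE construction).
    """
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        return 1.0
    n_minor = n_het + 2 * n_hom_minor
    n_minor = min(n_minor, 2 * n - n_minor)  # work with the rarer allele
    obs_het = n_het

    # log P(het = h | allele counts) up to a common constant
    def log_weight(h: int) -> float:
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        return (
            h * math.log(2)
            - math.lgamma(h + 1)
            - math.lgamma(hom_min + 1)
            - math.lgamma(hom_maj + 1)
        )

    hets = [h for h in range(n_minor % 2, n_minor + 1, 2) if n - h - (n_minor - h) // 2 >= 0]
    logs = np.array([log_weight(h) for h in hets])
    weights = np.exp(logs - logs.max())
    probs = weights / weights.sum()
    obs_idx = hets.index(obs_het if obs_het in hets else min(hets, key=lambda h: abs(h - obs_het)))
    p = float(probs[probs <= probs[obs_idx] * (1 + 1e-12)].sum())
    return min(p, 1.0)


def hwe_pvalue(
    n_hom_major: int, n_het: int, n_hom_minor: int, method: str = "auto"
) -> float:
    """HWE p-value; ``auto`` uses chi-square unless an expected cell is < 5."""
    if method == "chi2":
        return hwe_chi2_pvalue(n_hom_major, n_het, n_hom_minor)
    if method == "exact":
        return hwe_exact_pvalue(n_hom_major, n_het, n_hom_minor)
    if method != "auto":
        raise GenotypeDataError(f"unknown HWE method {method!r}")
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        return 1.0
    f = (n_het + 2 * n_hom_minor) / (2 * n)
    expected = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2]) * n
    if (expected < 5).any():
        return hwe_exact_pvalue(n_hom_major, n_het, n_hom_minor)
    return hwe_chi2_pvalue(n_hom_major, n_het, n_hom_minor)


def qc_filter(
    geno: GenotypeMatrix,
    pheno: PhenotypeVector,
    max_missing_rate: float = 0.10,
    min_maf: float = 0.05,
    hwe_alpha: float = 1e-4,
    hwe_method: str = "auto",
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop SNPs failing missingness, MAF or control-sample HWE filters.

    A SNP is removed when its missing rate is >= ``max_missing_rate``, its
    minor-allele frequency (over non-missing calls) is <= ``min_maf``, or the
    Hardy-Weinberg test computed on control samples only has p < ``hwe_alpha``.
    Each dropped SNP is reported with the first rule that triggered, checked
    in that order.
    """
    if pheno.n != geno.n_samples:
        raise GenotypeDataError("phenotype length does not match genotype rows")
    controls = geno.values[pheno.labels == 0, :]
    keep: list[int] = []
    dropped: list[tuple[str, str]] = []
    for j, snp in enumerate(geno.snps):
        col = geno.values[:, j]
        miss_rate = float((col == MISSING).mean())
        if miss_rate >= max_missing_rate:
            dropped.append((snp.snp_id, "missing_rate"))
            continue
        maf = minor_allele_freq(col)
        if maf is None or maf <= min_maf:
            dropped.append((snp.snp_id, "maf"))
            continue
        counts = _genotype_counts(controls[:, j])
        if hwe_pvalue(*counts, method=hwe_method) < hwe_alpha:
            dropped.append((snp.snp_id, "hwe"))
            continue
        keep.append(j)

    report = QcReport(
        n_input=geno.n_snps,
        n_kept=len(keep),
        dropped=dropped,
        thresholds={
            "max_missing_rate": max_missing_rate,
            "min_maf": min_maf,
            "hwe_alpha": hwe_alpha,
        },
    )
    filtered = geno.subset_snps(keep)
    surviving_genes = set(filtered.gene_ids)
    for gene in set(geno.gene_ids) - surviving_genes:
        raise GeneDepletedError(
            f"quality control removed every SNP of gene {gene!r}; pair untestable"
        )
    # refresh per-SNP MAF metadata after filtering
    filtered.snps = [
        replace(s, minor_allele_freq=minor_allele_freq(filtered.values[:, j]))
        for j, s in enumerate(filtered.snps)
    ]
    return filtered, report


def impute_missing(geno: GenotypeMatrix, strategy: str = "mode") -> GenotypeMatrix:
    """Resolve missing genotypes by per-SNP mode imputation or sample removal."""
    if strategy == "mode":
        values = geno.values.copy()
        for j in range(geno.n_snps):
            col = values[:, j]
            mask = col == MISSING
            if not mask.any():
                continue
            obs = col[~mask]
            if obs.size == 0:
                raise GenotypeDataError(
                    f"SNP {geno.snps[j].snp_id} has no observed genotypes to impute from"
                )
            counts = np.bincount(obs, minlength=3)
            col[mask] = int(np.argmax(counts))
        return GenotypeMatrix(values=values, snps=list(geno.snps),
                              sample_ids=list(geno.sample_ids))
    if strategy == "drop_sample":
        complete = ~(geno.values == MISSING).any(axis=1)
        return geno.subset_samples(np.flatnonzero(complete))
    raise GenotypeDataError(f"unknown imputation strategy {strategy!r}")
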