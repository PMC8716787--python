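"""Semi-empirical case-control simulator with two-locus penetrance models.

Genotypes are produced by resampling a phased haplotype pool — each
individual is the sum of two haplotypes drawn uniformly with replacement —
so the simulated data inherit the pool's local linkage-disequilibrium (LD)
structure. Disease status is assigned through a 3x3 penetrance table over the
genotypes of one causal SNP per gene: cell odds are gamma * (1+theta)^e(g1,g2)
with a model-specific integer exponent mask e, and the baseline odds gamma is
solved so the population prevalence matches its target.

The built-in pool generator emulates a small reference panel (default 90
haplotypes) with two gene blocks of 6 and 7 SNPs, the first in strong LD and
the second in weak LD, and minor-allele frequencies drawn from 0.2-0.4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .genotype_data import (
    GenePartition,
    GenotypeMatrix,
    PhenotypeVector,
    SnpInfo,
    write_gene_map,
    write_plink_raw,
)

__all__ = [
    "HaplotypePool",
    "PenetranceModel",
    "SimulatedDataset",
    "MODEL_EXPONENTS",
    "MODEL_NAMES",
    "SimulationError",
    "synth_haplotype_pool",
    "genotypes_from_pool",
    "causal_genotype_probs",
    "build_penetrance",
    "sample_case_control",
    "write_dataset",
]


class SimulationError(RuntimeError):
    """Raised on infeasible simulation settings."""


# ---------------------------------------------------------------------------
# haplotype pool
# ---------------------------------------------------------------------------


@dataclass
class HaplotypePool:
    """H x L matrix of phased binary haplotypes with a two-gene block map."""

    alleles: np.ndarray
    snps: list[SnpInfo]
    gene_blocks: GenePartition

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] < 2:
            raise SimulationError("haplotype pool needs >= 2 haplotypes")
        if not np.isin(self.alleles, (0, 1)).all():
            raise SimulationError("haplotype alleles must be binary")
        freqs = self.allele_freqs
        if np.any(freqs <= 0) or np.any(freqs > 0.5):
            raise SimulationError(
                "per-SNP minor-allele frequency must lie in (0, 0.5]"
            )

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    @property
    def allele_freqs(self) -> np.ndarray:
        return self.alleles.mean(axis=0)


def _binary_corr_from_latent(rho: float, q1: float, q2: float) -> float:
    """Pearson correlation of two latent-Gaussian-thresholded Bernoullis."""
    t1, t2 = stats.norm.ppf(1 - q1), stats.norm.ppf(1 - q2)
    # P(Z1 > t1, Z2 > t2) under correlation rho
    p11 = stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf(
        [-t1, -t2]
    )
    denom = np.sqrt(q1 * (1 - q1) * q2 * (1 - q2))
    return float((p11 - q1 * q2) / denom)


def _latent_rho(target_r: float, q1: float, q2: float) -> float:
    """Latent Gaussian correlation reproducing the target binary correlation."""
    if target_r <= 0:
        return 0.0
    hi = 0.999
    r_max = _binary_corr_from_latent(hi, q1, q2)
    if target_r >= r_max:
        if abs(q1 - q2) < 1e-12:
            return 1.0  # complete LD achievable only with equal frequencies
        raise SimulationError(
            f"target correlation {target_r:.3f} infeasible for MAFs "
            f"{q1:.3f}/{q2:.3f} (max {r_max:.3f})"
        )
    return float(
        optimize.brentq(
            lambda r: _binary_corr_from_latent(r, q1, q2) - target_r, 0.0, hi
        )
    )


def synth_haplotype_pool(
    n_haplotypes: int = 90,
    blocks: Sequence[tuple[int, float]] = ((6, 0.7), (7, 0.15)),
    target_mafs: Sequence[float] | None = None,
    seed: int = 0,
    gene_names: Sequence[str] = ("GENE1", "GENE2"),
) -> HaplotypePool:
    """Generate a synthetic haplotype pool with block-wise LD.

    Each block is an AR(1) latent Gaussian whose adjacent-SNP correlation is
    chosen so the binary haplotype r^2 approximates the block's target;
    latent values are thresholded at each SNP's empirical MAF quantile, which
    pins the realized pool MAF to the target within rounding (1/(2H)).

    ``blocks`` lists (n_snps, within-block adjacent r^2) per gene; exactly
    two blocks are mapped to two genes. Default: a 6-SNP strong-LD gene and a
    7-SNP weak-LD gene (emulating a pair of unlinked genes, one with a much
    tighter LD pattern than the other). Default MAFs stay within 0.2-0.4,
    jittered around a per-block base frequency; the jitter shrinks with the
    LD target, because strong binary LD is only attainable between loci of
    similar frequency.
    """
    if len(blocks) != 2:
        raise SimulationError("exactly two gene blocks are required")
    rng = np.random.default_rng(seed)
    n_total = sum(b[0] for b in blocks)
    if target_mafs is None:
        drawn = []
        for n_snps, r2 in blocks:
            base = rng.uniform(0.25, 0.35)
            jitter = rng.uniform(-1, 1, size=n_snps) * 0.1 * (1 - r2)
            drawn.append(np.clip(base + jitter, 0.2, 0.4))
        target_mafs = np.concatenate(drawn)
    target_mafs = np.asarray(target_mafs, dtype=float)
    if target_mafs.shape[0] != n_total:
        raise SimulationError("one target MAF per SNP is required")
    if np.any(target_mafs <= 0) or np.any(target_mafs > 0.5):
        raise SimulationError("target MAFs must lie in (0, 0.5]")

    columns: list[np.ndarray] = []
    snps: list[SnpInfo] = []
    s_lists: list[list[int]] = []
    col_idx = 0
    for b, ((n_snps, r2), gene) in enumerate(zip(blocks, gene_names)):
        if not 0.0 <= r2 <= 1.0:
            raise SimulationError("within-block r^2 must lie in [0, 1]")
        target_r = float(np.sqrt(r2))
        s_lists.append(list(range(col_idx, col_idx + n_snps)))
        latent_prev: np.ndarray | None = None
        for j in range(n_snps):
            maf = float(target_mafs[col_idx])
            if latent_prev is None or target_r == 0.0:
                latent = rng.standard_normal(n_haplotypes)
            else:
                prev_maf = float(target_mafs[col_idx - 1])
                rho = _latent_rho(target_r, prev_maf, maf)
                if rho >= 1.0:
                    latent = latent_prev.copy()
                else:
                    latent = rho * latent_prev + np.sqrt(1 - rho**2) * rng.standard_normal(
                        n_haplotypes
                    )
            # empirical-quantile threshold: exactly k minor alleles
            k = max(1, int(round(maf * n_haplotypes)))
            k = min(k, n_haplotypes // 2)
            col = np.zeros(n_haplotypes, dtype=np.uint8)
            col[np.argsort(latent)[-k:]] = 1
            columns.append(col)
            snps.append(
                SnpInfo(
                    snp_id=f"G{b + 1}_snp{j + 1}",
                    gene_id=gene,
                    minor_allele_freq=k / n_haplotypes,
                )
            )
            latent_prev = latent
            col_idx += 1

    partition = GenePartition(
        gene1_name=gene_names[0],
        gene2_name=gene_names[1],
        s1=tuple(s_lists[0]),
        s2=tuple(s_lists[1]),
    )
    return HaplotypePool(
        alleles=np.column_stack(columns), snps=snps, gene_blocks=partition
    )


def genotypes_from_pool(pool: HaplotypePool, n: int, seed: int = 0) -> GenotypeMatrix:
    """Draw n diploid genotypes: sums of two uniform haplotype draws.

    Expected genotype frequencies at each SNP are the Hardy-Weinberg products
    of the pool's haplotype allele frequencies.
    """
    if n < 1:
        raise SimulationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, pool.n_haplotypes, size=(n, 2))
    values = (pool.alleles[idx[:, 0]] + pool.alleles[idx[:, 1]]).astype(np.int8)
    return GenotypeMatrix(
        values=values,
        snps=list(pool.snps),
        sample_ids=[f"S{i}" for i in range(n)],
    )


# ---------------------------------------------------------------------------
# two-locus penetrance models
# ---------------------------------------------------------------------------


def _mask(pred) -> np.ndarray:
    g1, g2 = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
    return pred(g1, g2).astype(int)


#: integer exponent masks e(g1, g2): cell odds are gamma * (1 + theta) ** e.
MODEL_EXPONENTS: dict[str, np.ndarray] = {
    # risk requires two minor alleles at locus 1 and at least one at locus 2
    "recessive_dominant": _mask(lambda a, b: (a == 2) & (b >= 1)),
    # risk requires a carrier at both loci
    "dominant_dominant": _mask(lambda a, b: (a >= 1) & (b >= 1)),
    # risk when exactly one locus carries a minor allele
    "xor": _mask(lambda a, b: (a >= 1) ^ (b >= 1)),
    # risk once the total minor-allele count reaches two
    "threshold": _mask(lambda a, b: (a + b) >= 2),
    # one odds factor per carrier locus, amplifying jointly
    "multiplicative": _mask(lambda a, b: (a >= 1).astype(int) + (b >= 1)),
    # risk only for the double minor-homozygote (aabb)
    "recessive_recessive": _mask(lambda a, b: (a == 2) & (b == 2)),
}

MODEL_NAMES = tuple(MODEL_EXPONENTS)


@dataclass
class PenetranceModel:
    """Solved two-locus disease model.

    ``odds_table[g1, g2]`` is the disease odds of genotype combination
    (g1, g2); ``penetrance_table`` the corresponding case probability
    odds/(1+odds). ``gamma`` (the odds of the no-risk genotype) is solved so
    the model's population prevalence equals ``prevalence``.
    """

    model: str
    theta: float
    prevalence: float
    gamma: float
    exponent_table: np.ndarray
    odds_table: np.ndarray
    penetrance_table: np.ndarray
    genotype_probs: np.ndarray

    @property
    def odds_ratio(self) -> float:
        return 1.0 + self.theta

    def population_prevalence(self) -> float:
        return float((self.penetrance_table * self.genotype_probs).sum())


def causal_genotype_probs(
    pool: HaplotypePool, causal_pair: tuple[int, int]
) -> np.ndarray:
    """3x3 joint genotype probabilities of the causal pair under pool resampling.

    The two genes segregate independently, so the joint law is the product of
    the per-locus Hardy-Weinberg marginals at the pool's realized allele
    frequencies.
    """
    probs = []
    for snp in causal_pair:
        f = float(pool.allele_freqs[snp])
        probs.append(np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2]))
    return np.outer(probs[0], probs[1])


def build_penetrance(
    model: str,
    theta: float,
    prevalence: float,
    genotype_probs: np.ndarray,
    exponent_table: np.ndarray | None = None,
) -> PenetranceModel:
    """Solve the baseline odds gamma and assemble the penetrance tables.

    The population prevalence Sum_g penetrance(g) * Pr(g) is strictly
    increasing in gamma, so a bracketed root solve recovers gamma to a
    prevalence error below 1e-10. With theta = 0 (odds ratio 1) the closed
    form gamma = p / (1 - p) is returned exactly and every cell's penetrance
    equals the prevalence.
    """
    if exponent_table is None:
        if model not in MODEL_EXPONENTS:
            raise SimulationError(
                f"unknown model {model!r}; choose from {MODEL_NAMES} "
                "or supply exponent_table"
            )
        exponent_table = MODEL_EXPONENTS[model]
    exponent_table = np.asarray(exponent_table, dtype=float)
    if exponent_table.shape != (3, 3):
        raise SimulationError("exponent_table must be 3x3")
    genotype_probs = np.asarray(genotype_probs, dtype=float)
    if genotype_probs.shape != (3, 3) or abs(genotype_probs.sum() - 1) > 1e-8:
        raise SimulationError("genotype_probs must be a 3x3 distribution")
    if theta < 0:
        raise SimulationError("theta must be >= 0")
    if not 0 < prevalence < 1:
        raise SimulationError("prevalence must lie in (0, 1)")

    factor = (1.0 + theta) ** exponent_table

    def prev_of(gamma: float) -> float:
        odds = gamma * factor
        return float((odds / (1 + odds) * genotype_probs).sum())

    if theta == 0 or not exponent_table.any():
        gamma = prevalence / (1 - prevalence)
    else:
        lo, hi = prevalence * 1e-6, 1.0
        if prev_of(hi) < prevalence:  # pragma: no cover - prevalence < 0.5 always fits
            hi = 1e6
        try:
            gamma = float(
                optimize.brentq(
                    lambda g: prev_of(g) - prevalence, lo, hi,
                    xtol=1e-300, rtol=8.9e-16, maxiter=500,
                )
            )
        except ValueError as exc:
            raise SimulationError(
                f"gamma solve failed on bracket [{lo}, {hi}]: {exc}"
            ) from exc
        if abs(prev_of(gamma) - prevalence) >= 1e-10:
            raise SimulationError(
                f"gamma solver did not reach tolerance on bracket [{lo}, {hi}]"
            )
    odds = gamma * factor
    penetrance = odds / (1 + odds)
    return PenetranceModel(
        model=model,
        theta=float(theta),
        prevalence=float(prevalence),
        gamma=float(gamma),
        exponent_table=exponent_table,
        odds_table=odds,
        penetrance_table=penetrance,
        genotype_probs=genotype_probs,
    )


# ---------------------------------------------------------------------------
# case-control sampling
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    geno: GenotypeMatrix
    pheno: PhenotypeVector
    truth: dict = field(default_factory=dict)


def sample_case_control(
    pool: HaplotypePool,
    model: PenetranceModel,
    causal_pair: tuple[int, int],
    n_cases: int,
    n_controls: int,
    seed: int = 0,
    max_draws: int = 10**7,
) -> SimulatedDataset:
    """Rejection-sample a balanced-or-not case-control dataset.

    Individuals are drawn from the pool; each becomes a case with probability
    ``penetrance_table[g1, g2]`` at the causal pair and is kept while its
    quota (case or control) is unfilled. ``max_draws`` caps total draws so an
    unreachable quota (e.g. tiny prevalence with a huge case quota, or a
    degenerate penetrance of 1 with a control quota) fails loudly.
    """
    c1, c2 = causal_pair
    gene_of = {i: 1 for i in pool.gene_blocks.s1}
    gene_of.update({i: 2 for i in pool.gene_blocks.s2})
    if gene_of.get(c1) == gene_of.get(c2):
        raise SimulationError("causal SNPs must belong to different genes")
    if n_cases < 1 or n_controls < 1:
        raise SimulationError("need at least one case and one control")

    rng = np.random.default_rng(seed)
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    draws = 0
    batch = max(1024, 2 * (n_cases + n_controls))
    while len(cases) < n_cases or len(controls) < n_controls:
        if draws >= max_draws:
            raise SimulationError(
                f"attempt cap {max_draws} exceeded with "
                f"{len(cases)}/{n_cases} cases and "
                f"{len(controls)}/{n_controls} controls"
            )
        take = min(batch, max_draws - draws)
        idx = rng.integers(0, pool.n_haplotypes, size=(take, 2))
        geno = (pool.alleles[idx[:, 0]] + pool.alleles[idx[:, 1]]).astype(np.int8)
        pen = model.penetrance_table[geno[:, c1], geno[:, c2]]
        is_case = rng.random(take) < pen
        draws += take
        for row, case in zip(geno, is_case):
            if case and len(cases) < n_cases:
                cases.append(row)
            elif not case and len(controls) < n_controls:
                controls.append(row)

    values = np.vstack(cases + controls)
    labels = np.concatenate(
        [np.ones(n_cases, dtype=np.int64), np.zeros(n_controls, dtype=np.int64)]
    )
    order = np.random.default_rng(seed + 1).permutation(values.shape[0])
    geno = GenotypeMatrix(
        values=values[order],
        snps=list(pool.snps),
        sample_ids=[f"S{i}" for i in range(values.shape[0])],
    )
    pheno = PhenotypeVector(labels[order])
    truth = {
        "model": model.model,
        "theta": model.theta,
        "odds_ratio": model.odds_ratio,
        "prevalence": model.prevalence,
        "gamma": model.gamma,
        "causal_snp_1": pool.snps[c1].snp_id,
        "causal_snp_2": pool.snps[c2].snp_id,
        "causal_pair": (int(c1), int(c2)),
        "seed": int(seed),
        "n_draws": int(draws),
    }
    return SimulatedDataset(geno=geno, pheno=pheno, truth=truth)


def write_dataset(dataset: SimulatedDataset, outdir: str | Path, basename: str) -> dict:
    """Write PLINK .raw genotypes, the gene map TSV and the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "raw": outdir / f"{basename}.raw",
        "gene_map": outdir / f"{basename}.genes.tsv",
        "truth": outdir / f"{basename}.truth.json",
    }
    write_plink_raw(dataset.geno, dataset.pheno, paths["raw"])
    write_gene_map(dataset.geno.snps, paths["gene_map"])
    with open(paths["truth"], "w") as fh:
        json.dump(dataset.truth, fh, indent=2)
    return {k: str(v) for k, v in paths.items()}
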