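"""Permutation null distribution, p-values, and all-pairs gene screening.

The null distribution of the relative-error statistic is estimated by
shuffling the case/control labels m times and re-running the full paired
cross-validation (fresh label-stratified folds on each permuted labelling).
The p-value is the fraction of permuted statistics at least as large as the
observed one — an estimator that can legitimately return 0.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from statsmodels.stats.multitest import multipletests

from .boosted_additivity import BoostConfig, delta_err, make_folds
from .genotype_data import GenePartition, GenotypeMatrix, PhenotypeVector

__all__ = [
    "InteractionTestResult",
    "ScreenResult",
    "pvalue_from_deltas",
    "permutation_pvalue",
    "enumerate_gene_pairs",
    "screen_pairs",
    "pair_seed",
]

_SEED_MOD = 2**31


@dataclass
class InteractionTestResult:
    """Observed statistic, permutation null sample, and the resulting p-value."""

    gene1: str
    gene2: str
    delta_err0: float
    perm_deltas: list[float]
    m: int
    p_value: float
    seed: int
    config_snapshot: BoostConfig
    err_orig0: float = math.nan
    err_cons0: float = math.nan

    def to_dict(self) -> dict:
        return {
            "gene1": self.gene1,
            "gene2": self.gene2,
            "delta_err0": self.delta_err0,
            "err_orig0": self.err_orig0,
            "err_cons0": self.err_cons0,
            "m": self.m,
            "p_value": self.p_value,
            "seed": self.seed,
            "perm_deltas": list(self.perm_deltas),
        }


@dataclass
class ScreenResult:
    """Per-pair outcomes of an all-pairs (or listed-pairs) interaction screen."""

    rows: pd.DataFrame
    alpha: float
    adjust: str = "none"
    results: list[InteractionTestResult] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        payload = {
            "alpha": self.alpha,
            "adjust": self.adjust,
            "pairs": [r.to_dict() for r in self.results],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def pvalue_from_deltas(
    delta0: float, perm_deltas: Sequence[float], conservative: bool = False
) -> float:
    """Fraction of permuted statistics >= the observed one.

    Ties count toward the numerator. The default estimator is count/m and can
    return 0; ``conservative`` switches to (count+1)/(m+1), which cannot.
    """
    m = len(perm_deltas)
    if m < 1:
        raise ValueError("need at least one permutation")
    count = sum(1 for d in perm_deltas if d >= delta0)
    if conservative:
        return (count + 1) / (m + 1)
    return count / m


def _derive_seeds(seed: int, m: int) -> np.ndarray:
    """Pre-assigned per-permutation seeds, stable and below 2**31."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(m + 1, dtype=np.uint64) % _SEED_MOD


def _one_permutation(
    X: np.ndarray,
    y: np.ndarray,
    partition: GenePartition,
    config: BoostConfig,
    perm_seed: int,
) -> float:
    rng = np.random.default_rng(perm_seed)
    y_perm = y[rng.permutation(y.shape[0])]
    cfg = config.with_seed(int(perm_seed))
    folds = make_folds(y_perm, cfg.n_folds, cfg.seed)
    return delta_err(X, y_perm, partition, cfg, folds=folds).delta_err


def permutation_pvalue(
    geno: GenotypeMatrix | np.ndarray,
    pheno: PhenotypeVector | np.ndarray,
    partition: GenePartition,
    config: BoostConfig,
    m: int = 1000,
    seed: int = 0,
    n_jobs: int = 1,
    conservative: bool = False,
) -> InteractionTestResult:
    """Full permutation test for one gene pair.

    The observed statistic is computed on the given labels; each of the m
    permutations shuffles the labels with its own pre-assigned seed and
    re-runs the identical paired-CV procedure (folds re-stratified on the
    permuted labels). Results are reproducible from ``seed`` and independent
    of ``n_jobs``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    X = geno.values.astype(np.float32) if isinstance(geno, GenotypeMatrix) else np.asarray(geno, dtype=np.float32)
    y = np.asarray(pheno.labels if isinstance(pheno, PhenotypeVector) else pheno)
    if np.unique(y).size < 2:
        raise ValueError("labels are degenerate (single class)")
    seeds = _derive_seeds(seed, m)
    cfg0 = config.with_seed(int(seeds[0]))
    folds0 = make_folds(y, cfg0.n_folds, cfg0.seed)
    observed = delta_err(X, y, partition, cfg0, folds=folds0)
    if n_jobs == 1:
        perm = [
            _one_permutation(X, y, partition, config, int(s)) for s in seeds[1:]
        ]
    else:
        perm = Parallel(n_jobs=n_jobs)(
            delayed(_one_permutation)(X, y, partition, config, int(s))
            for s in seeds[1:]
        )
    p = pvalue_from_deltas(observed.delta_err, perm, conservative=conservative)
    return InteractionTestResult(
        gene1=partition.gene1_name,
        gene2=partition.gene2_name,
        delta_err0=observed.delta_err,
        perm_deltas=list(perm),
        m=m,
        p_value=p,
        seed=seed,
        config_snapshot=config,
        err_orig0=observed.err_orig,
        err_cons0=observed.err_cons,
    )


def enumerate_gene_pairs(genes: Sequence[str]) -> list[tuple[str, str]]:
    """All C(G, 2) unordered gene pairs, in sorted-name order."""
    unique = sorted(set(genes))
    if len(unique) != len(genes):
        raise ValueError("gene names must be unique")
    return list(combinations(unique, 2))


def pair_seed(master_seed: int, gene1: str, gene2: str) -> int:
    """Deterministic per-pair seed from the master seed and sorted gene names."""
    a, b = sorted((gene1, gene2))
    digest = hashlib.sha256(f"{master_seed}:{a}:{b}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % _SEED_MOD


def screen_pairs(
    geno: GenotypeMatrix,
    pheno: PhenotypeVector,
    pairs: Sequence[tuple[str, str]] | str,
    config: BoostConfig,
    m: int = 1000,
    alpha: float = 0.01,
    adjust: str = "none",
    seed: int = 0,
    n_jobs: int = 1,
) -> ScreenResult:
    """Run the permutation test on every requested gene pair.

    ``pairs="all"`` enumerates every unordered pair among the genes present
    in the genotype matrix. Each pair is tested on the submatrix of its SNPs
    with a seed derived from the master seed and the pair's sorted names, so
    the screen is reproducible regardless of execution order.
    """
    gene_cols: dict[str, list[int]] = {}
    for j, g in enumerate(geno.gene_ids):
        gene_cols.setdefault(g, []).append(j)
    if pairs == "all":
        pair_list = enumerate_gene_pairs(list(gene_cols))
    else:
        pair_list = [tuple(p) for p in pairs]
        if len(set(map(tuple, map(sorted, pair_list)))) != len(pair_list):
            raise ValueError("duplicate pair in explicit pair list")
        for g1, g2 in pair_list:
            for g in (g1, g2):
                if g not in gene_cols:
                    raise ValueError(f"unknown gene {g!r}")
    if adjust not in ("none", "bh"):
        raise ValueError("adjust must be 'none' or 'bh'")

    results: list[InteractionTestResult] = []
    for g1, g2 in pair_list:
        cols = gene_cols[g1] + gene_cols[g2]
        sub = geno.subset_snps(cols)
        partition = GenePartition(
            gene1_name=g1,
            gene2_name=g2,
            s1=tuple(range(len(gene_cols[g1]))),
            s2=tuple(range(len(gene_cols[g1]), len(cols))),
        )
        results.append(
            permutation_pvalue(
                sub, pheno, partition, config,
                m=m, seed=pair_seed(seed, g1, g2), n_jobs=n_jobs,
            )
        )

    pvals = np.array([r.p_value for r in results])
    if adjust == "bh":
        significant = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    else:
        significant = pvals < alpha
    rows = pd.DataFrame(
        {
            "gene1": [r.gene1 for r in results],
            "gene2": [r.gene2 for r in results],
            "delta_err0": [r.delta_err0 for r in results],
            "p_value": pvals,
            "significant": significant,
        }
    )
    return ScreenResult(rows=rows, alpha=alpha, adjust=adjust, results=results)
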