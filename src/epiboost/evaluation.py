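"""Monte-Carlo estimation of type-I error and power of the interaction test.

Each experimental setting (disease model, odds ratio, sample size) is
replicated: a fresh case-control dataset is simulated from a fixed template
haplotype pool with a randomly chosen cross-gene causal SNP pair, the full
permutation test is run, and the rejection fraction m1/replicates is
reported. With the odds ratio at 1 (theta = 0) the datasets are null and the
rejection fraction estimates type-I error; with OR > 1 it estimates power.

Per-replicate seeds are derived from the master seed and the setting, so any
single replicate can be reproduced in isolation and a partially completed
grid can be resumed from a checkpoint file.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .boosted_additivity import BoostConfig
from .disease_simulator import (
    HaplotypePool,
    build_penetrance,
    causal_genotype_probs,
    sample_case_control,
    synth_haplotype_pool,
)
from .permutation_test import permutation_pvalue

__all__ = [
    "ExperimentGrid",
    "PowerEstimate",
    "replicate_seed",
    "run_replicate",
    "estimate_type1",
    "estimate_power",
    "estimates_to_tsv",
]

_SEED_MOD = 2**31


@dataclass(frozen=True)
class ExperimentGrid:
    """Factorial design over disease models, odds ratios and sample sizes."""

    models: tuple[str, ...]
    odds_ratios: tuple[float, ...]
    sample_sizes: tuple[int, ...]
    prevalence: float = 0.01
    replicates: int = 100
    alpha: float = 0.05
    m_permutations: int = 1000
    boost: BoostConfig = field(default_factory=BoostConfig)
    seed: int = 0
    pool_haplotypes: int = 90
    pool_blocks: tuple[tuple[int, float], ...] = ((6, 0.8), (7, 0.2))

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")


@dataclass
class PowerEstimate:
    """Rejection fraction for one (model, OR, n) setting with its 95% CI."""

    model: str
    odds_ratio: float
    n: int
    replicates: int
    rejections: int
    power: float
    ci95: tuple[float, float]
    pvalues: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.power == self.rejections / self.replicates


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    a = (1 - level) / 2
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - a, k + 1, n - k))
    return lo, hi


def replicate_seed(master_seed: int, model: str, odds_ratio: float, n: int,
                   replicate: int) -> int:
    """Stable per-replicate seed from the master seed and the setting."""
    key = f"{master_seed}:{model}:{odds_ratio}:{n}:{replicate}"
    return int.from_bytes(hashlib.sha256(key.encode()).digest()[:4], "big") % _SEED_MOD


def run_replicate(
    pool: HaplotypePool,
    model: str,
    odds_ratio: float,
    n: int,
    prevalence: float,
    config: BoostConfig,
    m: int,
    seed: int,
) -> float:
    """Simulate one dataset under the setting and return its permutation p-value."""
    rng = np.random.default_rng(seed)
    c1 = int(rng.choice(pool.gene_blocks.s1))
    c2 = int(rng.choice(pool.gene_blocks.s2))
    pen = build_penetrance(
        model, odds_ratio - 1.0, prevalence, causal_genotype_probs(pool, (c1, c2))
    )
    data = sample_case_control(
        pool, pen, (c1, c2), n_cases=n // 2, n_controls=n - n // 2, seed=seed
    )
    result = permutation_pvalue(
        data.geno, data.pheno, pool.gene_blocks, config, m=m, seed=seed
    )
    return result.p_value


def _run_grid(grid: ExperimentGrid, checkpoint: str | Path | None) -> list[PowerEstimate]:
    done: dict[tuple, float] = {}
    if checkpoint is not None and Path(checkpoint).exists():
        prev = pd.read_csv(checkpoint, sep="\t")
        for row in prev.itertuples(index=False):
            done[(row.model, float(row.odds_ratio), int(row.n), int(row.replicate))] = (
                float(row.p_value)
            )
    pool = synth_haplotype_pool(
        n_haplotypes=grid.pool_haplotypes,
        blocks=grid.pool_blocks,
        seed=grid.seed,
    )
    estimates = []
    for model in grid.models:
        for odds in grid.odds_ratios:
            for n in grid.sample_sizes:
                pvals = []
                for rep in range(grid.replicates):
                    key = (model, float(odds), int(n), rep)
                    if key in done:
                        pvals.append(done[key])
                        continue
                    seed = replicate_seed(grid.seed, model, odds, n, rep)
                    p = run_replicate(
                        pool, model, odds, n, grid.prevalence,
                        grid.boost, grid.m_permutations, seed,
                    )
                    pvals.append(p)
                    if checkpoint is not None:
                        _append_checkpoint(checkpoint, model, odds, n, rep, p, seed)
                k = int(sum(p < grid.alpha for p in pvals))
                estimates.append(
                    PowerEstimate(
                        model=model,
                        odds_ratio=float(odds),
                        n=int(n),
                        replicates=grid.replicates,
                        rejections=k,
                        power=k / grid.replicates,
                        ci95=_clopper_pearson(k, grid.replicates),
                        pvalues=pvals,
                    )
                )
    return estimates


def _append_checkpoint(path, model, odds, n, rep, p, seed) -> None:
    path = Path(path)
    header = not path.exists()
    with open(path, "a") as fh:
        if header:
            fh.write("model\todds_ratio\tn\treplicate\tp_value\tseed\n")
        fh.write(f"{model}\t{odds}\t{n}\t{rep}\t{p}\t{seed}\n")


def estimate_type1(
    grid: ExperimentGrid, checkpoint: str | Path | None = None
) -> list[PowerEstimate]:
    """Null rejection rates; every odds ratio in the grid must be 1."""
    if any(o != 1.0 for o in grid.odds_ratios):
        raise ValueError("type-I error estimation requires OR = 1 throughout")
    return _run_grid(grid, checkpoint)


def estimate_power(
    grid: ExperimentGrid, checkpoint: str | Path | None = None
) -> list[PowerEstimate]:
    """Rejection rates under a true interaction; odds ratios must exceed 1."""
    if any(o <= 1.0 for o in grid.odds_ratios):
        raise ValueError("power estimation requires OR > 1 throughout")
    return _run_grid(grid, checkpoint)


def estimates_to_tsv(estimates: Sequence[PowerEstimate], path, seed: int | None = None) -> None:
    rows = [
        {
            "model": e.model,
            "odds_ratio": e.odds_ratio,
            "n": e.n,
            "replicates": e.replicates,
            "m1": e.rejections,
            "power": e.power,
            "ci_lo": e.ci95[0],
            "ci_hi": e.ci95[1],
            "seed": seed,
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
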