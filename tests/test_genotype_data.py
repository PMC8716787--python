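"""Genotype containers, readers, quality control and imputation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from epiboost.genotype_data import (
    MISSING,
    GenePartition,
    GenotypeDataError,
    GeneDepletedError,
    GenotypeMatrix,
    PhenotypeVector,
    SnpInfo,
    hwe_chi2_pvalue,
    hwe_exact_pvalue,
    impute_missing,
    minor_allele_freq,
    qc_filter,
    read_genotypes,
    write_gene_map,
    write_plink_raw,
    write_tsv,
)


def _write_gene_map(tmp_path, mapping):
    path = tmp_path / "genes.tsv"
    pd.DataFrame(
        [{"snp_id": s, "gene_id": g} for s, g in mapping.items()]
    ).to_csv(path, sep="\t", index=False)
    return path


class TestReaders:
    def test_smallest_valid_tsv(self, tmp_path):
        geno_path = tmp_path / "g.tsv"
        pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "rs1": [0, 1, 2], "rs2": [2, 0, 1],
             "label": [0, 1, 1]}
        ).to_csv(geno_path, sep="\t", index=False)
        gm = _write_gene_map(tmp_path, {"rs1": "A", "rs2": "B"})
        geno, pheno, part = read_genotypes(geno_path, "tsv", gm)
        assert geno.values.shape == (3, 2)
        assert pheno.n_cases == 2 and pheno.n_controls == 1
        assert part.s1 == (0,) and part.s2 == (1,)
        assert (part.gene1_name, part.gene2_name) == ("A", "B")

    def test_plink_raw_phenotype_recoding_and_na(self, tmp_path):
        raw = tmp_path / "g.raw"
        raw.write_text(
            "FID IID PAT MAT SEX PHENOTYPE rs1_A rs2_G\n"
            "f1 s1 0 0 1 1 0 2\n"
            "f2 s2 0 0 2 2 NA 1\n"
            "f3 s3 0 0 1 2 1 0\n"
        )
        gm = _write_gene_map(tmp_path, {"rs1": "A", "rs2": "B"})
        geno, pheno, part = read_genotypes(raw, "plink_raw", gm)
        assert pheno.labels.tolist() == [0, 1, 1]
        assert pheno.n_cases == 2
        assert geno.values[1, 0] == MISSING
        assert geno.snp_ids == ["rs1", "rs2"]

    def test_three_genes_rejected_for_pair_test(self, tmp_path):
        geno_path = tmp_path / "g.tsv"
        pd.DataFrame(
            {"sample_id": ["a", "b"], "rs1": [0, 1], "rs2": [1, 2], "rs3": [0, 0],
             "label": [0, 1]}
        ).to_csv(geno_path, sep="\t", index=False)
        gm = _write_gene_map(tmp_path, {"rs1": "A", "rs2": "B", "rs3": "C"})
        with pytest.raises(GenotypeDataError, match="exactly 2 genes"):
            read_genotypes(geno_path, "tsv", gm)
        geno, _, part = read_genotypes(geno_path, "tsv", gm, require_pair=False)
        assert part is None and geno.n_snps == 3

    def test_snp_missing_from_gene_map(self, tmp_path):
        geno_path = tmp_path / "g.tsv"
        pd.DataFrame(
            {"sample_id": ["a"], "rs1": [0], "rsX": [1], "label": [1]}
        ).to_csv(geno_path, sep="\t", index=False)
        gm = _write_gene_map(tmp_path, {"rs1": "A"})
        with pytest.raises(GenotypeDataError, match="absent from gene map"):
            read_genotypes(geno_path, "tsv", gm)

    def test_invalid_genotype_value(self, tmp_path):
        geno_path = tmp_path / "g.tsv"
        pd.DataFrame(
            {"sample_id": ["a"], "rs1": [3], "rs2": [0], "label": [1]}
        ).to_csv(geno_path, sep="\t", index=False)
        gm = _write_gene_map(tmp_path, {"rs1": "A", "rs2": "B"})
        with pytest.raises(GenotypeDataError):
            read_genotypes(geno_path, "tsv", gm)

    @pytest.mark.parametrize("writer,fmt", [(write_tsv, "tsv"), (write_plink_raw, "plink_raw")])
    def test_round_trip_preserves_values_order_labels(self, tmp_path, writer, fmt):
        rng = np.random.default_rng(3)
        values = rng.integers(0, 3, size=(8, 4)).astype(np.int8)
        values[2, 1] = MISSING
        snps = [SnpInfo(f"rs{i}", "A" if i < 2 else "B") for i in range(4)]
        geno = GenotypeMatrix(values, snps, [f"s{i}" for i in range(8)])
        pheno = PhenotypeVector(rng.integers(0, 2, size=8))
        path = tmp_path / f"out.{fmt}"
        writer(geno, pheno, path)
        gm = _write_gene_map(tmp_path, {s.snp_id: s.gene_id for s in snps})
        geno2, pheno2, _ = read_genotypes(path, fmt, gm)
        np.testing.assert_array_equal(geno2.values, geno.values)
        assert geno2.snp_ids == geno.snp_ids
        np.testing.assert_array_equal(pheno2.labels, pheno.labels)


class TestContainers:
    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(GenotypeDataError, match="unique"):
            GenotypeMatrix(
                np.zeros((2, 1), dtype=np.int8),
                [SnpInfo("rs1", "A")],
                ["s", "s"],
            )

    def test_partition_overlap_rejected(self):
        with pytest.raises(GenotypeDataError, match="overlap"):
            GenePartition("A", "B", (0, 3), (3, 4))

    def test_partition_coverage_check(self):
        part = GenePartition("A", "B", (0, 1), (2,))
        part.validate_against(3)
        with pytest.raises(GenotypeDataError):
            part.validate_against(4)

    def test_maf_invariant(self):
        with pytest.raises(GenotypeDataError):
            SnpInfo("rs1", "A", minor_allele_freq=0.7)


def exact_hwe_oracle(n_hom_major, n_het, n_hom_minor):
    """Brute-force exact HWE p-value: enumerate every genotype configuration
    with the observed allele counts and sum the probabilities of those no more
    probable than the observed one."""
    n = n_hom_major + n_het + n_hom_minor
    n_minor = n_het + 2 * n_hom_minor
    n_minor = min(n_minor, 2 * n - n_minor)

    def log_prob(h):
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        # multinomial coefficient x 2^h, normalized below
        return (
            h * math.log(2)
            - gammaln(h + 1) - gammaln(hom_min + 1) - gammaln(hom_maj + 1)
        )

    hs = list(range(n_minor % 2, n_minor + 1, 2))
    logs = np.array([log_prob(h) for h in hs])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[hs.index(n_het)]
    return probs[probs <= obs * (1 + 1e-12)].sum()


class TestHwe:
    # (hom_major, het, hom_minor) control genotype counts
    cases = [(81, 18, 1), (50, 40, 10), (88, 10, 2), (70, 21, 9), (25, 50, 25)]

    @pytest.mark.parametrize("counts", cases)
    def test_exact_matches_enumeration_oracle(self, counts):
        assert hwe_exact_pvalue(*counts) == pytest.approx(
            exact_hwe_oracle(*counts), rel=1e-9
        )

    def test_chi2_agrees_with_exact_for_large_counts(self):
        # far from equilibrium: both tests must reject decisively
        assert hwe_chi2_pvalue(500, 100, 400) < 1e-10
        assert hwe_exact_pvalue(500, 100, 400) < 1e-10
        # in equilibrium: neither rejects
        assert hwe_chi2_pvalue(360, 480, 160) > 0.5
        assert hwe_exact_pvalue(360, 480, 160) > 0.5


def _qc_fixture(column_missing=0.0, maf=0.3, n=100, seed=0):
    rng = np.random.default_rng(seed)
    values = rng.binomial(2, maf, size=(n, 3)).astype(np.int8)
    snps = [SnpInfo("target", "A"), SnpInfo("filler", "A"), SnpInfo("anchor", "B")]
    geno = GenotypeMatrix(values, snps, [f"s{i}" for i in range(n)])
    pheno = PhenotypeVector(np.r_[np.ones(n // 2, dtype=int), np.zeros(n - n // 2, dtype=int)])
    return geno, pheno


class TestQcFilter:
    def test_missing_rate_threshold_is_inclusive(self):
        geno, pheno = _qc_fixture()
        geno.values[:12, 0] = MISSING  # 12% missing
        filtered, report = qc_filter(geno, pheno, max_missing_rate=0.10)
        assert report.reasons() == {"target": "missing_rate"}
        assert filtered.snp_ids == ["filler", "anchor"]

    def test_maf_threshold_is_inclusive(self):
        geno, pheno = _qc_fixture()
        n = geno.n_samples
        col = np.zeros(n, dtype=np.int8)
        col[: int(0.04 * 2 * n) // 2 * 2 // 2] = 1  # 4 het carriers -> MAF 0.02
        geno.values[:, 0] = 0
        geno.values[:8, 0] = 1  # MAF = 8/200 = 0.04
        filtered, report = qc_filter(geno, pheno, min_maf=0.05)
        assert report.reasons() == {"target": "maf"}
        # boundary: MAF exactly 0.05 is dropped too
        geno.values[:, 0] = 0
        geno.values[:10, 0] = 1  # MAF = 10/200 = 0.05
        _, report = qc_filter(geno, pheno, min_maf=0.05)
        assert report.reasons() == {"target": "maf"}

    def test_hwe_on_controls_decided_by_exact_oracle(self):
        # controls are the second half of the fixture (pheno = cases first)
        geno, pheno = _qc_fixture(n=200)
        counts = (85, 10, 5)  # heterozygote deficit in the controls
        controls = np.repeat(np.array([0, 1, 2], dtype=np.int8), counts)
        cases = np.ones(100, dtype=np.int8)  # keeps overall MAF comfortable
        geno.values[:, 0] = np.r_[cases, controls]
        p_oracle = exact_hwe_oracle(*counts)
        assert 1e-4 < p_oracle < 1e-2
        # default alpha 1e-4 < oracle p: retained
        _, report = qc_filter(geno, pheno, hwe_alpha=1e-4, hwe_method="exact")
        assert "target" not in report.reasons()
        # alpha just above the oracle p flips the decision
        _, report = qc_filter(geno, pheno, hwe_alpha=p_oracle * 1.01,
                              hwe_method="exact")
        assert report.reasons().get("target") == "hwe"
        # equilibrium counts are never dropped: (81, 18, 1) sits exactly at HWE
        geno.values[100:, 0] = np.repeat(np.array([0, 1, 2], dtype=np.int8),
                                         (81, 18, 1))
        _, report = qc_filter(geno, pheno, hwe_alpha=0.05, hwe_method="exact")
        assert "target" not in report.reasons()

    def test_idempotent_and_reasons_partition_dropped(self):
        geno, pheno = _qc_fixture(n=120, seed=4)
        geno.values[:20, 0] = MISSING
        filtered, report = qc_filter(geno, pheno)
        refiltered, report2 = qc_filter(filtered, pheno)
        assert refiltered.snp_ids == filtered.snp_ids
        assert report2.dropped == []
        assert filtered.n_snps <= geno.n_snps
        assert set(report.dropped_ids) | set(filtered.snp_ids) == set(geno.snp_ids)
        assert len(report.dropped_ids) == len(set(report.dropped_ids))

    def test_gene_depletion_raises(self):
        geno, pheno = _qc_fixture()
        geno.values[:50, 2] = MISSING  # kills gene B's only SNP
        with pytest.raises(GeneDepletedError):
            qc_filter(geno, pheno)


class TestImputation:
    def test_mode_imputation(self):
        values = np.array([[0], [0], [MISSING], [2]], dtype=np.int8)
        geno = GenotypeMatrix(values, [SnpInfo("rs1", "A")], list("abcd"))
        out = impute_missing(geno, "mode")
        assert out.values[:, 0].tolist() == [0, 0, 0, 2]

    def test_no_missing_is_identity(self, small_matrix):
        out = impute_missing(small_matrix, "mode")
        np.testing.assert_array_equal(out.values, small_matrix.values)

    def test_drop_sample(self):
        values = np.array([[0], [MISSING], [1], [2], [0]], dtype=np.int8)
        geno = GenotypeMatrix(values, [SnpInfo("rs1", "A")], list("abcde"))
        out = impute_missing(geno, "drop_sample")
        assert out.n_samples == 4
        assert not out.has_missing()


def test_minor_allele_freq_folds_to_minor():
    col = np.array([2, 2, 2, 1], dtype=np.int8)  # allele freq 7/8
    assert minor_allele_freq(col) == pytest.approx(1 / 8)
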