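"""Genotype QC filters and measured-genotype association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pedvc import (GenotypeTable, MeasuredGenotypeAssociation,
                   bonferroni_threshold, compute_kinship, copy_filter,
                   measured_genotype_fit, qc_filter, variance_explained)
from pedvc.pipeline import _prepare_trait
from pedvc.simulate import QtlConfig, SimConfig, gene_drop, simulate_traits

from conftest import random_pedigree


def _table(dosages, chroms=None, ids=None):
    dosages = np.asarray(dosages, dtype=float)
    n_snps, n_ind = dosages.shape
    ids = ids or [f"i{k}" for k in range(n_ind)]
    snps = pd.DataFrame({
        "snp_id": [f"s{k}" for k in range(n_snps)],
        "chrom": chroms or ["1"] * n_snps,
        "pos_bp": np.arange(n_snps, dtype=float) * 1000,
        "allele_ref": "A", "allele_alt": "B",
    })
    return GenotypeTable(snps=snps, ids=ids, dosages=dosages)


class TestGenotypeTable:
    def test_rejects_bad_dosages(self):
        with pytest.raises(ValueError, match="dosages"):
            _table([[0, 1, 3.0]])

    def test_minor_orientation(self):
        gt = _table([[2, 2, 2, 1, 2, 2]])  # alt freq 11/12 -> flip
        oriented = gt.orient_minor()
        assert oriented.allele_freq[0] == pytest.approx(1 / 12)
        assert oriented.snps.loc[0, "allele_alt"] == "A"
        assert gt.minor_copies[0] == 1  # counted on the minor allele either way


class TestQcFilter:
    def test_call_rate_boundary_and_autosome_rule(self):
        """95.0% call rate retained (inclusive); 94% removed; X SNPs dropped."""
        rng = np.random.default_rng(0)
        n_snps, n_ind = 20, 6
        dos = rng.integers(0, 3, size=(n_snps, n_ind)).astype(float)
        dos[0, 0] = np.nan                      # ind 0: 19/20 = 95% -> keep
        dos[:2, 1] = np.nan                     # ind 1: 18/20 = 90% -> drop
        chroms = ["X"] + ["1"] * (n_snps - 1)
        gt = _table(dos, chroms=chroms)
        out = qc_filter(gt)
        assert "X" not in set(out.snps["chrom"])
        assert out.n_snps == n_snps - 1
        # call rates computed on autosomal SNPs only: ind 0 has 19/19
        assert "i1" not in out.ids and "i0" in out.ids
        assert np.all(out.allele_freq <= 0.5 + 1e-12)

    def test_hand_enumerated_counts(self):
        """10 SNPs x 6 individuals with one failing individual."""
        dos = np.tile([0.0, 1.0, 2.0, 1.0, 0.0, 1.0], (10, 1))
        dos[:6, 2] = np.nan  # individual i2: call rate 4/10 -> removed
        gt = _table(dos)
        out = qc_filter(gt)
        assert out.ids == ["i0", "i1", "i3", "i4", "i5"]
        assert out.n_snps == 10
        # per SNP: dosages (0,1,1,0,1) -> 3 copies, freq 0.3
        assert np.allclose(out.minor_copies, 3)
        assert np.allclose(out.allele_freq, 0.3)

    def test_empty_after_filter_errors(self):
        gt = _table([[0, 1]], chroms=["X"])
        with pytest.raises(ValueError, match="autosomal"):
            qc_filter(gt)


class TestCopyFilter:
    def test_threshold_inclusive(self):
        dos = np.zeros((3, 10))
        dos[0, :4] = 1.0   # 4 copies -> excluded
        dos[1, :5] = 1.0   # 5 copies -> included
        # SNP 2 monomorphic -> excluded
        out = copy_filter(_table(dos), min_copies=5)
        assert list(out.snps["snp_id"]) == ["s1"]

    def test_qc_then_copy_idempotent(self):
        rng = np.random.default_rng(5)
        dos = rng.integers(0, 3, size=(30, 12)).astype(float)
        dos[rng.random(size=dos.shape) < 0.03] = np.nan
        gt = _table(dos, chroms=["1"] * 25 + ["X"] * 5)
        once = copy_filter(qc_filter(gt))
        twice = copy_filter(qc_filter(once))
        assert once.ids == twice.ids
        assert list(once.snps["snp_id"]) == list(twice.snps["snp_id"])
        assert np.allclose(once.dosages, twice.dosages, equal_nan=True)


class TestBonferroni:
    def test_printed_threshold(self):
        thr = bonferroni_threshold(852, alpha=0.05)
        assert float(f"{thr:.2e}") == pytest.approx(5.87e-5)
        assert -np.log10(thr) == pytest.approx(4.23, abs=5e-3)

    def test_single_test(self):
        assert bonferroni_threshold(1) == 0.05

    def test_monotone_and_linear_in_alpha(self):
        assert bonferroni_threshold(100) < bonferroni_threshold(50)
        assert bonferroni_threshold(10, alpha=0.02) == pytest.approx(
            0.4 * bonferroni_threshold(10, alpha=0.05))


class TestVarianceExplained:
    def test_arithmetic(self):
        assert variance_explained(0.2, 0.5, 1.0) == pytest.approx(2.0)
        assert variance_explained(0.202, 0.478, 1.0) == pytest.approx(2.04, abs=5e-3)
        assert variance_explained(0.0, 0.3, 1.0) == 0.0

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            variance_explained(0.1, 0.0, 1.0)
        with pytest.raises(ValueError):
            variance_explained(0.1, 0.2, 0.0)


class TestMeasuredGenotypeFit:
    def test_constant_dosage_rejected(self):
        ped = random_pedigree(2, founder_couples=3, generations=3)
        two_phi = compute_kinship(ped).two_phi
        n = two_phi.shape[0]
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="constant"):
            measured_genotype_fit(rng.normal(size=n), np.ones((n, 1)),
                                  two_phi, np.zeros(n))

    def test_reduces_to_plain_regression_without_relatedness(self):
        """With 2Phi = I and no polygenic signal, the LRT equals the OLS one."""
        rng = np.random.default_rng(8)
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        dos = rng.binomial(2, 0.3, size=n).astype(float)
        y = X @ [1.0, 0.2] + 0.15 * dos + rng.normal(size=n)
        res = measured_genotype_fit(y, X, np.eye(n), dos)

        def ols_ml_loglik(design):
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            r = y - design @ beta
            s2 = (r @ r) / n
            return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)

        lam = 2 * (ols_ml_loglik(np.column_stack([X, dos])) - ols_ml_loglik(X))
        p_ols = stats.chi2.sf(lam, df=1)
        assert res.p_value == pytest.approx(p_ols, abs=1e-6)

    def test_recovers_planted_effect(self):
        """Causal-variant effect recovered within 3 SE on one simulated study."""
        cfg = SimConfig(
            seed=13, n_founder_couples=20, n_generations=4,
            chromosomes={"9": 30.0}, snps_per_cM=1.0,
            qtl=QtlConfig(chrom="9", pos_cM=15.0, freq=0.45,
                          variance_share=0.1), h2=0.15)
        from pedvc.simulate import simulate_pedigree
        ped = simulate_pedigree(cfg)
        kin = compute_kinship(ped)
        genotypes, mibd, qtl_dos = gene_drop(ped, cfg)
        pheno, truth = simulate_traits(ped, kin, cfg, qtl_dosage=qtl_dos)
        design, y = _prepare_trait(pheno, "gsp", False, True)
        gt = genotypes.take_individuals(design.ids)
        k = list(gt.snps["snp_id"]).index("qtl_causal")
        res = measured_genotype_fit(
            y, design.matrix, kin.subset(design.ids).two_phi, gt.dosages[k])
        beta_true = truth["qtl_beta_std"] * truth["trait_sd"]
        assert abs(abs(res.beta) - beta_true) < 3 * res.beta_se
        assert res.p_value < 1e-4

    def test_missing_dosages_complete_case(self):
        ped = random_pedigree(6, founder_couples=4, generations=3)
        two_phi = compute_kinship(ped).two_phi
        n = two_phi.shape[0]
        rng = np.random.default_rng(6)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        dos = rng.binomial(2, 0.4, size=n).astype(float)
        dos[:3] = np.nan
        y = rng.normal(size=n)
        res = measured_genotype_fit(y, X, two_phi, dos)
        assert res.n_used == n - 3


class TestRegionEstimator:
    def test_region_association_flags_causal_snp(self, small_study):
        study = small_study
        design, y = _prepare_trait(study.phenotypes, "gsp", True, True)
        model = MeasuredGenotypeAssociation(kinship=study.kinship, alpha=0.05)
        model.fit(study.genotypes, y, design)
        assert model.threshold_ == pytest.approx(0.05 / model.n_tests_)
        assert set(model.results_.columns) >= {
            "snp_id", "chrom", "pos_bp", "maf", "n_copies", "beta", "p",
            "var_explained_pct"}
        causal = model.results_[model.results_.snp_id == "qtl_causal"]
        assert len(causal) == 1
        # strong planted effect: the causal SNP clears the region threshold
        # (tightly linked neighbours may rank close to it)
        assert causal.p.iloc[0] < model.threshold_
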