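"""Linkage scan: locus fits, LOD scores, classification, support intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from pedvc import (LinkageScan, MibdTrack, VarianceComponentLinkage,
                   compute_kinship, fit_qtl_locus, genome_scan, lod_score,
                   one_lod_interval)
from pedvc.linkage import _classify
from pedvc.pipeline import _prepare_trait
from pedvc.simulate import SimConfig, simulate_traits

from conftest import random_pedigree


def _scan_from_lods(lods, chrom="11", start_cM=100.0, with_bp=True):
    pos = start_cM + np.arange(len(lods), dtype=float)
    table = pd.DataFrame({
        "chrom": chrom, "pos_cM": pos,
        "pos_bp": pos * 1e6 if with_bp else np.nan, "lod": lods,
    })
    peak = int(np.argmax(lods))
    return LinkageScan(
        table=table, peak_chrom=chrom, peak_cM=float(pos[peak]),
        peak_bp=float(pos[peak] * 1e6) if with_bp else float("nan"),
        peak_lod=float(lods[peak]),
        classification=_classify(max(lods), 3.0, 2.0), loglik_polygenic=0.0)


class TestLodScore:
    def test_equal_likelihoods_zero(self):
        assert lod_score(-10.0, -10.0) == 0.0

    def test_chi2_correspondence(self):
        # Lambda = 2.706 <-> LOD = 2.706 / (2 ln 10)
        assert lod_score(-10.0 + 1.353, -10.0) == pytest.approx(0.5875, abs=2e-4)

    def test_factor_of_1000_is_lod_3(self):
        assert lod_score(np.log(1000.0), 0.0) == pytest.approx(3.0)

    def test_rejects_nonnested(self):
        with pytest.raises(ValueError):
            lod_score(-11.0, -10.0)


class TestClassification:
    @pytest.mark.parametrize("peak,expected", [
        (3.18, "significant"), (3.0, "significant"),
        (2.01, "suggestive"), (2.0, "suggestive"), (2.99, "suggestive"),
        (1.99, "none"), (0.0, "none"),
    ])
    def test_lod_thresholds(self, peak, expected):
        assert _classify(peak, 3.0, 2.0) == expected


class TestFitQtlLocus:
    def test_matches_dense_oracle_on_toy(self):
        """Fitted-locus likelihood equals the dense MVN density there."""
        ped = random_pedigree(3, founder_couples=2, generations=2, sibship=1.5)
        kin = compute_kinship(ped)
        two_phi = kin.two_phi
        n = two_phi.shape[0]
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        Pi = np.eye(n)
        Pi[0, 1] = Pi[1, 0] = 0.5
        fit = fit_qtl_locus(y, X, two_phi, Pi)
        # recompute the density at the fitted parameters with brute force
        Om = (Pi * fit.sigma_q2 + two_phi * fit.sigma_a2
              + np.eye(n) * fit.sigma_e2)
        from pedvc.linkage import _locus_nll
        gq = fit.sigma_q2 / fit.sigma_e2
        ga = fit.sigma_a2 / fit.sigma_e2
        _, beta, _ = _locus_nll((gq, ga), Pi.copy(), two_phi, X, y)
        dense = multivariate_normal.logpdf(y, mean=X @ beta, cov=Om)
        assert fit.loglik == pytest.approx(dense, abs=1e-8)

    def test_pi_equal_two_phi_is_confounded(self):
        ped = random_pedigree(4, founder_couples=2, generations=2)
        two_phi = compute_kinship(ped).two_phi
        n = two_phi.shape[0]
        rng = np.random.default_rng(4)
        X = np.ones((n, 1))
        y = rng.normal(size=n)
        fit = fit_qtl_locus(y, X, two_phi, two_phi.copy())
        assert fit.confounded

    def test_misaligned_pi_rejected(self):
        ped = random_pedigree(4, founder_couples=2, generations=2)
        two_phi = compute_kinship(ped).two_phi
        n = two_phi.shape[0]
        with pytest.raises(ValueError, match="misaligned"):
            fit_qtl_locus(np.zeros(n), np.ones((n, 1)), two_phi,
                          np.eye(n - 1))


class TestOneLodInterval:
    def test_drop_rule_on_explicit_profile(self):
        # positions 100..105 with LODs below; peak 3.2, threshold 2.2
        scan = _scan_from_lods([1.9, 2.4, 3.2, 2.6, 2.1, 1.8])
        lo, hi, bp_lo, bp_hi = one_lod_interval(scan)
        assert (lo, hi) == (101.0, 103.0)  # the contiguous run with LOD >= 2.2
        assert bp_lo == pytest.approx(101e6)
        assert bp_hi == pytest.approx(103e6)

    def test_interval_contains_peak_and_endpoints_above_threshold(self):
        scan = _scan_from_lods([0.5, 2.5, 3.5, 3.0, 2.6, 2.45, 0.2])
        lo, hi, *_ = one_lod_interval(scan)
        assert lo <= scan.peak_cM <= hi
        inside = scan.table[(scan.table.pos_cM >= lo) & (scan.table.pos_cM <= hi)]
        assert (inside.lod >= scan.peak_lod - 1.0).all()

    def test_monotone_profile_clips_at_chromosome_end(self):
        scan = _scan_from_lods([1.0, 1.5, 2.2, 2.9, 3.6])
        lo, hi, *_ = one_lod_interval(scan)
        assert hi == scan.table.pos_cM.iloc[-1]
        assert lo == 103.0  # first position with LOD >= 2.6

    def test_weak_peak_returns_whole_chromosome_with_warning(self):
        scan = _scan_from_lods([0.2, 0.8, 0.5])
        with pytest.warns(UserWarning, match="undefined"):
            lo, hi, *_ = one_lod_interval(scan)
        assert (lo, hi) == (100.0, 102.0)

    def test_without_bp_returns_cm_only(self):
        scan = _scan_from_lods([2.0, 3.0, 2.2], with_bp=False)
        assert len(one_lod_interval(scan)) == 2


@pytest.fixture(scope="module")
def linked_trait():
    """A ~100-member pedigree, short chromosome, strong planted QTL."""
    from pedvc.simulate import QtlConfig, gene_drop, simulate_pedigree
    cfg = SimConfig(
        seed=31, n_founder_couples=8, n_generations=4, mean_sibship=3.0,
        chromosomes={"7": 20.0}, snps_per_cM=1.0,
        qtl=QtlConfig(chrom="7", pos_cM=10.0, freq=0.4, variance_share=0.4),
        h2=0.1,
    )
    ped = simulate_pedigree(cfg)
    kin = compute_kinship(ped)
    genotypes, mibd, qtl_dos = gene_drop(ped, cfg)
    pheno, truth = simulate_traits(ped, kin, cfg, qtl_dosage=qtl_dos, mibd=mibd)
    design, y = _prepare_trait(pheno, "gsp", False, True)
    return (kin.subset(design.ids), mibd.subset(design.ids), design, y, truth)


class TestGenomeScan:
    def test_full_and_fast_modes_agree_at_peak(self, linked_trait):
        kin, mibd, design, y, truth = linked_trait
        full = genome_scan(y, design.matrix, kin.two_phi, mibd, mode="full")
        fast = genome_scan(y, design.matrix, kin.two_phi, mibd, mode="fast",
                           refine_window=5.0)
        assert np.all(full.lods >= -1e-9)
        # fast mode is a nested submodel away from the refined window
        assert fast.peak_lod <= full.peak_lod + 0.05
        assert abs(fast.peak_cM - full.peak_cM) <= 2.0

    def test_lod_affine_invariance(self, linked_trait):
        kin, mibd, design, y, _ = linked_trait
        s1 = genome_scan(y, design.matrix, kin.two_phi, mibd, mode="fast")
        s2 = genome_scan(0.1 * y + 4.0, design.matrix, kin.two_phi, mibd,
                         mode="fast")
        assert np.allclose(s1.lods, s2.lods, atol=1e-5)

    def test_estimator_interface(self, linked_trait):
        kin, mibd, design, y, truth = linked_trait
        model = VarianceComponentLinkage(kinship=kin, mibd=mibd, mode="fast")
        model.fit(design, y)
        assert model.scan_.table.shape[0] == len(mibd)
        assert model.peak_lod_ == model.scan_.peak_lod
        if model.peak_lod_ > 1.0:
            lo, hi, *_ = model.interval_
            assert lo <= model.scan_.peak_cM <= hi
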