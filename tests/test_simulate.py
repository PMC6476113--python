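"""Generator properties: determinism, pedigree structure, IBD identities."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from pedvc import compute_kinship
from pedvc.simulate import (BivariateConfig, QtlConfig, SimConfig, gene_drop,
                            simulate_bivariate_traits, simulate_pedigree,
                            simulate_study, simulate_traits)
from pedvc.pipeline import _prepare_trait
from pedvc.vc import PolygenicModel


class TestSimulatePedigree:
    def test_bit_reproducible(self):
        cfg = SimConfig(seed=7, n_founder_couples=6, n_generations=3)
        a = simulate_pedigree(cfg).to_frame()
        b = simulate_pedigree(cfg).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_single_generation_is_founders_only(self):
        cfg = SimConfig(seed=1, n_founder_couples=10, n_generations=1)
        ped = simulate_pedigree(cfg)
        assert ped.n == 20
        assert ped.n_founders == 20
        km = compute_kinship(ped)
        assert np.allclose(km.phi, 0.5 * np.eye(20))

    def test_default_scale_and_depth(self):
        ped = simulate_pedigree(SimConfig(seed=2))
        assert 800 <= ped.n <= 1600
        # generation depth: longest ancestor chain covers >= 4 generations
        depth = np.zeros(ped.n, dtype=int)
        for k in ped.topo_order:
            f = ped.father_idx[k]
            if f >= 0:
                depth[k] = max(depth[f], depth[ped.mother_idx[k]]) + 1
        assert depth.max() >= 3
        # connected single family
        assert _n_components(ped) == 1

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            simulate_pedigree(SimConfig(n_founder_couples=0))


def _n_components(ped):
    parent = list(range(ped.n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for k in range(ped.n):
        for p in (ped.father_idx[k], ped.mother_idx[k]):
            if p >= 0:
                parent[find(k)] = find(p)
    return len({find(k) for k in range(ped.n)})


@pytest.fixture(scope="module")
def dropped():
    cfg = SimConfig(
        seed=19, n_founder_couples=6, n_generations=3, mean_sibship=2.5,
        chromosomes={"5": 25.0}, snps_per_cM=2.0,
        qtl=QtlConfig(chrom="5", pos_cM=12.0, freq=0.3, variance_share=0.1))
    ped = simulate_pedigree(cfg)
    genotypes, mibd, qtl_dos = gene_drop(ped, cfg)
    return cfg, ped, genotypes, mibd, qtl_dos


class TestGeneDrop:
    def test_reproducible(self, dropped):
        cfg, ped, genotypes, mibd, _ = dropped
        g2, m2, _ = gene_drop(ped, cfg)
        assert np.array_equal(genotypes.dosages, g2.dosages)
        assert np.array_equal(mibd.matrix(5), m2.matrix(5))

    def test_mibd_track_valid(self, dropped):
        _, _, _, mibd, _ = dropped
        mibd.validate()
        pos = mibd.positions
        assert np.all(np.diff(pos["pos_cM"]) > 0)

    def test_parent_offspring_share_half_everywhere(self, dropped):
        """A non-inbred parent-offspring pair has pi = 0.5 at every locus."""
        _, ped, _, mibd, _ = dropped
        # find a child of two founders (parent certainly non-inbred)
        k = next(k for k in range(ped.n)
                 if ped.father_idx[k] >= 0
                 and ped.father_idx[ped.father_idx[k]] < 0)
        f = ped.father_idx[k]
        for idx in range(len(mibd)):
            assert mibd.matrix(idx)[k, f] == pytest.approx(0.5)

    def test_full_sib_locus_distribution(self):
        """Single-locus sharing between full sibs is {0, 1/2, 1} w.p. 1/4,1/2,1/4."""
        rows = [("F", "0", "0", "m"), ("M", "0", "0", "f"),
                ("S1", "F", "M", "m"), ("S2", "F", "M", "f")]
        from pedvc import load_pedigree
        ped = load_pedigree(rows)
        values = []
        for seed in range(400):
            cfg = SimConfig(seed=seed, chromosomes={"1": 1.0}, snps_per_cM=0.0,
                            qtl=QtlConfig(chrom="1", pos_cM=0.0,
                                          variance_share=0.0))
            _, mibd, _ = gene_drop(ped, cfg)
            values.append(mibd.matrix(0)[2, 3])
        values = np.array(values)
        assert set(np.unique(values)) <= {0.0, 0.5, 1.0}
        assert np.mean(values == 0.0) == pytest.approx(0.25, abs=0.07)
        assert np.mean(values == 0.5) == pytest.approx(0.50, abs=0.08)
        assert np.mean(values == 1.0) == pytest.approx(0.25, abs=0.07)

    def test_mean_sharing_approaches_additive_relationship(self):
        """Averaging pi over many independent 1 cM chromosomes gives 2 phi."""
        cfg = SimConfig(
            seed=23, n_founder_couples=3, n_generations=3, mean_sibship=2.5,
            chromosomes={str(c): 1.0 for c in range(1, 201)}, snps_per_cM=0.0,
            qtl=QtlConfig(chrom="1", pos_cM=0.0, variance_share=0.0))
        ped = simulate_pedigree(cfg)
        _, mibd, _ = gene_drop(ped, cfg)
        mean_pi = np.mean([mibd.matrix(k) for k in range(len(mibd))], axis=0)
        two_phi = compute_kinship(ped).two_phi
        # diagonal: mean(1 + F-indicator) vs 1 + F
        assert np.max(np.abs(mean_pi - two_phi)) < 0.12

    def test_causal_dosage_frequency(self, dropped):
        cfg, _, genotypes, _, qtl_dos = dropped
        assert qtl_dos is not None
        freq = qtl_dos.mean() / 2
        assert 0.05 < freq < 0.6  # realized founder-allele frequency
        assert "qtl_causal" in set(genotypes.snps["snp_id"])


class TestSimulateTraits:
    def test_pure_noise_trait_fits_near_zero_h2(self):
        cfg = SimConfig(seed=29, n_founder_couples=15, n_generations=4,
                        h2=0.0, qtl=QtlConfig(variance_share=0.0),
                        chromosomes={"1": 10.0}, snps_per_cM=1.0)
        ped = simulate_pedigree(cfg)
        kin = compute_kinship(ped)
        pheno, truth = simulate_traits(ped, kin, cfg)
        design, y = _prepare_trait(pheno, "gsp", False, True)
        fit = PolygenicModel(kinship=kin.subset(design.ids)).fit(design, y)
        assert fit.h2_ < 0.15
        assert truth["h2"] == 0.0

    def test_oversubscribed_variance_rejected(self):
        cfg = SimConfig(h2=0.9, qtl=QtlConfig(variance_share=0.2))
        with pytest.raises(ValueError, match="exceeds 1"):
            cfg.validate()

    def test_perfect_genetic_correlation_limit(self):
        """rho_g=1, rho_e=0, h2=1 for both: the trait pair is identical."""
        cfg = SimConfig(
            seed=3, n_founder_couples=6, n_generations=3,
            bivariate=BivariateConfig(rho_g=1.0, rho_e=0.0, h2_a=1.0, h2_b=1.0))
        ped = simulate_pedigree(cfg)
        kin = compute_kinship(ped)
        biv = simulate_bivariate_traits(ped, kin, cfg)
        assert np.corrcoef(biv["trait_a"], biv["trait_b"])[0, 1] > 0.999

    def test_study_bundle_consistent(self, small_study):
        study = small_study
        assert study.pedigree.n == len(study.kinship.ids)
        assert set(study.phenotypes["id"]) == set(study.pedigree.ids)
        assert study.genotypes.ids == list(study.pedigree.ids)
        assert study.truth["qtl_snp_id"] == "qtl_causal"
        # phenotype covariates respect declared ranges
        assert study.phenotypes["age"].between(18, 88).all()
        assert (study.phenotypes["bmi"] > 0).all()
        assert (study.phenotypes["storage_days"] >= 0).all()

    def test_trait_reproducible(self, small_study):
        study = small_study
        pheno2, _ = simulate_traits(
            study.pedigree, study.kinship, study.config,
            qtl_dosage=study.genotypes.dosages[
                list(study.genotypes.snps["snp_id"]).index("qtl_causal")],
            mibd=study.mibd)
        assert np.array_equal(pheno2["gsp"], study.phenotypes["gsp"])
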