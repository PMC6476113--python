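"""Shared fixtures: small pedigrees and a compact simulated study."""

import numpy as np
import pytest

from pedvc import SimConfig, QtlConfig, compute_kinship, load_pedigree
from pedvc.simulate import simulate_pedigree, simulate_study


@pytest.fixture
def trio():
    """Father, mother, child."""
    return load_pedigree([
        ("F", "0", "0", "m"), ("M", "0", "0", "f"), ("C", "F", "M", "m"),
    ])


@pytest.fixture
def three_gen():
    """Two founder couples, full sibs, half sibs and first cousins.

    C, D full sibs of (A, B); G child of C x E; H child of F x D, so G and H
    are first cousins; K child of D x J is half-sib to H through D.
    """
    return load_pedigree([
        ("A", "0", "0", "1"), ("B", "0", "0", "2"),
        ("C", "A", "B", "1"), ("D", "A", "B", "2"),
        ("E", "0", "0", "2"), ("F", "0", "0", "1"), ("J", "0", "0", "1"),
        ("G", "C", "E", "1"), ("H", "F", "D", "2"), ("K", "J", "D", "1"),
    ])


@pytest.fixture
def inbred_ped():
    """Offspring of a full-sib mating (F = 1/4)."""
    return load_pedigree([
        ("A", "0", "0", "1"), ("B", "0", "0", "2"),
        ("C", "A", "B", "1"), ("D", "A", "B", "2"),
        ("I", "C", "D", "2"),
    ])


def random_pedigree(seed: int, founder_couples: int = 4, generations: int = 4,
                    sibship: float = 2.5):
    """A small random multigenerational pedigree (deterministic per seed)."""
    cfg = SimConfig(
        seed=seed, n_founder_couples=founder_couples,
        n_generations=generations, mean_sibship=sibship,
    )
    return simulate_pedigree(cfg)


@pytest.fixture(scope="session")
def small_study():
    """A compact full study: one 30 cM chromosome, planted QTL at 15 cM."""
    cfg = SimConfig(
        seed=3, n_founder_couples=10, n_generations=4, mean_sibship=3.0,
        chromosomes={"1": 30.0}, snps_per_cM=2.0,
        qtl=QtlConfig(chrom="1", pos_cM=15.0, freq=0.4, variance_share=0.3),
        h2=0.2,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def medium_kinship():
    """Kinship of a ~60-member pedigree used by model tests."""
    ped = random_pedigree(seed=11)
    return ped, compute_kinship(ped)
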