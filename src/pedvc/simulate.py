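"""Synthetic cohort generator: pedigree, gene-dropped genotypes, true MIBD, traits.

Emulates the statistical structure of a single extended multigenerational
pedigree study of a weakly heritable quantitative trait: ~1,000 related
individuals over >= 4 generations, a localized QTL on a 1 cM map grid, and
fixed effects of age, age^2, sex, their interactions, BMI and serum storage
time. Defaults for the covariate distributions (age uniform on 18-88, 55%
female, BMI ~ N(22.3, 3.7^2)) and the trait location/scale follow published
cohort summaries for this kind of study; they are realistic dressing, not a
claim of reproducing any particular cohort.

Design choices:

* Pedigree growth is by random monogamous mating within a generation, with
  unmatched spouses drawn as immigrant founders; sibling unions are excluded,
  more distant consanguinity is allowed (as in real isolate populations).
  The largest connected component is returned.
* Meiosis uses the Haldane (no-interference) map: crossover count Poisson
  with mean (length cM)/100, positions uniform. Founder haplotypes carry
  globally unique allele labels, so IBD sharing at any position is exact:
  pi(i, j) = (number of IBD allele pairs among the four cross pairs) / 2.
* The QTL is an explicit causal diallelic variant by default (detectable by
  both linkage and association); a latent locus-specific normal effect with
  covariance Pi-hat sigma_q^2 is available as a flag.
* One pseudo-random stream per purpose (pedigree / meiosis / founder alleles
  / covariates / trait noise), each keyed by a fixed offset from the master
  seed, so e.g. drawing extra traits does not perturb the pedigree.

Every generator is bit-reproducible given (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree, compute_kinship, load_pedigree, KinshipMatrix
from .linkage import MibdTrack

__all__ = [
    "SimConfig",
    "QtlConfig",
    "BivariateConfig",
    "SimStudy",
    "simulate_pedigree",
    "gene_drop",
    "simulate_traits",
    "simulate_bivariate_traits",
    "simulate_study",
]

# fixed stream keys: (master_seed, key) seeds an independent generator
_STREAM_PEDIGREE = 11
_STREAM_MEIOSIS = 23
_STREAM_ALLELES = 37
_STREAM_COVARIATES = 41
_STREAM_TRAIT = 53
_STREAM_BIVARIATE = 67


@dataclass(frozen=True)
class QtlConfig:
    """A causal locus: position on the map, allele frequency, variance share."""

    chrom: str = "11"
    pos_cM: float = 123.0
    freq: float = 0.35
    variance_share: float = 0.15
    latent: bool = False  # draw a Pi-structured normal instead of a variant


@dataclass(frozen=True)
class BivariateConfig:
    """Truth for the correlated trait pair."""

    rho_g: float = 0.35
    rho_e: float = 0.10
    h2_a: float = 0.30
    h2_b: float = 0.30


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator, with study-scale defaults."""

    seed: int = 0
    # pedigree structure
    n_founder_couples: int = 45
    n_generations: int = 4
    mean_sibship: float = 3.2
    p_marry: float = 0.75
    p_within: float = 0.55
    p_female: float = 0.55
    # genetic map: chromosome -> length in cM, 1 cM MIBD grid
    chromosomes: dict = field(default_factory=lambda: {"11": 140.0})
    grid_cM: float = 1.0
    bp_per_cM: float = 950_000.0
    snps_per_cM: float = 12.0
    snp_freq_range: tuple = (0.02, 0.5)
    # trait model (variance of a + q + e standardized to 1)
    h2: float = 0.16
    qtl: QtlConfig = field(default_factory=QtlConfig)
    # covariate effect sizes on the standardized trait scale
    beta_age: float = 0.010
    beta_age2: float = 2.0e-4
    beta_sex: float = 0.15
    beta_bmi: float = 0.020
    beta_storage: float = 1.0e-4
    # covariate distributions
    age_range: tuple = (18.0, 88.0)
    bmi_mean: float = 22.3
    bmi_sd: float = 3.7
    storage_range: tuple = (100.0, 1500.0)
    # output trait location/scale (GSP-like, umol/L)
    trait_mean: float = 353.5
    trait_sd: float = 92.0
    albumin_mean: float = 4.0
    albumin_sd: float = 0.25
    bivariate: BivariateConfig = field(default_factory=BivariateConfig)

    def validate(self) -> None:
        if self.n_founder_couples < 1:
            raise ValueError("need at least one founder couple")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if not 0.0 < self.qtl.freq < 1.0:
            raise ValueError("QTL allele frequency must be in (0, 1)")
        if self.h2 + self.qtl.variance_share > 1.0:
            raise ValueError("h2 + QTL variance share exceeds 1")
        for c, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {c} has non-positive length")
        b = self.bivariate
        if abs(b.rho_g) > 1 or abs(b.rho_e) > 1:
            raise ValueError("|rho_g| and |rho_e| must be <= 1")


def _rng(cfg: SimConfig, key: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, key])


# --------------------------------------------------------------------------
# pedigree
# --------------------------------------------------------------------------

def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Grow a multigenerational pedigree by random monogamous mating.

    Generation 0 is ``n_founder_couples`` founder couples. In each later
    generation, offspring counts are Poisson(mean_sibship) per couple; a
    fraction ``p_marry`` of offspring reproduce, pairing within their own
    generation (never with a sibling) with probability ``p_within`` and with
    an immigrant founder otherwise. Returns the largest connected component,
    relabelled 1..n with parents before offspring.
    """
    cfg.validate()
    rng = _rng(cfg, _STREAM_PEDIGREE)
    rows: list[tuple[int, int, int, str]] = []  # id, father, mother, sex
    next_id = 1

    def new_person(father, mother, sex) -> int:
        nonlocal next_id
        rows.append((next_id, father, mother, sex))
        next_id += 1
        return next_id - 1

    couples: list[tuple[int, int]] = []
    for _ in range(cfg.n_founder_couples):
        fa = new_person(0, 0, "male")
        mo = new_person(0, 0, "female")
        couples.append((fa, mo))

    parents_of: dict[int, tuple[int, int]] = {}
    for _gen in range(1, cfg.n_generations):
        kids: list[tuple[int, str]] = []
        for fa, mo in couples:
            for _ in range(rng.poisson(cfg.mean_sibship)):
                sex = "female" if rng.random() < cfg.p_female else "male"
                kid = new_person(fa, mo, sex)
                parents_of[kid] = (fa, mo)
                kids.append((kid, sex))
        if not kids:
            couples = []
            continue
        marrying = [k for k in kids if rng.random() < cfg.p_marry]
        within = [k for k in marrying if rng.random() < cfg.p_within]
        outside = [k for k in marrying if k not in within]
        males = [k for k, s in within if s == "male"]
        females = [k for k, s in within if s == "female"]
        rng.shuffle(males)
        rng.shuffle(females)
        couples = []
        for fa, mo in zip(males, females):
            if parents_of.get(fa) == parents_of.get(mo):
                outside.append((fa, "male"))  # would be a sibling union
                outside.append((mo, "female"))
                continue
            couples.append((fa, mo))
        # unmatched within-pool members also marry immigrants
        leftover = males[len(females):] + females[len(males):]
        for kid in leftover:
            sex = next(s for k, s in kids if k == kid)
            outside.append((kid, sex))
        for kid, sex in outside:
            spouse_sex = "female" if sex == "male" else "male"
            spouse = new_person(0, 0, spouse_sex)
            couples.append((kid, spouse) if sex == "male" else (spouse, kid))

    frame = pd.DataFrame(rows, columns=["id", "father", "mother", "sex"])
    frame = _largest_component(frame)
    return load_pedigree(frame)


def _largest_component(frame: pd.DataFrame) -> pd.DataFrame:
    """Keep the largest connected family (union-find over parent-child edges)."""
    if (frame[["father", "mother"]] == 0).all().all():
        return frame  # founders only: no edges to connect
    ids = frame["id"].to_numpy()
    index = {i: k for k, i in enumerate(ids)}
    parent = np.arange(len(ids))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for _, row in frame.iterrows():
        for p in (row["father"], row["mother"]):
            if p != 0:
                union(index[row["id"]], index[p])
    roots = np.array([find(k) for k in range(len(ids))])
    best = np.bincount(roots).argmax()
    return frame[roots == best].reset_index(drop=True)


# --------------------------------------------------------------------------
# gene dropping along a chromosome map
# --------------------------------------------------------------------------

def _drop_chromosome(ped: Pedigree, length_cM: float, positions: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Founder-label haplotypes at ``positions`` for every individual.

    Returns int32 labels of shape (n, 2, n_positions). Crossovers follow the
    Haldane model; a meiosis picks a random starting haplotype and switches
    at each crossover.
    """
    n = ped.n
    npos = positions.shape[0]
    labels = np.zeros((n, 2, npos), dtype=np.int32)
    label = 0
    for k in range(n):
        if ped.father_idx[k] < 0:
            labels[k, 0, :] = label
            labels[k, 1, :] = label + 1
            label += 2

    def gamete(parent_idx: int) -> np.ndarray:
        k = rng.poisson(length_cM / 100.0)
        if k == 0:
            return labels[parent_idx, int(rng.integers(2)), :]
        xpos = np.sort(rng.uniform(0.0, length_cM, size=k))
        phase = (int(rng.integers(2)) + np.searchsorted(xpos, positions)) % 2
        return np.where(phase == 0, labels[parent_idx, 0, :], labels[parent_idx, 1, :])

    for k in ped.topo_order:
        if ped.father_idx[k] < 0:
            continue
        labels[k, 0, :] = gamete(ped.father_idx[k])
        labels[k, 1, :] = gamete(ped.mother_idx[k])
    return labels


@dataclass
class SimStudy:
    """Everything one simulated study produces."""

    config: SimConfig
    pedigree: Pedigree
    kinship: KinshipMatrix
    phenotypes: pd.DataFrame
    genotypes: "GenotypeTable"
    mibd: MibdTrack
    truth: dict


def gene_drop(ped: Pedigree, cfg: SimConfig):
    """Drop founder haplotypes: returns (GenotypeTable, MibdTrack, qtl_dosage).

    SNP positions are uniform on each chromosome at density ``snps_per_cM``
    with counted-allele frequencies uniform in ``snp_freq_range`` assigned to
    founder alleles; the causal variant sits exactly at the configured QTL
    position. The MIBD track holds the exact IBD-sharing labels at the 1 cM
    grid (expectation over loci of pi(i, j) is 2 phi(i, j)).
    """
    from .association import GenotypeTable

    cfg.validate()
    rng_meiosis = _rng(cfg, _STREAM_MEIOSIS)
    rng_alleles = _rng(cfg, _STREAM_ALLELES)
    n = ped.n

    snp_records = []
    snp_dosages = []
    grid_records = []
    grid_labels = []
    qtl_dosage = None

    for chrom, length in cfg.chromosomes.items():
        grid = np.arange(0.0, length + cfg.grid_cM / 2.0, cfg.grid_cM)
        n_snps = int(round(cfg.snps_per_cM * length))
        snp_pos = np.sort(rng_alleles.uniform(0.0, length, size=n_snps))
        has_qtl = (str(chrom) == str(cfg.qtl.chrom)) and not cfg.qtl.latent
        eval_pos = np.concatenate([grid, snp_pos, [cfg.qtl.pos_cM]]) if has_qtl \
            else np.concatenate([grid, snp_pos])
        eval_pos, inverse = np.unique(eval_pos, return_inverse=True)
        labels = _drop_chromosome(ped, length, eval_pos, rng_meiosis)

        idx_grid = inverse[: grid.shape[0]]
        idx_snp = inverse[grid.shape[0]: grid.shape[0] + n_snps]
        grid_records.append(pd.DataFrame({
            "chrom": str(chrom), "pos_cM": grid,
            "pos_bp": np.round(grid * cfg.bp_per_cM),
        }))
        grid_labels.append(labels[:, :, idx_grid].transpose(2, 0, 1))

        n_founder_alleles = 2 * ped.n_founders
        freqs = rng_alleles.uniform(*cfg.snp_freq_range, size=n_snps)
        for j in range(n_snps):
            allele_of_label = (
                rng_alleles.random(n_founder_alleles) < freqs[j]).astype(np.int8)
            lab = labels[:, :, idx_snp[j]]
            dos = allele_of_label[lab[:, 0]] + allele_of_label[lab[:, 1]]
            snp_records.append({
                "snp_id": f"snp_{chrom}_{j:05d}", "chrom": str(chrom),
                "pos_bp": float(np.round(snp_pos[j] * cfg.bp_per_cM)),
                "allele_ref": "A", "allele_alt": "B",
            })
            snp_dosages.append(dos.astype(float))
        if has_qtl:
            idx_qtl = inverse[-1]
            allele_of_label = (
                rng_alleles.random(n_founder_alleles) < cfg.qtl.freq).astype(np.int8)
            lab = labels[:, :, idx_qtl]
            qtl_dosage = (
                allele_of_label[lab[:, 0]] + allele_of_label[lab[:, 1]]
            ).astype(float)
            snp_records.append({
                "snp_id": "qtl_causal", "chrom": str(chrom),
                "pos_bp": float(np.round(cfg.qtl.pos_cM * cfg.bp_per_cM)),
                "allele_ref": "A", "allele_alt": "B",
            })
            snp_dosages.append(qtl_dosage)

    snps = pd.DataFrame(snp_records)
    order = np.lexsort((snps["pos_bp"].to_numpy(), snps["chrom"].to_numpy()))
    genotypes = GenotypeTable(
        snps=snps.iloc[order], ids=list(ped.ids),
        dosages=np.asarray(snp_dosages)[order],
    )
    positions = pd.concat(grid_records, ignore_index=True)
    mibd = MibdTrack(
        ids=list(ped.ids), positions=positions,
        labels=np.concatenate(grid_labels, axis=0),
    )
    return genotypes, mibd, qtl_dosage


# --------------------------------------------------------------------------
# traits
# --------------------------------------------------------------------------

def _covariates(ped: Pedigree, cfg: SimConfig) -> pd.DataFrame:
    rng = _rng(cfg, _STREAM_COVARIATES)
    n = ped.n
    age = rng.uniform(*cfg.age_range, size=n)
    bmi = np.maximum(rng.normal(cfg.bmi_mean, cfg.bmi_sd, size=n), 13.0)
    storage = np.round(rng.uniform(*cfg.storage_range, size=n))
    return pd.DataFrame({
        "id": list(ped.ids), "sex": ped.sex, "age": np.round(age, 1),
        "bmi": np.round(bmi, 2), "storage_days": storage,
    })


def _fixed_effects(cov: pd.DataFrame, cfg: SimConfig) -> np.ndarray:
    age_c = cov["age"].to_numpy() - np.mean(cfg.age_range)
    male = (cov["sex"].to_numpy() == "male").astype(float)
    return (
        cfg.beta_age * age_c
        + cfg.beta_age2 * age_c**2
        + cfg.beta_sex * male
        + cfg.beta_bmi * (cov["bmi"].to_numpy() - cfg.bmi_mean)
        + cfg.beta_storage * (cov["storage_days"].to_numpy()
                              - np.mean(cfg.storage_range))
    )


def _chol_two_phi(kinship: KinshipMatrix) -> np.ndarray:
    two_phi = kinship.two_phi + 1e-10 * np.eye(len(kinship.ids))
    return np.linalg.cholesky(two_phi)


def simulate_traits(ped: Pedigree, kinship: KinshipMatrix, cfg: SimConfig,
                    qtl_dosage=None, mibd: MibdTrack | None = None):
    """Simulate the GSP-like trait: y = covariates + a + q + e.

    ``a`` ~ N(0, 2Phi sigma_a^2); ``q`` is the centered causal-variant dosage
    scaled so its realized variance share is ``qtl.variance_share`` (or, in
    latent mode, a normal draw with covariance Pi-hat sigma_q^2 at the QTL
    grid position); ``e`` is independent noise making up the remainder of the
    unit standardized variance. Returns (phenotype table, truth dict).
    """
    cfg.validate()
    rng = _rng(cfg, _STREAM_TRAIT)
    n = ped.n
    L = _chol_two_phi(kinship)
    sigma_a = np.sqrt(cfg.h2)
    a = sigma_a * (L @ rng.standard_normal(n))

    share = cfg.qtl.variance_share
    beta_q = 0.0
    if share > 0 and not cfg.qtl.latent:
        if qtl_dosage is None:
            raise ValueError("need the causal dosage to simulate a variant QTL")
        p_hat = float(np.mean(qtl_dosage) / 2.0)
        denom = 2.0 * p_hat * (1.0 - p_hat)
        if denom <= 0:
            raise ValueError("causal variant is monomorphic in this pedigree")
        beta_q = float(np.sqrt(share / denom))
        q = beta_q * (qtl_dosage - 2.0 * p_hat)
    elif share > 0:
        if mibd is None:
            raise ValueError("latent QTL mode needs the MIBD track")
        pos = mibd.positions
        at = np.where(
            (pos["chrom"] == str(cfg.qtl.chrom))
            & (np.abs(pos["pos_cM"] - cfg.qtl.pos_cM) < cfg.grid_cM / 2.0))[0]
        k = int(at[0]) if at.size else int(np.argmin(
            np.abs(pos["pos_cM"] - cfg.qtl.pos_cM)))
        Lq = np.linalg.cholesky(mibd.matrix(k) + 1e-8 * np.eye(n))
        q = np.sqrt(share) * (Lq @ rng.standard_normal(n))
    else:
        q = np.zeros(n)

    sigma_e2 = 1.0 - cfg.h2 - share
    e = np.sqrt(sigma_e2) * rng.standard_normal(n)

    cov = _covariates(ped, cfg)
    y_std = _fixed_effects(cov, cfg) + a + q + e
    pheno = cov.copy()
    pheno["gsp"] = np.round(cfg.trait_mean + cfg.trait_sd * y_std, 2)
    pheno["albumin"] = np.round(
        rng.normal(cfg.albumin_mean, cfg.albumin_sd, size=n), 3)
    truth = {
        "h2": cfg.h2,
        "qtl_variance_share": share,
        "qtl_chrom": str(cfg.qtl.chrom),
        "qtl_pos_cM": cfg.qtl.pos_cM,
        "qtl_pos_bp": float(np.round(cfg.qtl.pos_cM * cfg.bp_per_cM)),
        "qtl_beta_std": beta_q,
        "qtl_snp_id": "qtl_causal" if (share > 0 and not cfg.qtl.latent) else None,
        "sigma_e2": sigma_e2,
        "trait_sd": cfg.trait_sd,
    }
    return pheno, truth


def simulate_bivariate_traits(ped: Pedigree, kinship: KinshipMatrix,
                              cfg: SimConfig) -> pd.DataFrame:
    """Simulate a correlated trait pair with genetic correlation rho_g.

    (a_A, a_B) are jointly normal with cross-covariance rho_g over the
    2Phi structure; (e_A, e_B) likewise with correlation rho_e. Both traits
    are standardized (unit total variance) before the shared covariate
    effects are added. Returns a table with trait_a/trait_b plus covariates.
    """
    cfg.validate()
    b = cfg.bivariate
    rng = _rng(cfg, _STREAM_BIVARIATE)
    n = ped.n
    L = _chol_two_phi(kinship)
    za = rng.standard_normal(n)
    zb = rng.standard_normal(n)
    aA = np.sqrt(b.h2_a) * (L @ za)
    aB = np.sqrt(b.h2_b) * (L @ (b.rho_g * za + np.sqrt(1 - b.rho_g**2) * zb))
    ea = rng.standard_normal(n)
    eb = rng.standard_normal(n)
    eA = np.sqrt(1 - b.h2_a) * ea
    eB = np.sqrt(1 - b.h2_b) * (b.rho_e * ea + np.sqrt(1 - b.rho_e**2) * eb)
    cov = _covariates(ped, cfg)
    fx = _fixed_effects(cov, cfg)
    out = cov.copy()
    out["trait_a"] = fx + aA + eA
    out["trait_b"] = fx + aB + eB
    return out


def simulate_study(cfg: SimConfig) -> SimStudy:
    """One full synthetic study: pedigree, kinship, genotypes, MIBD, traits."""
    ped = simulate_pedigree(cfg)
    kin = compute_kinship(ped)
    genotypes, mibd, qtl_dosage = gene_drop(ped, cfg)
    pheno, truth = simulate_traits(ped, kin, cfg, qtl_dosage=qtl_dosage, mibd=mibd)
    biv = simulate_bivariate_traits(ped, kin, cfg)
    pheno = pheno.merge(biv[["id", "trait_a", "trait_b"]], on="id")
    truth.update({
        "rho_g": cfg.bivariate.rho_g, "rho_e": cfg.bivariate.rho_e,
        "h2_a": cfg.bivariate.h2_a, "h2_b": cfg.bivariate.h2_b,
    })
    return SimStudy(
        config=cfg, pedigree=ped, kinship=kin, phenotypes=pheno,
        genotypes=genotypes, mibd=mibd, truth=truth,
    )
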