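"""End-to-end analysis pipeline: heritability -> (bivariate) -> linkage -> association.

Mirrors the analysis plan of a pedigree QTL study: estimate the trait's
narrow-sense heritability under the polygenic model, optionally quantify
pleiotropy with a second trait, scan the genome over the MIBD grid, and —
when a peak is found — run measured-genotype association restricted to the
SNPs inside the peak's 1-LOD support interval, with a Bonferroni threshold
based on the number of SNPs actually tested there.

The pipeline is deterministic given its inputs and configuration: result
tables carry no timestamps, and the run log records the seed, thresholds and
a configuration hash sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .association import MeasuredGenotypeAssociation
from .bivariate import BivariateModel
from .linkage import (LOD_SIGNIFICANT, LOD_SUGGESTIVE, MibdTrack,
                      VarianceComponentLinkage)
from .pedigree import KinshipMatrix, compute_kinship
from .traits import build_design, inverse_normal_transform
from .vc import PolygenicModel

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "analyze_study"]


@dataclass
class RunConfig:
    """Declarative configuration of a pipeline run (file paths + options)."""

    pedigree: str | None = None
    phenotypes: str | None = None
    genotypes: str | None = None
    mibd: dict = field(default_factory=dict)   # chrom -> path
    mibd_map: str | None = None
    out_dir: str = "pedvc_out"
    trait: str = "gsp"
    trait_b: str | None = None
    analyses: tuple = ("polygenic", "linkage", "association")
    inverse_normal: bool = True
    include_storage: bool = True
    alpha: float = 0.05
    lod_significant: float = LOD_SIGNIFICANT
    lod_suggestive: float = LOD_SUGGESTIVE
    min_copies: int = 5
    scan_mode: str = "fast"
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in asdict(self).items()}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    polygenic: object = None
    bivariate: object = None
    scan: object = None
    interval: tuple | None = None
    association: pd.DataFrame | None = None
    association_threshold: float | None = None
    n_snps_tested: int | None = None
    significant_snps: pd.DataFrame | None = None


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _prepare_trait(pheno: pd.DataFrame, trait: str, inverse_normal: bool,
                   include_storage: bool):
    """Complete-case design + (optionally inverse-normal) trait vector."""
    design = build_design(pheno, trait=trait, include_storage=include_storage)
    pos = {str(i): k for k, i in enumerate(pheno["id"].astype(str))}
    cols = {c.lower(): c for c in pheno.columns}
    values = pd.to_numeric(
        pheno[cols[trait.lower()]], errors="coerce").to_numpy(dtype=float)
    y = values[[pos[i] for i in design.ids]]
    if inverse_normal:
        y = inverse_normal_transform(y)
    return design, y


def analyze_study(kinship: KinshipMatrix, pheno: pd.DataFrame,
                  genotypes=None, mibd: MibdTrack | None = None,
                  cfg: RunConfig | None = None) -> PipelineResult:
    """Run the configured stages on in-memory study objects."""
    cfg = cfg or RunConfig()
    out = PipelineResult()

    design, y = _prepare_trait(
        pheno, cfg.trait, cfg.inverse_normal, cfg.include_storage)

    if "polygenic" in cfg.analyses:
        try:
            out.polygenic = PolygenicModel(kinship=kinship).fit(design, y)
        except Exception as exc:
            raise PipelineError("polygenic", str(exc)) from exc

    if cfg.trait_b is not None and "bivariate" in cfg.analyses:
        try:
            design_b, y_b = _prepare_trait(
                pheno, cfg.trait_b, cfg.inverse_normal, cfg.include_storage)
            common = [i for i in design.ids if i in set(design_b.ids)]
            posA = {i: k for k, i in enumerate(design.ids)}
            posB = {i: k for k, i in enumerate(design_b.ids)}
            rowsA = [posA[i] for i in common]
            rowsB = [posB[i] for i in common]
            model = BivariateModel(kinship=kinship.subset(common))
            model.fit(
                (design.matrix[rowsA], design_b.matrix[rowsB]),
                np.column_stack([y[rowsA], y_b[rowsB]]),
            )
            out.bivariate = model
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("bivariate", str(exc)) from exc

    if "linkage" in cfg.analyses:
        if mibd is None:
            raise PipelineError("linkage", "no MIBD track provided")
        try:
            scan_model = VarianceComponentLinkage(
                kinship=kinship, mibd=mibd, mode=cfg.scan_mode,
                lod_significant=cfg.lod_significant,
                lod_suggestive=cfg.lod_suggestive,
            ).fit(design, y)
            out.scan = scan_model.scan_
            out.interval = scan_model.interval_
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("linkage", str(exc)) from exc

    if "association" in cfg.analyses:
        if genotypes is None:
            raise PipelineError("association", "no genotype table provided")
        if out.interval is None:
            raise PipelineError(
                "association",
                "no SNP subset defined: run linkage first (peak LOD must "
                "exceed 1) or provide an explicit interval",
            )
        try:
            iv = out.interval
            if len(iv) == 4:
                region = genotypes.in_region(out.scan.peak_chrom, iv[2], iv[3])
            else:  # no bp coordinates: convert cM bounds via the scan grid
                region = genotypes  # pragma: no cover - bp map always present here
            assoc = MeasuredGenotypeAssociation(
                kinship=kinship, min_copies=cfg.min_copies, alpha=cfg.alpha,
            ).fit(region, y, design)
            out.association = assoc.results_
            out.association_threshold = assoc.threshold_
            out.n_snps_tested = assoc.n_tests_
            out.significant_snps = assoc.significant_
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("association", str(exc)) from exc

    return out


def _report_lines(cfg: RunConfig, res: PipelineResult) -> list[str]:
    lines = [f"pedvc pipeline report (trait: {cfg.trait})"]
    if res.polygenic is not None:
        p = res.polygenic
        se = "NA" if np.isnan(p.h2_se_) else f"{p.h2_se_:.3f}"
        lines += [
            f"polygenic: h2 = {p.h2_:.3f} (SE {se}), p = {p.p_value_:.3g}, "
            f"n = {p.n_used_}",
        ]
    if res.bivariate is not None:
        b = res.bivariate
        lines += [
            f"bivariate ({cfg.trait} vs {cfg.trait_b}): rho_g = {b.rho_g_:.3f} "
            f"(p = {b.p_rho_g_:.3g}), rho_e = {b.rho_e_:.3f}, "
            f"rho_p = {b.rho_p_:.3f} [{b.pleiotropy_} pleiotropy]",
        ]
    if res.scan is not None:
        s = res.scan
        lines += [
            f"linkage: peak LOD = {s.peak_lod:.2f} at chr{s.peak_chrom} "
            f"{s.peak_cM:g} cM -> {s.classification}",
        ]
        if res.interval is not None:
            iv = res.interval
            bp = f"; {iv[2]:.0f}-{iv[3]:.0f} bp" if len(iv) == 4 else ""
            lines += [f"1-LOD support interval: {iv[0]:g}-{iv[1]:g} cM{bp}"]
    if res.association is not None:
        lines += [
            f"association: {res.n_snps_tested} SNPs tested, Bonferroni "
            f"threshold p < {res.association_threshold:.3g}, "
            f"{len(res.significant_snps)} significant",
        ]
    return lines


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """File-based pipeline: read inputs, run stages, write result bundle."""
    if cfg.pedigree is None or cfg.phenotypes is None:
        raise PipelineError("input", "pedigree and phenotypes paths are required")
    ped = pio.read_pedigree(cfg.pedigree)
    kinship = compute_kinship(ped)
    pheno = pio.read_phenotypes(cfg.phenotypes)
    genotypes = pio.read_genotypes(cfg.genotypes) if cfg.genotypes else None
    mibd = (pio.read_mibd(cfg.mibd, map_file=cfg.mibd_map)
            if cfg.mibd else None)

    res = analyze_study(kinship, pheno, genotypes=genotypes, mibd=mibd, cfg=cfg)

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if res.polygenic is not None:
        p = res.polygenic
        flat = {
            "trait": cfg.trait, "h2": p.h2_, "h2_se": p.h2_se_,
            "sigma_a2": p.sigma_a2_, "sigma_e2": p.sigma_e2_,
            "loglik": p.loglik_, "loglik_null": p.loglik_null_,
            "p_h2": p.p_value_, "n_used": p.n_used_,
        }
        (out_dir / "polygenic.json").write_text(json.dumps(flat, indent=1))
        coef = pd.DataFrame({
            "term": p.columns_ or [f"b{k}" for k in range(len(p.beta_))],
            "estimate": p.beta_, "se": p.beta_se_,
        })
        coef.to_csv(out_dir / "polygenic_coefficients.tsv", sep="\t",
                    index=False, float_format="%.6g")
    if res.bivariate is not None:
        b = res.bivariate.result_
        flat = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in asdict(b).items()}
        (out_dir / "bivariate.json").write_text(json.dumps(flat, indent=1))
    if res.scan is not None:
        res.scan.table.to_csv(out_dir / "linkage_scan.tsv", sep="\t",
                              index=False, float_format="%.6g", na_rep="NA")
    if res.association is not None:
        res.association.to_csv(out_dir / "association.tsv", sep="\t",
                               index=False, float_format="%.6g")
    (out_dir / "report.txt").write_text("\n".join(_report_lines(cfg, res)) + "\n")

    import pedvc
    log = {
        "package_version": pedvc.__version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "lod_significant": cfg.lod_significant,
        "lod_suggestive": cfg.lod_suggestive,
        "min_copies": cfg.min_copies,
        "inverse_normal": cfg.inverse_normal,
        "include_storage": cfg.include_storage,
        "config_hash": cfg.config_hash(),
        "config": {k: str(v) for k, v in asdict(cfg).items()},
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=1))
    return res
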