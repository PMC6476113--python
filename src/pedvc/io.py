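"""Readers and writers for the package's plain-text file formats.

Formats (all tab- or comma-separated with a header, missing as empty/NA):

* pedigree: ``id,father,mother,sex``; missing parent ``0`` or empty; sex
  ``1``/``2`` or ``m``/``f``.
* phenotypes: CSV keyed by ``id`` with trait and covariate columns.
* genotypes (SNP-major): ``snp_id chrom pos_bp allele_ref allele_alt`` then
  one dosage column per individual id; ``NA`` or ``.`` for missing. A
  converter from the transposed (individual-major) layout is provided.
* MIBD: one file per chromosome, long format ``id1 id2 pos_cM pihat``
  including self pairs, plus an optional map file
  ``chrom pos_cM pos_bp``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import GenotypeTable
from .linkage import MibdTrack
from .pedigree import KinshipMatrix, Pedigree, load_pedigree

__all__ = [
    "read_pedigree", "write_pedigree",
    "read_phenotypes", "write_phenotypes",
    "read_genotypes", "write_genotypes", "read_genotypes_transposed",
    "read_mibd", "write_mibd",
    "read_kinship", "write_kinship",
]

_NA = ["", "NA", "na", "."]


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", na_values=_NA,
                       keep_default_na=True, dtype=str)


def read_pedigree(path) -> Pedigree:
    return load_pedigree(_read_table(path))


def write_pedigree(ped: Pedigree, path, sep: str = "\t") -> None:
    ped.to_frame().to_csv(path, sep=sep, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep=None, engine="python", na_values=_NA)
    cols = {c.lower(): c for c in pheno.columns}
    if "id" not in cols:
        raise ValueError("phenotype file lacks an 'id' column")
    pheno = pheno.rename(columns={cols["id"]: "id"})
    pheno["id"] = pheno["id"].astype(str)
    return pheno


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False, na_rep="NA")


def read_genotypes(path) -> GenotypeTable:
    raw = pd.read_csv(path, sep=None, engine="python", na_values=_NA, dtype=str)
    meta_cols = ["snp_id", "chrom", "pos_bp", "allele_ref", "allele_alt"]
    for c in meta_cols:
        if c not in raw.columns:
            raise ValueError(f"genotype file lacks required column {c!r}")
    ids = [c for c in raw.columns if c not in meta_cols]
    dosages = raw[ids].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    snps = raw[meta_cols].copy()
    snps["pos_bp"] = pd.to_numeric(snps["pos_bp"])
    return GenotypeTable(snps=snps, ids=ids, dosages=dosages)


def write_genotypes(gt: GenotypeTable, path, sep: str = "\t") -> None:
    out = gt.snps[["snp_id", "chrom", "pos_bp", "allele_ref", "allele_alt"]].copy()
    dos = pd.DataFrame(gt.dosages, columns=gt.ids)
    pd.concat([out.reset_index(drop=True), dos], axis=1).to_csv(
        path, sep=sep, index=False, na_rep="NA", float_format="%.6g")


def read_genotypes_transposed(path) -> GenotypeTable:
    """Read the individual-major layout: rows are individuals (first column
    ``id``), remaining columns are SNP ids; chromosome/position metadata is
    parsed from SNP column names of the form ``chrom:pos_bp[:snp_id]``."""
    raw = pd.read_csv(path, sep=None, engine="python", na_values=_NA, dtype=str)
    cols = {c.lower(): c for c in raw.columns}
    if "id" not in cols:
        raise ValueError("transposed genotype file lacks an 'id' column")
    ids = raw[cols["id"]].astype(str).tolist()
    snp_cols = [c for c in raw.columns if c != cols["id"]]
    records = []
    for c in snp_cols:
        parts = str(c).split(":")
        if len(parts) < 2:
            raise ValueError(
                f"SNP column {c!r} is not of the form chrom:pos_bp[:snp_id]")
        records.append({
            "snp_id": parts[2] if len(parts) > 2 else c,
            "chrom": parts[0], "pos_bp": float(parts[1]),
            "allele_ref": "A", "allele_alt": "B",
        })
    dosages = raw[snp_cols].apply(
        pd.to_numeric, errors="coerce").to_numpy(dtype=float).T
    return GenotypeTable(snps=pd.DataFrame(records), ids=ids, dosages=dosages)


def write_mibd(track: MibdTrack, directory, prefix: str = "mibd") -> dict:
    """Write one long-format file per chromosome; returns {chrom: path}."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = track.n_individuals
    iu = np.triu_indices(n)
    paths = {}
    for chrom, grp in track.positions.groupby("chrom", sort=False):
        frames = []
        for k in grp.index:
            pi = track.matrix(int(k))
            frames.append(pd.DataFrame({
                "id1": [track.ids[i] for i in iu[0]],
                "id2": [track.ids[j] for j in iu[1]],
                "pos_cM": track.positions.loc[k, "pos_cM"],
                "pihat": pi[iu],
            }))
        path = directory / f"{prefix}.{chrom}.tsv"
        pd.concat(frames, ignore_index=True).to_csv(
            path, sep="\t", index=False, float_format="%.6g")
        paths[str(chrom)] = path
    map_path = directory / f"{prefix}.map.tsv"
    track.positions.to_csv(map_path, sep="\t", index=False, na_rep="NA")
    paths["map"] = map_path
    return paths


def read_mibd(files: dict, map_file=None) -> MibdTrack:
    """Read MIBD matrices from {chrom: path} long-format files.

    Pairs absent from a file get pihat 0 (unrelated); the diagonal must be
    present. ``map_file`` supplies bp coordinates per (chrom, pos_cM).
    """
    bp_lookup = {}
    if map_file is not None:
        m = pd.read_csv(map_file, sep=None, engine="python", na_values=_NA,
                        dtype={"chrom": str})
        bp_lookup = {
            (c, float(p)): float(b)
            for c, p, b in zip(m["chrom"], m["pos_cM"], m["pos_bp"])
        }

    ids: list[str] | None = None
    matrices = []
    records = []
    for chrom, path in files.items():
        long = pd.read_csv(path, sep=None, engine="python", na_values=_NA)
        for c in ("id1", "id2", "pos_cM", "pihat"):
            if c not in long.columns:
                raise ValueError(f"MIBD file {path} lacks column {c!r}")
        long["id1"] = long["id1"].astype(str)
        long["id2"] = long["id2"].astype(str)
        if ids is None:
            ids = sorted(set(long["id1"]) | set(long["id2"]))
        index = {m_: k for k, m_ in enumerate(ids)}
        for pos, grp in long.groupby("pos_cM", sort=True):
            pi = np.zeros((len(ids), len(ids)))
            i = grp["id1"].map(index).to_numpy()
            j = grp["id2"].map(index).to_numpy()
            v = grp["pihat"].to_numpy(dtype=float)
            pi[i, j] = v
            pi[j, i] = v
            matrices.append(pi)
            records.append({
                "chrom": str(chrom), "pos_cM": float(pos),
                "pos_bp": bp_lookup.get((str(chrom), float(pos)), np.nan),
            })
    return MibdTrack(ids=ids, positions=pd.DataFrame(records), matrices=matrices)


def write_kinship(km: KinshipMatrix, path, sep: str = "\t") -> None:
    km.to_frame().to_csv(path, sep=sep, index_label="id", float_format="%.8g")


def read_kinship(path) -> KinshipMatrix:
    frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return KinshipMatrix(ids=[str(i) for i in frame.index],
                         phi=frame.to_numpy(dtype=float))
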