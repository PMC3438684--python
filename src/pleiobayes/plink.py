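"""PLINK 1 binary (bed/bim/fam) reader/writer and the package's text tables.

The bed file is SNP-major: after the magic bytes ``0x6C 0x1B`` and the mode
byte ``0x01``, each SNP occupies ceil(n/4) bytes of 2-bit genotype codes,
subjects packed low-bit-first within each byte:

    00 = homozygous A1, 01 = missing, 10 = heterozygous, 11 = homozygous A2.

Because the method needs two dichotomous phenotypes and the fam file carries
only one phenotype column, phenotypes travel in a separate tab-separated
file with columns FID, IID, Da, Db; the fam phenotype column is written as
missing (-9).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, PhenotypeTable
from .simulate import CausalSpec, SimulatedStudy

_MAGIC = bytes([0x6C, 0x1B])
# 2-bit code -> internal genotype (0=AA/homA1, 1=AB, 2=BB/homA2, -1=missing)
_DECODE = np.array([0, -1, 1, 2], dtype=np.int8)
# internal genotype -> 2-bit code (index -1 wraps to the last entry)
_ENCODE = np.array([0b00, 0b10, 0b11, 0b01], dtype=np.uint8)
_SHIFTS = np.array([0, 2, 4, 6], dtype=np.uint8)


def read_plink1(prefix: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a bed/bim/fam trio; returns the genotype matrix and fam table."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    n, p = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:2]) != _MAGIC:
        raise ValueError(
            "not a PLINK 1 bed file: expected magic bytes 0x6C 0x1B"
        )
    if raw[2] != 0x01:
        raise ValueError(
            "sample-major bed files are not supported; expected SNP-major mode byte 0x01"
        )
    bps = (n + 3) // 4  # bytes per SNP record
    body = raw[3:]
    if len(body) != p * bps:
        raise ValueError(
            f"truncated bed file: expected {p * bps} data bytes, found {len(body)}"
        )
    codes = (body.reshape(p, bps)[:, :, None] >> _SHIFTS) & 0b11
    geno = _DECODE[codes.reshape(p, bps * 4)[:, :n]].T  # (n, p)
    alleles = bim[["a1", "a2"]].to_numpy(dtype=object)
    return (
        GenotypeMatrix(geno, bim["snp_id"].to_numpy(dtype=object), alleles),
        fam,
    )


def write_plink1(
    genotypes: GenotypeMatrix,
    prefix: str | Path,
    fam: pd.DataFrame | None = None,
) -> None:
    """Write a SNP-major bed/bim/fam trio; byte output is deterministic."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, p = genotypes.n_subjects, genotypes.n_snps
    bps = (n + 3) // 4
    g = genotypes.genotypes.T  # (p, n)
    padded = np.zeros((p, bps * 4), dtype=np.int8)  # pad codes to hom A1
    padded[:, :n] = g
    codes = _ENCODE[padded]  # int8 -1 indexes the last entry (missing code)
    packed = np.zeros((p, bps), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4] << _SHIFTS[k]
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC + b"\x01")
        fh.write(packed.tobytes())
    alleles = genotypes.alleles
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for i, sid in enumerate(genotypes.snp_ids):
            fh.write(f"1\t{sid}\t0\t{i + 1}\t{alleles[i][0]}\t{alleles[i][1]}\n")
    if fam is None:
        fam = pd.DataFrame(
            {
                "fid": [f"F{i}" for i in range(n)],
                "iid": [f"I{i}" for i in range(n)],
                "father": 0,
                "mother": 0,
                "sex": 0,
                "phenotype": -9,
            }
        )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def write_phenotypes(
    phenotypes: PhenotypeTable, path: str | Path, fam: pd.DataFrame | None = None
) -> None:
    n = phenotypes.n_subjects
    fid = fam["fid"] if fam is not None else [f"F{i}" for i in range(n)]
    iid = fam["iid"] if fam is not None else [f"I{i}" for i in range(n)]
    df = pd.DataFrame({"FID": fid, "IID": iid, "Da": phenotypes.da})
    df["Db"] = phenotypes.db if phenotypes.db is not None else -9
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> tuple[PhenotypeTable, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
    db = df["Db"].to_numpy() if "Db" in df and (df["Db"] > 0).all() else None
    return PhenotypeTable(da=df["Da"].to_numpy(), db=db), df


def write_truth(specs: list[CausalSpec], snp_ids: np.ndarray, path: str | Path) -> None:
    rows = [
        {
            "snp_id": snp_ids[s.snp_index],
            "target": s.target,
            "maf": s.maf,
            "or_a": "" if s.or_a is None else s.or_a,
            "or_b": "" if s.or_b is None else s.or_b,
            "mode": s.mode,
            "disease_allele": s.disease_allele,
        }
        for s in specs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write discovery/validation PLINK trios, phenotype tables, and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for role, g, p in (
        ("discovery", study.discovery_genotypes, study.discovery_phenotypes),
        ("validation", study.validation_genotypes, study.validation_phenotypes),
    ):
        write_plink1(g, outdir / role)
        write_phenotypes(p, outdir / f"{role}.pheno.tsv")
    write_truth(study.specs, study.discovery_genotypes.snp_ids, outdir / "truth.tsv")
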