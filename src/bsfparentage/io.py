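"""Reading and writing genotype matrices (VCF v4.2, PED/MAP) and pedigrees.

VCF positions are 1-based (internal locus tables store them as given).
Genotype coding on disk follows the usual conventions: GT "0/0", "0/1",
"1/1", "./." for VCF; two allele columns per SNP with "0 0" as missing for
PED. Only biallelic SNP records are accepted from VCF; anything else is
skipped and counted.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, SAMPLE_COLUMNS
from .simpop import Pedigree

_GT_CODE = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a VCF v4.2 with GT (and DP when depths are present)."""
    path = Path(path)
    loci = matrix.loci
    contigs = list(dict.fromkeys(loci["chrom"]))
    has_dp = matrix.depth is not None
    fmt = "GT:DP" if has_dp else "GT"
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bsfparentage\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=RAD,Number=1,Type=String,Description="RAD locus id">\n')
        fh.write('##INFO=<ID=RPOS,Number=1,Type=Integer,'
                 'Description="Position of the SNP within the RAD locus">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                     'Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids) + "\n")
        for j in range(matrix.n_loci):
            row = loci.iloc[j]
            info = f"RAD={row['rad_locus']};RPOS={row['pos_in_locus']}"
            fields = [str(row["chrom"]), str(int(row["pos"])), str(row["id"]),
                      "A", "C", ".", "PASS", info, fmt]
            for i in range(matrix.n_samples):
                g = gt_str[int(matrix.calls[i, j])]
                if has_dp:
                    g += f":{int(matrix.depth[i, j])}"
                fields.append(g)
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path, samples_csv: str | Path | None = None
             ) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix; non-biallelic-SNP records skipped.

    When ``samples_csv`` (a pedigree/sample sidecar table with columns
    ``id, colony, generation, family, role, sire, dam``) is given, its rows
    are matched to the VCF samples; otherwise placeholder metadata is built.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    calls, meta, depths = [], [], []
    n_skipped = 0
    has_dp = False
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            n_skipped += 1
            continue
        gts = var.genotype.array()
        dose = gts[:, 0] + gts[:, 1]
        dose = np.where((gts[:, 0] < 0) | (gts[:, 1] < 0), MISSING, dose)
        calls.append(dose.astype(np.int8))
        info = dict(var.INFO)
        meta.append({"id": var.ID or f"{var.CHROM}:{var.POS}", "chrom": var.CHROM,
                     "pos": var.POS, "rad_locus": info.get("RAD", var.ID or ""),
                     "pos_in_locus": int(info.get("RPOS", 0))})
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            has_dp = True
            depths.append(dp[:, 0])
        else:
            depths.append(np.zeros(len(sample_ids), dtype=np.int32))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic/non-SNP records",
                      stacklevel=2)
    if not calls:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    call_mat = np.stack(calls, axis=1)
    depth_mat = np.stack(depths, axis=1).astype(np.int32) if has_dp else None
    if samples_csv is not None:
        ped = pd.read_csv(samples_csv, dtype=str).fillna("")
        ped["generation"] = ped["generation"].astype(int)
        ped = ped.set_index("id").loc[sample_ids].reset_index()
    else:
        ped = pd.DataFrame({"id": sample_ids})
        for col in SAMPLE_COLUMNS:
            if col not in ped:
                ped[col] = "" if col != "generation" else 0
    return GenotypeMatrix(calls=call_mat, samples=ped,
                          loci=pd.DataFrame(meta), depth=depth_mat)


# ---------------------------------------------------------------------------
# PED / MAP
# ---------------------------------------------------------------------------

def write_ped(matrix: GenotypeMatrix, prefix: str | Path) -> None:
    """Write Plink-style text PED/MAP (<prefix>.ped, <prefix>.map)."""
    prefix = Path(prefix)
    loci = matrix.loci
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, row in loci.iterrows():
            fh.write(f"{row['chrom']}\t{row['id']}\t0\t{int(row['pos'])}\n")
    allele = {0: ("A", "A"), 1: ("A", "C"), 2: ("C", "C"), -1: ("0", "0")}
    samples = matrix.samples
    sex = {"sire": "1", "dam": "2"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(matrix.n_samples):
            s = samples.iloc[i]
            row = [str(s.get("family", "0") or "0"), s["id"],
                   str(s.get("sire", "0") or "0"), str(s.get("dam", "0") or "0"),
                   sex.get(s.get("role", ""), "0"), "-9"]
            for j in range(matrix.n_loci):
                row.extend(allele[int(matrix.calls[i, j])])
            fh.write("\t".join(row) + "\n")


def read_ped(prefix: str | Path) -> GenotypeMatrix:
    """Read text PED/MAP written by :func:`write_ped` (or Plink --recode)."""
    prefix = Path(prefix)
    map_rows = pd.read_csv(prefix.with_suffix(".map"), sep=r"\s+", header=None,
                           names=["chrom", "id", "cm", "pos"])
    loci = pd.DataFrame(
        {"id": map_rows["id"], "chrom": map_rows["chrom"], "pos": map_rows["pos"],
         "rad_locus": map_rows["id"], "pos_in_locus": 0})
    samples, calls = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            fam, iid, sire, dam, sex, _ = parts[:6]
            alleles = parts[6:]
            if len(alleles) != 2 * len(loci):
                raise ValueError("PED allele columns do not match MAP loci")
            role = {"1": "sire", "2": "dam"}.get(sex, "")
            samples.append({"id": iid, "colony": "", "generation": 0,
                            "family": "" if fam == "0" else fam, "role": role,
                            "sire": "" if sire == "0" else sire,
                            "dam": "" if dam == "0" else dam})
            g = np.empty(len(loci), dtype=np.int8)
            for j in range(len(loci)):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                if a == "0" or b == "0":
                    g[j] = MISSING
                else:
                    g[j] = (a != "A") + (b != "A")
            calls.append(g)
    return GenotypeMatrix(calls=np.stack(calls), samples=pd.DataFrame(samples),
                          loci=loci)


# ---------------------------------------------------------------------------
# pedigree tables
# ---------------------------------------------------------------------------

def write_pedigree_csv(pedigree: Pedigree, path: str | Path) -> None:
    pedigree.to_dataframe().to_csv(path, index=False)


def read_genotypes(path: str | Path, fmt: str | None = None,
                   samples_csv: str | Path | None = None) -> GenotypeMatrix:
    """Dispatch on format: 'vcf' or 'ped' (inferred from the extension)."""
    path = Path(path)
    if fmt is None:
        fmt = "ped" if path.suffix in (".ped", ".map") else "vcf"
    if fmt == "vcf":
        return read_vcf(path, samples_csv=samples_csv)
    if fmt == "ped":
        m = read_ped(path.with_suffix(""))
        if samples_csv is not None:
            ped = pd.read_csv(samples_csv, dtype=str).fillna("")
            ped["generation"] = ped["generation"].astype(int)
            m.samples = ped.set_index("id").loc[m.sample_ids].reset_index()
        return m
    raise ValueError(f"unknown format {fmt!r}")
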