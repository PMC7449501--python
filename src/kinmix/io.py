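"""Readers and writers for the file formats the tool touches.

Conventions: positions are 1-based (VCF-native) everywhere; the designated
"1" allele is the VCF ALT allele, and ``freqA``/``freqB`` in the frequency
table refer to that ALT allele; genetic-map cumulative cM converts to
crossover probability at 1 cM = 0.01 before clamping.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .data import PhasedGenome, SiteTable
from .simulate import Tract, TruthRecord

__all__ = [
    "write_phased_vcf", "read_phased_vcf", "write_freqs", "read_freqs",
    "write_genetic_map", "read_genetic_map", "assemble_site_table",
    "write_truth", "read_truth", "write_json",
]

_VCF_HEADER = """##fileformat=VCFv4.2
##source=kinmix
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_phased_vcf(path, genomes, sites: SiteTable) -> None:
    """Write phased biallelic genotypes (REF=A, ALT=C; "1" = ALT)."""
    genomes = [genomes] if isinstance(genomes, PhasedGenome) else list(genomes)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for lab, sl in sites._runs():
            fh.write(f"##contig=<ID={lab}>\n")
        names = "\t".join(g.sample_id for g in genomes)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{names}\n")
        for i in range(sites.n):
            gts = "\t".join(f"{g.h1[i]}|{g.h2[i]}" for g in genomes)
            fh.write(f"{sites.chrom[i]}\t{sites.pos_bp[i]}\t.\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def read_phased_vcf(path, drop_bad: bool = False):
    """Read phased diploid GTs from a VCF.

    Returns ``(genomes, skeleton)`` where skeleton is a DataFrame with
    chrom/pos/ref/alt per retained record.  Multiallelic, non-SNP, missing
    or unphased records are fatal by default (``drop_bad=True`` drops them
    and reports counts in ``skeleton.attrs['dropped']``).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: no samples in VCF")
    rows, h1s, h2s = [], [], []
    dropped = {"multiallelic_or_not_snp": 0, "unphased_or_missing": 0}
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            if drop_bad:
                dropped["multiallelic_or_not_snp"] += 1
                continue
            raise ValueError(f"{path}: record {var.CHROM}:{var.POS} is not a "
                             "biallelic SNP")
        gts = var.genotypes  # [allele1, allele2, phased] per sample
        if any(g[0] < 0 or g[1] < 0 or not g[2] for g in gts):
            if drop_bad:
                dropped["unphased_or_missing"] += 1
                continue
            raise ValueError(f"{path}: record {var.CHROM}:{var.POS} has an "
                             "unphased or missing genotype")
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        h1s.append([g[0] for g in gts])
        h2s.append([g[1] for g in gts])
    if not rows:
        raise ValueError(f"{path}: no usable records")
    h1 = np.asarray(h1s, dtype=np.uint8)
    h2 = np.asarray(h2s, dtype=np.uint8)
    genomes = [PhasedGenome(h1[:, j], h2[:, j], samples[j])
               for j in range(len(samples))]
    skeleton = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    skeleton.attrs["dropped"] = dropped
    return genomes, skeleton


def write_freqs(path, sites: SiteTable, allele: str = "C") -> None:
    pd.DataFrame({
        "chrom": sites.chrom, "pos": sites.pos_bp, "allele": allele,
        "freqA": sites.freqA, "freqB": sites.freqB,
    }).to_csv(path, sep="\t", index=False)


def read_freqs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "allele", "freqA", "freqB"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_genetic_map(path, gmap) -> None:
    gmap.to_dataframe().to_csv(path, sep="\t", index=False)


def read_genetic_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "cM"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)} "
                         "(HapMap-style: chrom, pos, rate cM/Mb, cumulative cM)")
    for _, sub in df.groupby("chrom", sort=False):
        if np.any(np.diff(sub["pos"].to_numpy()) <= 0) or \
                np.any(np.diff(sub["cM"].to_numpy()) < 0):
            raise ValueError(f"{path}: genetic map is not sorted")
    return df


def assemble_site_table(skeleton: pd.DataFrame, genomes, freqs: pd.DataFrame,
                        gmap_df: pd.DataFrame):
    """Join VCF records with the frequency table and the genetic map.

    Sites missing a frequency entry (by chrom, pos, ALT allele) or lying
    outside the map of their chromosome are dropped; counts are reported.
    Returns ``(sites, genomes, info)``.
    """
    genomes = [genomes] if isinstance(genomes, PhasedGenome) else list(genomes)
    key = freqs.set_index(["chrom", "pos", "allele"])
    n = len(skeleton)
    keep = np.zeros(n, dtype=bool)
    fA = np.full(n, np.nan)
    fB = np.full(n, np.nan)
    for i, row in enumerate(skeleton.itertuples(index=False)):
        k = (str(row.chrom), int(row.pos), str(row.alt))
        if k in key.index:
            rec = key.loc[k]
            fA[i], fB[i] = float(rec["freqA"]), float(rec["freqB"])
            keep[i] = True
    no_freq = int(n - keep.sum())

    gp = np.full(n, np.nan)
    for chrom, sub in gmap_df.groupby("chrom", sort=False):
        sel = (skeleton["chrom"].astype(str) == str(chrom)).to_numpy() & keep
        if not sel.any():
            continue
        pos = skeleton.loc[sel, "pos"].to_numpy(dtype=np.float64)
        mpos = sub["pos"].to_numpy(dtype=np.float64)
        mcm = sub["cM"].to_numpy(dtype=np.float64)
        inside = (pos >= mpos[0]) & (pos <= mpos[-1])
        vals = np.interp(pos, mpos, mcm) / 100.0   # cM -> Morgans
        vals[~inside] = np.nan
        gp[np.flatnonzero(sel)] = vals
    no_map = int((keep & ~np.isfinite(gp)).sum())
    keep &= np.isfinite(gp)
    if not keep.any():
        raise ValueError("no sites overlap the frequency table and the map")

    idx = np.flatnonzero(keep)
    sites = SiteTable(
        chrom=skeleton["chrom"].astype(str).to_numpy(dtype=object)[idx],
        pos_bp=skeleton["pos"].to_numpy(dtype=np.int64)[idx],
        freqA=fA[idx], freqB=fB[idx], gen_pos=gp[idx],
    )
    genomes = [g.subset(idx) for g in genomes]
    info = {"n_input": n, "n_retained": int(keep.sum()),
            "dropped_no_frequency": no_freq, "dropped_outside_map": no_map}
    return sites, genomes, info


# ----------------------------------------------------------------------
# JSON artifacts
# ----------------------------------------------------------------------
def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def write_truth(path, truths) -> None:
    write_json(path, [t.to_dict() for t in truths])


def read_truth(path) -> list[TruthRecord]:
    with open(path) as fh:
        raw = json.load(fh)
    out = []
    for rec in raw:
        gens = {}
        for k, v in rec["generations"].items():
            gens[int(k)] = {
                "ancestor_ids": v["ancestor_ids"],
                "proportions": v["proportions"],
                "tracts": [[Tract(**t) for t in tl] for tl in v["tracts"]],
            }
        out.append(TruthRecord(sample_id=rec["sample_id"],
                               focal_prop=rec["focal_prop"],
                               generations=gens))
    return out
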