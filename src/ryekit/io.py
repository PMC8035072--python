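"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: per-bin count TSV, pairs-style Hi-C link TSV, genotype TSV (wide,
one site per row, ``dosage:depth`` cells), VCF (read via cyvcf2; a minimal
writer is provided so generated fixtures round-trip), site-annotation TSV,
BLAST outfmt-6 tables, gene-position TSV, BED interval files, and the
long-format window-statistic TSV shared by all windowed outputs.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hic import RegionSet, SVCall
from .karyotype import BinnedDepthProfile
from .popgen import GenotypeMatrix
from .synteny import BLAST6_COLUMNS

__all__ = [
    "write_bin_counts",
    "read_bin_counts",
    "write_pairs",
    "read_pairs",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "read_vcf",
    "write_vcf",
    "write_annotations",
    "read_annotations",
    "write_blast_tab",
    "read_blast_tab",
    "write_gene_positions",
    "read_gene_positions",
    "write_bed",
    "read_bed",
    "read_groups",
]


# -- binned counts -----------------------------------------------------------

def write_bin_counts(profiles: Iterable[BinnedDepthProfile], path: str) -> None:
    frames = []
    for prof in profiles:
        f = prof.bins[["chrom", "bin_start", "count"]].copy()
        f.insert(0, "sample_id", prof.sample_id)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_bin_counts(path: str, bin_size: int = 1_000_000) -> list[BinnedDepthProfile]:
    df = pd.read_csv(path, sep="\t")
    return [
        BinnedDepthProfile(sample_id=str(sid), bins=sub.drop(columns="sample_id").reset_index(drop=True), bin_size=bin_size)
        for sid, sub in df.groupby("sample_id", sort=True)
    ]


# -- Hi-C pairs --------------------------------------------------------------

def write_pairs(links: pd.DataFrame, path: str) -> None:
    links[["chrom1", "pos1", "chrom2", "pos2"]].to_csv(path, sep="\t", index=False)


def read_pairs(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- genotype matrix ---------------------------------------------------------

_SITE_COLS = ["chrom", "pos", "ref", "alt", "qual"]


def write_genotype_tsv(gm: GenotypeMatrix, path: str) -> None:
    """Wide TSV: site columns then one ``dosage:depth`` column per sample."""
    out = gm.sites[[c for c in _SITE_COLS if c in gm.sites.columns]].copy()
    depth = gm.depth if gm.depth is not None else np.zeros_like(gm.calls)
    for i, sample in enumerate(gm.samples):
        g = gm.calls[i].astype(object)
        cells = [
            f"{'.' if v == -1 else int(v)}:{int(d)}" for v, d in zip(g, depth[i])
        ]
        out[sample] = cells
    out.to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    site_cols = [c for c in _SITE_COLS if c in df.columns]
    samples = [c for c in df.columns if c not in site_cols]
    n_sites, n_samples = len(df), len(samples)
    calls = np.empty((n_samples, n_sites), dtype=np.int8)
    depth = np.empty((n_samples, n_sites), dtype=np.int64)
    for i, sample in enumerate(samples):
        parts = df[sample].str.split(":", expand=True)
        g = parts[0].to_numpy()
        calls[i] = np.where(g == ".", -1, g).astype(np.int8)
        depth[i] = parts[1].astype(np.int64)
    return GenotypeMatrix(samples=samples, sites=df[site_cols], calls=calls, depth=depth)


def read_vcf(path: str) -> GenotypeMatrix:
    """Biallelic SNPs from a VCF; honors per-call FORMAT/DP and site QUAL."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, call_cols, depth_cols = [], [], []
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            continue
        rows.append(
            {
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": v.ALT[0],
                "qual": v.QUAL if v.QUAL is not None else np.nan,
            }
        )
        # cyvcf2 gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = v.gt_types
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=-1)
        call_cols.append(dosage.astype(np.int8))
        try:
            dp = v.format("DP")[:, 0]
            dp = np.where(dp < 0, 0, dp)
        except (TypeError, KeyError):
            dp = np.zeros(len(samples), dtype=np.int64)
        depth_cols.append(dp.astype(np.int64))
    vcf.close()
    if not rows:
        raise ValueError(f"no biallelic SNPs in {path}")
    return GenotypeMatrix(
        samples=samples,
        sites=pd.DataFrame(rows),
        calls=np.column_stack(call_cols),
        depth=np.column_stack(depth_cols),
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(gm: GenotypeMatrix, path: str, contig_lengths: Mapping[str, int] | None = None) -> None:
    """Minimal uncompressed VCF with GT:DP, enough to round-trip fixtures."""
    depth = gm.depth if gm.depth is not None else np.zeros_like(gm.calls)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={int(length)}>\n")
        else:
            for chrom in pd.unique(gm.sites["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples) + "\n")
        qual = gm.sites["qual"] if "qual" in gm.sites.columns else pd.Series(np.nan, index=gm.sites.index)
        for j, row in gm.sites.iterrows():
            q = "." if pd.isna(qual.iloc[j]) else f"{qual.iloc[j]:.1f}"
            cells = [
                f"{_GT_STR[int(gm.calls[i, j])]}:{int(depth[i, j])}"
                for i in range(gm.n_samples)
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}\t{q}\tPASS\t.\tGT:DP\t"
                + "\t".join(cells)
                + "\n"
            )


# -- site annotations --------------------------------------------------------

def write_annotations(annotations: pd.DataFrame, path: str) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def read_annotations(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- BLAST tabular -----------------------------------------------------------

def write_blast_tab(hits: pd.DataFrame, path: str, extra_cols: Sequence[str] = ("subject_genome",)) -> None:
    cols = BLAST6_COLUMNS + [c for c in extra_cols if c in hits.columns]
    hits[cols].to_csv(path, sep="\t", index=False, header=False)


def read_blast_tab(path: str, extra_cols: Sequence[str] = ("subject_genome",)) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    names = BLAST6_COLUMNS + list(extra_cols)
    df.columns = names[: df.shape[1]]
    return df


def write_gene_positions(positions: pd.DataFrame, path: str) -> None:
    positions[["gene_id", "chrom", "pos"]].to_csv(path, sep="\t", index=False)


def read_gene_positions(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- BED ---------------------------------------------------------------------

def write_bed(intervals: Iterable, path: str) -> None:
    """BED (0-based, half-open) for SVCall lists or (chrom, start, end) triples."""
    with open(path, "w") as fh:
        for iv in intervals:
            if isinstance(iv, SVCall):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.type}\t{iv.score:.4f}\n")
            else:
                chrom, start, end = iv[:3]
                fh.write(f"{chrom}\t{int(start)}\t{int(end)}\n")


def read_bed(path: str) -> RegionSet:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            regions.append((chrom, int(start), int(end)))
    return RegionSet(regions)


def read_sv_calls(path: str) -> list[SVCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            sv_type = parts[3] if len(parts) > 3 else "candidate"
            score = float(parts[4]) if len(parts) > 4 else 0.0
            calls.append(SVCall(chrom, start, end, sv_type, score))
    return calls


# -- misc --------------------------------------------------------------------

def read_groups(path: str) -> dict[str, list[str]]:
    """Two-column TSV sample_id<TAB>group -> {group: [samples]}."""
    df = pd.read_csv(path, sep="\t")
    sample_col, group_col = df.columns[:2]
    out: dict[str, list[str]] = {}
    for sample, group in zip(df[sample_col], df[group_col]):
        out.setdefault(str(group), []).append(str(sample))
    return out
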