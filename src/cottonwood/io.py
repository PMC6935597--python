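"""Readers and writers for the formats the pipeline touches.

Canonical genotype TSV dialect: one row per individual, first column the
individual id, remaining columns loci, codes 0/1/2/NA (count of the
alternate allele).  VCF is accepted as an alternative genotype source and
as the carrier of pool allelic depths (AD).  All coordinates inside the
package are 1-based inclusive; BED export is the only 0-based half-open
surface.

Every table written by :func:`write_table` carries a comment header naming
the tool version and a hash of the parameters that produced it, so runs
are machine-recoverable from their outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from . import __version__
from .containers import GenotypeMatrix
from .sim import PoolReadCounts

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_population_map",
    "write_bed",
    "write_table",
    "read_table",
    "read_pool_vcf",
    "write_pool_vcf",
    "pool_counts_to_variant_table",
]

_MISSING_TOKENS = {"NA", "NaN", "", ".", "-9"}


def config_hash(params: Mapping) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, params: Optional[Mapping] = None,
                index: bool = True) -> None:
    """Write a TSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# cottonwood v{__version__}\n")
        if params is not None:
            fh.write(f"# config_hash={config_hash(params)}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_genotypes(
    path,
    format: str = "tsv",
    individuals: Optional[pd.DataFrame] = None,
    loci: Optional[pd.DataFrame] = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from the canonical TSV or from VCF.

    TSV: header row of locus ids, first column individual ids, codes
    0/1/2/NA.  VCF: diploid GT fields map 0/0 -> 0, 0/1 -> 1, 1/1 -> 2,
    ./. -> missing; multi-allelic records are skipped and their count
    stored in ``calls.attrs['n_multiallelic_skipped']``.  Missing
    individual/locus metadata is filled with placeholders.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
        df.index = df.index.astype(str)
        vals = df.apply(
            lambda col: col.map(
                lambda x: np.nan if (pd.isna(x) or str(x).strip() in _MISSING_TOKENS)
                else float(x)
            )
        )
        calls = vals
        n_multi = 0
        locus_meta = pd.DataFrame(
            {"chrom": ".", "pos": 0, "gene": "."}, index=calls.columns
        )
    elif format == "vcf":
        records = []
        locus_rows = []
        samples = None
        n_multi = 0
        with pysam.VariantFile(str(path)) as vcf:
            samples = list(vcf.header.samples)
            for rec in vcf:
                if rec.alts is None or len(rec.alts) != 1:
                    n_multi += 1
                    continue
                row = []
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt is None or any(a is None for a in gt):
                        row.append(np.nan)
                    else:
                        row.append(float(sum(gt)))
                locus_id = rec.id or f"{rec.chrom}:{rec.pos}"
                records.append((locus_id, row))
                locus_rows.append((locus_id, rec.chrom, rec.pos))
        calls = pd.DataFrame(
            {lid: vals for lid, vals in records}, index=pd.Index(samples, name="individual")
        )
        locus_meta = pd.DataFrame(
            [(c, p) for _, c, p in locus_rows],
            columns=["chrom", "pos"],
            index=[lid for lid, _, _ in locus_rows],
        )
        locus_meta["gene"] = "."
    else:
        raise ValueError(f"unknown genotype format {format!r}")

    if individuals is None:
        individuals = pd.DataFrame(
            {"population": "unknown"}, index=calls.index
        )
    else:
        individuals = individuals.loc[calls.index]
    if loci is None:
        loci = locus_meta
    gm = GenotypeMatrix(calls, individuals, loci)
    gm.calls.attrs["n_multiallelic_skipped"] = n_multi
    return gm


def write_genotypes(g: GenotypeMatrix, path, params: Optional[Mapping] = None) -> None:
    df = g.calls.copy()
    out = df.map(lambda x: "NA" if pd.isna(x) else str(int(x)))
    write_table(out, path, params)


def read_population_map(path) -> pd.DataFrame:
    """Read an individual -> population (and optional group) map TSV."""
    df = read_table(path, index_col=0, dtype=str)
    return df


def write_bed(regions: pd.DataFrame, path) -> None:
    """Write 1-based inclusive regions as sorted 0-based half-open BED.

    ``regions`` needs columns chrom, start, end with start <= end.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if len(regions):
        bad = regions["start"] > regions["end"]
        if bad.any():
            row = regions[bad].iloc[0]
            raise ValueError(
                f"invalid region {row['chrom']}:{row['start']}-{row['end']} "
                "(start > end)"
            )
        regions = regions.sort_values(["chrom", "start"])
    with open(path, "w") as fh:
        for _, row in regions.iterrows():
            fh.write(f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}\n")


def read_pool_vcf(
    path, merged_sample: str = "MERGED"
) -> tuple[pd.DataFrame, list]:
    """Read a pool VCF with per-sample AD fields into a raw variant table.

    Each VCF sample is a pool; its alternate-allele frequency is
    AD[1] / sum(AD) and its coverage sum(AD).  A sample named
    ``merged_sample`` supplies the merged-pool columns; if absent the
    merged depths are the sums over pools.  Multi-allelic sites are kept
    (``n_alleles`` column) so the filter can reject them explicitly.

    Returns (variant table, pool names).
    """
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        pools = [s for s in samples if s != merged_sample]
        for rec in vcf:
            n_alleles = 1 + (len(rec.alts) if rec.alts else 0)
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "n_alleles": n_alleles,
                "qual": rec.qual if rec.qual is not None else np.nan,
            }
            tot_ref = tot_alt = 0
            for s in pools:
                ad = rec.samples[s].get("AD")
                if ad is None or ad[0] is None:
                    row[f"freq_{s}"] = np.nan
                    row[f"cov_{s}"] = 0
                    continue
                ref_d = ad[0]
                alt_d = sum(a for a in ad[1:] if a is not None)
                cov = ref_d + alt_d
                row[f"cov_{s}"] = cov
                row[f"freq_{s}"] = alt_d / cov if cov else np.nan
                tot_ref += ref_d
                tot_alt += alt_d
            if merged_sample in samples:
                ad = rec.samples[merged_sample].get("AD")
                if ad is None or ad[0] is None:
                    row["freq_merged"] = np.nan
                    row["cov_merged"] = 0
                else:
                    cov = ad[0] + sum(a for a in ad[1:] if a is not None)
                    row["cov_merged"] = cov
                    row["freq_merged"] = (cov - ad[0]) / cov if cov else np.nan
            else:
                cov = tot_ref + tot_alt
                row["cov_merged"] = cov
                row["freq_merged"] = tot_alt / cov if cov else np.nan
            rows.append(row)
    return pd.DataFrame(rows), pools


def write_pool_vcf(counts: PoolReadCounts, path, include_merged: bool = True) -> None:
    """Write simulated pool read counts as a minimal VCF with AD fields.

    One sample per pool plus a MERGED sample summing depths across pools.
    REF/ALT are placeholder A/T since only depths matter downstream.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pools = list(counts.ref_depth.columns)
    samples = pools + (["MERGED"] if include_merged else [])
    contigs = list(pd.unique(counts.snps["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=cottonwood-v{__version__}\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref,alt)">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        ref = counts.ref_depth.to_numpy(dtype=int)
        alt = counts.alt_depth.to_numpy(dtype=int)
        for i, (snp_id, meta) in enumerate(counts.snps.iterrows()):
            fields = [
                str(meta["chrom"]), str(int(meta["pos"])), str(snp_id),
                "A", "T", "99", "PASS", ".", "AD",
            ]
            for j in range(len(pools)):
                fields.append(f"{ref[i, j]},{alt[i, j]}")
            if include_merged:
                fields.append(f"{ref[i].sum()},{alt[i].sum()}")
            fh.write("\t".join(fields) + "\n")


def pool_counts_to_variant_table(counts: PoolReadCounts, qual: float = 99.0) -> pd.DataFrame:
    """Raw variant table (filter_pool_variants input) from simulated counts.

    Merged depths are the per-SNP sums over pools; sites are biallelic by
    construction.
    """
    cov = counts.coverage
    out = counts.snps[["chrom", "pos"]].copy()
    out["n_alleles"] = 2
    out["qual"] = qual
    for pool in counts.ref_depth.columns:
        c = cov[pool]
        with np.errstate(invalid="ignore", divide="ignore"):
            f = counts.alt_depth[pool] / c
        out[f"freq_{pool}"] = f.where(c > 0, np.nan)
        out[f"cov_{pool}"] = c
    mcov = cov.sum(axis=1)
    malt = counts.alt_depth.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mf = malt / mcov
    out["freq_merged"] = mf.where(mcov > 0, np.nan)
    out["cov_merged"] = mcov
    return out.reset_index(drop=True)
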