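"""Pool-sequencing differentiation: variant filtering, endemic SNP
classification, heterozygosity-based Fst and windowed genome scans.

Allele frequencies (not raw read counts) feed the Fst calculation: per SNP
the within-side heterozygosity Hs is the mean of 2p(1-p) over the two
sides of the contrast and the total Ht is 2 p_bar (1 - p_bar) with p_bar
the unweighted mean across sides; the multilocus index is the ratio of
sums (sum Ht - sum Hs) / sum Ht, to which monomorphic SNPs contribute
zeros when included.  No pool-size or coverage variance correction is
applied, a documented limitation of frequency-based pool Fst.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .containers import PoolFrequencies

__all__ = [
    "PoolFilterRules",
    "filter_pool_variants",
    "apply_detection_limit",
    "classify_endemic",
    "EndemicSummary",
    "pool_fst",
    "FstResult",
    "pairwise_fst_matrix",
    "one_vs_rest_fst",
    "fst_scan",
    "FstScan",
]

_CHROM_RE = re.compile(r"^(chr)?\d+$", re.IGNORECASE)


@dataclass
class PoolFilterRules:
    """Retention rules for raw pool variant calls.

    A SNP is retained iff it is biallelic, called in every individual pool
    with coverage inside [min_cov, max_cov] (inclusive), called in the
    merged pool with coverage >= merged_min_cov, has quality >= min_qual,
    and lies on a named chromosome (scaffolds dropped).
    """

    min_cov: int = 150
    max_cov: int = 500
    merged_min_cov: int = 200
    min_qual: float = 20.0
    chromosomes: Optional[Sequence[str]] = None  # None = r"(chr)?\d+" names


def _is_chromosome(chrom: str, allowed: Optional[set]) -> bool:
    if allowed is not None:
        return chrom in allowed
    return bool(_CHROM_RE.match(str(chrom).replace("Chr", "").replace("chr", ""))
                or _CHROM_RE.match(str(chrom)))


def filter_pool_variants(
    variants: pd.DataFrame,
    pools: Sequence[str],
    pool_sizes: Union[int, pd.Series] = 20,
    rules: PoolFilterRules = PoolFilterRules(),
) -> tuple[PoolFrequencies, pd.Series]:
    """Apply the retention rules to a raw variant table.

    ``variants`` needs columns ``chrom``, ``pos``, ``n_alleles``, ``qual``,
    ``freq_<pool>`` / ``cov_<pool>`` for each individual pool, and
    ``freq_merged`` / ``cov_merged`` for the merged calls (NaN frequency =
    not called in that pool).  Returns the surviving SNPs as
    :class:`PoolFrequencies` plus a Series of rejection counts per rule
    (a SNP is charged to the first rule it fails, in the order biallelic,
    chromosome, quality, pool coverage, merged pool).
    """
    for pool in pools:
        for pre in ("freq", "cov"):
            col = f"{pre}_{pool}"
            if col not in variants.columns:
                raise ValueError(f"variant table lacks required column {col!r}")
    allowed = set(rules.chromosomes) if rules.chromosomes is not None else None

    df = variants.reset_index(drop=True)
    n = len(df)
    reason = np.full(n, "", dtype=object)

    biallelic = df["n_alleles"].to_numpy() == 2
    on_chrom = df["chrom"].map(lambda c: _is_chromosome(c, allowed)).to_numpy()
    qual_ok = df["qual"].to_numpy(dtype=float) >= rules.min_qual
    cov_ok = np.ones(n, dtype=bool)
    for pool in pools:
        cov = df[f"cov_{pool}"].to_numpy(dtype=float)
        called = ~df[f"freq_{pool}"].isna().to_numpy()
        cov_ok &= called & (cov >= rules.min_cov) & (cov <= rules.max_cov)
    if "cov_merged" in df.columns:
        mcov = df["cov_merged"].to_numpy(dtype=float)
        mcalled = ~df["freq_merged"].isna().to_numpy()
        merged_ok = mcalled & (mcov >= rules.merged_min_cov)
    else:
        raise ValueError("variant table lacks merged-pool columns")

    reason[~biallelic] = "not_biallelic"
    reason[(reason == "") & ~on_chrom] = "not_on_chromosome"
    reason[(reason == "") & ~qual_ok] = "low_quality"
    reason[(reason == "") & ~cov_ok] = "pool_coverage"
    reason[(reason == "") & ~merged_ok] = "merged_pool"
    keep = reason == ""

    rejected = pd.Series(reason[~keep]).value_counts()
    kept = df[keep]
    freqs = kept[[f"freq_{p}" for p in pools]].copy()
    freqs.columns = list(pools)
    cov = kept[[f"cov_{p}" for p in pools]].copy()
    cov.columns = list(pools)
    snp_cols = ["chrom", "pos"] + (
        ["freq_merged", "cov_merged"] if "freq_merged" in kept.columns else []
    )
    snps = kept[snp_cols].copy()
    if isinstance(pool_sizes, pd.Series):
        sizes = pool_sizes.loc[list(pools)]
    else:
        sizes = pd.Series(int(pool_sizes), index=list(pools))
    pf = PoolFrequencies(freqs, cov, snps, sizes).sort_by_position()
    return pf, rejected


def apply_detection_limit(p: PoolFrequencies, limit: float = 0.02) -> PoolFrequencies:
    """Zero out frequencies strictly below the pool-seq detection limit.

    Frequencies exactly at the limit are kept.  Idempotent.
    """
    if not (0.0 <= limit < 0.5):
        raise ValueError("limit must lie in [0, 0.5)")
    f = p.freqs.where(p.freqs >= limit, 0.0)
    snps = p.snps.copy()
    if "freq_merged" in snps.columns:
        snps["freq_merged"] = snps["freq_merged"].where(
            snps["freq_merged"] >= limit, 0.0
        )
    return PoolFrequencies(f, p.coverage, snps, p.pool_sizes)


@dataclass
class EndemicSummary:
    """Per-SNP polymorphism categories and per-pool counts."""

    categories: pd.Series  # invariant | polymorphic_in_all | endemic:<pool> | shared_subset
    summary: pd.DataFrame  # per pool: n_polymorphic, n_endemic[, n_endemic_excl_admixed]
    n_polymorphic_in_all: int
    n_invariant: int


def _categorize(poly: pd.DataFrame) -> pd.Series:
    n_poly = poly.sum(axis=1)
    cat = pd.Series("shared_subset", index=poly.index, dtype=object)
    cat[n_poly == 0] = "invariant"
    cat[n_poly == poly.shape[1]] = "polymorphic_in_all"
    single = n_poly == 1
    if single.any():
        which = poly.loc[single].idxmax(axis=1)
        cat.loc[single] = "endemic:" + which.astype(str)
    return cat


def classify_endemic(
    p: PoolFrequencies, admixed_pool: Optional[str] = None
) -> EndemicSummary:
    """Classify each SNP by which pools it is polymorphic in.

    A SNP is polymorphic in a pool iff 0 < frequency < 1.  When
    ``admixed_pool`` is named, endemic counts are also computed over the
    remaining pools only (``n_endemic_excl_admixed``), since alleles
    segregating in an admixed pool are expected to echo its source groups.
    """
    if len(p.pools) < 2:
        raise ValueError("need at least two pools")
    f = p.freqs
    poly = (f > 0) & (f < 1)
    cat = _categorize(poly)
    rows = {}
    for pool in p.pools:
        rows[pool] = {
            "n_polymorphic": int(poly[pool].sum()),
            "n_endemic": int((cat == f"endemic:{pool}").sum()),
        }
    if admixed_pool is not None:
        others = [q for q in p.pools if q != admixed_pool]
        cat_excl = _categorize(poly[others])
        for pool in others:
            rows[pool]["n_endemic_excl_admixed"] = int(
                (cat_excl == f"endemic:{pool}").sum()
            )
    summary = pd.DataFrame(rows).T
    return EndemicSummary(
        categories=cat,
        summary=summary,
        n_polymorphic_in_all=int((cat == "polymorphic_in_all").sum()),
        n_invariant=int((cat == "invariant").sum()),
    )


@dataclass
class FstResult:
    """Multilocus Fst and per-SNP track for one contrast."""

    contrast: str
    fst: float
    undefined: bool
    track: pd.DataFrame = field(repr=False)  # chrom, pos, hs, ht, fst
    n_snps: int = 0


def _nei_two_sides(fa: np.ndarray, fb: np.ndarray):
    hs = (2 * fa * (1 - fa) + 2 * fb * (1 - fb)) / 2.0
    pbar = (fa + fb) / 2.0
    ht = 2 * pbar * (1 - pbar)
    return hs, ht


def pool_fst(
    p: PoolFrequencies,
    contrast: Union[tuple, str],
    include_monomorphic: bool = True,
) -> FstResult:
    """Heterozygosity-based Fst for a pair of pools or one pool vs the rest.

    ``contrast`` is either ``(pool_a, pool_b)`` or a single pool name, in
    which case the second side is the unweighted mean frequency of the
    other pools.  SNPs monomorphic on both sides contribute zero to both
    the Hs and Ht sums; excluding them (``include_monomorphic=False``)
    drops them from the sums entirely.
    """
    if isinstance(contrast, str):
        if contrast not in p.pools:
            raise ValueError(f"unknown pool {contrast!r}")
        rest = [q for q in p.pools if q != contrast]
        fa = p.freqs[contrast].to_numpy(dtype=float)
        fb = p.freqs[rest].mean(axis=1).to_numpy(dtype=float)
        name = f"{contrast}_vs_rest"
    else:
        a, b = contrast
        for q in (a, b):
            if q not in p.pools:
                raise ValueError(f"unknown pool {q!r}")
        fa = p.freqs[a].to_numpy(dtype=float)
        fb = p.freqs[b].to_numpy(dtype=float)
        name = f"{a}_vs_{b}"

    hs, ht = _nei_two_sides(fa, fb)
    if include_monomorphic:
        sel = np.ones(len(hs), dtype=bool)
    else:
        sel = ht > 0
    sum_ht = float(ht[sel].sum())
    sum_hs = float(hs[sel].sum())
    undefined = sum_ht == 0.0
    fst = float("nan") if undefined else (sum_ht - sum_hs) / sum_ht
    with np.errstate(invalid="ignore", divide="ignore"):
        per_snp = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), np.nan)
    track = pd.DataFrame(
        {
            "chrom": p.snps["chrom"].to_numpy(),
            "pos": p.snps["pos"].to_numpy(),
            "hs": hs,
            "ht": ht,
            "fst": per_snp,
        },
        index=p.freqs.index,
    )
    return FstResult(name, fst, undefined, track, n_snps=int(sel.sum()))


def pairwise_fst_matrix(
    p: PoolFrequencies, include_monomorphic: bool = True
) -> pd.DataFrame:
    """Symmetric matrix of multilocus pairwise pool Fst (diagonal 0)."""
    pools = p.pools
    mat = pd.DataFrame(0.0, index=pools, columns=pools)
    for i, a in enumerate(pools):
        for b in pools[i + 1 :]:
            fst = pool_fst(p, (a, b), include_monomorphic).fst
            mat.loc[a, b] = mat.loc[b, a] = fst
    return mat


def one_vs_rest_fst(
    p: PoolFrequencies, include_monomorphic: bool = True
) -> pd.Series:
    """Multilocus Fst of each pool against the mean of the others."""
    return pd.Series(
        {q: pool_fst(p, q, include_monomorphic).fst for q in p.pools},
        name="fst_one_vs_rest",
    )


@dataclass
class FstScan:
    """Windowed Fst track with flagged peak regions."""

    windows: pd.DataFrame  # chrom, start, end, n_snps, mean_fst, is_peak
    peaks: pd.DataFrame  # chrom, start, end (1-based inclusive, merged)
    threshold: float


def fst_scan(
    track: pd.DataFrame,
    window_size_bp: int = 500_000,
    min_snps: int = 5,
    peak_quantile: float = 0.99,
) -> FstScan:
    """Tile each chromosome with half-open windows and flag Fst peaks.

    Windows are [start, start + window) with 1-based starts; a window needs
    at least ``min_snps`` SNPs with a defined per-SNP Fst to score.
    Windows whose mean is strictly above the ``peak_quantile`` quantile of
    all window means are peaks; adjacent peak windows merge into regions.
    A constant track yields no peaks (nothing exceeds the quantile
    strictly).
    """
    t = track.dropna(subset=["fst"]).sort_values(["chrom", "pos"])
    rows = []
    for chrom, sub in t.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        win_idx = (pos - 1) // window_size_bp
        for w in np.unique(win_idx):
            vals = sub["fst"].to_numpy()[win_idx == w]
            if len(vals) < min_snps:
                continue
            start = int(w) * window_size_bp + 1
            rows.append(
                (chrom, start, start + window_size_bp, len(vals), float(vals.mean()))
            )
    windows = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_snps", "mean_fst"]
    )
    if windows.empty:
        return FstScan(windows.assign(is_peak=[]), windows.copy(), float("nan"))
    threshold = float(windows["mean_fst"].quantile(peak_quantile))
    windows["is_peak"] = windows["mean_fst"] > threshold

    peaks = []
    for chrom, sub in windows[windows["is_peak"]].groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur_start = cur_end = None
        for _, row in sub.iterrows():
            if cur_end is not None and row["start"] == cur_end:
                cur_end = row["end"]
            else:
                if cur_start is not None:
                    peaks.append((chrom, cur_start, cur_end - 1))
                cur_start, cur_end = row["start"], row["end"]
        if cur_start is not None:
            peaks.append((chrom, cur_start, cur_end - 1))
    peaks_df = pd.DataFrame(peaks, columns=["chrom", "start", "end"])
    return FstScan(windows, peaks_df, threshold)
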