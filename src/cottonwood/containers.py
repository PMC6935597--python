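"""Core in-memory containers shared across the pipeline.

Genotypes are diploid biallelic calls coded as the count of the alternate
allele (0, 1, 2) with ``NaN`` for missing.  Pool data carry per-pool
alternate-allele frequencies and read coverages for SNPs located on a
reference assembly.  All genomic coordinates inside the package are 1-based
inclusive; BED export is the only 0-based surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan

_VALID_CODES = frozenset({0.0, 1.0, 2.0})


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotype calls with individual and locus metadata.

    Parameters
    ----------
    calls
        DataFrame of shape (individuals, loci); values in {0, 1, 2, NaN}.
        Index = individual ids, columns = locus ids.
    individuals
        Per-individual metadata indexed like ``calls``; expected columns
        include ``population`` and optionally ``latitude`` / ``longitude``.
    loci
        Per-locus metadata indexed like ``calls.columns``; expected columns
        include ``chrom``, ``pos`` and optionally ``gene``.
    """

    calls: pd.DataFrame
    individuals: pd.DataFrame
    loci: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.calls.index.is_unique:
            raise ValueError("individual ids must be unique")
        if not self.calls.columns.is_unique:
            raise ValueError("locus ids must be unique")
        if not self.calls.index.equals(self.individuals.index):
            raise ValueError("calls.index and individuals.index differ")
        if not self.calls.columns.equals(self.loci.index):
            raise ValueError("calls.columns and loci.index differ")
        vals = self.calls.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, [0.0, 1.0, 2.0]))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {vals[i, j]!r} for individual "
                f"{self.calls.index[i]!r} at locus {self.calls.columns[j]!r}"
            )

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls.loc[ids], self.individuals.loc[ids], self.loci
        )

    def subset_loci(self, locus_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls[locus_ids], self.individuals, self.loci.loc[locus_ids]
        )

    def missing_fraction(self) -> pd.Series:
        """Per-individual fraction of missing calls."""
        return self.calls.isna().mean(axis=1)


@dataclass
class PoolFrequencies:
    """Per-pool alternate-allele frequencies and coverages for filtered SNPs.

    ``freqs`` and ``coverage`` are (SNP, pool) DataFrames with identical
    shape; ``snps`` holds chrom/pos metadata on the same index, sorted by
    chromosome then position; ``pool_sizes`` maps pool name to the number of
    diploid individuals in the pool.
    """

    freqs: pd.DataFrame
    coverage: pd.DataFrame
    snps: pd.DataFrame
    pool_sizes: pd.Series

    def __post_init__(self) -> None:
        if not self.freqs.index.equals(self.coverage.index):
            raise ValueError("freqs and coverage indices differ")
        if not self.freqs.columns.equals(self.coverage.columns):
            raise ValueError("freqs and coverage pools differ")
        if not self.freqs.index.equals(self.snps.index):
            raise ValueError("freqs and snps indices differ")
        f = self.freqs.to_numpy(dtype=float)
        if np.nanmin(f, initial=0.0) < 0 or np.nanmax(f, initial=0.0) > 1:
            raise ValueError("pool allele frequencies must lie in [0, 1]")
        missing_pools = set(self.freqs.columns) - set(self.pool_sizes.index)
        if missing_pools:
            raise ValueError(f"pool sizes missing for {sorted(missing_pools)}")

    @property
    def pools(self) -> list:
        return list(self.freqs.columns)

    @property
    def n_snps(self) -> int:
        return self.freqs.shape[0]

    def merged_freq(self) -> pd.Series:
        """Unweighted mean frequency across pools (equal pool sizes)."""
        return self.freqs.mean(axis=1)

    def sort_by_position(self) -> "PoolFrequencies":
        order = self.snps.sort_values(["chrom", "pos"]).index
        return PoolFrequencies(
            self.freqs.loc[order],
            self.coverage.loc[order],
            self.snps.loc[order],
            self.pool_sizes,
        )
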