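"""Sample-retention filters for SNP-array genotype data.

The chain mirrors the usual pre-analysis hygiene for range-wide tree
collections: drop interspecific hybrids flagged by a diagnostic SNP panel,
collapse clonal ramets to a single genet, and discard individuals with
excessive missing data.  The fixed order is hybrids -> clones ->
missingness and the whole chain is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = ["QCReport", "exclude_hybrids", "remove_clones", "filter_missingness", "run_qc"]


@dataclass
class QCReport:
    """Counts and ids removed by one filter step."""

    step: str
    n_input: int
    removed_ids: list
    n_retained: int

    @property
    def n_removed(self) -> int:
        return len(self.removed_ids)

    def __post_init__(self) -> None:
        assert self.n_removed + self.n_retained == self.n_input


def exclude_hybrids(
    g: GenotypeMatrix,
    diagnostic_panel: pd.Series,
    max_foreign_fraction: float = 0.1,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove individuals carrying too many non-focal diagnostic alleles.

    ``diagnostic_panel`` maps panel locus id -> the genotype code (0 or 2)
    the focal species is expected to be fixed for.  An individual's foreign
    fraction is (number of non-focal alleles) / (2 * panel loci called);
    strictly exceeding ``max_foreign_fraction`` removes it.  An F1 hybrid is
    heterozygous at every panel locus, foreign fraction 0.5.
    """
    missing = [loc for loc in diagnostic_panel.index if loc not in g.calls.columns]
    if missing:
        raise ValueError(f"diagnostic panel locus {missing[0]!r} absent from genotypes")
    sub = g.calls[list(diagnostic_panel.index)].to_numpy(dtype=float)
    expected = diagnostic_panel.to_numpy(dtype=float)
    # foreign allele count per call: |genotype - expected-fixed code|
    foreign = np.abs(sub - expected[None, :])
    called = ~np.isnan(sub)
    with np.errstate(invalid="ignore"):
        frac = np.nansum(foreign, axis=1) / (2 * called.sum(axis=1))
    frac = np.where(called.sum(axis=1) == 0, 0.0, frac)
    keep = frac <= max_foreign_fraction
    removed = list(g.calls.index[~keep])
    out = g.subset_individuals(g.calls.index[keep])
    return out, QCReport("hybrids", g.n_individuals, removed, out.n_individuals)


def remove_clones(
    g: GenotypeMatrix, max_mismatch: int = 0
) -> tuple[GenotypeMatrix, QCReport]:
    """Collapse putative clones, keeping the first individual in input order.

    Two individuals are clonemates when their genotypes mismatch (counting
    |g_i - g_j| > 0 per locus, ignoring loci missing in either) at no more
    than ``max_mismatch`` loci.  Clone groups are formed greedily in input
    order, so membership is stable and reproducible.
    """
    vals = g.calls.to_numpy(dtype=float)
    n = vals.shape[0]
    keep = np.ones(n, dtype=bool)
    kept_rows: list[int] = []
    for i in range(n):
        dup = False
        for j in kept_rows:
            both = ~np.isnan(vals[i]) & ~np.isnan(vals[j])
            mism = np.count_nonzero(vals[i, both] != vals[j, both])
            if mism <= max_mismatch:
                dup = True
                break
        if dup:
            keep[i] = False
        else:
            kept_rows.append(i)
    removed = list(g.calls.index[~keep])
    out = g.subset_individuals(g.calls.index[keep])
    return out, QCReport("clones", g.n_individuals, removed, out.n_individuals)


def filter_missingness(
    g: GenotypeMatrix, threshold: float = 0.10
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove individuals missing strictly more than ``threshold`` of loci."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    frac = g.missing_fraction()
    keep = frac <= threshold
    removed = list(g.calls.index[~keep])
    out = g.subset_individuals(g.calls.index[keep])
    return out, QCReport("missingness", g.n_individuals, removed, out.n_individuals)


def run_qc(
    g: GenotypeMatrix,
    diagnostic_panel: pd.Series | None = None,
    max_foreign_fraction: float = 0.1,
    max_mismatch: int = 0,
    missing_threshold: float = 0.10,
) -> tuple[GenotypeMatrix, list[QCReport]]:
    """Full chain: hybrids -> clones -> missingness; reports are additive."""
    reports = []
    if diagnostic_panel is not None and len(diagnostic_panel):
        g, rep = exclude_hybrids(g, diagnostic_panel, max_foreign_fraction)
        reports.append(rep)
    g, rep = remove_clones(g, max_mismatch)
    reports.append(rep)
    g, rep = filter_missingness(g, missing_threshold)
    reports.append(rep)
    return g, reports
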