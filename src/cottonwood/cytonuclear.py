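"""Chloroplast haplotypes and cytonuclear discordance (capture) detection.

Chloroplast SNPs are maternally inherited and effectively haploid, so the
ordered allele string across the retained cpSNPs defines a haplotype.  A
haplotype is assigned to the nuclear lineage in which its pure carriers
predominate; an individual whose nuclear lineage differs from its
haplotype's lineage of origin is a capture event, counted directionally
(cp donor lineage -> nuclear recipient lineage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .admixture import LineageClassification

__all__ = [
    "HaplotypeTable",
    "CaptureReport",
    "build_cp_haplotypes",
    "map_haplotypes_to_lineages",
    "detect_capture",
]


@dataclass
class HaplotypeTable:
    """Per-individual chloroplast haplotype labels and their catalogue."""

    assignments: pd.Series  # individual id -> haplotype string
    catalogue: pd.DataFrame  # haplotype -> count, frequency (sorted by count)
    excluded: list  # individuals dropped for missing cp calls
    lineage_map: Optional[pd.DataFrame] = None  # haplotype -> lineage, confidence

    @property
    def n_haplotypes(self) -> int:
        return len(self.catalogue)


def build_cp_haplotypes(cp_genotypes: pd.DataFrame) -> HaplotypeTable:
    """Concatenate haploid cpSNP alleles into per-individual haplotypes.

    ``cp_genotypes`` is individuals x cp loci with haploid allele codes
    (0/1, or single letters); diploid-style heterozygous codes (genotype 1
    on the 0/1/2 scale) are organellar impossibilities and raise.
    Individuals with any missing call are excluded and listed.
    """
    vals = cp_genotypes.to_numpy()
    numeric = np.issubdtype(np.asarray(vals).dtype, np.number)
    if numeric:
        arr = cp_genotypes.to_numpy(dtype=float)
        het = arr == 1.0
        # haploid data coded 0/1 never hits 2; a 2 alongside a 1 signals
        # diploid-style coding where 1 means heterozygous
        if (arr == 2.0).any() and het.any():
            i, j = np.argwhere(het)[0]
            raise ValueError(
                f"heterozygous organellar call for individual "
                f"{cp_genotypes.index[i]!r} at locus {cp_genotypes.columns[j]!r}"
            )
        missing = np.isnan(arr)
        alleles = np.where(arr > 0, "1", "0")
    else:
        missing = pd.isna(cp_genotypes).to_numpy()
        alleles = np.asarray(vals, dtype=object)
        for j, col in enumerate(cp_genotypes.columns):
            seen = {a for a in alleles[:, j] if not pd.isna(a)}
            if any(isinstance(a, str) and len(a) > 1 for a in seen):
                i = next(
                    i for i, a in enumerate(alleles[:, j])
                    if isinstance(a, str) and len(a) > 1
                )
                raise ValueError(
                    f"heterozygous organellar call for individual "
                    f"{cp_genotypes.index[i]!r} at locus {col!r}"
                )

    complete = ~missing.any(axis=1)
    excluded = list(cp_genotypes.index[~complete])
    idx = cp_genotypes.index[complete]
    haps = pd.Series(
        ["".join(str(a) for a in row) for row in alleles[complete]],
        index=idx,
        name="haplotype",
    )
    counts = haps.value_counts()
    catalogue = pd.DataFrame(
        {"count": counts, "frequency": counts / counts.sum()}
    )
    return HaplotypeTable(haps, catalogue, excluded)


def map_haplotypes_to_lineages(
    h: HaplotypeTable,
    cls: LineageClassification,
    purity_threshold: float = 0.9,
) -> pd.DataFrame:
    """Assign each haplotype to the modal nuclear lineage of its pure carriers.

    Confidence = fraction of pure carriers in the modal lineage.  Ties go to
    the lowest lineage index with a warning; haplotypes with no pure carrier
    are left unmapped (lineage -1) and flagged.
    """
    lineage = cls.lineage_of(purity_threshold)
    rows = []
    for hap in h.catalogue.index:
        carriers = h.assignments.index[h.assignments == hap]
        carriers = [c for c in carriers if c in lineage.index]
        pure = [c for c in carriers if lineage.loc[c] >= 0]
        if not pure:
            rows.append((hap, -1, float("nan"), 0))
            continue
        counts = lineage.loc[pure].value_counts()
        top = counts.max()
        modal = sorted(counts[counts == top].index)
        if len(modal) > 1:
            warnings.warn(
                f"haplotype {hap!r} splits evenly between lineages {modal}; "
                f"mapped to lineage {modal[0]}"
            )
        rows.append((hap, int(modal[0]), top / counts.sum(), len(pure)))
    out = pd.DataFrame(
        rows, columns=["haplotype", "lineage", "confidence", "n_pure_carriers"]
    ).set_index("haplotype")
    h.lineage_map = out
    return out


@dataclass
class CaptureReport:
    """Directional cytonuclear discordance counts.

    ``pair_counts.loc[i, j]`` = individuals whose nuclear lineage is j but
    whose chloroplast haplotype maps to lineage i (a capture of lineage i's
    chloroplast into lineage j's nuclear background).
    """

    pair_counts: pd.DataFrame  # cp donor lineage x nuclear lineage
    events: pd.DataFrame  # per-individual rows: nuclear, cp lineage, haplotype
    n_concordant: int
    n_excluded_admixed: int
    n_excluded_unmapped: int

    @property
    def n_discordant(self) -> int:
        return int(self.pair_counts.to_numpy().sum())

    def asymmetry_ratio(self, donor: int, recipient: int) -> float:
        """Count(donor->recipient) / count(recipient->donor)."""
        fwd = self.pair_counts.loc[donor, recipient]
        rev = self.pair_counts.loc[recipient, donor]
        return float(fwd) / float(rev) if rev else float("inf")


def detect_capture(
    h: HaplotypeTable,
    cls: LineageClassification,
    lineage_map: Optional[pd.DataFrame] = None,
    nuclear_threshold: float = 0.667,
) -> CaptureReport:
    """Count directional capture events among haplotyped individuals.

    An individual counts as a capture i -> j when it is pure at
    ``nuclear_threshold`` for lineage j and carries a haplotype mapped to
    lineage i != j.  Admixed individuals and carriers of unmapped
    haplotypes are excluded and tallied separately.
    """
    if lineage_map is None:
        lineage_map = h.lineage_map
    if lineage_map is None:
        raise ValueError("haplotype->lineage map required; run map_haplotypes_to_lineages")
    present = set(h.assignments.unique())
    unmapped_haps = present - set(lineage_map.index[lineage_map["lineage"] >= 0])
    nuclear = cls.lineage_of(nuclear_threshold)

    lineages = sorted(
        set(lineage_map.loc[lineage_map["lineage"] >= 0, "lineage"].astype(int))
        | set(int(x) for x in nuclear.unique() if x >= 0)
    )
    pair = pd.DataFrame(0, index=lineages, columns=lineages)
    events = []
    n_conc = n_adm = n_unm = 0
    for ind, hap in h.assignments.items():
        if ind not in nuclear.index:
            continue
        if hap in unmapped_haps:
            n_unm += 1
            continue
        nuc = int(nuclear.loc[ind])
        if nuc < 0:
            n_adm += 1
            continue
        cp = int(lineage_map.loc[hap, "lineage"])
        if cp == nuc:
            n_conc += 1
        else:
            pair.loc[cp, nuc] += 1
            events.append((ind, nuc, cp, hap))
    events_df = pd.DataFrame(
        events, columns=["individual", "nuclear_lineage", "cp_lineage", "haplotype"]
    ).set_index("individual") if events else pd.DataFrame(
        columns=["nuclear_lineage", "cp_lineage", "haplotype"]
    )
    return CaptureReport(pair, events_df, n_conc, n_adm, n_unm)
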