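"""Diversity and differentiation statistics for diploid SNP data.

Implements the classical heterozygosity-based indices (Ho, Hs, Ht, Fis),
two multilocus Fst estimators -- Nei's Gst = (Ht - Hs) / Ht computed as a
ratio of multilocus means, and the Weir-Cockerham variance-components
estimator theta -- and a three-level hierarchical AMOVA (among groups /
among populations within groups / within populations) on allele indicator
variables, with permutation tests for Fct and Fsc.

Multilocus aggregation follows the low-bias convention: numerators and
denominators are summed over loci before the ratio is taken.  Negative
per-locus estimates are retained in the sums; only the headline Fst is
truncated at zero (the raw value is also reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = [
    "expected_heterozygosity",
    "DiversityIndices",
    "diversity_indices",
    "HierarchicalF",
    "amova_hierarchical",
]


def expected_heterozygosity(p):
    """He = 2 p (1 - p) for a biallelic locus; vectorized over ``p``."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("allele frequency must lie in [0, 1]")
    out = 2.0 * arr * (1.0 - arr)
    return out if out.ndim else float(out)


@dataclass
class DiversityIndices:
    """Multilocus diversity summary for one grouping of populations."""

    n_individuals: int
    n_populations: int
    Ho: float
    Hs: float
    Ht: float
    Fis: float
    Fst_gst: float  # Nei Gst = (Ht - Hs) / Ht, truncated at 0
    Fst_gst_raw: float
    Fst_theta: float  # Weir-Cockerham theta, truncated at 0
    Fst_theta_raw: float
    per_locus: pd.DataFrame = field(repr=False, default=None)


def _pop_allele_stats(calls: np.ndarray, pop_idx: np.ndarray, n_pops: int):
    """Per population x locus: allele counts, alt counts, het counts.

    Missing calls drop out locus-wise.  Returns (n_alleles, alt_alleles,
    n_ind_called, n_het) each of shape (n_pops, n_loci).
    """
    n_loci = calls.shape[1]
    called = ~np.isnan(calls)
    onehot = np.zeros((n_pops, calls.shape[0]))
    onehot[pop_idx, np.arange(calls.shape[0])] = 1.0
    n_called = onehot @ called  # individuals called
    alt = onehot @ np.nan_to_num(calls)
    het = onehot @ ((calls == 1.0) & called).astype(float)
    return 2.0 * n_called, alt, n_called, het


def _weir_cockerham(n_i, p_i, h_i):
    """Per-locus Weir-Cockerham variance components (a, b, c).

    n_i, p_i, h_i: (pops, loci) arrays of sample sizes (individuals),
    alternate-allele frequencies and observed heterozygote fractions.
    Populations with no data at a locus are excluded locus-wise.
    """
    valid = n_i > 0
    r = valid.sum(axis=0).astype(float)
    n_tot = np.where(valid, n_i, 0.0)
    nbar = n_tot.sum(axis=0) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_tot.sum(axis=0) - (n_tot**2).sum(axis=0) / n_tot.sum(axis=0)) / (r - 1)
        pbar = (n_tot * np.where(valid, p_i, 0.0)).sum(axis=0) / n_tot.sum(axis=0)
        s2 = (n_tot * np.where(valid, (p_i - pbar) ** 2, 0.0)).sum(axis=0) / (
            (r - 1) * nbar
        )
        hbar = (n_tot * np.where(valid, h_i, 0.0)).sum(axis=0) / n_tot.sum(axis=0)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    return a, b, c


def diversity_indices(
    g: GenotypeMatrix,
    populations: Optional[pd.Series] = None,
    min_pop_size: int = 3,
    sample_size_correction: bool = True,
) -> DiversityIndices:
    """Multilocus Ho, Hs, Ht, Fis and Fst over populations.

    Populations with fewer than ``min_pop_size`` individuals are dropped
    before any calculation.  ``Hs`` gets Nei's small-sample factor
    2n/(2n - 1) per population and locus when ``sample_size_correction`` is
    set; ``Ht`` uses the unweighted mean allele frequency across
    populations.  Both Nei Gst (ratio of multilocus means) and the
    Weir-Cockerham theta are reported.
    """
    if populations is None:
        populations = g.individuals["population"]
    populations = populations.loc[g.calls.index]
    sizes = populations.value_counts()
    valid_pops = sizes[sizes >= min_pop_size].index
    if len(valid_pops) < 2:
        raise ValueError(
            f"need at least two populations with >= {min_pop_size} individuals"
        )
    keep = populations.isin(valid_pops)
    calls = g.calls.loc[keep].to_numpy(dtype=float)
    pops = populations.loc[keep]
    pop_names = list(pd.unique(pops))
    pop_idx = pops.map({p: i for i, p in enumerate(pop_names)}).to_numpy()
    P = len(pop_names)

    n_alleles, alt, n_called, het = _pop_allele_stats(calls, pop_idx, P)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.where(n_alleles > 0, n_alleles, 1), np.nan)
        ho = np.where(n_called > 0, het / np.where(n_called > 0, n_called, 1), np.nan)
    hs = 2.0 * p * (1.0 - p)
    if sample_size_correction:
        with np.errstate(invalid="ignore", divide="ignore"):
            hs = hs * n_alleles / np.maximum(n_alleles - 1, 1)
    pbar = np.nanmean(p, axis=0)
    ht = 2.0 * pbar * (1.0 - pbar)

    Ho = float(np.nanmean(np.nanmean(ho, axis=0)))
    Hs_loc = np.nanmean(hs, axis=0)
    Hs = float(np.nanmean(Hs_loc))
    Ht = float(np.nanmean(ht))
    gst_raw = (np.nansum(ht) - np.nansum(Hs_loc)) / np.nansum(ht)
    Fis = 1.0 - Ho / Hs if Hs > 0 else float("nan")

    a, b, c = _weir_cockerham(n_called, p, np.nan_to_num(ho))
    denom = np.nansum(a + b + c)
    theta_raw = float(np.nansum(a) / denom) if denom > 0 else float("nan")

    per_locus = pd.DataFrame(
        {
            "Ho": np.nanmean(ho, axis=0),
            "Hs": Hs_loc,
            "Ht": ht,
            "wc_a": a,
            "wc_b": b,
            "wc_c": c,
        },
        index=g.calls.columns,
    )
    return DiversityIndices(
        n_individuals=int(keep.sum()),
        n_populations=P,
        Ho=Ho,
        Hs=Hs,
        Ht=Ht,
        Fis=float(Fis),
        Fst_gst=max(float(gst_raw), 0.0),
        Fst_gst_raw=float(gst_raw),
        Fst_theta=max(theta_raw, 0.0) if np.isfinite(theta_raw) else theta_raw,
        Fst_theta_raw=theta_raw,
        per_locus=per_locus,
    )


@dataclass
class HierarchicalF:
    """Three-level AMOVA result on allele indicators."""

    Fct: float  # among groups
    Fsc: float  # among populations within groups
    Fst: float  # among populations overall
    sigma2_among_groups: float
    sigma2_among_pops: float
    sigma2_within: float
    p_Fct: Optional[float] = None
    p_Fsc: Optional[float] = None
    n_permutations: int = 0

    @property
    def sigma2_total(self) -> float:
        return (
            self.sigma2_among_groups + self.sigma2_among_pops + self.sigma2_within
        )


def _amova_components(alt, n_alleles, group_of_pop):
    """Summed-over-loci AMOVA variance components from per-pop allele counts.

    alt, n_alleles: (pops, loci) alternate-allele counts and allele totals.
    group_of_pop: (pops,) integer group index.  Returns (s2a, s2b, s2c)
    summed over loci.  The decomposition treats each allele copy as an
    observation of the 0/1 alternate indicator, so the within-population
    sum of squares at a locus is n p (1 - p).
    """
    G = group_of_pop.max() + 1
    n_g = np.zeros((G, alt.shape[1]))
    alt_g = np.zeros((G, alt.shape[1]))
    np.add.at(n_g, group_of_pop, n_alleles)
    np.add.at(alt_g, group_of_pop, alt)
    s2a = s2b = s2c = 0.0
    for l in range(alt.shape[1]):
        n_p = n_alleles[:, l]
        ok = n_p > 0
        if ok.sum() < 2:
            continue
        n_p = n_p[ok]
        a_p = alt[ok, l]
        gop = group_of_pop[ok]
        p_p = a_p / n_p
        N = n_p.sum()
        n_gl = np.bincount(gop, weights=n_p, minlength=G)
        a_gl = np.bincount(gop, weights=a_p, minlength=G)
        gok = n_gl > 0
        if gok.sum() < 2:
            continue
        p_g = np.where(gok, a_gl / np.where(gok, n_gl, 1), 0.0)
        p_tot = a_p.sum() / N
        P_eff = len(n_p)
        G_eff = int(gok.sum())
        ss_within = float((n_p * p_p * (1 - p_p)).sum())
        ss_pops = float((n_p * (p_p - p_g[gop]) ** 2).sum())
        ss_groups = float((n_gl[gok] * (p_g[gok] - p_tot) ** 2).sum())
        df_w = N - P_eff
        df_b = P_eff - G_eff
        df_a = G_eff - 1
        if df_w <= 0 or df_b <= 0 or df_a <= 0:
            continue
        sum_np2_over_ng = float(
            sum(
                (n_p[gop == g] ** 2).sum() / n_gl[g]
                for g in np.flatnonzero(gok)
            )
        )
        n_prime = (N - sum_np2_over_ng) / df_b
        n_dprime = (sum_np2_over_ng - (n_p**2).sum() / N) / df_a
        n_tprime = (N - (n_gl[gok] ** 2).sum() / N) / df_a
        ms_w = ss_within / df_w
        ms_b = ss_pops / df_b
        ms_a = ss_groups / df_a
        c_l = ms_w
        b_l = (ms_b - c_l) / n_prime
        a_l = (ms_a - c_l - n_dprime * b_l) / n_tprime
        s2a += a_l
        s2b += b_l
        s2c += c_l
    return s2a, s2b, s2c


def _f_from_components(s2a, s2b, s2c):
    tot = s2a + s2b + s2c
    fct = s2a / tot if tot else float("nan")
    fsc = s2b / (s2b + s2c) if (s2b + s2c) else float("nan")
    fst = (s2a + s2b) / tot if tot else float("nan")
    return fct, fsc, fst


def amova_hierarchical(
    g: GenotypeMatrix,
    groups: pd.Series,
    populations: Optional[pd.Series] = None,
    min_pop_size: int = 3,
    n_permutations: int = 999,
    seed: int = 0,
) -> HierarchicalF:
    """Hierarchical AMOVA: among groups / among pops within groups / within.

    ``groups`` maps individual id -> group label.  Permutation p-values:
    Fct by permuting whole populations among groups, Fsc by permuting
    individuals among populations within their group.  Set
    ``n_permutations=0`` to skip the tests.
    """
    if populations is None:
        populations = g.individuals["population"]
    populations = populations.loc[g.calls.index]
    groups = groups.loc[g.calls.index]
    sizes = populations.value_counts()
    valid_pops = sizes[sizes >= min_pop_size].index
    keep = populations.isin(valid_pops)
    calls = g.calls.loc[keep].to_numpy(dtype=float)
    pops = populations.loc[keep]
    grps = groups.loc[keep]

    pop_names = list(pd.unique(pops))
    pop_idx = pops.map({p: i for i, p in enumerate(pop_names)}).to_numpy()
    P = len(pop_names)
    group_names = list(pd.unique(grps))
    if len(group_names) < 2:
        raise ValueError("need at least two groups")
    # group of each population (populations are nested in groups)
    pop_group = np.empty(P, dtype=int)
    gmap = {n: i for i, n in enumerate(group_names)}
    for i, p in enumerate(pop_names):
        labels = set(grps[pops == p])
        if len(labels) != 1:
            raise ValueError(f"population {p!r} spans multiple groups")
        pop_group[i] = gmap[labels.pop()]
    for gi in range(len(group_names)):
        if not (pop_group == gi).any():
            raise ValueError(
                f"group {group_names[gi]!r} has no population of size >= {min_pop_size}"
            )

    n_alleles, alt, _, _ = _pop_allele_stats(calls, pop_idx, P)
    s2a, s2b, s2c = _amova_components(alt, n_alleles, pop_group)
    fct, fsc, fst = _f_from_components(s2a, s2b, s2c)

    p_fct = p_fsc = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits_ct = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pop_group)
            pa, pb, pc = _amova_components(alt, n_alleles, perm)
            if _f_from_components(pa, pb, pc)[0] >= fct - 1e-12:
                hits_ct += 1
        p_fct = (hits_ct + 1) / (n_permutations + 1)

        hits_sc = 0
        ind_group = pop_group[pop_idx]
        for _ in range(n_permutations):
            new_pop = pop_idx.copy()
            for gi in range(len(group_names)):
                members = np.flatnonzero(ind_group == gi)
                new_pop[members] = pop_idx[members][rng.permutation(members.size)]
            na, al, _, _ = _pop_allele_stats(calls, new_pop, P)
            pa, pb, pc = _amova_components(al, na, pop_group)
            if _f_from_components(pa, pb, pc)[1] >= fsc - 1e-12:
                hits_sc += 1
        p_fsc = (hits_sc + 1) / (n_permutations + 1)

    return HierarchicalF(
        Fct=fct,
        Fsc=fsc,
        Fst=fst,
        sigma2_among_groups=s2a,
        sigma2_among_pops=s2b,
        sigma2_within=s2c,
        p_Fct=p_fct,
        p_Fsc=p_fsc,
        n_permutations=n_permutations,
    )
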