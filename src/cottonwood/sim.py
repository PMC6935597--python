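"""Synthetic data generation for the full analysis pipeline.

Three generators are provided:

``simulate_lineages``
    Structured SNP-array data: several nuclear lineages diverged under the
    Balding-Nichols model, two-lineage admixed individuals, maternally
    inherited chloroplast haplotypes with planted capture (cytonuclear
    discordance) events, plus optional clones, interspecific F1 hybrids and
    missing calls.  Every planted feature is recorded in a truth ledger so
    downstream detectors can be scored exactly.

``simulate_pools``
    Pool sequencing of groups of diploids: negative-binomial read coverage
    per SNP and binomial allele sampling around the true pool frequency,
    with a symmetric per-read error rate.

``simulate_divergence_afs``
    Two-deme forward Wright-Fisher evolution of independent biallelic loci
    from ancestral standing variation, under four divergence scenarios:
    strict isolation, isolation with continuous migration, ancient
    migration (isolation after an early migration epoch) and secondary
    contact (migration resumes after an isolation epoch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, PoolFrequencies

__all__ = [
    "LineageSimSpec",
    "LineageSimResult",
    "DivergenceModelSpec",
    "PoolReadCounts",
    "simulate_lineages",
    "simulate_pools",
    "simulate_divergence_afs",
]

DIVERGENCE_MODELS = (
    "isolation",
    "isolation_with_migration",
    "ancient_migration",
    "secondary_contact",
)


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")


@dataclass
class LineageSimSpec:
    """Parameters of the structured-lineage SNP-array generator.

    ``lineage_fst`` gives each lineage's Balding-Nichols divergence
    parameter F: lineage allele frequencies are Beta-distributed around a
    shared ancestral frequency with variance F * p * (1 - p).
    ``capture_rates[i][j]`` is the probability that an individual whose
    nuclear lineage is i carries the chloroplast haplotype of lineage j
    (a planted capture event); the diagonal must be zero.

    Defaults emulate a range-wide tree survey: ~1,000 individuals spread
    thinly over ~250 localities (three lineages x 84 localities x 4
    trees), genotyped at 93 nuclear and 3 chloroplast SNPs.
    """

    n_lineages: int = 3
    n_pops_per_lineage: int = 84
    n_ind_per_pop: int = 4
    n_loci: int = 93
    lineage_fst: Sequence[float] = (0.15, 0.15, 0.15)
    admix_fraction: float = 0.1
    capture_rates: Optional[Sequence[Sequence[float]]] = None
    missing_rate: float = 0.01
    clone_rate: float = 0.0
    hybrid_rate: float = 0.0
    n_diagnostic_loci: int = 0
    n_cp_loci: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lineages < 2:
            raise ValueError("n_lineages must be at least 2")
        if len(self.lineage_fst) != self.n_lineages:
            raise ValueError("lineage_fst must have one entry per lineage")
        for f in self.lineage_fst:
            if not (0.0 < f < 1.0):
                raise ValueError(f"lineage_fst entries must lie in (0, 1), got {f}")
        _check_prob("admix_fraction", self.admix_fraction)
        _check_prob("missing_rate", self.missing_rate)
        _check_prob("clone_rate", self.clone_rate)
        _check_prob("hybrid_rate", self.hybrid_rate)
        if self.missing_rate >= 1 or self.clone_rate >= 1:
            raise ValueError("missing_rate and clone_rate must be < 1")
        if self.capture_rates is None:
            self.capture_rates = np.zeros((self.n_lineages, self.n_lineages))
        cr = np.asarray(self.capture_rates, dtype=float)
        if cr.shape != (self.n_lineages, self.n_lineages):
            raise ValueError("capture_rates must be n_lineages x n_lineages")
        if (cr < 0).any() or (cr > 1).any():
            raise ValueError("capture_rates entries must be probabilities")
        if np.diag(cr).any():
            raise ValueError("capture_rates diagonal must be zero")
        if cr.sum(axis=1).max() > 1:
            raise ValueError("capture_rates rows must sum to at most 1")
        self.capture_rates = cr
        if self.n_cp_loci < self.n_lineages.bit_length():
            raise ValueError("n_cp_loci too small to encode distinct haplotypes")


@dataclass
class LineageSimResult:
    """Outputs of :func:`simulate_lineages`."""

    genotypes: GenotypeMatrix
    cp_genotypes: pd.DataFrame  # individuals x cp loci, haploid codes {0,1}
    q_true: pd.DataFrame  # individuals x lineages, rows sum to 1
    ledger: pd.DataFrame  # per-individual ground truth
    lineage_freqs: pd.DataFrame  # lineages x loci true allele frequencies

    @property
    def capture_events(self) -> pd.DataFrame:
        """Planted capture events: rows of the ledger where cp was replaced."""
        return self.ledger[self.ledger["captured"]]


def _cp_haplotype_patterns(n_lineages: int, n_cp_loci: int) -> np.ndarray:
    """Lineage-diagnostic haploid allele patterns, one row per lineage.

    With n_cp_loci >= n_lineages each lineage gets a one-hot pattern (plus
    the all-reference pattern for lineage 0 when loci are scarce the binary
    code of the lineage index is used instead); patterns are distinct by
    construction.
    """
    if n_cp_loci >= n_lineages:
        pat = np.zeros((n_lineages, n_cp_loci), dtype=int)
        for k in range(1, n_lineages):
            pat[k, k - 1] = 1
        return pat
    pat = np.zeros((n_lineages, n_cp_loci), dtype=int)
    for k in range(n_lineages):
        for b in range(n_cp_loci):
            pat[k, b] = (k >> b) & 1
    return pat


def simulate_lineages(spec: LineageSimSpec) -> LineageSimResult:
    """Generate structured genotype, chloroplast and admixture truth data.

    The generative model: a shared ancestral allele frequency per locus is
    drawn Uniform(0.05, 0.95); each lineage's frequency is Beta-distributed
    around it (Balding-Nichols, variance F p (1-p)).  Pure individuals have
    admixture vector e_k; a fraction ``admix_fraction`` are two-lineage
    mixtures with weight Uniform(0.2, 0.8).  Genotypes are
    Binomial(2, q . p_locus).  The chloroplast haplotype equals the pattern
    of the individual's nuclear (max-Q) lineage except for planted capture
    events, which replace it with another lineage's pattern and are recorded
    in the ledger.  Clones copy an earlier individual of the same
    population; missing calls are masked independently afterwards.
    """
    rng = np.random.default_rng(spec.seed)
    K = spec.n_lineages
    n_pops = K * spec.n_pops_per_lineage
    n_ind = n_pops * spec.n_ind_per_pop
    L = spec.n_loci

    # Balding-Nichols lineage frequencies around a shared ancestral frequency
    p_anc = rng.uniform(0.05, 0.95, size=L)
    lin_freq = np.empty((K, L))
    for k, f in enumerate(spec.lineage_fst):
        if f < 1e-8:  # no-drift limit; Beta parameters would overflow
            lin_freq[k] = p_anc
        else:
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            lin_freq[k] = rng.beta(a, b)

    pop_of = np.repeat(np.arange(n_pops), spec.n_ind_per_pop)
    home_lineage = pop_of // spec.n_pops_per_lineage

    # admixture vectors
    q = np.zeros((n_ind, K))
    q[np.arange(n_ind), home_lineage] = 1.0
    is_admixed = rng.random(n_ind) < spec.admix_fraction
    partner = np.full(n_ind, -1)
    for i in np.flatnonzero(is_admixed):
        others = [k for k in range(K) if k != home_lineage[i]]
        j = others[rng.integers(len(others))]
        w = rng.uniform(0.2, 0.8)
        q[i] = 0.0
        q[i, home_lineage[i]] = w
        q[i, j] = 1 - w
        partner[i] = j
    nuclear_lineage = q.argmax(axis=1)  # ties broken toward lowest index

    p_ind = q @ lin_freq
    geno = rng.binomial(2, p_ind).astype(float)

    # interspecific F1 hybrids: one haploid genome from the focal gene pool,
    # one from an unrelated species (allele ~ Bernoulli(0.5))
    is_hybrid = rng.random(n_ind) < spec.hybrid_rate
    if is_hybrid.any():
        idx = np.flatnonzero(is_hybrid)
        focal = rng.binomial(1, p_ind[idx])
        foreign = rng.binomial(1, 0.5, size=(len(idx), L))
        geno[idx] = (focal + foreign).astype(float)

    # diagnostic panel: focal species fixed for the reference allele; F1
    # hybrids heterozygous at every panel locus
    D = spec.n_diagnostic_loci
    if D:
        diag = np.zeros((n_ind, D))
        diag[is_hybrid] = 1.0
        geno = np.hstack([geno, diag])

    # chloroplast origin = nuclear lineage, except planted captures
    cp_lineage = nuclear_lineage.copy()
    captured = np.zeros(n_ind, dtype=bool)
    cr = np.asarray(spec.capture_rates)
    if cr.any():
        u = rng.random(n_ind)
        for i in range(n_ind):
            if is_hybrid[i] or is_admixed[i]:
                continue  # captures planted on pure non-hybrid trees only
            cum = 0.0
            for j in range(K):
                cum += cr[nuclear_lineage[i], j]
                if u[i] < cum:
                    cp_lineage[i] = j
                    captured[i] = True
                    break

    patterns = _cp_haplotype_patterns(K, spec.n_cp_loci)
    cp_calls = patterns[cp_lineage].astype(float)

    # clones: copy nuclear + cp calls from an earlier member of the same pop
    clone_of = np.full(n_ind, -1)
    if spec.clone_rate > 0:
        draw = rng.random(n_ind)
        for i in range(n_ind):
            earlier = np.flatnonzero((pop_of == pop_of[i]) & (np.arange(n_ind) < i))
            if earlier.size and draw[i] < spec.clone_rate:
                src = earlier[rng.integers(earlier.size)]
                geno[i] = geno[src]
                cp_calls[i] = cp_calls[src]
                cp_lineage[i] = cp_lineage[src]
                captured[i] = captured[src]
                clone_of[i] = src

    # missingness, masked after cloning so clones differ only by missing calls
    if spec.missing_rate > 0:
        mask = rng.random(geno.shape) < spec.missing_rate
        geno[mask] = np.nan

    ind_ids = pd.Index([f"ind{i:04d}" for i in range(n_ind)], name="individual")
    pop_ids = [f"pop{p:03d}" for p in pop_of]
    nuc_ids = [f"snp{j:03d}" for j in range(L)]
    diag_ids = [f"diag{j:02d}" for j in range(D)]
    locus_ids = pd.Index(nuc_ids + diag_ids, name="locus")

    # illustrative map positions: loci spread over 19 chromosomes
    chroms = [f"Chr{(j % 19) + 1:02d}" for j in range(L)] + ["ChrUn"] * D
    pos = [100_000 * (j // 19 + 1) for j in range(L)] + list(range(1, D + 1))
    genes = [f"gene{j:03d}" for j in range(L)] + ["diagnostic"] * D
    loci = pd.DataFrame({"chrom": chroms, "pos": pos, "gene": genes}, index=locus_ids)

    # rough latitude/longitude gradient per lineage, jittered within pops
    lat = 40 + 4 * home_lineage + rng.normal(0, 0.5, n_ind)
    lon = -100 + 10 * home_lineage + rng.normal(0, 1.0, n_ind)
    individuals = pd.DataFrame(
        {"population": pop_ids, "latitude": lat, "longitude": lon}, index=ind_ids
    )

    gm = GenotypeMatrix(
        pd.DataFrame(geno, index=ind_ids, columns=locus_ids), individuals, loci
    )
    cp_cols = pd.Index([f"cp{j}" for j in range(spec.n_cp_loci)], name="locus")
    cp_df = pd.DataFrame(cp_calls, index=ind_ids, columns=cp_cols)
    q_df = pd.DataFrame(
        q, index=ind_ids, columns=[f"lineage{k}" for k in range(K)]
    )
    ledger = pd.DataFrame(
        {
            "population": pop_ids,
            "lineage": nuclear_lineage,
            "is_admixed": is_admixed,
            "admix_partner": partner,
            "is_hybrid": is_hybrid,
            "clone_of": [ind_ids[s] if s >= 0 else "" for s in clone_of],
            "cp_lineage": cp_lineage,
            "captured": captured,
        },
        index=ind_ids,
    )
    return LineageSimResult(gm, cp_df, q_df, ledger, pd.DataFrame(
        lin_freq, index=[f"lineage{k}" for k in range(K)], columns=locus_ids[: L + D][:L]
    ))


@dataclass
class PoolReadCounts:
    """Simulated per-pool read counts at each SNP."""

    ref_depth: pd.DataFrame  # SNPs x pools
    alt_depth: pd.DataFrame
    snps: pd.DataFrame  # chrom, pos
    pool_sizes: pd.Series  # diploid individuals per pool

    @property
    def coverage(self) -> pd.DataFrame:
        return self.ref_depth + self.alt_depth

    def to_pool_frequencies(self) -> PoolFrequencies:
        """Observed alternate-allele frequencies (alt / coverage)."""
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.alt_depth / cov
        return PoolFrequencies(f.fillna(0.0), cov, self.snps, self.pool_sizes)


def true_pool_frequencies(
    genotypes: GenotypeMatrix, pools: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """True alternate-allele frequency per pool from member genotypes.

    Missing calls are ignored locus-wise; each pool must be non-empty.
    """
    cols = {}
    for name, members in pools.items():
        members = list(members)
        if not members:
            raise ValueError(f"pool {name!r} is empty")
        sub = genotypes.calls.loc[members]
        cols[name] = sub.mean(axis=0, skipna=True) / 2.0
    return pd.DataFrame(cols)


def simulate_pools(
    freqs: pd.DataFrame,
    mean_coverage: float,
    coverage_dispersion: float = 5.0,
    error_rate: float = 0.001,
    pool_size: int | Mapping[str, int] = 20,
    snps: Optional[pd.DataFrame] = None,
    seed: int = 0,
) -> PoolReadCounts:
    """Simulate pool-sequencing read counts from true pool frequencies.

    Coverage per SNP and pool is negative-binomial with the given mean and
    gamma shape ``coverage_dispersion`` (variance mu + mu^2/shape; larger
    shape = closer to Poisson).  Alternate reads are
    Binomial(coverage, f') with f' = f (1 - e) + (1 - f) e for per-read
    error rate e.

    Parameters
    ----------
    freqs
        (SNP, pool) DataFrame of true alternate-allele frequencies, e.g.
        from :func:`true_pool_frequencies`.
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    if freqs.shape[1] == 0:
        raise ValueError("no pools given")
    _check_prob("error_rate", error_rate)
    rng = np.random.default_rng(seed)
    f = freqs.to_numpy(dtype=float)
    if np.isnan(f).any():
        raise ValueError("pool frequencies contain NaN")
    shape = float(coverage_dispersion)
    p_nb = shape / (shape + mean_coverage)
    cov = rng.negative_binomial(shape, p_nb, size=f.shape)
    f_err = f * (1 - error_rate) + (1 - f) * error_rate
    alt = rng.binomial(cov, f_err)
    ref = cov - alt
    if snps is None:
        snps = pd.DataFrame(
            {"chrom": "Chr01", "pos": np.arange(1, len(freqs) + 1)},
            index=freqs.index,
        )
    if isinstance(pool_size, Mapping):
        sizes = pd.Series({p: pool_size[p] for p in freqs.columns})
    else:
        sizes = pd.Series(int(pool_size), index=freqs.columns)
    return PoolReadCounts(
        pd.DataFrame(ref, index=freqs.index, columns=freqs.columns),
        pd.DataFrame(alt, index=freqs.index, columns=freqs.columns),
        snps,
        sizes,
    )


@dataclass
class DivergenceModelSpec:
    """Two-deme divergence scenario for forward Wright-Fisher simulation.

    ``m12`` is the fraction of deme 1's parents drawn from deme 2 each
    generation (and symmetrically for ``m21``).  ``T_switch`` is measured in
    generations before present: under ``ancient_migration`` migration is
    active only while more than ``T_switch`` generations remain; under
    ``secondary_contact`` only during the last ``T_switch`` generations.
    """

    model: Literal[
        "isolation", "isolation_with_migration", "ancient_migration", "secondary_contact"
    ]
    Ne: int = 1000
    T_split: int = 1000
    m12: float = 0.0
    m21: float = 0.0
    T_switch: Optional[int] = None
    n_loci: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in DIVERGENCE_MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        for name, m in (("m12", self.m12), ("m21", self.m21)):
            if not (0.0 <= m <= 0.5):
                raise ValueError(f"{name} must lie in [0, 0.5], got {m}")
        if self.model == "isolation" and (self.m12 or self.m21):
            raise ValueError("isolation model requires m12 = m21 = 0")
        if self.model in ("ancient_migration", "secondary_contact"):
            if self.T_switch is None:
                raise ValueError(f"{self.model} requires T_switch")
            if self.T_switch >= self.T_split:
                raise ValueError("T_switch must be smaller than T_split")
        if self.Ne <= 0 or self.T_split < 0 or self.n_loci <= 0:
            raise ValueError("Ne and n_loci must be positive, T_split >= 0")


def simulate_divergence_afs(spec: DivergenceModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Evolve independent loci in two demes and return final frequencies.

    Ancestral standing variation is Beta(0.5, 0.5) per locus; both demes
    start at the ancestral frequency and then drift as Wright-Fisher
    populations of 2 Ne chromosomes, with deterministic migration applied
    before each binomial resampling step during the model's migration
    epochs.  No new mutation is introduced, so under strict isolation any
    variant shared between demes traces to the ancestral pool.
    """
    rng = np.random.default_rng(spec.seed)
    p0 = rng.beta(0.5, 0.5, size=spec.n_loci)
    p1 = p0.copy()
    p2 = p0.copy()
    two_ne = 2 * spec.Ne
    for t_ago in range(spec.T_split, 0, -1):
        if spec.model == "isolation":
            migrating = False
        elif spec.model == "isolation_with_migration":
            migrating = True
        elif spec.model == "ancient_migration":
            migrating = t_ago > spec.T_switch
        else:  # secondary_contact
            migrating = t_ago <= spec.T_switch
        if migrating and (spec.m12 or spec.m21):
            new1 = (1 - spec.m12) * p1 + spec.m12 * p2
            new2 = (1 - spec.m21) * p2 + spec.m21 * p1
            p1, p2 = new1, new2
        p1 = rng.binomial(two_ne, p1) / two_ne
        p2 = rng.binomial(two_ne, p2) / two_ne
    return p1, p2
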