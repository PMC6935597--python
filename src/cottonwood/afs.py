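"""Two-dimensional joint allele-frequency spectra and divergence-model
scoring.

For pools of N and M diploids the joint spectrum is a (2N+1) x (2M+1)
count matrix: each SNP increments the cell addressed by its rounded
allele-count class in each pool.  Alleles are polarized against the
reference genome (the alternate allele is treated as derived), the only
polarization available without an outgroup.  The low-frequency corner --
cells rare in BOTH pools -- can be masked, since frequencies near the
pool-seq detection limit are unreliable and visually swamp the spectrum.

Observed spectra are scored against candidate divergence scenarios by
simulating each scenario's expected spectrum (forward Wright-Fisher, see
:mod:`cottonwood.sim`) and computing the Jensen-Shannon divergence between
normalized grids over unmasked cells.  Scenarios that differ only in the
timing of migration (isolation-with-migration vs ancient migration vs
secondary contact) produce near-identical spectra; near-ties are therefore
reported explicitly rather than broken silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .containers import PoolFrequencies
from .sim import DivergenceModelSpec, simulate_divergence_afs

__all__ = [
    "AFSGrid",
    "ModelScore",
    "build_afs",
    "mask_low_freq",
    "expected_afs",
    "classify_divergence_model",
]


@dataclass
class AFSGrid:
    """Joint allele-frequency spectrum for two pools.

    ``counts[i, j]`` = number of SNPs whose derived-allele count class is i
    in pool A (0..2N) and j in pool B (0..2M).  ``mask`` marks cells
    excluded from display and model scoring.  Expected (simulated) grids
    are normalized to unit mass over unmasked cells and flagged
    ``normalized``.
    """

    counts: np.ndarray
    pool_a: str
    pool_b: str
    n_a: int  # diploids in pool A
    n_b: int
    mask: np.ndarray = None
    normalized: bool = False
    polarization: str = "alternate allele vs reference genome"

    def __post_init__(self) -> None:
        expected_shape = (2 * self.n_a + 1, 2 * self.n_b + 1)
        if self.counts.shape != expected_shape:
            raise ValueError(
                f"grid shape {self.counts.shape} != {expected_shape} for pools "
                f"of {self.n_a} and {self.n_b} diploids"
            )
        if self.mask is None:
            self.mask = np.zeros_like(self.counts, dtype=bool)

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    @property
    def n_snps(self) -> float:
        """Total mass including masked cells."""
        return float(self.counts.sum())

    def unmasked_counts(self) -> np.ndarray:
        return np.where(self.mask, 0.0, self.counts)

    def normalized_unmasked(self) -> np.ndarray:
        u = self.unmasked_counts().astype(float)
        total = u.sum()
        if total == 0:
            raise ValueError("grid is empty after masking")
        return u / total

    def transpose(self) -> "AFSGrid":
        return AFSGrid(
            self.counts.T.copy(), self.pool_b, self.pool_a, self.n_b, self.n_a,
            self.mask.T.copy(), self.normalized, self.polarization,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(range(2 * self.n_a + 1), name=f"count_{self.pool_a}"),
            columns=pd.Index(range(2 * self.n_b + 1), name=f"count_{self.pool_b}"),
        )


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


def build_afs(p: PoolFrequencies, pool_a: str, pool_b: str) -> AFSGrid:
    """Accumulate the joint spectrum of two pools from their frequencies.

    Cell indices are round(freq * 2N) with half-away-from-zero rounding;
    the grid total equals the number of SNPs.
    """
    for q in (pool_a, pool_b):
        if q not in p.pools:
            raise ValueError(f"unknown pool {q!r}")
        if q not in p.pool_sizes.index or pd.isna(p.pool_sizes[q]):
            raise ValueError(f"pool size missing for {q!r}")
    n_a = int(p.pool_sizes[pool_a])
    n_b = int(p.pool_sizes[pool_b])
    ia = _round_half_away(p.freqs[pool_a].to_numpy(dtype=float) * 2 * n_a)
    ib = _round_half_away(p.freqs[pool_b].to_numpy(dtype=float) * 2 * n_b)
    counts = np.zeros((2 * n_a + 1, 2 * n_b + 1), dtype=float)
    np.add.at(counts, (ia, ib), 1.0)
    return AFSGrid(counts, pool_a, pool_b, n_a, n_b)


def mask_low_freq(g: AFSGrid, cutoff: float = 0.05) -> AFSGrid:
    """Mask cells with frequency <= cutoff on BOTH axes.

    The masked corner spans allele counts 0..floor(cutoff * 2N) on each
    axis (for 20-diploid pools and a 5% cutoff: the 3 x 3 corner of counts
    {0, 1, 2}).  Cells rare on only one axis are untouched.  Counts are
    preserved; masked cells are merely excluded from display and scoring.
    """
    if not (0.0 <= cutoff < 0.5):
        raise ValueError("cutoff must lie in [0, 0.5)")
    ka = int(np.floor(cutoff * 2 * g.n_a))
    kb = int(np.floor(cutoff * 2 * g.n_b))
    mask = g.mask.copy()
    mask[: ka + 1, : kb + 1] = True
    return AFSGrid(
        g.counts.copy(), g.pool_a, g.pool_b, g.n_a, g.n_b, mask,
        g.normalized, g.polarization,
    )


def expected_afs(
    spec: DivergenceModelSpec,
    n_a: int,
    n_b: int,
    n_reps: int = 5,
    mask_cutoff: Optional[float] = None,
    pool_a: str = "demeA",
    pool_b: str = "demeB",
) -> AFSGrid:
    """Simulated expected spectrum for one divergence scenario.

    Each replicate evolves ``spec.n_loci`` loci forward in time, samples
    2N / 2M allele draws per deme (binomial around the deme frequency) and
    accumulates the grid; replicates (seeded spec.seed, spec.seed+1, ...)
    are averaged and the result normalized to unit mass over unmasked
    cells.
    """
    grid = np.zeros((2 * n_a + 1, 2 * n_b + 1), dtype=float)
    for rep in range(n_reps):
        rep_spec = DivergenceModelSpec(
            model=spec.model, Ne=spec.Ne, T_split=spec.T_split,
            m12=spec.m12, m21=spec.m21, T_switch=spec.T_switch,
            n_loci=spec.n_loci, seed=spec.seed + rep,
        )
        p1, p2 = simulate_divergence_afs(rep_spec)
        rng = np.random.default_rng(rep_spec.seed + 1_000_003)
        ia = rng.binomial(2 * n_a, p1)
        ib = rng.binomial(2 * n_b, p2)
        np.add.at(grid, (ia, ib), 1.0)
    grid /= n_reps
    out = AFSGrid(grid, pool_a, pool_b, n_a, n_b)
    if mask_cutoff is not None:
        out = mask_low_freq(out, mask_cutoff)
    norm = out.normalized_unmasked()
    return AFSGrid(
        norm, out.pool_a, out.pool_b, out.n_a, out.n_b, out.mask,
        normalized=True, polarization=out.polarization,
    )


@dataclass
class ModelScore:
    """Divergence of the observed spectrum from each candidate scenario."""

    scores: pd.Series  # model label -> Jensen-Shannon divergence
    best: str
    tied: list  # labels within tie_tol of the best (incl. best) when >1
    n_reps: int
    seed: int

    @property
    def is_tie(self) -> bool:
        return len(self.tied) > 1


def classify_divergence_model(
    observed: AFSGrid,
    candidates: dict | Sequence[DivergenceModelSpec],
    n_reps: int = 5,
    seed: int = 0,
    tie_tol: float = 0.10,
) -> ModelScore:
    """Score an observed spectrum against candidate divergence scenarios.

    ``candidates`` maps label -> :class:`DivergenceModelSpec` (a plain
    sequence is labelled by each spec's model name).  The score is the
    Jensen-Shannon divergence (natural log) between the normalized
    observed and expected grids over the observed grid's unmasked cells.
    Candidates whose score is within ``tie_tol`` (relative) of the minimum
    are reported as a tie set.
    """
    if not isinstance(candidates, dict):
        candidates = {spec.model: spec for spec in candidates}
    if len(candidates) < 2:
        raise ValueError("need at least two candidate models")
    obs = observed.normalized_unmasked().ravel()

    scores = {}
    for label, spec in candidates.items():
        rep_spec = DivergenceModelSpec(
            model=spec.model, Ne=spec.Ne, T_split=spec.T_split,
            m12=spec.m12, m21=spec.m21, T_switch=spec.T_switch,
            n_loci=spec.n_loci, seed=seed + spec.seed,
        )
        exp_grid = expected_afs(rep_spec, observed.n_a, observed.n_b, n_reps)
        exp = np.where(observed.mask, 0.0, exp_grid.counts)
        total = exp.sum()
        if total == 0:
            scores[label] = float("inf")
            continue
        scores[label] = float(jensenshannon(obs, exp.ravel() / total) ** 2)
    s = pd.Series(scores).sort_values()
    best = s.index[0]
    cut = s.iloc[0] + tie_tol * max(s.iloc[0], 1e-12)
    tied = list(s.index[s <= cut])
    return ModelScore(s, best, tied if len(tied) > 1 else [best], n_reps, seed)
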