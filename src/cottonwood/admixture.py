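"""Admixture proportions: parsing, threshold classification, supervised EM.

Model-based clustering itself (Structure-style MCMC) is delegated to
external software; this module consumes its Q-matrices.  A supervised EM
estimator is provided as plumbing so the pipeline can run end-to-end when
reference lineage allele frequencies are available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = [
    "QMatrix",
    "LineageClassification",
    "read_q_matrix",
    "classify_individuals",
    "estimate_admixture_em",
]

DEFAULT_THRESHOLDS = (0.667, 0.9)


@dataclass
class QMatrix:
    """Per-individual admixture proportions over K clusters."""

    q: pd.DataFrame  # individuals x clusters, rows sum to 1

    def __post_init__(self) -> None:
        vals = self.q.to_numpy(dtype=float)
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("Q-values must lie in [0, 1]")
        bad = np.abs(vals.sum(axis=1) - 1.0) > 1e-6
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"Q-matrix row {row} ({self.q.index[row]!r}) sums to "
                f"{vals[row].sum():.6f}, expected 1"
            )

    @property
    def k(self) -> int:
        return self.q.shape[1]

    @property
    def individuals(self) -> pd.Index:
        return self.q.index


def read_q_matrix(path, dialect: str = "tsv") -> QMatrix:
    """Read a Q-matrix from a plain TSV or a Structure-style output file.

    ``tsv``: header row, first column = individual id, remaining columns =
    cluster proportions.  ``structure``: whitespace-separated rows of the
    form ``idx label (miss%) pop : q1 q2 ... qK`` (the colon separates
    metadata from proportions); no header.  Rows whose proportions are off
    unity by more than 1e-3 are rejected with their row number; rows are
    renormalized to machine precision otherwise.
    """
    path = Path(path)
    ids: list[str] = []
    rows: list[list[float]] = []
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = list(df.index.astype(str))
        rows = df.to_numpy(dtype=float).tolist()
    elif dialect == "structure":
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" in line:
                meta, qpart = line.split(":", 1)
                label = meta.split()[1]
            else:
                parts = line.split()
                label, qpart = parts[0], " ".join(parts[1:])
            rows.append([float(x) for x in qpart.split()])
            ids.append(label)
    else:
        raise ValueError(f"unknown Q-matrix dialect {dialect!r}")

    k = len(rows[0]) if rows else 0
    for i, r in enumerate(rows, start=1):
        if len(r) != k:
            raise ValueError(f"row {i}: expected {k} clusters, found {len(r)}")
        s = sum(r)
        if abs(s - 1.0) > 1e-3:
            raise ValueError(f"row {i}: Q-values sum to {s:.4f}, expected 1")
    arr = np.asarray(rows, dtype=float)
    arr = arr / arr.sum(axis=1, keepdims=True)
    q = pd.DataFrame(
        arr, index=pd.Index(ids, name="individual"),
        columns=[f"cluster{j}" for j in range(k)],
    )
    return QMatrix(q)


@dataclass
class LineageClassification:
    """Threshold classes derived from a Q-matrix.

    ``table`` has one row per individual: ``max_cluster`` (index of the
    largest Q, ties to the lowest index), ``max_q``, and for each threshold
    t a boolean ``pure@t`` plus ``class@t`` (the cluster index for pure
    individuals, -1 for admixed).
    """

    table: pd.DataFrame
    thresholds: tuple

    def pure_mask(self, threshold: float) -> pd.Series:
        return self.table[f"pure@{threshold:g}"]

    def lineage_of(self, threshold: float) -> pd.Series:
        """Cluster index for individuals pure at ``threshold``; -1 otherwise."""
        return self.table[f"class@{threshold:g}"]

    def population_modal_class(
        self, populations: pd.Series, threshold: float
    ) -> pd.Series:
        cls = self.lineage_of(threshold)
        return cls.groupby(populations.loc[cls.index]).agg(
            lambda s: s.mode().iloc[0]
        )


def classify_individuals(
    q: QMatrix, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> LineageClassification:
    """Classify individuals as pure (max Q strictly above t) or admixed.

    An individual exactly at a threshold is admixed (strict inequality).
    """
    for t in thresholds:
        if not (1.0 / q.k < t <= 1.0):
            raise ValueError(f"threshold {t} outside (1/K, 1]")
    vals = q.q.to_numpy(dtype=float)
    max_cluster = vals.argmax(axis=1)
    max_q = vals.max(axis=1)
    data = {"max_cluster": max_cluster, "max_q": max_q}
    for t in sorted(thresholds):
        pure = max_q > t
        data[f"pure@{t:g}"] = pure
        data[f"class@{t:g}"] = np.where(pure, max_cluster, -1)
    return LineageClassification(
        pd.DataFrame(data, index=q.q.index), tuple(sorted(thresholds))
    )


def estimate_admixture_em(
    g: GenotypeMatrix,
    ref_freqs: pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> tuple[QMatrix, pd.DataFrame]:
    """Supervised admixture: per-individual EM on the binomial mixture.

    ``ref_freqs`` is (lineages x loci) alternate-allele frequencies, clamped
    to [1e-4, 1 - 1e-4].  Each of an individual's two allele copies at a
    locus is attributed to lineage k with prior q_k; the E-step computes
    copy-level responsibilities and the M-step averages them.  The observed
    log-likelihood is non-decreasing; convergence when its change drops
    below ``tol``.

    Returns the Q-matrix and a diagnostics frame (loglik, n_iter,
    converged, degenerate).
    """
    loci = [l for l in ref_freqs.columns if l in g.calls.columns]
    if not loci:
        raise ValueError("no overlap between reference loci and genotype loci")
    P = ref_freqs[loci].to_numpy(dtype=float)
    P = np.clip(P, 1e-4, 1 - 1e-4)
    K = P.shape[0]
    degenerate = bool(np.allclose(P, P[0], atol=1e-12))
    if degenerate:
        warnings.warn(
            "reference frequencies identical across lineages; admixture "
            "proportions are not identifiable, returning uniform 1/K"
        )
    calls = g.calls[loci].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    n_ind = calls.shape[0]
    qs = np.empty((n_ind, K))
    diags = []
    for i in range(n_ind):
        geno = calls[i]
        obs = ~np.isnan(geno)
        gi = geno[obs]
        Pl = P[:, obs]  # K x L'
        if degenerate or obs.sum() == 0:
            qs[i] = 1.0 / K
            diags.append((float("nan"), 0, True))
            continue
        q = rng.dirichlet(np.ones(K))
        prev_ll = -np.inf
        ll = prev_ll
        converged = False
        n_it = 0
        for n_it in range(1, max_iter + 1):
            f = q @ Pl  # per-locus alt-copy probability
            f = np.clip(f, 1e-12, 1 - 1e-12)
            # copy-level responsibilities: alt copies vs ref copies
            r_alt = (q[:, None] * Pl) / f  # K x L'
            r_ref = (q[:, None] * (1 - Pl)) / (1 - f)
            weights = (gi * r_alt + (2 - gi) * r_ref).sum(axis=1)
            q = weights / weights.sum()
            ll = float(
                (gi * np.log(f) + (2 - gi) * np.log(1 - f)).sum()
                + np.log(np.array([2.0 if x == 1 else 1.0 for x in gi])).sum()
            )
            if ll - prev_ll < -1e-8:
                raise AssertionError("EM log-likelihood decreased")
            if abs(ll - prev_ll) < tol:
                converged = True
                break
            prev_ll = ll
        qs[i] = q
        diags.append((ll, n_it, converged))

    q_df = pd.DataFrame(
        qs, index=g.calls.index, columns=list(ref_freqs.index)
    )
    diag_df = pd.DataFrame(
        diags, index=g.calls.index, columns=["loglik", "n_iter", "converged"]
    )
    diag_df["degenerate"] = degenerate
    return QMatrix(q_df), diag_df
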