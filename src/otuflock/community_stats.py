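"""Community-level statistics: rarefaction, Bray-Curtis dissimilarity,
richness, exact rarefaction curves, and shared-OTU (Venn) partitions."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.spatial.distance import squareform, pdist

from .io_formats import CommunityMatrix

logger = logging.getLogger(__name__)


@dataclass
class DissimilarityMatrix:
    """Symmetric sample x sample dissimilarities in [0, 1], zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match sample ids")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be exactly zero")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("dissimilarities must lie in [0, 1]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def rarefy(matrix: CommunityMatrix, depth: int | str = "min",
           seed: int = 0) -> CommunityMatrix:
    """Subsample each sample WITHOUT replacement to a common depth.

    ``depth="min"`` uses the minimum positive sample total. Samples whose
    total is below the depth (including all-zero samples) are dropped with a
    logged warning. Every retained row sums exactly to ``depth``.
    """
    totals = matrix.sample_totals()
    if depth == "min":
        positive = totals[totals > 0]
        if positive.size == 0:
            raise ValueError("cannot rarefy: every sample is empty")
        depth = int(positive.min())
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    keep = [i for i, t in enumerate(totals) if t >= depth]
    dropped = [matrix.sample_ids[i] for i, t in enumerate(totals) if t < depth]
    if dropped:
        logger.warning("rarefy: dropping sample(s) below depth %d: %s",
                       depth, ", ".join(dropped))
    if not keep:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    rows = np.empty((len(keep), len(matrix.otu_ids)), dtype=np.int64)
    for r, i in enumerate(keep):
        rows[r] = rng.multivariate_hypergeometric(matrix.counts[i], depth)
    return CommunityMatrix(
        sample_ids=[matrix.sample_ids[i] for i in keep],
        otu_ids=list(matrix.otu_ids),
        counts=rows,
        sample_meta=matrix.sample_meta.iloc[keep].copy(),
    )


def rarefy_mean(matrix: CommunityMatrix, depth: int | str = "min",
                seed: int = 0, n_draws: int = 100) -> pd.DataFrame:
    """Mean rarefied counts over repeated draws (not the default workflow)."""
    acc = None
    for k in range(n_draws):
        m = rarefy(matrix, depth, seed=seed + k)
        frame = m.to_frame()
        acc = frame if acc is None else acc + frame
    return acc / n_draws


def bray_curtis(matrix: CommunityMatrix) -> DissimilarityMatrix:
    """Bray-Curtis: BC(u, v) = 1 - 2 * sum(min(u, v)) / (sum(u) + sum(v))."""
    counts = matrix.counts.astype(float)
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("Bray-Curtis is undefined for all-zero samples")
    vals = squareform(pdist(counts, metric="braycurtis"))
    np.fill_diagonal(vals, 0.0)
    return DissimilarityMatrix(list(matrix.sample_ids), vals)


def richness(matrix: CommunityMatrix) -> pd.Series:
    """Per-sample count of OTUs with count > 0."""
    return pd.Series((matrix.counts > 0).sum(axis=1), index=matrix.sample_ids,
                     name="richness")


def rarefaction_curve(sample_counts: Sequence[int],
                      depths: Sequence[int]) -> list[float]:
    """Exact expected richness at each subsampling depth.

    E[S(n)] = sum_i (1 - C(N - N_i, n) / C(N, n)) with N the sample total and
    N_i the per-OTU counts; evaluated with log-gamma for stability.
    """
    counts = np.asarray([c for c in sample_counts if c > 0], dtype=np.int64)
    if counts.size == 0:
        return [0.0 for _ in depths]
    if np.any(counts < 0):
        raise ValueError("negative counts")
    N = int(counts.sum())
    out = []
    for n in depths:
        n = int(n)
        if n < 0 or n > N:
            raise ValueError(f"depth {n} outside [0, {N}]")
        if n == 0:
            out.append(0.0)
            continue
        # log C(N - Ni, n) - log C(N, n); OTUs with N - Ni < n are always seen
        rem = N - counts
        feasible = rem >= n
        log_p_missing = np.full(counts.shape, -np.inf)
        r = rem[feasible].astype(float)
        log_p_missing[feasible] = (
            gammaln(r + 1) - gammaln(r - n + 1) - (gammaln(N + 1) - gammaln(N - n + 1))
        )
        out.append(float(np.sum(1.0 - np.exp(log_p_missing))))
    return out


def shared_otus(matrix: CommunityMatrix,
                groups: Mapping[str, str]) -> dict[frozenset, int]:
    """Counts of the group-membership Venn partition.

    An OTU belongs to a group if any sample of that group has count > 0.
    Returns counts keyed by the non-empty membership combination (frozenset
    of group names); the partition sums to the number of OTUs observed in at
    least one sample.
    """
    missing = [s for s in matrix.sample_ids if s not in groups]
    if missing:
        raise ValueError(f"sample(s) without a group: {missing}")
    group_names = sorted(set(groups.values()))
    present = matrix.counts > 0
    membership: dict[frozenset, int] = {}
    for j in range(len(matrix.otu_ids)):
        in_groups = frozenset(
            g for g in group_names
            if any(present[i, j] for i, s in enumerate(matrix.sample_ids) if groups[s] == g)
        )
        if in_groups:
            membership[in_groups] = membership.get(in_groups, 0) + 1
    return membership
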