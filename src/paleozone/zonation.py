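"""Stratigraphically constrained clustering (CONISS) with broken-stick zoning.

CONISS is agglomerative clustering in which only stratigraphically adjacent
clusters may fuse, with the incremental sum-of-squares (Ward) criterion:
the pair merged is the one whose fusion least increases total within-zone
dispersion.  Dispersion of a cluster ``c`` is computed from the supplied
pairwise dissimilarities as ``sum_{i<j in c} d_ij / |c|`` (for squared
Euclidean input this equals the within-cluster sum of squares, which is
Grimm's classic formulation; any dissimilarity — e.g. Bray-Curtis — is
accepted, generalizing the criterion the way stratigraphic packages do).

The number of significant zones is chosen with the broken-stick model: the
proportional dispersion reduction of the split into k zones is compared to
the null expectation ``sum_{i=k}^{n} (1/i) / n``; scanning k = 2, 3, ...,
the chosen count is the largest k for which every split up to k beats its
expectation (pure noise therefore yields k = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .resemblance import ResemblanceMatrix, KIND_DISSIMILARITY

__all__ = ["Merge", "ZonationResult", "coniss", "broken_stick_table", "broken_stick_select", "cut"]


@dataclass
class Merge:
    step: int
    left: tuple[int, int]    # (first, last) sample index of the upper block
    right: tuple[int, int]   # (first, last) of the lower, adjacent block
    increase: float          # within-zone dispersion increase of this fusion
    height: float            # cumulative dispersion after this fusion


@dataclass
class ZonationResult:
    """Full constrained merge tree over a stratigraphically ordered core."""

    sample_ids: list[str]
    merges: list[Merge]
    total_dispersion: float
    coefficient: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def increments(self) -> np.ndarray:
        return np.array([m.increase for m in self.merges])

    @property
    def heights(self) -> np.ndarray:
        return np.array([m.height for m in self.merges])

    def boundaries(self, k: int) -> list[int]:
        """Zone boundaries for a k-zone cut: the last sample index (0-based)
        of each zone except the deepest-cut one, in stratigraphic order."""
        return sorted(m.left[1] for m in self.merges[self.n - k :])

    def zones(self, k: int) -> np.ndarray:
        """Contiguous zone labels for a k-zone cut; the deepest zone is 1."""
        if not 1 <= k <= self.n:
            raise ValueError(f"k must be in [1, {self.n}]")
        bounds = self.boundaries(k)
        labels = np.empty(self.n, dtype=int)
        zone_of_block = k  # shallowest block receives the highest label
        start = 0
        for b in bounds + [self.n - 1]:
            labels[start : b + 1] = zone_of_block
            zone_of_block -= 1
            start = b + 1
        return labels


def coniss(matrix: ResemblanceMatrix) -> ZonationResult:
    """Constrained incremental sum-of-squares clustering of ordered samples.

    Samples must already be in stratigraphic order.  Ties in fusion cost are
    broken by merging the shallowest eligible pair, which makes the merge
    sequence deterministic.
    """
    if matrix.kind != KIND_DISSIMILARITY:
        raise ValueError("coniss requires a dissimilarity matrix")
    n = matrix.n
    if n < 2:
        raise ValueError("need at least two samples")
    d = matrix.values
    # pairwise-sum table between current blocks; blocks stay contiguous
    blocks: list[list[int]] = [[i] for i in range(n)]
    disp: list[float] = [0.0] * n
    merges: list[Merge] = []
    cumulative = 0.0
    for step in range(1, n):
        best_inc, best_idx, best_disp = np.inf, -1, 0.0
        for idx in range(len(blocks) - 1):
            union = blocks[idx] + blocks[idx + 1]
            pair_sum = 0.0
            for a_pos, i in enumerate(union):
                for j in union[a_pos + 1 :]:
                    pair_sum += d[i, j]
            union_disp = pair_sum / len(union)
            inc = union_disp - disp[idx] - disp[idx + 1]
            if inc < best_inc - 1e-15:  # strict improvement; first wins ties
                best_inc, best_idx, best_disp = inc, idx, union_disp
        i = best_idx
        cumulative += best_inc
        merges.append(
            Merge(
                step=step,
                left=(blocks[i][0], blocks[i][-1]),
                right=(blocks[i + 1][0], blocks[i + 1][-1]),
                increase=best_inc,
                height=cumulative,
            )
        )
        blocks[i] = blocks[i] + blocks[i + 1]
        disp[i] = best_disp
        del blocks[i + 1], disp[i + 1]
    return ZonationResult(
        sample_ids=list(matrix.sample_ids),
        merges=merges,
        total_dispersion=cumulative,
        coefficient=f"{matrix.coefficient} ({matrix.transform})",
    )


def broken_stick_table(result: ZonationResult, max_k: int | None = None) -> pd.DataFrame:
    """Observed vs broken-stick-expected dispersion reduction per split."""
    n = result.n
    max_k = n if max_k is None else max_k
    if max_k > n:
        raise ValueError(f"max_k={max_k} exceeds n={n}")
    inc = result.increments
    total = inc.sum()
    rows = []
    harmonic_tail = sum(1.0 / i for i in range(2, n + 1))
    for k in range(2, max_k + 1):
        observed = inc[n - k] / total if total > 0 else 0.0
        expected = harmonic_tail / n
        rows.append({"k": k, "observed": observed, "expected": expected,
                     "significant": observed > expected})
        harmonic_tail -= 1.0 / k
    return pd.DataFrame(rows)


def broken_stick_select(result: ZonationResult, max_k: int | None = None) -> int:
    """Number of significant zones: largest k with splits 2..k all beating
    the broken-stick expectation; 1 if the first split already fails."""
    table = broken_stick_table(result, max_k)
    chosen = 1
    for _, row in table.iterrows():
        if row["significant"]:
            chosen = int(row["k"])
        else:
            break
    return chosen


def cut(result: ZonationResult, k: int | None = None, height: float | None = None) -> np.ndarray:
    """Zone assignment for a chosen zone count or dendrogram height.

    Exactly one of *k* and *height* must be given.  A height cut keeps all
    merges with cumulative dispersion <= height.
    """
    if (k is None) == (height is None):
        raise ValueError("give exactly one of k or height")
    if height is not None:
        h = result.heights
        if height < 0 or height > h[-1]:
            raise ValueError(f"height outside dendrogram range [0, {h[-1]:.4g}]")
        k = result.n - int(np.sum(h <= height))
    return result.zones(int(k))
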