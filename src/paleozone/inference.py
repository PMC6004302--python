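"""Permutation tests: one-way ANOSIM, RELATE matrix correlation, Spearman.

All three are rank-based, suiting the skewed distributions typical of
assemblage and geochemical data.  Permutation p-values carry the add-one
correction ``p = (1 + #{perm >= obs}) / (1 + n_perm)`` so p is never zero;
permutation streams are reproducible from the recorded ``(seed, n_perm)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .resemblance import ResemblanceMatrix, KIND_DISSIMILARITY, convert

__all__ = ["TestResult", "anosim", "anosim_exhaustive_p", "relate", "spearman_profiles"]

DEFAULT_N_PERM = 999


@dataclass
class TestResult:
    statistic: str
    value: float
    p_value: float | None
    n_perm: int
    n: int
    seed: int | None = None
    group_sizes: dict | None = None
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "statistic": self.statistic,
            "value": self.value,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "n": self.n,
            "seed": self.seed,
        }
        if self.group_sizes:
            out["group_sizes"] = self.group_sizes
        out.update(self.extra)
        return out


def _anosim_stat(rank_matrix: np.ndarray, groups: np.ndarray, denom: float) -> float:
    same = groups[:, None] == groups[None, :]
    iu = np.triu_indices_from(rank_matrix, k=1)
    within = same[iu]
    r = rank_matrix[iu]
    return (r[~within].mean() - r[within].mean()) / denom


def anosim(
    matrix: ResemblanceMatrix,
    groups,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> TestResult:
    """One-way analysis of similarities.

    ``R = (mean between-group rank - mean within-group rank) / (M/2)`` with
    ``M = n(n-1)/2`` off-diagonal pairs, ranked with average ties.  The null
    distribution comes from random relabelings of the samples.
    """
    matrix = convert(matrix, KIND_DISSIMILARITY)
    groups = np.asarray(groups)
    n = matrix.n
    if len(groups) != n:
        raise ValueError("one group label per sample required")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2 or np.any(counts < 2):
        raise ValueError("need >= 2 groups with >= 2 members each")
    iu = np.triu_indices(n, k=1)
    condensed = matrix.values[iu]
    if np.all(condensed == condensed[0]):
        raise ValueError("all dissimilarities tied; R undefined")
    ranks = np.zeros((n, n))
    ranks[iu] = rankdata(condensed)
    ranks = ranks + ranks.T
    m = n * (n - 1) / 2
    denom = m / 2.0
    observed = _anosim_stat(ranks, groups, denom)
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(groups)
            if _anosim_stat(ranks, perm, denom) >= observed:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
    return TestResult(
        statistic="ANOSIM_R",
        value=float(observed),
        p_value=p,
        n_perm=n_perm,
        n=n,
        seed=seed,
        group_sizes={str(l): int(c) for l, c in zip(labels, counts)},
    )


def anosim_exhaustive_p(matrix: ResemblanceMatrix, groups) -> float:
    """Exact p by full enumeration of distinct relabelings (small n only)."""
    matrix = convert(matrix, KIND_DISSIMILARITY)
    groups = np.asarray(groups)
    n = matrix.n
    iu = np.triu_indices(n, k=1)
    ranks = np.zeros((n, n))
    ranks[iu] = rankdata(matrix.values[iu])
    ranks = ranks + ranks.T
    denom = n * (n - 1) / 4.0
    observed = _anosim_stat(ranks, groups, denom)
    seen = set()
    hits = total = 0
    for perm in _iter_permutations(groups):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if _anosim_stat(ranks, np.asarray(perm), denom) >= observed - 1e-12:
            hits += 1
    return hits / total


def relate(
    matrix_a: ResemblanceMatrix,
    matrix_b: ResemblanceMatrix,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> TestResult:
    """Mantel-type Spearman rank correlation between two resemblance matrices.

    Both inputs are converted to dissimilarity form, so a positive rho means
    agreement of the two distance structures.  Significance: sample labels
    of the second matrix are permuted (rows and columns jointly).
    """
    a = convert(matrix_a, KIND_DISSIMILARITY)
    b = convert(matrix_b, KIND_DISSIMILARITY)
    n = a.n
    if b.n != n:
        raise ValueError("matrix size mismatch")
    iu = np.triu_indices(n, k=1)
    va, vb = a.values[iu], b.values[iu]
    if np.all(va == va[0]) or np.all(vb == vb[0]):
        raise ValueError("constant matrix: rho undefined")
    ra = rankdata(va)
    observed = float(spearmanr(va, vb).statistic)
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            order = rng.permutation(n)
            vb_perm = b.values[np.ix_(order, order)][iu]
            # spearman of fixed ra against permuted b ranks
            rho = np.corrcoef(ra, rankdata(vb_perm))[0, 1]
            if rho >= observed - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
    return TestResult(
        statistic="RELATE_rho",
        value=observed,
        p_value=p,
        n_perm=n_perm,
        n=len(va),
        seed=seed,
        extra={"n_samples": n},
    )


def spearman_profiles(
    x,
    y,
    n_perm: int = 0,
    seed: int | None = None,
) -> TestResult:
    """Spearman correlation of two depth-aligned series.

    The analytic two-sided p uses the t approximation; an optional
    permutation p (shuffling y) is added when ``n_perm > 0``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series length mismatch")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant series: rho undefined")
    res = spearmanr(x, y)
    rho, p = float(res.statistic), float(res.pvalue)
    extra = {"analytic_p": p}
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        rx = rankdata(x)
        hits = 0
        for _ in range(n_perm):
            r = np.corrcoef(rx, rankdata(rng.permutation(y)))[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
        extra["permutation_p"] = p
    return TestResult(
        statistic="Spearman_rho",
        value=rho,
        p_value=p,
        n_perm=n_perm,
        n=len(x),
        seed=seed,
        extra=extra,
    )
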