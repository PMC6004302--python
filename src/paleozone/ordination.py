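"""Non-metric multidimensional scaling (NMDS) of a dissimilarity matrix.

Kruskal-style NMDS: find an m-dimensional configuration whose inter-point
distances reproduce the *rank order* of the input dissimilarities.  Each
iteration fits disparities by monotone (isotonic, pool-adjacent-violators)
regression of configuration distances on the dissimilarity order — ties
handled by Kruskal's primary (weak) approach — then improves the
configuration with the Guttman majorization transform.  Fit quality is
Kruskal stress-1, ``sqrt(sum (d - dhat)^2 / sum d^2)``; multiple random
starts guard against local minima.  The best configuration is centered and
rotated to its principal axes so axis 1 carries maximal variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .resemblance import ResemblanceMatrix, KIND_DISSIMILARITY, convert
from .core_io import AssemblageCounts

__all__ = ["OrdinationResult", "nmds", "zone_overlay", "taxon_scores"]


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coords: np.ndarray          # n x m, centered, principal-axis rotated
    stress: float               # Kruskal stress-1 of the best start
    n_iter: int
    n_starts: int
    best_start: int
    converged: bool
    seed: int | None = None
    stress_trace: np.ndarray | None = None  # per-iteration stress, best start
    meta: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords,
            index=self.sample_ids,
            columns=[f"NMDS{i+1}" for i in range(self.coords.shape[1])],
        )
        df.index.name = "sample_id"
        return df


def _stress_and_disparities(d_config: np.ndarray, order: np.ndarray) -> tuple[float, np.ndarray]:
    """Kruskal stress-1 and PAVA disparities for one configuration."""
    fitted = isotonic_regression(d_config[order]).x
    dhat = np.empty_like(fitted)
    dhat[order] = fitted
    denom = float((d_config**2).sum())
    if denom == 0:
        return 1.0, dhat
    stress = float(np.sqrt(((d_config - dhat) ** 2).sum() / denom))
    return stress, dhat


def _single_start(
    diss: np.ndarray, init: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, float, int, bool, np.ndarray]:
    n, m = init.shape
    x = init - init.mean(axis=0)
    trace = []
    last = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d = pdist(x)
        # primary (weak) ties: within tied dissimilarities, order by current
        # distance so PAVA imposes no constraint inside a tie block
        order = np.lexsort((d, diss))
        stress, dhat = _stress_and_disparities(d, order)
        # rescale disparities to the size of the configuration distances
        scale = np.sqrt((d**2).sum() / max((dhat**2).sum(), 1e-300))
        dhat = dhat * scale
        trace.append(stress)
        if abs(last - stress) < tol:
            converged = True
            break
        last = stress
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        b = -squareform(ratio)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = b @ x / n
        x -= x.mean(axis=0)
    return x, trace[-1], it, converged, np.array(trace)


def nmds(
    matrix: ResemblanceMatrix,
    m: int = 2,
    n_starts: int = 50,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> OrdinationResult:
    """Best-of-``n_starts`` NMDS of a dissimilarity matrix into ``m`` axes.

    Start 0 seeds from classical (metric) scaling of the input; remaining
    starts are random.  Fixed ``seed`` makes the result bit-reproducible.
    """
    matrix = convert(matrix, KIND_DISSIMILARITY)
    n = matrix.n
    if not 1 <= m < n:
        raise ValueError("need 1 <= m < n")
    diss = matrix.condensed()
    rng = np.random.default_rng(seed)
    best = None
    for start in range(n_starts):
        if start == 0:
            init = _classical_mds(matrix.values, m)
        else:
            init = rng.standard_normal((n, m))
        x, stress, iters, converged, trace = _single_start(diss, init, tol, max_iter)
        if best is None or stress < best[1]:
            best = (x, stress, iters, converged, trace, start)
    x, stress, iters, converged, trace, start = best
    # principal-axis rotation
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    return OrdinationResult(
        sample_ids=list(matrix.sample_ids),
        coords=x,
        stress=stress,
        n_iter=iters,
        n_starts=n_starts,
        best_start=start,
        converged=converged,
        seed=seed,
        stress_trace=trace,
        meta={"m": m, "tol": tol, "max_iter": max_iter},
    )


def _classical_mds(d: np.ndarray, m: int) -> np.ndarray:
    """Torgerson scaling used as the deterministic first start."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:m]
    lam = np.clip(w[idx], 0, None)
    return v[:, idx] * np.sqrt(lam)


def taxon_scores(result: OrdinationResult, counts: AssemblageCounts) -> pd.DataFrame:
    """Weighted-average taxon positions in the ordination space."""
    if list(counts.sample_ids) != list(result.sample_ids):
        raise ValueError("sample mismatch between ordination and counts")
    w = counts.values
    totals = w.sum(axis=0)
    scores = np.full((counts.n_taxa, result.coords.shape[1]), np.nan)
    nz = totals > 0
    scores[nz] = (w[:, nz].T @ result.coords) / totals[nz, None]
    return pd.DataFrame(
        scores,
        index=counts.taxa,
        columns=[f"NMDS{i+1}" for i in range(result.coords.shape[1])],
    )


def zone_overlay(result: OrdinationResult, zones) -> dict:
    """Group ordination coordinates by zone; report centroid separations.

    Returns a dict with a tagged coordinate table, per-zone centroids, mean
    within-zone spread (distance to own centroid) and mean between-centroid
    distance.
    """
    zones = np.asarray(zones)
    if len(zones) != len(result.sample_ids):
        raise ValueError("zone/sample mismatch")
    df = result.to_dataframe()
    df["zone"] = zones
    centroids = df.groupby("zone").mean(numeric_only=True)
    spread = {}
    for z, grp in df.groupby("zone"):
        delta = grp.drop(columns="zone").to_numpy() - centroids.loc[z].to_numpy()
        spread[z] = float(np.linalg.norm(delta, axis=1).mean())
    cc = centroids.to_numpy()
    if len(cc) > 1:
        between = float(pdist(cc).mean())
    else:
        between = 0.0
    return {
        "coordinates": df,
        "centroids": centroids,
        "within_spread": spread,
        "mean_between_centroid_distance": between,
    }
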