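"""Geochemical covariate screening and derived series.

The screening chain, in fixed order:

1. censoring screen — drop an element when more than 25% of its values are
   missing or beyond a detection limit; surviving below-limit values are
   substituted with DL/2, above-limit values with the DL;
2. aluminum normalization — divide every element by same-depth Al
   (stratigraphically immobile), removing grain-size/dilution signal; Al
   itself leaves the covariate set (its normalized profile is constant 1);
3. redundancy reduction — per-element Euclidean distance matrices are
   compared pairwise by Spearman rank correlation of their off-diagonal
   entries (a second-stage resemblance comparison); within any pair more
   correlated than ``rho_threshold``, the element whose own distance matrix
   correlates more weakly with the biotic resemblance (RELATE rho) is
   dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .core_io import (
    GeochemProfile,
    CENSOR_NONE,
    CENSOR_BELOW,
    CENSOR_ABOVE,
    CENSOR_MISSING,
)
from .resemblance import ResemblanceMatrix, euclidean_matrix
from .inference import relate

__all__ = [
    "ScreenedGeochem",
    "censoring_screen",
    "aluminum_normalize",
    "redox_ratios",
    "redundancy_reduce",
]

CENSOR_THRESHOLD = 0.25
RHO_THRESHOLD = 0.95

DROP_CENSORED = "gt25pct_censored"
DROP_REDUNDANT = "redundant"
DROP_MANUAL = "manual"


@dataclass
class ScreenedGeochem:
    """Survivors and casualties of a screening step, with an audit trail."""

    profile: GeochemProfile
    dropped: dict[str, str] = field(default_factory=dict)      # element -> reason
    substitutions: dict[str, int] = field(default_factory=dict)  # element -> n cells
    redundancy_matrix: pd.DataFrame | None = None
    audit: dict = field(default_factory=dict)

    @property
    def retained(self) -> list[str]:
        return self.profile.elements


def censoring_screen(
    profile: GeochemProfile, threshold: float = CENSOR_THRESHOLD
) -> ScreenedGeochem:
    """Drop elements with too many censored/missing values; substitute the rest.

    Below-detection cells become DL/2, above-detection cells the DL itself
    (the cell value carries the detection limit for censored entries).
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    keep_conc: dict[str, np.ndarray] = {}
    keep_flags: dict[str, np.ndarray] = {}
    dropped: dict[str, str] = {}
    substitutions: dict[str, int] = {}
    for el in profile.elements:
        frac = profile.censored_fraction(el)
        if frac > threshold:
            dropped[el] = DROP_CENSORED
            continue
        vals = profile.concentrations[el].copy()
        fl = profile.flags[el]
        below = fl == CENSOR_BELOW
        vals[below] = vals[below] / 2.0
        n_sub = int(below.sum() + (fl == CENSOR_ABOVE).sum())
        if np.any(fl == CENSOR_MISSING):
            # interior gaps are interpolated over depth (rare after the screen)
            miss = fl == CENSOR_MISSING
            vals[miss] = np.interp(
                profile.depths[miss], profile.depths[~miss], vals[~miss]
            )
            n_sub += int(miss.sum())
        keep_conc[el] = vals
        keep_flags[el] = fl.copy()
        if n_sub:
            substitutions[el] = n_sub
    screened = GeochemProfile(
        profile.depths.copy(), keep_conc, keep_flags,
        {el: profile.original_units.get(el, "ppm") for el in keep_conc},
    )
    return ScreenedGeochem(
        screened,
        dropped=dropped,
        substitutions=substitutions,
        audit={
            "step": "censoring_screen",
            "threshold": threshold,
            "substitution_rule": "DL/2 below, DL above, depth-interpolated missing",
        },
    )


def aluminum_normalize(profile: GeochemProfile, reference: str = "Al") -> GeochemProfile:
    """Divide every element by the same-sample reference element (default Al).

    The result is unitless (ppm/ppm); the reference leaves the covariate
    set.  Errors if the reference is censored or zero anywhere.
    """
    if reference not in profile.elements:
        raise ValueError(f"reference element {reference!r} absent")
    ref = profile.concentrations[reference]
    if np.any(profile.flags[reference] != CENSOR_NONE):
        raise ValueError(f"{reference} censored at some depth; cannot normalize")
    if np.any(ref == 0):
        raise ValueError(f"{reference} is zero at some depth; cannot normalize")
    conc = {
        el: profile.concentrations[el] / ref
        for el in profile.elements
        if el != reference
    }
    flags = {el: profile.flags[el].copy() for el in conc}
    units = {el: f"{profile.original_units.get(el, 'ppm')}/{reference}" for el in conc}
    return GeochemProfile(profile.depths.copy(), conc, flags, units)


def redox_ratios(
    profile: GeochemProfile,
    numerators: tuple[str, ...] = ("As", "Hg", "Fe"),
    tracers: tuple[str, ...] = ("S", "Mn"),
) -> pd.DataFrame:
    """Element : redox-tracer ratio series used to flag post-depositional
    mobilization.  A zero tracer leaves NaN at that depth (flagged, kept)."""
    missing = [t for t in tracers if t not in profile.elements]
    if missing:
        raise ValueError(f"tracer elements absent: {missing}")
    out = pd.DataFrame({"depth": profile.depths})
    for num in numerators:
        if num not in profile.elements:
            continue
        for tr in tracers:
            denom = profile.concentrations[tr]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(denom != 0, profile.concentrations[num] / denom, np.nan)
            out[f"{num}/{tr}"] = ratio
    return out


def redundancy_reduce(
    profile: GeochemProfile,
    biotic: ResemblanceMatrix,
    rho_threshold: float = RHO_THRESHOLD,
    n_perm: int = 0,
    seed: int | None = None,
) -> ScreenedGeochem:
    """Drop the weaker member of every highly inter-correlated element pair.

    'Weaker' means a lower RELATE rho against the biotic resemblance; ties
    are broken by fewer censored entries, then alphabetically.
    """
    elements = profile.elements
    if len(elements) < 2:
        raise ValueError("need at least two elements")
    if len(profile.depths) < 3:
        raise ValueError("need at least three samples")
    ids = [str(d) for d in profile.depths]
    matrices = {el: euclidean_matrix(profile.concentrations[el], ids) for el in elements}
    iu = np.triu_indices(len(ids), k=1)
    red = pd.DataFrame(np.eye(len(elements)), index=elements, columns=elements)
    for i, a in enumerate(elements):
        for b in elements[i + 1 :]:
            rho = float(
                spearmanr(matrices[a].values[iu], matrices[b].values[iu]).statistic
            )
            red.loc[a, b] = red.loc[b, a] = rho
    biotic_rho = {
        el: relate(matrices[el], biotic, n_perm=n_perm, seed=seed).value
        for el in elements
    }
    censored = {el: int(np.sum(profile.flags[el] != CENSOR_NONE)) for el in elements}

    dropped: dict[str, str] = {}
    audit_pairs = []
    for i, a in enumerate(elements):
        for b in elements[i + 1 :]:
            if a in dropped or b in dropped:
                continue
            if red.loc[a, b] > rho_threshold:
                # weaker biotic rho loses; ties: more censored, then later name
                key = lambda el: (biotic_rho[el], -censored[el], _rev(el))
                loser = min((a, b), key=key)
                dropped[loser] = DROP_REDUNDANT
                audit_pairs.append(
                    {
                        "pair": [a, b],
                        "rho": red.loc[a, b],
                        "dropped": loser,
                        "biotic_rho": {a: biotic_rho[a], b: biotic_rho[b]},
                    }
                )
    keep = [el for el in elements if el not in dropped]
    screened = GeochemProfile(
        profile.depths.copy(),
        {el: profile.concentrations[el].copy() for el in keep},
        {el: profile.flags[el].copy() for el in keep},
        {el: profile.original_units.get(el, "ppm") for el in keep},
    )
    return ScreenedGeochem(
        screened,
        dropped=dropped,
        redundancy_matrix=red,
        audit={
            "step": "redundancy_reduce",
            "rho_threshold": rho_threshold,
            "biotic_rho": biotic_rho,
            "pairs": audit_pairs,
        },
    )


def _rev(name: str) -> tuple[int, ...]:
    """Sort key making alphabetically-earlier names 'larger' (retained)."""
    return tuple(-ord(c) for c in name)
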