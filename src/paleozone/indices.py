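"""Shannon diversity with health bands and the difflugiid/centropyxid ratio.

The Shannon Diversity Index (SDI, nats) of a sample with proportions p_i is
``-sum(p_i ln p_i)`` over positive entries.  Lake-health bands follow the
convention used in Arcellinida bio-monitoring: stable for SDI in [2.5, 3.5],
in transition for [1.5, 2.5), stressed below 1.5.

The stress ratio is ``D / (D + C)`` where D sums difflugiid-lineage taxa
flagged ``in_dc_ratio`` and C sums centropyxid taxa.  *Arcella vulgaris*
(group ``other``) and *Cucurbitella tricuspis* (planktic eutrophication
indicator) are excluded from both sums.  Values below 0.55 mark a stressed,
centropyxid-dominated assemblage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import AssemblageCounts, TaxonRegistry

__all__ = ["IndexRecord", "shannon_index", "sdi_band", "dc_ratio", "index_profile"]

DC_STRESS_CUTOFF = 0.55

BAND_STABLE = "stable"
BAND_TRANSITION = "transition"
BAND_STRESSED = "stressed"


@dataclass
class IndexRecord:
    sample_id: str
    depth: float
    sdi: float
    richness: int
    band: str
    dc_ratio: float
    dc_stressed: bool


def sdi_band(sdi: float) -> str:
    """Health band for an SDI value; the 2.5 boundary belongs to 'stable'."""
    if sdi >= 2.5:
        return BAND_STABLE
    if sdi >= 1.5:
        return BAND_TRANSITION
    return BAND_STRESSED


def shannon_index(abundances) -> tuple[float, str]:
    """SDI (nats) and health band for one sample's abundance vector.

    Scale-invariant: counts and proportions give the same value.  Zero
    entries are excluded from the sum; an all-zero sample is an error.
    """
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative abundances")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero sample has no diversity")
    p = x[x > 0] / total
    p = p[p > 0]  # guard against underflow of extreme count ratios
    sdi = float(-(p * np.log(p)).sum())
    return sdi, sdi_band(sdi)


def dc_ratio(
    abundances, taxa: list[str], registry: TaxonRegistry
) -> tuple[float, bool]:
    """Difflugiid/centropyxid stress ratio ``D / (D + C)`` for one sample.

    Returns the ratio and a stress flag (ratio < 0.55).  Taxa outside both
    groups, and difflugiids with ``in_dc_ratio=False``, contribute to
    neither sum.
    """
    x = np.asarray(abundances, dtype=float)
    if len(x) != len(taxa):
        raise ValueError("abundance/taxon length mismatch")
    d = c = 0.0
    for value, taxon in zip(x, taxa):
        entry = registry.lookup(taxon)
        if entry.functional_group == "centropyxid":
            c += value
        elif entry.functional_group == "difflugiid" and entry.in_dc_ratio:
            d += value
    if d + c == 0:
        raise ValueError("no ratio-eligible taxa present (D + C = 0)")
    ratio = d / (d + c)
    return ratio, ratio < DC_STRESS_CUTOFF


def index_profile(counts: AssemblageCounts, registry: TaxonRegistry) -> pd.DataFrame:
    """Down-core table of SDI, band, richness and D/C ratio, one row per sample.

    SDI is computed on renormalized relative abundances.
    """
    rows = []
    for i, sid in enumerate(counts.sample_ids):
        x = counts.values[i]
        sdi, band = shannon_index(x)
        ratio, stressed = dc_ratio(x, counts.taxa, registry)
        rows.append(
            IndexRecord(
                sample_id=sid,
                depth=float(counts.nominal_depths[i]),
                sdi=sdi,
                richness=int((x > 0).sum()),
                band=band,
                dc_ratio=ratio,
                dc_stressed=stressed,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
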