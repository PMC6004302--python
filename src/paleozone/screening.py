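"""Count-significance screening and abundance transformations.

Two screens are applied before any multivariate analysis:

* a per-sample *probable error* test — a sample's total specimen count must
  exceed ``pe = 1.96 * s / sqrt(T_i)`` (``s``: standard deviation of
  per-sample totals, ``T_i``: the sample's total) and a minimum count
  (default 150 specimens);
* a per-taxon *standard error* test — a taxon is retained if in at least one
  sample its binomial standard error ``S_Xi = 1.96 * sqrt(X(1-X)/N)`` is
  smaller than its fractional abundance ``X``.

The probable-error formula in the source literature is ambiguous about the
square-root argument (it is printed with the fractional abundance ``X_i``
but compared against a *total count*).  The default here substitutes the
sample total, which makes the comparison dimensionally coherent; the
literal reading (``X_i`` = the sample's fractional share of all specimens
counted) is available via ``interpretation="literal"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import AssemblageCounts

__all__ = [
    "ScreeningResult",
    "probable_error_screen",
    "species_error_screen",
    "to_relative",
    "sqrt_transform",
]

DEFAULT_MIN_TOTAL = 150  # target minimum specimen count per sample


@dataclass
class ScreeningResult:
    """Outcome of a screening pass.

    ``sample_table`` has one row per sample (total, pe, passed);
    ``taxon_table`` one row per taxon (max abundance, min standard error at
    that abundance, retained).  ``screened`` holds the surviving submatrix.
    """

    sample_table: pd.DataFrame
    taxon_table: pd.DataFrame
    screened: AssemblageCounts
    s: float | None = None
    notes: list[str] | None = None

    @property
    def n_samples_passed(self) -> int:
        return int(self.sample_table["passed"].sum())

    @property
    def n_taxa_retained(self) -> int:
        return int(self.taxon_table["retained"].sum())

    def report(self) -> pd.DataFrame:
        """Long-format report: one row per sample and per taxon."""
        s = self.sample_table.assign(kind="sample").rename(columns={"sample_id": "id"})
        t = self.taxon_table.assign(kind="taxon").rename(columns={"taxon": "id"})
        return pd.concat([s, t], ignore_index=True)


def _totals(counts: AssemblageCounts, assumed_total: float = DEFAULT_MIN_TOTAL):
    """Per-sample totals; relative-mode data without totals assume the target
    minimum count (noted in the result)."""
    notes = []
    if counts.totals is not None:
        totals = np.asarray(counts.totals, dtype=float)
    elif counts.mode == "counts":
        totals = counts.values.sum(axis=1)
    else:
        totals = np.full(counts.n_samples, float(assumed_total))
        notes.append(
            f"per-sample totals unavailable; assumed N_i = {assumed_total} "
            "(the targeted minimum count) for error formulas"
        )
    return totals, notes


def probable_error_screen(
    counts: AssemblageCounts,
    min_total: int = DEFAULT_MIN_TOTAL,
    interpretation: str = "total",
) -> ScreeningResult:
    """Screen samples on total count vs probable error.

    A sample passes iff its total ``T_i`` exceeds its probable error *and*
    ``T_i >= min_total``.  ``interpretation`` selects the sqrt argument:
    ``"total"`` (default) uses ``T_i``; ``"literal"`` uses the sample's
    fractional share ``T_i / sum(T)``.
    """
    if interpretation not in ("total", "literal"):
        raise ValueError(f"unknown interpretation {interpretation!r}")
    totals, notes = _totals(counts)
    if np.any(totals <= 0):
        raise ValueError("probable_error_screen needs positive per-sample totals")
    s = float(np.std(totals, ddof=1)) if len(totals) > 1 else 0.0
    arg = totals if interpretation == "total" else totals / totals.sum()
    pe = 1.96 * s / np.sqrt(arg)
    passed = (totals > pe) & (totals >= min_total)
    table = pd.DataFrame(
        {
            "sample_id": counts.sample_ids,
            "total": totals,
            "probable_error": pe,
            "passed": passed,
        }
    )
    keep = np.flatnonzero(passed)
    screened = counts.replace(
        sample_ids=[counts.sample_ids[i] for i in keep],
        depth_top=counts.depth_top[keep],
        depth_bottom=counts.depth_bottom[keep],
        values=counts.values[keep],
        totals=totals[keep],
    )
    taxon_table = pd.DataFrame({"taxon": counts.taxa, "retained": True})
    return ScreeningResult(table, taxon_table, screened, s=s, notes=notes)


def species_error_screen(counts: AssemblageCounts) -> ScreeningResult:
    """Retain taxa whose standard error beats their abundance in >= 1 sample.

    The retention decision is dataset-level: a taxon significant anywhere in
    the core is kept everywhere (the profile of a taxon is interpreted as a
    whole).
    """
    totals, notes = _totals(counts)
    if np.any(totals <= 0):
        raise ValueError("species_error_screen needs positive per-sample totals N_i")
    if counts.mode == "counts":
        X = counts.values / totals[:, None]
    else:
        X = counts.values / counts.values.sum(axis=1, keepdims=True)
    S = 1.96 * np.sqrt(X * (1.0 - X) / totals[:, None])
    significant = S < X  # X == 0 gives S == 0, which does not qualify
    retained = significant.any(axis=0)
    taxon_table = pd.DataFrame(
        {
            "taxon": counts.taxa,
            "max_abundance": X.max(axis=0),
            "n_significant_samples": significant.sum(axis=0),
            "retained": retained,
        }
    )
    keep = np.flatnonzero(retained)
    screened = counts.replace(
        taxa=[counts.taxa[i] for i in keep],
        values=counts.values[:, keep],
        mode="transformed" if counts.mode == "relative" else counts.mode,
        totals=None if counts.mode == "counts" else counts.totals,
    )
    if counts.mode == "relative":
        # dropping columns breaks the row-sum invariant; flag mode change
        notes = notes + ["mode set to 'transformed' after taxon removal"]
    sample_table = pd.DataFrame(
        {"sample_id": counts.sample_ids, "total": totals, "passed": True}
    )
    return ScreeningResult(sample_table, taxon_table, screened, notes=notes)


def to_relative(counts: AssemblageCounts) -> AssemblageCounts:
    """Renormalize each row to sum to exactly 1."""
    sums = counts.values.sum(axis=1)
    if np.any(sums == 0):
        bad = counts.sample_ids[int(np.argmax(sums == 0))]
        raise ValueError(f"cannot renormalize all-zero sample {bad!r}")
    totals = counts.totals if counts.totals is not None else (
        sums if counts.mode == "counts" else None
    )
    return counts.replace(values=counts.values / sums[:, None], mode="relative", totals=totals)


def sqrt_transform(counts: AssemblageCounts) -> AssemblageCounts:
    """Element-wise square root; result is flagged ``mode='transformed'``."""
    return counts.replace(values=np.sqrt(counts.values), mode="transformed", totals=counts.totals)
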