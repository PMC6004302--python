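"""Validated in-memory containers and CSV readers/writers for core datasets.

The data model mirrors what a down-core microfossil study produces:

* an assemblage table (samples x taxa, counts or relative abundances),
* a taxon registry assigning each taxon to a functional group,
* a geochemistry profile (depth x element, with detection-limit flags),
* a loss-on-ignition (LOI) series partitioning sediment mass, and
* an age-depth tie-point table.

Depth convention: sample *i* of a 1-cm-resolution core spans the interval
``(i-1, i]`` cm and its *nominal* depth is the interval bottom ``i``.  All
downstream operations use nominal depths.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssemblageCounts",
    "TaxonRegistry",
    "GeochemProfile",
    "LOISeries",
    "AgeDepthTable",
    "read_assemblage_table",
    "write_assemblage_table",
    "read_taxon_registry",
    "write_taxon_registry",
    "read_geochem_table",
    "write_geochem_table",
    "read_loi_table",
    "write_loi_table",
    "read_age_table",
    "write_age_table",
    "to_ppm",
    "default_registry",
    "frame_lake_assemblage",
    "frame_lake_registry",
    "frame_lake_loi",
    "frame_lake_age_table",
    "frame_lake_printed_indices",
    "frame_lake_radiocarbon",
]

#: Multiplicative factors to parts-per-million.
_UNIT_TO_PPM = {"ppm": 1.0, "ppb": 1e-3, "%": 1e4, "pct": 1e4, "percent": 1e4}

#: Censoring states for geochemical measurements.
CENSOR_NONE = "none"
CENSOR_BELOW = "below_DL"
CENSOR_ABOVE = "above_DL"
CENSOR_MISSING = "missing"

FUNCTIONAL_GROUPS = ("centropyxid", "difflugiid", "other")


def to_ppm(value: float, unit: str) -> float:
    """Convert a concentration from *unit* ('%', 'ppm', 'ppb') to ppm."""
    try:
        return value * _UNIT_TO_PPM[unit.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown concentration unit: {unit!r}") from None


def _normalize_taxon(name: str) -> str:
    """Matching key for a taxon name: case-folded, quote-stripped, synonym-mapped.

    'Medilous corona' and 'Mediolus corona' are treated as the same taxon (both
    spellings occur in the source literature).
    """
    key = re.sub(r"[\"“”']", "", name).strip().lower()
    key = re.sub(r"\s+", " ", key)
    key = key.replace("medilous", "mediolus")
    return key


# ---------------------------------------------------------------------------
# Assemblage table
# ---------------------------------------------------------------------------

@dataclass
class AssemblageCounts:
    """A samples x taxa abundance matrix indexed by depth.

    Parameters
    ----------
    sample_ids : ordered sample labels (shallow to deep).
    taxa : taxon names, one per column.
    depth_top, depth_bottom : interval bounds per sample, cm.  Nominal depth
        is ``depth_bottom``.
    values : non-negative (n_samples, n_taxa) matrix.
    mode : 'counts' (integers), 'relative' (rows sum to ~1) or 'transformed'
        (output of a transformation; no row-sum constraint).
    totals : per-sample specimen counts N_i; required in counts mode.
    """

    sample_ids: list[str]
    taxa: list[str]
    depth_top: np.ndarray
    depth_bottom: np.ndarray
    values: np.ndarray
    mode: str = "counts"
    totals: np.ndarray | None = None
    row_sum_tolerance: float = 0.05

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.depth_top = np.asarray(self.depth_top, dtype=float)
        self.depth_bottom = np.asarray(self.depth_bottom, dtype=float)
        if self.totals is not None:
            self.totals = np.asarray(self.totals, dtype=float)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        n, t = self.values.shape
        if len(self.sample_ids) != n or len(self.taxa) != t:
            raise ValueError("label lengths do not match the value matrix")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if np.any(self.values < 0):
            bad = self.sample_ids[int(np.argwhere(self.values < 0)[0, 0])]
            raise ValueError(f"negative abundance in sample {bad!r}")
        d = self.nominal_depths
        if np.any(np.diff(d) <= 0):
            raise ValueError("nominal depths must be strictly increasing down-core")
        if np.any(self.depth_bottom <= self.depth_top):
            raise ValueError("each depth interval needs depth_top < depth_bottom")
        if np.any(self.depth_top[1:] < self.depth_bottom[:-1] - 1e-9):
            raise ValueError("depth intervals overlap")
        if self.mode == "counts":
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("counts mode requires integer values")
            if self.totals is None:
                self.totals = self.values.sum(axis=1)
            elif not np.allclose(self.totals, self.values.sum(axis=1)):
                raise ValueError("totals disagree with row sums in counts mode")
        elif self.mode == "relative":
            sums = self.values.sum(axis=1)
            off = np.abs(sums - 1.0) > self.row_sum_tolerance
            if np.any(off):
                bad = self.sample_ids[int(np.argmax(off))]
                raise ValueError(
                    f"relative-mode row for sample {bad!r} sums to "
                    f"{sums[np.argmax(off)]:.3f}, outside 1 +/- {self.row_sum_tolerance}"
                )
        elif self.mode != "transformed":
            raise ValueError(f"unknown mode {self.mode!r}")

    # -- convenience --------------------------------------------------------
    @property
    def nominal_depths(self) -> np.ndarray:
        return self.depth_bottom

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxa)
        df.insert(0, "depth_top", self.depth_top)
        df.insert(1, "depth_bottom", self.depth_bottom)
        return df

    def replace(self, **kw) -> "AssemblageCounts":
        base = dict(
            sample_ids=list(self.sample_ids),
            taxa=list(self.taxa),
            depth_top=self.depth_top.copy(),
            depth_bottom=self.depth_bottom.copy(),
            values=self.values.copy(),
            mode=self.mode,
            totals=None if self.totals is None else self.totals.copy(),
            row_sum_tolerance=self.row_sum_tolerance,
        )
        base.update(kw)
        return AssemblageCounts(**base)


def read_assemblage_table(
    path: str | Path,
    mode: str = "counts",
    tolerance: float = 0.05,
    delimiter: str | None = None,
    registry: "TaxonRegistry | None" = None,
) -> AssemblageCounts:
    """Read a samples x taxa CSV/TSV into a validated :class:`AssemblageCounts`.

    The file must have ``sample_id``, ``depth_top`` and ``depth_bottom``
    columns followed by one column per taxon.  An optional ``total`` column
    carries per-sample specimen counts.  When *registry* is given, taxa that
    do not resolve are reported in the raised error.
    """
    if delimiter is None:  # sniff CSV vs TSV from the header line
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        delimiter = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    required = {"sample_id", "depth_top", "depth_bottom"}
    if not required.issubset(df.columns):
        raise ValueError(f"assemblage table needs columns {sorted(required)}")
    if df["sample_id"].duplicated().any() or df["depth_bottom"].duplicated().any():
        raise ValueError("duplicate sample ids or depths in assemblage table")
    totals = None
    taxon_cols = [c for c in df.columns if c not in required and c != "total"]
    if "total" in df.columns:
        totals = df["total"].to_numpy(dtype=float)
    if registry is not None:
        unknown = [t for t in taxon_cols if not registry.knows(t)]
        if unknown:
            raise KeyError(f"taxa absent from registry: {unknown}")
    counts = AssemblageCounts(
        sample_ids=[str(s) for s in df["sample_id"]],
        taxa=taxon_cols,
        depth_top=df["depth_top"].to_numpy(dtype=float),
        depth_bottom=df["depth_bottom"].to_numpy(dtype=float),
        values=df[taxon_cols].to_numpy(dtype=float),
        mode=mode,
        totals=totals,
        row_sum_tolerance=tolerance,
    )
    return counts


def write_assemblage_table(counts: AssemblageCounts, path: str | Path) -> None:
    """Serialize at full precision so a read round-trips bit-exactly."""
    df = counts.to_dataframe().reset_index(names="sample_id")
    if counts.mode == "counts" or counts.totals is not None:
        df["total"] = counts.totals
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Taxon registry
# ---------------------------------------------------------------------------

@dataclass
class TaxonEntry:
    taxon_id: str
    display_name: str
    functional_group: str
    in_dc_ratio: bool
    notes: str = ""


@dataclass
class TaxonRegistry:
    """Taxon -> functional group (centropyxid / difflugiid / other) mapping.

    ``in_dc_ratio`` flags whether a taxon enters the difflugiid/centropyxid
    stress ratio; the planktic eutrophication indicator *Cucurbitella
    tricuspis* is difflugiid-lineage but conventionally excluded.
    """

    entries: dict[str, TaxonEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in self.entries.values():
            if e.functional_group not in FUNCTIONAL_GROUPS:
                raise ValueError(
                    f"unknown functional group {e.functional_group!r} for {e.taxon_id!r}"
                )

    def add(self, entry: TaxonEntry) -> None:
        key = _normalize_taxon(entry.taxon_id)
        if key in self.entries:
            raise ValueError(f"duplicate taxon id {entry.taxon_id!r}")
        if entry.functional_group not in FUNCTIONAL_GROUPS:
            raise ValueError(f"unknown functional group {entry.functional_group!r}")
        self.entries[key] = entry

    def knows(self, taxon: str) -> bool:
        return _normalize_taxon(taxon) in self.entries

    def lookup(self, taxon: str) -> TaxonEntry:
        try:
            return self.entries[_normalize_taxon(taxon)]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} not in registry") from None

    def group_of(self, taxon: str) -> str:
        return self.lookup(taxon).functional_group

    def resolve(self, taxa: Iterable[str]) -> list[TaxonEntry]:
        return [self.lookup(t) for t in taxa]

    def __len__(self) -> int:
        return len(self.entries)


# The 32 taxa of the Frame Lake study.  Group assignment: genus Centropyxis ->
# centropyxid; Arcella vulgaris -> other; everything in the Difflugia lineage
# (Difflugia, Lesquereusia, Lagenodifflugia, Pontigulasia, Mediolus,
# Cucurbitella, Conicocassis) -> difflugiid.  C. tricuspis is excluded from
# the stress ratio (planktic eutrophication indicator, not a benthic
# health signal).
_DEFAULT_TAXA: list[tuple[str, str, bool, str]] = [
    ("Arcella vulgaris", "other", False, "excluded from D/C ratio"),
    ('Centropyxis aculeata "aculeata"', "centropyxid", True, ""),
    ('Centropyxis aculeata "discoides"', "centropyxid", True, ""),
    ('Centropyxis constricta "aerophila"', "centropyxid", True, ""),
    ('Centropyxis constricta "constricta"', "centropyxid", True, ""),
    ('Centropyxis constricta "spinosa"', "centropyxid", True, ""),
    ("Centropyxis pontigulasiformis", "centropyxid", True, ""),
    ("Cucurbitella tricuspis", "difflugiid", False, "planktic eutrophication indicator; excluded from D/C ratio"),
    ("Difflugia bidens", "difflugiid", True, ""),
    ('Difflugia urceolata "urceolata"', "difflugiid", True, ""),
    ('Difflugia urceolata "elongata"', "difflugiid", True, ""),
    ("Difflugia urens", "difflugiid", True, ""),
    ("Lesquereusia spiralis", "difflugiid", True, ""),
    ("Lagenodifflugia vas", "difflugiid", True, ""),
    ("Pontigulasia compressa", "difflugiid", True, ""),
    ('Difflugia glans "magna"', "difflugiid", True, ""),
    ('Difflugia glans "distenda"', "difflugiid", True, ""),
    ("Mediolus corona", "difflugiid", True, "also spelled 'Medilous corona'"),
    ('Difflugia oblonga "oblonga"', "difflugiid", True, ""),
    ('Difflugia oblonga "spinosa"', "difflugiid", True, ""),
    ('Difflugia oblonga "lanceolata"', "difflugiid", True, ""),
    ('Difflugia oblonga "tenuis"', "difflugiid", True, ""),
    ('Difflugia oblonga "glans"', "difflugiid", True, ""),
    ('Difflugia oblonga "triangularis"', "difflugiid", True, ""),
    ('Difflugia oblonga "linearis"', "difflugiid", True, ""),
    ('Difflugia protaeiformis "protaeiformis"', "difflugiid", True, ""),
    ('Difflugia protaeiformis "claviformis"', "difflugiid", True, ""),
    ('Difflugia protaeiformis "curvicaulis"', "difflugiid", True, ""),
    ('Difflugia protaeiformis "amphoralis"', "difflugiid", True, ""),
    ('Difflugia protaeiformis "acuminata"', "difflugiid", True, ""),
    ('Difflugia protaeiformis "scapellum"', "difflugiid", True, ""),
    ("Conicocassis potigulasiformis", "difflugiid", True, ""),
]


def default_registry() -> TaxonRegistry:
    """Registry covering the 32 Arcellinida taxa of the Frame Lake core."""
    reg = TaxonRegistry()
    for name, group, in_ratio, notes in _DEFAULT_TAXA:
        reg.add(TaxonEntry(name, name, group, in_ratio, notes))
    return reg


def read_taxon_registry(path: str | Path) -> TaxonRegistry:
    df = pd.read_csv(path)
    needed = {"taxon_id", "functional_group", "in_dc_ratio"}
    if not needed.issubset(df.columns):
        raise ValueError(f"registry needs columns {sorted(needed)}")
    reg = TaxonRegistry()
    for _, row in df.iterrows():
        reg.add(
            TaxonEntry(
                taxon_id=row["taxon_id"],
                display_name=row.get("display_name", row["taxon_id"]),
                functional_group=str(row["functional_group"]).strip().lower(),
                in_dc_ratio=bool(row["in_dc_ratio"]),
                notes=str(row["notes"]) if "notes" in df.columns and pd.notna(row["notes"]) else "",
            )
        )
    return reg


def write_taxon_registry(registry: TaxonRegistry, path: str | Path) -> None:
    rows = [
        {
            "taxon_id": e.taxon_id,
            "display_name": e.display_name,
            "functional_group": e.functional_group,
            "in_dc_ratio": e.in_dc_ratio,
            "notes": e.notes,
        }
        for e in registry.entries.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Geochemistry
# ---------------------------------------------------------------------------

@dataclass
class GeochemProfile:
    """Depth-indexed element concentrations, stored in ppm with censor flags."""

    depths: np.ndarray
    concentrations: dict[str, np.ndarray]   # element -> ppm values
    flags: dict[str, np.ndarray]            # element -> censor state strings
    original_units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("geochemistry depths must be strictly increasing")
        for el, vals in self.concentrations.items():
            vals = np.asarray(vals, dtype=float)
            self.concentrations[el] = vals
            fl = np.asarray(self.flags.get(el, np.full(len(vals), CENSOR_NONE)))
            self.flags[el] = fl
            if len(vals) != len(self.depths) or len(fl) != len(self.depths):
                raise ValueError(f"length mismatch for element {el!r}")
            ok = fl == CENSOR_NONE
            if np.any(vals[ok] < 0):
                raise ValueError(f"negative uncensored concentration for {el!r}")

    @property
    def elements(self) -> list[str]:
        return list(self.concentrations)

    def censored_fraction(self, element: str) -> float:
        fl = self.flags[element]
        return float(np.mean(fl != CENSOR_NONE))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"depth": self.depths})
        for el in self.elements:
            df[el] = self.concentrations[el]
            df[f"{el}_flag"] = self.flags[el]
        return df


_CENSOR_RE = re.compile(r"^\s*([<>])\s*([0-9.eE+-]+)\s*$")


def _parse_cell(cell) -> tuple[float, str]:
    """Parse one geochemistry cell: '<x' / '>x' carry a detection limit."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return np.nan, CENSOR_MISSING
    s = str(cell).strip()
    if s == "" or s.lower() in {"na", "nan", "-", "--"}:
        return np.nan, CENSOR_MISSING
    m = _CENSOR_RE.match(s)
    if m:
        return float(m.group(2)), CENSOR_BELOW if m.group(1) == "<" else CENSOR_ABOVE
    try:
        return float(s), CENSOR_NONE
    except ValueError:
        raise ValueError(f"non-numeric uncensored geochemistry cell: {cell!r}") from None


def read_geochem_table(path: str | Path, unit_map: Mapping[str, str] | None = None) -> GeochemProfile:
    """Read a depth x element table; all concentrations converted to ppm.

    *unit_map* gives each element's original unit ('%', 'ppm', 'ppb');
    elements not listed are assumed to be ppm already.
    """
    df = pd.read_csv(path, dtype=str)
    if "depth" not in df.columns:
        raise ValueError("geochemistry table needs a 'depth' column")
    unit_map = dict(unit_map or {})
    depths = df["depth"].astype(float).to_numpy()
    conc: dict[str, np.ndarray] = {}
    flags: dict[str, np.ndarray] = {}
    units: dict[str, str] = {}
    for el in [c for c in df.columns if c != "depth"]:
        unit = unit_map.get(el, "ppm")
        factor = to_ppm(1.0, unit)
        parsed = [_parse_cell(c) for c in df[el]]
        conc[el] = np.array([v * factor for v, _ in parsed])
        flags[el] = np.array([f for _, f in parsed])
        units[el] = unit
    return GeochemProfile(depths, conc, flags, units)


def write_geochem_table(profile: GeochemProfile, path: str | Path) -> None:
    """Write ppm values; censored cells serialize as '<DL' / '>DL' / blank."""
    out = {"depth": [f"{d:.17g}" for d in profile.depths]}
    for el in profile.elements:
        cells = []
        for v, f in zip(profile.concentrations[el], profile.flags[el]):
            if f == CENSOR_MISSING:
                cells.append("")
            elif f == CENSOR_BELOW:
                cells.append(f"<{v:.17g}")
            elif f == CENSOR_ABOVE:
                cells.append(f">{v:.17g}")
            else:
                cells.append(f"{v:.17g}")
        out[el] = cells
    pd.DataFrame(out).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Loss on ignition
# ---------------------------------------------------------------------------

@dataclass
class LOISeries:
    """Loss-on-ignition mass fractions per depth.

    ``water`` is a fraction of wet mass; ``organics + carbonates +
    minerogenics`` partition the dry mass and must close to 1 within
    *closure_tolerance* (printed tables round to 2 decimals).
    """

    depths: np.ndarray
    water: np.ndarray
    organics: np.ndarray
    carbonates: np.ndarray
    minerogenics: np.ndarray
    closure_tolerance: float = 0.02

    def __post_init__(self) -> None:
        for name in ("depths", "water", "organics", "carbonates", "minerogenics"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("LOI depths must be strictly increasing")
        for name in ("water", "organics", "carbonates", "minerogenics"):
            v = getattr(self, name)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"LOI fraction {name!r} outside [0, 1]")
        closure = self.organics + self.carbonates + self.minerogenics
        if np.any(np.abs(closure - 1.0) > self.closure_tolerance):
            i = int(np.argmax(np.abs(closure - 1.0)))
            raise ValueError(
                f"dry-mass fractions at depth {self.depths[i]} sum to {closure[i]:.3f}"
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth": self.depths,
                "water": self.water,
                "organics": self.organics,
                "carbonates": self.carbonates,
                "minerogenics": self.minerogenics,
            }
        )


def read_loi_table(path: str | Path, closure_tolerance: float = 0.02) -> LOISeries:
    df = pd.read_csv(path, float_precision="round_trip")
    needed = {"depth", "water", "organics", "carbonates", "minerogenics"}
    if not needed.issubset(df.columns):
        raise ValueError(f"LOI table needs columns {sorted(needed)}")
    return LOISeries(
        df["depth"].to_numpy(),
        df["water"].to_numpy(),
        df["organics"].to_numpy(),
        df["carbonates"].to_numpy(),
        df["minerogenics"].to_numpy(),
        closure_tolerance=closure_tolerance,
    )


def write_loi_table(loi: LOISeries, path: str | Path) -> None:
    loi.to_dataframe().to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Age-depth tie points
# ---------------------------------------------------------------------------

@dataclass
class Hiatus:
    """A depositional gap: instantaneous in depth, long in time."""

    depth: float
    age_above: float | None = None     # youngest side, year AD
    age_below_label: str | None = None  # e.g. ">7,000 BP" when undated below


@dataclass
class AgeDepthTable:
    """Tie points (depth cm, calendar year AD) with optional rates and hiatuses."""

    depths: np.ndarray
    years: np.ndarray
    rates: np.ndarray | None = None       # cm/yr, aligned with depths
    ash_rates: np.ndarray | None = None   # alternative rate estimate
    hiatuses: list[Hiatus] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.years = np.asarray(self.years, dtype=float)
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("tie-point depths must be strictly increasing")
        # ages must not get younger with depth within a continuous segment
        bounds = sorted(h.depth for h in self.hiatuses)
        seg = np.searchsorted(bounds, self.depths, side="left")
        for s in np.unique(seg):
            yy = self.years[seg == s]
            if np.any(np.diff(yy) > 0):
                raise ValueError("age reversal within a continuous segment")
        for name in ("rates", "ash_rates"):
            r = getattr(self, name)
            if r is not None:
                r = np.asarray(r, dtype=float)
                if len(r) != len(self.depths):
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, r)

    @property
    def n_tie_points(self) -> int:
        return len(self.depths)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"depth": self.depths, "year_ad": self.years})
        if self.rates is not None:
            df["sed_rate_cm_yr"] = self.rates
        if self.ash_rates is not None:
            df["sed_rate_ash_cm_yr"] = self.ash_rates
        return df


def read_age_table(path: str | Path) -> AgeDepthTable:
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"depth", "year_ad"}.issubset(df.columns):
        raise ValueError("age table needs 'depth' and 'year_ad' columns")
    df = df[pd.notna(df["year_ad"])]
    hiatuses = []
    if "hiatus_below_label" in df.columns:
        for _, row in df[pd.notna(df["hiatus_below_label"])].iterrows():
            hiatuses.append(
                Hiatus(float(row["depth"]), float(row["year_ad"]), str(row["hiatus_below_label"]))
            )
    return AgeDepthTable(
        df["depth"].to_numpy(dtype=float),
        df["year_ad"].to_numpy(dtype=float),
        rates=df["sed_rate_cm_yr"].to_numpy(dtype=float) if "sed_rate_cm_yr" in df.columns else None,
        ash_rates=df["sed_rate_ash_cm_yr"].to_numpy(dtype=float) if "sed_rate_ash_cm_yr" in df.columns else None,
        hiatuses=hiatuses,
    )


def write_age_table(table: AgeDepthTable, path: str | Path) -> None:
    df = table.to_dataframe()
    if table.hiatuses:
        df["hiatus_below_label"] = [
            next((h.age_below_label for h in table.hiatuses if h.depth == d), None)
            for d in table.depths
        ]
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Packaged Frame Lake fixtures (printed data tables of the source study)
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("paleozone.data").joinpath(name)


def frame_lake_assemblage(registry: TaxonRegistry | None = None) -> AssemblageCounts:
    """The 30-sample x 32-taxon relative-abundance table of the Frame Lake core."""
    with resources.as_file(_data_path("frame_lake_assemblage.csv")) as p:
        return read_assemblage_table(p, mode="relative", tolerance=0.05, registry=registry)


def frame_lake_registry() -> TaxonRegistry:
    with resources.as_file(_data_path("frame_lake_registry.csv")) as p:
        return read_taxon_registry(p)


def frame_lake_loi() -> LOISeries:
    with resources.as_file(_data_path("frame_lake_loi.csv")) as p:
        return read_loi_table(p)


def frame_lake_age_table() -> AgeDepthTable:
    """Pb-210 / ash-layer tie points above the 17 cm unconformity (21 points)."""
    with resources.as_file(_data_path("frame_lake_ages.csv")) as p:
        return read_age_table(p)


def frame_lake_printed_indices() -> pd.DataFrame:
    """Printed Shannon index and D/C ratio rows, for comparison only."""
    with resources.as_file(_data_path("frame_lake_printed_indices.csv")) as p:
        return pd.read_csv(p)


def frame_lake_radiocarbon() -> pd.DataFrame:
    """Radiocarbon dates (annotation only; jumbled above the unconformity)."""
    with resources.as_file(_data_path("frame_lake_radiocarbon.csv")) as p:
        return pd.read_csv(p)
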