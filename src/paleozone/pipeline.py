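"""Configuration-driven orchestration of the full core analysis.

Stages run in the order the method demands: read -> screen -> indices ->
geochemistry screening -> biotic resemblance -> constrained zonation with
broken-stick selection -> ANOSIM over the zones -> RELATE of every
environmental covariate against the biotic matrix (ranked by rho) -> NMDS
-> chronological annotation of the zones.  Every stage writes its table
under the configured output directory and the run report records config,
package version, content hashes and wall time per stage, so a re-run with
identical inputs is verifiably identical.

Missing optional inputs degrade gracefully: without geochemistry the
biotic-only branch still completes and the report logs the skipped stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import (
    read_assemblage_table,
    read_taxon_registry,
    read_geochem_table,
    read_loi_table,
    read_age_table,
    default_registry,
)
from .screening import probable_error_screen, species_error_screen, to_relative, sqrt_transform
from .indices import index_profile
from .geochem import censoring_screen, aluminum_normalize, redundancy_reduce
from .resemblance import bray_curtis, euclidean_matrix
from .zonation import coniss, broken_stick_table, broken_stick_select
from .inference import anosim, relate
from .ordination import nmds, zone_overlay
from .chronology import build_age_model, BelowHiatus

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("paleozone.pipeline")


@dataclass
class PipelineConfig:
    """Flat-key run configuration; any unset optional input skips its stage."""

    assemblage: str
    outdir: str
    registry: str | None = None
    loi: str | None = None
    geochem: str | None = None
    geochem_units: dict = field(default_factory=dict)
    ages: str | None = None
    mode: str = "relative"
    row_tolerance: float = 0.05
    min_total: int = 150
    censor_threshold: float = 0.25
    rho_threshold: float = 0.95
    al_normalize: bool = True
    biotic_transform: str = "sqrt"       # matrix for ANOSIM / RELATE / NMDS
    zonation_transform: str = "none"     # matrix for CONISS
    zonation_coefficient: str = "bray-curtis"  # or "sq-euclidean"
    max_k: int | None = None
    n_perm: int = 999
    seed: int | None = None
    nmds_dims: int = 2
    nmds_starts: int = 50
    delimiter: str | None = None

    def __post_init__(self) -> None:
        if self.n_perm > 0 and self.seed is None:
            raise ValueError("a seed is mandatory when permutation tests are enabled")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _biotic_matrix(rel, transform: str, coefficient: str = "bray-curtis"):
    if transform == "sqrt":
        data = sqrt_transform(rel)
        expect = True
    elif transform == "none":
        data = rel
        expect = False
    else:
        raise ValueError(f"unknown transform {transform!r}")
    if coefficient == "bray-curtis":
        return bray_curtis(data, expect_transformed=expect)
    if coefficient == "sq-euclidean":
        m = euclidean_matrix(data.values, list(data.sample_ids), name="sq-euclidean")
        m.values[:] = m.values**2
        m.transform = transform
        return m
    raise ValueError(f"unknown coefficient {coefficient!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
        "skipped": {},
        "outputs": {},
    }

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn()
            except Exception as exc:
                log.error("stage %s failed: %s", name, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            report["stages"][name] = {"seconds": round(time.perf_counter() - t0, 4)}
            log.info("stage %s: done", name)
            return out

        return wrap

    # -- read ---------------------------------------------------------------
    @stage("read")
    def _read():
        registry = (
            read_taxon_registry(config.registry) if config.registry else default_registry()
        )
        counts = read_assemblage_table(
            config.assemblage,
            mode=config.mode,
            tolerance=config.row_tolerance,
            delimiter=config.delimiter,
            registry=registry,
        )
        loi = read_loi_table(config.loi) if config.loi else None
        geochem = (
            read_geochem_table(config.geochem, config.geochem_units)
            if config.geochem
            else None
        )
        ages = read_age_table(config.ages) if config.ages else None
        return registry, counts, loi, geochem, ages

    registry, counts, loi, geochem, ages = _read

    # -- screening ----------------------------------------------------------
    @stage("screening")
    def _screen():
        pe = probable_error_screen(counts, min_total=config.min_total)
        sp = species_error_screen(pe.screened)
        path = outdir / "screening.csv"
        pd.concat([pe.report(), sp.report()], ignore_index=True).to_csv(path, index=False)
        report["outputs"]["screening"] = str(path)
        report["screening"] = {
            "samples_passed": pe.n_samples_passed,
            "taxa_retained": sp.n_taxa_retained,
            "s": pe.s,
            "notes": (pe.notes or []) + (sp.notes or []),
        }
        return pe

    pe_result = _screen
    rel = to_relative(pe_result.screened)

    # -- indices ------------------------------------------------------------
    @stage("indices")
    def _indices():
        prof = index_profile(rel, registry)
        path = outdir / "indices.csv"
        prof.to_csv(path, index=False)
        report["outputs"]["indices"] = str(path)
        report["indices"] = {
            "mean_sdi": float(prof["sdi"].mean()),
            "mean_dc_ratio": float(prof["dc_ratio"].mean()),
            "n_stressed": int(prof["dc_stressed"].sum()),
        }
        return prof

    indices_df = _indices

    # -- biotic resemblance ---------------------------------------------------
    @stage("resemblance")
    def _resemblance():
        biotic = _biotic_matrix(rel, config.biotic_transform)
        path = outdir / "biotic_matrix.csv"
        biotic.to_dataframe().to_csv(path, float_format="%.17g")
        report["outputs"]["biotic_matrix"] = str(path)
        report["resemblance"] = {
            "coefficient": biotic.coefficient,
            "transform": config.biotic_transform,
            "kind": biotic.kind,
            "sha256": _sha256(path),
            "note": (
                "matrix computed from renormalized relative abundances; with "
                "near-equal specimen totals this is rank-equivalent to the "
                "count-based matrix"
            ),
        }
        return biotic

    biotic = _resemblance

    # -- geochemistry ---------------------------------------------------------
    screened_geochem = None
    if geochem is not None:
        @stage("geochem")
        def _geochem():
            cens = censoring_screen(geochem, config.censor_threshold)
            profile = cens.profile
            if config.al_normalize and "Al" in profile.elements:
                profile = aluminum_normalize(profile)
            red = redundancy_reduce(
                profile, biotic, rho_threshold=config.rho_threshold,
                n_perm=0, seed=config.seed,
            )
            path = outdir / "geochem_screened.csv"
            red.profile.to_dataframe().to_csv(path, index=False, float_format="%.17g")
            audit = {
                "censoring": cens.audit | {"dropped": cens.dropped,
                                           "substitutions": cens.substitutions},
                "redundancy": {
                    "dropped": red.dropped,
                    "rho_threshold": config.rho_threshold,
                    "pairs": red.audit["pairs"],
                },
                "al_normalized": config.al_normalize and "Al" in cens.profile.elements,
            }
            (outdir / "geochem_audit.json").write_text(json.dumps(audit, indent=2, default=float))
            report["outputs"]["geochem"] = str(path)
            report["geochem"] = {
                "retained": red.retained,
                "dropped": {**cens.dropped, **red.dropped},
            }
            return red

        screened_geochem = _geochem
    else:
        report["skipped"]["geochem"] = "no geochemistry input configured"
        log.warning("geochem input missing; geochemical stages skipped")

    # -- zonation -------------------------------------------------------------
    @stage("zonation")
    def _zonation():
        zmatrix = _biotic_matrix(rel, config.zonation_transform, config.zonation_coefficient)
        tree = coniss(zmatrix)
        k = broken_stick_select(tree, config.max_k)
        zones = tree.zones(k)
        bs = broken_stick_table(tree, config.max_k)
        zone_df = pd.DataFrame(
            {
                "sample_id": rel.sample_ids,
                "depth": rel.nominal_depths,
                "zone": zones,
            }
        )
        zone_df.to_csv(outdir / "zones.csv", index=False)
        bs.to_csv(outdir / "broken_stick.csv", index=False)
        (outdir / "merge_tree.json").write_text(
            json.dumps(
                [
                    {"step": m.step, "left": m.left, "right": m.right,
                     "increase": m.increase, "height": m.height}
                    for m in tree.merges
                ],
                indent=2,
            )
        )
        report["outputs"]["zones"] = str(outdir / "zones.csv")
        sizes = pd.Series(zones).value_counts().sort_index()
        report["zonation"] = {
            "coefficient": f"{config.zonation_coefficient} on "
                           f"{'sqrt ' if config.zonation_transform == 'sqrt' else ''}relative abundances",
            "chosen_k": int(k),
            "zone_sizes_deep_to_shallow": sizes.tolist(),
            "boundaries_after_sample": [rel.sample_ids[b] for b in tree.boundaries(k)],
        }
        return tree, k, zones

    tree, chosen_k, zones = _zonation

    # -- ANOSIM ---------------------------------------------------------------
    @stage("anosim")
    def _anosim():
        if chosen_k < 2:
            report["anosim"] = {"skipped": "single zone; no grouping to test"}
            return None
        res = anosim(biotic, zones, n_perm=config.n_perm, seed=config.seed)
        report["anosim"] = res.as_dict()
        return res

    _anosim

    # -- RELATE ranked covariates ----------------------------------------------
    @stage("relate")
    def _relate():
        covariates: dict[str, np.ndarray] = {}
        if loi is not None:
            covariates.update(
                {
                    "minerogenics": loi.minerogenics,
                    "organics": loi.organics,
                    "water": loi.water,
                    "carbonates": loi.carbonates,
                }
            )
        if screened_geochem is not None:
            covariates.update(screened_geochem.profile.concentrations)
        if not covariates:
            report["skipped"]["relate"] = "no environmental covariates available"
            return None
        rows = []
        for name, series in covariates.items():
            if len(series) != biotic.n:
                report["skipped"][f"relate:{name}"] = "sample count mismatch"
                continue
            env = euclidean_matrix(series, list(biotic.sample_ids), name=f"euclidean:{name}")
            try:
                res = relate(biotic, env, n_perm=config.n_perm, seed=config.seed)
            except ValueError as exc:  # e.g. a constant covariate
                report["skipped"][f"relate:{name}"] = str(exc)
                continue
            rows.append({"covariate": name, "rho": res.value, "p": res.p_value,
                         "n_perm": res.n_perm})
        ranked = pd.DataFrame(rows).sort_values("rho", ascending=False, ignore_index=True)
        path = outdir / "relate_ranked.csv"
        ranked.to_csv(path, index=False)
        report["outputs"]["relate"] = str(path)
        report["relate"] = ranked.to_dict(orient="records")
        return ranked

    _relate

    # -- NMDS -----------------------------------------------------------------
    @stage("nmds")
    def _nmds():
        res = nmds(
            biotic, m=config.nmds_dims, n_starts=config.nmds_starts, seed=config.seed
        )
        overlay = zone_overlay(res, zones)
        df = overlay["coordinates"].reset_index(names="sample_id")
        path = outdir / "nmds.csv"
        df.to_csv(path, index=False, float_format="%.17g")
        report["outputs"]["nmds"] = str(path)
        report["nmds"] = {
            "stress": res.stress,
            "converged": res.converged,
            "n_starts": res.n_starts,
            "best_start": res.best_start,
            "within_spread": overlay["within_spread"],
            "mean_between_centroid_distance": overlay["mean_between_centroid_distance"],
        }
        return res

    _nmds

    # -- chronology -------------------------------------------------------------
    if ages is not None:
        @stage("chronology")
        def _chronology():
            model = build_age_model(ages)
            annotations = []
            for z in sorted(set(zones)):
                idx = np.flatnonzero(zones == z)
                top_depth = float(counts.depth_top[idx[0]])
                bottom_depth = float(counts.depth_bottom[idx[-1]])
                lo, hi = model.depth_range
                young = model.assign_age(max(top_depth, lo)) if top_depth <= hi else None
                old = model.assign_age(min(bottom_depth, hi)) if bottom_depth >= lo else None
                if bottom_depth > hi:
                    probe = model.assign_age(bottom_depth)
                    label = probe.label if isinstance(probe, BelowHiatus) else None
                    annotations.append(
                        {"zone": int(z), "age_range": f"pre-hiatus, {label}"}
                    )
                else:
                    annotations.append(
                        {
                            "zone": int(z),
                            "year_oldest": float(old) if old is not None else None,
                            "year_youngest": float(young) if young is not None else None,
                            "age_range": f"{old:.0f}-{young:.0f} AD",
                        }
                    )
            path = outdir / "zone_ages.csv"
            pd.DataFrame(annotations).to_csv(path, index=False)
            report["outputs"]["zone_ages"] = str(path)
            report["chronology"] = {"zones": annotations}
            return model

        _chronology
    else:
        report["skipped"]["chronology"] = "no age-depth input configured"

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=float))
    report["outputs"]["report"] = str(report_path)
    return report
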