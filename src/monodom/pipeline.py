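"""End-to-end orchestration: stems -> surfaces -> patches -> analyses.

`analyze_site` runs the full measurement chain for one site's census pair
and returns a report dictionary; `run_pipeline` drives it from a YAML/dict
configuration over any number of sites (field data read from delimited
stem tables, or synthetic data generated on the fly) and writes all
intermediate artifacts.  Every stage is a pure function of (inputs,
config, seed), so reruns are bit-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import boundary as bd
from . import gyration as gy
from . import patches as pa
from . import surfaces as sf
from . import tables as tb
from .simulate import SimulationConfig, PatchSpec, simulate
from .stems import (CensusTable, PlotGeometry, impute_missing_coordinates,
                    read_stem_table, select_target_stems, write_stem_table)
from .vectorfield import bootstrap_ba_change, difference_surface, slope_aspect

log = logging.getLogger("monodom")

__all__ = ["build_intensity_surface", "analyze_site", "run_pipeline", "load_config"]


def build_intensity_surface(
    stems: pd.DataFrame,
    plot: PlotGeometry,
    pad: int = 200,
    radius: float = sf.ONE_HECTARE_RADIUS,
) -> sf.BAGrid:
    """Raw stem points -> smoothed BA ha⁻¹ surface on the 1 m lattice.

    Rasterise BA to 1 m² cells, reflection-pad, apply the one-hectare
    circular focal sum and the 3x3 mean, then crop back to the plot.
    """
    grid = sf.rasterize_ba(stems, plot)
    grid = sf.reflect_pad(grid, pad)
    grid = sf.focal_circular_sum(grid, radius)
    grid = sf.smooth_mean_3x3(grid)
    return sf.crop_to_plot(grid)


def _boundary_vertices(geom) -> np.ndarray:
    """All exterior-ring vertices of a (multi)polygon, closing point dropped."""
    parts = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
    return np.vstack([np.asarray(p.exterior.coords)[:-1] for p in parts])


def analyze_site(
    census1: CensusTable,
    census3: CensusTable,
    plot: PlotGeometry,
    species: str,
    threshold: float = 20.0,
    max_reuse: int = 2,
    seed: int = 0,
    n_boot: int = 10_000,
    n_perm: int = 10_000,
    pad: int = 200,
    min_area: float = 300.0,
    isolation: float = 30.0,
    bandwidth: float = 25.0,
    site: str = "site",
    outdir: str | Path | None = None,
) -> dict:
    """Run all three analyses for one site and return the report dict."""
    rng = np.random.default_rng(seed)
    years = (census1.census_year, census3.census_year)
    dt = years[1] - years[0]

    stems = {}
    surfaces = {}
    for label, census in (("t1", census1), ("t3", census3)):
        sel = select_target_stems(census.records, species)
        if sel["x"].isna().any() or sel["y"].isna().any():
            sel = impute_missing_coordinates(sel, seed=rng)
        stems[label] = sel
        surfaces[label] = build_intensity_surface(sel, plot, pad=pad)
        log.info("%s %s: %d target stems", site, label, len(sel))

    # --- gyration ---------------------------------------------------------
    awm = {}
    occupancy = {}
    for label in ("t1", "t3"):
        comps = gy.connected_patches(surfaces[label], threshold)
        awm[label] = gy.area_weighted_mean_rog(comps)
        occupancy[label] = gy.percent_occupancy(surfaces[label], threshold)
    rate = gy.expansion_rate(awm["t1"], awm["t3"], dt)
    gyration_report = {
        "awm_rog_t1_m": awm["t1"], "awm_rog_t3_m": awm["t3"],
        "occupancy_t1_pct": occupancy["t1"], "occupancy_t3_pct": occupancy["t3"],
        "pct_increase": 100.0 * (occupancy["t3"] - occupancy["t1"]) / occupancy["t1"]
        if occupancy["t1"] > 0 else float("nan"),
        "awm_rog_rate_m_yr": rate,
        "boundary_advance_disc_estimate_m_yr": gy.boundary_rate_from_awm(rate),
    }

    # --- boundary movement ------------------------------------------------
    sets = {}
    for label in ("t1", "t3"):
        ps = pa.close_with_plot_boundary(
            surfaces[label], threshold, plot, site=site, census=label)
        sets[label] = pa.filter_and_merge(ps, min_area=min_area, isolation=isolation)
        log.info("%s %s: %d tracked patch units", site, label, len(sets[label]))
    pairs_t, un1, un3 = pa.track_across_censuses(sets["t1"], sets["t3"])
    movement_rows = []
    for p1, p3 in pairs_t:
        v1 = _boundary_vertices(p1.geometry)
        v3 = _boundary_vertices(p3.geometry)
        # a strongly expanded (or multipart) boundary can carry more than
        # max_reuse times the early vertices; widen the cap just enough
        reuse = max(max_reuse, -(-len(v3) // len(v1)))
        if reuse > max_reuse:
            log.info("%s patch %s: raising reuse cap %d -> %d",
                     site, p1.id, max_reuse, reuse)
        matched = bd.assign_quadrants(
            bd.match_vertices(v3, v1, reuse), p1.centroid)
        models = bd.fit_all_quadrants(matched, years)
        perm = bd.pairing_permutation_test(
            v3, v1, p1.centroid, years, reuse, n_perm,
            rng.integers(2**31))
        radial = bd.radial_movement_test(
            matched, p1.centroid, years, n_perm, rng.integers(2**31))
        for q, model in models.items():
            col = "ns" if q in "NS" else "ew"
            sub = matched[matched[col] == q]
            boot_mean, lo, hi = bd.bootstrap_rate(
                sub, model.response, years, n_boot, rng.integers(2**31))
            move_p = bd.movement_permutation_test(
                sub, model.response, years, n_perm, rng.integers(2**31)).p
            movement_rows.append({
                "site": site, "patch": p1.id, "quadrant": q,
                "rate": model.beta1, "ci_low": lo, "ci_high": hi,
                "boot_mean": boot_mean, "sigma": model.sigma,
                "delta": model.delta, "n_pairs": model.n_pairs,
                "pairing_perm_p": perm[q].p if q in perm else float("nan"),
                "movement_perm_p": move_p,
                "patch_radial_rate": radial.observed,
                "patch_radial_perm_p": radial.p,
            })
    movement = pd.DataFrame(movement_rows)

    # --- vector field -----------------------------------------------------
    kde = {label: sf.kernel_intensity(stems[label], plot, bandwidth)
           for label in ("t1", "t3")}
    diff = difference_surface(kde["t3"], kde["t1"])
    field = slope_aspect(diff)
    ba_mean, ba_lo, ba_hi = bootstrap_ba_change(
        diff, n_boot=n_boot, seed=rng.integers(2**31))
    vector_report = {
        "ba_change_mean_m2_ha": ba_mean,
        "ba_change_ci_low": ba_lo, "ba_change_ci_high": ba_hi,
        "mean_vector_magnitude": float(np.nanmean(field.magnitude)),
    }

    report = {
        "site": site,
        "n_target_stems": {k: int(len(v)) for k, v in stems.items()},
        "gyration": gyration_report,
        "movement": movement_rows,
        "vector_field": vector_report,
        "unmatched_patches": {"t1": len(un1), "t3": len(un3)},
    }
    if len(movement):
        oriented = tb.orient_rates(movement)
        mean, me = tb.overall_mean_with_me(oriented["oriented_rate"])
        report["oriented_mean_rate_m_yr"] = mean
        report["oriented_mean_me"] = me
        report["radial_advance_estimate_m_yr"] = bd.radial_rate_from_group_mean(mean)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for label in ("t1", "t3"):
            write_stem_table(stems[label], outdir / f"{site}_{label}_stems.csv")
            sf.write_ascii_grid(surfaces[label], outdir / f"{site}_{label}_ba_ha.asc")
            pa.write_geojson(sets[label], outdir / f"{site}_{label}_patches.geojson")
        movement.to_csv(outdir / f"{site}_movement.csv", index=False)
        with open(outdir / f"{site}_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _site_inputs(site_cfg: dict, seed: int):
    """Resolve one site block to (census1, census3, plot, species)."""
    if "synthetic" in site_cfg:
        syn = dict(site_cfg["synthetic"])
        syn.setdefault("seed", seed)
        patches = [PatchSpec(**p) for p in syn.pop("patches", [{}])]
        plot = PlotGeometry(**syn.pop("plot", {}))
        cfg = SimulationConfig(plot=plot, patches=patches, **syn)
        pair = simulate(cfg)
        return pair.census1, pair.census3, plot, cfg.target_species, pair
    plot = PlotGeometry(**site_cfg.get("plot", {}))
    years = site_cfg.get("years", [1995.0, 2007.0])
    colmap = site_cfg.get("column_map")
    c1 = CensusTable(read_stem_table(site_cfg["census1"], colmap), years[0])
    c3 = CensusTable(read_stem_table(site_cfg["census3"], colmap), years[1])
    return c1, c3, plot, site_cfg.get("species", "GILDE"), None


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run every configured site and assemble the cross-site report."""
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir or config.get("outdir", "monodom_out"))
    seed = int(config.get("seed", 0))
    n_boot = int(config.get("n_boot", 10_000))
    n_perm = int(config.get("n_perm", 10_000))
    site_reports = []
    for name, site_cfg in config["sites"].items():
        c1, c3, plot, species, pair = _site_inputs(site_cfg, seed)
        rep = analyze_site(
            c1, c3, plot, species,
            threshold=site_cfg.get("threshold", 20.0),
            max_reuse=site_cfg.get("max_reuse", 2),
            seed=seed, n_boot=n_boot, n_perm=n_perm,
            pad=site_cfg.get("pad", 200),
            site=name, outdir=outdir,
        )
        if pair is not None:
            rep["truth"] = pair.truth
            with open(outdir / f"{name}_truth.json", "w") as fh:
                json.dump(pair.truth, fh, indent=2, default=float)
        site_reports.append(rep)

    rates = [r["gyration"]["awm_rog_rate_m_yr"] for r in site_reports]
    pcts = [r["gyration"]["pct_increase"] for r in site_reports
            if np.isfinite(r["gyration"]["pct_increase"])]
    report = {
        "seed": seed,
        "sites": site_reports,
        "site_rate_summary": gy.site_summary(rates),
        "pct_increase_summary": gy.site_summary(pcts) if pcts else None,
    }
    all_moves = [m for r in site_reports for m in r["movement"]]
    if all_moves:
        oriented = tb.orient_rates(pd.DataFrame(all_moves))
        mean, me = tb.overall_mean_with_me(oriented["oriented_rate"])
        report["overall_oriented_mean_m_yr"] = mean
        report["overall_oriented_me"] = me
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
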