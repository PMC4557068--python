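"""End-to-end synthetic study: generate inputs, build every intermediate
product, and run the driver attribution.

This is the orchestration layer the command line and the reproduction
script share.  Each step delegates to the corresponding module:
charcoal compositing (:mod:`sedfire.composite`), pollen-to-biomass
transfer functions (:mod:`sedfire.mat`), driver extraction
(:mod:`sedfire.drivers`) and the semipartial correlation panel
(:mod:`sedfire.attribution`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import attribution, composite, drivers, mat, synth
from .core import BROADLEAVES, CONIFERS, GENERA, ZONES


def millennial_from_composite(series, n_millennia=8):
    return attribution.downsample_millennial(series.bin_age, series.mean, n_millennia)


def run_study(
    cfg: synth.SynthConfig,
    params: composite.TransformParams | None = None,
    optimize_radii: bool = False,
    k: int = 5,
):
    """Run the whole synthetic study under one seed.

    Returns a dict with the generated truth, the per-zone biomass-burning
    composites, the fossil biomass reconstruction, the assembled panel
    per climate model, and the attribution tables.

    ``optimize_radii`` switches on the per-genus source-radius sweep
    (otherwise the generator's true radii are used for calibration,
    which is the faster default for a full pipeline run); ``k`` is the
    analogue count used when the sweep is on.
    """
    params = params or composite.TransformParams()
    rng = np.random.default_rng([int(cfg.seed), 100])

    records, char_truth = synth.gen_charcoal_records(cfg)
    modern, grid, cal_truth = synth.gen_modern_calibration(cfg)
    fossil, fossil_truth = synth.gen_fossil_pollen(cfg, charcoal_records=records)
    fields, population, grid_truth = synth.gen_driver_grids(cfg)

    # 1. regional biomass-burning composites
    composites = {}
    for zone in ZONES:
        zone_records = [r for r in records if r.meta.zone == zone]
        composites[zone] = composite.composite_bootstrap(zone_records, params, rng=rng)

    # 2. pollen -> biomass transfer functions and fossil reconstruction
    if optimize_radii:
        radii = {}
        radius_tables = {}
        for genus in GENERA:
            best, table = mat.optimize_radius(grid, modern, mat.DEFAULT_RADII_KM, genus, k=k)
            radii[genus] = best
            radius_tables[genus] = table
    else:
        radii = dict(cfg.true_source_radius_km)
        radius_tables = None
    calibration = mat.build_calibration(grid, modern, radii)
    tfs = mat.fit_transfer_functions(calibration, rng=rng)
    reconstruction = mat.reconstruct_biomass(tfs, fossil, records)

    # 3. driver series per zone
    sites_by_zone = {z: [r.meta for r in records if r.meta.zone == z] for z in ZONES}
    driver_table = drivers.zone_driver_table(fields, population, sites_by_zone)

    # 4. panel assembly and attribution, once per climate model
    results = {}
    panels = {}
    for model in ("hadcm3like", "ccsm3like"):
        series_by_region = {}
        for zone in ZONES:
            comp = composites[zone]
            mapping = {"biomass_burning": millennial_from_composite(comp, cfg.n_millennia)}

            rec = reconstruction[reconstruction["zone"] == zone]
            genus_mill = pd.DataFrame(
                {
                    g: attribution.downsample_millennial(rec["age"], rec[g], cfg.n_millennia)
                    for g in GENERA
                }
            )
            mapping["tree_biomass"] = genus_mill.sum(axis=1)
            ratio = mat.conifer_broadleaf_ratio(genus_mill)
            mapping["conifer_broadleaf_ratio"] = ratio["ratio"]

            zt = driver_table[driver_table["zone"] == zone]
            pop = zt[zt["variable"] == "pop_density"].set_index("millennium")["value"]
            mapping["pop_density"] = pop
            for name, (variable, season) in {
                "T_spring": ("temperature", "MAM"), "T_summer": ("temperature", "JJA"),
                "P_spring": ("precipitation", "MAM"), "P_summer": ("precipitation", "JJA"),
            }.items():
                sel = zt[(zt["variable"] == variable) & (zt["season"] == season) & (zt["model"] == model)]
                mapping[name] = sel.set_index("millennium")["value"]
            series_by_region[zone] = mapping
        panel = attribution.assemble_panel(series_by_region)
        panels[model] = panel
        results[model] = attribution.run_attribution(panel, model=model)

    return {
        "records": records,
        "composites": composites,
        "calibration": calibration,
        "transfer_functions": tfs,
        "radius_tables": radius_tables,
        "reconstruction": reconstruction,
        "driver_table": driver_table,
        "panels": panels,
        "attribution": results,
        "truth": {"charcoal": char_truth, "calibration": cal_truth,
                  "fossil": fossil_truth, "grids": grid_truth},
    }


def composite_to_frame(series) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_age": series.bin_age,
            "mean": series.mean,
            "ci_low": series.ci_low,
            "ci_high": series.ci_high,
            "n_records": series.n_records,
            "n_boot": series.n_boot,
            "bandwidth": series.bandwidth,
        }
    )
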