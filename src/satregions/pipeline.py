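"""Seeded end-to-end pipeline: simulate -> regionalize -> aggregate ->
crossval -> compare -> agegap, with every artifact written under one
output directory and stamped in a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import agegap as ag
from . import compare as cmp
from .aggregate import quintile_split, region_estimates, weighted_mean
from .crossval import optimal_scale, sweep_scales
from .io import (
    FLOAT_FORMAT,
    PipelineConfig,
    read_individuals,
    read_tracts,
    write_individuals,
    write_region_assignment,
    write_region_hulls,
    write_tracts,
    write_tracts_geojson,
)
from .regionalize import regionalize
from .synthetic import simulate

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "regionalize", "aggregate", "crossval", "compare", "agegap")


def config_hash(config: PipelineConfig) -> str:
    payload = asdict(config)
    payload["sim"]["covariate_effects"] = dict(payload["sim"]["covariate_effects"])
    payload["sim"]["age_profile"] = list(payload["sim"]["age_profile"])
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, outdir: Optional[str] = None) -> Dict[str, object]:
    """Execute the requested stages, writing artifacts and a manifest.

    Stages run in canonical order; later stages reuse in-memory results
    from earlier ones or load the corresponding artifacts from a prior
    run in the same directory.  Returns the in-memory results keyed by
    stage name.
    """
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    requested = [s for s in STAGE_ORDER if s in config.stages]
    unknown = set(config.stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown pipeline stage(s): {sorted(unknown)}")

    results: Dict[str, object] = {}
    manifest = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    tracts = individuals = partition = estimates = None

    def need_tracts():
        nonlocal tracts, individuals
        if tracts is None:
            tracts = read_tracts(out / "tracts.csv")
            individuals = read_individuals(out / "individuals.csv")
        return tracts, individuals

    for stage in requested:
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                tracts, individuals = simulate(config.sim)
                write_tracts(tracts, out / "tracts.csv")
                write_tracts_geojson(tracts, out / "tracts.geojson")
                write_individuals(individuals, out / "individuals.csv")
                records = {"tracts": len(tracts), "individuals": len(individuals)}
                results[stage] = (tracts, individuals)
            elif stage == "regionalize":
                t, _ = need_tracts()
                partition = regionalize(
                    t, config.threshold_n, config.cell_size, axis_rule=config.axis_rule
                )
                write_region_assignment(partition, out / "regions.csv", seed=config.seed)
                write_region_hulls(partition, t, out / "region_hulls.geojson")
                records = {"regions": partition.n_regions}
                results[stage] = partition
            elif stage == "aggregate":
                t, ind = need_tracts()
                if partition is None:
                    partition = regionalize(
                        t, config.threshold_n, config.cell_size, axis_rule=config.axis_rule
                    )
                estimates = region_estimates(partition, ind, t)
                estimates.to_csv(out / "region_estimates.csv", float_format=FLOAT_FORMAT)
                records = {"regions": len(estimates)}
                results[stage] = estimates
            elif stage == "crossval":
                t, _ = need_tracts()
                curve = sweep_scales(
                    t,
                    config.thresholds,
                    n_draws=config.n_draws,
                    n_offsets=config.n_offsets,
                    cell_size=config.cell_size,
                    seed=config.seed,
                    axis_rule=config.axis_rule,
                )
                curve.to_csv(out / "cv_curve.csv", index=False, float_format=FLOAT_FORMAT)
                records = {
                    "thresholds": len(curve),
                    "optimal_threshold": optimal_scale(curve),
                }
                results[stage] = curve
            elif stage == "compare":
                if estimates is None:
                    t, ind = need_tracts()
                    if partition is None:
                        partition = regionalize(
                            t, config.threshold_n, config.cell_size,
                            axis_rule=config.axis_rule,
                        )
                    estimates = region_estimates(partition, ind, t)
                tables = {
                    "compare_quintiles": cmp.comparison_table(estimates, "quintile"),
                    "compare_urban_rural": cmp.comparison_table(estimates, "urban"),
                    "compare_quintiles_urban": cmp.comparison_table(
                        estimates, "quintile", subset="urban"
                    ),
                    "compare_quintiles_rural": cmp.comparison_table(
                        estimates, "quintile", subset="rural"
                    ),
                }
                for name, table in tables.items():
                    table.to_csv(out / f"{name}.csv", float_format=FLOAT_FORMAT)
                records = {name: len(tbl) for name, tbl in tables.items()}
                results[stage] = tables
            elif stage == "agegap":
                t, ind = need_tracts()
                urban_series = ind["urban"] if "urban" in ind.columns else ind[
                    "tract_id"
                ].map(t.set_index("tract_id")["urban"])
                urban_mask = urban_series.to_numpy(dtype=bool)
                mix_u = ag.group_age_mix(ind, urban_mask)
                mix_r = ag.group_age_mix(ind, ~urban_mask)
                profile = ag.age_profile_from_individuals(ind)
                simulated = ag.counterfactual_gap(mix_u, mix_r, profile)
                w = ind["weight"].to_numpy()
                ls = ind["ls"].to_numpy(dtype=float)
                observed = weighted_mean(ls[~urban_mask], w[~urban_mask]) - weighted_mean(
                    ls[urban_mask], w[urban_mask]
                )
                payload = {
                    "mix_urban": mix_u.tolist(),
                    "mix_rural": mix_r.tolist(),
                    "age_profile": profile.tolist(),
                    "simulated_gap": simulated,
                    "observed_gap": observed,
                    "gap_share": ag.gap_share(simulated, observed),
                }
                (out / "agegap.json").write_text(json.dumps(payload, indent=2))
                records = {"bins": len(profile)}
                results[stage] = payload
            else:  # pragma: no cover
                raise AssertionError(stage)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
        elapsed = time.perf_counter() - t0
        manifest["stages"][stage] = {"seconds": round(elapsed, 3), "records": records}
        logger.info("stage %-11s %6.2fs %s", stage, elapsed, records)

    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
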