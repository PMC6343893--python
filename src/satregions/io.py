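"""Reading and writing the pipeline's interchange formats.

Tabular artifacts are headered CSV with 12 significant digits; tract
centroids and region hulls can additionally be exported as GeoJSON
(abstract planar coordinates, no CRS).  Pipeline configuration is YAML.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import ConvexHull, QhullError

from .config import SimConfig
from .regionalize import Partition

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"

TRACT_REQUIRED = ["tract_id", "x", "y", "stratum_id", "urban", "n_k", "w_k"]
INDIVIDUAL_REQUIRED = ["tract_id", "weight", "ls", "age_bin"]


class SchemaError(ValueError):
    """A file does not carry the documented columns."""


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file is missing required column(s): {missing}")


def _check_numeric(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad) > 0:
            raise ValueError(
                f"{what}: non-numeric value in column '{col}' at row {bad[0] + 2} "
                "(1-based, counting the header)"
            )
        df[col] = coerced


def write_tracts(tracts: pd.DataFrame, path) -> None:
    tracts.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_tracts(path) -> pd.DataFrame:
    """Read a tract table (CSV, or GeoJSON points by file suffix)."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        return read_tracts_geojson(path)
    df = pd.read_csv(path)
    _check_columns(df, TRACT_REQUIRED, "tract")
    if len(df) == 0:
        warnings.warn(f"{path}: tract file is empty")
        return df
    _check_numeric(df, ["x", "y", "n_k", "w_k"], str(path))
    df["urban"] = df["urban"].astype(bool)
    df["n_k"] = df["n_k"].astype(int)
    return df


def write_tracts_geojson(tracts: pd.DataFrame, path) -> None:
    """Tract centroids as GeoJSON Point features (tract_id in properties)."""
    features = []
    prop_cols = [c for c in tracts.columns if c not in ("x", "y")]
    for _, row in tracts.iterrows():
        props = {}
        for c in prop_cols:
            v = row[c]
            props[c] = v.item() if isinstance(v, np.generic) else (
                None if (isinstance(v, float) and np.isnan(v)) else v
            )
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(row["x"]), float(row["y"])]},
                "properties": props,
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_tracts_geojson(path) -> pd.DataFrame:
    data = json.loads(Path(path).read_text())
    rows = []
    for feat in data.get("features", []):
        props = dict(feat.get("properties", {}))
        coords = feat["geometry"]["coordinates"]
        props["x"], props["y"] = float(coords[0]), float(coords[1])
        rows.append(props)
    df = pd.DataFrame(rows)
    if len(df) == 0:
        warnings.warn(f"{path}: empty GeoJSON tract collection")
        return df
    _check_columns(df, TRACT_REQUIRED, "tract GeoJSON")
    return df


def write_individuals(individuals: pd.DataFrame, path) -> None:
    individuals.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_individuals(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, INDIVIDUAL_REQUIRED, "individual")
    if len(df) == 0:
        warnings.warn(f"{path}: individual file is empty")
        return df
    _check_numeric(df, ["weight", "ls", "age_bin"], str(path))
    df["age_bin"] = df["age_bin"].astype(int)
    return df


def write_region_assignment(partition: Partition, path, seed: Optional[int] = None) -> None:
    """Tract-to-region assignment with the partition's provenance columns."""
    df = partition.labels.rename("region_id").rename_axis("tract_id").reset_index()
    df["threshold_n"] = partition.threshold_n
    df["offset_x"], df["offset_y"] = partition.grid_offset
    df["seed"] = seed if seed is not None else ""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_region_assignment(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ["tract_id", "region_id"], "region assignment")
    return df


def write_region_hulls(partition: Partition, tracts: pd.DataFrame, path) -> None:
    """Convex hulls of each region's tract centroids, for inspection."""
    pos = tracts.set_index("tract_id")[["x", "y"]]
    features = []
    for region in partition.regions:
        pts = pos.loc[region.tract_ids].to_numpy(dtype=float)
        pts = np.unique(pts, axis=0)
        if len(pts) >= 3:
            try:
                hull = ConvexHull(pts)
                ring = pts[hull.vertices].tolist()
                ring.append(ring[0])
                geometry = {"type": "Polygon", "coordinates": [ring]}
            except QhullError:  # collinear members
                geometry = {"type": "MultiPoint", "coordinates": pts.tolist()}
        else:
            geometry = {"type": "MultiPoint", "coordinates": pts.tolist()}
        features.append(
            {
                "type": "Feature",
                "geometry": geometry,
                "properties": {"region_id": region.region_id, "count": region.count},
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters (see the module docstrings)."""

    sim: SimConfig = field(default_factory=SimConfig)
    threshold_n: int = 400
    thresholds: Tuple[int, ...] = (50, 100, 200, 400, 800, 1600, 3200, 6400)
    n_draws: int = 5
    n_offsets: int = 4
    cell_size: Optional[float] = None
    axis_rule: str = "halve-longer"
    seed: int = 0
    outdir: str = "satregions_out"
    stages: Tuple[str, ...] = (
        "simulate", "regionalize", "aggregate", "crossval", "compare", "agegap",
    )

    def __post_init__(self) -> None:
        self.sim = self.sim.replace(seed=self.seed)


def load_config(path, **overrides) -> PipelineConfig:
    """Load a YAML pipeline config; keyword overrides win over the file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    if "seed" not in raw:
        raise SchemaError("pipeline config must provide a seed")
    sim_kwargs = raw.pop("sim", {})
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    if "thresholds" in raw:
        raw["thresholds"] = tuple(int(t) for t in raw["thresholds"])
    sim = SimConfig(**{**sim_kwargs, "seed": raw["seed"]})
    return PipelineConfig(sim=sim, **raw)
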