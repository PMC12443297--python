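"""Delimited-text and GeoJSON input/output, plus the end-to-end pipeline.

Fixed column schemas (UTF-8 CSV with a header row):

* provider table: ``site_id, provider_id, classification, capacity, x, y, period``
* area table: ``area_id, x, y, population, commuters_car, commuters_transit,
  commuters_walk, rural_urban_class, deprivation_quartile``
* travel-time matrix: first column ``area_id``, remaining headers are site
  IDs, cells are minutes with ``inf`` marking unreachable pairs
* access surface: ``area_id, mode, classification, period, access_per_100k``
* disparity report: ``classification, metric, stratum_variable, stratum, n,
  median, diff_vs_ref, p_value, test``

Area and site identifiers are always read as strings so FIPS-style leading
zeros survive a round trip.  A thin ``column_aliases`` mapping lets files
with real-world headers be consumed without renaming on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import composite as composite_mod
from . import stats as stats_mod
from .errors import ConfigurationError, SchemaError
from .fca import e2sfca
from .region import RegionConfig, SyntheticRegion, generate_region
from .types import MODES, AccessSurface, AreaUnit, DecaySchedule, ProviderSite, TravelTimeMatrix

__all__ = [
    "read_provider_table", "write_provider_table",
    "read_area_table", "write_area_table",
    "read_matrix", "write_matrix",
    "read_surface", "write_surface",
    "write_report", "read_report",
    "export_geojson", "read_geojson_polygons", "region_polygons",
    "RunConfig", "run_pipeline",
]

logger = logging.getLogger(__name__)

PROVIDER_COLUMNS = ("site_id", "provider_id", "classification", "capacity", "x", "y", "period")
AREA_COLUMNS = ("area_id", "x", "y", "population", "commuters_car", "commuters_transit",
                "commuters_walk", "rural_urban_class", "deprivation_quartile")
COMMUTER_COLUMNS = ("commuters_car", "commuters_transit", "commuters_walk")


@dataclass
class TableReadResult:
    """Parsed records plus the count of rows dropped for bad coordinates."""

    records: list
    n_dropped: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _load_frame(path: str | Path, required: Sequence[str],
                column_aliases: Mapping[str, str] | None = None) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str)
    if column_aliases:
        frame = frame.rename(columns=dict(column_aliases))
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return frame


def _numeric_rows(frame: pd.DataFrame, cols: Sequence[str]) -> tuple[pd.DataFrame, int]:
    """Coerce coordinate columns, dropping and counting unparseable rows."""
    converted = frame.copy()
    for c in cols:
        converted[c] = pd.to_numeric(converted[c], errors="coerce")
    good = converted[list(cols)].notna().all(axis=1)
    n_dropped = int((~good).sum())
    if n_dropped:
        logger.warning("dropped %d row(s) with unparseable coordinates", n_dropped)
    return converted[good], n_dropped


def read_provider_table(path: str | Path,
                        column_aliases: Mapping[str, str] | None = None) -> TableReadResult:
    """Provider sites from CSV; bad-coordinate rows dropped and counted."""
    frame = _load_frame(path, [c for c in PROVIDER_COLUMNS if c != "capacity"], column_aliases)
    if "capacity" not in frame.columns:
        frame["capacity"] = "1"
    frame, n_dropped = _numeric_rows(frame, ("x", "y", "capacity"))
    sites = [
        ProviderSite(site_id=str(r.site_id), provider_id=str(r.provider_id),
                     classification=str(r.classification), capacity=float(r.capacity),
                     x=float(r.x), y=float(r.y), period=str(r.period))
        for r in frame.itertuples()
    ]
    return TableReadResult(sites, n_dropped)


def write_provider_table(sites: Sequence[ProviderSite], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in sites], columns=PROVIDER_COLUMNS) \
        .to_csv(path, index=False)


def read_area_table(path: str | Path,
                    column_aliases: Mapping[str, str] | None = None,
                    require_commuters: bool = True) -> TableReadResult:
    """Area units from CSV; FIPS-style IDs keep their leading zeros.

    Negative populations are a :class:`SchemaError`; absent commuter columns
    are an error unless ``require_commuters=False`` (composites cannot be
    computed without them).
    """
    base = ["area_id", "x", "y", "population"]
    frame = _load_frame(path, base, column_aliases)
    missing_commuters = [c for c in COMMUTER_COLUMNS if c not in frame.columns]
    if missing_commuters and require_commuters:
        raise SchemaError(
            f"{path}: missing commuter column(s) {missing_commuters}; "
            "the commuting-share composite cannot be computed without them"
        )
    for c in COMMUTER_COLUMNS:
        if c not in frame.columns:
            frame[c] = "0"
    for c in ("rural_urban_class", "deprivation_quartile"):
        if c not in frame.columns:
            frame[c] = ""
    frame, n_dropped = _numeric_rows(frame, ("x", "y"))
    pops = pd.to_numeric(frame["population"], errors="raise")
    if (pops < 0).any():
        bad = frame.loc[pops < 0, "area_id"].tolist()
        raise SchemaError(f"{path}: negative population for area(s) {bad}")
    areas = [
        AreaUnit(
            area_id=str(r.area_id), x=float(r.x), y=float(r.y),
            population=float(r.population),
            commuters_car=float(r.commuters_car),
            commuters_transit=float(r.commuters_transit),
            commuters_walk=float(r.commuters_walk),
            rural_urban_class=str(r.rural_urban_class),
            deprivation_quartile=str(r.deprivation_quartile),
        )
        for r in frame.itertuples()
    ]
    return TableReadResult(areas, n_dropped)


def write_area_table(areas: Sequence[AreaUnit], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(a) for a in areas], columns=AREA_COLUMNS) \
        .to_csv(path, index=False)


def read_matrix(path: str | Path, mode: str) -> TravelTimeMatrix:
    """Travel-time matrix CSV: area_id column, site-ID headers, ``inf`` tokens."""
    frame = pd.read_csv(path, dtype=str)
    first = frame.columns[0]
    frame = frame.set_index(first)
    values = frame.apply(lambda col: pd.to_numeric(col, errors="coerce")).to_numpy(dtype=float)
    if np.isnan(values).any():
        raise SchemaError(f"{path}: non-numeric travel-time cell (use 'inf' for unreachable)")
    return TravelTimeMatrix(mode, [str(i) for i in frame.index],
                            [str(c) for c in frame.columns], values)


def write_matrix(matrix: TravelTimeMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, index=True, na_rep="inf")


def write_surface(surface: AccessSurface, path: str | Path) -> None:
    surface.to_frame().to_csv(path, index=False)


def read_surface(path: str | Path) -> AccessSurface:
    frame = pd.read_csv(path, dtype={"area_id": str})
    needed = ("area_id", "mode", "classification", "period", "access_per_100k")
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing surface column(s) {missing}")
    meta = frame[["mode", "classification", "period"]].drop_duplicates()
    if len(meta) != 1:
        raise SchemaError(f"{path}: a surface file must hold one mode/classification/period")
    mode, classification, period = (str(meta.iloc[0][c]) if pd.notna(meta.iloc[0][c]) else ""
                                    for c in ("mode", "classification", "period"))
    values = pd.Series(frame["access_per_100k"].to_numpy(dtype=float),
                       index=frame["area_id"].astype(str))
    return AccessSurface(mode, classification, period, values)


def write_report(report: Sequence[stats_mod.StratifiedComparison], path: str | Path) -> None:
    pd.concat([block.to_frame() for block in report], ignore_index=True).to_csv(path, index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# GeoJSON

def region_polygons(region: SyntheticRegion) -> dict[str, dict]:
    """Voronoi-like cells around area centroids as GeoJSON geometry dicts."""
    from shapely import geometry as geom
    from shapely.ops import voronoi_diagram

    if not region.areas:
        return {}
    pts = geom.MultiPoint([(a.x, a.y) for a in region.areas])
    pad = 0.05 * region.config.region_radius_min + 1.0
    envelope = geom.box(*(geom.MultiPoint(pts.geoms).buffer(pad).bounds))
    cells = voronoi_diagram(pts, envelope=envelope)
    out: dict[str, dict] = {}
    remaining = list(cells.geoms)
    for a in region.areas:
        p = geom.Point(a.x, a.y)
        for i, cell in enumerate(remaining):
            if cell.covers(p):
                out[a.area_id] = geom.mapping(cell.intersection(envelope))
                remaining.pop(i)
                break
    return out


def export_geojson(surface: AccessSurface, polygons: Mapping[str, dict]) -> tuple[dict, int]:
    """FeatureCollection of area polygons carrying the access value.

    ``polygons`` maps area_id to a GeoJSON geometry dict (or a shapely
    geometry).  Areas without a polygon are skipped and counted; the skip
    count is the second return value.
    """
    try:
        from shapely.geometry import mapping as shp_mapping
        from shapely.geometry.base import BaseGeometry
    except ImportError:  # pragma: no cover
        BaseGeometry = ()  # type: ignore[assignment]
        shp_mapping = None
    features = []
    skipped = 0
    for area_id, value in surface.values.items():
        g = polygons.get(area_id)
        if g is None:
            skipped += 1
            continue
        if BaseGeometry and isinstance(g, BaseGeometry):
            g = shp_mapping(g)
        if not isinstance(g, dict) or "type" not in g:
            raise SchemaError(f"polygon for area {area_id!r} is not a GeoJSON geometry")
        features.append({
            "type": "Feature",
            "geometry": g,
            "properties": {
                "area_id": area_id,
                "access_per_100k": float(value),
                "mode": surface.mode,
                "classification": surface.classification,
                "period": surface.period,
            },
        })
    if skipped:
        logger.warning("export_geojson: %d area(s) lacked polygons and were skipped", skipped)
    return {"type": "FeatureCollection", "features": features}, skipped


def read_geojson_polygons(path: str | Path) -> dict[str, dict]:
    """Geometry dicts keyed by the ``area_id`` feature property."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection" or "features" not in doc:
        raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")
    out = {}
    for feat in doc["features"]:
        props = feat.get("properties") or {}
        if "area_id" in props and feat.get("geometry"):
            out[str(props["area_id"])] = feat["geometry"]
    return out


# ---------------------------------------------------------------------------
# Pipeline

@dataclass
class RunConfig:
    """End-to-end run settings: inputs (or a simulation), schedule, outputs.

    Exactly one of ``simulate`` or (``provider_path``, ``area_path``,
    ``matrix_paths``) feeds the pipeline.
    """

    out_dir: str | Path = "outputs"
    seed: int = 0
    simulate: RegionConfig | None = None
    provider_path: str | Path | None = None
    area_path: str | Path | None = None
    matrix_paths: Mapping[str, str | Path] = field(default_factory=dict)
    polygons_path: str | Path | None = None
    classifications: tuple[str, ...] | None = None  # None: all present
    periods: tuple[str, ...] | None = None
    zone_bounds: tuple[float, ...] = (10.0, 20.0, 30.0)
    zone_weights: tuple[float, ...] = (1.00, 0.68, 0.22)
    zero_excess_threshold: float = 0.25

    def schedule(self) -> DecaySchedule:
        return DecaySchedule(self.zone_bounds, self.zone_weights)

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("provider_path", "area_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ConfigurationError(f"{name} missing or nonexistent: {p}")
            for mode, p in self.matrix_paths.items():
                if not Path(p).exists():
                    raise ConfigurationError(f"matrix_paths[{mode!r}] nonexistent: {p}")
        self.schedule()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """simulate/load -> per-mode access -> composite -> compare -> export.

    Writes surfaces, composites, the disparity report, a GeoJSON map when
    polygons are available, and a ``manifest.json`` recording input hashes,
    outputs and every exclusion count.  Deterministic given the seed.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    schedule = config.schedule()
    manifest: dict = {"seed": config.seed, "inputs": {}, "outputs": [], "counts": {}}

    polygons: dict[str, dict] = {}
    if config.simulate is not None:
        region_cfg = dataclasses.replace(config.simulate, seed=config.seed)
        region = generate_region(region_cfg)
        areas = region.areas
        sites = [s for p in region.periods for s in region.providers[p]]
        matrices = region.matrices
        write_area_table(areas, out_dir / "areas.csv")
        write_provider_table(sites, out_dir / "providers.csv")
        for mode, m in matrices.items():
            write_matrix(m, out_dir / f"matrix_{mode}.csv")
        manifest["outputs"] += ["areas.csv", "providers.csv"] + [
            f"matrix_{mode}.csv" for mode in matrices
        ]
        polygons = region_polygons(region)
    else:
        area_result = read_area_table(config.area_path)
        provider_result = read_provider_table(config.provider_path)
        areas = area_result.records
        sites = provider_result.records
        manifest["counts"]["dropped_area_rows"] = area_result.n_dropped
        manifest["counts"]["dropped_provider_rows"] = provider_result.n_dropped
        matrices = {mode: read_matrix(p, mode) for mode, p in config.matrix_paths.items()}
        for name in ("provider_path", "area_path"):
            manifest["inputs"][name] = _sha256(Path(getattr(config, name)))
        for mode, p in config.matrix_paths.items():
            manifest["inputs"][f"matrix_{mode}"] = _sha256(Path(p))
        if config.polygons_path:
            polygons = read_geojson_polygons(config.polygons_path)
            manifest["inputs"]["polygons"] = _sha256(Path(config.polygons_path))

    classifications = config.classifications or tuple(sorted({s.classification for s in sites}))
    periods = config.periods or tuple(dict.fromkeys(s.period for s in sites))
    if not set(matrices) >= set(MODES):
        missing = sorted(set(MODES) - set(matrices))
        raise ConfigurationError(
            f"pipeline stage 'composite' needs matrices for all of {MODES}; missing {missing}"
        )

    shares_table = composite_mod.mode_share_table(areas)
    shares_table.to_csv(out_dir / "mode_shares.csv", index=False)
    manifest["outputs"].append("mode_shares.csv")
    manifest["counts"]["fallback_car_only_areas"] = int(shares_table["fallback_car_only"].sum())

    report_blocks: list[stats_mod.StratifiedComparison] = []
    for classification in classifications:
        by_period: dict[str, AccessSurface] = {}
        for period in periods:
            per_mode = {}
            for mode in MODES:
                surf = e2sfca(sites, areas, matrices[mode], schedule,
                              classification=classification, period=period)
                per_mode[mode] = surf
                name = f"access_{classification}_{period}_{mode}.csv"
                write_surface(surf, out_dir / name)
                manifest["outputs"].append(name)
            comp = composite_mod.composite_surface(
                per_mode["car"], per_mode["transit"], per_mode["walk"], areas)
            name = f"access_{classification}_{period}_composite.csv"
            write_surface(comp, out_dir / name)
            manifest["outputs"].append(name)
            by_period[period] = comp
            if polygons:
                doc, skipped = export_geojson(comp, polygons)
                map_name = f"map_{classification}_{period}_composite.geojson"
                with open(out_dir / map_name, "w", encoding="utf-8") as fh:
                    json.dump(doc, fh)
                manifest["outputs"].append(map_name)
                manifest["counts"][f"map_skipped_{classification}_{period}"] = skipped
        has_strata = any(a.rural_urban_class for a in areas)
        if has_strata:
            cfg = stats_mod.ReportConfig(zero_excess_threshold=config.zero_excess_threshold)
            report_blocks += stats_mod.disparity_report(by_period, areas, cfg)
            if len(by_period) >= 2:
                first, last = list(by_period)[0], list(by_period)[-1]
                change = stats_mod.percent_change(by_period[first], by_period[last])
                manifest["counts"][f"undefined_pct_change_{classification}"] = change.n_undefined

    if report_blocks:
        write_report(report_blocks, out_dir / "disparity_report.csv")
        manifest["outputs"].append("disparity_report.csv")

    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out_dir
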