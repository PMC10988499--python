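"""Readers and writers for the package's plain-text interchange formats.

Formats
-------
* Capillary coordinates: CSV with header ``x_um,y_um``.
* Fibre outlines: GeoJSON FeatureCollection of Polygons, optional
  property ``fiber_type``.
* Tension / flow traces: CSV with header ``time_s,value``.
* Metabolite matrix: CSV; first column sample id, second column group
  label, remaining columns one per compound.
* Tessellations: GeoJSON FeatureCollection with properties
  ``area_um2``, ``boundary_flag``, ``source_index``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from .datatypes import (
    CapillaryMap,
    DomainTessellation,
    FlowTrace,
    MetaboliteMatrix,
    SupplyIndices,
    TensionTrace,
    ValidationError,
)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# capillary maps
# ---------------------------------------------------------------------------

def read_capillary_map(
    path: PathLike,
    frame: tuple[float, float],
    fibres_path: Optional[PathLike] = None,
    region_label: str = "whole",
    animal_id: str = "",
    group_label: str = "",
) -> CapillaryMap:
    """Read a capillary coordinate table (and optional fibre GeoJSON).

    Coordinates are taken verbatim (no rescaling). A point outside the
    frame or a duplicated point raises :class:`ValidationError` naming
    the offending row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("x_um", "y_um"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    pts = df[["x_um", "y_um"]].to_numpy(dtype=float)
    fibres = fibre_types = None
    if fibres_path is not None:
        fibres, fibre_types = read_fibre_geojson(fibres_path)
    return CapillaryMap(
        frame_width=float(frame[0]),
        frame_height=float(frame[1]),
        capillaries=pts,
        fibres=fibres,
        fibre_types=fibre_types,
        region_label=region_label,
        animal_id=animal_id,
        group_label=group_label,
    )


def write_capillary_map(cmap: CapillaryMap, path: PathLike) -> None:
    df = pd.DataFrame(cmap.capillaries, columns=["x_um", "y_um"])
    df.to_csv(path, index=False)


def read_fibre_geojson(path: PathLike) -> tuple[list[Polygon], list[Optional[str]]]:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: expected a GeoJSON FeatureCollection")
    polys: list[Polygon] = []
    types: list[Optional[str]] = []
    for feat in gj.get("features", []):
        geom = shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise ValidationError(f"{path}: fibre geometry must be a Polygon")
        polys.append(geom)
        types.append((feat.get("properties") or {}).get("fiber_type"))
    return polys, types


def write_fibre_geojson(
    fibres: Sequence[Polygon],
    path: PathLike,
    fibre_types: Optional[Sequence[Optional[str]]] = None,
) -> None:
    feats = []
    for k, poly in enumerate(fibres):
        props = {}
        if fibre_types is not None and fibre_types[k] is not None:
            props["fiber_type"] = fibre_types[k]
        feats.append(
            {"type": "Feature", "geometry": mapping(poly), "properties": props}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def read_tension_trace(
    path: PathLike, stimulation_window: tuple[float, float]
) -> TensionTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_trace_columns(df, path)
    return TensionTrace(
        time=df["time_s"].to_numpy(float),
        tension=df["value"].to_numpy(float),
        stimulation_window=stimulation_window,
    )


def write_tension_trace(trace: TensionTrace, path: PathLike) -> None:
    pd.DataFrame({"time_s": trace.time, "value": trace.tension}).to_csv(
        path, index=False
    )


def read_flow_trace(
    path: PathLike,
    stimulation_window: tuple[float, float],
    pressure_path: Optional[PathLike] = None,
) -> FlowTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_trace_columns(df, path)
    pressure = None
    if pressure_path is not None:
        dp = pd.read_csv(pressure_path, float_precision="round_trip")
        _require_trace_columns(dp, pressure_path)
        pressure = dp["value"].to_numpy(float)
    return FlowTrace(
        time=df["time_s"].to_numpy(float),
        flow=df["value"].to_numpy(float),
        stimulation_window=stimulation_window,
        pressure=pressure,
    )


def write_flow_trace(trace: FlowTrace, path: PathLike) -> None:
    pd.DataFrame({"time_s": trace.time, "value": trace.flow}).to_csv(
        path, index=False
    )


def _require_trace_columns(df: pd.DataFrame, path: PathLike) -> None:
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")


# ---------------------------------------------------------------------------
# metabolite matrices
# ---------------------------------------------------------------------------

def read_metabolite_matrix(path: PathLike) -> MetaboliteMatrix:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 3:
        raise ValidationError(
            f"{path}: need sample id, group and at least one compound column"
        )
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    groups = df.iloc[:, 1].astype(str).tolist()
    compounds = list(df.columns[2:])
    return MetaboliteMatrix(
        intensities=df.iloc[:, 2:].to_numpy(float),
        sample_groups=groups,
        compound_ids=compounds,
        sample_ids=sample_ids,
    )


def write_metabolite_matrix(matrix: MetaboliteMatrix, path: PathLike) -> None:
    ids = matrix.sample_ids or [f"S{i}" for i in range(matrix.n_samples)]
    df = pd.DataFrame(matrix.intensities, columns=matrix.compound_ids)
    df.insert(0, "group", matrix.sample_groups)
    df.insert(0, "sample_id", ids)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["region", "CF", "CD_per_mm2", "CSA_um2", "CDA_um2", "logSD"]


def write_results_table(records: Sequence[SupplyIndices], path: PathLike) -> None:
    """Write supply indices with a stable column order and full precision."""
    if len(records) == 0:
        raise ValidationError("refusing to write an empty results table")
    rows = [
        {
            "region": r.region_label,
            "CF": r.CF,
            "CD_per_mm2": r.CD,
            "CSA_um2": r.CSA,
            "CDA_um2": r.CDA_mean,
            "logSD": r.logSD,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(
        path, index=False
    )


def write_tessellation_geojson(tess: DomainTessellation, path: PathLike) -> None:
    feats = []
    for k, poly in enumerate(tess.domains):
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(poly),
                "properties": {
                    "area_um2": float(tess.areas[k]),
                    "boundary_flag": bool(tess.boundary_flags[k]),
                    "source_index": int(tess.source_index[k]),
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
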