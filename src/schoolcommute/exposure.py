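"""Per-participant exposure measures.

Five predictors drive the analysis: three school-catchment ("buffer")
measures — residents per hectare, street intersections per hectare, and a
normalised-entropy mixed-use diversity index (z-scored across schools) — and
two home–school route measures: network distance (km) and pedestrian route
directness (PRD = network distance / straight-line distance).
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping as geom_mapping, shape
from shapely.strtree import STRtree

from .coding import dichotomize_acs
from .network import (
    StreetNetwork,
    Snap,
    UnroutableError,
    _dijkstra_from_snap,
    count_intersections,
    euclidean_distance,
    network_buffer,
    snap_to_network,
)

__all__ = [
    "LAND_USE_CLASSES",
    "Parcel",
    "BufferMeasures",
    "prd",
    "resident_density",
    "intersection_density",
    "mixed_use_index",
    "z_scores",
    "compute_buffer_measures",
    "build_exposure_table",
    "parcels_to_geojson",
    "parcels_from_geojson",
    "attach_residents",
]

LAND_USE_CLASSES = (
    "residential",
    "industrial",
    "retail",
    "office",
    "public_service",
    "recreational",
)

#: network-buffer thresholds (m) per age group — the distance a child or an
#: adolescent is typically willing to walk to school.
DEFAULT_THRESHOLDS_M = {"child": 1250.0, "adolescent": 1350.0}


@dataclass
class Parcel:
    parcel_id: str
    polygon: shapely.Geometry
    use_class: str
    floor_area_m2: float
    residents: float = 0.0

    def __post_init__(self) -> None:
        if self.use_class not in LAND_USE_CLASSES:
            raise ValueError(f"unknown use class {self.use_class!r}")


@dataclass
class BufferMeasures:
    school_id: str
    threshold_m: float
    area_ha: float
    n_intersections: int
    residents: float
    residents_density: float
    intersection_density: float
    mixed_use_raw: float
    mixed_use_z: float = math.nan


# ---------------------------------------------------------------------------
# scalar measures
# ---------------------------------------------------------------------------

def prd(network_dist_m: float, euclid_dist_m: float) -> float:
    """Pedestrian route directness: network / straight-line distance.

    1.0 is a perfectly direct route.  Values below 1 are geometrically
    impossible on consistent inputs and indicate address errors; they are
    returned but a data-quality warning is emitted.
    """
    if euclid_dist_m <= 0:
        raise ValueError("straight-line distance must be positive (home at school?)")
    r = network_dist_m / euclid_dist_m
    if r < 1.0 - 1e-9:
        warnings.warn(
            f"PRD {r:.3f} < 1: network distance shorter than straight line; "
            "check input coordinates", stacklevel=2)
    return r


def resident_density(residents: float, area_ha: float) -> float:
    """Residents per hectare of buffer footprint."""
    if area_ha <= 0:
        raise ValueError("area must be positive")
    if residents < 0:
        raise ValueError("residents must be non-negative")
    return residents / area_ha


def intersection_density(n_intersections: float, area_ha: float) -> float:
    """Street intersections (degree >= 3 nodes) per hectare."""
    if area_ha <= 0:
        raise ValueError("area must be positive")
    if n_intersections < 0:
        raise ValueError("count must be non-negative")
    return n_intersections / area_ha


def mixed_use_index(areas: Mapping[str, float], k: int | None = 6) -> float:
    """Normalised Shannon entropy of land-use floor-area shares.

    H = -sum(p_i ln p_i) / ln k over classes with positive share.  ``k`` is
    fixed at the six canonical classes by default, so a missing class lowers
    the index (evenness across the named uses); ``k=None`` normalises by the
    number of present classes instead, for sensitivity analysis.
    """
    vals = {c: float(a) for c, a in areas.items() if a > 0}
    unknown = set(vals) - set(LAND_USE_CLASSES)
    if unknown:
        raise ValueError(f"unknown use classes: {sorted(unknown)}")
    total = sum(vals.values())
    if total <= 0:
        raise ValueError("total floor area must be positive")
    kk = len(vals) if k is None else int(k)
    if kk <= 1:
        return 0.0
    h = -sum((a / total) * math.log(a / total) for a in vals.values())
    return h / math.log(kk)


def z_scores(values: Sequence[float]) -> np.ndarray:
    """(x - mean) / SD with the population (n-denominator) SD convention."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to standardise")
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero standard deviation; cannot standardise")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# buffer measures
# ---------------------------------------------------------------------------

def compute_buffer_measures(net: StreetNetwork, school_id: str,
                            school_xy: tuple[float, float],
                            threshold_m: float,
                            parcels: Sequence[Parcel],
                            margin_m: float = 25.0,
                            entropy_k: int | None = 6) -> BufferMeasures:
    """Catchment measures for one school at one threshold.

    Parcels partially inside the footprint contribute floor area and
    residents proportionally to their intersected area fraction (areal
    weighting).
    """
    sa = network_buffer(net, school_xy, threshold_m, margin_m=margin_m,
                        school_id=school_id)
    n_int = count_intersections(sa, net)
    class_areas = {c: 0.0 for c in LAND_USE_CLASSES}
    residents = 0.0
    if parcels:
        tree = STRtree([p.polygon for p in parcels])
        for idx in tree.query(sa.footprint, predicate="intersects"):
            p = parcels[int(idx)]
            if p.polygon.area <= 0:
                continue
            frac = p.polygon.intersection(sa.footprint).area / p.polygon.area
            class_areas[p.use_class] += p.floor_area_m2 * frac
            residents += p.residents * frac
    mix = (mixed_use_index(class_areas, k=entropy_k)
           if sum(class_areas.values()) > 0 else 0.0)
    return BufferMeasures(
        school_id=school_id,
        threshold_m=float(threshold_m),
        area_ha=sa.area_ha,
        n_intersections=n_int,
        residents=residents,
        residents_density=resident_density(residents, sa.area_ha),
        intersection_density=intersection_density(n_int, sa.area_ha),
        mixed_use_raw=mix,
    )


# ---------------------------------------------------------------------------
# exposure table
# ---------------------------------------------------------------------------

EXPOSURE_COLUMNS = [
    "pid", "age_group", "school_id", "distance_km", "prd",
    "res_density", "int_density", "mixed_use_z", "acs_trips", "acs_binary",
    "flags",
]


def build_exposure_table(
    participants: pd.DataFrame,
    schools: pd.DataFrame,
    net: StreetNetwork,
    parcels: Sequence[Parcel],
    thresholds_m: Mapping[str, float] | None = None,
    margin_m: float = 25.0,
    entropy_k: int | None = 6,
    strict_prd: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble one exposure record per routable participant.

    Parameters
    ----------
    participants:
        columns ``pid, age_group, home_x, home_y, school_id`` and optionally
        ``trips`` (0–10, nullable).
    schools:
        columns ``school_id, x, y``.
    thresholds_m:
        buffer threshold per age group; defaults to 1250 m for children and
        1350 m for adolescents.
    strict_prd:
        drop (rather than flag) records with PRD < 1.

    Returns
    -------
    (exposure table, exclusion log) — the log has columns ``pid, reason``.
    """
    thresholds_m = dict(DEFAULT_THRESHOLDS_M if thresholds_m is None
                        else thresholds_m)
    school_xy = {str(r.school_id): (float(r.x), float(r.y))
                 for r in schools.itertuples()}
    unknown = set(participants["school_id"].astype(str)) - set(school_xy)
    if unknown:
        raise ValueError(f"participants reference unknown school ids: {sorted(unknown)}")

    # buffer measures once per (school, threshold) actually used
    combos = {(str(sid), thresholds_m[ag]) for sid, ag in
              zip(participants["school_id"].astype(str), participants["age_group"])}
    buffers: dict[tuple[str, float], BufferMeasures] = {}
    for sid, thr in sorted(combos):
        buffers[(sid, thr)] = compute_buffer_measures(
            net, sid, school_xy[sid], thr, parcels,
            margin_m=margin_m, entropy_k=entropy_k)
    if len(buffers) >= 2:
        try:
            zs = z_scores([b.mixed_use_raw for b in buffers.values()])
            for b, z in zip(buffers.values(), zs):
                b.mixed_use_z = float(z)
        except ValueError:  # identical mix everywhere: carry raw deviation 0
            for b in buffers.values():
                b.mixed_use_z = 0.0
    else:
        for b in buffers.values():
            b.mixed_use_z = 0.0

    # school routing structures, once per school
    school_dist: dict[str, dict[int, float]] = {}
    school_snap: dict[str, Snap] = {}
    for sid, xy in school_xy.items():
        snap = snap_to_network(net, xy)
        school_snap[sid] = snap
        school_dist[sid] = _dijkstra_from_snap(net, snap)

    records = []
    excluded = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # PRD<1 handled via flags here
        for row in participants.itertuples():
            pid = row.pid
            hx, hy = float(row.home_x), float(row.home_y)
            if not (math.isfinite(hx) and math.isfinite(hy)):
                excluded.append((pid, "bad_address"))
                continue
            sid = str(row.school_id)
            flags: list[str] = []
            hsnap = snap_to_network(net, (hx, hy))
            dist = school_dist[sid]
            u, v, w = net.edges[hsnap.edge_id]
            cands = []
            if u in dist:
                cands.append(dist[u] + hsnap.offset_m)
            if v in dist:
                cands.append(dist[v] + (w - hsnap.offset_m))
            if hsnap.edge_id == school_snap[sid].edge_id:
                cands.append(abs(hsnap.offset_m - school_snap[sid].offset_m))
            if not cands:
                excluded.append((pid, "unroutable"))
                continue
            net_d = min(cands)
            euc_d = euclidean_distance((hx, hy), school_xy[sid])
            if euc_d <= 0:
                excluded.append((pid, "home_at_school"))
                continue
            ratio = net_d / euc_d
            if ratio < 1.0 - 1e-9:
                if strict_prd:
                    excluded.append((pid, "prd_lt_1"))
                    continue
                flags.append("prd_lt_1")
            bm = buffers[(sid, thresholds_m[row.age_group])]
            trips = getattr(row, "trips", None)
            has_trips = trips is not None and pd.notna(trips)
            records.append({
                "pid": pid,
                "age_group": row.age_group,
                "school_id": sid,
                "distance_km": net_d / 1000.0,
                "prd": ratio,
                "res_density": bm.residents_density,
                "int_density": bm.intersection_density,
                "mixed_use_z": bm.mixed_use_z,
                "acs_trips": int(trips) if has_trips else pd.NA,
                "acs_binary": dichotomize_acs(int(trips)) if has_trips else pd.NA,
                "flags": ";".join(flags),
            })
    table = pd.DataFrame(records, columns=EXPOSURE_COLUMNS)
    log = pd.DataFrame(excluded, columns=["pid", "reason"])
    return table, log


# ---------------------------------------------------------------------------
# parcel I/O
# ---------------------------------------------------------------------------

def parcels_to_geojson(parcels: Sequence[Parcel]) -> dict:
    feats = []
    for p in parcels:
        feats.append({
            "type": "Feature",
            "geometry": geom_mapping(p.polygon),
            "properties": {
                "parcel_id": p.parcel_id,
                "use_class": p.use_class,
                "floor_area_m2": round(p.floor_area_m2, 2),
                "residents": round(p.residents, 3),
            },
        })
    return {"type": "FeatureCollection", "features": feats}


def parcels_from_geojson(obj: dict | str) -> list[Parcel]:
    if isinstance(obj, str):
        with open(obj) as fh:
            obj = json.load(fh)
    out = []
    for feat in obj["features"]:
        props = feat["properties"]
        out.append(Parcel(
            parcel_id=str(props["parcel_id"]),
            polygon=shape(feat["geometry"]),
            use_class=props["use_class"],
            floor_area_m2=float(props["floor_area_m2"]),
            residents=float(props.get("residents", 0.0)),
        ))
    return out


def attach_residents(parcels: Sequence[Parcel], residents: pd.DataFrame) -> None:
    """Overwrite parcel resident counts from a CSV-style table keyed by
    ``parcel_id`` with column ``residents``."""
    counts = dict(zip(residents["parcel_id"].astype(str),
                      residents["residents"].astype(float)))
    for p in parcels:
        if p.parcel_id in counts:
            p.residents = counts[p.parcel_id]
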