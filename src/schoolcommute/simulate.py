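"""Synthetic city and commuting-behaviour generator.

Generates every input the pipeline reads — street network, land-use parcels
with residents, schools, participant roster — with known ground truth, so the
whole analysis chain can be exercised and its estimators validated without
any external data.

Morphology model
----------------
A square block grid with three controllable departures from the pure grid:
a per-district cul-de-sac rate (edges removed, creating dead-ends and longer
detours), a number of non-crossable "superblocks" (interior nodes removed and
land use forced to a single non-residential class, the classic
walled-campus/industrial-estate situation), and district-level land-use
mixing drawn from a Dirichlet over the six canonical use classes.  Residents
are proportional to residential floor area with lognormal noise, which makes
residents density track (inversely) the mixed-use index across schools — the
collinearity structure the model-sequence protocol reacts to.

Behaviour model
---------------
Active status is Bernoulli with logit equal to a group intercept plus known
coefficients applied to the pipeline's *own* computed exposure design
(median-dummied buffer measures, continuous distance and PRD), so parameter
recovery isolates estimation error from exposure error.  Intercepts are
parameterised as target active shares applied to group-mean-centred
predictors.  Trip counts respect the dichotomisation boundary exactly:
active draws uniform {4..10}, non-active uniform {0..3}.
"""
from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from . import coding
from .exposure import LAND_USE_CLASSES, Parcel, build_exposure_table
from .network import StreetNetwork, network_to_geojson

__all__ = [
    "CityConfig",
    "BehaviourModel",
    "City",
    "TABLE_SIGNS_PRESET",
    "distance_threshold_model",
    "generate_city",
    "generate_participants",
    "place_homes",
    "design_from_exposures",
    "draw_outcomes",
    "write_city",
    "write_participants",
]


@dataclass(frozen=True)
class CityConfig:
    """Parameters of the synthetic city and sample.

    Defaults mirror the study conditions: 24 schools (8 primary, 14
    secondary, 2 mixed), 826 children and 2142 adolescents, active shares
    near 68%/71%, and home–school distance distributions with medians around
    0.7–0.9 km and heavy right tails (truncated by the city extent).
    """

    blocks: int = 28
    block_m: float = 120.0
    culdesac_frac: float = 0.12
    n_superblocks: int = 2
    superblock_blocks: int = 3
    district_blocks: int = 7
    landuse_conc: float = 6.0
    landuse_mean_shares: tuple[float, ...] = (0.55, 0.05, 0.12, 0.08, 0.10, 0.10)
    far: float = 1.5                      # floor-area ratio of parcels
    res_rate_per_m2: float = 0.02         # residents per m2 residential floor
    resident_noise_sd: float = 0.35
    street_halfwidth_m: float = 8.0
    n_primary: int = 8
    n_secondary: int = 14
    n_mixed: int = 2
    school_min_sep_m: float = 500.0
    n_children: int = 826
    n_adolescents: int = 2142
    home_dist_median_km: Mapping[str, float] = field(
        default_factory=lambda: {"child": 0.69, "adolescent": 0.86})
    home_dist_sigma: Mapping[str, float] = field(
        default_factory=lambda: {"child": 1.1, "adolescent": 1.2})
    missing_acs_frac: float = 0.15
    bike_frac: float = 0.003
    bad_address_frac: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blocks < 4:
            raise ValueError("need at least a 4x4 block grid")
        if not 0 <= self.culdesac_frac < 1:
            raise ValueError("culdesac_frac must be in [0, 1)")
        if abs(sum(self.landuse_mean_shares) - 1.0) > 1e-9 or \
                len(self.landuse_mean_shares) != len(LAND_USE_CLASSES):
            raise ValueError("landuse_mean_shares must be 6 values summing to 1")
        for frac in (self.missing_acs_frac, self.bike_frac, self.bad_address_frac):
            if not 0 <= frac < 1:
                raise ValueError("defect fractions must be in [0, 1)")


#: predictors of the behaviour model, on the analysis design scale
BEHAVIOUR_PREDICTORS = ("res_dummy", "int_dummy", "mix_dummy",
                        "distance_km", "prd")


@dataclass(frozen=True)
class BehaviourModel:
    """Known-truth logistic commuting model per age group.

    ``coef`` maps group -> predictor -> log-odds slope.  With
    ``center=True`` the intercept is derived from ``target_active`` (the
    group's active share) applied to group-mean-centred predictors; with
    ``center=False`` the provided ``intercept`` is used on raw predictors.
    """

    coef: Mapping[str, Mapping[str, float]]
    target_active: Mapping[str, float] = field(
        default_factory=lambda: {"child": 0.679, "adolescent": 0.714})
    center: bool = True
    intercept: Mapping[str, float] | None = None

    def to_dict(self) -> dict:
        return {
            "coef": {g: dict(c) for g, c in self.coef.items()},
            "target_active": dict(self.target_active),
            "center": self.center,
            "intercept": dict(self.intercept) if self.intercept else None,
        }


#: default preset whose slope signs mirror the published age-group contrast:
#: children -,-,-,+ and adolescents +,+,-,+ on (intersections, mixed uses,
#: distance, PRD); residents slope is zero in both groups.
TABLE_SIGNS_PRESET = BehaviourModel(coef={
    "child": {"res_dummy": 0.0, "int_dummy": -0.369, "mix_dummy": -0.420,
              "distance_km": -0.14, "prd": 2.428},
    "adolescent": {"res_dummy": 0.0, "int_dummy": 0.495, "mix_dummy": 0.711,
                   "distance_km": -0.144, "prd": 1.257},
})


def distance_threshold_model(threshold_km: float = 1.25,
                             slope: float = 8.0) -> BehaviourModel:
    """Sharp distance-rule behaviour: P(active) = expit(slope·(thr − d)).

    Useful for checking that the ROC/Youden machinery recovers a planted
    distance cutoff.
    """
    coef = {g: {"res_dummy": 0.0, "int_dummy": 0.0, "mix_dummy": 0.0,
                "distance_km": -slope, "prd": 0.0}
            for g in ("child", "adolescent")}
    icept = {g: slope * threshold_km for g in ("child", "adolescent")}
    return BehaviourModel(coef=coef, center=False, intercept=icept)


@dataclass
class City:
    net: StreetNetwork
    parcels: list[Parcel]
    schools: pd.DataFrame       # school_id, x, y, type (primary|secondary|mixed)
    config: CityConfig
    districts: np.ndarray       # district id per block (blocks x blocks)


# ---------------------------------------------------------------------------
# city generation
# ---------------------------------------------------------------------------

def _node_id(i: int, j: int, n: int) -> int:
    return i * n + j


def generate_city(cfg: CityConfig) -> City:
    """Build the street network, parcels (with residents) and schools.

    Deterministic given ``cfg.seed``.  If school placement fails (grid too
    fragmented for the separation constraint) generation is retried with a
    derived seed up to 5 times before raising.
    """
    last_err: Exception | None = None
    for attempt in range(5):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, attempt]))
        try:
            return _generate_city_once(cfg, rng)
        except RuntimeError as err:
            last_err = err
    raise RuntimeError(f"city generation failed after 5 attempts: {last_err}")


def _generate_city_once(cfg: CityConfig, rng: np.random.Generator) -> City:
    B = cfg.blocks
    n = B + 1
    bm = cfg.block_m

    nodes = {_node_id(i, j, n): (i * bm, j * bm) for i in range(n) for j in range(n)}
    edges: list[tuple[int, int, float]] = []
    for i in range(n):
        for j in range(n):
            if i + 1 < n:
                edges.append((_node_id(i, j, n), _node_id(i + 1, j, n), bm))
            if j + 1 < n:
                edges.append((_node_id(i, j, n), _node_id(i, j + 1, n), bm))

    # superblocks: non-crossable k x k block regions
    k = cfg.superblock_blocks
    sb_cells: set[tuple[int, int]] = set()
    sb_regions: list[tuple[int, int]] = []
    guard = 0
    while len(sb_regions) < cfg.n_superblocks and guard < 200:
        guard += 1
        i0 = int(rng.integers(1, B - k))
        j0 = int(rng.integers(1, B - k))
        cells = {(i, j) for i in range(i0, i0 + k) for j in range(j0, j0 + k)}
        near = {(i + di, j + dj) for i, j in cells for di in (-1, 0, 1)
                for dj in (-1, 0, 1)}
        if near & sb_cells:
            continue
        sb_regions.append((i0, j0))
        sb_cells |= cells
    interior_nodes = set()
    for i0, j0 in sb_regions:
        for i in range(i0 + 1, i0 + k):
            for j in range(j0 + 1, j0 + k):
                interior_nodes.add(_node_id(i, j, n))
    edges = [(u, v, w) for u, v, w in edges
             if u not in interior_nodes and v not in interior_nodes]

    # district map and per-district cul-de-sac intensity / land-use shares
    db = cfg.district_blocks
    nd = math.ceil(B / db)
    districts = np.zeros((B, B), dtype=int)
    for bi in range(B):
        for bj in range(B):
            districts[bi, bj] = (bi // db) * nd + (bj // db)
    d_ids = np.unique(districts)
    cul_factor = {int(d): float(np.exp(rng.normal(0.0, 0.5))) for d in d_ids}
    alpha = cfg.landuse_conc * np.asarray(cfg.landuse_mean_shares)
    d_shares = {int(d): rng.dirichlet(alpha) for d in d_ids}

    def edge_district(u: int, v: int) -> int:
        (xu, yu), (xv, yv) = nodes[u], nodes[v]
        mx, my = (xu + xv) / 2, (yu + yv) / 2
        bi = min(int(mx // bm), B - 1)
        bj = min(int(my // bm), B - 1)
        return int(districts[bi, bj])

    kept = []
    for u, v, w in edges:
        p = min(0.9, cfg.culdesac_frac * cul_factor[edge_district(u, v)])
        if rng.random() >= p:
            kept.append((u, v, w))

    # largest connected component
    import networkx as nx
    g = nx.Graph()
    g.add_weighted_edges_from(kept)
    if g.number_of_nodes() == 0:
        raise RuntimeError("all edges removed; lower culdesac_frac")
    comp = max(nx.connected_components(g), key=len)
    kept = [(u, v, w) for u, v, w in kept if u in comp and v in comp]
    net = StreetNetwork({m: nodes[m] for m in comp}, kept)

    # parcels: one strip per present use class per block
    parcels: list[Parcel] = []
    hw = cfg.street_halfwidth_m
    sb_class_by_region = {
        (i0, j0): str(rng.choice(["industrial", "public_service", "recreational"]))
        for i0, j0 in sb_regions}
    sb_class = {}
    for (i0, j0), cls in sb_class_by_region.items():
        for i in range(i0, i0 + k):
            for j in range(j0, j0 + k):
                sb_class[(i, j)] = cls
    for bi in range(B):
        for bj in range(B):
            x0, y0 = bi * bm + hw, bj * bm + hw
            x1, y1 = (bi + 1) * bm - hw, (bj + 1) * bm - hw
            if (bi, bj) in sb_class:
                shares = np.zeros(len(LAND_USE_CLASSES))
                shares[LAND_USE_CLASSES.index(sb_class[(bi, bj)])] = 1.0
            else:
                base = d_shares[int(districts[bi, bj])]
                shares = rng.dirichlet(10.0 * base + 0.02)
            xs = x0
            width = x1 - x0
            for cls, s in zip(LAND_USE_CLASSES, shares):
                if s < 0.01:
                    continue
                xe = min(x1, xs + s * width)
                if xe - xs < 1e-6:
                    continue
                poly = Polygon([(xs, y0), (xe, y0), (xe, y1), (xs, y1)])
                floor = poly.area * cfg.far
                res = 0.0
                if cls == "residential":
                    sd = cfg.resident_noise_sd
                    res = floor * cfg.res_rate_per_m2 * float(
                        np.exp(rng.normal(-sd * sd / 2, sd)))
                parcels.append(Parcel(
                    parcel_id=f"b{bi:02d}_{bj:02d}_{cls}",
                    polygon=poly, use_class=cls,
                    floor_area_m2=floor, residents=res))
                xs = xe

    # schools at well-separated network nodes
    cand = sorted(net.nodes)
    total_schools = cfg.n_primary + cfg.n_secondary + cfg.n_mixed
    chosen: list[int] = []
    order = rng.permutation(len(cand))
    for idx in order:
        node = cand[int(idx)]
        xy = net.nodes[node]
        if all(math.dist(xy, net.nodes[c]) >= cfg.school_min_sep_m for c in chosen):
            chosen.append(node)
        if len(chosen) == total_schools:
            break
    if len(chosen) < total_schools:
        raise RuntimeError("could not place all schools with the separation constraint")
    types = (["primary"] * cfg.n_primary + ["secondary"] * cfg.n_secondary
             + ["mixed"] * cfg.n_mixed)
    schools = pd.DataFrame({
        "school_id": [f"s{i:02d}" for i in range(total_schools)],
        "x": [net.nodes[c][0] for c in chosen],
        "y": [net.nodes[c][1] for c in chosen],
        "type": types,
    })
    return City(net=net, parcels=parcels, schools=schools, config=cfg,
                districts=districts)


# ---------------------------------------------------------------------------
# participants and outcomes
# ---------------------------------------------------------------------------

def _place_home(rng: np.random.Generator, school_xy: tuple[float, float],
                dist_m: float, extent_m: float) -> tuple[float, float]:
    sx, sy = school_xy
    for _ in range(30):
        ang = rng.uniform(0, 2 * math.pi)
        x, y = sx + dist_m * math.cos(ang), sy + dist_m * math.sin(ang)
        if 0 <= x <= extent_m and 0 <= y <= extent_m:
            return (x, y)
    # clamp the radius along the last drawn direction
    lo, hi = 0.0, dist_m
    for _ in range(40):
        mid = (lo + hi) / 2
        x, y = sx + mid * math.cos(ang), sy + mid * math.sin(ang)
        if 0 <= x <= extent_m and 0 <= y <= extent_m:
            lo = mid
        else:
            hi = mid
    return (sx + lo * math.cos(ang), sy + lo * math.sin(ang))


def place_homes(cfg: CityConfig, city: City,
                rng: np.random.Generator) -> pd.DataFrame:
    """Roster skeleton: school assignment and home placement, no outcomes."""
    extent = cfg.blocks * cfg.block_m
    allowed = {
        "child": city.schools.loc[city.schools["type"].isin(["primary", "mixed"]),
                                  "school_id"].tolist(),
        "adolescent": city.schools.loc[city.schools["type"].isin(["secondary", "mixed"]),
                                       "school_id"].tolist(),
    }
    sxy = {str(r.school_id): (float(r.x), float(r.y))
           for r in city.schools.itertuples()}
    rows = []
    pid = 0
    for group, count in (("child", cfg.n_children), ("adolescent", cfg.n_adolescents)):
        mu = math.log(cfg.home_dist_median_km[group] * 1000.0)
        sig = cfg.home_dist_sigma[group]
        for _ in range(count):
            sid = str(rng.choice(allowed[group]))
            d = float(rng.lognormal(mu, sig))
            hx, hy = _place_home(rng, sxy[sid], d, extent)
            rows.append({"pid": f"p{pid:05d}", "age_group": group,
                         "gender": str(rng.choice(["male", "female"])),
                         "home_x": hx, "home_y": hy, "school_id": sid})
            pid += 1
    return pd.DataFrame(rows)


def design_from_exposures(exposures: pd.DataFrame) -> pd.DataFrame:
    """Exposure table -> behaviour design matrix indexed by pid (median
    dummies over the participant-level columns, route measures continuous)."""
    design = exposures.set_index("pid").copy()
    design["res_dummy"] = coding.median_dummy(design["res_density"])
    design["int_dummy"] = coding.median_dummy(design["int_density"])
    design["mix_dummy"] = coding.median_dummy(design["mixed_use_z"])
    return design


def draw_outcomes(design: pd.DataFrame, model: BehaviourModel,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Bernoulli active status and trip counts from the behaviour model.

    ``design`` must carry ``age_group`` plus the behaviour predictors and be
    indexed by pid.  Returns a frame indexed like ``design`` with columns
    ``p_active, active, trips``.
    """
    out = pd.DataFrame(index=design.index,
                       columns=["p_active", "active", "trips"], dtype=object)
    for group in ("child", "adolescent"):
        mask = (design["age_group"] == group).to_numpy()
        if not mask.any():
            continue
        sub = design.loc[mask]
        coef = model.coef[group]
        eta = np.zeros(len(sub))
        if model.center:
            eta += math.log(model.target_active[group]
                            / (1 - model.target_active[group]))
            for pred, b in coef.items():
                x = sub[pred].to_numpy(dtype=float)
                eta += b * (x - np.nanmean(x))
        else:
            assert model.intercept is not None
            eta += model.intercept[group]
            for pred, b in coef.items():
                eta += b * sub[pred].to_numpy(dtype=float)
        p = 1.0 / (1.0 + np.exp(-eta))
        # records lacking exposures (e.g. unroutable homes) fall back to the
        # group's baseline probability
        baseline = (model.target_active[group] if model.center
                    else 1.0 / (1.0 + math.exp(-model.intercept[group])))
        p = np.where(np.isfinite(p), p, baseline)
        active = rng.random(len(p)) < p
        trips = np.where(active, rng.integers(4, 11, len(p)),
                         rng.integers(0, 4, len(p)))
        out.loc[mask, "p_active"] = p
        out.loc[mask, "active"] = active
        out.loc[mask, "trips"] = trips
    return out


def generate_participants(
    cfg: CityConfig,
    city: City,
    model: BehaviourModel = TABLE_SIGNS_PRESET,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Roster with homes, schools, and behaviour-model outcomes.

    Exposures entering the outcome model are computed with the pipeline's own
    operations on the generated city.  Defects (missing outcome, bike mode,
    corrupted home coordinates) are injected at the configured fractions to
    exercise the exclusion rules.

    Returns (participant table, truth metadata).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if seed is None else seed, 7]))
    roster = place_homes(cfg, city, rng)
    exposures, _ = build_exposure_table(roster, city.schools, city.net,
                                        city.parcels)
    design = design_from_exposures(exposures).reindex(roster["pid"])
    design["age_group"] = roster.set_index("pid")["age_group"]
    drawn = draw_outcomes(design, model, rng)
    roster["trips"] = pd.array(
        [int(t) if pd.notna(t) else pd.NA
         for t in drawn.reindex(roster["pid"])["trips"]], dtype="Int64")
    roster["mode"] = np.where(roster["trips"].astype(float) >= coding.ACTIVE_MIN_TRIPS,
                              "walk", "motorised")

    # defect injection: disjoint sets of corrupted records
    n = len(roster)
    order = rng.permutation(n)
    n_missing = int(round(cfg.missing_acs_frac * n))
    n_bike = int(round(cfg.bike_frac * n))
    n_bad = int(round(cfg.bad_address_frac * n))
    idx_missing = order[:n_missing]
    idx_bike = order[n_missing:n_missing + n_bike]
    idx_bad = order[n_missing + n_bike:n_missing + n_bike + n_bad]
    roster.loc[roster.index[idx_missing], "trips"] = pd.NA
    roster.loc[roster.index[idx_missing], "mode"] = "missing"
    roster.loc[roster.index[idx_bike], "mode"] = "bike"
    roster.loc[roster.index[idx_bad], ["home_x", "home_y"]] = np.nan

    truth = {
        "seed": int(cfg.seed if seed is None else seed),
        "model": model.to_dict(),
        "n_children": int(cfg.n_children),
        "n_adolescents": int(cfg.n_adolescents),
        "injected": {"missing_acs": int(n_missing), "bike": int(n_bike),
                     "bad_address": int(n_bad)},
    }
    return roster, truth


# ---------------------------------------------------------------------------
# deterministic writers
# ---------------------------------------------------------------------------

def write_city(city: City, outdir: str) -> None:
    from .exposure import parcels_to_geojson

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "network.geojson"), "w") as fh:
        json.dump(network_to_geojson(city.net), fh, sort_keys=True,
                  separators=(",", ":"))
    with open(os.path.join(outdir, "parcels.geojson"), "w") as fh:
        obj = parcels_to_geojson(city.parcels)
        # round coordinates for byte-stable output
        for feat in obj["features"]:
            feat["geometry"]["coordinates"] = [
                [[round(x, 3), round(y, 3)] for x, y in ring]
                for ring in feat["geometry"]["coordinates"]]
        json.dump(obj, fh, sort_keys=True, separators=(",", ":"))
    sch = city.schools.copy()
    sch["x"] = sch["x"].map(lambda v: f"{v:.3f}")
    sch["y"] = sch["y"].map(lambda v: f"{v:.3f}")
    sch.to_csv(os.path.join(outdir, "schools.csv"), index=False)


def write_participants(roster: pd.DataFrame, truth: dict, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    out = roster.copy()
    for col in ("home_x", "home_y"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    out.to_csv(os.path.join(outdir, "participants.csv"), index=False)
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, sort_keys=True, indent=1)
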