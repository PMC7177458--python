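"""End-to-end orchestration.

Runs the stages in order — exposure assembly, outcome coding/exclusions,
logistic model sequence, ROC thresholds, PRD cross-table — writes one CSV or
JSON artifact per stage plus a single ``report.json``, and is deterministic
under a fixed seed and configuration.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import association, coding, crosstab, exposure, roc
from .exposure import DEFAULT_THRESHOLDS_M, parcels_from_geojson, attach_residents
from .network import network_from_geojson, network_from_edge_csv

log = logging.getLogger("schoolcommute")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_inputs"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    network_path: str
    participants_path: str
    schools_path: str
    parcels_path: str
    residents_path: str | None = None
    thresholds_m: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS_M))
    prd_edges: Sequence[float] = crosstab.DEFAULT_PRD_EDGES
    prob_cutoff: float = 0.50
    vif_threshold: float = 2.0
    ci_method: str = "wald"
    strict_prd: bool = False
    seed: int = 0
    outdir: str = "run_out"

    def __post_init__(self) -> None:
        if not 0 < self.prob_cutoff < 1:
            raise ValueError("prob_cutoff must be in (0, 1)")
        e = list(self.prd_edges)
        if any(b <= a for a, b in zip(e[:-1], e[1:])):
            raise ValueError("prd_edges must be strictly increasing")
        if any(t <= 0 for t in self.thresholds_m.values()):
            raise ValueError("buffer thresholds must be positive")


def load_inputs(cfg: RunConfig):
    net = (network_from_edge_csv(cfg.network_path)
           if cfg.network_path.endswith(".csv")
           else network_from_geojson(cfg.network_path))
    participants = pd.read_csv(cfg.participants_path)
    schools = pd.read_csv(cfg.schools_path)
    parcels = parcels_from_geojson(cfg.parcels_path)
    if cfg.residents_path:
        attach_residents(parcels, pd.read_csv(cfg.residents_path))
    return net, participants, schools, parcels


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(name, exc) from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and return the report dict (also written to
    ``<outdir>/report.json``)."""
    os.makedirs(cfg.outdir, exist_ok=True)
    net, participants, schools, parcels = _stage("load")(load_inputs)(cfg)

    retained, excl_log = _stage("coding")(coding.apply_exclusions)(participants)
    log.info("exclusions: %s", excl_log["reason"].value_counts().to_dict())

    exposures, route_log = _stage("exposure")(exposure.build_exposure_table)(
        retained, schools, net, parcels,
        thresholds_m=cfg.thresholds_m, strict_prd=cfg.strict_prd)
    full_log = pd.concat([excl_log, route_log], ignore_index=True)
    exposures.to_csv(os.path.join(cfg.outdir, "exposures.csv"), index=False,
                     float_format="%.6f")
    full_log.to_csv(os.path.join(cfg.outdir, "exclusions.csv"), index=False)

    seq = _stage("association")(association.run_model_sequence)(
        exposures, cutoff=cfg.prob_cutoff, vif_threshold=cfg.vif_threshold)
    with open(os.path.join(cfg.outdir, "models.json"), "w") as fh:
        json.dump(seq.to_dict(), fh, indent=1, sort_keys=True)

    thresholds = _stage("thresholds")(roc.threshold_report)(exposures)
    with open(os.path.join(cfg.outdir, "roc.json"), "w") as fh:
        json.dump({k: v.to_dict() for k, v in thresholds.items()}, fh,
                  indent=1, sort_keys=True)
    pd.concat({k: v.curve_frame() for k, v in thresholds.items()},
              names=["analysis", "i"]).to_csv(
        os.path.join(cfg.outdir, "roc_curves.csv"), float_format="%.6f")

    xt = _stage("crosstab")(crosstab.build_crosstab)(exposures, edges=cfg.prd_edges)
    xt.display().to_csv(os.path.join(cfg.outdir, "crosstab.csv"))

    report = {
        "config": {**dataclasses.asdict(cfg),
                   "thresholds_m": dict(cfg.thresholds_m),
                   "prd_edges": list(cfg.prd_edges)},
        "exclusions": full_log["reason"].value_counts().to_dict(),
        "n_records": int(len(exposures)),
        "active_share_pct": round(
            100.0 * pd.to_numeric(exposures["acs_binary"],
                                  errors="coerce").mean(), 2),
        "association": seq.to_dict(),
        "thresholds": {k: v.to_dict() for k, v in thresholds.items()},
        "crosstab": xt.to_dict(),
    }
    # hash covers analytic content only, not filesystem paths in the config
    payload = json.dumps({k: v for k, v in report.items() if k != "config"},
                         sort_keys=True, indent=1, default=float)
    report["report_sha256"] = hashlib.sha256(payload.encode()).hexdigest()
    with open(os.path.join(cfg.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1, default=float)
    return report
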