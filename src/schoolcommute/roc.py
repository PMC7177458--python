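"""ROC / Youden-index threshold analysis for route measures.

The empirical ROC curve is evaluated at thresholds placed midway between
consecutive distinct scores (plus sentinels beyond the extremes).  AUC is the
trapezoidal area, which equals the Mann–Whitney concordance probability; its
95% CI uses the Hanley–McNeil variance.  The optimal cutoff maximises the
Youden index J = sensitivity + specificity − 1, with ties broken toward the
more inclusive active class.  A curve is "valid" when AUC ≥ 0.5 with 0.5
outside the CI; within (0.5, 0.75) it is additionally labelled exploratory.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["RocResult", "roc_analysis", "threshold_report", "plot_roc"]

Orientation = Literal["higher", "lower", "auto"]


@dataclass
class RocResult:
    points: np.ndarray          # (n, 2) of (1 - specificity, sensitivity), (0,0)..(1,1)
    thresholds: np.ndarray      # candidate cutoffs in score units
    j_values: np.ndarray
    auc: float
    ci: tuple[float, float]
    cutoff: float
    j_max: float
    orientation: Literal["higher", "lower"]
    validity: Literal["valid", "valid-exploratory", "invalid"]
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci": list(self.ci),
            "cutoff": self.cutoff,
            "j_max": self.j_max,
            "orientation": self.orientation,
            "validity": self.validity,
            "degenerate": self.degenerate,
        }

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["fpr", "tpr"])


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1 - auc)
           + (n_pos - 1) * (q1 - auc * auc)
           + (n_neg - 1) * (q2 - auc * auc)) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def roc_analysis(scores: Sequence[float], labels: Sequence[int],
                 orientation: Orientation = "auto") -> RocResult:
    """Empirical ROC of a binary outcome against a continuous score.

    ``orientation='higher'`` means positives (active) tend to score above the
    cutoff; ``'lower'`` means below.  ``'auto'`` picks whichever gives
    AUC >= 0.5.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    classes = set(np.unique(y))
    if classes != {0, 1}:
        raise ValueError("labels must contain both classes 0 and 1")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)

    degenerate = len(np.unique(s)) == 1

    def build(sign: float):
        z = sign * s
        uniq = np.unique(z)
        if len(uniq) == 1:
            thr = np.array([uniq[0]])
        else:
            mids = (uniq[:-1] + uniq[1:]) / 2.0
            thr = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
        # predicted positive when z > threshold
        tpr = np.array([np.mean(z[y == 1] > t) for t in thr])
        fpr = np.array([np.mean(z[y == 0] > t) for t in thr])
        order = np.argsort(thr)[::-1]  # descending threshold -> increasing fpr
        pts = np.column_stack([fpr[order], tpr[order]])
        pts = np.vstack([[0.0, 0.0], pts, [1.0, 1.0]])
        auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
        return thr, tpr, fpr, pts, auc

    if orientation == "auto":
        _, _, _, _, auc_hi = build(1.0)
        orientation = "higher" if auc_hi >= 0.5 else "lower"
    sign = 1.0 if orientation == "higher" else -1.0
    thr_z, tpr, fpr, pts, auc = build(sign)

    j = tpr - fpr
    j_max = float(j.max())
    # ties toward the more inclusive active class: lowest cutoff for
    # 'higher' orientation, highest for 'lower' (both are lowest in z-space)
    best = int(np.flatnonzero(j >= j_max - 1e-12).min())
    cutoff = float(sign * thr_z[best])

    if degenerate:
        auc, j_max = 0.5, 0.0
    se = _hanley_mcneil_se(auc, n_pos, n_neg)
    zc = 1.959963984540054
    ci = (max(0.0, auc - zc * se), min(1.0, auc + zc * se))
    if degenerate or not (auc >= 0.5 and (ci[0] > 0.5 or ci[1] < 0.5)):
        validity = "invalid"
    elif auc < 0.75:
        validity = "valid-exploratory"
    else:
        validity = "valid"
    return RocResult(points=pts, thresholds=sign * thr_z, j_values=j,
                     auc=auc, ci=ci, cutoff=cutoff, j_max=j_max,
                     orientation=orientation, validity=validity,
                     degenerate=degenerate)


def threshold_report(records: pd.DataFrame) -> dict[str, RocResult]:
    """The four route-measure threshold analyses.

    PRD for all participants and per age group with active participants
    above the cutoff, and network distance (km) for all participants with
    active participants below the cutoff.
    """
    df = records.dropna(subset=["acs_binary"]).copy()
    df["acs_binary"] = df["acs_binary"].astype(int)
    out: dict[str, RocResult] = {}

    def one(name: str, sub: pd.DataFrame, col: str, orient: Orientation):
        if sub.empty:
            raise ValueError(f"empty stratum for {name}")
        if sub["acs_binary"].nunique() < 2:
            raise ValueError(f"stratum {name!r} has a single outcome class")
        out[name] = roc_analysis(sub[col], sub["acs_binary"], orientation=orient)

    one("prd_all", df, "prd", "higher")
    one("prd_children", df[df["age_group"] == "child"], "prd", "higher")
    one("prd_adolescents", df[df["age_group"] == "adolescent"], "prd", "higher")
    one("distance_all", df, "distance_km", "lower")
    return out


def plot_roc(results: Mapping[str, RocResult], path: str) -> None:
    """Small-multiple ROC panels (one per analysis) written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(results)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.2), squeeze=False)
    for ax, (name, r) in zip(axes[0], results.items()):
        ax.plot(r.points[:, 0], r.points[:, 1], lw=1.5)
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_title(f"{name}\nAUC={r.auc:.3f} cut={r.cutoff:.3f}", fontsize=8)
        ax.set_xlabel("1 - specificity", fontsize=8)
        ax.set_ylabel("sensitivity", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
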