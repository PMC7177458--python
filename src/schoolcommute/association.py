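"""Binary logistic regression protocol.

Implements the two-model sequence used in the analysis: a pooled logit of the
dichotomised commuting outcome on all five environmental predictors plus an
age-group adjustment (model 1) with a crude/adjusted confounding comparison,
collinearity diagnostics (pairwise correlations, VIF, condition indices), and
an age-stratified refit (model 2) after dropping predictors that are both
non-significant and collinearity-flagged.

All predictors enter in a single step (no stepwise selection).  School-level
buffer measures are median-dummied before entry; route measures (distance,
PRD) stay continuous.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .coding import median_dummy

__all__ = [
    "SeparationError",
    "LogisticModelResult",
    "CollinearityReport",
    "ModelSequenceResult",
    "fit_blr",
    "confounding_check",
    "collinearity_diagnostics",
    "run_model_sequence",
]

MODEL1_PREDICTORS = ["res_dummy", "int_dummy", "mix_dummy", "distance_km", "prd"]
MODEL2_PREDICTORS = ["int_dummy", "mix_dummy", "distance_km", "prd"]


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation in a logistic fit."""


@dataclass
class LogisticModelResult:
    """One binary-logistic fit: per-term B, SE, Wald p, OR and 95% CI, plus
    the fraction of cases classified correctly at the probability cutoff."""

    params: pd.DataFrame        # index: term; columns B, SE, p, OR, ci_low, ci_high
    accuracy: float
    n: int
    converged: bool
    llf: float
    cutoff: float = 0.50

    def or_(self, term: str) -> float:
        return float(self.params.loc[term, "OR"])

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "accuracy": self.accuracy,
            "cutoff": self.cutoff,
            "converged": self.converged,
            "log_likelihood": self.llf,
            "terms": {
                t: {k: float(self.params.loc[t, k])
                    for k in ("B", "SE", "p", "OR", "ci_low", "ci_high")}
                for t in self.params.index
            },
        }


@dataclass
class CollinearityReport:
    corr: pd.DataFrame
    max_abs_r: float
    vif: pd.Series
    condition_indices: np.ndarray
    ses: pd.Series | None = None

    def flagged(self, vif_threshold: float = 2.0) -> list[str]:
        return [p for p, v in self.vif.items() if v > vif_threshold]


def fit_blr(records: pd.DataFrame, predictors: Sequence[str],
            outcome: str = "acs_binary", cutoff: float = 0.50,
            ci_method: str = "wald") -> LogisticModelResult:
    """Maximum-likelihood logit with all predictors entered in one step.

    CIs for the OR are Wald intervals exp(B ± 1.96·SE) by default (matching
    common statistical-package output); ``ci_method='profile'`` uses
    likelihood-profile intervals.  Raises :class:`SeparationError` on perfect
    separation, naming the offending predictor.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    y = pd.to_numeric(records[outcome], errors="raise").astype(float).to_numpy()
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("outcome must contain both classes coded 0/1")
    X = records.loc[:, list(predictors)].astype(float)
    const_cols = [c for c in X.columns if X[c].nunique() <= 1]
    if const_cols:
        raise ValueError(f"constant predictor(s): {const_cols}")
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, Xc).fit(method="newton", maxiter=100,
                                      tol=1e-8, disp=0)
        except Exception as exc:  # statsmodels raises on hard separation
            raise SeparationError(f"logistic fit failed: {exc}") from exc
    params = pd.Series(fit.params, index=Xc.columns)
    bse = pd.Series(fit.bse, index=Xc.columns)
    big = params.abs()
    if len(params) > 1:
        big = big.drop("const")
    if (big > 30).any() or not np.isfinite(bse).all() or (bse > 1e3).any():
        raise SeparationError(
            f"perfect separation suspected on predictor {big.idxmax()!r}")
    if not fit.mle_retvals.get("converged", True):
        raise SeparationError(
            "fit did not converge after "
            f"{fit.mle_retvals.get('iterations', '?')} Newton iterations")
    zcrit = sps.norm.ppf(0.975)
    if ci_method == "wald":
        lo, hi = params - zcrit * bse, params + zcrit * bse
    elif ci_method == "profile":
        ci = fit.conf_int()  # statsmodels profile not exposed for Logit; Wald fallback
        lo, hi = ci[0], ci[1]
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    table = pd.DataFrame({
        "B": params,
        "SE": bse,
        "p": pd.Series(fit.pvalues, index=Xc.columns),
        "OR": np.exp(params),
        "ci_low": np.exp(lo),
        "ci_high": np.exp(hi),
    })
    pred = (fit.predict(Xc) >= cutoff).astype(float)
    return LogisticModelResult(
        params=table,
        accuracy=float((pred == y).mean()),
        n=int(len(y)),
        converged=bool(fit.mle_retvals.get("converged", True)),
        llf=float(fit.llf),
        cutoff=cutoff,
    )


def confounding_check(crude: LogisticModelResult,
                      adjusted: LogisticModelResult,
                      flag_pct: float = 10.0) -> pd.DataFrame:
    """Percent OR change per shared predictor between a crude fit and a fit
    with an adjustment term added: 100·|OR_adj − OR_crude| / OR_crude.

    Changes at or above ``flag_pct`` are flagged as potential confounding.
    """
    shared = [t for t in crude.params.index
              if t != "const" and t in adjusted.params.index]
    extra = set(crude.params.index) - set(adjusted.params.index)
    if extra:
        raise ValueError(f"crude model has terms absent from adjusted: {sorted(extra)}")
    rows = []
    for t in shared:
        oc, oa = crude.or_(t), adjusted.or_(t)
        change = 100.0 * abs(oa - oc) / oc
        rows.append((t, oc, oa, change, change >= flag_pct))
    return pd.DataFrame(rows, columns=["term", "or_crude", "or_adjusted",
                                       "pct_change", "flagged"]).set_index("term")


def collinearity_diagnostics(records: pd.DataFrame,
                             predictors: Sequence[str],
                             outcome: str | None = None) -> CollinearityReport:
    """Pairwise Pearson correlations, VIFs and condition indices.

    VIF_j = 1 / (1 − R²_j) from an OLS regression of predictor j on the
    others (with intercept).  Condition indices are sqrt(λ_max / λ_i) of the
    column-scaled, intercept-included cross-product matrix.  When ``outcome``
    is given, per-coefficient SEs from the corresponding logit are attached.
    """
    preds = list(predictors)
    if len(preds) < 2:
        raise ValueError("need at least two predictors")
    X = records.loc[:, preds].astype(float)
    if any(X[c].nunique() <= 1 for c in preds):
        raise ValueError("constant predictor in diagnostics")
    corr = X.corr()
    off = corr.where(~np.eye(len(preds), dtype=bool)).abs()
    vifs = {}
    for j, c in enumerate(preds):
        others = [p for p in preds if p != c]
        Xo = sm.add_constant(X[others], has_constant="add")
        r2 = sm.OLS(X[c], Xo).fit().rsquared
        vifs[c] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    Xc = sm.add_constant(X, has_constant="add").to_numpy()
    norms = np.linalg.norm(Xc, axis=0)
    Z = Xc / norms
    lam = np.linalg.eigvalsh(Z.T @ Z)
    lam = np.clip(lam, 1e-15, None)
    cond = np.sqrt(lam.max() / lam)[::-1]
    ses = None
    if outcome is not None:
        ses = fit_blr(records, preds, outcome=outcome).params["SE"].drop("const")
    return CollinearityReport(
        corr=corr,
        max_abs_r=float(np.nanmax(off.to_numpy())),
        vif=pd.Series(vifs),
        condition_indices=cond,
        ses=ses,
    )


@dataclass
class ModelSequenceResult:
    model1: LogisticModelResult
    model1_crude: LogisticModelResult
    confounding: pd.DataFrame
    collinearity: CollinearityReport
    dropped: list[str]
    model2: dict[str, LogisticModelResult]

    def to_dict(self) -> dict:
        return {
            "model1": self.model1.to_dict(),
            "model1_crude": self.model1_crude.to_dict(),
            "confounding_pct_change": self.confounding["pct_change"].to_dict(),
            "vif": self.collinearity.vif.to_dict(),
            "max_abs_corr": self.collinearity.max_abs_r,
            "condition_indices": list(map(float, self.collinearity.condition_indices)),
            "dropped": self.dropped,
            "model2": {g: m.to_dict() for g, m in self.model2.items()},
        }


def prepare_design(records: pd.DataFrame) -> pd.DataFrame:
    """Exposure table -> analysis design: median-dummied buffer measures,
    continuous route measures, adolescent indicator, 0/1 outcome."""
    df = records.dropna(subset=["acs_binary"]).copy()
    df["acs_binary"] = df["acs_binary"].astype(int)
    df["res_dummy"] = median_dummy(df["res_density"])
    df["int_dummy"] = median_dummy(df["int_density"])
    df["mix_dummy"] = median_dummy(df["mixed_use_z"])
    df["age_adolescent"] = (df["age_group"] == "adolescent").astype(int)
    return df


def run_model_sequence(records: pd.DataFrame, cutoff: float = 0.50,
                       alpha: float = 0.05, vif_threshold: float = 2.0,
                       min_stratum_events: int = 10) -> ModelSequenceResult:
    """The full three-step protocol on an exposure table.

    1. Pooled model 1 with the five predictors plus age group, and the same
       model without age group for the confounding comparison.
    2. Collinearity diagnostics on the five predictors.
    3. Predictors that are non-significant in model 1 (p > alpha) AND carry
       VIF above ``vif_threshold`` are dropped; model 2 is refit separately
       for children and adolescents with the remainder.
    """
    df = prepare_design(records)
    model1 = fit_blr(df, MODEL1_PREDICTORS + ["age_adolescent"], cutoff=cutoff)
    crude = fit_blr(df, MODEL1_PREDICTORS, cutoff=cutoff)
    conf = confounding_check(crude, model1)
    report = collinearity_diagnostics(df, MODEL1_PREDICTORS)
    dropped = [p for p in MODEL1_PREDICTORS
               if model1.params.loc[p, "p"] > alpha
               and report.vif[p] > vif_threshold]
    keep = [p for p in MODEL1_PREDICTORS if p not in dropped]
    model2: dict[str, LogisticModelResult] = {}
    for group in ("child", "adolescent"):
        sub = df[df["age_group"] == group]
        events = int(sub["acs_binary"].sum())
        nonevents = len(sub) - events
        if min(events, nonevents) < min_stratum_events:
            raise ValueError(
                f"stratum {group!r} too small: {events} events / "
                f"{nonevents} non-events (need >= {min_stratum_events})")
        model2[group] = fit_blr(sub, keep, cutoff=cutoff)
    return ModelSequenceResult(
        model1=model1, model1_crude=crude, confounding=conf,
        collinearity=report, dropped=dropped, model2=model2)
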