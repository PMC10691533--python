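"""Module eigengenes and survival association.

A module eigengene is the first principal component of the module's
standardized gene-by-sample submatrix, oriented to correlate positively with
the module's mean expression. Samples are stratified at the median eigengene
into high/low groups and a Cox proportional-hazards model (Efron tie
handling) tests whether group membership predicts survival; modules with
Wald P < 0.05 are prognostic, with direction "poor" when HR > 1. A
continuous-eigengene Cox mode is available for per-SD hazard estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

logger = logging.getLogger("panconet")


@dataclass
class Eigengene:
    module_id: str
    scores: pd.Series          # per-sample, zero mean
    variance_explained: float
    orientation: int           # +1 kept, -1 flipped


@dataclass
class CoxResult:
    module_id: str
    beta: float                # log hazard ratio (high vs low, or per SD)
    hr: float
    p: float
    prognostic: bool
    direction: str             # "poor" if HR > 1 else "good"
    mode: str = "median-split"
    warning: str | None = None


def compute_eigengene(module: set[str], expr: pd.DataFrame,
                      module_id: str = "module") -> Eigengene:
    """First PC of the module's standardized submatrix, sign-anchored.

    Zero-variance genes are dropped with a warning; fewer than two usable
    genes is an error. Scores are mean-centered; the sign convention makes
    corr(score, mean module expression) >= 0.
    """
    genes = sorted(set(module) & set(expr.index))
    if len(genes) < 2:
        raise ValueError(f"module {module_id}: fewer than 2 genes in matrix")
    X = expr.loc[genes].to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("module %s: dropping %d zero-variance genes",
                       module_id, int((~keep).sum()))
        X, sd = X[keep], sd[keep]
        if X.shape[0] < 2:
            raise ValueError(f"module {module_id}: fewer than 2 non-constant "
                             "genes")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    score = Vt[0] * S[0]
    var_explained = float(S[0] ** 2 / (S ** 2).sum())
    mean_profile = Z.mean(axis=0)
    sign = 1
    c = np.corrcoef(score, mean_profile)[0, 1]
    if np.isfinite(c) and c < 0:
        sign = -1
        score = -score
    score = score - score.mean()
    return Eigengene(module_id, pd.Series(score, index=expr.columns),
                     var_explained, sign)


def median_stratify(scores: pd.Series) -> pd.Series:
    """Label samples 'high' (> median) or 'low' (<= median)."""
    if len(scores) < 2:
        raise ValueError("need at least 2 samples")
    if scores.nunique() == 1:
        raise ValueError("degenerate stratification: all scores identical")
    med = scores.median()
    return pd.Series(np.where(scores > med, "high", "low"),
                     index=scores.index)


def cox_fit(groups: pd.Series, survival: pd.DataFrame,
            module_id: str = "module") -> CoxResult:
    """Cox PH fit of survival on the binary high/low indicator (Efron ties)."""
    df = _align(groups, survival)
    x = (df["group"] == "high").astype(float)
    if x.nunique() < 2:
        raise ValueError("both groups must be non-empty")
    return _cox(x, df, module_id, mode="median-split")


def cox_fit_continuous(scores: pd.Series, survival: pd.DataFrame,
                       module_id: str = "module") -> CoxResult:
    """Cox PH fit on the standardized continuous eigengene (per-SD HR)."""
    df = survival.loc[survival.index.intersection(scores.index)].copy()
    z = scores.loc[df.index]
    sd = z.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate eigengene: zero variance")
    return _cox((z - z.mean()) / sd, df, module_id, mode="continuous")


def _align(groups: pd.Series, survival: pd.DataFrame) -> pd.DataFrame:
    common = survival.index.intersection(groups.index)
    if len(common) == 0:
        raise ValueError("no overlapping samples between groups and survival")
    df = survival.loc[common, ["time", "event"]].copy()
    df["group"] = groups.loc[common]
    return df.dropna(subset=["time", "event"])


def _cox(x: pd.Series, df: pd.DataFrame, module_id: str,
         mode: str) -> CoxResult:
    if (df["event"] == 1).sum() == 0:
        raise ValueError("zero events: Cox model undefined")
    data = pd.DataFrame({"time": df["time"].astype(float),
                         "event": df["event"].astype(int),
                         "x": np.asarray(x, dtype=float)})
    cph = CoxPHFitter()
    warning = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col="time", event_col="event")
        beta = float(cph.params_["x"])
        p = float(cph.summary.loc["x", "p"])
    except ConvergenceError:
        # complete separation: cap the coefficient and flag it
        warning = "separation: beta capped"
        logger.warning("cox_fit %s: %s", module_id, warning)
        sign = 1.0 if data.loc[data.event == 1, "x"].mean() >= \
            data["x"].mean() else -1.0
        beta, p = sign * 10.0, np.nan
    hr = float(np.exp(beta))
    prognostic = bool(np.isfinite(p) and p < 0.05)
    return CoxResult(module_id, beta, hr, p, prognostic,
                     "poor" if hr > 1 else "good", mode, warning)


def kaplan_meier(groups: pd.Series,
                 survival: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group: columns time, survival."""
    df = _align(groups, survival)
    out = {}
    for label in sorted(df["group"].unique()):
        sub = df[df["group"] == label]
        if sub.empty:
            raise ValueError(f"empty group {label!r}")
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"])
        curve = km.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        out[str(label)] = curve
    return out


def flag_prognostic(results: list[CoxResult],
                    alpha: float = 0.05) -> list[CoxResult]:
    """Keep results with Wald p < alpha; direction annotated from HR."""
    kept = []
    for r in results:
        if np.isfinite(r.p) and r.p < alpha:
            r.prognostic = True
            r.direction = "poor" if r.hr > 1 else "good"
            kept.append(r)
    return kept


def cox_results_to_frame(results: list[CoxResult]) -> pd.DataFrame:
    return pd.DataFrame([{"module_id": r.module_id, "beta": r.beta,
                          "hr": r.hr, "p": r.p, "prognostic": r.prognostic,
                          "direction": r.direction, "mode": r.mode}
                         for r in results])
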