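"""Gene-signature risk scoring and survival comparison.

A fixed signature (gene, coefficient) defines a linear risk score per
patient; the cohort is split at the median score (ties go to the low
group, so "high risk" means strictly above the median), and overall
survival of the two groups is compared with the Kaplan-Meier estimator and
the log-rank test. Coefficient fitting (Cox/Lasso) is out of scope here:
coefficients arrive as input, and because the median split is invariant
under monotone transforms, a pure linear combination without intercept is
sufficient.

Expression units must match the units the coefficients were trained on;
that is the caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank


def read_signature(path: str | Path) -> pd.Series:
    """Signature coefficients from a two-column TSV (gene, beta)."""
    df = pd.read_csv(path, sep="\t")
    sig = pd.Series(df.iloc[:, 1].values.astype(float), index=df.iloc[:, 0].values, name="beta")
    if sig.index.has_duplicates:
        raise ValueError("duplicate genes in signature")
    if len(sig) == 0:
        raise ValueError("empty signature")
    return sig


def read_survival(path: str | Path) -> pd.DataFrame:
    """Survival table from TSV with columns sample, time, event."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time", "event"}
    if not required <= set(df.columns):
        raise ValueError(f"survival table needs columns {sorted(required)}")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be > 0")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 or 1")
    return df.set_index("sample")


def risk_score(expr: pd.DataFrame | pd.Series | Mapping[str, float], signature: pd.Series):
    """Linear predictor sum(beta_g * expr_g) per sample.

    ``expr`` may be a gene -> value mapping (returns a float) or a
    gene x sample DataFrame (returns a per-sample Series). Every signature
    gene must be present.
    """
    if isinstance(expr, Mapping) and not isinstance(expr, pd.Series):
        expr = pd.Series(expr)
    missing = [g for g in signature.index if g not in expr.index]
    if missing:
        raise KeyError(f"signature genes missing from expression: {missing}")
    sub = expr.loc[signature.index]
    if isinstance(expr, pd.DataFrame):
        return pd.Series(signature.values @ sub.values, index=expr.columns, name="risk_score")
    return float(np.dot(signature.values, sub.values))


def median_split(scores: pd.Series) -> pd.Series:
    """High/low grouping at the median risk score.

    Strictly above the median -> "high"; at or below -> "low" (for even n
    the median is the midpoint of the two central order statistics, so a
    tie-free even cohort splits exactly in half). All-identical scores
    admit no split and raise.
    """
    if len(scores) < 2:
        raise ValueError("need >=2 samples to split")
    if scores.nunique() == 1:
        raise ValueError("all risk scores identical; no median split possible")
    med = float(scores.median())
    return pd.Series(np.where(scores > med, "high", "low"), index=scores.index, name="group")


@dataclass
class KMCurve:
    """Product-limit survival estimate as a step function."""

    table: pd.DataFrame  # columns: time, n_at_risk, n_events, n_censored, survival

    def survival(self, t: float) -> float:
        times = self.table["time"].values
        i = np.searchsorted(times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.table["survival"].values[i])

    __call__ = survival


def km_curve(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Subjects censored at an event time are counted at risk for that time
    (censoring processed after events, the standard convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times <= 0).any():
        raise ValueError("times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    et = kmf.event_table.copy()  # indexed by time; includes t=0 row
    et = et[et.index > 0]
    surv = [kmf.predict(t) for t in et.index]
    table = pd.DataFrame(
        {
            "time": et.index.values,
            "n_at_risk": et["at_risk"].values.astype(int),
            "n_events": et["observed"].values.astype(int),
            "n_censored": et["censored"].values.astype(int),
            "survival": np.asarray(surv, dtype=float),
        }
    ).reset_index(drop=True)
    return KMCurve(table)


def logrank_test(
    groups: Sequence[str], times: Sequence[float], events: Sequence[int]
) -> tuple[float, float]:
    """Two-group log-rank test: chi-square (1 df) and p.

    Standard observed-minus-expected statistic with hypergeometric
    variance accumulated over distinct event times.
    """
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(labels)}")
    mask = groups == labels[0]
    res = _lifelines_logrank(
        times[mask], times[~mask], event_observed_A=events[mask], event_observed_B=events[~mask]
    )
    return float(res.test_statistic), float(res.p_value)


def risk_stratify(
    expr: pd.DataFrame,
    signature: pd.Series,
    survival: pd.DataFrame,
) -> dict:
    """Score, split at the median, and compare survival between risk groups.

    ``expr`` is gene x sample in the signature's training units;
    ``survival`` is indexed by sample with columns time, event. Returns a
    report with per-sample scores and groups, per-group KM curves, and the
    log-rank result.
    """
    scores = risk_score(expr, signature)
    scores = scores.loc[[s for s in scores.index if s in survival.index]]
    if len(scores) < 2:
        raise ValueError("fewer than 2 scored samples have survival records")
    groups = median_split(scores)
    surv = survival.loc[scores.index]
    km = {
        label: km_curve(surv.loc[groups == label, "time"], surv.loc[groups == label, "event"])
        for label in ("high", "low")
    }
    chi2, p = logrank_test(groups.values, surv["time"].values, surv["event"].values)
    return {
        "scores": scores,
        "groups": groups,
        "median_score": float(scores.median()),
        "n_high": int((groups == "high").sum()),
        "n_low": int((groups == "low").sum()),
        "km": km,
        "logrank_chi2": chi2,
        "logrank_p": p,
    }
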