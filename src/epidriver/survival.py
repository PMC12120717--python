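"""Pathway-activity survival stratification.

A per-sample pathway activity score is computed PLAGE-style: the genes
of the set are z-scored on log2(count+1) expression and the activity is
the leading right singular vector of that genes × samples matrix, with
its sign fixed so that activity correlates non-negatively with the mean
z-scored expression of the set.  Samples are split at the maximally
selected log-rank cutpoint and compared with Kaplan–Meier curves and
the two-group log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import ExpressionMatrix, SurvivalTable


@dataclass
class KMCurve:
    """Product-limit survival estimate at the distinct event times."""

    times: np.ndarray  # ordered distinct event times
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    events: np.ndarray


@dataclass
class ActivityResult:
    scores: pd.Series  # per-sample activity
    cutoff: float
    groups: pd.Series  # 'high' iff score > cutoff else 'low'
    logrank_chi2: float
    logrank_p: float


# ---------------------------------------------------------------------------
# PLAGE activity
# ---------------------------------------------------------------------------


def plage_score(
    expr: ExpressionMatrix | pd.DataFrame, gene_set, log_transform: bool = True
) -> pd.Series:
    """PLAGE-style pathway activity: leading right singular vector of the
    per-gene z-scored expression submatrix, sign-fixed to correlate
    non-negatively with the mean z-scored expression of the set."""
    counts = expr.counts if isinstance(expr, ExpressionMatrix) else expr
    gene_set = list(gene_set)
    if not gene_set:
        raise ValidationError("empty gene set")
    missing = [g for g in gene_set if g not in counts.index]
    if missing:
        raise ValidationError(f"genes absent from expression matrix: {missing}")
    if counts.shape[1] < 2:
        raise ValidationError("PLAGE requires >= 2 samples")
    X = counts.loc[gene_set].to_numpy(float)
    if log_transform:
        X = np.log2(X + 1)
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = gene_set[int(np.flatnonzero(sd == 0)[0])]
        raise ValidationError(f"zero-variance gene in set: {bad!r}")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    activity = vt[0]
    mean_z = Z.mean(axis=0)
    if np.dot(activity, mean_z - mean_z.mean()) < 0:
        activity = -activity
    return pd.Series(activity, index=counts.columns)


# ---------------------------------------------------------------------------
# log-rank machinery
# ---------------------------------------------------------------------------


def _logrank_oev(time, event, in_group):
    """Summed (O − E, Var) for group membership `in_group` over all
    distinct event times (hypergeometric variance)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    in_group = np.asarray(in_group, bool)
    order = np.argsort(time, kind="mergesort")
    time, event, in_group = time[order], event[order], in_group[order]
    oe = 0.0
    var = 0.0
    n = len(time)
    i = 0
    while i < n:
        t = time[i]
        j = i
        while j < n and time[j] == t:
            j += 1
        d = int(event[i:j].sum())
        if d > 0:
            at_risk = n - i
            at_risk_g = int(in_group[i:].sum())
            d_g = int(event[i:j][in_group[i:j]].sum())
            frac = at_risk_g / at_risk
            oe += d_g - d * frac
            if at_risk > 1:
                var += d * frac * (1 - frac) * (at_risk - d) / (at_risk - 1)
        i = j
    return oe, var


def logrank_test(survival: SurvivalTable, groups: pd.Series) -> tuple[float, float]:
    """Two-group log-rank test.

    ``groups`` maps every sample of the survival table to one of exactly
    two labels; returns (chi-square statistic, p from chi2 with 1 df).
    """
    groups = groups.loc[survival.data.index]
    labels = groups.unique()
    if len(labels) != 2 or groups.value_counts().min() == 0:
        raise ValidationError("log-rank test requires exactly 2 non-empty groups")
    in_group = (groups == labels[0]).to_numpy()
    oe, var = _logrank_oev(survival.time, survival.event, in_group)
    if var == 0:
        return 0.0, 1.0
    chi2 = oe * oe / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def optimal_cutoff(
    scores: pd.Series, survival: SurvivalTable, min_prop: float = 0.1
) -> float:
    """Maximally selected log-rank cutpoint.

    Candidates are the midpoints between consecutive sorted unique
    scores that leave at least ``min_prop`` of the samples on each side;
    the cutpoint maximising |standardized log-rank statistic| wins, ties
    going to the smaller cutpoint.
    """
    scores = scores.loc[survival.data.index]
    n = len(scores)
    if n < 10:
        raise ValidationError("cutpoint selection requires >= 10 samples")
    if survival.event.sum() < 1:
        raise ValidationError("cutpoint selection requires >= 1 event")
    uniq = np.unique(scores.to_numpy(float))
    if uniq.size < 2:
        raise ValidationError("all scores equal; no cutpoint exists")
    candidates = (uniq[:-1] + uniq[1:]) / 2
    s = scores.to_numpy(float)
    time, event = survival.time, survival.event
    best = None
    for c in candidates:
        high = s > c
        n_high = int(high.sum())
        if min(n_high, n - n_high) < min_prop * n:
            continue
        oe, var = _logrank_oev(time, event, high)
        z = abs(oe) / np.sqrt(var) if var > 0 else 0.0
        if best is None or z > best[0] + 1e-12:
            best = (z, c)
    if best is None:
        raise ValidationError("no candidate cutpoint satisfies the min_prop constraint")
    return float(best[1])


def km_estimate(survival: SurvivalTable) -> KMCurve:
    """Kaplan–Meier product-limit estimate.

    Samples censored exactly at an event time remain at risk for that
    time.  Reported at the distinct times with at least one event.
    """
    time = survival.time
    event = survival.event
    if len(time) < 1:
        raise ValidationError("empty survival table")
    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    times, surv, at_risk_l, events_l = [], [], [], []
    s = 1.0
    n = len(time)
    i = 0
    while i < n:
        t = time[i]
        j = i
        while j < n and time[j] == t:
            j += 1
        d = int(event[i:j].sum())
        if d > 0:
            r = n - i
            s *= 1 - d / r
            times.append(t)
            surv.append(s)
            at_risk_l.append(r)
            events_l.append(d)
        i = j
    return KMCurve(
        np.array(times), np.array(surv), np.array(at_risk_l, int), np.array(events_l, int)
    )


def stratify_by_activity(
    expr: ExpressionMatrix | pd.DataFrame,
    gene_set,
    survival: SurvivalTable,
    min_prop: float = 0.1,
) -> ActivityResult:
    """End-to-end axis stratification: PLAGE activity → maximally selected
    cutpoint → high/low groups → log-rank test."""
    scores = plage_score(expr, gene_set)
    scores = scores.loc[survival.data.index]
    cutoff = optimal_cutoff(scores, survival, min_prop=min_prop)
    groups = pd.Series(
        np.where(scores > cutoff, "high", "low"), index=scores.index
    )
    chi2, p = logrank_test(survival, groups)
    return ActivityResult(scores, cutoff, groups, chi2, p)
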