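"""Clinical prediction-model validation battery.

Discrimination (ROC AUC with a DeLong 95% CI), overall accuracy (Brier
score), calibration (quantile-binned reliability table and the
predicted/observed event ratio with a bootstrap CI), cutoff diagnostics
(sensitivity/specificity/PPV/NPV and the rates clinicians actually quote:
events among predicted-negatives, non-events among predicted-positives),
risk-group stratification, and decision-curve analysis.

Conventions: predicted probabilities live in [0, 1]; outcomes are 0/1; a
patient is predicted positive iff probability >= cutoff (ties count as
positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScoredOutcomes",
    "RiskGroupTable",
    "NetBenefitCurve",
    "auc",
    "brier",
    "calibration_table",
    "predicted_observed_ratio",
    "cutoff_metrics",
    "assign_risk_group",
    "risk_group_table",
    "decision_curve",
    "pool_risk_table",
    "RISK_GROUP_EDGES",
    "RISK_GROUP_LABELS",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class ScoredOutcomes:
    """Paired predicted probabilities and observed binary outcomes."""

    probabilities: np.ndarray
    outcomes: np.ndarray
    ids: Sequence | None = None

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.outcomes = np.asarray(self.outcomes, dtype=int)
        if self.probabilities.shape != self.outcomes.shape:
            raise ValueError("probabilities and outcomes differ in length")
        if self.probabilities.ndim != 1:
            raise ValueError("expected 1-d sequences")
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.all(np.isin(self.outcomes, (0, 1))):
            raise ValueError("outcomes must be binary 0/1")

    def __len__(self) -> int:
        return len(self.outcomes)

    @property
    def prevalence(self) -> float:
        return float(self.outcomes.mean())


# -- discrimination -------------------------------------------------------------


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auc(scored: ScoredOutcomes, ci_method: str = "delong") -> dict:
    """ROC area with a 95% CI.

    The point estimate is the all-pairs concordance with half credit for
    ties, identical to trapezoidal integration of the empirical ROC curve.
    The default CI is DeLong's; ``ci_method="bootstrap"`` uses 2,000
    percentile resamples (seeded).
    """
    y = scored.outcomes
    p = scored.probabilities
    pos = p[y == 1]
    neg = p[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("AUC needs both outcome classes present")
    all_ranks = _midranks(p)
    pos_ranks = all_ranks[y == 1]
    estimate = (pos_ranks.sum() - m * (m + 1) / 2) / (m * n)
    if ci_method == "delong":
        # structural components via midranks (DeLong, DeLong & Clarke-Pearson)
        rx = _midranks(pos)
        ry = _midranks(neg)
        v10 = (all_ranks[y == 1] - rx) / n
        v01 = 1.0 - (all_ranks[y == 0] - ry) / m
        s10 = v10.var(ddof=1) if m > 1 else 0.0
        s01 = v01.var(ddof=1) if n > 1 else 0.0
        se = float(np.sqrt(s10 / m + s01 / n))
        lo, hi = estimate - Z_95 * se, estimate + Z_95 * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(0)
        reps = []
        idx = np.arange(len(y))
        for _ in range(2000):
            b = rng.choice(idx, size=len(idx), replace=True)
            yb, pb = y[b], p[b]
            if yb.min() == yb.max():
                continue
            mb = int(yb.sum())
            rb = _midranks(pb)[yb == 1]
            reps.append((rb.sum() - mb * (mb + 1) / 2) / (mb * (len(yb) - mb)))
        lo, hi = np.percentile(reps, [2.5, 97.5])
        se = float(np.std(reps, ddof=1))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return {
        "auc": float(estimate),
        "ci_low": float(max(0.0, lo)),
        "ci_high": float(min(1.0, hi)),
        "se": se,
        "n_pos": m,
        "n_neg": n,
    }


def brier(scored: ScoredOutcomes) -> float:
    """Mean squared difference between prediction and outcome."""
    if len(scored) == 0:
        raise ValueError("empty input")
    return float(np.mean((scored.probabilities - scored.outcomes) ** 2))


# -- calibration -----------------------------------------------------------------


def calibration_table(scored: ScoredOutcomes, n_bins: int = 10) -> pd.DataFrame:
    """Quantile-binned reliability table.

    Bins are deciles of the predicted probabilities by default; bins whose
    quantile boundaries coincide are merged, so ties never split a bin.
    Each row reports mean predicted probability, observed event rate, count
    and an exact (Clopper–Pearson) 95% CI for the observed rate.
    """
    if len(scored) == 0:
        raise ValueError("empty input")
    p = scored.probabilities
    y = scored.outcomes
    edges = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)))
    if len(edges) == 1:  # all predictions identical: one bin
        edges = np.array([edges[0], edges[0]])
    bin_idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        mask = bin_idx == b
        count = int(mask.sum())
        if count == 0:
            continue
        events = int(y[mask].sum())
        rate = events / count
        lo = stats.beta.ppf(0.025, events, count - events + 1) if events > 0 else 0.0
        hi = (
            stats.beta.ppf(0.975, events + 1, count - events)
            if events < count
            else 1.0
        )
        rows.append(
            {
                "bin_low": float(edges[b]),
                "bin_high": float(edges[b + 1]),
                "mean_predicted": float(p[mask].mean()),
                "observed_rate": rate,
                "count": count,
                "events": events,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    table = pd.DataFrame(rows)
    assert table["count"].sum() == len(scored)
    return table


def predicted_observed_ratio(
    scored: ScoredOutcomes, n_boot: int = 2000, seed: int = 0
) -> dict:
    """(Sum of predictions) / (observed events), with a bootstrap 95% CI.

    Calibration-in-the-large: 1 means the model predicts as many events as
    were observed.  The CI resamples patients (percentile method).
    """
    events = int(scored.outcomes.sum())
    if events == 0:
        raise ValueError("no observed events; ratio undefined")
    ratio = float(scored.probabilities.sum() / events)
    rng = np.random.default_rng(seed)
    n = len(scored)
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        e = scored.outcomes[idx].sum()
        if e == 0:
            continue
        reps.append(scored.probabilities[idx].sum() / e)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return {"ratio": ratio, "ci_low": float(lo), "ci_high": float(hi)}


# -- cutoff diagnostics ----------------------------------------------------------


def cutoff_metrics(scored: ScoredOutcomes, cutoff: float) -> dict:
    """All 2x2-table quantities at one decision cutoff.

    Predicted positive iff probability >= cutoff.  Besides sensitivity,
    specificity, PPV and NPV, reports the event rate among
    predicted-negatives (the false-negative rate a rule-out test quotes)
    and the non-event fraction among predicted-positives (false discovery).
    Undefined ratios (empty denominators) are returned as NaN.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    pred_pos = scored.probabilities >= cutoff
    y = scored.outcomes.astype(bool)
    tp = int(np.sum(pred_pos & y))
    fp = int(np.sum(pred_pos & ~y))
    fn = int(np.sum(~pred_pos & y))
    tn = int(np.sum(~pred_pos & ~y))

    def ratio(a: int, b: int) -> float:
        return a / b if b > 0 else float("nan")

    return {
        "cutoff": cutoff,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "fn_rate_predicted_negative": ratio(fn, fn + tn),
        "false_discovery_predicted_positive": ratio(fp, tp + fp),
    }


# -- risk groups -----------------------------------------------------------------

#: half-open probability intervals [low, high) per risk group; the
#: low/intermediate boundary sits at 0.05 so that "<5% risk" pools exactly
#: the first two groups.
RISK_GROUP_EDGES = (0.0, 0.01, 0.05, 0.15, 0.25, 1.0)
RISK_GROUP_LABELS = ("very_low", "low", "intermediate", "high_intermediate", "high")


def assign_risk_group(p: float) -> str:
    """Map a predicted probability to its risk-group label."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    for label, lo, hi in zip(RISK_GROUP_LABELS, RISK_GROUP_EDGES, RISK_GROUP_EDGES[1:]):
        if p < hi:
            return label
    return RISK_GROUP_LABELS[-1]  # p == 1.0


@dataclass
class RiskGroupTable:
    """Per-group counts, events and observed prevalence.

    Groups partition [0, 1]; counts always sum to the cohort size.
    """

    labels: tuple[str, ...] = RISK_GROUP_LABELS
    edges: tuple[float, ...] = RISK_GROUP_EDGES
    counts: tuple[int, ...] = ()
    events: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.labels) + 1 != len(self.edges):
            raise ValueError("edges must bracket the labels")
        if len(self.counts) != len(self.labels) or len(self.events) != len(self.labels):
            raise ValueError("counts/events must align with labels")
        for c, e in zip(self.counts, self.events):
            if e > c:
                raise ValueError("more events than patients in a group")

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def prevalence(self, label: str) -> float:
        i = self.labels.index(label)
        return self.events[i] / self.counts[i] if self.counts[i] else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.labels,
                "prob_low": self.edges[:-1],
                "prob_high": self.edges[1:],
                "count": self.counts,
                "events": self.events,
                "prevalence": [
                    e / c if c else float("nan")
                    for c, e in zip(self.counts, self.events)
                ],
            }
        )


def risk_group_table(scored: ScoredOutcomes) -> RiskGroupTable:
    """Stratify a scored cohort into the standard risk groups."""
    if len(scored) == 0:
        raise ValueError("empty input")
    counts = []
    events = []
    for lo, hi in zip(RISK_GROUP_EDGES, RISK_GROUP_EDGES[1:]):
        last = hi == RISK_GROUP_EDGES[-1]
        mask = (scored.probabilities >= lo) & (
            (scored.probabilities <= hi) if last else (scored.probabilities < hi)
        )
        counts.append(int(mask.sum()))
        events.append(int(scored.outcomes[mask].sum()))
    return RiskGroupTable(counts=tuple(counts), events=tuple(events))


def pool_risk_table(table: RiskGroupTable, boundary: float) -> dict:
    """Pool risk groups below/above a boundary that coincides with a group edge.

    Reports the cohort fraction below the boundary, the event rate among the
    pooled-below patients (the rule-out false-negative rate), and the
    non-event fraction among pooled-above patients (false discovery above).
    """
    if boundary not in table.edges:
        raise ValueError(
            f"boundary {boundary} is not a group edge (edges: {table.edges})"
        )
    split = table.edges.index(boundary)
    n_below = sum(table.counts[:split])
    e_below = sum(table.events[:split])
    n_above = sum(table.counts[split:])
    e_above = sum(table.events[split:])
    total = table.total
    return {
        "boundary": boundary,
        "n_below": n_below,
        "events_below": e_below,
        "n_above": n_above,
        "events_above": e_above,
        "proportion_below": n_below / total if total else float("nan"),
        "fn_rate_below": e_below / n_below if n_below else float("nan"),
        "false_discovery_above": (n_above - e_above) / n_above
        if n_above
        else float("nan"),
    }


# -- decision curves --------------------------------------------------------------


@dataclass
class NetBenefitCurve:
    """Net benefit across threshold probabilities for model / treat-all / none."""

    thresholds: np.ndarray
    model: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.model = np.asarray(self.model, dtype=float)
        self.treat_all = np.asarray(self.treat_all, dtype=float)
        if self.treat_none is None:
            self.treat_none = np.zeros_like(self.thresholds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "net_benefit_model": self.model,
                "net_benefit_treat_all": self.treat_all,
                "net_benefit_treat_none": self.treat_none,
            }
        )


def decision_curve(
    scored: ScoredOutcomes, thresholds: Sequence[float] | np.ndarray
) -> NetBenefitCurve:
    """Decision-curve analysis.

    Net benefit of the model at threshold t is TP/n - (FP/n) * t/(1-t) with
    predicted-positive iff probability >= t; treat-all is the same quantity
    when everyone is treated; treat-none is identically zero.
    """
    t = np.asarray(thresholds, dtype=float)
    if np.any((t <= 0) | (t >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(scored)
    if n == 0:
        raise ValueError("empty input")
    y = scored.outcomes
    p = scored.probabilities
    pi = y.mean()
    odds = t / (1 - t)
    pred_pos = p[None, :] >= t[:, None]
    tp = (pred_pos & (y == 1)[None, :]).sum(axis=1) / n
    fp = (pred_pos & (y == 0)[None, :]).sum(axis=1) / n
    model = tp - fp * odds
    treat_all = pi - (1 - pi) * odds
    return NetBenefitCurve(t, model, treat_all)
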