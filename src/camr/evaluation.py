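"""Survival-prediction metrics and alignment diagnostics.

Harrell's concordance index and a cumulative/dynamic AUC at a time
threshold score the risk predictions; a median-risk split with a two-group
log-rank test (via lifelines) checks stratification; and the mean pairwise
distance between per-modality centroids of the invariant representations
quantifies the residual modality gap in the common subspace.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from lifelines.statistics import logrank_test as _lifelines_logrank
from sklearn.metrics import roc_auc_score

from .data_model import SurvivalLabels


@dataclasses.dataclass
class EvaluationReport:
    """Metrics for one scored cohort."""

    cindex: float
    auc: float
    n_comparable_pairs: int
    risk_groups: list[str]
    logrank_chi2: float
    logrank_p: float
    alignment_distance: float | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def concordance_index(risk, labels: SurvivalLabels) -> tuple[float, int]:
    """Harrell's C-index.

    A pair (i, j) with T_i < T_j is comparable iff the earlier patient had
    an event. A comparable pair scores 1 if risk_i > risk_j, 0.5 on a risk
    tie, 0 otherwise. Returns (concordant fraction, comparable-pair count).
    """
    r = np.asarray(risk, dtype=float).reshape(-1)
    t, e = labels.time, labels.event
    if len(r) != len(labels):
        raise ValueError("risk and labels lengths differ")
    if len(r) < 2 or e.sum() == 0:
        raise ValueError("need >= 2 patients and >= 1 event")
    # comparable[i, j]: T_i < T_j and E_i = 1
    earlier = t[:, None] < t[None, :]
    comparable = earlier & (e[:, None] == 1)
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    higher = r[:, None] > r[None, :]
    tied = r[:, None] == r[None, :]
    score = (comparable & higher).sum() + 0.5 * (comparable & tied).sum()
    return float(score / n_pairs), n_pairs


def time_threshold_auc(risk, labels: SurvivalLabels,
                       t_star: float | None = None) -> float:
    """Cumulative-case / dynamic-control AUC at time t_star.

    Cases are patients with an observed event at or before t_star, controls
    are patients still at risk beyond t_star; patients censored at or before
    t_star are excluded. Defaults t_star to the median observed time.
    """
    r = np.asarray(risk, dtype=float).reshape(-1)
    t, e = labels.time, labels.event
    if t_star is None:
        t_star = float(np.median(t))
    if t_star <= 0:
        raise ValueError("t_star must be positive")
    case = (t <= t_star) & (e == 1)
    control = t > t_star
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError(f"no cases or no controls at t*={t_star}")
    keep = case | control
    return float(roc_auc_score(case[keep].astype(int), r[keep]))


def median_risk_split(risk) -> list[str]:
    """Split patients at the median risk: above -> "high", at or below ->
    "low" (ties go low so the rule is deterministic with discretized risks)."""
    r = np.asarray(risk, dtype=float).reshape(-1)
    if len(r) < 2:
        raise ValueError("need at least two patients to split")
    med = np.median(r)
    return ["high" if x > med else "low" for x in r]


def logrank_test(groups, labels: SurvivalLabels) -> tuple[float, float]:
    """Two-group log-rank test (1 df); returns (chi2, p)."""
    g = np.asarray(groups)
    names = np.unique(g)
    if len(names) != 2:
        raise ValueError(f"need exactly two non-empty groups, got {list(names)}")
    a, b = (g == names[0]), (g == names[1])
    if labels.event.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = _lifelines_logrank(labels.time[a], labels.time[b],
                             event_observed_A=labels.event[a],
                             event_observed_B=labels.event[b])
    return float(res.test_statistic), float(res.p_value)


def alignment_distance(h_pc, h_gc, h_cc) -> float:
    """Mean Euclidean distance between per-modality centroids of the
    invariant representations: 0 iff all three centroids coincide."""
    mats = [np.asarray(h, dtype=float) for h in (h_pc, h_gc, h_cc)]
    if len({m.shape for m in mats}) != 1:
        raise ValueError("invariant representation matrices must share a shape")
    cents = [m.mean(axis=0) for m in mats]
    pairs = [(0, 1), (0, 2), (1, 2)]
    return float(np.mean([np.linalg.norm(cents[i] - cents[j]) for i, j in pairs]))


def evaluate_risk(risk, labels: SurvivalLabels,
                  invariant_reps=None) -> EvaluationReport:
    """Bundle all metrics for a scored cohort into one report."""
    c, n_pairs = concordance_index(risk, labels)
    try:
        auc = time_threshold_auc(risk, labels)
    except ValueError:
        auc = float("nan")
    groups = median_risk_split(risk)
    try:
        chi2, p = logrank_test(groups, labels)
    except ValueError:
        chi2, p = float("nan"), float("nan")
    dist = alignment_distance(*invariant_reps) if invariant_reps is not None else None
    return EvaluationReport(cindex=c, auc=auc, n_comparable_pairs=n_pairs,
                            risk_groups=groups, logrank_chi2=chi2, logrank_p=p,
                            alignment_distance=dist)
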