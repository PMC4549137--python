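"""Edge-wise group statistics, feature selection and behavior correlations.

Each edge's patient and control connectivity values are compared with a
two-tailed two-sample t-test (pooled-variance Student by default, Welch by
flag).  Feature selection keeps edges with p strictly below an uncorrected
threshold (default 0.001) — deliberately uncorrected, since it is a
feature-selection step rather than an inference; the expected
false-positive count (threshold x number of edges) is reported as context.
Edge-behavior associations are Pearson correlations over patients only.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

BEHAVIOR_COVARIATES = ("sara", "cag_expansion", "years_of_symptoms")


@dataclass
class EdgeStat:
    edge: int                 # canonical edge index
    t: float
    p: float                  # two-tailed
    direction: str            # "increase" | "decrease" (patients vs controls)
    mean_patient: float
    mean_control: float


@dataclass
class SelectionResult:
    threshold: float
    selected: list[int]                 # edge ids, ascending by (p, edge id)
    stats: pd.DataFrame                 # full per-edge table
    expected_false_positives: float = field(init=False)

    def __post_init__(self):
        self.expected_false_positives = self.threshold * len(self.stats)


def edge_ttest(patient_values: np.ndarray, control_values: np.ndarray,
               edge: int = 0, welch: bool = False) -> EdgeStat:
    """Two-tailed two-sample t-test on one edge.

    Student pooled-variance by default (df = n1 + n2 - 2); the direction
    label follows the sign of (patient mean - control mean).
    """
    x = np.asarray(patient_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 values per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("zero pooled variance on this edge")
    res = sp_stats.ttest_ind(x, y, equal_var=not welch)
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t):
        raise ValueError("zero pooled variance on this edge")
    diff = x.mean() - y.mean()
    return EdgeStat(edge=edge, t=t, p=p,
                    direction="increase" if diff >= 0 else "decrease",
                    mean_patient=float(x.mean()),
                    mean_control=float(y.mean()))


def edge_ttests(patient_edges: np.ndarray, control_edges: np.ndarray,
                welch: bool = False) -> pd.DataFrame:
    """Vectorized t-tests over all edges.

    ``patient_edges``/``control_edges`` are subjects x edges arrays.
    Returns a DataFrame with columns edge, t, p, direction, mean_patient,
    mean_control.
    """
    X = np.asarray(patient_edges, dtype=float)
    Y = np.asarray(control_edges, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError("edge tables must be 2-D with matching edge counts")
    if X.shape[0] < 2 or Y.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    res = sp_stats.ttest_ind(X, Y, axis=0, equal_var=not welch)
    mean_p = X.mean(axis=0)
    mean_c = Y.mean(axis=0)
    diff = mean_p - mean_c
    return pd.DataFrame({
        "edge": np.arange(X.shape[1]),
        "t": res.statistic,
        "p": res.pvalue,
        "direction": np.where(diff >= 0, "increase", "decrease"),
        "mean_patient": mean_p,
        "mean_control": mean_c,
    })


def select_edges(stats: pd.DataFrame, threshold: float = 0.001
                 ) -> SelectionResult:
    """Keep edges with p strictly below ``threshold`` (no correction).

    The result is sorted ascending by p, ties broken by edge id, so the
    report order is deterministic.
    """
    if not {"edge", "p"} <= set(stats.columns):
        raise ValueError("stats table needs 'edge' and 'p' columns")
    hits = stats[stats["p"] < threshold].sort_values(
        ["p", "edge"], kind="mergesort")
    return SelectionResult(threshold=float(threshold),
                           selected=[int(e) for e in hits["edge"]],
                           stats=stats)


@dataclass
class BehavioralAssoc:
    edge: int
    covariate: str
    r: float
    p: float                  # two-tailed, t approximation with df = n - 2
    n: int


def behavior_correlation(edge_values: np.ndarray, covariate_values: np.ndarray,
                         edge: int = 0, covariate: str = "sara"
                         ) -> BehavioralAssoc:
    """Pearson correlation between one edge and one clinical covariate.

    Computed over patients only (controls have no severity scores).
    """
    x = np.asarray(edge_values, dtype=float)
    y = np.asarray(covariate_values, dtype=float)
    if x.size != y.size:
        raise ValueError("edge and covariate vectors differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 patients")
    if np.ptp(y) == 0:
        raise ValueError(f"covariate {covariate!r} is constant")
    if np.ptp(x) == 0:
        raise ValueError("edge values are constant")
    res = sp_stats.pearsonr(x, y)
    return BehavioralAssoc(edge=edge, covariate=covariate,
                           r=float(res.statistic), p=float(res.pvalue),
                           n=int(x.size))


def behavior_correlations(patient_edges: np.ndarray, selected: list[int],
                          covariates: pd.DataFrame) -> pd.DataFrame:
    """Edge-behavior Pearson correlations for every selected edge x covariate."""
    rows = []
    for name in BEHAVIOR_COVARIATES:
        if name not in covariates.columns:
            continue
        y = covariates[name].to_numpy(dtype=float)
        for e in selected:
            assoc = behavior_correlation(patient_edges[:, e], y,
                                         edge=e, covariate=name)
            rows.append({"edge": e, "covariate": name,
                         "r": assoc.r, "p": assoc.p, "n": assoc.n})
    return pd.DataFrame(rows, columns=["edge", "covariate", "r", "p", "n"])
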