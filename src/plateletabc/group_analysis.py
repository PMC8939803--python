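"""Group-level analysis of per-subject parameter estimates.

Which of the seven model parameters separate the clinical groups?  Each
parameter is tested with the rank-based Kruskal-Wallis H-test (the null
being equal group medians), globally across all groups and post hoc for
every group pair, with Benjamini-Hochberg control of the false discovery
rate within each comparison's family of seven tests.  Parameters flagged
significant are the "discriminating parameters"; the pathology test then
classifies a subject as diseased or healthy by whichever group median its
estimate of a discriminating parameter is nearer to.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulator import PARAM_NAMES

__all__ = [
    "GroupTestResult",
    "kruskal_wallis",
    "bh_adjust",
    "identify_discriminating_parameters",
    "discriminating_parameters",
    "classify_pathology",
    "pathology_test",
    "sensitivity_specificity",
]


@dataclasses.dataclass(frozen=True)
class GroupTestResult:
    parameter: str
    comparison: str            # "all" or "groupA|groupB"
    statistic: float
    p_value: float
    p_adjusted: float
    significant: bool


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H statistic (tie-corrected) and chi-square p-value."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        raise ValueError("Kruskal-Wallis undefined: all values identical")
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def identify_discriminating_parameters(
    map_table: pd.DataFrame,
    alpha: float = 0.05,
    group_col: str = "group",
    parameters: Sequence[str] = PARAM_NAMES,
) -> list[GroupTestResult]:
    """Kruskal-Wallis screening of every parameter, global and pairwise.

    ``map_table`` holds one row per subject with a group label column and
    one column per parameter (typically the MAP estimates).  BH adjustment
    is applied within each comparison across the family of parameters
    (matching a per-column correction); significance is strict
    ``p_adjusted < alpha``.
    """
    if group_col not in map_table.columns:
        raise ValueError(f"missing group column {group_col!r}")
    groups = sorted(map_table[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    counts = map_table[group_col].value_counts()
    if counts.min() < 2:
        raise ValueError("every group needs at least two subjects")

    comparisons: list[tuple[str, list[str]]] = [("all", groups)]
    comparisons += [(f"{a}|{b}", [a, b]) for a, b in itertools.combinations(groups, 2)]

    results: list[GroupTestResult] = []
    for comp_name, comp_groups in comparisons:
        stats_p = []
        for param in parameters:
            values = [
                map_table.loc[map_table[group_col] == g, param].to_numpy()
                for g in comp_groups
            ]
            stats_p.append(kruskal_wallis(values))
        p_adj = bh_adjust([p for _, p in stats_p])
        for param, (h, p), pa in zip(parameters, stats_p, p_adj):
            results.append(
                GroupTestResult(
                    parameter=param,
                    comparison=comp_name,
                    statistic=h,
                    p_value=p,
                    p_adjusted=float(pa),
                    significant=bool(pa < alpha),
                )
            )
    return results


def discriminating_parameters(results: Sequence[GroupTestResult]) -> dict[str, list[str]]:
    """Comparison -> list of significant parameters (the Table-2-style view)."""
    out: dict[str, list[str]] = {}
    for r in results:
        out.setdefault(r.comparison, [])
        if r.significant:
            out[r.comparison].append(r.parameter)
    return out


def classify_pathology(
    value: float,
    healthy_median: float,
    disease_median: float,
    healthy_label: str = "healthy",
    disease_label: str = "disease",
) -> str:
    """Nearest-median assignment of one subject's discriminating-parameter value.

    Equidistant values are assigned to the healthy group (conservative
    tie-break).
    """
    if not (np.isfinite(healthy_median) and np.isfinite(disease_median)):
        raise ValueError("medians must be finite")
    if healthy_median == disease_median:
        raise ValueError("pathology test undefined: equal group medians")
    if abs(value - healthy_median) <= abs(value - disease_median):
        return healthy_label
    return disease_label


def pathology_test(
    map_table: pd.DataFrame,
    parameter: str,
    healthy_label: str,
    disease_label: str,
    group_col: str = "group",
    leave_one_out: bool = False,
) -> pd.DataFrame:
    """Run the nearest-median test for one healthy-vs-disease pair.

    Medians are computed in-sample by default; ``leave_one_out`` recomputes
    the medians without the subject under test, avoiding leakage.
    Returns a frame with columns subject index, truth and prediction.
    """
    sel = map_table[map_table[group_col].isin([healthy_label, disease_label])]
    if sel.empty:
        raise ValueError("no subjects in the requested groups")
    rows = []
    for idx, row in sel.iterrows():
        rest = sel.drop(idx) if leave_one_out else sel
        med_h = rest.loc[rest[group_col] == healthy_label, parameter].median()
        med_d = rest.loc[rest[group_col] == disease_label, parameter].median()
        pred = classify_pathology(
            row[parameter], med_h, med_d, healthy_label, disease_label
        )
        rows.append({"subject": idx, "truth": row[group_col], "prediction": pred})
    return pd.DataFrame(rows)


def sensitivity_specificity(
    predictions: Sequence[str],
    truth: Sequence[str],
    disease_label: str,
) -> tuple[float, float]:
    """TP/(TP+FN) over diseased subjects and TN/(TN+FP) over the rest."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must have equal length")
    is_disease = truth == disease_label
    if not is_disease.any() or is_disease.all():
        raise ValueError("both classes must be present in the truth labels")
    pred_disease = predictions == disease_label
    sensitivity = float((pred_disease & is_disease).sum() / is_disease.sum())
    specificity = float((~pred_disease & ~is_disease).sum() / (~is_disease).sum())
    return sensitivity, specificity
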