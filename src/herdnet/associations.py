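"""Spearman rank-correlation association of activities and attributes with
network indices.

Three analysis data sets are assembled from the index table:

1. ``global_vs_activity`` — one row per network: the three global indices
   plus seven binary activity indicators (exactly one is 1 per row);
2. ``local_vs_activity`` — one row per (network, vertex): the four
   centralities plus the same indicators;
3. ``attribute_vs_centrality`` — the local rows augmented with the
   vertex's age and gender (1 = female, 2 = male), analyzed one activity
   at a time.

Every (variable, index) pair is tested with a two-tailed Spearman rank
correlation: mid-ranks for ties, p from the t approximation
t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom (an exact
permutation p is available for tiny samples).  Significance is flagged at
the 0.05 and 0.01 levels; no multiple-testing correction is applied by
default (a Holm adjustment can be switched on).  Pairs with a constant
variable (e.g. a centrality that never varies) are reported as missing
with the reason logged.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .indices import GLOBAL_INDICES, LOCAL_INDICES, IndexTable
from .records import ACTIVITIES, Animal, ValidationError, roster_dataframe

logger = logging.getLogger(__name__)

SIG_NONE = "ns"
SIG_05 = "p<0.05"
SIG_01 = "p<0.01"
SIG_MISSING = "missing"


@dataclass(frozen=True)
class AssociationResult:
    """One Spearman test: variable vs index (optionally within an activity)."""

    dataset: str
    variable: str
    index: str
    activity_context: str | None
    n: int
    rho: float
    p: float
    significance: str


@dataclass(frozen=True)
class AnalysisDatasets:
    """The three assembled data sets (see module docstring)."""

    global_vs_activity: pd.DataFrame
    local_vs_activity: pd.DataFrame
    attribute_vs_centrality: pd.DataFrame


def spearman(
    x, y, *, method: str = "t", max_exact_n: int = 10
) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks and a two-tailed p-value.

    rho is the Pearson correlation of the mid-ranks (average ranks for
    ties).  With ``method="t"`` the p-value comes from the t statistic
    rho*sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom; |rho| = 1 gives
    p = 0.  ``method="exact"`` enumerates all permutations (n <= 10 only).
    Raises :class:`ValidationError` on constant input (undefined ranks
    correlation) or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman requires two equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise ValidationError(f"spearman requires n >= 3, got n={n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("spearman is undefined for a constant vector")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rho = _pearson(rx, ry)
    if method == "exact":
        if n > max_exact_n:
            raise ValidationError(
                f"exact permutation p only supported for n <= {max_exact_n}"
            )
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = _pearson(rx, np.asarray(perm))
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        return rho, count / total
    if method != "t":
        raise ValidationError(f"unknown p-value method {method!r}")
    if abs(rho) >= 1.0 - 1e-15:
        return float(np.sign(rho)), 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    return float(a @ b) / denom


def significance_flag(p: float) -> str:
    if not np.isfinite(p):
        return SIG_MISSING
    if p < 0.01:
        return SIG_01
    if p < 0.05:
        return SIG_05
    return SIG_NONE


# ---------------------------------------------------------------------------
# Data set assembly


def assemble_datasets(
    index_table: IndexTable,
    roster: list[Animal],
    *,
    include_empty_networks: bool = True,
) -> AnalysisDatasets:
    """Build the three analysis data sets from the index table.

    ``include_empty_networks`` keeps networks with no edges as cases at
    their degenerate index values (the default; rare activities then
    contribute strong negative density contrast rather than near-empty
    samples).
    """
    glob = index_table.globals_.copy()
    loc = index_table.locals_.copy()
    roster_df = roster_dataframe(roster)
    unknown = set(loc["animal_id"].unique()) - set(roster_df.index)
    if unknown:
        raise ValidationError(f"index table references animals not on roster: {sorted(unknown)}")
    if not include_empty_networks:
        nonempty = glob.loc[glob["density"] > 0, "network_id"]
        glob = glob[glob["network_id"].isin(nonempty)].reset_index(drop=True)
        loc = loc[loc["network_id"].isin(nonempty)].reset_index(drop=True)
    for act in ACTIVITIES:
        indicator = (glob["activity"] == act).astype(np.int8)
        glob[f"is_{act}"] = indicator
    for act in ACTIVITIES:
        loc[f"is_{act}"] = (loc["activity"] == act).astype(np.int8)
    attr = loc[["network_id", "activity", "period", "animal_id", *LOCAL_INDICES]].merge(
        roster_df, left_on="animal_id", right_index=True, how="left"
    )
    return AnalysisDatasets(
        global_vs_activity=glob,
        local_vs_activity=loc,
        attribute_vs_centrality=attr,
    )


# ---------------------------------------------------------------------------
# Association runs


def _test_pair(
    dataset: str,
    variable: str,
    index: str,
    x: np.ndarray,
    y: np.ndarray,
    activity_context: str | None = None,
    method: str = "t",
) -> AssociationResult:
    try:
        rho, p = spearman(x, y, method=method)
        flag = significance_flag(p)
    except ValidationError as exc:
        logger.warning(
            "dataset %s: %s vs %s%s reported missing (%s)",
            dataset,
            variable,
            index,
            f" [{activity_context}]" if activity_context else "",
            exc,
        )
        rho, p, flag = float("nan"), float("nan"), SIG_MISSING
    return AssociationResult(
        dataset=dataset,
        variable=variable,
        index=index,
        activity_context=activity_context,
        n=len(x),
        rho=rho,
        p=p,
        significance=flag,
    )


def run_associations(
    datasets: AnalysisDatasets,
    *,
    method: str = "t",
    holm: bool = False,
) -> list[AssociationResult]:
    """All Spearman tests for the three data sets.

    Default full design: 7 x 3 = 21 global, 7 x 4 = 28 local, and
    7 x 2 x 4 = 56 attribute results.  ``holm`` applies a Holm step-down
    adjustment to the p-values within each data set (off by default).
    """
    results: list[AssociationResult] = []
    glob = datasets.global_vs_activity
    for act in ACTIVITIES:
        x = glob[f"is_{act}"].to_numpy()
        for index in GLOBAL_INDICES:
            results.append(
                _test_pair(
                    "global_vs_activity", act, index, x,
                    glob[index].to_numpy(), method=method,
                )
            )
    loc = datasets.local_vs_activity
    for act in ACTIVITIES:
        x = loc[f"is_{act}"].to_numpy()
        for index in LOCAL_INDICES:
            results.append(
                _test_pair(
                    "local_vs_activity", act, index, x,
                    loc[index].to_numpy(), method=method,
                )
            )
    attr = datasets.attribute_vs_centrality
    for act in ACTIVITIES:
        sub = attr[attr["activity"] == act]
        for variable in ("age", "gender"):
            x = sub[variable].to_numpy(dtype=float)
            for index in LOCAL_INDICES:
                results.append(
                    _test_pair(
                        "attribute_vs_centrality", variable, index,
                        x, sub[index].to_numpy(),
                        activity_context=act, method=method,
                    )
                )
    if holm:
        results = _holm_adjust(results)
    return results


def _holm_adjust(results: list[AssociationResult]) -> list[AssociationResult]:
    adjusted: list[AssociationResult] = []
    for dataset in sorted({r.dataset for r in results}):
        grp = [r for r in results if r.dataset == dataset]
        tested = [r for r in grp if np.isfinite(r.p)]
        order = np.argsort([r.p for r in tested])
        m = len(tested)
        adj = {}
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * tested[idx].p))
            adj[id(tested[idx])] = running
        for r in grp:
            if id(r) in adj:
                p = adj[id(r)]
                adjusted.append(
                    AssociationResult(
                        r.dataset, r.variable, r.index, r.activity_context,
                        r.n, r.rho, p, significance_flag(p),
                    )
                )
            else:
                adjusted.append(r)
    return adjusted


def results_dataframe(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dataset": r.dataset,
                "variable": r.variable,
                "index": r.index,
                "activity_context": r.activity_context or "",
                "n": r.n,
                "rho": r.rho,
                "p": r.p,
                "significance": r.significance,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Correlogram tables


def _cell(rho: float, significance: str) -> str:
    if significance == SIG_MISSING or not np.isfinite(rho):
        return "NA"
    marker = {SIG_01: "**", SIG_05: "*"}.get(significance, "")
    return f"{rho:.2f}{marker}"


def correlogram_tables(results: list[AssociationResult]) -> dict[str, pd.DataFrame]:
    """Matrix-form correlograms: signed rho with */** significance markers.

    Keys: ``global_vs_activity`` and ``local_vs_activity`` (rows = indices,
    columns = activities) and ``age`` / ``gender`` (rows = centralities,
    columns = activity context).
    """
    tables: dict[str, pd.DataFrame] = {}
    for dataset, rows in (
        ("global_vs_activity", GLOBAL_INDICES),
        ("local_vs_activity", LOCAL_INDICES),
    ):
        grp = {
            (r.index, r.variable): _cell(r.rho, r.significance)
            for r in results
            if r.dataset == dataset
        }
        tables[dataset] = pd.DataFrame(
            [[grp.get((idx, act), "NA") for act in ACTIVITIES] for idx in rows],
            index=list(rows),
            columns=list(ACTIVITIES),
        )
    for variable in ("age", "gender"):
        grp = {
            (r.index, r.activity_context): _cell(r.rho, r.significance)
            for r in results
            if r.dataset == "attribute_vs_centrality" and r.variable == variable
        }
        if grp:
            tables[variable] = pd.DataFrame(
                [[grp.get((idx, act), "NA") for act in ACTIVITIES] for idx in LOCAL_INDICES],
                index=list(LOCAL_INDICES),
                columns=list(ACTIVITIES),
            )
    return tables


def render_correlogram(table: pd.DataFrame) -> str:
    """Fixed-width text rendering of a correlogram table."""
    return table.to_string(justify="right")
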