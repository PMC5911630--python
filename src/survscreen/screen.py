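"""The biosignature screen: per gene, per clinical subgroup, stratify at
the median, fit survival, score, classify -- plus tumor/normal
expression comparison and target ranking.

Every cell of the screen table runs the same pipeline:
``select_subgroup -> median_split -> cox_fit (log-rank p) -> hr_score ->
classify``.  Degenerate cells (constant marker, no events, monotone
likelihood) are recorded as failed rows with machine-readable reason
codes instead of being dropped, so screens over many genes degrade
gracefully.  The p-value fed to the score is the log-rank p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .scoring import classify_score, hr_score
from .stratify import SubgroupSpec, median_split, select_subgroup
from .survival import cox_fit, restrict_horizon

__all__ = [
    "ExpressionComparison",
    "BiosignatureScreen",
    "run_screen",
    "compare_expression",
    "rank_targets",
    "SCREEN_COLUMNS",
]

logger = logging.getLogger(__name__)

SCREEN_COLUMNS = [
    "gene",
    "subgroup",
    "n",
    "n_events",
    "hr",
    "ci_low",
    "ci_high",
    "logrank_p",
    "wald_p",
    "score",
    "significant",
    "status",
    "reason",
]

#: p-value clamp applied inside the screen so that chi-square tail
#: underflow on extreme markers yields a finite (huge) score instead of
#: an error
P_FLOOR = 1e-300


@dataclass(frozen=True)
class ExpressionComparison:
    """Tumor-vs-normal mean expression comparison for one gene."""

    gene: str
    design: str  # "paired" | "unpaired"
    mean_normal: float
    mean_tumor: float
    t_statistic: float
    p: float
    n: int


def _screen_cell(cohort: pd.DataFrame, gene: str, spec: SubgroupSpec, horizon: float | None):
    row = {"gene": gene, "subgroup": str(spec), "status": "ok", "reason": ""}
    try:
        sub = select_subgroup(cohort, spec)
    except ValueError as exc:
        row.update(status="failed", reason="empty_subgroup")
        logger.info("screen cell %s/%s failed: %s", gene, spec, exc)
        return row
    values = sub[gene].to_numpy(dtype=float)
    time = sub["time_months"].to_numpy(dtype=float)
    event = sub["event"].to_numpy().astype(bool)
    if horizon is not None:
        time, event = restrict_horizon(time, event, horizon)
    row["n"] = len(sub)
    row["n_events"] = int(event.sum())
    try:
        high = median_split(values)
    except ValueError:
        row.update(status="failed", reason="constant_marker")
        logger.info("screen cell %s/%s: constant marker", gene, spec)
        return row
    if not event.any():
        row.update(status="failed", reason="no_events")
        return row
    try:
        res = cox_fit(time, event, high)
    except ValueError as exc:
        row.update(status="failed", reason="no_events")
        logger.info("screen cell %s/%s failed: %s", gene, spec, exc)
        return row
    score = hr_score([(res.hr, res.logrank_p)], p_floor=P_FLOOR)
    row.update(
        hr=res.hr,
        ci_low=res.ci95[0],
        ci_high=res.ci95[1],
        logrank_p=res.logrank_p,
        wald_p=res.wald_p,
        score=score,
        significant=classify_score(score),
    )
    if not res.converged:
        row.update(status="failed", reason="nonconvergence", significant=False)
    return row


def run_screen(
    cohort: pd.DataFrame,
    genes: Sequence[str],
    subgroups: Sequence[SubgroupSpec] | None = None,
    *,
    horizon: float | None = 60.0,
) -> pd.DataFrame:
    """Run the full screen and return the gene x subgroup table.

    Parameters
    ----------
    cohort
        Cohort table with ``time_months``, ``event``, clinical label
        columns, and one column per gene.
    genes
        Marker columns to screen (must exist in the cohort; non-empty).
    subgroups
        Subgroup specs; defaults to the single spec ``all``.  The median
        split is recomputed inside each subgroup.
    horizon
        Administrative restriction in months (60 = 5-year OS);
        ``None`` disables clipping.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list must be non-empty")
    missing = [g for g in genes if g not in cohort.columns]
    if missing:
        raise ValueError(f"genes not present in cohort: {missing}")
    if not subgroups:
        subgroups = [SubgroupSpec("all")]
    rows = [
        _screen_cell(cohort, gene, spec, horizon) for gene in genes for spec in subgroups
    ]
    table = pd.DataFrame(rows).reindex(columns=SCREEN_COLUMNS)
    _assert_scores_consistent(table)
    return table


def _assert_scores_consistent(table: pd.DataFrame) -> None:
    """Internal consistency: the score column must equal the composite
    score recomputed from the table's own hr and logrank_p columns."""
    ok = table["status"] == "ok"
    for _, row in table[ok].iterrows():
        expected = hr_score([(row["hr"], row["logrank_p"])], p_floor=P_FLOOR)
        if not np.isclose(expected, row["score"], rtol=1e-12, atol=0):
            raise AssertionError(
                f"inconsistent score for {row['gene']}/{row['subgroup']}"
            )


class BiosignatureScreen(BaseEstimator):
    """Sklearn-style front end for the screen.

    ``fit(cohort)`` runs :func:`run_screen` and stores the result as
    ``screen_table_``; parameters are the gene list, subgroup specs and
    the follow-up horizon.
    """

    def __init__(
        self,
        genes: Sequence[str] | None = None,
        subgroups: Sequence[SubgroupSpec] | None = None,
        horizon: float | None = 60.0,
    ):
        self.genes = genes
        self.subgroups = subgroups
        self.horizon = horizon

    def fit(self, X: pd.DataFrame, y=None):
        genes = self.genes
        if genes is None:
            # every column after the clinical block is a marker
            from .simulate import CLINICAL_COLUMNS

            genes = [c for c in X.columns if c not in CLINICAL_COLUMNS]
        self.screen_table_ = run_screen(X, genes, self.subgroups, horizon=self.horizon)
        return self

    def transform(self, X=None) -> pd.DataFrame:
        return self.screen_table_


def compare_expression(
    normal,
    tumor,
    design: str = "paired",
    *,
    gene: str = "",
    welch: bool = False,
) -> ExpressionComparison:
    """Tumor-vs-normal mean expression comparison.

    Paired design: one-sample t-test on the matched differences.
    Unpaired design: classical pooled-variance two-sample Student t
    (``welch=True`` switches to the unequal-variance form).  Two-sided
    p-values throughout.
    """
    normal = np.asarray(normal, dtype=float)
    tumor = np.asarray(tumor, dtype=float)
    if design == "paired":
        if normal.shape != tumor.shape:
            raise ValueError("paired design requires equal, aligned arms")
        if normal.size < 2:
            raise ValueError("paired design requires at least 2 pairs")
        diff = tumor - normal
        if np.all(diff == diff[0]):
            if diff[0] == 0:
                t, p = 0.0, 1.0
            else:
                raise ValueError(
                    "zero variance in paired differences: t-statistic undefined"
                )
        else:
            t, p = stats.ttest_rel(tumor, normal)
        n = normal.size
    elif design == "unpaired":
        if normal.size < 2 or tumor.size < 2:
            raise ValueError("unpaired design requires at least 2 values per arm")
        t, p = stats.ttest_ind(tumor, normal, equal_var=not welch)
        n = min(normal.size, tumor.size)
    else:
        raise ValueError(f"design must be 'paired' or 'unpaired', got {design!r}")
    return ExpressionComparison(
        gene=gene,
        design=design,
        mean_normal=float(normal.mean()),
        mean_tumor=float(tumor.mean()),
        t_statistic=float(t),
        p=float(p),
        n=int(n),
    )


def rank_targets(
    table: pd.DataFrame,
    comparisons: Iterable[ExpressionComparison] = (),
) -> pd.DataFrame:
    """Order screened genes by targeting priority.

    Genes are ranked by the number of subgroups in which they are
    significant (descending), ties broken by mean score (descending).
    A gene whose tumor mean does not exceed its normal mean, or whose
    comparison p >= 0.05, is flagged ``expression-unsupported`` and
    demoted below every supported gene; genes with no comparison are
    flagged ``no-expression-data`` and sit between the two.
    """
    comp_by_gene = {c.gene: c for c in comparisons}
    records = []
    for gene, grp in table.groupby("gene", sort=False):
        ok = grp[grp["status"] == "ok"]
        n_sig = int(ok["significant"].fillna(False).sum()) if not ok.empty else 0
        mean_score = float(ok["score"].mean()) if not ok.empty else float("-inf")
        comp = comp_by_gene.get(gene)
        if comp is None:
            support = "no-expression-data"
        elif comp.mean_tumor > comp.mean_normal and comp.p < 0.05:
            support = "supported"
        else:
            support = "expression-unsupported"
        records.append(
            {
                "gene": gene,
                "n_significant": n_sig,
                "mean_score": mean_score,
                "expression_support": support,
            }
        )
    tier = {"supported": 0, "no-expression-data": 1, "expression-unsupported": 2}
    records.sort(key=lambda r: (tier[r["expression_support"]], -r["n_significant"], -r["mean_score"]))
    ranked = pd.DataFrame(records)
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    return ranked
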