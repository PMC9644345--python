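"""Differential-expression filter between two conditions.

The decision rule is the filter, not the test engine: a gene is called up
(or down) when the condition-mean fold change reaches ``fc_threshold``
(1.5 by default), the adjusted p-value is below ``alpha`` (0.05), and the
better-expressed condition clears the ``min_expression`` floor (1 RPKM).
Genes below the floor are never tested and carry status ``low_expression``.

The default test engine is a Welch two-sample t-test on log2(RPKM + 1)
with Benjamini-Hochberg adjustment across tested genes. With two groups
this is the natural reduction of a one-way ANOVA on the log scale. A
precomputed p-value column may be supplied instead, in which case only
the threshold logic is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .io import ExpressionTable

log = logging.getLogger(__name__)

__all__ = ["DEResult", "differential_expression", "write_de_table"]

STATUSES = ("up", "down", "ns", "low_expression")


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    mean_a: float
    mean_b: float
    fold_change: float  # mean_b / mean_a
    log2fc: float
    p_raw: float
    p_adj: float
    status: str


def differential_expression(
    expr: ExpressionTable,
    cond_a: str,
    cond_b: str,
    config: AnalysisConfig | None = None,
    p_raw: np.ndarray | None = None,
) -> list[DEResult]:
    """Per-gene up/down/ns/low_expression calls for condition B vs A.

    Fold change is the ratio of raw-RPKM condition means (B over A).
    ``p_raw`` overrides the built-in Welch test with externally supplied
    raw p-values (one per gene); BH adjustment is still applied across
    genes passing the expression floor.
    """
    config = config or AnalysisConfig()
    a = expr.condition_matrix(cond_a)
    b = expr.condition_matrix(cond_b)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    n = len(expr.gene_ids)

    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_a > 0, mean_b / mean_a, np.where(mean_b > 0, np.inf, np.nan))
        log2fc = np.log2(fc)

    tested = np.maximum(mean_a, mean_b) >= config.min_expression
    praw_full = np.full(n, np.nan)
    if tested.any():
        if p_raw is not None:
            if len(p_raw) != n:
                raise ValueError("p_raw length must match the number of genes")
            praw_full[tested] = np.asarray(p_raw, dtype=float)[tested]
        else:
            la = np.log2(a[tested] + 1.0)
            lb = np.log2(b[tested] + 1.0)
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = stats.ttest_ind(lb, la, axis=1, equal_var=False)
            pvals = np.asarray(res.pvalue, dtype=float)
            # zero variance in both groups: the statistic is 0/0 or inf;
            # the test is undefined either way
            degenerate = ~np.isfinite(pvals) | (
                (la.var(axis=1) == 0) & (lb.var(axis=1) == 0)
            )
            if degenerate.any():
                log.warning(
                    "%d gene(s) with degenerate replicate variance; p set to 1",
                    int(degenerate.sum()),
                )
                pvals[degenerate] = 1.0
            praw_full[tested] = pvals
        padj_full = np.full(n, np.nan)
        padj_full[tested] = multipletests(praw_full[tested], method="fdr_bh")[1]
    else:
        padj_full = np.full(n, np.nan)

    results = []
    for i, gene in enumerate(expr.gene_ids):
        if not tested[i]:
            status = "low_expression"
        elif padj_full[i] < config.alpha and fc[i] >= config.fc_threshold:
            status = "up"
        elif padj_full[i] < config.alpha and fc[i] <= 1.0 / config.fc_threshold:
            status = "down"
        else:
            status = "ns"
        results.append(
            DEResult(
                gene_id=gene,
                mean_a=float(mean_a[i]),
                mean_b=float(mean_b[i]),
                fold_change=float(fc[i]) if np.isfinite(fc[i]) or np.isinf(fc[i]) else float("nan"),
                log2fc=float(log2fc[i]),
                p_raw=float(praw_full[i]),
                p_adj=float(padj_full[i]),
                status=status,
            )
        )
    n_low = int((~tested).sum())
    log.info(
        "DE %s vs %s: %d up, %d down, %d ns, %d below %.3g RPKM floor",
        cond_b, cond_a,
        sum(r.status == "up" for r in results),
        sum(r.status == "down" for r in results),
        sum(r.status == "ns" for r in results),
        n_low, config.min_expression,
    )
    return results


def write_de_table(path, results: list[DEResult]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tmean_a\tmean_b\tfold_change\tlog2fc\tp_raw\tp_adj\tstatus\n")
        for r in results:
            fh.write(
                f"{r.gene_id}\t{r.mean_a:.6g}\t{r.mean_b:.6g}\t{r.fold_change:.6g}"
                f"\t{r.log2fc:.6g}\t{r.p_raw:.6g}\t{r.p_adj:.6g}\t{r.status}\n"
            )
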