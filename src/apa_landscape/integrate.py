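"""Cross-stage statistics: hypergeometric target-set enrichment, APA
direction vs expression analysis, distal-usage ratios, and ratio-vs-
regulator correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    N: int          # universe size (expressed transcripts/genes)
    K: int          # marked set (e.g. CLIP targets)
    n: int          # drawn set (e.g. APA-changed genes)
    k: int          # overlap
    p_value: float  # upper tail, P(X >= k)


def _log_comb(n, r):
    return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), summed in log
    space for numerical stability at genome-scale N."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K, n <= N")
    if k > min(n, K):
        raise ValueError("overlap k cannot exceed min(n, K)")
    if k <= max(0, n + K - N):
        return 1.0
    i = np.arange(k, min(n, K) + 1)
    log_terms = (_log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n))
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def hypergeom_enrichment(universe: set, marked: set, drawn: set) -> EnrichmentResult:
    """Enrichment of ``drawn`` in ``marked`` against ``universe``.

    Genes outside the universe are dropped from both sets with a warning;
    the id spaces must already match (no gene/transcript mixing).
    """
    if not universe:
        raise ValueError("universe is empty")
    marked_in = set(marked) & universe
    drawn_in = set(drawn) & universe
    if len(marked_in) < len(marked) or len(drawn_in) < len(drawn):
        log.warning("dropped %d marked and %d drawn ids outside the universe",
                    len(marked) - len(marked_in), len(drawn) - len(drawn_in))
    N, K, n = len(universe), len(marked_in), len(drawn_in)
    k = len(marked_in & drawn_in)
    return EnrichmentResult(N=N, K=K, n=n, k=k, p_value=hypergeom_pvalue(N, K, n, k))


def define_universe(expression: pd.DataFrame, sample_conditions: dict[str, str],
                    conditions: tuple[str, str]) -> set:
    """Expressed-id universe: ids with count > 0 in any sample of either
    named condition.  ``expression`` is an id x sample count table."""
    cols = [s for s, c in sample_conditions.items() if c in conditions]
    unknown = set(conditions) - set(sample_conditions.values())
    if unknown:
        raise ValueError(f"unknown condition label(s): {sorted(unknown)}")
    if not cols:
        raise ValueError("no samples matched the requested conditions")
    sub = expression[cols]
    return set(expression.index[(sub > 0).any(axis=1)])


@dataclass
class DirectionSummary:
    genes: pd.DataFrame       # gene_id, effect, log2fc (ordered by effect)
    mean_log2fc: float
    ci_low: float
    ci_high: float
    p_value: float            # one-sample two-sided t-test of log2FC vs 0
    computable: bool


def direction_analysis(apa: pd.DataFrame, expr: pd.DataFrame, top_n: int = 50,
                       alpha: float = 0.05) -> DirectionSummary:
    """Expression direction of the strongest APA-and-DE genes.

    Genes significant in both tables (FDR < ``alpha``) are ranked by
    expression FDR (ties: |log2FC| descending), truncated to ``top_n``,
    and their log2 fold changes tested against zero with a one-sample
    two-sided t-test.  The output table is ordered by APA effect, most
    shortened to most lengthened.
    """
    merged = apa.merge(expr, on="gene_id", suffixes=("_apa", "_expr"))
    sel = merged[(merged["fdr_apa"] < alpha) & (merged["fdr_expr"] < alpha)].copy()
    sel["abs_fc"] = sel["log2fc"].abs()
    sel = sel.sort_values(["fdr_expr", "abs_fc"], ascending=[True, False],
                          kind="mergesort").head(top_n)
    sel = sel.sort_values("effect", kind="mergesort")
    table = sel[["gene_id", "effect", "log2fc", "fdr_apa", "fdr_expr"]].reset_index(drop=True)
    fc = sel["log2fc"].to_numpy()
    if fc.size < 3:
        log.warning("direction analysis: only %d qualifying genes (<3); "
                    "t-test not computable", fc.size)
        return DirectionSummary(genes=table, mean_log2fc=float(fc.mean()) if fc.size else np.nan,
                                ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                                computable=False)
    mean = float(fc.mean())
    if np.ptp(fc) == 0.0:
        p = 1.0 if mean == 0.0 else 0.0
        ci_low = ci_high = mean
    else:
        t, p = stats.ttest_1samp(fc, 0.0)
        sem = stats.sem(fc)
        half = float(stats.t.ppf(0.975, fc.size - 1) * sem)
        ci_low, ci_high = mean - half, mean + half
        p = float(p)
    return DirectionSummary(genes=table, mean_log2fc=mean, ci_low=ci_low,
                            ci_high=ci_high, p_value=p, computable=True)


def distal_usage_ratio(distal_expr: float, total_expr: float) -> float:
    """Distal-isoform share of total gene expression, in [0,1] whenever
    distal <= total.  Undefined (NaN) for zero total."""
    if total_expr == 0:
        log.warning("distal_usage_ratio: zero total expression")
        return float("nan")
    return distal_expr / total_expr


def long_short_ratio(long_expr: float, short_expr: float) -> float:
    """Long- to short-3'UTR isoform expression ratio (>= 0)."""
    if short_expr == 0:
        log.warning("long_short_ratio: zero short-isoform expression")
        return float("nan")
    return long_expr / short_expr


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    slope: float
    intercept: float


def ratio_regulator_correlation(ratios: pd.Series | np.ndarray,
                                regulator: pd.Series | np.ndarray,
                                log2: bool = False,
                                pseudocount: float = 0.01) -> CorrelationResult:
    """Pearson correlation between per-cell-line isoform ratios and
    regulator expression, with missing pairs dropped.

    With ``log2`` both variables are log2(x + pseudocount) transformed.
    Zero variance in either variable leaves r undefined (NaN).
    """
    x = np.asarray(ratios, dtype=float)
    y = np.asarray(regulator, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need >= 3 paired observations, got {x.size}")
    if log2:
        x = np.log2(x + pseudocount)
        y = np.log2(y + pseudocount)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        log.warning("zero variance: correlation undefined")
        return CorrelationResult(r=float("nan"), p_value=float("nan"), n=int(x.size),
                                 slope=float("nan"), intercept=float("nan"))
    lr = stats.linregress(y, x)  # ratio as response for the plotting fit
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p_value=float(p), n=int(x.size),
                             slope=float(lr.slope), intercept=float(lr.intercept))
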