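"""Per-gene APA shift statistic, significance testing, poly(A) tail-length
tests and gene-level expression tests.

The APA effect size is a difference of *distal usage indices*.  Within a
gene, peaks are ranked proximal->distal and given position scores
s_j = j/(m-1) in [0,1]; a condition's distal index is the usage-weighted
mean of the scores, D_c = sum_j u_cj * s_j.  The effect is
Delta = D_treatment - D_control, bounded in [-1,1]; positive values mean a
shift toward distal cleavage (3'UTR lengthening), negative toward proximal
(shortening).  Significance uses a G-test (likelihood-ratio chi-squared)
of homogeneity on the replicate-pooled condition x peak table, followed by
Benjamini-Hochberg FDR across genes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .peaks import UsageMatrix

log = logging.getLogger(__name__)


def _pooled_condition_counts(usage: UsageMatrix, control: str, treatment: str):
    cond = np.asarray(usage.conditions)
    for name in (control, treatment):
        if name not in cond:
            raise ValueError(f"condition {name!r} not present in usage matrix samples")
    nc = usage.counts[:, cond == control].sum(axis=1)
    nt = usage.counts[:, cond == treatment].sum(axis=1)
    return nc.astype(float), nt.astype(float)


def distal_index(counts: np.ndarray) -> float:
    """Usage-weighted mean of rank position scores j/(m-1) for one condition."""
    counts = np.asarray(counts, dtype=float)
    m = counts.size
    if m < 2:
        raise ValueError("distal index needs >= 2 peaks")
    total = counts.sum()
    if total <= 0:
        raise ValueError("distal index undefined for zero total count")
    scores = np.arange(m) / (m - 1)
    return float((counts / total) @ scores)


def apa_effect(usage: UsageMatrix, control: str, treatment: str) -> dict:
    """Effect size for one gene: Delta = D_treatment - D_control.

    Raises ValueError for genes with fewer than two peaks or a zero-count
    condition; callers that scan many genes should catch and log.
    """
    if usage.n_peaks < 2:
        raise ValueError(f"{usage.gene_id}: APA effect needs >= 2 peaks")
    nc, nt = _pooled_condition_counts(usage, control, treatment)
    d_control = distal_index(nc)
    d_treatment = distal_index(nt)
    return {"gene_id": usage.gene_id, "m": usage.n_peaks,
            "distal_index_control": d_control,
            "distal_index_treatment": d_treatment,
            "effect": d_treatment - d_control}


def g_test(table: np.ndarray) -> tuple[float, int, float]:
    """G statistic (2 * sum O*ln(O/E)), degrees of freedom and p-value for
    a 2 x m homogeneity test.  Zero observed cells contribute 0."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] != 2:
        raise ValueError("expected a 2 x m contingency table")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if total <= 0 or np.any(row <= 0):
        raise ValueError("G-test needs positive counts in both conditions")
    exp = row @ col / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    g = float(2.0 * terms.sum())
    df = obs.shape[1] - 1
    p = float(stats.chi2.sf(g, df)) if df > 0 else 1.0
    return g, df, p


def apa_test(matrices: list[UsageMatrix], control: str, treatment: str,
             alpha: float = 0.05, min_effect: float = 0.1) -> pd.DataFrame:
    """Per-gene APA shift test across a collection of usage matrices.

    Peaks with zero pooled counts in both conditions are dropped from that
    gene's test (reducing m).  Genes with fewer than two informative peaks
    or an all-zero condition are skipped.  Direction calls require both
    FDR < ``alpha`` and |Delta| >= ``min_effect``; positive calls are
    ``lengthening`` (distal shift), negative ``shortening``.
    """
    rows = []
    for um in matrices:
        if um.n_peaks < 2:
            log.debug("skipping %s: fewer than 2 peaks", um.gene_id)
            continue
        nc, nt = _pooled_condition_counts(um, control, treatment)
        keep = (nc + nt) > 0
        if keep.sum() < um.n_peaks:
            log.debug("%s: dropped %d empty peak(s)", um.gene_id,
                      int(um.n_peaks - keep.sum()))
        nc, nt = nc[keep], nt[keep]
        if nc.size < 2:
            continue
        if nc.sum() == 0 or nt.sum() == 0:
            log.debug("skipping %s: a condition has zero reads", um.gene_id)
            continue
        g, df, p = g_test(np.vstack([nc, nt]))
        rows.append({"gene_id": um.gene_id, "m": int(nc.size),
                     "distal_index_control": distal_index(nc),
                     "distal_index_treatment": distal_index(nt),
                     "effect": distal_index(nt) - distal_index(nc),
                     "statistic": g, "df": df, "p_value": p})
    res = pd.DataFrame(rows, columns=["gene_id", "m", "distal_index_control",
                                      "distal_index_treatment", "effect",
                                      "statistic", "df", "p_value"])
    if res.empty:
        res["fdr"] = pd.Series(dtype=float)
        res["call"] = pd.Series(dtype=object)
        return res
    res["fdr"] = multipletests(res["p_value"], method="fdr_bh")[1]
    sig = res["fdr"] < alpha
    res["call"] = "none"
    res.loc[sig & (res["effect"] >= min_effect), "call"] = "lengthening"
    res.loc[sig & (res["effect"] <= -min_effect), "call"] = "shortening"
    return res


def tail_test(reads: pd.DataFrame, control: str, treatment: str,
              alpha: float = 0.05) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene poly(A) tail-length change test plus per-sample global means.

    ``reads`` must carry a ``gene_id`` column (see
    :func:`assign_reads_to_genes`).  Per gene x sample the tail mean is the
    read-weighted mean tail length; a Welch two-sample t-test compares
    replicate means between conditions.  Genes lacking two replicates in
    either condition are skipped.  A degenerate statistic (zero variance,
    identical means) is reported as p = 1.
    """
    global_means = reads.groupby("sample")["tail_length"].mean()
    if "gene_id" not in reads.columns:
        raise ValueError("tail_test needs a gene_id column; assign reads to genes first")
    tab = (reads.dropna(subset=["gene_id"])
                .groupby(["gene_id", "condition", "sample"])["tail_length"]
                .mean().reset_index())
    rows = []
    for gid, grp in tab.groupby("gene_id", sort=True):
        a = grp.loc[grp["condition"] == control, "tail_length"].to_numpy()
        b = grp.loc[grp["condition"] == treatment, "tail_length"].to_numpy()
        if a.size < 2 or b.size < 2:
            continue
        if np.ptp(np.concatenate([a, b])) == 0.0:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_ind(b, a, equal_var=False)
            if np.isnan(p):
                stat, p = 0.0, 1.0
        rows.append({"gene_id": gid, "mean_control": float(a.mean()),
                     "mean_treatment": float(b.mean()),
                     "statistic": float(stat), "p_value": float(p)})
    res = pd.DataFrame(rows, columns=["gene_id", "mean_control", "mean_treatment",
                                      "statistic", "p_value"])
    if not res.empty:
        res["fdr"] = multipletests(res["p_value"], method="fdr_bh")[1]
    else:
        res["fdr"] = pd.Series(dtype=float)
    return res, global_means


def assign_reads_to_genes(reads: pd.DataFrame, peaks) -> pd.DataFrame:
    """Attach a ``gene_id`` column by locating each read's last templated
    position inside a called peak interval (same chromosome and strand).
    Reads outside any peak get NA."""
    import bisect
    by_cs: dict[tuple[str, str], tuple[list[int], list[int], list[str]]] = {}
    for p in peaks:
        key = (p.chrom, p.strand)
        by_cs.setdefault(key, ([], [], []))
    for p in sorted(peaks, key=lambda p: p.start):
        s, e, g = by_cs[(p.chrom, p.strand)]
        s.append(p.start)
        e.append(p.end)
        g.append(p.gene_id)
    out = reads.copy()
    gene_col = []
    for chrom, strand, pos in zip(out["chrom"], out["strand"], out["pos_1based"]):
        tup = by_cs.get((chrom, strand))
        gid = None
        if tup:
            s, e, g = tup
            i = bisect.bisect_right(s, pos - 1) - 1
            if i >= 0 and pos - 1 < e[i]:
                gid = g[i]
        gene_col.append(gid)
    out["gene_id"] = gene_col
    return out


def expression_test(matrices: list[UsageMatrix], control: str, treatment: str) -> pd.DataFrame:
    """Gene-level expression change from summed peak counts.

    Expression per gene x sample is the sum of its peak counts; counts per
    million (CPM) normalise to the included genes' library totals; tests
    are Welch t-tests on log2(CPM + 0.5) across replicates with BH FDR.
    log2FC is the treatment minus control mean of log2 CPM.
    """
    if not matrices:
        raise ValueError("no usage matrices supplied")
    samples = matrices[0].samples
    conditions = np.asarray(matrices[0].conditions)
    gene_ids = [m.gene_id for m in matrices]
    totals = np.vstack([m.counts.sum(axis=0) for m in matrices]).astype(float)
    lib = totals.sum(axis=0)
    if np.any(lib == 0):
        bad = [s for s, l in zip(samples, lib) if l == 0]
        raise ValueError(f"library size is zero for sample(s) {bad}")
    cpm = totals / lib * 1e6
    logcpm = np.log2(cpm + 0.5)
    is_c = conditions == control
    is_t = conditions == treatment
    if not is_c.any() or not is_t.any():
        raise ValueError("control/treatment labels not found among samples")
    rows = []
    for gid, lrow in zip(gene_ids, logcpm):
        a, b = lrow[is_c], lrow[is_t]
        if np.ptp(np.concatenate([a, b])) == 0.0:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_ind(b, a, equal_var=False)
            if np.isnan(p):
                stat, p = 0.0, 1.0
        rows.append({"gene_id": gid, "log2fc": float(b.mean() - a.mean()),
                     "mean_log2cpm": float(lrow.mean()),
                     "statistic": float(stat), "p_value": float(p)})
    res = pd.DataFrame(rows)
    res["fdr"] = multipletests(res["p_value"], method="fdr_bh")[1]
    cpm_df = pd.DataFrame(cpm, index=gene_ids, columns=samples)
    res.attrs["cpm"] = cpm_df
    return res
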