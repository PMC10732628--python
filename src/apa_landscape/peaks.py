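"""Cleavage/polyadenylation peak calling from poly(A)-evidenced 3' ends,
genomic classification against an annotation, and per-gene usage matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation

log = logging.getLogger(__name__)

CATEGORIES = ("utr3", "exon", "ncrna_downstream", "intron", "antisense", "unassigned")


@dataclass
class PolyAPeak:
    """A clustered cleavage site.

    ``start``/``end`` are 0-based half-open; ``summit`` is the modal read
    end as a 1-based position (ties broken toward the smallest genomic
    coordinate).  ``counts`` maps sample -> read count.
    """

    peak_id: str
    chrom: str
    strand: str
    start: int
    end: int
    summit: int
    counts: dict[str, int]
    category: str | None = None
    gene_id: str | None = None

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class UsageMatrix:
    """Per-gene peak x sample count matrix, rows ordered proximal->distal
    in transcript orientation (+ strand ascending genomic coordinate,
    - strand descending)."""

    gene_id: str
    peak_ids: list[str]
    counts: np.ndarray            # shape (n_peaks, n_samples)
    samples: list[str]
    conditions: list[str]         # condition label per sample
    strand: str = "+"

    @property
    def n_peaks(self) -> int:
        return self.counts.shape[0]

    @property
    def apa_testable(self) -> bool:
        return self.n_peaks >= 2


def call_peaks(reads: pd.DataFrame, a_min: int = 4, merge_gap: int = 10,
               min_reads: int = 10, samples: list[str] | None = None) -> list[PolyAPeak]:
    """Single-linkage cluster poly(A)-evidenced read ends into peaks.

    Reads with fewer than ``a_min`` non-templated adenosines are discarded
    as lacking poly(A) evidence.  Remaining 1-based end positions are
    clustered per chromosome x strand, joining neighbours at most
    ``merge_gap`` nt apart; clusters with fewer than ``min_reads`` total
    reads (summed over all samples) are dropped.
    """
    if a_min < 0 or merge_gap < 0 or min_reads < 0:
        raise ValueError("a_min, merge_gap and min_reads must be non-negative")
    if reads.empty:
        raise ValueError("read table is empty")
    if samples is None:
        samples = sorted(reads["sample"].unique())

    kept = reads[reads["n_nontemplated_A"] >= a_min]
    peaks: list[PolyAPeak] = []
    n = 0
    for (chrom, strand), grp in sorted(kept.groupby(["chrom", "strand"], sort=False),
                                       key=lambda kv: kv[0]):
        pos = np.sort(grp["pos_1based"].to_numpy())
        if pos.size == 0:
            continue
        # cluster boundaries where the sorted gap exceeds merge_gap
        breaks = np.flatnonzero(np.diff(pos) > merge_gap) + 1
        bounds = np.concatenate([[0], breaks, [pos.size]])
        order = grp.sort_values("pos_1based", kind="mergesort")
        pos_all = order["pos_1based"].to_numpy()
        samp_all = order["sample"].to_numpy()
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            if b1 - b0 < 1:
                continue
            cpos = pos_all[b0:b1]
            csamp = samp_all[b0:b1]
            if cpos.size < min_reads:
                continue
            uniq, cnt = np.unique(cpos, return_counts=True)
            summit = int(uniq[np.argmax(cnt)])  # np.unique sorted -> ties to smallest
            counts = {s: 0 for s in samples}
            for s, c in zip(*np.unique(csamp, return_counts=True)):
                counts[str(s)] = int(c)
            peaks.append(PolyAPeak(
                peak_id=f"peak{n:05d}", chrom=chrom, strand=strand,
                start=int(cpos.min()) - 1, end=int(cpos.max()), summit=summit,
                counts=counts))
            n += 1
    return peaks


def _downstream_distance(strand: str, end3: int, point: int) -> int:
    """Distance from a 3' end to a point, positive when the point lies
    downstream in transcript orientation (0-based positions)."""
    return point - end3 if strand == "+" else end3 - point


def classify_peaks(peaks: list[PolyAPeak], annotation: GenomeAnnotation,
                   downstream_allowance: int = 2000) -> list[PolyAPeak]:
    """Assign each peak one category by its summit with strict priority:

    1. ``utr3`` — summit inside an annotated 3'UTR, or up to
       ``downstream_allowance`` nt downstream of a 3'UTR end and not
       inside another same-strand gene;
    2. ``exon`` — summit in an exon of a same-strand gene;
    3. ``ncrna_downstream`` — summit within the allowance downstream of a
       non-coding gene end;
    4. ``intron`` — summit inside a same-strand gene but no exon;
    5. ``antisense`` — summit inside an opposite-strand gene;
    6. ``unassigned``.

    Ties across candidate genes break by nearest annotated 3'UTR end,
    then lexicographic gene id.
    """
    opposite = {"+": "-", "-": "+"}
    for pk in peaks:
        p0 = pk.summit - 1  # 0-based point
        pk.category, pk.gene_id = _classify_point(
            annotation, pk.chrom, pk.strand, p0, downstream_allowance, opposite)
    return peaks


def _classify_point(annotation, chrom, strand, p0, allowance, opposite):
    same_genes = annotation.genes_at(chrom, p0, strand)
    same_ids = {g.gene_id for g in same_genes}

    # 1) utr3: inside an annotated 3'UTR
    in_utr = [u for u in annotation.utr3_at(chrom, p0, strand)]
    if in_utr:
        gid = _nearest_by_utr_end(annotation, {u.gene_id for u in in_utr}, strand, p0)
        return "utr3", gid
    # ... or within the downstream allowance of a 3'UTR end, not inside
    # another same-strand gene
    cands = []
    for gid, utrs in annotation.utr3_by_gene.items():
        g = annotation.genes_by_id[gid]
        if g.chrom != chrom or g.strand != strand:
            continue
        end3 = annotation.utr3_end_of(gid)
        d = _downstream_distance(strand, end3, p0)
        if 0 < d <= allowance and not (same_ids - {gid}):
            cands.append((abs(d), gid))
    if cands:
        cands.sort()
        return "utr3", cands[0][1]

    # 2) exon of a same-strand gene
    exon_hits = sorted(
        g.gene_id for g in same_genes
        if any(e.start <= p0 < e.end for e in annotation.exons_by_gene.get(g.gene_id, ())))
    if exon_hits:
        return "exon", _nearest_by_utr_end(annotation, set(exon_hits), strand, p0)

    # 3) downstream of a non-coding gene end
    nc = []
    for g in annotation.genes:
        if g.chrom != chrom or g.strand != strand or g.biotype == "protein_coding":
            continue
        d = _downstream_distance(strand, g.three_prime_end, p0)
        if 0 < d <= allowance:
            nc.append((abs(d), g.gene_id))
    if nc:
        nc.sort()
        return "ncrna_downstream", nc[0][1]

    # 4) intron
    if same_genes:
        return "intron", sorted(same_ids)[0]

    # 5) antisense
    anti = annotation.genes_at(chrom, p0, opposite[strand])
    if anti:
        return "antisense", sorted(g.gene_id for g in anti)[0]

    return "unassigned", None


def _nearest_by_utr_end(annotation, gene_ids: set[str], strand: str, p0: int) -> str:
    scored = []
    for gid in gene_ids:
        end3 = annotation.utr3_end_of(gid)
        d = abs(p0 - end3) if end3 is not None else np.inf
        scored.append((d, gid))
    scored.sort(key=lambda t: (t[0], t[1]))
    return scored[0][1]


def category_counts(peaks: list[PolyAPeak]) -> dict[str, int]:
    """Peak tally per category; always partitions the input exactly."""
    out = {c: 0 for c in CATEGORIES}
    for p in peaks:
        out[p.category] += 1
    return out


def build_usage_matrices(peaks: list[PolyAPeak],
                         sample_conditions: dict[str, str],
                         samples: list[str] | None = None) -> list[UsageMatrix]:
    """Group 3'UTR peaks per gene into proximal->distal count matrices.

    Single-peak genes are still emitted (``apa_testable`` False).
    """
    utr_peaks = [p for p in peaks if p.category == "utr3" and p.gene_id]
    if samples is None:
        seen: dict[str, None] = {}
        for p in utr_peaks:
            for s in p.counts:
                seen.setdefault(s)
        samples = sorted(seen)
    by_gene: dict[str, list[PolyAPeak]] = {}
    for p in utr_peaks:
        by_gene.setdefault(p.gene_id, []).append(p)
    out = []
    for gid in sorted(by_gene):
        ps = by_gene[gid]
        strand = ps[0].strand
        ps.sort(key=lambda p: p.summit, reverse=(strand == "-"))
        counts = np.array([[p.counts.get(s, 0) for s in samples] for p in ps],
                          dtype=np.int64)
        out.append(UsageMatrix(
            gene_id=gid, peak_ids=[p.peak_id for p in ps], counts=counts,
            samples=list(samples),
            conditions=[sample_conditions[s] for s in samples], strand=strand))
    return out


def peaks_to_frame(peaks: list[PolyAPeak], samples: list[str] | None = None) -> pd.DataFrame:
    """BED6+ table: category, gene_id, summit (1-based), per-sample counts."""
    if samples is None:
        seen: dict[str, None] = {}
        for p in peaks:
            for s in p.counts:
                seen.setdefault(s)
        samples = sorted(seen)
    rows = []
    for p in peaks:
        row = {"chrom": p.chrom, "start": p.start, "end": p.end, "name": p.peak_id,
               "score": p.total, "strand": p.strand,
               "category": p.category or "", "gene_id": p.gene_id or "",
               "summit": p.summit}
        for s in samples:
            row[f"count_{s}"] = p.counts.get(s, 0)
        rows.append(row)
    cols = ["chrom", "start", "end", "name", "score", "strand", "category",
            "gene_id", "summit"] + [f"count_{s}" for s in samples]
    return pd.DataFrame(rows, columns=cols)


def frame_to_peaks(df: pd.DataFrame) -> list[PolyAPeak]:
    samples = [c[len("count_"):] for c in df.columns if c.startswith("count_")]
    out = []
    for _, r in df.iterrows():
        out.append(PolyAPeak(
            peak_id=str(r["name"]), chrom=str(r["chrom"]), strand=str(r["strand"]),
            start=int(r["start"]), end=int(r["end"]), summit=int(r["summit"]),
            counts={s: int(r[f"count_{s}"]) for s in samples},
            category=(str(r["category"]) or None) if pd.notna(r["category"]) else None,
            gene_id=(str(r["gene_id"]) or None) if pd.notna(r["gene_id"]) else None))
    return out
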