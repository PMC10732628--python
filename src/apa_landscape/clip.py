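"""Multi-experiment CLIP peak integration: 3'UTR restriction, consensus
region building, and support-threshold shortlisting.

Peaks from several CLIP experiments (HITS-CLIP, eCLIP, PAR-CLIP are
treated exchangeably) are pooled per chromosome x strand and merged
transitively wherever they overlap; each merged *consensus region*
records how many distinct experiments contributed at least one peak,
which supports shortlisting high-confidence targets (e.g. >= 4 of 7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation

log = logging.getLogger(__name__)


@dataclass
class ClipPeakSet:
    """Peaks from one CLIP experiment (BED6-shaped DataFrame)."""

    experiment_id: str
    peaks: pd.DataFrame  # chrom, start, end, name, score, strand
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.peaks) and (self.peaks["end"] <= self.peaks["start"]).any():
            raise ValueError(f"{self.experiment_id}: degenerate peak interval")


@dataclass
class ConsensusRegion:
    region_id: str
    chrom: str
    strand: str
    start: int
    end: int
    support: int
    members: dict[str, list[str]] = field(default_factory=dict)  # experiment -> peak names
    transcripts: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    in_utr3: bool = False

    @property
    def centre(self) -> int:
        return (self.start + self.end) // 2


def restrict_to_utr3(peak_set: ClipPeakSet, annotation: GenomeAnnotation) -> ClipPeakSet:
    """Keep peaks whose centre (floor of the interval midpoint) lies in an
    annotated same-strand 3'UTR; annotate transcript and gene."""
    df = peak_set.peaks
    keep_rows = []
    for _, r in df.iterrows():
        centre = (int(r["start"]) + int(r["end"])) // 2
        hits = annotation.utr3_at(str(r["chrom"]), centre, str(r["strand"]))
        if hits:
            row = r.copy()
            row["transcript_id"] = ",".join(sorted({u.transcript_id for u in hits}))
            row["gene_id"] = ",".join(sorted({u.gene_id for u in hits}))
            keep_rows.append(row)
    cols = list(df.columns) + ["transcript_id", "gene_id"]
    out = pd.DataFrame(keep_rows, columns=cols).reset_index(drop=True)
    return ClipPeakSet(experiment_id=peak_set.experiment_id, peaks=out,
                       source=peak_set.source)


def build_consensus(peak_sets: list[ClipPeakSet],
                    min_overlap: int = 1) -> list[ConsensusRegion]:
    """Merge overlapping peaks across experiments into consensus regions.

    Overlap requires at least ``min_overlap`` shared nucleotides.  Support
    counts distinct experiments, not peaks.
    """
    if not peak_sets:
        raise ValueError("at least one peak set is required")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    seen = set()
    for ps in peak_sets:
        if ps.experiment_id in seen:
            raise ValueError(f"duplicate experiment_id {ps.experiment_id!r}")
        seen.add(ps.experiment_id)

    pooled = []
    for ps in peak_sets:
        for _, r in ps.peaks.iterrows():
            pooled.append((str(r["chrom"]), str(r["strand"]), int(r["start"]),
                           int(r["end"]), ps.experiment_id, str(r["name"])))
    regions: list[ConsensusRegion] = []
    n = 0
    by_cs: dict[tuple[str, str], list[tuple]] = {}
    for rec in pooled:
        by_cs.setdefault((rec[0], rec[1]), []).append(rec)
    for (chrom, strand) in sorted(by_cs):
        recs = sorted(by_cs[(chrom, strand)], key=lambda r: (r[2], r[3], r[4], r[5]))
        cur: list[tuple] = []
        cur_end = None
        for rec in recs:
            if cur and rec[2] <= cur_end - min_overlap:
                cur.append(rec)
                cur_end = max(cur_end, rec[3])
            else:
                if cur:
                    regions.append(_make_region(n, chrom, strand, cur))
                    n += 1
                cur = [rec]
                cur_end = rec[3]
        if cur:
            regions.append(_make_region(n, chrom, strand, cur))
            n += 1
    return regions


def _make_region(n, chrom, strand, members) -> ConsensusRegion:
    by_exp: dict[str, list[str]] = {}
    for _, _, _, _, exp, name in members:
        by_exp.setdefault(exp, []).append(name)
    return ConsensusRegion(
        region_id=f"region{n:05d}", chrom=chrom, strand=strand,
        start=min(m[2] for m in members), end=max(m[3] for m in members),
        support=len(by_exp), members=by_exp)


def assign_regions(regions: list[ConsensusRegion],
                   annotation: GenomeAnnotation) -> list[ConsensusRegion]:
    """Attach transcript/gene ids via the 3'UTR containing each region's
    midpoint; multi-transcript hits report all of them."""
    for reg in regions:
        hits = annotation.utr3_at(reg.chrom, reg.centre, reg.strand)
        reg.transcripts = sorted({u.transcript_id for u in hits})
        reg.genes = sorted({u.gene_id for u in hits})
        reg.in_utr3 = bool(hits)
    return regions


def shortlist(regions: list[ConsensusRegion], min_support: int,
              n_experiments: int | None = None
              ) -> tuple[list[ConsensusRegion], pd.DataFrame]:
    """Regions with support >= ``min_support`` plus the distinct
    transcript/gene companion table."""
    if n_experiments is not None and min_support > n_experiments:
        log.warning("min_support=%d exceeds the %d experiments: empty shortlist",
                    min_support, n_experiments)
        return [], pd.DataFrame(columns=["transcript_id", "gene_id", "n_regions"])
    kept = [r for r in regions if r.support >= min_support]
    tally: dict[tuple[str, str], int] = {}
    for r in kept:
        genes = r.genes or [""]
        txs = r.transcripts or [""]
        for tx, g in zip(txs, genes if len(genes) == len(txs) else [genes[0]] * len(txs)):
            tally[(tx, g)] = tally.get((tx, g), 0) + 1
    table = pd.DataFrame(
        [{"transcript_id": tx, "gene_id": g, "n_regions": c}
         for (tx, g), c in sorted(tally.items()) if tx],
        columns=["transcript_id", "gene_id", "n_regions"])
    return kept, table


def regions_to_frame(regions: list[ConsensusRegion]) -> pd.DataFrame:
    """BED6+: support, contributing experiments, transcript ids."""
    rows = []
    for r in regions:
        rows.append({"chrom": r.chrom, "start": r.start, "end": r.end,
                     "name": r.region_id, "score": r.support, "strand": r.strand,
                     "support": r.support,
                     "experiments": ",".join(sorted(r.members)),
                     "transcripts": ",".join(r.transcripts)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score",
                                       "strand", "support", "experiments",
                                       "transcripts"])
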