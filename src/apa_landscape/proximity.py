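"""Proximity of CLIP binding to atlas cleavage/polyadenylation sites:
within-window annotation and CPA-anchored coverage metaprofiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, PolyAAtlas
from .clip import ClipPeakSet, ConsensusRegion

log = logging.getLogger(__name__)


def annotate_proximity(regions: list[ConsensusRegion], atlas: PolyAAtlas,
                       window: int = 100) -> tuple[pd.DataFrame, float]:
    """Distance from each region centre to the nearest same-strand atlas
    cluster, plus the fraction of target genes with a within-window region.

    Distance is 0 when the centre falls inside a cluster, otherwise the
    gap to the nearest cluster edge, signed by transcript orientation
    (positive = centre downstream of the CPA).  The window test is
    boundary-inclusive: |distance| <= window.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    rows = []
    empty = atlas.clusters.empty
    if empty:
        log.warning("empty atlas: all regions flagged outside the window")
    for reg in regions:
        centre = reg.centre
        if empty:
            rows.append({"region_id": reg.region_id, "nearest_cluster_id": "",
                         "distance": np.nan, "within_window": False,
                         "genes": ",".join(reg.genes)})
            continue
        cl = atlas.on(reg.chrom, reg.strand)
        if cl.empty:
            rows.append({"region_id": reg.region_id, "nearest_cluster_id": "",
                         "distance": np.nan, "within_window": False,
                         "genes": ",".join(reg.genes)})
            continue
        starts = cl["start"].to_numpy()
        ends = cl["end"].to_numpy()
        inside = (starts <= centre) & (centre < ends)
        if inside.any():
            idx = int(np.flatnonzero(inside)[0])
            dist = 0
        else:
            # gap to the nearest cluster edge (edges at start, end-1)
            gaps = np.where(centre < starts, starts - centre,
                            np.where(centre >= ends, centre - (ends - 1), 0))
            idx = int(np.argmin(gaps))
            genomic = centre - (ends[idx] - 1) if centre >= ends[idx] else centre - starts[idx]
            # sign by transcript orientation: positive = downstream of CPA
            dist = int(genomic if reg.strand == "+" else -genomic)
        rows.append({"region_id": reg.region_id,
                     "nearest_cluster_id": str(cl["cluster_id"].iloc[idx]),
                     "distance": dist, "within_window": bool(abs(dist) <= window),
                     "genes": ",".join(reg.genes)})
    table = pd.DataFrame(rows, columns=["region_id", "nearest_cluster_id",
                                        "distance", "within_window", "genes"])
    gene_hit: dict[str, bool] = {}
    for reg, within in zip(regions, table["within_window"]):
        for g in reg.genes:
            gene_hit[g] = gene_hit.get(g, False) or bool(within)
    fraction = (sum(gene_hit.values()) / len(gene_hit)) if gene_hit else float("nan")
    return table, fraction


@dataclass
class Metaprofile:
    offsets: np.ndarray        # -flank .. +flank, transcript orientation
    mean_coverage: np.ndarray  # in [0,1]
    n_utrs: int
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets,
                             "mean_coverage": self.mean_coverage})


def _anchor_for_utr(utr, atlas: PolyAAtlas) -> int | None:
    """Midpoint of the highest-TPM atlas cluster overlapping the 3'UTR
    (TPM ties break toward the most distal cluster)."""
    cl = atlas.overlapping(utr.chrom, utr.start, utr.end, utr.strand)
    if cl.empty:
        return None
    top = cl[cl["tpm"] == cl["tpm"].max()]
    if utr.strand == "+":
        row = top.loc[top["start"].idxmax()]
    else:
        row = top.loc[top["start"].idxmin()]
    return (int(row["start"]) + int(row["end"])) // 2


def metaprofile(peaks: pd.DataFrame, atlas: PolyAAtlas,
                annotation: GenomeAnnotation, flank: int = 500,
                label: str = "", target_genes: list[str] | None = None) -> Metaprofile:
    """Mean binary peak coverage around each targeted 3'UTR's top CPA.

    For every evaluated 3'UTR the anchor is the midpoint of its
    highest-TPM overlapping atlas cluster; at each offset in
    [-flank, +flank] (transcript orientation) the UTR scores 1 when any
    peak of the set covers that genomic position.  The profile is the
    mean over anchored UTRs, so values lie in [0,1].  UTRs with no
    overlapping atlas cluster are excluded (counted in the log).
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    utrs = annotation.utr3
    if target_genes is not None:
        tg = set(target_genes)
        utrs = [u for u in utrs if u.gene_id in tg]

    by_cs: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for _, r in peaks.iterrows():
        by_cs.setdefault((str(r["chrom"]), str(r["strand"])), []).append(
            (int(r["start"]), int(r["end"])))

    width = 2 * flank + 1
    acc = np.zeros(width, dtype=float)
    n_used = 0
    n_skipped = 0
    for utr in utrs:
        anchor = _anchor_for_utr(utr, atlas)
        if anchor is None:
            n_skipped += 1
            continue
        cover = np.zeros(width, dtype=bool)
        for start, end in by_cs.get((utr.chrom, utr.strand), ()):
            # genomic window of the profile
            lo, hi = anchor - flank, anchor + flank
            s, e = max(start, lo), min(end, hi + 1)
            if s >= e:
                continue
            if utr.strand == "+":
                cover[s - lo:e - lo] = True
            else:
                # transcript orientation: offset = anchor - genomic position
                cover[hi + 1 - e:hi + 1 - s] = True
        acc += cover
        n_used += 1
    if n_skipped:
        log.info("metaprofile: %d 3'UTR(s) had no atlas cluster and were excluded",
                 n_skipped)
    mean = acc / n_used if n_used else acc
    return Metaprofile(offsets=np.arange(-flank, flank + 1),
                       mean_coverage=mean, n_utrs=n_used, label=label)
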