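"""Genome annotation and poly(A)-site atlas containers plus GTF/BED/TSV readers and writers.

All coordinates are held internally as 0-based half-open intervals
(BED convention).  GTF files use 1-based inclusive coordinates and are
converted on read/write.  Point positions in TSV tables (read 3' ends,
peak summits) are 1-based.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-")


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based
    end: int    # half-open
    biotype: str = "protein_coding"

    @property
    def three_prime_end(self) -> int:
        """0-based position of the last transcribed base (transcript orientation)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int


@dataclass(frozen=True)
class Feature:
    """Exon / CDS / 3'UTR interval attached to a transcript."""
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int


@dataclass
class GenomeAnnotation:
    """Gene models with per-chromosome lookup arrays.

    ``utr3`` holds one three_prime_utr interval per transcript when
    annotated (or inferred from CDS on read).
    """

    genes: list[Gene] = field(default_factory=list)
    transcripts: list[Transcript] = field(default_factory=list)
    exons: list[Feature] = field(default_factory=list)
    cds: list[Feature] = field(default_factory=list)
    utr3: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index()

    def _index(self) -> None:
        self.genes_by_id = {g.gene_id: g for g in self.genes}
        self.utr3_by_gene: dict[str, list[Feature]] = {}
        for u in self.utr3:
            self.utr3_by_gene.setdefault(u.gene_id, []).append(u)
        self.exons_by_gene: dict[str, list[Feature]] = {}
        for e in self.exons:
            self.exons_by_gene.setdefault(e.gene_id, []).append(e)
        self._gene_arrays: dict[str, tuple[np.ndarray, np.ndarray, list[Gene]]] = {}
        by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs = sorted(gs, key=lambda g: (g.start, g.gene_id))
            starts = np.array([g.start for g in gs], dtype=np.int64)
            ends = np.array([g.end for g in gs], dtype=np.int64)
            self._gene_arrays[chrom] = (starts, ends, gs)

    # -- queries ---------------------------------------------------------

    def genes_at(self, chrom: str, pos: int, strand: str | None = None) -> list[Gene]:
        """Genes whose span contains 0-based position ``pos``."""
        if chrom not in self._gene_arrays:
            return []
        starts, ends, gs = self._gene_arrays[chrom]
        mask = (starts <= pos) & (pos < ends)
        hits = [gs[i] for i in np.nonzero(mask)[0]]
        if strand is not None:
            hits = [g for g in hits if g.strand == strand]
        return hits

    def utr3_at(self, chrom: str, pos: int, strand: str | None = None) -> list[Feature]:
        hits = []
        for u in self.utr3:
            if u.chrom == chrom and u.start <= pos < u.end:
                if strand is None or u.strand == strand:
                    hits.append(u)
        return hits

    def utr3_end_of(self, gene_id: str) -> int | None:
        """0-based position of the most distal annotated 3'UTR end for a gene."""
        utrs = self.utr3_by_gene.get(gene_id)
        if not utrs:
            return None
        strand = utrs[0].strand
        if strand == "+":
            return max(u.end for u in utrs) - 1
        return min(u.start for u in utrs)


@dataclass
class PolyAAtlas:
    """Catalogue of cleavage/polyadenylation clusters with TPM expression.

    Backed by a DataFrame with columns chrom, start, end, cluster_id,
    score, strand, tpm (0-based half-open intervals).
    """

    clusters: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.clusters
        if len(df) and (df["tpm"] < 0).any():
            raise ValueError("atlas TPM values must be >= 0")
        if len(df) and (df["end"] <= df["start"]).any():
            raise ValueError("atlas cluster intervals must be non-degenerate")

    def on(self, chrom: str, strand: str) -> pd.DataFrame:
        df = self.clusters
        return df[(df["chrom"] == chrom) & (df["strand"] == strand)]

    def overlapping(self, chrom: str, start: int, end: int, strand: str) -> pd.DataFrame:
        df = self.on(chrom, strand)
        return df[(df["start"] < end) & (df["end"] > start)]


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _parse_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path) -> GenomeAnnotation:
    """Parse a GTF (1-based inclusive) into 0-based half-open gene models.

    Transcripts lacking a ``three_prime_utr`` feature get one inferred as
    the terminal-exon region downstream of the last CDS, when CDS records
    are present; otherwise none.
    """
    genes, transcripts, exons, cds, utr3 = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GTF line {lineno}: expected 9 fields, got {len(fields)}")
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attr = fields
            try:
                start = int(start_s) - 1  # to 0-based
                end = int(end_s)          # inclusive -> half-open
            except ValueError as exc:
                raise ValueError(f"malformed GTF line {lineno}: non-integer coordinates") from exc
            if strand not in VALID_STRANDS:
                raise ValueError(f"unknown strand {strand!r} at GTF line {lineno}")
            attrs = _parse_attributes(attr)
            gid = attrs.get("gene_id")
            if gid is None:
                raise ValueError(f"malformed GTF line {lineno}: missing gene_id")
            if ftype == "gene":
                genes.append(Gene(gid, chrom, strand, start, end,
                                  attrs.get("gene_biotype", "protein_coding")))
            elif ftype == "transcript":
                transcripts.append(Transcript(attrs["transcript_id"], gid, chrom, strand, start, end))
            elif ftype == "exon":
                exons.append(Feature(attrs["transcript_id"], gid, chrom, strand, start, end))
            elif ftype == "CDS":
                cds.append(Feature(attrs["transcript_id"], gid, chrom, strand, start, end))
            elif ftype == "three_prime_utr":
                utr3.append(Feature(attrs["transcript_id"], gid, chrom, strand, start, end))

    have_utr = {u.transcript_id for u in utr3}
    cds_by_tx: dict[str, list[Feature]] = {}
    for c in cds:
        cds_by_tx.setdefault(c.transcript_id, []).append(c)
    exons_by_tx: dict[str, list[Feature]] = {}
    for e in exons:
        exons_by_tx.setdefault(e.transcript_id, []).append(e)
    for tx in transcripts:
        if tx.transcript_id in have_utr or tx.transcript_id not in cds_by_tx:
            continue
        txe = exons_by_tx.get(tx.transcript_id, [])
        txc = cds_by_tx[tx.transcript_id]
        if tx.strand == "+":
            cds_end = max(c.end for c in txc)
            term = max(txe, key=lambda e: e.end, default=None)
            if term is not None and term.end > cds_end:
                utr3.append(Feature(tx.transcript_id, tx.gene_id, tx.chrom, tx.strand,
                                    max(term.start, cds_end), term.end))
        else:
            cds_start = min(c.start for c in txc)
            term = min(txe, key=lambda e: e.start, default=None)
            if term is not None and term.start < cds_start:
                utr3.append(Feature(tx.transcript_id, tx.gene_id, tx.chrom, tx.strand,
                                    term.start, min(term.end, cds_start)))

    return GenomeAnnotation(genes=genes, transcripts=transcripts, exons=exons,
                            cds=cds, utr3=utr3)


def write_gtf(annotation: GenomeAnnotation, path) -> None:
    """Emit GTF 2.2 (1-based inclusive), deterministically ordered."""
    buf = io.StringIO()

    def row(chrom, ftype, start, end, strand, attrs):
        attr_s = " ".join(f'{k} "{v}";' for k, v in attrs)
        buf.write(f"{chrom}\tapa_landscape\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attr_s}\n")

    tx_by_gene: dict[str, list[Transcript]] = {}
    for t in annotation.transcripts:
        tx_by_gene.setdefault(t.gene_id, []).append(t)
    feats_by_tx: dict[str, list[tuple[str, Feature]]] = {}
    for kind, feats in (("exon", annotation.exons), ("CDS", annotation.cds),
                        ("three_prime_utr", annotation.utr3)):
        for f in feats:
            feats_by_tx.setdefault(f.transcript_id, []).append((kind, f))

    for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        row(g.chrom, "gene", g.start, g.end, g.strand,
            [("gene_id", g.gene_id), ("gene_biotype", g.biotype)])
        for t in sorted(tx_by_gene.get(g.gene_id, []), key=lambda t: t.transcript_id):
            row(t.chrom, "transcript", t.start, t.end, t.strand,
                [("gene_id", g.gene_id), ("transcript_id", t.transcript_id)])
            order = {"exon": 0, "CDS": 1, "three_prime_utr": 2}
            for kind, f in sorted(feats_by_tx.get(t.transcript_id, []),
                                  key=lambda kf: (order[kf[0]], kf[1].start)):
                row(f.chrom, kind, f.start, f.end, f.strand,
                    [("gene_id", g.gene_id), ("transcript_id", t.transcript_id)])
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path, extra_cols: int = 0) -> pd.DataFrame:
    """Read BED6(+k).  0-based half-open preserved; extras kept by position."""
    names = BED6_COLS + [f"extra_{i + 1}" for i in range(extra_cols)]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=names, dtype={"chrom": str, "name": str, "strand": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names)
    if len(df) and df[BED6_COLS].isna().any().any():
        raise ValueError(f"{path}: BED requires at least 6 columns")
    if len(df):
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad = ~df["strand"].isin(VALID_STRANDS)
        if bad.any():
            raise ValueError(f"{path}: unknown strand value {df.loc[bad, 'strand'].iloc[0]!r}")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_atlas(path) -> PolyAAtlas:
    """Atlas BED6+1: col 7 is the cluster TPM."""
    df = read_bed(path, extra_cols=1)
    df = df.rename(columns={"extra_1": "tpm"})
    if len(df):
        df["tpm"] = df["tpm"].astype(float)
    else:
        df["tpm"] = pd.Series(dtype=float)
    return PolyAAtlas(clusters=df.rename(columns={"name": "cluster_id"}))


def write_atlas(atlas: PolyAAtlas, path) -> None:
    df = atlas.clusters.rename(columns={"cluster_id": "name"})
    write_bed(df[BED6_COLS + ["tpm"]], path)


# ---------------------------------------------------------------------------
# Read-record / generic TSV
# ---------------------------------------------------------------------------

READS_COLUMNS = ["sample", "condition", "chrom", "pos_1based", "strand",
                 "n_nontemplated_A", "tail_length"]


def read_reads_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"sample": str, "condition": str, "chrom": str, "strand": str})
    missing = [c for c in READS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing read-table columns {missing}")
    if len(df) and (df["pos_1based"] < 1).any():
        raise ValueError(f"{path}: read positions must be >= 1 (1-based)")
    return df


def write_reads_tsv(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# 3'-end read records; pos_1based = last templated base (1-based); "
                 "tail_length in nt\n")
        df.to_csv(fh, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
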