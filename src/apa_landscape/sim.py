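"""Synthetic two-condition 3'-end sequencing world with known ground truth.

Generates a compact genome annotation, a poly(A)-site atlas, per-read
3'-end records with poly(A) tails, and multi-experiment CLIP peak sets,
mirroring a two-condition (epithelial vs mesenchymal) study with
triplicate libraries and seven CLIP experiments.  Every stochastic choice
flows from ``SimConfig.seed``, so identical configs give byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import (Feature, Gene, GenomeAnnotation, PolyAAtlas, Transcript,
                         write_atlas, write_bed, write_gtf, write_reads_tsv, write_tsv)

CONDITIONS = ("epithelial", "mesenchymal")

#: fraction of simulated genes annotated as non-coding (lincRNA-like)
NONCODING_FRACTION = 0.1
#: max |jitter| of a read's last templated position around its true site (nt)
READ_JITTER = 2
#: fraction of reads whose non-templated A count falls below the default
#: caller threshold, exercising the poly(A)-evidence filter
SUBTHRESHOLD_A_FRACTION = 0.05
#: minimum spacing between cleavage sites within one 3'UTR (nt)
MIN_SITE_SPACING = 50
#: probability that a true APA shift is toward the distal site (lengthening)
DISTAL_SHIFT_PROB = 2 / 3


@dataclass
class SimConfig:
    """Parameters of the simulated study.

    Defaults mirror the study shape: 3 replicates per condition, genes
    with 1-4 cleavage/polyadenylation (CPA) sites, a minority of genes
    truly shifted between conditions, and 7 CLIP experiments detecting
    bound genes independently with probability ``clip_detection_prob``.
    """

    n_genes: int = 200
    n_chroms: int = 2
    utr_len_range: tuple[int, int] = (500, 2000)
    sites_per_gene_range: tuple[int, int] = (1, 4)
    frac_shifted: float = 0.15
    effect_range: tuple[float, float] = (0.1, 0.6)  # |delta| of the distal-usage shift
    reads_per_gene_mean: float = 300.0
    n_replicates_per_condition: int = 3
    tail_mean: float = 70.0
    tail_sd: float = 20.0
    n_clip_experiments: int = 7
    clip_detection_prob: float = 0.7
    clip_jitter_sd: float = 30.0
    clip_noise_peaks_per_experiment: int = 50
    frac_clip_bound: float = 0.3
    seed: int = 0
    chrom_len: int | None = None  # auto-sized when None
    intergenic_gap: tuple[int, int] = (2500, 5000)

    def validate(self) -> None:
        for name in ("n_genes", "n_chroms", "n_replicates_per_condition",
                     "n_clip_experiments"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.clip_noise_peaks_per_experiment < 0:
            raise ValueError("clip_noise_peaks_per_experiment must be >= 0")
        for name in ("frac_shifted", "clip_detection_prob", "frac_clip_bound"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0,1], got {v}")
        lo, hi = self.sites_per_gene_range
        if not (1 <= lo <= hi <= 6):
            raise ValueError("sites_per_gene_range must lie within [1,6]")
        lo, hi = self.effect_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("effect_range magnitudes must lie in (0,1]")
        if self.utr_len_range[0] < MIN_SITE_SPACING * self.sites_per_gene_range[1] + 100:
            raise ValueError(
                f"utr_len_range[0]={self.utr_len_range[0]} too small to place "
                f"{self.sites_per_gene_range[1]} sites >= {MIN_SITE_SPACING} nt apart")
        if self.reads_per_gene_mean <= 0 or self.tail_mean <= 0 or self.tail_sd < 0:
            raise ValueError("read depth and tail parameters must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("utr_len_range", "sites_per_gene_range", "effect_range",
                    "intergenic_gap"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    strand: str
    biotype: str
    sites: list[int]              # 0-based last-templated positions, proximal->distal
    usage_a: np.ndarray           # baseline usage, sums to 1
    usage_b: np.ndarray           # condition-B usage, sums to 1
    delta: float                  # true distal-usage shift (0 for null genes)
    clip_bound: bool
    clip_detected: list[bool]     # per experiment
    clip_anchor: int | None       # 0-based CPA the CLIP signal centres on
    tail_mean: float
    tail_sd: float


@dataclass
class GroundTruth:
    genes: dict[str, GeneTruth] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes.values():
            rows.append({
                "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
                "biotype": g.biotype,
                "sites": ",".join(str(s + 1) for s in g.sites),  # 1-based in files
                "usage_a": ",".join(f"{u:.6f}" for u in g.usage_a),
                "usage_b": ",".join(f"{u:.6f}" for u in g.usage_b),
                "delta": f"{g.delta:.6f}",
                "clip_bound": int(g.clip_bound),
                "clip_detected": ",".join(str(int(d)) for d in g.clip_detected),
                "tail_mean": g.tail_mean, "tail_sd": g.tail_sd,
            })
        return pd.DataFrame(rows)


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    # one independent, reproducible stream per simulation stage
    return np.random.default_rng([int(cfg.seed) % (2**31), stage])


def _place_sites(rng, utr_start: int, utr_end: int, k: int, strand: str) -> list[int]:
    """k cleavage positions inside [utr_start, utr_end), >=50 nt apart,
    the most distal exactly at the transcript-orientation UTR end.
    Returned proximal -> distal."""
    span = utr_end - utr_start
    distal_rel = span - 1
    if k == 1:
        rel = [distal_rel]
    else:
        lo, hi = 20, distal_rel - MIN_SITE_SPACING
        for _ in range(200):
            cand = np.sort(rng.integers(lo, hi + 1, size=k - 1))
            all_rel = np.concatenate([cand, [distal_rel]])
            if np.all(np.diff(all_rel) >= MIN_SITE_SPACING):
                rel = list(all_rel)
                break
        else:  # dense UTR: fall back to even spacing
            rel = list(np.linspace(lo, distal_rel, k).round().astype(int))
    if strand == "+":
        return [utr_start + r for r in rel]
    # minus strand: transcript runs right-to-left, distal = leftmost
    return [utr_end - 1 - r for r in rel]


def _usage_vectors(rng, k: int, delta: float) -> tuple[np.ndarray, np.ndarray]:
    """Baseline and shifted usage with distal-index difference exactly delta.

    The shift moves probability mass |delta| between the proximal-most and
    distal-most sites (rank scores 0 and 1), so D_B - D_A = delta exactly.
    The donor site is guaranteed enough baseline mass for the transfer.
    """
    if k == 1 or delta == 0.0:
        u = rng.dirichlet(np.ones(k))
        return u, u.copy()
    donor = 0 if delta > 0 else k - 1
    receiver = k - 1 if delta > 0 else 0
    donor_mass = abs(delta) + rng.uniform(0.05, 0.3)
    donor_mass = min(donor_mass, 0.9)
    rest = rng.dirichlet(np.ones(k - 1)) * (1.0 - donor_mass)
    u = np.empty(k)
    u[donor] = donor_mass
    u[[i for i in range(k) if i != donor]] = rest
    ub = u.copy()
    ub[donor] -= abs(delta)
    ub[receiver] += abs(delta)
    return u, ub


def simulate_annotation(cfg: SimConfig) -> tuple[GenomeAnnotation, PolyAAtlas, GroundTruth]:
    """Lay out non-overlapping gene models, their CPA sites, usage vectors
    and CLIP-binding ground truth; derive the matching poly(A)-site atlas."""
    cfg.validate()
    rng = _rng(cfg, 1)

    genes, transcripts, exons, cds_feats, utrs = [], [], [], [], []
    truth = GroundTruth()
    atlas_rows = []

    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1

    n_coding = 0
    gene_plan = []  # (gene_id, chrom, strand, start, end, utr_iv, biotype, k)
    gidx = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        cursor = int(rng.integers(*cfg.intergenic_gap))
        for _ in range(per_chrom[ci]):
            gene_id = f"G{gidx:04d}"
            gidx += 1
            strand = "+" if rng.random() < 0.5 else "-"
            noncoding = rng.random() < NONCODING_FRACTION
            utr_len = int(rng.integers(cfg.utr_len_range[0], cfg.utr_len_range[1] + 1))
            body_len = 1400  # exon1 (400) + intron (800) + 200 nt of coding terminal exon
            gene_len = body_len + utr_len
            start = cursor
            end = start + gene_len
            if cfg.chrom_len is not None and end > cfg.chrom_len:
                raise ValueError(
                    f"infeasible packing: gene {gene_id} would end at {end} > "
                    f"chrom_len={cfg.chrom_len} on {chrom}; increase chrom_len "
                    f"or reduce n_genes/utr_len_range")
            k = (1 if noncoding
                 else int(rng.integers(cfg.sites_per_gene_range[0],
                                       cfg.sites_per_gene_range[1] + 1)))
            if strand == "+":
                utr_iv = (end - utr_len, end)
            else:
                utr_iv = (start, start + utr_len)
            gene_plan.append((gene_id, chrom, strand, start, end, utr_iv,
                              "lincRNA" if noncoding else "protein_coding", k))
            if not noncoding:
                n_coding += 1
            cursor = end + int(rng.integers(*cfg.intergenic_gap))

    # choose shifted genes among multi-site coding genes, CLIP-bound among coding
    multi = [p[0] for p in gene_plan if p[7] >= 2 and p[6] == "protein_coding"]
    coding = [p[0] for p in gene_plan if p[6] == "protein_coding"]
    n_shift = int(round(cfg.frac_shifted * len(multi)))
    shifted = set(rng.choice(multi, size=min(n_shift, len(multi)), replace=False)) if multi else set()
    n_bound = int(round(cfg.frac_clip_bound * len(coding)))
    bound = set(rng.choice(coding, size=min(n_bound, len(coding)), replace=False)) if coding else set()

    for gene_id, chrom, strand, start, end, utr_iv, biotype, k in gene_plan:
        tx_id = f"{gene_id}.t1"
        genes.append(Gene(gene_id, chrom, strand, start, end, biotype))
        transcripts.append(Transcript(tx_id, gene_id, chrom, strand, start, end))
        if strand == "+":
            e1 = (start, start + 400)
            e2 = (start + 1200, end)
        else:
            e1 = (end - 400, end)
            e2 = (start, end - 1200)
        exons.append(Feature(tx_id, gene_id, chrom, strand, *e1))
        exons.append(Feature(tx_id, gene_id, chrom, strand, *e2))
        if biotype == "protein_coding":
            utrs.append(Feature(tx_id, gene_id, chrom, strand, *utr_iv))
            if strand == "+":
                cds_feats.append(Feature(tx_id, gene_id, chrom, strand, start, start + 400))
                cds_feats.append(Feature(tx_id, gene_id, chrom, strand, start + 1200, utr_iv[0]))
            else:
                cds_feats.append(Feature(tx_id, gene_id, chrom, strand, end - 400, end))
                cds_feats.append(Feature(tx_id, gene_id, chrom, strand, utr_iv[1], end - 1200))

        if biotype == "protein_coding":
            sites = _place_sites(rng, utr_iv[0], utr_iv[1], k, strand)
        else:
            # ncRNA cleavage just downstream of the annotated gene end
            sites = [end - 1 + 20] if strand == "+" else [start - 20]
        is_shifted = gene_id in shifted
        if is_shifted:
            mag = rng.uniform(*cfg.effect_range)
            delta = mag if rng.random() < DISTAL_SHIFT_PROB else -mag
        else:
            delta = 0.0
        usage_a, usage_b = _usage_vectors(rng, len(sites), delta)
        is_bound = gene_id in bound
        detected = list(rng.random(cfg.n_clip_experiments) < cfg.clip_detection_prob) \
            if is_bound else [False] * cfg.n_clip_experiments
        mean_usage = (usage_a + usage_b) / 2.0
        anchor = None
        if is_bound:
            # CLIP signal centres on the most-used CPA (ties -> distal)
            anchor = sites[int(np.flatnonzero(mean_usage == mean_usage.max())[-1])]
        truth.genes[gene_id] = GeneTruth(
            gene_id, chrom, strand, biotype, sites, usage_a, usage_b, delta,
            is_bound, detected, anchor, cfg.tail_mean, cfg.tail_sd)

        for j, (site, mu) in enumerate(zip(sites, mean_usage)):
            atlas_rows.append({
                "chrom": chrom, "start": max(site - 10, 0), "end": site + 11,
                "cluster_id": f"atlas_{gene_id}_{j}", "score": 0, "strand": strand,
                "tpm": round(float(mu) * 100.0, 4)})

    annotation = GenomeAnnotation(genes=genes, transcripts=transcripts,
                                  exons=exons, cds=cds_feats, utr3=utrs)
    atlas = PolyAAtlas(clusters=pd.DataFrame(atlas_rows).sort_values(
        ["chrom", "start", "cluster_id"], kind="mergesort").reset_index(drop=True))
    return annotation, atlas, truth


def sample_names(cfg: SimConfig) -> list[tuple[str, str]]:
    """(sample, condition) pairs, condition A first."""
    out = []
    for cond in CONDITIONS:
        for r in range(1, cfg.n_replicates_per_condition + 1):
            out.append((f"{cond}_{r}", cond))
    return out


def simulate_reads(cfg: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Per-read 3'-end records for all samples.

    Gene totals are negative-binomially dispersed around
    ``reads_per_gene_mean`` times a per-sample library factor; reads fall
    on CPA sites multinomially with the condition's usage vector; the
    templated end jitters by at most ``READ_JITTER`` nt.
    """
    cfg.validate()
    rng = _rng(cfg, 2)
    samples = sample_names(cfg)
    lib_factor = {s: float(rng.lognormal(0.0, 0.15)) for s, _ in samples}

    recs: list[tuple] = []
    nb_size = 10.0  # NB dispersion (shape); CV^2 = 1/mu + 1/size
    for gene_id in sorted(truth.genes):
        g = truth.genes[gene_id]
        for sample, cond in samples:
            usage = g.usage_a if cond == CONDITIONS[0] else g.usage_b
            mu = cfg.reads_per_gene_mean * lib_factor[sample]
            total = int(rng.negative_binomial(nb_size, nb_size / (nb_size + mu)))
            if total == 0:
                continue
            site_counts = rng.multinomial(total, usage)
            for site, n in zip(g.sites, site_counts):
                if n == 0:
                    continue
                jit = rng.integers(-READ_JITTER, READ_JITTER + 1, size=n)
                if g.strand == "+":
                    pos = site + 1 + jit  # 1-based
                else:
                    pos = site + 1 - jit
                below = rng.random(n) < SUBTHRESHOLD_A_FRACTION
                n_a = np.where(below, rng.integers(0, 4, size=n),
                               4 + rng.poisson(6.0, size=n))
                tails = np.maximum(np.rint(rng.normal(g.tail_mean, g.tail_sd, size=n)), 1)
                for p, a, t in zip(pos, n_a, tails):
                    recs.append((sample, cond, g.chrom, int(max(p, 1)), g.strand,
                                 int(a), int(t)))
    return pd.DataFrame(recs, columns=["sample", "condition", "chrom", "pos_1based",
                                       "strand", "n_nontemplated_A", "tail_length"])


def simulate_clip(cfg: SimConfig, annotation: GenomeAnnotation,
                  truth: GroundTruth) -> list[pd.DataFrame]:
    """One BED6 peak table per CLIP experiment.

    Each bound gene contributes, in each experiment where it was detected,
    a 30-80 nt peak centred Normal(anchor CPA, ``clip_jitter_sd``) and
    clipped into its 3'UTR; background noise peaks land at uniform
    non-3'UTR positions within gene bodies.
    """
    cfg.validate()
    rng = _rng(cfg, 3)
    out: list[pd.DataFrame] = []
    gene_list = sorted(annotation.genes_by_id)
    for e in range(cfg.n_clip_experiments):
        exp_id = f"clipexp{e + 1}"
        rows = []
        pk = 0
        for gene_id in sorted(truth.genes):
            g = truth.genes[gene_id]
            if not (g.clip_bound and g.clip_detected[e]):
                continue
            utr = annotation.utr3_by_gene[gene_id][0]
            width = int(rng.integers(30, 81))
            centre = int(round(g.clip_anchor + rng.normal(0.0, cfg.clip_jitter_sd)))
            # the peak centre must stay inside the 3'UTR; the interval may overhang
            centre = int(np.clip(centre, utr.start, utr.end - 1))
            start = centre - width // 2
            rows.append({"chrom": g.chrom, "start": start, "end": start + width,
                         "name": f"{exp_id}_peak{pk}", "score": 0, "strand": g.strand})
            pk += 1
        for _ in range(cfg.clip_noise_peaks_per_experiment):
            gid = gene_list[int(rng.integers(len(gene_list)))]
            gene = annotation.genes_by_id[gid]
            width = int(rng.integers(30, 81))
            utrs = annotation.utr3_by_gene.get(gid, [])
            for _try in range(10):
                centre = int(rng.integers(gene.start + width, gene.end - width))
                if not any(u.start <= centre < u.end for u in utrs):
                    break
            start = centre - width // 2
            rows.append({"chrom": gene.chrom, "start": start, "end": start + width,
                         "name": f"{exp_id}_noise{pk}", "score": 0, "strand": gene.strand})
            pk += 1
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
        df = df.sort_values(["chrom", "start", "name"], kind="mergesort").reset_index(drop=True)
        df.attrs["experiment_id"] = exp_id
        out.append(df)
    return out


def simulate_dataset(cfg: SimConfig, outdir) -> dict[str, Path]:
    """Run all three simulation stages and write every output file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, atlas, truth = simulate_annotation(cfg)
    reads = simulate_reads(cfg, truth)
    clip_sets = simulate_clip(cfg, annotation, truth)

    paths = {"annotation": outdir / "annotation.gtf",
             "atlas": outdir / "atlas.bed",
             "reads": outdir / "reads.tsv",
             "truth": outdir / "truth.tsv",
             "config": outdir / "config_used.yaml"}
    write_gtf(annotation, paths["annotation"])
    write_atlas(atlas, paths["atlas"])
    write_reads_tsv(reads, paths["reads"])
    write_tsv(truth.to_frame(), paths["truth"],
              comment="ground truth; sites are 1-based last templated positions, proximal->distal")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    for i, df in enumerate(clip_sets, start=1):
        p = outdir / f"clip_{i}.bed"
        write_bed(df, p)
        paths[f"clip_{i}"] = p
    return paths
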