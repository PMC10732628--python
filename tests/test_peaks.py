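"""Peak calling, classification priority scheme, and usage matrices."""

import numpy as np
import pandas as pd
import pytest

import apa_landscape as al
from apa_landscape.annotation import Feature, Gene, GenomeAnnotation, Transcript
from apa_landscape.peaks import CATEGORIES


def reads_frame(positions, sample="s1", condition="A", chrom="chr1", strand="+",
                n_a=10, tail=70):
    return pd.DataFrame({
        "sample": sample, "condition": condition, "chrom": chrom,
        "pos_1based": list(positions), "strand": strand,
        "n_nontemplated_A": n_a, "tail_length": tail})


def brute_force_clusters(positions, merge_gap):
    """O(n^2) single-linkage clustering oracle: repeatedly merge any two
    clusters whose closest members are within merge_gap."""
    clusters = [[p] for p in positions]
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if min(abs(a - b) for a in clusters[i] for b in clusters[j]) <= merge_gap:
                    clusters[i] += clusters.pop(j)
                    merged = True
                    break
            if merged:
                break
    return sorted(tuple(sorted(c)) for c in clusters)


def test_adjacent_ends_form_one_peak_with_tie_broken_summit():
    reads = reads_frame([100] * 5 + [101] * 5 + [102] * 5)
    pks = al.call_peaks(reads, min_reads=10)
    assert len(pks) == 1
    assert pks[0].summit == 100  # equal counts: tie -> smallest coordinate
    assert (pks[0].start, pks[0].end) == (99, 102)


def test_gap_beyond_merge_distance_splits_peaks():
    reads = reads_frame([100] * 10 + [150] * 10)
    pks = al.call_peaks(reads, merge_gap=10, min_reads=10)
    assert len(pks) == 2


def test_a_min_filter_discards_unevidenced_reads():
    low = reads_frame([100] * 20, n_a=2)
    high = reads_frame([200] * 20, n_a=6)
    pks = al.call_peaks(pd.concat([low, high]), a_min=4, min_reads=10)
    assert [p.summit for p in pks] == [200]


def test_call_peaks_matches_brute_force_oracle():
    """Production clustering equals the O(n^2) transitive-merge oracle on
    randomised toy inputs (<=200 reads)."""
    rng = np.random.default_rng(42)
    for trial in range(20):
        positions = sorted(rng.integers(1, 400, size=rng.integers(5, 200)))
        gap = int(rng.integers(1, 15))
        reads = reads_frame(positions)
        pks = al.call_peaks(reads, merge_gap=gap, min_reads=1)
        got = sorted((p.start + 1, p.end) for p in pks)
        expected = [(c[0], c[-1]) for c in brute_force_clusters(positions, gap)]
        assert got == sorted(expected), f"trial {trial} gap {gap}"


def test_min_reads_and_merge_gap_monotonicity():
    rng = np.random.default_rng(7)
    positions = list(rng.integers(1, 2000, size=300))
    reads = reads_frame(positions)
    n_by_minreads = [len(al.call_peaks(reads, min_reads=m, merge_gap=5))
                     for m in (1, 2, 5, 10, 20)]
    assert n_by_minreads == sorted(n_by_minreads, reverse=True)
    n_by_gap = [len(al.call_peaks(reads, min_reads=1, merge_gap=g))
                for g in (1, 3, 10, 30)]
    assert n_by_gap == sorted(n_by_gap, reverse=True)


def test_per_sample_counts_tallied():
    r1 = reads_frame([100] * 6, sample="s1")
    r2 = reads_frame([101] * 7, sample="s2", condition="B")
    pks = al.call_peaks(pd.concat([r1, r2]), min_reads=10)
    assert len(pks) == 1
    assert pks[0].counts == {"s1": 6, "s2": 7}


def test_negative_parameters_rejected():
    with pytest.raises(ValueError):
        al.call_peaks(reads_frame([1]), a_min=-1)
    with pytest.raises(ValueError):
        al.call_peaks(reads_frame([1]), merge_gap=-1)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def toy_annotation():
    """A + strand coding gene with a 3'UTR ending at 2000, a second
    same-strand gene at 3000-4000, a - strand gene at 6000-7000, a
    non-coding gene at 9000-9500, and an isolated gene at 20000-22000
    for allowance-boundary checks."""
    genes = [Gene("gA", "chr1", "+", 0, 2000),
             Gene("gB", "chr1", "+", 3000, 4000),
             Gene("gC", "chr1", "-", 6000, 7000),
             Gene("gN", "chr1", "+", 9000, 9500, biotype="lincRNA"),
             Gene("gD", "chr1", "+", 20000, 22000)]
    tx = [Transcript(f"{g.gene_id}.t", g.gene_id, g.chrom, g.strand, g.start, g.end)
          for g in genes]
    exons = [Feature("gA.t", "gA", "chr1", "+", 0, 2000),
             Feature("gB.t", "gB", "chr1", "+", 3000, 3300),
             Feature("gB.t", "gB", "chr1", "+", 3800, 4000),
             Feature("gC.t", "gC", "chr1", "-", 6000, 7000),
             Feature("gN.t", "gN", "chr1", "+", 9000, 9500),
             Feature("gD.t", "gD", "chr1", "+", 20000, 22000)]
    utr3 = [Feature("gA.t", "gA", "chr1", "+", 1500, 2000),
            Feature("gB.t", "gB", "chr1", "+", 3900, 4000),
            Feature("gC.t", "gC", "chr1", "-", 6000, 6400),
            Feature("gD.t", "gD", "chr1", "+", 21500, 22000)]
    return GenomeAnnotation(genes=genes, transcripts=tx, exons=exons, cds=[], utr3=utr3)


def peak_at(summit_1based, strand="+", chrom="chr1"):
    return al.PolyAPeak(peak_id="p", chrom=chrom, strand=strand,
                        start=summit_1based - 1, end=summit_1based,
                        summit=summit_1based, counts={"s1": 20})


@pytest.mark.parametrize("summit, strand, category, gene", [
    (1700, "+", "utr3", "gA"),            # inside annotated 3'UTR
    (2500, "+", "utr3", "gA"),            # 500 nt downstream of the UTR end, intergenic
    (3100, "+", "exon", "gB"),            # within allowance of gA but inside gB: falls through
    (3500, "+", "intron", "gB"),          # inside gB between its exons
    (8000, "+", "unassigned", None),      # > 2000 nt downstream of every UTR, intergenic
    (6500, "+", "antisense", "gC"),       # inside - strand gene only
    (6200, "-", "utr3", "gC"),            # minus-strand UTR
    (5800, "-", "utr3", "gC"),            # 200 nt downstream of - strand UTR end (6000)
    (9600, "+", "ncrna_downstream", "gN"),  # just past the non-coding gene end
    (100, "+", "exon", "gA"),             # exon upstream of the UTR
])
def test_classification_priority_scheme(toy_annotation, summit, strand, category, gene):
    pk = peak_at(summit, strand)
    al.classify_peaks([pk], toy_annotation)
    assert (pk.category, pk.gene_id) == (category, gene)


def test_downstream_allowance_boundary_is_inclusive(toy_annotation):
    # gD's UTR ends at 0-based 21999; exactly 2000 nt downstream is 23999
    pk = peak_at(24000, "+")
    al.classify_peaks([pk], toy_annotation)
    assert (pk.category, pk.gene_id) == ("utr3", "gD")
    pk2 = peak_at(24001, "+")
    al.classify_peaks([pk2], toy_annotation)
    assert pk2.category == "unassigned"


def test_category_partition_property(called_peaks):
    counts = al.category_counts(called_peaks)
    assert set(counts) == set(CATEGORIES)
    assert sum(counts.values()) == len(called_peaks)
    assert all(p.gene_id for p in called_peaks
               if p.category in ("utr3", "exon", "intron"))


def test_peak_count_per_gene_matches_true_site_count(world, called_peaks):
    """With read jitter below the merge gap and sites >= 50 nt apart, each
    true site that clears min_reads appears as exactly one peak."""
    truth = world["truth"]
    by_gene = {}
    for p in called_peaks:
        if p.category == "utr3":
            by_gene.setdefault(p.gene_id, []).append(p)
    n_checked = 0
    for g in truth.genes.values():
        if g.biotype != "protein_coding":
            continue
        # count sites with comfortable read support in the simulation
        expected = sum(1 for u in (g.usage_a + g.usage_b) / 2 if u * 300 * 6 >= 30)
        got = len(by_gene.get(g.gene_id, []))
        if expected == len(g.sites):  # all sites clearly above threshold
            assert got == expected, g.gene_id
            n_checked += 1
    assert n_checked >= 20


# ---------------------------------------------------------------------------
# usage matrices
# ---------------------------------------------------------------------------

def test_minus_strand_usage_rows_are_proximal_to_distal():
    pks = [al.PolyAPeak("p1", "chr1", "-", 3999, 4000, 4000, {"s1": 5},
                        category="utr3", gene_id="g"),
           al.PolyAPeak("p2", "chr1", "-", 4999, 5000, 5000, {"s1": 7},
                        category="utr3", gene_id="g")]
    mats = al.build_usage_matrices(pks, {"s1": "A"})
    assert mats[0].peak_ids == ["p2", "p1"]  # 5000 is proximal on - strand
    assert mats[0].counts[:, 0].tolist() == [7, 5]


def test_single_peak_gene_emitted_but_not_testable():
    pks = [al.PolyAPeak("p1", "chr1", "+", 99, 100, 100, {"s1": 30},
                        category="utr3", gene_id="g")]
    mats = al.build_usage_matrices(pks, {"s1": "A"})
    assert len(mats) == 1
    assert not mats[0].apa_testable


def test_usage_matrix_order_matches_true_site_order(world, called_peaks, sample_conditions):
    truth = world["truth"]
    mats = {m.gene_id: m for m in al.build_usage_matrices(called_peaks, sample_conditions)}
    checked = 0
    for g in truth.genes.values():
        if g.biotype != "protein_coding" or len(g.sites) < 3 or g.gene_id not in mats:
            continue
        m = mats[g.gene_id]
        if m.n_peaks != len(g.sites):
            continue
        pk_by_id = {p.peak_id: p for p in called_peaks}
        summits = [pk_by_id[pid].summit - 1 for pid in m.peak_ids]
        # proximal->distal order must match the true 5'->3' site order
        assert summits == sorted(summits, reverse=(g.strand == "-"))
        np.testing.assert_allclose(summits, g.sites, atol=5)
        checked += 1
    assert checked >= 3
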