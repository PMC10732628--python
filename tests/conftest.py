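import numpy as np
import pandas as pd
import pytest

import apa_landscape as al


@pytest.fixture(scope="session")
def small_cfg() -> al.SimConfig:
    return al.SimConfig(n_genes=60, n_chroms=2, seed=1)


@pytest.fixture(scope="session")
def world(small_cfg):
    """One simulated dataset shared across tests: annotation, atlas,
    ground truth, reads and CLIP peak sets."""
    ann, atlas, truth = al.simulate_annotation(small_cfg)
    reads = al.simulate_reads(small_cfg, truth)
    clip_sets = al.simulate_clip(small_cfg, ann, truth)
    return {"cfg": small_cfg, "ann": ann, "atlas": atlas, "truth": truth,
            "reads": reads, "clip": clip_sets}


@pytest.fixture(scope="session")
def called_peaks(world):
    pks = al.call_peaks(world["reads"])
    al.classify_peaks(pks, world["ann"])
    return pks


@pytest.fixture(scope="session")
def sample_conditions(world):
    reads = world["reads"]
    return dict(reads[["sample", "condition"]].drop_duplicates().itertuples(index=False))


@pytest.fixture(scope="session")
def usage_matrices(called_peaks, sample_conditions):
    return al.build_usage_matrices(called_peaks, sample_conditions)


def make_usage(counts, samples=None, conditions=None, gene_id="G", strand="+"):
    """Build a UsageMatrix from a peaks x samples count array."""
    counts = np.asarray(counts, dtype=np.int64)
    n = counts.shape[1]
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    if conditions is None:
        half = n // 2
        conditions = ["A"] * half + ["B"] * (n - half)
    return al.UsageMatrix(gene_id=gene_id, peak_ids=[f"p{i}" for i in range(counts.shape[0])],
                          counts=counts, samples=list(samples),
                          conditions=list(conditions), strand=strand)
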