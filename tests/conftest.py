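"""Shared synthetic fixtures; heavy ones are session-scoped."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from screg import cnn, synth
from screg._types import NucleusFeatureMatrix


@pytest.fixture(scope="session")
def small_world():
    """Genome + 3 enhancer classes + fragments for clustering/peak tests."""
    genome = synth.make_genome(2, 300_000, gc=0.45, seed=7)
    truth = synth.plant_enhancers(genome, n_classes=3, regions_per_class=40,
                                  motif_len=8, seed=1)
    fragments = synth.simulate_fragments(
        truth, n_nuclei=150, depth_mean=1000, doublet_rate=0.0, n_batches=1, seed=2
    )
    return genome, truth, fragments


@pytest.fixture(scope="session")
def multiome_world():
    """World with doublets, batches and multiome RNA for QC/impute/link tests."""
    genome = synth.make_genome(1, 400_000, gc=0.45, seed=11)
    truth = synth.plant_enhancers(genome, n_classes=3, regions_per_class=40,
                                  motif_len=8, seed=3)
    fragments = synth.simulate_fragments(
        truth, n_nuclei=400, depth_mean=600, doublet_rate=0.10, n_batches=2,
        seed=4, multiome_fraction=0.4,
    )
    rna = synth.simulate_multiome_rna(truth, fragments, n_genes=60,
                                      linked_fraction=0.4, seed=5)
    return genome, truth, fragments, rna


@pytest.fixture(scope="session")
def enhancer_examples():
    """5-class planted-motif training set for the sequence classifier."""
    genome = synth.make_genome(2, 1_500_000, gc=0.45, seed=7)
    truth = synth.plant_enhancers(genome, n_classes=5, regions_per_class=400,
                                  motif_len=8, seed=1)
    examples = []
    for name, cls in truth.class_of_region.items():
        r = truth.regions[truth.regions["name"] == name].iloc[0]
        centre = (r.start + r.end) // 2
        seq = genome.sequence[r.chrom][centre - 200 : centre + 201]
        examples.append(cnn.EnhancerExample(cnn.one_hot(seq), cls))
    return genome, truth, examples


@pytest.fixture(scope="session")
def trained_model(enhancer_examples):
    """Desk-scale classifier trained on the planted-motif examples."""
    _, _, examples = enhancer_examples
    model, report = cnn.train_cnn(examples, cnn.desk_spec(epochs=14), seed=0)
    return model, report


@pytest.fixture(scope="session")
def linked_accessibility():
    """Accessibility matrix with planted co-accessible peak pairs."""
    rng = np.random.default_rng(0)
    n_nuclei, n_peaks, spacing = 300, 60, 10_000
    pos = np.arange(n_peaks) * spacing + 5000
    peaks = pd.DataFrame({"chrom": "chr1", "start": pos - 200, "end": pos + 200})
    true_pairs = [(i, i + 1) for i in range(0, 40, 4)]
    lam = np.full((n_nuclei, n_peaks), 2.0)
    for i, j in true_pairs:
        f = rng.gamma(2, 1.5, size=n_nuclei)
        lam[:, i] += 2 * f
        lam[:, j] += 2 * f
    X = rng.poisson(lam)
    mat = NucleusFeatureMatrix(
        sp.csr_matrix(X),
        [f"n{i}" for i in range(n_nuclei)],
        [f"chr1:{s}-{e}" for s, e in zip(peaks["start"], peaks["end"])],
        feature_kind="peak",
    )
    return mat, peaks, true_pairs
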