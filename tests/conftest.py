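"""Shared fixtures: tiny hand-built genotype matrices and synthetic sources."""

import numpy as np
import pytest

from deintrogress.genotype_io import CollectionMeta, GenotypeMatrix, LocusInfo
from deintrogress.popgen import AlleleFreqs


def make_gm(dosage, missing=None, sample_prefix="ind", locus_prefix="L", alleles=None):
    """Build a GenotypeMatrix from a nested list / array of dosages."""
    dosage = np.asarray(dosage)
    n, L = dosage.shape
    individuals = [f"{sample_prefix}{i}" for i in range(n)]
    loci = [
        LocusInfo(f"{locus_prefix}{j}", alleles[j] if alleles else ("A", "B"))
        for j in range(L)
    ]
    return GenotypeMatrix(individuals, loci, dosage, missing)


def make_freqs(freq, label="pop", n_per_locus=1000):
    freq = np.asarray(freq, dtype=float)
    return AlleleFreqs(
        label,
        [f"L{j}" for j in range(len(freq))],
        freq,
        np.full(len(freq), n_per_locus),
    )


@pytest.fixture
def tiny_gm():
    """3 individuals x 4 loci with one masked cell."""
    dosage = [[0, 1, 2, 1], [1, 1, 0, 2], [2, 0, 1, 0]]
    missing = np.zeros((3, 4), dtype=bool)
    missing[1, 2] = True
    return make_gm(dosage, missing)


@pytest.fixture
def two_pop_meta():
    def build(gm, split):
        meta = []
        for i, s in enumerate(gm.individuals):
            label = "A" if i < split else "B"
            meta.append(CollectionMeta(s, label, "river", 2000, "wild_caught"))
        return meta

    return build
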