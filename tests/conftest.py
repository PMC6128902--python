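import numpy as np
import pandas as pd
import pytest

from dosagelens import (
    CoverageTrack, FragmentSet, GeneAnnotation, GenomeModel, SimConfig,
)


@pytest.fixture
def tiny_genome():
    return GenomeModel(("chrX", "chr2"), {"chrX": 10_000, "chr2": 10_000}, "chrX")


@pytest.fixture
def tiny_annotation():
    return GeneAnnotation(pd.DataFrame({
        "gene_id": ["gA", "gB", "gC"],
        "chrom": ["chr2", "chr2", "chrX"],
        "start": [1000, 5000, 2000],
        "end": [3000, 7000, 4500],
        "strand": ["+", "-", "+"],
    }))


def make_fragments(rows, **prov):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "mapq", "dup_flag"])
    return FragmentSet(df, **prov)


@pytest.fixture
def frag_factory():
    return make_fragments


def make_track(genome, binsize, arrays, normalization="raw"):
    data = {c: np.asarray(arrays[c], dtype=float) for c in genome.names}
    return CoverageTrack(genome=genome, binsize=binsize, data=data,
                         normalization=normalization)


@pytest.fixture
def track_factory():
    return make_track


@pytest.fixture
def small_cfg():
    # scaled-down study conditions for fast end-to-end tests
    return SimConfig(chrom_length_bp=100_000, n_genes_per_chrom=20,
                     n_has=10, n_auto_sites_per_cluster=(4, 3, 3), seed=7)
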