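import numpy as np
import pandas as pd
import pytest

from emkmer.io import IPD_COLUMNS, ReferenceSet, SampleKinetics, aggregate_medians
from emkmer.kmers import MotifKey
from emkmer.simulate import GenomeSpec, MotifPlant, SimConfig, plant_and_simulate


def make_records(rows):
    """rows: (contig, position, strand, read_id, ipd) tuples."""
    return pd.DataFrame(rows, columns=IPD_COLUMNS)


def kinetics_from_map(role, entries, min_depth=1):
    """entries: {(contig, strand, position): [ipd, ...]}"""
    rows = []
    for (c, s, p), ipds in entries.items():
        for i, v in enumerate(ipds):
            rows.append((c, p, s, f"r{c}{s}{p}_{i}", v))
    return aggregate_medians(make_records(rows), role=role, min_depth=min_depth)


@pytest.fixture
def tiny_ref():
    return ReferenceSet([("c1", "GATCGATC")])


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-motif dataset shared by integration-style tests.

    20 kb genome, one strong GATC plant, 10X/10X; enough occurrences for
    4/5-mers to be scorable but cheap to simulate.
    """
    g = GenomeSpec(
        name="g",
        length=20_000,
        coverage=10.0,
        plants=(MotifPlant(MotifKey("GATC", 1)),),
    )
    return plant_and_simulate(SimConfig(genomes=(g,), seed=7))
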