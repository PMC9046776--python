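"""Shared fixtures: toy genomes, synthetic cytoband maps, tiny pair tables.

All fixtures are generated programmatically; the cytoband maps are
synthetic stand-ins whose band boundaries are chosen so that the genomic
coordinates exercised by the nomenclature tests fall in the bands a
GRCh37 cytoband file would give them.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from matesv import GenomeMap
from matesv.pairio import PAIR_FRAME_COLUMNS

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def toy_genome():
    return GenomeMap(chromosomes=(("chr1", 30_000_000), ("chr2", 30_000_000)))


@pytest.fixture(scope="session")
def banded_toy_genome():
    """Toy genome with p/q bands for nomenclature round-trips."""
    bands = []
    for chrom in ("chr1", "chr2"):
        bands += [
            (chrom, 1, 10_000_000, "p11"),
            (chrom, 10_000_001, 15_000_000, "q11"),
            (chrom, 15_000_001, 30_000_000, "q12"),
        ]
    return GenomeMap(chromosomes=(("chr1", 30_000_000), ("chr2", 30_000_000)),
                     cytobands=tuple(bands))


@pytest.fixture(scope="session")
def grch37_like_genome():
    """Synthetic cytoband context for the coordinates used in the
    reference-table nomenclature checks (band extents approximate GRCh37)."""
    chroms = (
        ("chr5", 181_000_000), ("chr7", 160_000_000), ("chr13", 115_000_000),
        ("chr14", 107_000_000), ("chr8", 146_000_000),
    )
    bands = (
        ("chr5", 1, 48_800_000, "p11"),
        ("chr5", 48_800_001, 88_000_000, "q14.1"),
        ("chr5", 88_000_001, 92_300_000, "q14.3"),
        ("chr5", 92_300_001, 181_000_000, "q15"),
        ("chr7", 1, 60_100_000, "p11"),
        ("chr7", 60_100_001, 130_000_000, "q31"),
        ("chr7", 130_000_001, 132_600_000, "q32.3"),
        ("chr7", 132_600_001, 138_200_000, "q33"),
        ("chr7", 138_200_001, 160_000_000, "q34"),
        ("chr13", 1, 17_700_000, "p11"),
        ("chr13", 17_700_001, 36_000_000, "q13.1"),
        ("chr13", 36_000_001, 40_100_000, "q13.3"),
        ("chr13", 40_100_001, 115_000_000, "q14"),
        ("chr14", 1, 17_200_000, "p11"),
        ("chr14", 17_200_001, 44_000_000, "q21.1"),
        ("chr14", 44_000_001, 47_200_000, "q21.2"),
        ("chr14", 47_200_001, 107_000_000, "q21.3"),
        ("chr8", 1, 2_200_000, "p23.3"),
        ("chr8", 2_200_001, 6_200_000, "p23.2"),
        ("chr8", 6_200_001, 12_700_000, "p23.1"),
        ("chr8", 12_700_001, 19_000_000, "p22"),
        ("chr8", 19_000_001, 146_000_000, "q11"),
    )
    return GenomeMap(chromosomes=chroms, cytobands=bands)


def make_pair_frame(rows):
    """rows: (pair_id, chrom_a, pos_a, strand_a, chrom_b, pos_b, strand_b)
    with MAPQ 60 and no duplicate flag."""
    data = [(r[0], r[1], r[2], r[3], 60, r[4], r[5], r[6], 60, False)
            for r in rows]
    return pd.DataFrame(data, columns=list(PAIR_FRAME_COLUMNS))


@pytest.fixture
def pair_frame_factory():
    return make_pair_frame
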