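import numpy as np
import pandas as pd
import pytest

import kataegis as kg


@pytest.fixture(scope="session")
def small_genome():
    """Two-chromosome 700-kb random genome with sequence, GC 0.38."""
    return kg.generate_genome({"chr1": 400_000, "chr2": 300_000}, 0.38, seed=101)


@pytest.fixture(scope="session")
def lengths_only_genome():
    """Yeast-scale 16-chromosome genome without sequence."""
    return kg.GenomeModel(
        names=list(kg.SACCER3_LENGTHS), lengths=dict(kg.SACCER3_LENGTHS)
    )


@pytest.fixture
def tiny_catalog():
    return kg.catalog_from_records(
        [
            ("c1", "chr1", 100, "C", "T"),
            ("c1", "chr1", 600, "G", "A"),
            ("c2", "chr2", 50, "C", "G"),
        ]
    )


def make_catalog(rows, provenance=""):
    return kg.MutationCatalog(
        pd.DataFrame(rows, columns=["clone", "chrom", "pos", "ref", "alt"]),
        provenance,
    )


@pytest.fixture
def make_positions_catalog():
    """Catalog with C>T mutations at given positions on one clone/chromosome."""

    def _make(positions, clone="c1", chrom="chr1"):
        return make_catalog([(clone, chrom, p, "C", "T") for p in positions])

    return _make
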