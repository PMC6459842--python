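import numpy as np
import pandas as pd
import pytest

from splicevo import catalog as cat
from splicevo import simulate as sim


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort reused across read-only tests."""
    cfg = sim.SimConfig(seed=11, n_individuals_per_pop=(40, 40), n_genes=12)
    return sim.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_catalog(small_cohort):
    kept, _ = cat.assign_junctions(
        small_cohort.junctions, small_cohort.annotation,
        small_cohort.fpkm, small_cohort.metadata)
    table = cat.build_catalog(kept, small_cohort.annotation,
                              small_cohort.metadata, small_cohort.gerp)
    return kept, table


@pytest.fixture(scope="session")
def species_tree():
    from splicevo.evolution import DatedTree

    newick, ages = sim.build_species_tree()
    return DatedTree(newick, ages)


def toy_junctions(rows, samples=("s1", "s2")):
    """Build a junction table from (chrom, start, end, strand, gene,
    counts-per-sample) tuples."""
    recs = []
    for chrom, start, end, strand, gene, counts in rows:
        rec = dict(chrom=chrom, start=start, end=end, strand=strand,
                   gene_id=gene)
        rec.update(dict(zip(samples, counts)))
        recs.append(rec)
    return pd.DataFrame(recs)


@pytest.fixture
def toy_meta():
    return pd.DataFrame(dict(sample=["s1", "s2"],
                             individual=["i1", "i1"],
                             population=["AFB", "AFB"],
                             condition=["NS", "LPS"]))
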