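import numpy as np
import pytest

from chromoscope import simulate as sim
from chromoscope import expression as xp
from chromoscope import effects as fx


@pytest.fixture(scope="session")
def fig1():
    return sim.fig1_like()


@pytest.fixture(scope="session")
def fig1_counts(fig1):
    """One seeded draw of the trio count matrices for the preset."""
    rng = np.random.default_rng(7)
    gene_counts, exon_counts, samples = sim.simulate_trio_counts(
        fig1.genes,
        fig1.baselines,
        fig1.effect_multipliers,
        rng,
        cell_type_programs=sim.fig1_cell_type_programs(fig1),
        fragment_bounds=sim.fig1_fragment_bounds(),
    )
    return gene_counts, exon_counts, samples


@pytest.fixture(scope="session")
def fig1_effects(fig1):
    return fx.classify_genes(fig1.genes, fig1.rearrangement)


@pytest.fixture(scope="session")
def fig1_comparisons(fig1_counts):
    gene_counts, _, samples = fig1_counts
    norm = gene_counts / xp.size_factors(gene_counts)
    merged, sheet = xp.merge_groups(norm, samples)
    return xp.trio_compare(merged, sheet), sheet
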