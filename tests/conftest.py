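import numpy as np
import pytest

from pvrnet import (
    CountMatrix,
    GeneSet,
    PipelineConfig,
    SimulationDesign,
    enrichment_analysis,
    expression_filter,
    k_hop_neighborhood,
    run_de,
    simulate_counts,
    simulate_network,
)


def reduced_enrichment_pipeline(rep_seed, rho, de_fraction=0.1,
                                iterations=199, null_top_k=None):
    """Counts -> DE -> planted network -> enrichment, at reduced size.

    With ``null_top_k`` set (used when no effects are planted), the gene
    set is the top-k genes by exact-test p instead of the intersection —
    a fixed-size selection whose network overlap is still governed by
    the uniform placement null.
    """
    design = SimulationDesign(
        n_genes=400,
        samples_per_group={"RPE": 4, "TNT": 4, "PVR": 2},
        dispersion=0.05,
        de_fraction=de_fraction,
        library_size_range=(5e4, 1e5),
        rng_seed=rep_seed,
    )
    cm, truth = simulate_counts(design)
    filt = expression_filter(cm)
    res_a, _, sig = run_de(filt, ("RPE", "TNT"), PipelineConfig())
    if null_top_k is not None:
        sig = GeneSet("null_top", res_a.table.nsmallest(null_top_k, "pvalue")["gene"])
    seed_gene = filt.gene_ids[0]
    net = simulate_network(
        380, 3, seed_gene, rho, truth, rep_seed + 10_000, target_hood_frac=0.35
    )
    hood = k_hop_neighborhood(net, seed_gene, 2)
    universe = GeneSet("universe", filt.gene_ids)
    hood = GeneSet("hood", hood.genes & universe.genes)
    de = GeneSet("de", sig.genes & universe.genes)
    if len(de) == 0:
        return None
    return enrichment_analysis(de, hood, universe, iterations, rep_seed)


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 genes x 4 samples, two groups, hand-enterable numbers."""
    counts = np.array(
        [
            [10, 12, 100, 110],
            [50, 55, 50, 52],
            [0, 1, 40, 38],
        ]
    )
    samples = ["a1", "a2", "b1", "b2"]
    groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    return CountMatrix(["g1", "g2", "g3"], samples, counts, groups)


@pytest.fixture(scope="session")
def small_simulation():
    """One fixed small three-group simulation shared across tests."""
    design = SimulationDesign(
        n_genes=400,
        samples_per_group={"RPE": 5, "TNT": 5, "PVR": 3},
        dispersion=0.05,
        library_size_range=(2e5, 4e5),
        rng_seed=42,
    )
    cm, truth = simulate_counts(design)
    return design, cm, truth
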