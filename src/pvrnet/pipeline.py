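"""End-to-end orchestration of the transcriptome analysis.

Given counts + groups and an interaction network, run both DE methods
for each pairwise comparison, intersect with the two-fold rule, tally
Venn overlaps, decompose the significant genes by SVD, score the seed
neighborhood enrichment, and build the annotated sub-network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

from .core_io import CountMatrix, GeneSet, PipelineConfig
from .diffexpr import (
    DEResult,
    estimate_common_dispersion,
    exact_test_nb,
    expression_filter,
    logcpm_welch_test,
    significant_genes,
    venn_overlap,
)
from .graphstats import betweenness, detect_communities, induce_subnetwork
from .netenrich import EnrichmentResult, enrichment_analysis, k_hop_neighborhood
from .svd_eigen import eigen_decompose, eigenspace_coordinates, transform_expression

__all__ = ["PipelineResult", "run_de", "run_pipeline"]


@dataclass
class PipelineResult:
    filtered: CountMatrix
    de_results: dict[str, tuple[DEResult, DEResult]]
    significant: dict[str, GeneSet]
    venn: dict[str, int] | None
    fractions: list[float]
    group_coordinates: pd.DataFrame | None
    enrichment: dict[str, EnrichmentResult] = field(default_factory=dict)
    subnetwork: nx.Graph | None = None
    communities: object = None


def run_de(
    cm: CountMatrix, comparison: tuple[str, str], config: PipelineConfig
) -> tuple[DEResult, DEResult, GeneSet]:
    """Both DE methods plus the intersected significant set (pre-filtered counts)."""
    phi = estimate_common_dispersion(cm, comparison)
    res_a = exact_test_nb(cm, comparison, phi, config.prior_count)
    res_b = logcpm_welch_test(cm, comparison, config.prior_count)
    return res_a, res_b, significant_genes(res_a, res_b, config)


def run_pipeline(
    cm: CountMatrix,
    network: nx.Graph | None = None,
    seed_gene: str | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    config = config or PipelineConfig()
    min_cpm, min_samples = config.expression_filter
    filtered = expression_filter(cm, min_cpm, min_samples)

    de_results: dict[str, tuple[DEResult, DEResult]] = {}
    significant: dict[str, GeneSet] = {}
    for ga, gb in combinations(filtered.groups, 2):
        res_a, res_b, sig = run_de(filtered, (ga, gb), config)
        de_results[sig.name] = (res_a, res_b)
        significant[sig.name] = sig

    sets = list(significant.values())
    venn = venn_overlap(sets[:3]) if len(sets) >= 2 else None

    all_sig = GeneSet("all_significant", set().union(*(s.genes for s in sets)))
    fractions, coords = [], None
    if len(all_sig) >= 2:
        expr = transform_expression(filtered)
        dec = eigen_decompose(expr, all_sig)
        fractions = list(dec.fractions)
        coords = eigenspace_coordinates(
            dec, "group_sums", (1, 2), filtered.group_of
        )

    result = PipelineResult(
        filtered, de_results, significant, venn, fractions, coords
    )

    if network is not None and seed_gene is not None:
        hood = k_hop_neighborhood(network, seed_gene, config.k_hops)
        universe = GeneSet("universe", filtered.gene_ids)
        net_in_universe = GeneSet(hood.name, hood.genes & universe.genes)
        for name, sig in significant.items():
            if len(sig) == 0:
                continue
            result.enrichment[name] = enrichment_analysis(
                sig,
                net_in_universe,
                universe,
                iterations=config.n_iterations,
                rng_seed=config.rng_seed,
            )
        # sub-network from the RPE-vs-PVR-style comparison if present, else first
        target = next(
            (n for n in significant if set(n.split("_vs_")) == {"RPE", "PVR"}),
            next(iter(significant), None),
        )
        if target and len(significant[target]) > 0:
            overlap_genes = GeneSet(
                f"{target}_x_network", significant[target].genes & hood.genes
            )
            if len(overlap_genes) > 0:
                sub = induce_subnetwork(network, overlap_genes, keep_seed=seed_gene)
                if sub.number_of_nodes():
                    result.subnetwork = sub
                    result.communities = detect_communities(sub, config.rng_seed)
    return result
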