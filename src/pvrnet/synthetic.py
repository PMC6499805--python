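"""Synthetic data with the statistical structure of the three-group study.

Generates (i) negative-binomial count matrices for control RPE,
TNT-treated RPE (TGFb1 + TNFa) and patient PVR membranes, with planted
fold-changes and a PVR-as-mixture structure reflecting residual RPE
populations inside dissected membranes; (ii) scale-free interaction
networks in which differentially expressed genes are preferentially
wired into a seed gene's two-hop neighborhood; (iii) replicate membrane
counts with separate between-line and within-line variability.

NB parameterization throughout: variance = mu + phi * mu^2 (the common
dispersion convention of count-based DE), so phi = 0 is Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import CountMatrix

__all__ = [
    "SimulationDesign",
    "simulate_counts",
    "simulate_network",
    "simulate_membrane_counts",
]

GROUPS = ("RPE", "TNT", "PVR")


@dataclass
class SimulationDesign:
    """Parameters of the synthetic three-group count experiment.

    Attributes
    ----------
    n_genes : int
        Number of simulated genes.
    samples_per_group : mapping group -> int
        Replicates for RPE, TNT, PVR (default 3 each).
    baseline_log2_mean, baseline_log2_sd : float
        Per-gene baseline relative abundance is ``2**Normal(mean, sd)``,
        normalized to proportions before library-size scaling.
    library_size_range : (float, float)
        Library sizes are log-uniform over this range.
    dispersion : float or per-gene array
        NB dispersion phi, variance = mu + phi mu^2.
    de_fraction : float
        Fraction of genes with a planted TNT-vs-RPE effect.
    effect_log2fc_mean, effect_log2fc_sd : float
        Planted |log2 fold-change| ~ Normal, sign random per gene.
        Default mean 2 (four-fold), matching strong treatment effects.
    pvr_mixture : float in [0, 1]
        pi: PVR group mean = (1 - pi) * TNT-like mean + pi * RPE mean on
        the linear scale, modelling PVR membranes that still contain an
        RPE-like cell population.
    rng_seed : int
    """

    n_genes: int = 5000
    samples_per_group: dict[str, int] = field(
        default_factory=lambda: {"RPE": 3, "TNT": 3, "PVR": 3}
    )
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 2.0
    library_size_range: tuple[float, float] = (0.5e6, 2e6)
    dispersion: float | np.ndarray = 0.1
    de_fraction: float = 0.1
    effect_log2fc_mean: float = 2.0
    effect_log2fc_sd: float = 0.25
    pvr_mixture: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.pvr_mixture <= 1:
            raise ValueError("pvr_mixture must lie in [0, 1]")
        if np.any(np.asarray(self.dispersion) < 0):
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        for g, n in self.samples_per_group.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs >= 2 samples")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Draw NB(mean, var = mean + phi mean^2); phi == 0 falls back to Poisson."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi == 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        r = 1.0 / phi[~pois]
        p = r / (r + mean[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def simulate_counts(design: SimulationDesign) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate the three-group count matrix and its ground-truth table.

    Returns the CountMatrix and a truth table with one row per gene:
    true DE status and true log2FC for each pairwise comparison.
    Deterministic for a fixed design (identical seed, identical output).
    """
    rng = np.random.default_rng(design.rng_seed)
    G = design.n_genes

    baseline = 2.0 ** rng.normal(design.baseline_log2_mean, design.baseline_log2_sd, G)
    rel_rpe = baseline / baseline.sum()

    n_de = int(round(design.de_fraction * G))
    de_idx = rng.choice(G, size=n_de, replace=False)
    lfc = np.zeros(G)
    magnitudes = rng.normal(design.effect_log2fc_mean, design.effect_log2fc_sd, n_de)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc[de_idx] = signs * np.abs(magnitudes)

    rel_tnt = rel_rpe * 2.0**lfc
    pi = design.pvr_mixture
    rel_pvr = (1.0 - pi) * rel_tnt + pi * rel_rpe
    # renormalize so each group's relative abundances are proportions
    group_rel = {
        "RPE": rel_rpe / rel_rpe.sum(),
        "TNT": rel_tnt / rel_tnt.sum(),
        "PVR": rel_pvr / rel_pvr.sum(),
    }

    lo, hi = design.library_size_range
    sample_ids, group_of, cols = [], {}, []
    for group in GROUPS:
        n = design.samples_per_group.get(group, 0)
        for rep in range(n):
            sid = f"{group}_{rep + 1}"
            lib = np.exp(rng.uniform(np.log(lo), np.log(hi)))
            mu = lib * group_rel[group]
            cols.append(_nb_sample(rng, mu, design.dispersion))
            sample_ids.append(sid)
            group_of[sid] = group
    counts = np.column_stack(cols)
    gene_ids = [f"G{i:05d}" for i in range(G)]

    true_lfc_tnt = np.log2(group_rel["TNT"] / group_rel["RPE"])
    true_lfc_pvr = np.log2(group_rel["PVR"] / group_rel["RPE"])
    is_de = np.zeros(G, dtype=bool)
    is_de[de_idx] = True
    truth = pd.DataFrame(
        {
            "gene": gene_ids,
            "is_de_TNT_vs_RPE": is_de,
            "true_log2fc_TNT_vs_RPE": true_lfc_tnt,
            "true_log2fc_PVR_vs_RPE": true_lfc_pvr,
            "in_network": False,
        }
    )
    return CountMatrix(gene_ids, sample_ids, counts, group_of), truth


def simulate_network(
    n_nodes: int,
    m_attach: int,
    seed_gene: str,
    enrichment_rho: float,
    truth: pd.DataFrame,
    rng_seed: int = 0,
    score_range: tuple[int, int] = (700, 999),
    target_hood_frac: float = 0.2,
) -> nx.Graph:
    """Scale-free interaction network with planted neighborhood enrichment.

    A preferential-attachment graph on ``n_nodes`` nodes is built; the
    seed gene is placed on the node whose two-hop neighborhood covers a
    fraction of the graph closest to ``target_hood_frac`` (a hub's
    two-hop set in a scale-free graph swallows most nodes, which would
    leave no room for enrichment — real seed-gene neighborhoods are a
    minority of the genome).  Gene identifiers
    from the truth table's universe are assigned to the remaining nodes
    such that genes flagged DE land inside the seed's two-hop
    neighborhood with ``enrichment_rho``-fold the probability of non-DE
    genes (rho = 1 is uniform assignment, the enrichment null).  Edge
    confidence scores are uniform integers in ``score_range`` (STRING
    combined-score scale).  The truth table's ``in_network`` column is
    updated in place for the genes placed in the graph.
    """
    if enrichment_rho < 1:
        raise ValueError("enrichment_rho must be >= 1")
    all_genes = list(truth["gene"])
    if seed_gene not in all_genes:
        raise ValueError(f"seed gene {seed_gene!r} not in the gene universe")
    universe = [g for g in all_genes if g != seed_gene]
    if n_nodes - 1 > len(universe):
        raise ValueError("n_nodes exceeds gene universe size")
    rng = np.random.default_rng(rng_seed)

    skeleton = nx.barabasi_albert_graph(n_nodes, m_attach, seed=int(rng.integers(2**31)))
    target = target_hood_frac * n_nodes
    seed_node = min(
        skeleton.nodes,
        key=lambda v: (
            abs(len(nx.single_source_shortest_path_length(skeleton, v, cutoff=2))
                - 1 - target),
            v,
        ),
    )
    hood = set(nx.single_source_shortest_path_length(skeleton, seed_node, cutoff=2))
    hood.discard(seed_node)
    others = [v for v in skeleton.nodes if v != seed_node]

    # choose which genes enter the graph, then which of those sit in the
    # 2-hop neighborhood, with DE genes rho-fold upweighted for the latter
    de_of = dict(zip(truth["gene"], truth["is_de_TNT_vs_RPE"]))
    chosen = rng.choice(len(universe), size=len(others), replace=False)
    genes = [universe[i] for i in chosen]
    de_flags = np.array([de_of[g] for g in genes])
    weights = np.where(de_flags, enrichment_rho, 1.0)
    weights = weights / weights.sum()
    in_hood = rng.choice(len(genes), size=len(hood), replace=False, p=weights)
    hood_genes = [genes[i] for i in in_hood]
    rest_genes = [g for i, g in enumerate(genes) if i not in set(in_hood)]
    rng.shuffle(rest_genes)

    label: dict[int, str] = {seed_node: seed_gene}
    hood_nodes = sorted(hood)
    rest_nodes = [v for v in others if v not in hood]
    for node, gene in zip(hood_nodes, hood_genes):
        label[node] = gene
    for node, gene in zip(rest_nodes, rest_genes):
        label[node] = gene

    graph = nx.Graph()
    graph.add_nodes_from(label.values())
    for a, b in skeleton.edges:
        graph.add_edge(label[a], label[b], score=int(rng.integers(*score_range)))

    truth.loc[truth["gene"].isin(label.values()), "in_network"] = True
    return graph


def simulate_membrane_counts(
    n_lines: int,
    experiments_per_line: int,
    grand_mean: float,
    between_line_cv: float,
    within_line_cv: float,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Replicate membrane counts for donor lines (line, experiment, count).

    Line means are lognormal around ``grand_mean`` with the between-line
    CV; per-experiment counts are lognormal around the line mean with
    the within-line CV, rounded to integers.  A CV of c maps to the
    lognormal sigma via sigma^2 = ln(1 + c^2), with mu chosen so the
    arithmetic mean is preserved.
    """
    if grand_mean <= 0:
        raise ValueError("grand_mean must be positive")
    if between_line_cv < 0 or within_line_cv < 0:
        raise ValueError("CV parameters must be >= 0")
    rng = np.random.default_rng(rng_seed)

    def _lognormal(mean: float, cv: float, size: int) -> np.ndarray:
        if cv == 0:
            return np.full(size, mean)
        sigma2 = np.log1p(cv**2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size)

    rows = []
    line_means = _lognormal(grand_mean, between_line_cv, n_lines)
    for li, lm in enumerate(line_means):
        vals = _lognormal(lm, within_line_cv, experiments_per_line)
        for ei, v in enumerate(vals):
            rows.append((chr(ord("A") + li % 26) + ("" if li < 26 else str(li)),
                         f"exp{ei + 1}", int(round(v))))
    return pd.DataFrame(rows, columns=["line", "experiment", "count"])
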