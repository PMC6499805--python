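"""Dual-method differential expression with fold-change intersection.

The study's "significantly changing genes" are those called by two
independent count-based tools and passing a two-fold change threshold.
Here the two routes are (A) a conditional negative-binomial exact test
in the classic count-test tradition — condition on each gene's total
across both groups after equalizing library sizes, compute the
two-sided tail of the group-A sum under a common dispersion — and (B) a
Welch unequal-variance t-test on log2(CPM + prior).  A gene is
significant when BOTH routes give BH q <= alpha AND at least a two-fold
change in concordant directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .core_io import CountMatrix, GeneSet, PipelineConfig

__all__ = [
    "DEResult",
    "cpm",
    "expression_filter",
    "estimate_common_dispersion",
    "exact_test_nb",
    "logcpm_welch_test",
    "bh_adjust",
    "significant_genes",
    "venn_overlap",
]


@dataclass
class DEResult:
    """Per-gene log2FC / p / q for one method on one comparison.

    ``table`` columns: gene, log2fc (group B over A on the CPM + prior
    scale), pvalue, qvalue.  ``comparison`` is "<A>_vs_<B>".
    """

    table: pd.DataFrame
    method: str
    comparison: str

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])


def cpm(counts: np.ndarray, lib_sizes: np.ndarray | None = None) -> np.ndarray:
    """Counts-per-million columns; library size defaults to column sum."""
    counts = np.asarray(counts, dtype=float)
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    return counts / np.asarray(lib_sizes, dtype=float) * 1e6


def expression_filter(
    cm: CountMatrix, min_cpm: float = 1.0, min_samples: int | None = None
) -> CountMatrix:
    """Keep genes with CPM > min_cpm in at least min_samples samples.

    min_samples defaults to the smallest group size.
    """
    if min_samples is None:
        min_samples = min(
            sum(1 for s in cm.sample_ids if cm.group_of[s] == g) for g in cm.groups
        )
    keep = (cpm(cm.counts) > min_cpm).sum(axis=1) >= min_samples
    return CountMatrix(
        [g for g, k in zip(cm.gene_ids, keep) if k],
        list(cm.sample_ids),
        cm.counts[keep, :],
        dict(cm.group_of),
    )


def _comparison_counts(
    cm: CountMatrix, comparison: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    ga, gb = comparison
    ia, ib = cm.sample_indices(ga), cm.sample_indices(gb)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("each group needs >= 2 samples")
    lib = cm.library_sizes()
    return cm.counts[:, ia], cm.counts[:, ib], lib[ia], lib[ib]


def estimate_common_dispersion(
    cm: CountMatrix, comparison: tuple[str, str]
) -> float:
    """Method-of-moments common NB dispersion for one two-group comparison.

    Counts are scaled to a common library size; per-gene within-group
    sample means m and variances v are pooled, and phi is the
    through-origin regression of the excess variance (v - m) on m^2,
    floored at zero.  Under var = mu + phi mu^2 this is unbiased to
    first order and collapses to 0 for Poisson data.
    """
    a, b, la, lb = _comparison_counts(cm, comparison)
    ref = np.exp(np.mean(np.log(np.concatenate([la, lb]))))
    ya, yb = a * (ref / la), b * (ref / lb)
    num, den = 0.0, 0.0
    for y in (ya, yb):
        m = y.mean(axis=1)
        v = y.var(axis=1, ddof=1)
        num += np.sum((v - m) * m**2)
        den += np.sum(m**4)
    if den == 0:
        return 0.0
    return max(0.0, num / den)


def _conditional_log_pmf(total: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """log pmf of the group-A pseudo-count sum given the two-group total.

    Group sums of n iid NB(mu, phi) are NB with size n/phi; conditioning
    on the total makes the mean parameter cancel, leaving a distribution
    that depends only on (total, n_a, n_b, phi).  With phi = 0 the group
    sums are Poisson and the conditional is Binomial(total, n_a/(n_a+n_b)).
    """
    ks = np.arange(total + 1)
    if phi == 0:
        lp = stats.binom.logpmf(ks, total, n_a / (n_a + n_b))
    else:
        ra, rb = n_a / phi, n_b / phi
        # NB size-r log-pmf up to terms constant in k; p cancels in the ratio
        lg = (
            stats.nbinom.logpmf(ks, ra, 0.5)
            + stats.nbinom.logpmf(total - ks, rb, 0.5)
        )
        lp = lg - logsumexp(lg)
    return lp


def exact_test_nb(
    cm: CountMatrix,
    comparison: tuple[str, str],
    dispersion: float,
    prior_count: float = 0.5,
) -> DEResult:
    """Conditional NB exact test (method A).

    Library sizes are equalized to their geometric mean by scaling
    counts to pseudo-counts (rounded half away from zero).  For each
    gene the two-sided p doubles the smaller conditional tail of the
    group-A sum given the total, capped at 1.  All-zero genes get p = 1
    and log2FC = 0.  log2FC is the log-ratio of mean CPM + prior
    (B over A).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    a, b, la, lb = _comparison_counts(cm, comparison)
    ref = np.exp(np.mean(np.log(np.concatenate([la, lb]))))
    # round half away from zero (counts are non-negative: floor(x + 0.5))
    pa = np.floor(a * (ref / la) + 0.5).astype(np.int64)
    pb = np.floor(b * (ref / lb) + 0.5).astype(np.int64)
    n_a, n_b = a.shape[1], b.shape[1]

    sa, sb = pa.sum(axis=1), pb.sum(axis=1)
    totals = sa + sb
    pvals = np.ones(len(totals))
    cache: dict[int, np.ndarray] = {}
    for i, (t, x) in enumerate(zip(totals, sa)):
        if t == 0:
            continue
        lp = cache.get(t)
        if lp is None:
            lp = _conditional_log_pmf(int(t), n_a, n_b, dispersion)
            if len(cache) < 4096:
                cache[int(t)] = lp
        lo = logsumexp(lp[: x + 1])
        hi = logsumexp(lp[x:])
        pvals[i] = min(1.0, 2.0 * np.exp(min(lo, hi)))

    mean_cpm_a = cpm(a, la).mean(axis=1)
    mean_cpm_b = cpm(b, lb).mean(axis=1)
    log2fc = np.log2(mean_cpm_b + prior_count) - np.log2(mean_cpm_a + prior_count)
    log2fc[totals == 0] = 0.0
    table = pd.DataFrame(
        {
            "gene": cm.gene_ids,
            "log2fc": log2fc,
            "pvalue": pvals,
            "qvalue": bh_adjust(pvals),
        }
    )
    return DEResult(table, "exactA", f"{comparison[0]}_vs_{comparison[1]}")


def logcpm_welch_test(
    cm: CountMatrix,
    comparison: tuple[str, str],
    prior_count: float = 0.5,
) -> DEResult:
    """Welch unequal-variance t-test on log2(CPM + prior) (method B)."""
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    a, b, la, lb = _comparison_counts(cm, comparison)
    ya = np.log2(cpm(a, la) + prior_count)
    yb = np.log2(cpm(b, lb) + prior_count)
    with warnings.catch_warnings():
        # genes constant within both groups yield 0/0 -> nan -> p = 1
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(yb, ya, axis=1, equal_var=False)
    pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    log2fc = yb.mean(axis=1) - ya.mean(axis=1)
    table = pd.DataFrame(
        {
            "gene": cm.gene_ids,
            "log2fc": log2fc,
            "pvalue": pvals,
            "qvalue": bh_adjust(pvals),
        }
    )
    return DEResult(table, "welchB", f"{comparison[0]}_vs_{comparison[1]}")


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_genes(
    res_a: DEResult,
    res_b: DEResult,
    config: PipelineConfig | None = None,
) -> GeneSet:
    """Genes significant by both methods with concordant >= 2-fold change.

    Requires q <= fdr_alpha in both methods, |log2FC| >= log2(fc_threshold)
    in both (inclusive), and agreeing fold-change direction.
    """
    config = config or PipelineConfig()
    if res_a.genes != res_b.genes:
        raise ValueError("DE results cover different gene universes")
    if res_a.comparison != res_b.comparison:
        raise ValueError("DE results cover different comparisons")
    ta, tb = res_a.table, res_b.table
    thr = np.log2(config.fc_threshold)
    ok = (
        (ta["qvalue"].to_numpy() <= config.fdr_alpha)
        & (tb["qvalue"].to_numpy() <= config.fdr_alpha)
        & (np.abs(ta["log2fc"].to_numpy()) >= thr)
        & (np.abs(tb["log2fc"].to_numpy()) >= thr)
        & (np.sign(ta["log2fc"].to_numpy()) == np.sign(tb["log2fc"].to_numpy()))
    )
    return GeneSet(res_a.comparison, ta.loc[ok, "gene"])


def venn_overlap(sets: list[GeneSet]) -> dict[str, int]:
    """Exact region cardinalities of a 2- or 3-set Venn diagram.

    Keys are region masks like "110" (member of sets 1 and 2, not 3),
    ordered as the input list; only nonempty-universe regions appear
    (the all-zeros region is excluded).
    """
    if len(sets) not in (2, 3):
        raise ValueError("venn_overlap supports 2 or 3 sets")
    union = set().union(*(s.genes for s in sets))
    n = len(sets)
    regions = {format(i, f"0{n}b"): 0 for i in range(1, 2**n)}
    for g in union:
        mask = "".join("1" if g in s else "0" for s in sets)
        regions[mask] += 1
    return regions
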