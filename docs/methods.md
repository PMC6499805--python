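# Methods

## Study design being modeled

Three groups of bulk RNA-seq samples: control retinal pigment
epithelium (RPE), RPE treated with TGFβ1 + TNFα (TNT), and
patient-dissected PVR membranes. Dissected membranes plausibly carry a
residual population of ordinary RPE cells, so the PVR expression
profile is modeled as a mixture of a TNT-like perturbed profile and the
RPE baseline. The pipeline identifies genes changing between groups,
summarizes their covariance structure by SVD, and asks whether the
changing genes are enriched in the interaction-network neighborhood of
a seed gene (p38-MAPK in the motivating study).

## Differential expression

Two deliberately different routes are intersected:

- **Conditional NB exact test (method A).** Counts are scaled to
  pseudo-counts at the geometric-mean library size (rounded half away
  from zero). For a gene, the group sums of $n$ i.i.d. NB variables with
  variance $\mu + \varphi\mu^2$ are NB with size $n/\varphi$; the
  distribution of the group-A sum conditioned on the two-group total is
  free of the mean parameter and is enumerated exactly over
  $0..\mathrm{total}$. Two-sided $p$ doubles the smaller tail, capped at
  1. At $\varphi = 0$ this collapses to the binomial conditional
  (Poisson limit). All-zero genes get $p = 1$, $\log_2\mathrm{FC} = 0$.
  Enumeration cost is linear in the per-gene total, so a full comparison
  costs $O(\text{total reads})$ regardless of gene count; identical
  totals share one cached pmf.
- **Welch test on log-CPM (method B).** Unequal-variance $t$ on
  $\log_2(\mathrm{CPM} + 0.5)$; its fold-change is the difference of
  transformed group means.

A common dispersion $\hat\varphi$ is estimated by method of moments:
the through-origin regression slope of the within-group excess variance
$(v - m)$ on $m^2$ after scaling to a common library size, pooled over
genes and groups, floored at 0. This is first-order unbiased under the
NB variance law and exactly 0 for replicate-identical counts.

Significance requires BH $q \le \alpha$ (default 0.05) in **both**
methods plus a concordant $|\log_2\mathrm{FC}| \ge \log_2 2$ (inclusive)
in both. Intersecting two methods was chosen over a union because it is
the conservative reading of "two tools agreed" and keeps the observed
false-discovery rate well under the nominal level in simulation; the
cost is reduced power at very small replicate numbers (at 3 vs 3 the
Welch route has almost no BH-adjusted power, so the intersection is
near-empty — a real property of tiny designs, not a defect).
Before testing, genes must exceed CPM 1 in at least
(smallest group size) samples.

This dual route is a stand-in for the edgeR + DESeq2 pair used in the
motivating study, preserving the "two independent methods + two-fold
threshold" logic rather than either tool's exact inference; numeric
agreement with those tools is not claimed.

## SVD eigengene analysis

The expression matrix (default $\log_2(\mathrm{CPM}+1)$, uncentered)
restricted to the significant genes is decomposed $X = U S V^{\mathsf T}$.
Fractions $p_k = s_k^2/\sum s_j^2$ quantify each dimension's share of
the total squared signal. Because the matrix is uncentered (SVD, not
PCA), the first dimension absorbs the shared expression scale and its
fraction is typically > 90% on synthetic data; a row-centered variant
is available. Signs are fixed by making the first nonzero loading of
each left vector positive, so results do not depend on the LAPACK
driver. Polar coordinates use 1-based dimension indices,
$\theta \in [0^\circ, 360^\circ)$ counter-clockwise from the first
requested axis, with the origin assigned $\theta = 0$ by convention.
Group coordinates are vector sums of member-sample projections, which
by linearity equal the projection of the summed expression.

## Network enrichment

The seed's $k$-hop neighborhood ($k = 2$ by default, seed included;
exclusion available) is intersected with the expression-filtered gene
universe. The observed overlap $x$ of a significant set of size $n$ is
referred to:

- the hypergeometric expectation $nK/N$;
- a resampling null — $B$ (default 1000) uniform draws of $n$ genes
  without replacement, with the add-one empirical
  $p = (1 + \#\{\text{null} \ge x\})/(B+1)$, which can never be 0;
- a Bayes factor for the binomial proportion: point null
  $p_0 = K/N$ versus a logistic prior on $\operatorname{logit} p$
  centered at $\operatorname{logit} p_0$ with scale $r = 1/2$ (the
  convention of the standard proportion Bayes-factor test). The marginal
  likelihood is computed by adaptive quadrature on the standardized
  logit axis after shifting by the integrand mode, which keeps the
  computation stable both for near-delta priors ($r \to 0$, where
  $\ln\mathrm{BF} \to 0$) and for large $n$ where the likelihood is
  much narrower than the prior. Both $\ln\mathrm{BF}$ and
  $\log_{10}\mathrm{BF}$ are reported because the headline "log BF"
  convention is base-ambiguous.

## Sub-network statistics

The significant ∩ neighborhood genes induce a vertex subgraph.
Betweenness is exact, unweighted, unnormalized, with each unordered
source–target pair counted once (a star center over $k$ leaves scores
$\binom{k}{2}$) — stated so numbers are comparable across tools. Edge
confidence scores do not influence shortest paths, matching common
STRING/Cytoscape defaults. Communities come from greedy modularity
maximization (CNM), a deterministic stand-in for the GLay layout
plugin: the claim exercised is that communities exist and can be
color-coded, not a specific partition. Exported GraphML carries
betweenness (node size / edge thickness), community (color), and Venn
region (shape) attributes.

## Membrane-count variability

CV% is $100\,s/\bar{x}$ with the $n-1$ sample standard deviation. The
interline CV pools every experiment of every line into one sample —
the only reading consistent with a single CV reported "across all
experiments" — and therefore includes the between-line mean spread;
the intraline CV uses one focal line. The non-genetic fraction
$100 \times \mathrm{CV}_\mathrm{intra}/\mathrm{CV}_\mathrm{inter}$
can exceed 100% when the focal line is noisier than the pool; it is
then flagged, never clipped. With the published values
(intra 70.67%, inter 86.7%) the fraction is 81.5%.

## Synthetic data

- **Counts.** Per-gene baseline relative abundance
  $\propto 2^{\mathcal N(4, 2)}$; planted effects on a `de_fraction`
  (default 10%) of genes with $|\log_2\mathrm{FC}| \sim \mathcal N(2,
  0.25)$ (four-fold, the effect size the recovery checks are specified
  at) and random sign; PVR group means are the linear-scale mixture
  $(1-\pi)\,\mu_\mathrm{TNT} + \pi\,\mu_\mathrm{RPE}$ with $\pi = 0.3$
  by default. Mixing is applied to means rather than to sampled counts —
  simpler and approximately NB-marginal-preserving. Library sizes are
  log-uniform over 0.5–2 × 10⁶ to exercise CPM normalization; counts
  are NB with variance $\mu + \varphi\mu^2$ ($\varphi = 0$ → Poisson).
  Default group sizes are 3/3/3 — a realistic bulk design; power-facing
  checks use 5 vs 5 where stated.
- **Network.** Barabási–Albert preferential attachment, edge scores
  uniform in 700–999 (so the default high-confidence cutoff keeps the
  planted structure). The seed gene is placed on the node whose 2-hop
  neighborhood is closest to 20% of the graph: a hub's 2-hop set in a
  scale-free graph swallows most nodes, which would leave no room for
  enrichment, and real seed-gene neighborhoods are a small minority of
  the genome. Genes enter the neighborhood with probability weighted
  $\rho$-fold for DE genes; $\rho = 1$ is the exact placement null.
- **Membrane counts.** Lognormal line means around the grand mean with
  the between-line CV, lognormal experiments within lines with the
  within-line CV (σ² = ln(1+CV²), mean-preserving), rounded to
  integers. Lognormal was chosen over gamma for two-parameter
  transparency; the CV analysis is scale-free either way.

What the generator does **not** emulate: gene length/GC bias, batch
effects, single-cell zero inflation, correlated genes beyond the
planted structure, and tag-wise dispersion. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to those real-data features.

## Problem sizes and numerical choices

Simulation-based checks use 20 replicates of 5000 genes (5 vs 5,
$\varphi = 0.05$) for DE recovery, 100 reduced replicates (400 genes,
4 vs 4, 380-node networks) for the enrichment calibration, 200
experiments/line for CV recovery, and $B = 50\,000$ draws for the
resampling-moment check — sizes at which the Monte-Carlo error is
comfortably inside each asserted tolerance. Quadrature targets 10⁻⁹
relative error (checked against a 10⁶-point dense grid to 10⁻⁴); SVD
checks run at 10⁻⁸; exact-test enumeration is compared to an
independent brute-force conditional pmf at 10⁻¹⁰. Ties in BH are
handled by the step-up definition; pseudo-count rounding is half away
from zero; empty DE sets short-circuit enrichment rather than erroring.

## Known limitations

- The DE stand-ins are not edgeR/DESeq2; fidelity is at the level of
  the decision rule (two methods + two-fold + FDR), not per-gene
  statistics.
- A single common dispersion is estimated; no tag-wise shrinkage, no
  GLM designs beyond two groups, no covariates.
- The headline numbers of the motivating study (gene counts, SVD
  fractions, the specific Bayes factor) depend on its accession data
  and tool versions and are not reproduced here; they anchor the
  synthetic design instead.
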