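"""Dual DE methods against enumeration / hand-computed oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from pvrnet import CountMatrix, GeneSet, PipelineConfig
from pvrnet.diffexpr import (
    DEResult,
    bh_adjust,
    cpm,
    estimate_common_dispersion,
    exact_test_nb,
    expression_filter,
    logcpm_welch_test,
    significant_genes,
    venn_overlap,
)
from pvrnet.synthetic import SimulationDesign, simulate_counts


def _cm(rows, n_a, n_b, genes=None):
    """Count matrix with groups A (first n_a columns) and B."""
    rows = np.atleast_2d(np.asarray(rows))
    samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    groups = {s: ("A" if s.startswith("a") else "B") for s in samples}
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    return CountMatrix(genes, samples, rows, groups)


def conditional_pmf_oracle(total, n_a, n_b, phi):
    """Brute-force conditional pmf of the group-A sum given the total.

    Directly multiplies the two group-sum NB pmfs (size n/phi, any
    common success probability — it cancels) over all k and normalizes
    with a plain float sum.  Poisson/binomial when phi == 0.
    """
    ks = np.arange(total + 1)
    if phi == 0:
        w = np.array(
            [math.comb(total, int(k)) * (n_a / (n_a + n_b)) ** k
             * (n_b / (n_a + n_b)) ** (total - k) for k in ks]
        )
    else:
        ra, rb = n_a / phi, n_b / phi

        def nbw(k, r):
            return math.exp(
                math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
            ) * 0.25**k  # common (1-p)^k factor, p-part cancels

        w = np.array([nbw(int(k), ra) * nbw(int(total - k), rb) for k in ks])
    return w / w.sum()


def two_sided_p_oracle(sa, total, n_a, n_b, phi):
    pmf = conditional_pmf_oracle(total, n_a, n_b, phi)
    return min(1.0, 2.0 * min(pmf[: sa + 1].sum(), pmf[sa:].sum()))


class TestDispersion:
    def test_simulation_recovery(self):
        design = SimulationDesign(
            n_genes=40,
            samples_per_group={"RPE": 200, "TNT": 200, "PVR": 2},
            dispersion=0.1,
            de_fraction=0.0,
            baseline_log2_sd=1.0,
            library_size_range=(2e5, 2e5),
            rng_seed=13,
        )
        cm, _ = simulate_counts(design)
        phi = estimate_common_dispersion(cm, ("RPE", "TNT"))
        assert 0.07 <= phi <= 0.13

    def test_replicate_identical_counts_give_zero(self):
        cm = _cm([[10, 10, 20, 20], [5, 5, 8, 8]], 2, 2)
        assert estimate_common_dispersion(cm, ("A", "B")) == 0.0

    def test_single_gene_constant_counts(self):
        cm = _cm([[10, 10, 10, 10]], 2, 2)
        assert estimate_common_dispersion(cm, ("A", "B")) == 0.0

    def test_requires_two_samples_per_group(self):
        counts = np.array([[1, 2, 3]])
        cm = CountMatrix(
            ["g"], ["a", "b", "c"], counts, {"a": "A", "b": "A", "c": "B"}
        )
        with pytest.raises(ValueError, match=">= 2 samples"):
            estimate_common_dispersion(cm, ("A", "B"))


class TestExactTest:
    def test_binomial_tail_zero_vs_ten(self):
        """A={0}, B={10} per sample-pair sums with equal libsizes, phi=0."""
        # embed in a constant background gene so library sizes are equal
        cm = _cm([[0, 0, 10, 10], [1000, 1000, 990, 990]], 2, 2)
        res = exact_test_nb(cm, ("A", "B"), 0.0)
        p = res.table.set_index("gene").loc["g0", "pvalue"]
        assert p == pytest.approx(two_sided_p_oracle(0, 20, 2, 2, 0.0), rel=1e-10)

    def test_symmetric_case_capped_at_one(self):
        cm = _cm([[5, 5, 5, 5], [100, 100, 100, 100]], 2, 2)
        res = exact_test_nb(cm, ("A", "B"), 0.0)
        assert (res.table["pvalue"] == 1.0).all()

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    def test_matches_enumeration_oracle_small_totals(self, phi):
        """Random small tables: p equals the conditional-pmf enumeration."""
        rng = np.random.default_rng(21)
        rows = rng.integers(0, 8, size=(30, 6))  # totals <= 48
        # pad with a balancing gene so all library sizes are equal
        pad = rows.sum(axis=0).max() - rows.sum(axis=0)
        cm = _cm(np.vstack([rows, 500 + pad]), 3, 3)
        res = exact_test_nb(cm, ("A", "B"), phi)
        for i in range(30):
            sa, t = rows[i, :3].sum(), rows[i].sum()
            if t == 0:
                expect = 1.0
            else:
                expect = two_sided_p_oracle(int(sa), int(t), 3, 3, phi)
            assert res.table["pvalue"][i] == pytest.approx(expect, abs=1e-10)

    def test_all_zero_gene_gets_p_one_fc_zero(self):
        cm = _cm([[0, 0, 0, 0], [10, 10, 10, 10]], 2, 2)
        res = exact_test_nb(cm, ("A", "B"), 0.2)
        row = res.table.set_index("gene").loc["g0"]
        assert row["pvalue"] == 1.0 and row["log2fc"] == 0.0

    def test_negative_dispersion_rejected(self, tiny_counts):
        with pytest.raises(ValueError):
            exact_test_nb(tiny_counts, ("A", "B"), -0.1)


class TestWelch:
    def test_identical_groups_give_p_one_fc_zero(self):
        cm = _cm([[7, 9, 7, 9], [3, 5, 3, 5]], 2, 2)
        res = logcpm_welch_test(cm, ("A", "B"))
        assert np.allclose(res.table["pvalue"], 1.0)
        assert np.allclose(res.table["log2fc"], 0.0)

    def test_matches_textbook_welch_on_3v3(self):
        """Hand-worked Welch: explicit t, Welch-Satterthwaite df, survival."""
        cm = _cm([[10, 14, 12, 30, 27, 33], [50, 50, 50, 50, 50, 50]], 3, 3)
        res = logcpm_welch_test(cm, ("A", "B"), prior_count=0.5)
        ya = np.log2(cpm(cm.counts[:, :3]) + 0.5)[0]
        yb = np.log2(cpm(cm.counts[:, 3:]) + 0.5)[0]
        va, vb = ya.var(ddof=1) / 3, yb.var(ddof=1) / 3
        t = (yb.mean() - ya.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        expect = 2 * stats.t.sf(abs(t), df)
        assert res.table["pvalue"][0] == pytest.approx(expect, abs=1e-8)
        assert res.table["log2fc"][0] == pytest.approx(yb.mean() - ya.mean())

    def test_sample_order_invariance(self, small_simulation):
        _, cm, _ = small_simulation
        perm = np.random.default_rng(0).permutation(cm.n_samples)
        shuffled = CountMatrix(
            cm.gene_ids,
            [cm.sample_ids[i] for i in perm],
            cm.counts[:, perm],
            cm.group_of,
        )
        p1 = logcpm_welch_test(cm, ("RPE", "TNT")).table["pvalue"]
        p2 = logcpm_welch_test(shuffled, ("RPE", "TNT")).table["pvalue"]
        assert np.allclose(p1, p2)


class TestAntisymmetry:
    def test_swapping_groups_negates_fc_keeps_p(self, small_simulation):
        _, cm, _ = small_simulation
        for method in (
            lambda c, comp: exact_test_nb(c, comp, 0.05),
            lambda c, comp: logcpm_welch_test(c, comp),
        ):
            fwd = method(cm, ("RPE", "TNT")).table
            rev = method(cm, ("TNT", "RPE")).table
            assert np.allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-10)
            assert np.allclose(fwd["pvalue"], rev["pvalue"], atol=1e-12)


class TestBH:
    def test_definitional_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_all_equal_and_singleton(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_brute_force_definition(self):
        """q_i = min over j with p_j >= p_i of min(1, m p_j / rank_j)."""
        rng = np.random.default_rng(4)
        p = rng.uniform(size=37)
        order = np.argsort(p)
        m = len(p)
        stepped = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        expect = np.empty(m)
        expect[order] = np.minimum(stepped, 1.0)
        assert np.allclose(bh_adjust(p), expect)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestSignificantGenes:
    @staticmethod
    def _res(method, genes, lfc, q, comparison="A_vs_B"):
        import pandas as pd

        return DEResult(
            pd.DataFrame(
                {"gene": genes, "log2fc": lfc, "pvalue": q, "qvalue": q}
            ),
            method,
            comparison,
        )

    def test_requires_significance_in_both_methods(self):
        a = self._res("exactA", ["g1"], [3.0], [0.01])
        b = self._res("welchB", ["g1"], [3.0], [0.2])
        assert len(significant_genes(a, b, PipelineConfig())) == 0

    def test_twofold_threshold_inclusive(self):
        genes = ["g1", "g2", "g3"]
        lfc = np.log2([1.5, 2.0, 4.0])
        a = self._res("exactA", genes, lfc, [0.0] * 3)
        b = self._res("welchB", genes, lfc, [0.0] * 3)
        sig = significant_genes(a, b, PipelineConfig(fc_threshold=2))
        assert sig.genes == {"g2", "g3"}

    def test_discordant_direction_excluded(self):
        a = self._res("exactA", ["g1"], [2.0], [0.0])
        b = self._res("welchB", ["g1"], [-2.0], [0.0])
        assert len(significant_genes(a, b)) == 0

    def test_mismatched_universe_rejected(self):
        a = self._res("exactA", ["g1"], [2.0], [0.0])
        b = self._res("welchB", ["g2"], [2.0], [0.0])
        with pytest.raises(ValueError, match="universe"):
            significant_genes(a, b)

    def test_recovers_planted_effects(self, small_simulation):
        """Planted four-fold effects at 5v5: sensitive with few false calls."""
        design, cm, truth = small_simulation
        filt = expression_filter(cm)
        phi = estimate_common_dispersion(filt, ("RPE", "TNT"))
        a = exact_test_nb(filt, ("RPE", "TNT"), phi)
        b = logcpm_welch_test(filt, ("RPE", "TNT"))
        sig = significant_genes(a, b, PipelineConfig())
        de = set(truth.loc[truth.is_de_TNT_vs_RPE, "gene"]) & set(filt.gene_ids)
        tp = len(sig.genes & de)
        assert tp / len(de) > 0.7
        assert (len(sig) - tp) / max(len(sig), 1) <= 0.1


class TestTypeIControl:
    def test_null_simulations_stay_near_alpha(self):
        """No planted effects: pass rate at alpha=0.05 stays near nominal."""
        rates = []
        for rep in range(12):
            design = SimulationDesign(
                n_genes=150,
                samples_per_group={"RPE": 4, "TNT": 4, "PVR": 2},
                dispersion=0.05,
                de_fraction=0.0,
                library_size_range=(5e4, 1e5),
                rng_seed=300 + rep,
            )
            cm, _ = simulate_counts(design)
            filt = expression_filter(cm)
            phi = estimate_common_dispersion(filt, ("RPE", "TNT"))
            a = exact_test_nb(filt, ("RPE", "TNT"), phi)
            b = logcpm_welch_test(filt, ("RPE", "TNT"))
            sig = significant_genes(a, b, PipelineConfig())
            rates.append(len(sig) / filt.n_genes)
        se = math.sqrt(0.05 * 0.95 / (12 * 150))
        assert np.mean(rates) <= 0.05 + 3 * se


class TestVenn:
    def test_two_set_regions(self):
        counts = venn_overlap([GeneSet("x", {"A", "B"}), GeneSet("y", {"B", "C"})])
        assert counts == {"10": 1, "01": 1, "11": 1}

    def test_identical_sets_all_in_intersection(self):
        s = GeneSet("x", {"A", "B", "C"})
        counts = venn_overlap([s, s, s])
        assert counts["111"] == 3 and sum(counts.values()) == 3

    def test_matches_brute_force_membership(self):
        rng = np.random.default_rng(6)
        pool = [f"g{i}" for i in range(40)]
        sets = [
            GeneSet(str(k), rng.choice(pool, rng.integers(5, 25), replace=False))
            for k in range(3)
        ]
        counts = venn_overlap(sets)
        union = set().union(*(s.genes for s in sets))
        assert sum(counts.values()) == len(union)
        for g in union:
            mask = "".join("1" if g in s.genes else "0" for s in sets)
            assert counts[mask] >= 1
        brute = {}
        for g in union:
            mask = "".join("1" if g in s.genes else "0" for s in sets)
            brute[mask] = brute.get(mask, 0) + 1
        for k, v in brute.items():
            assert counts[k] == v

    def test_more_than_three_sets_rejected(self):
        with pytest.raises(ValueError):
            venn_overlap([GeneSet(str(i), {"a"}) for i in range(4)])
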