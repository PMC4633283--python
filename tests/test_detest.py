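"""The DE core: filter, dispersion, exact test, BH, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, nbinom

from switchgrain.data import Comparison, StudyDesign
from switchgrain.detest import (DEConfig, NBExactTestModel, bh_adjust,
                                estimate_global_dispersion, low_quantity_filter,
                                nb_exact_test, run_comparison)
from switchgrain.exceptions import ConfigError
from switchgrain.simulate import SimulationConfig, simulate_dataset

from conftest import make_matrix


@pytest.fixture
def ab_design():
    return StudyDesign(samples=("A", "B"), replicates=3)


def rpm_matrix(rows, ab_design, theta_ids=None):
    m = make_matrix(rows, ab_design, unit="RPM")
    return m


class TestLowQuantityFilter:
    def test_all_replicates_at_six_kept(self, ab_design):
        m = rpm_matrix([[6, 6, 6, 0, 0, 0]], ab_design)
        kept = low_quantity_filter(m, Comparison("A", "B"), 5.0)
        assert list(kept) == ["e0"]

    def test_single_outlier_replicate_excluded(self, ab_design):
        # A = [15, 0, 0]: the full mean is exactly 5 but two of the three
        # two-replicate means are 7.5, 7.5, 0 -> the 0 pair fails
        m = rpm_matrix([[15, 0, 0, 0, 0, 0]], ab_design)
        kept = low_quantity_filter(m, Comparison("A", "B"), 5.0)
        assert len(kept) == 0

    def test_zero_threshold_keeps_everything(self, ab_design):
        rng = np.random.default_rng(0)
        m = rpm_matrix(rng.uniform(0, 10, size=(50, 6)), ab_design)
        kept = low_quantity_filter(m, Comparison("A", "B"), 0.0)
        assert len(kept) == 50

    def test_boundary_exactly_at_threshold_kept(self, ab_design):
        m = rpm_matrix([[5, 5, 5, 0, 0, 0]], ab_design)
        assert len(low_quantity_filter(m, Comparison("A", "B"), 5.0)) == 1

    def test_requires_rpm_unit(self, ab_design):
        m = make_matrix([[6, 6, 6, 0, 0, 0]], ab_design, unit="raw")
        with pytest.raises(ConfigError):
            low_quantity_filter(m, Comparison("A", "B"), 5.0)


class TestExactTest:
    def test_symmetric_outcome_p_one(self):
        assert nb_exact_test([5], [5], 0.1) == pytest.approx(1.0, abs=1e-9)
        assert nb_exact_test([3, 3, 4], [4, 3, 3], 0.0) == pytest.approx(1.0, abs=1e-9)

    def test_binomial_enumeration_poisson_limit(self):
        # phi=0, one library each side, total 4: conditional is Binomial(4, 1/2)
        # with pmf (1,4,6,4,1)/16. Summing outcomes no more likely than the
        # observed one: s=0 -> (1+1)/16, s=1 -> (1+4+4+1)/16.
        assert nb_exact_test([0], [4], 0.0) == pytest.approx(2 / 16, abs=1e-12)
        assert nb_exact_test([1], [3], 0.0) == pytest.approx(10 / 16, abs=1e-12)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    @pytest.mark.parametrize("sizes", [(1, 1), (3, 3)])
    def test_matches_enumeration_oracle_small_grid(self, phi, sizes):
        """Independent oracle: conditional pmf from scipy nbinom/binom at an
        arbitrary mean (the conditional law is mean-free)."""
        n_a, n_b = sizes
        mu = 7.3
        for t in range(0, 31, 3):
            y = np.arange(t + 1)
            if phi == 0:
                pmf = binom.pmf(y, t, n_a / (n_a + n_b))
            else:
                ra, rb = n_a / phi, n_b / phi
                fa = nbinom.pmf(y, ra, ra / (ra + n_a * mu))
                fb = nbinom.pmf(t - y, rb, rb / (rb + n_b * mu))
                pmf = fa * fb
                pmf = pmf / pmf.sum()
            for s in range(t + 1):
                expected = pmf[pmf <= pmf[s] * (1 + 1e-12)].sum()
                counts_a = [s] + [0] * (n_a - 1)
                counts_b = [t - s] + [0] * (n_b - 1)
                got = nb_exact_test(counts_a, counts_b, phi)
                assert got == pytest.approx(min(1.0, expected), abs=1e-8)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ConfigError):
            nb_exact_test([1], [2], -0.1)


class TestBH:
    def test_hand_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        ref = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(pvals), ref, atol=1e-12)


class TestDispersion:
    def test_identical_replicates_no_overdispersion(self, design):
        col = np.arange(10.0, 110.0, 5.0)
        m = make_matrix(np.tile(col[:, None], 15), design)
        est = estimate_global_dispersion(m)
        assert est.phi <= 1e-4

    def test_event_order_invariant(self):
        cfg = SimulationConfig(n_genes=200, depth=500_000.0, dispersion=0.15, seed=3,
                               isoforms_per_gene={1: 1.0}, expression_range=(10.0, 400.0),
                               low_expression_fraction=0.0, fraction_induced=0,
                               fraction_repressed=0, fraction_switch=0)
        m = simulate_dataset(cfg).gene_counts
        est1 = estimate_global_dispersion(m)
        shuffled = m.with_data(m.data.iloc[::-1])
        est2 = estimate_global_dispersion(shuffled)
        assert est1.phi == pytest.approx(est2.phi, rel=1e-6)

    def test_recovers_simulated_dispersion(self):
        cfg = SimulationConfig(n_genes=5000, depth=1_000_000.0, dispersion=0.2, seed=7,
                               isoforms_per_gene={1: 1.0}, expression_range=(5.0, 150.0),
                               low_expression_fraction=0.0, fraction_induced=0,
                               fraction_repressed=0, fraction_switch=0)
        m = simulate_dataset(cfg).gene_counts
        est = estimate_global_dispersion(m)
        assert 0.14 <= est.phi <= 0.26

    def test_moments_fallback_reasonable(self):
        cfg = SimulationConfig(n_genes=3000, depth=1_000_000.0, dispersion=0.2, seed=8,
                               isoforms_per_gene={1: 1.0}, expression_range=(5.0, 150.0),
                               low_expression_fraction=0.0, fraction_induced=0,
                               fraction_repressed=0, fraction_switch=0)
        m = simulate_dataset(cfg).gene_counts
        est = estimate_global_dispersion(m, method="moments")
        assert 0.1 <= est.phi <= 0.3


@pytest.fixture(scope="module")
def de_dataset():
    cfg = SimulationConfig(n_genes=400, depth=1_000_000.0, dispersion=0.1, seed=21,
                           expression_range=(5.0, 600.0), low_expression_fraction=0.2,
                           fraction_induced=0.05, fraction_repressed=0.05,
                           fraction_switch=0.0, isoforms_per_gene={1: 1.0})
    return simulate_dataset(cfg)


class TestRunComparison:
    def test_filtered_event_never_de(self, de_dataset, pair_24fe_ut):
        res = run_comparison(de_dataset.gene_counts, pair_24fe_ut)
        filtered = res.frame[res.frame["filtered"]]
        assert (filtered["status"] == "").all()
        assert res.n_de == res.n_induced + res.n_repressed

    def test_fold_change_symmetry(self, de_dataset, pair_24fe_ut):
        model = NBExactTestModel(de_dataset.gene_counts)
        fwd = model.fit(pair_24fe_ut)
        rev = model.fit(pair_24fe_ut.swapped())
        tested = fwd.tested.index
        assert np.allclose(fwd.frame.loc[tested, "log2_fc"],
                           -rev.frame.loc[tested, "log2_fc"], equal_nan=True)
        assert np.allclose(fwd.frame.loc[tested, "pvalue"],
                           rev.frame.loc[tested, "pvalue"], atol=1e-10)
        assert fwd.n_induced == rev.n_repressed and fwd.n_repressed == rev.n_induced

    def test_thresholds_are_monotone(self, de_dataset, pair_24fe_ut):
        base = run_comparison(de_dataset.gene_counts, pair_24fe_ut,
                              DEConfig(alpha=0.05, min_fold_change=1.5))
        stricter_alpha = run_comparison(de_dataset.gene_counts, pair_24fe_ut,
                                        DEConfig(alpha=0.01, min_fold_change=1.5))
        stricter_fc = run_comparison(de_dataset.gene_counts, pair_24fe_ut,
                                     DEConfig(alpha=0.05, min_fold_change=3.0))
        assert stricter_alpha.n_de <= base.n_de
        assert stricter_fc.n_de <= base.n_de

    def test_recovers_true_induction(self, de_dataset, pair_24fe_ut):
        res = run_comparison(de_dataset.gene_counts, pair_24fe_ut)
        truth = de_dataset.truth.true_class("gene", pair_24fe_ut)
        called = set(res.de_ids)
        strong_true = {
            g for g in truth.index[truth != "Null"]
            if de_dataset.truth.gene_roles.at[g, "base_rpm"] >= 50
        }
        if strong_true:
            assert len(called & strong_true) / len(strong_true) >= 0.9

    def test_summary_mentions_counts(self, de_dataset, pair_24fe_ut):
        res = run_comparison(de_dataset.gene_counts, pair_24fe_ut)
        text = res.summary()
        assert "24Fe/UT" in text and str(res.n_de) in text


def test_strong_induction_detected_across_seeds():
    """One event with a true 8-fold induction at ~100 RPM is called Induced
    in nearly every replicate simulation."""
    design = StudyDesign(samples=("A", "B"), replicates=3)
    hits = 0
    n_seeds = 100
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        r = 1 / 0.1
        null_mu = np.full((30, 6), 100.0)
        counts = rng.negative_binomial(r, r / (r + null_mu)).astype(float)
        induced = np.concatenate([
            rng.negative_binomial(r, r / (r + 800.0), 3),
            rng.negative_binomial(r, r / (r + 100.0), 3),
        ]).astype(float)
        vals = np.vstack([induced, counts])
        m = make_matrix(vals, design)
        res = run_comparison(m, Comparison("A", "B"), dispersion=0.1)
        if res.frame.iloc[0]["status"] == "Induced":
            hits += 1
    assert hits >= 95
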