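"""Composite-likelihood-ratio scan tests: closed-form worked examples,
grid/oracle equivalence, and null calibration properties."""

import numpy as np
import pytest
from scipy.stats import binom, spearmanr

from balsel.b2_scan import (
    B2Config,
    SpectrumModel,
    b2_clr,
    b2_scan,
    background_sfs,
    balanced_component,
    informative_sites,
)
from balsel.wf_engine import HaplotypeSample


def make_sample(matrix, positions, length=10_000, subs=()):
    return HaplotypeSample(
        tau_label="t",
        matrix=np.asarray(matrix, dtype=np.uint8),
        positions=np.asarray(positions, dtype=np.int64),
        substitution_positions=np.asarray(subs, dtype=np.int64),
        balanced_col=None,
        total_length=length,
        generation=0,
    )


def one_over_k_model(n):
    g = np.zeros(n)
    g[: n - 1] = 1.0 / np.arange(1, n)
    return SpectrumModel(n=n, g=g / g.sum())


class TestBackgroundSfs:
    def test_single_site_without_pseudocount(self):
        m = np.zeros((4, 1), dtype=np.uint8)
        m[:3, 0] = 1  # k = 3 of n = 4
        model = background_sfs([make_sample(m, [100])], pseudocount=0.0)
        assert model.g[2] == 1.0

    def test_substitutions_fill_top_class(self):
        m = np.zeros((4, 1), dtype=np.uint8)
        m[0, 0] = 1
        model = background_sfs(
            [make_sample(m, [100], subs=[200, 300])], pseudocount=0.0
        )
        assert model.g[3] == pytest.approx(2 / 3)

    def test_normalised(self):
        rng = np.random.default_rng(0)
        m = (rng.random((10, 30)) < 0.3).astype(np.uint8)
        model = background_sfs([make_sample(m, np.arange(1, 31) * 100)])
        assert model.g.sum() == pytest.approx(1.0)

    def test_mixed_sample_sizes_rejected(self):
        a = make_sample(np.zeros((4, 1), dtype=np.uint8), [10])
        b = make_sample(np.zeros((6, 1), dtype=np.uint8), [10])
        a.matrix[0, 0] = b.matrix[0, 0] = 1
        with pytest.raises(ValueError):
            background_sfs([a, b])

    def test_neutral_equilibrium_spectrum_close_to_one_over_k(self):
        """Pooled neutral equilibrium data (msprime as the coalescent
        oracle): the unfolded background spectrum follows g(k) ~ 1/k."""
        import msprime

        samples = []
        # recombination matters here: pooled high-frequency classes are
        # dominated by rare root-adjacent branches, so rank stability needs
        # many independent marginal genealogies, not more mutations
        reps = msprime.sim_ancestry(
            samples=50,  # 100 chromosomes
            population_size=1000,
            sequence_length=1_000_000,
            recombination_rate=1e-6,
            num_replicates=30,
            random_seed=41,
        )
        for i, ts in enumerate(reps):
            mts = msprime.sim_mutations(ts, rate=2.5e-7, random_seed=i + 1)
            m = mts.genotype_matrix().T
            m = m[:, (m.max(axis=0) == 1)].astype(np.uint8)
            k = m.sum(axis=0)
            m = m[:, (k >= 1) & (k <= 99)]
            samples.append(
                make_sample(m, np.arange(1, m.shape[1] + 1), length=1_000_000)
            )
        model = background_sfs(samples)
        n = model.n
        assert n == 100
        rho = spearmanr(model.g[: n - 1], 1.0 / np.arange(1, n)).statistic
        assert rho >= 0.99


class TestBalancedComponent:
    def test_mode_at_half_for_beta_half(self):
        h = balanced_component(0.5, 100)
        # C(100,50) 0.5^100 ~ 0.0796; k=0 mass is negligible at n=100
        assert h[49] == pytest.approx(0.0796, abs=0.0005)

    def test_sums_to_one(self):
        for beta in (0.1, 0.5, 0.9):
            assert balanced_component(beta, 50).sum() == pytest.approx(1.0)

    def test_beta_near_one_peaks_at_substitution_class(self):
        h = balanced_component(0.999, 100)
        assert np.argmax(h) == 99  # k = n, the substitution-like limit

    def test_rejects_invalid_beta(self):
        with pytest.raises(ValueError):
            balanced_component(1.0, 100)


class TestB2Clr:
    def test_null_nested_so_clr_nonnegative(self):
        model = one_over_k_model(10)
        rng = np.random.default_rng(1)
        sites = [(int(p), int(k)) for p, k in zip(
            rng.choice(9999, 20, replace=False) + 1, rng.integers(1, 10, 20)
        )]
        clr, _, _ = b2_clr(5000, sites, model)
        assert clr >= 0.0

    def test_single_site_closed_form(self):
        """One k = 50 site at the test position with g ~ 1/k:
        CLR = 2 ln(h_0.5(50) / g(50)) ~ 6.05."""
        model = one_over_k_model(100)
        g50 = model.g[49]
        assert g50 == pytest.approx(0.003863, abs=2e-5)
        clr, beta_hat, _ = b2_clr(5000, [(5000, 50)], model)
        h50 = balanced_component(0.5, 100)[49]
        expected = 2 * np.log(h50 / g50)
        assert expected == pytest.approx(6.05, abs=0.02)
        assert clr == pytest.approx(expected, rel=1e-9)
        assert beta_hat == pytest.approx(0.5)

    def test_second_identical_site_doubles_clr(self):
        model = one_over_k_model(100)
        clr1, _, _ = b2_clr(5000, [(5000, 50)], model)
        clr2, _, _ = b2_clr(5000, [(5000, 50), (5000, 50)], model)
        assert clr2 == pytest.approx(2 * clr1, rel=1e-9)

    def test_translation_invariance(self):
        model = one_over_k_model(20)
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(9000, 15, replace=False) + 1)
        ks = rng.integers(1, 20, 15)
        sites = list(zip(pos.tolist(), ks.tolist()))
        shifted = [(p + 123_456, k) for p, k in sites]
        clr_a, ba, aa = b2_clr(int(pos[7]), sites, model)
        clr_b, bb, ab = b2_clr(int(pos[7]) + 123_456, shifted, model)
        assert clr_a == pytest.approx(clr_b, rel=1e-12)
        assert (ba, aa) == (bb, ab)

    def test_matches_brute_force_grid_evaluation(self):
        """Direct loop over the (beta, A) grid reproduces the vectorised
        maximisation on random instances."""
        model = one_over_k_model(12)
        config = B2Config(
            beta_grid=(0.1, 0.3, 0.5, 0.7, 0.9),
            footprint_grid=(100.0, 1000.0, 10_000.0),
        )
        rng = np.random.default_rng(17)
        for _ in range(10):
            n_sites = int(rng.integers(2, 12))
            pos = np.sort(rng.choice(9999, n_sites, replace=False) + 1)
            ks = rng.integers(1, 12, n_sites)  # keep g(k) > 0 (k < n)
            sites = list(zip(pos.tolist(), ks.tolist()))
            test_pos = int(rng.integers(1, 10_000))
            clr, _, _ = b2_clr(test_pos, sites, model, config)
            best = 0.0
            for beta in config.beta_grid:
                h = balanced_component(beta, 12)
                for a in config.footprint_grid:
                    ll = 0.0
                    for p, k in sites:
                        alpha = np.exp(-abs(p - test_pos) / a)
                        mix = alpha * h[k - 1] + (1 - alpha) * model.g[k - 1]
                        ll += np.log(mix / model.g[k - 1])
                    best = max(best, 2 * ll)
            assert clr == pytest.approx(best, rel=1e-10)

    def test_optimal_count_at_test_site_never_decreases_clr(self):
        """Replacing the count at the test site with the count maximising
        h_beta_hat(k)/g(k) under the previous maximiser never lowers the
        maximised CLR (each per-site term is monotone in h/g)."""
        model = one_over_k_model(20)
        rng = np.random.default_rng(23)
        checked = 0
        for _ in range(20):
            pos = np.sort(rng.choice(5000, 8, replace=False) + 1)
            ks = rng.integers(1, 15, 8)
            sites = list(zip(pos.tolist(), ks.tolist()))
            test_pos = int(pos[3])
            clr_before, beta_hat, _ = b2_clr(test_pos, sites, model)
            if not np.isfinite(beta_hat):
                continue  # no-signal maximiser: nothing to improve on
            h = balanced_component(beta_hat, 20)
            with np.errstate(divide="ignore"):
                ratio = np.where(model.g > 0, h / np.maximum(model.g, 1e-300), 0.0)
            k_star = int(np.argmax(ratio[:19])) + 1  # keep g(k) > 0
            boosted = list(sites)
            boosted[3] = (sites[3][0], k_star)
            clr_after, _, _ = b2_clr(test_pos, boosted, model)
            assert clr_after >= clr_before - 1e-9
            checked += 1
        assert checked >= 5


class TestB2Scan:
    def test_scan_scores_every_snp(self):
        rng = np.random.default_rng(31)
        m = (rng.random((10, 25)) < 0.4).astype(np.uint8)
        keep = (m.sum(0) > 0) & (m.sum(0) < 10)
        m = m[:, keep]
        sample = make_sample(m, np.sort(rng.choice(9999, keep.sum(), replace=False)) + 1)
        model = background_sfs([sample])
        result = b2_scan(sample, model)
        assert result.n_snps == sample.n_sites
        assert (result.scores >= 0).all()

    def test_substitutions_enter_informative_sites(self):
        m = np.zeros((4, 1), dtype=np.uint8)
        m[0, 0] = 1
        sample = make_sample(m, [100], subs=[5000])
        pos, ks = informative_sites(sample)
        assert pos.tolist() == [100, 5000]
        assert ks.tolist() == [1, 4]
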