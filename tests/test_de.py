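"""NB dispersion estimation and likelihood-ratio testing against
brute-force grid-search oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from craniodev._nb import group_profile_loglik
from craniodev.de import DispersionEstimates, adjust_fdr
from craniodev.de import estimate_common_dispersion, estimate_tagwise_dispersions
from craniodev.de import nb_loglik_single
from craniodev.de import test_pairwise as pairwise_lrt
from craniodev.normalize import NormalizationFactors


def _nb_counts(rng, mu, phi, n_samples):
    mu = np.atleast_1d(mu)[:, None]
    shape = np.broadcast_to(1.0 / np.atleast_1d(phi)[:, None],
                            (mu.shape[0], n_samples))
    lam = rng.gamma(shape, np.atleast_1d(phi)[:, None] * mu)
    return rng.poisson(lam)


def _frame(y):
    return pd.DataFrame(
        y,
        index=[f"g{i:04d}" for i in range(y.shape[0])],
        columns=[f"s{j}" for j in range(y.shape[1])],
    )


def _groups(counts, sizes=(4, 4)):
    labels = []
    for i, n in enumerate(sizes):
        labels += [chr(ord("A") + i)] * n
    return pd.Series(labels, index=counts.columns)


class TestCommonDispersion:
    def test_poisson_data_gives_near_zero(self):
        rng = np.random.default_rng(0)
        mu = rng.lognormal(5, 1, 2000)
        y = rng.poisson(mu[:, None] * np.ones(8))
        counts = _frame(y)
        fac = NormalizationFactors.unit(counts)
        est = estimate_common_dispersion(counts, _groups(counts), fac)
        assert est < 0.01

    def test_recovers_planted_dispersion(self):
        rng = np.random.default_rng(1)
        mu = rng.lognormal(4, 1, 2000)
        counts = _frame(_nb_counts(rng, mu, 0.1, 8))
        fac = NormalizationFactors.unit(counts)
        est = estimate_common_dispersion(counts, _groups(counts), fac)
        assert 0.08 <= est <= 0.12

    def test_single_gene_optimum_matches_grid_search(self):
        rng = np.random.default_rng(2)
        counts = _frame(_nb_counts(rng, np.array([200.0]), 0.2, 8))
        fac = NormalizationFactors.unit(counts)
        groups = _groups(counts)
        est = estimate_common_dispersion(counts, groups, fac)
        y = counts.to_numpy(float)
        S = fac.effective_lib_size.to_numpy()
        cols = [np.arange(4), np.arange(4, 8)]
        grid = np.exp(np.linspace(np.log(1e-6), np.log(10.0), 10_000))
        ll = [group_profile_loglik(y, S, cols, p, adjust=True).sum()
              for p in grid]
        best = grid[int(np.argmax(ll))]
        # agreement within the grid's own resolution
        assert abs(np.log(est) - np.log(best)) < np.log(grid[1] / grid[0]) * 2

    def test_all_zero_matrix_errors(self):
        counts = _frame(np.zeros((5, 8), dtype=int))
        fac = NormalizationFactors(
            lib_size=pd.Series(1e6, index=counts.columns),
            factor=pd.Series(1.0, index=counts.columns),
        )
        with pytest.raises(ValueError):
            estimate_common_dispersion(counts, _groups(counts), fac)


class TestTagwiseDispersion:
    @pytest.fixture(scope="class")
    def fitted(self):
        # four groups of four replicates, the study's per-stage layout
        rng = np.random.default_rng(3)
        mu = rng.lognormal(5.5, 0.6, 400)
        phi = np.where(np.arange(400) % 2 == 0, 0.05, 0.4)
        counts = _frame(_nb_counts(rng, mu, phi, 16))
        fac = NormalizationFactors.unit(counts)
        groups = _groups(counts, sizes=(4, 4, 4, 4))
        common = estimate_common_dispersion(counts, groups, fac)
        return counts, fac, groups, common, phi, mu

    def test_huge_prior_recovers_common(self, fitted):
        counts, fac, groups, common, _, _ = fitted
        est = estimate_tagwise_dispersions(
            counts, groups, fac, common, prior_weight=1e9, trend=False
        )
        assert np.allclose(est.tagwise, common, rtol=1e-4, atol=1e-6)

    def test_zero_prior_matches_per_gene_grid_mle(self, fitted):
        counts, fac, groups, common, _, _ = fitted
        est = estimate_tagwise_dispersions(
            counts, groups, fac, common, prior_weight=0.0
        )
        y = counts.to_numpy(float)
        S = fac.effective_lib_size.to_numpy()
        cols = [np.arange(i, i + 4) for i in range(0, 16, 4)]
        grid = np.exp(
            np.linspace(np.log(common / 2**8), np.log(common * 2**8), 4000)
        )
        L = np.stack(
            [group_profile_loglik(y, S, cols, p, adjust=True) for p in grid],
            axis=1,
        )
        oracle = grid[np.argmax(L, axis=1)]
        interior = (oracle > grid[0] * 1.01) & (oracle < grid[-1] * 0.99)
        assert np.allclose(
            np.log(est.tagwise.to_numpy()[interior]),
            np.log(oracle[interior]),
            atol=0.02,
        )

    def test_shrunken_estimates_order_heterogeneous_truth(self, fitted):
        counts, fac, groups, common, phi, mu = fitted
        est = estimate_tagwise_dispersions(counts, groups, fac, common)
        well = mu >= 100
        low = est.tagwise.to_numpy()[well & (phi == 0.05)]
        high = est.tagwise.to_numpy()[well & (phi == 0.4)]
        # pairwise ordering consistent with truth for >= 90% of pairs
        frac = np.mean(low[:, None] < high[None, :])
        assert frac >= 0.9

    def test_validation_rejects_bad_values(self):
        with pytest.raises(ValueError):
            DispersionEstimates(common=-1.0, tagwise=pd.Series([0.1]))
        with pytest.raises(ValueError):
            DispersionEstimates(common=0.1, tagwise=pd.Series([np.nan]))


def _de_setup(y, sizes=(4, 4)):
    counts = _frame(y)
    groups = _groups(counts, sizes)
    samples = pd.DataFrame(
        {
            "sample_id": counts.columns,
            "taxon": groups.to_numpy(),
            "stage": "st",
            "replicate": np.arange(y.shape[1]),
        }
    )
    fac = NormalizationFactors(
        lib_size=pd.Series(1e6, index=counts.columns),
        factor=pd.Series(1.0, index=counts.columns),
    )
    disp = DispersionEstimates(
        common=0.1, tagwise=pd.Series(0.1, index=counts.index)
    )
    return counts, samples, fac, disp


class TestPairwise:
    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(4)
        half = rng.poisson(100.0, size=(50, 4))
        y = np.hstack([half, half])  # group B duplicates group A
        counts, samples, fac, disp = _de_setup(y)
        res = pairwise_lrt(counts, samples, "A", "B", fac, disp)
        assert np.allclose(res["logFC"], 0.0)
        assert np.allclose(res["PValue"], 1.0)

    def test_group_swap_flips_logfc_and_keeps_p(self):
        rng = np.random.default_rng(5)
        y = _nb_counts(rng, rng.lognormal(5, 1, 80), 0.1, 8)
        counts, samples, fac, disp = _de_setup(y)
        ab = pairwise_lrt(counts, samples, "A", "B", fac, disp)
        ba = pairwise_lrt(counts, samples, "B", "A", fac, disp)
        assert np.allclose(ab["logFC"], -ba["logFC"], atol=1e-12)
        assert np.allclose(ab["PValue"], ba["PValue"], atol=1e-12)

    def test_lrt_statistic_matches_grid_mle_oracle(self):
        y = np.array([[10, 12, 9, 11, 30, 28, 33, 35]])
        counts, samples, fac, disp = _de_setup(y)
        res = pairwise_lrt(counts, samples, "A", "B", fac, disp)
        from scipy.stats import chi2

        lrt = chi2.isf(res["PValue"].iloc[0], df=1)
        S = fac.effective_lib_size.to_numpy()
        rates = np.linspace(1e-7, 60e-6, 240_001)  # counts per library unit

        def best(yy, ss):
            return max(nb_loglik_single(yy, ss, r, 0.1) for r in rates)

        ll_alt = best(y[0, :4], S[:4]) + best(y[0, 4:], S[4:])
        ll_null = best(y[0], S)
        assert 2 * (ll_alt - ll_null) == pytest.approx(lrt, abs=1e-4)

    def test_unknown_taxon_errors(self):
        y = np.ones((3, 8), dtype=int)
        counts, samples, fac, disp = _de_setup(y)
        with pytest.raises(ValueError, match="unknown taxon"):
            pairwise_lrt(counts, samples, "A", "Z", fac, disp)

    def test_lrt_nonnegative_and_probabilities_valid(self):
        rng = np.random.default_rng(6)
        y = _nb_counts(rng, rng.lognormal(3, 2, 300), 0.3, 8)
        counts, samples, fac, disp = _de_setup(y)
        res = pairwise_lrt(counts, samples, "A", "B", fac, disp)
        assert ((res["PValue"] >= 0) & (res["PValue"] <= 1)).all()
        assert ((res["FDR"] >= 0) & (res["FDR"] <= 1)).all()
        assert (res["FDR"] >= res["PValue"] - 1e-12).all()


class TestAdjustFdr:
    def test_single_p_unchanged(self):
        assert adjust_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_bh(self):
        q = adjust_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(q, 0.05)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_permutation_equivariance(self, ps, rnd):
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        direct = adjust_fdr(ps)
        permuted = adjust_fdr([ps[i] for i in perm])
        assert np.allclose([direct[i] for i in perm], permuted)
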