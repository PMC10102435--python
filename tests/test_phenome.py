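"""Phenome preparation and MPMM imputation contracts."""

import numpy as np
import pandas as pd
import pytest

from bgpwas import phenome as ph
from bgpwas import synthetic as syn
from bgpwas.phenome import PhenomeError

from conftest import recovery_r, trait_matrix


class TestFilterTraits:
    def test_strictly_greater_boundary(self):
        # 10 accessions: 4/10 missing is dropped, 3/10 sits on the boundary and stays
        vals = np.ones((10, 2))
        vals[:4, 0] = np.nan
        vals[:3, 1] = np.nan
        tm, report = ph.filter_traits(trait_matrix(vals), max_missing_frac=0.30)
        assert tm.trait_names == ["t1"]
        assert report.dropped == ["t0"]

    def test_count_on_wide_synthetic_table(self):
        # 234 traits; exactly 124 built with <=30% missing, the rest above
        rng = np.random.default_rng(77)
        n = 50
        vals = rng.standard_normal((n, 234))
        n_missing = np.array([int(0.3 * n)] * 124 + [int(0.3 * n) + 1 + rng.integers(0, 10) for _ in range(110)])
        rng.shuffle(n_missing)
        for j, m in enumerate(n_missing):
            vals[rng.choice(n, m, replace=False), j] = np.nan
        tm = trait_matrix(vals)
        # independent brute-force count
        expected = sum(np.isnan(vals[:, j]).mean() <= 0.30 for j in range(234))
        assert expected == 124
        filtered, _ = ph.filter_traits(tm, 0.30)
        assert filtered.p == 124

    def test_all_dropped_is_an_error(self):
        vals = np.full((4, 2), np.nan)
        vals[0] = 1.0
        with pytest.raises(PhenomeError, match="no traits survive"):
            ph.filter_traits(trait_matrix(vals), max_missing_frac=0.30)


class TestDropCorrelated:
    def test_duplicate_dropped_earlier_kept(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(40)
        vals = np.column_stack([base, rng.standard_normal(40), base])
        tm, report = ph.drop_correlated(trait_matrix(vals))
        assert tm.trait_names == ["t0", "t1"]
        assert report[0][0] == "t2" and report[0][1] == "t0"
        assert report[0][2] == pytest.approx(1.0)

    def test_independent_traits_retained(self):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal((1000, 2))
        assert abs(np.corrcoef(vals.T)[0, 1]) < 0.95  # direct check
        tm, report = ph.drop_correlated(trait_matrix(vals))
        assert tm.p == 2 and report == []

    def test_three_mutual_duplicates_keep_first(self):
        base = np.arange(10.0)
        vals = np.column_stack([base, base, base])
        tm, _ = ph.drop_correlated(trait_matrix(vals))
        assert tm.trait_names == ["t0"]

    def test_sparse_overlap_pair_warns_and_keeps(self):
        vals = np.full((10, 2), np.nan)
        vals[:, 0] = np.arange(10.0)
        vals[:2, 1] = [1.0, 2.0]  # only 2 shared observations
        with pytest.warns(RuntimeWarning, match="fewer than"):
            tm, _ = ph.drop_correlated(trait_matrix(vals))
        assert tm.p == 2


class TestStandardize:
    def test_hand_example_n_minus_1_sd(self):
        tm = ph.standardize(trait_matrix(np.array([[2.0], [4.0], [6.0]])))
        np.testing.assert_allclose(tm.values[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)
        # (2,4,6): mean 4, sd 2 with the n-1 denominator
        assert tm.standardization["t0"] == (4.0, 2.0)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        tm = ph.standardize(trait_matrix(rng.standard_normal((30, 4))))
        again = ph.standardize(tm)
        np.testing.assert_allclose(again.values, tm.values, atol=1e-12)

    def test_observed_moments(self):
        rng = np.random.default_rng(4)
        vals = rng.standard_normal((50, 3)) * 7 + 2
        vals[rng.random((50, 3)) < 0.2] = np.nan
        tm = ph.standardize(trait_matrix(vals))
        for j in range(3):
            obs = tm.values[tm.mask[:, j], j]
            assert abs(obs.mean()) < 1e-8
            assert abs(obs.std(ddof=1) - 1) < 1e-8

    def test_constant_trait_rejected_by_name(self):
        with pytest.raises(PhenomeError, match="t0"):
            ph.standardize(trait_matrix(np.array([[5.0], [5.0], [5.0]])))


class TestMPMMImpute:
    def test_fully_observed_returns_input_exactly(self):
        rng = np.random.default_rng(5)
        tm = ph.standardize(trait_matrix(rng.standard_normal((20, 4))))
        fit = ph.mpmm_impute(tm, np.eye(20))
        np.testing.assert_array_equal(fit.imputed, tm.values)

    def test_duplicate_trait_recovers_masked_entry(self):
        # oracle: with an exact duplicate column the conditional mean of the
        # masked entry given its twin is the twin's value itself
        rng = np.random.default_rng(42)
        n = 80
        base = rng.standard_normal(n)
        vals = np.column_stack([base, base.copy(), rng.standard_normal(n)])
        tm = ph.standardize(trait_matrix(vals))
        mask = tm.mask.copy()
        mask[5, 1] = False
        masked = ph.TraitMatrix(np.where(mask, tm.values, np.nan), mask,
                                tm.accession_ids, tm.trait_names)
        fit = ph.mpmm_impute(masked, np.eye(n))
        assert abs(fit.imputed[5, 1] - tm.values[5, 0]) < 0.1

    def test_rank2_simulation_recovery_beats_mean_imputation(self, small_pop):
        tm, _ = syn.simulate_phenome(small_pop.kinship, p=10, rank=2,
                                     noise_cov=0.3, seed=4)
        tm = ph.standardize(tm)
        masked, truth = syn.mask_missing(tm, 0.1, seed=5)
        fit = ph.mpmm_impute(masked, small_pop.kinship, ph.MPMMSpec(max_iter=200))
        r = recovery_r(fit.imputed, truth.held_out)
        assert r >= 0.8
        colmeans = np.nanmean(masked.values, axis=0)
        base = np.array([colmeans[j] for _, j in truth.held_out])
        true = np.array(list(truth.held_out.values()))
        r_mean = abs(float(np.corrcoef(base, true)[0, 1]))
        assert r > r_mean
        # observed entries byte-preserved
        np.testing.assert_array_equal(fit.imputed[masked.mask], masked.values[masked.mask])

    def test_objective_trace_monotone(self, small_pop):
        tm, _ = syn.simulate_phenome(small_pop.kinship, p=8, rank=2, noise_cov=0.5, seed=9)
        tm = ph.standardize(tm)
        masked, _ = syn.mask_missing(tm, 0.15, seed=10)
        fit = ph.mpmm_impute(masked, small_pop.kinship, ph.MPMMSpec(max_iter=60))
        diffs = np.diff(fit.elbo_trace)
        assert diffs.min() > -1e-6

    def test_kinship_beats_identity_when_genetic_variance_dominates(self):
        # per-trait independent genetic effects: only relatives inform a
        # masked entry, so the true K must beat K = I (20-rep average)
        def recover(use_k, seed):
            n, p = 100, 8
            pop = syn.simulate_population(n, 300, 2, block_structure=5, fst=0.35, seed=seed)
            tm, _ = syn.simulate_phenome(pop.kinship, p=p, rank=p, noise_cov=0.5,
                                         beta=np.eye(p), seed=seed + 1)
            tm = ph.standardize(tm)
            masked, truth = syn.mask_missing(tm, 0.1, seed=seed + 2)
            K = pop.kinship.values if use_k else np.eye(n)
            fit = ph.mpmm_impute(masked, K, ph.MPMMSpec(rank=p, max_iter=80))
            return recovery_r(fit.imputed, truth.held_out)

        seeds = [1000 + 7 * s for s in range(20)]
        with_k = np.mean([recover(True, s) for s in seeds])
        without = np.mean([recover(False, s) for s in seeds])
        assert with_k > without

    def test_exchangeability_under_row_permutation(self, tiny_pop):
        tm, _ = syn.simulate_phenome(tiny_pop.kinship, p=5, rank=2, noise_cov=0.5, seed=6)
        tm = ph.standardize(tm)
        masked, _ = syn.mask_missing(tm, 0.2, seed=7)
        fit = ph.mpmm_impute(masked, tiny_pop.kinship, ph.MPMMSpec(max_iter=40))
        perm = np.random.default_rng(8).permutation(tm.n)
        pm = ph.TraitMatrix(masked.values[perm], masked.mask[perm],
                            [masked.accession_ids[i] for i in perm], masked.trait_names)
        Kp = tiny_pop.kinship.values[np.ix_(perm, perm)]
        fit_p = ph.mpmm_impute(pm, Kp, ph.MPMMSpec(max_iter=40))
        np.testing.assert_allclose(fit_p.imputed, fit.imputed[perm], atol=1e-6)

    def test_residual_covariance_symmetric_psd(self, tiny_pop):
        tm, _ = syn.simulate_phenome(tiny_pop.kinship, p=6, rank=2, noise_cov=0.5, seed=12)
        tm = ph.standardize(tm)
        masked, _ = syn.mask_missing(tm, 0.1, seed=13)
        fit = ph.mpmm_impute(masked, tiny_pop.kinship, ph.MPMMSpec(max_iter=40))
        for M in (fit.E_mean, fit.B_implied):
            np.testing.assert_allclose(M, M.T, atol=1e-8)
            assert np.linalg.eigvalsh(M).min() > -1e-8

    def test_non_psd_kinship_rejected_with_eigenvalue(self):
        tm = ph.standardize(trait_matrix(np.random.default_rng(1).standard_normal((4, 2))))
        K = np.eye(4)
        K[0, 1] = K[1, 0] = 2.0  # indefinite
        with pytest.raises(PhenomeError, match="eigenvalue"):
            ph.mpmm_impute(tm, K)

    def test_dimension_mismatch_rejected(self):
        tm = ph.standardize(trait_matrix(np.random.default_rng(1).standard_normal((4, 2))))
        with pytest.raises(PhenomeError, match="does not match"):
            ph.mpmm_impute(tm, np.eye(5))


class TestPropertyBased:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        n=st.integers(6, 15),
        p=st.integers(2, 5),
        seed=st.integers(0, 10_000),
        rate=st.floats(0.0, 0.4),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_imputation_never_touches_observed_entries(self, n, p, seed, rate):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal((n, p)) + rng.standard_normal((n, 1))
        mask = rng.random((n, p)) >= rate
        mask[0, :] = True  # keep every trait observed somewhere
        mask[:, 0] = True
        masked = trait_matrix(np.where(mask, vals, np.nan))
        fit = ph.mpmm_impute(masked, np.eye(n), ph.MPMMSpec(max_iter=15))
        np.testing.assert_array_equal(fit.imputed[mask], vals[mask])
        assert np.all(np.isfinite(fit.imputed))

    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_standardize_moments_for_arbitrary_scales(self, seed, scale):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal((12, 3)) * scale + rng.uniform(-50, 50)
        tm = ph.standardize(trait_matrix(vals))
        np.testing.assert_allclose(tm.values.mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(tm.values.std(axis=0, ddof=1), 1, atol=1e-8)


def test_dataframe_roundtrip_preserves_missingness():
    df = pd.DataFrame({"x": [1.0, np.nan, 3.0], "y": [4.0, 5.0, 6.0]},
                      index=["a", "b", "c"])
    tm = ph.TraitMatrix.from_dataframe(df)
    assert tm.mask.sum() == 5
    back = tm.to_dataframe()
    assert np.isnan(back.loc["b", "x"])
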