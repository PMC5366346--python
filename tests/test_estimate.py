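"""Trait estimation: regressions, logistic fits, allometry, profiles, PCA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import legumorph as lm
from legumorph.errors import (DataValidationError, DegenerateFitError,
                              InsufficientDataError)


class TestLeafAppearance:
    @pytest.mark.parametrize("phyllochron", [32.6, 64.2])
    def test_recovers_generating_phyllochron_exactly(self, phyllochron):
        tt = np.arange(0.0, 1500.0, 105.0)
        fit = lm.fit_leaf_appearance(tt, tt / phyllochron)
        assert fit.phyllochron == pytest.approx(phyllochron, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.tt_start == pytest.approx(0.0, abs=1e-6)

    def test_filter_excludes_censuses_below_three_leaves(self):
        tt = np.array([0.0, 50.0, 100.0, 200.0, 300.0, 400.0])
        count = np.array([0.0, 1.0, 2.0, 4.0, 6.0, 8.0])  # kink below count 3
        fit = lm.fit_leaf_appearance(tt, count)
        assert fit.n_used == 3
        assert fit.phyllochron == pytest.approx(50.0)

    def test_two_exact_points_interpolate(self):
        fit = lm.fit_leaf_appearance([100.0, 200.0], [4.0, 8.0])
        assert fit.r2 == pytest.approx(1.0)
        assert fit.phyllochron == pytest.approx(25.0)

    def test_insufficient_and_degenerate_inputs(self):
        with pytest.raises(InsufficientDataError):
            lm.fit_leaf_appearance([100.0], [5.0])
        with pytest.raises(DegenerateFitError):
            lm.fit_leaf_appearance([0.0, 100.0, 200.0], [8.0, 6.0, 4.0])


class TestLogisticFit:
    def test_exact_recovery_from_noiseless_logistic(self):
        tau = np.linspace(-2.0, 5.0, 40)
        length = 30.0 / (1.0 + np.exp(-2.0 * (tau - 1.0)))
        fit = lm.fit_logistic_growth(tau, length, "petiole")
        assert fit.l_max == pytest.approx(30.0, rel=1e-6)
        assert fit.s == pytest.approx(2.0, rel=1e-6)
        assert fit.t50 == pytest.approx(1.0, abs=1e-6)

    def test_d95_identity_holds_on_fit_record(self):
        tau = np.linspace(0.0, 8.0, 30)
        length = 12.0 / (1.0 + np.exp(-1.3 * (tau - 2.0)))
        fit = lm.fit_logistic_growth(tau, length)
        assert fit.d95 == pytest.approx(2.0 * math.log(19.0) / fit.s, rel=1e-12)

    def test_d95_from_prescribed_steepness(self):
        s_true = 2.0 * math.log(19.0) / 2.5
        tau = np.linspace(-3.0, 4.0, 50)
        fit = lm.fit_logistic_growth(tau, 8.0 / (1.0 + np.exp(-s_true * tau)))
        assert fit.d95 == pytest.approx(2.5, rel=1e-6)

    def test_constrained_lmax_mode(self):
        tau = np.linspace(-2.0, 5.0, 40)
        length = 30.0 / (1.0 + np.exp(-2.0 * (tau - 1.0)))
        fit = lm.fit_logistic_growth(tau, length, fix_lmax=30.0)
        assert fit.l_max == 30.0
        assert fit.s == pytest.approx(2.0, rel=1e-6)

    def test_flat_series_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            lm.fit_logistic_growth([0, 1, 2, 3], [5.0, 5.0, 5.0, 5.0])

    def test_shared_fit_pools_replicates_with_distinct_maxima(self):
        tau = np.linspace(-1.0, 6.0, 35)
        series = [(tau, lmax / (1.0 + np.exp(-1.8 * (tau - 0.7))))
                  for lmax in (5.0, 9.0, 13.0)]
        fit = lm.fit_shared_logistic(series, "petiole")
        assert fit.s == pytest.approx(1.8, rel=1e-6)
        assert fit.t50 == pytest.approx(0.7, abs=1e-6)
        assert fit.l_max == pytest.approx([5.0, 9.0, 13.0], rel=1e-6)


class TestD95Conversions:
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(0.05, 50.0))
    def test_round_trip_identity(self, s):
        assert lm.s_from_d95(lm.d95_from_s(s)) == pytest.approx(s, rel=1e-12)

    def test_closed_form_values(self):
        assert lm.d95_from_s(2.0 * math.log(19.0)) == pytest.approx(1.0)
        assert lm.s_from_d95(5.0) == pytest.approx(1.1778, rel=1e-4)

    def test_domain_errors(self):
        with pytest.raises(lm.ConfigurationError):
            lm.d95_from_s(0.0)
        with pytest.raises(lm.ConfigurationError):
            lm.s_from_d95(-2.0)


class TestGrowthCessationTruncation:
    def test_series_cut_after_four_identical_readings(self):
        tau = np.arange(10.0)
        length = np.array([1.0, 2.0, 4.0, 6.0, 6.0, 6.0, 6.0, 6.0, 6.0, 6.0])
        t, l = lm.truncate_after_growth_stops(tau, length)
        assert list(l) == [1.0, 2.0, 4.0, 6.0]

    def test_continuous_series_untouched(self):
        tau = np.arange(8.0)
        length = np.linspace(0.1, 5.0, 8)
        t, l = lm.truncate_after_growth_stops(tau, length)
        assert len(l) == 8


class TestBranchingProbability:
    @staticmethod
    def _table(bursts):
        rows = []
        for plant, ranks in bursts.items():
            for rank in range(1, 6):
                rows.append({"plant_id": plant, "axis_id": "main", "category": "main",
                             "phytomer_rank": rank, "burst_observed": rank in ranks,
                             "tt": 50.0 * rank if rank in ranks else np.nan})
        return pd.DataFrame(rows)

    def test_probability_one_where_every_plant_burst(self):
        table = self._table({"p1": {1, 2}, "p2": {1, 2}, "p3": {1, 2}})
        res = lm.branching_probability(table, at_tt=150.0)
        probs = res.table.set_index("position")["probability"]
        assert probs[1] == 1.0 and probs[2] == 1.0 and probs[4] == 0.0

    def test_all_zero_probabilities_flagged_flat(self):
        table = self._table({"p1": set(), "p2": set()})
        res = lm.branching_probability(table, at_tt=500.0)
        assert res.flag == "flat"
        assert (res.table["probability"] == 0).all()

    def test_simulated_cohort_reaches_probability_one(self, alfalfa):
        from legumorph.synthetic import (NoiseModel, SamplingSchedule,
                                         generate_observations)
        ds, _ = generate_observations(alfalfa, SamplingSchedule(horizon_days=40),
                                      NoiseModel.noiseless(), n_plants=3,
                                      tables=("branching",))
        tt_eval = 40 * 15.0
        res = lm.branching_probability(ds.branching, at_tt=tt_eval)
        elapsed = res.table["position"] * alfalfa.phy0 + alfalfa.ram_dist * alfalfa.phy0
        fully = res.table.loc[elapsed <= tt_eval, "probability"]
        assert (fully == 1.0).all()

    def test_apex_convention_reverses_positions(self):
        table = self._table({"p1": {1, 2, 3}})
        res = lm.branching_probability(table, at_tt=500.0, convention="apex", top_rank=5)
        assert list(res.table["position"]) == [1, 2, 3, 4, 5]
        assert res.table.loc[res.table["position"] == 5, "probability"].iloc[0] == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(InsufficientDataError):
            lm.branching_probability(self._table({}), at_tt=100.0)


class TestAllometry:
    @staticmethod
    def _scans(n, coef=0.694, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        L = rng.uniform(1.0, 8.0, n)
        w = rng.uniform(0.4, 0.8, n) * L
        leaflets = rng.choice([3, 5, 9, 15], n)
        area = coef * L * w * leaflets
        if noise_sd:
            area = area * (1.0 + rng.normal(0.0, noise_sd, n))
        return pd.DataFrame({"leaflet_length_cm": L, "leaflet_width_cm": w,
                             "n_leaflets": leaflets, "area_cm2": area})

    def test_exact_recovery_of_shape_coefficient(self):
        fit = lm.fit_allometry(self._scans(40))
        assert fit.coefficient == pytest.approx(0.694, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_pooled_species_match_single_species_under_one_law(self):
        pooled = pd.concat([self._scans(30, seed=1), self._scans(30, seed=2)])
        single = self._scans(30, seed=1)
        assert lm.fit_allometry(pooled).coefficient == pytest.approx(
            lm.fit_allometry(single).coefficient, rel=1e-12)

    def test_recovery_within_two_percent_under_five_percent_noise(self):
        fit = lm.fit_allometry(self._scans(200, noise_sd=0.05, seed=42))
        assert fit.coefficient == pytest.approx(0.694, rel=0.02)

    def test_too_few_scans_rejected(self):
        with pytest.raises(InsufficientDataError):
            lm.fit_allometry(self._scans(2))


class TestRelativeProfile:
    def test_reference_is_first_rank_attaining_maximum(self):
        rel, ref = lm.relative_profile([1, 2, 3, 4, 5], [2.0, 5.0, 8.0, 8.0, 8.0])
        assert ref == 3
        assert rel.max() == 1.0 and rel[2] == 1.0

    def test_constant_profile_is_all_ones(self):
        rel, ref = lm.relative_profile([1, 2, 3], [4.0, 4.0, 4.0])
        assert np.allclose(rel, 1.0) and ref == 1

    def test_peak_at_rank_twelve(self):
        ranks = np.arange(1, 15)
        values = np.where(ranks <= 12, ranks.astype(float), 24.0 - ranks)
        _, ref = lm.relative_profile(ranks, values)
        assert ref == 12

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateFitError):
            lm.relative_profile([1, 2], [0.0, 0.0])


class TestTraitMatrix:
    @staticmethod
    def _records(n=50, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            row = {c: rng.uniform(1.0, 5.0) for c in lm.TRAIT_COLUMNS}
            row["species"] = f"sp{i % 5}"
            rows.append(row)
        return pd.DataFrame(rows)

    def test_fifty_individuals_twelve_traits(self):
        tm = lm.assemble_trait_matrix(self._records())
        assert tm.values.shape == (50, 12)
        assert not tm.imputed.to_numpy().any()

    def test_missing_cell_imputed_by_species_mean_with_flag(self):
        rec = self._records(6)
        rec.loc[0, "t50_in"] = np.nan
        with pytest.warns(UserWarning, match="imputed"):
            tm = lm.assemble_trait_matrix(rec)
        peers = rec[rec["species"] == rec.loc[0, "species"]]["t50_in"].dropna()
        assert tm.values.loc[0, "t50_in"] == pytest.approx(peers.mean())
        assert tm.imputed.loc[0, "t50_in"]

    def test_individual_missing_most_traits_excluded(self):
        rec = self._records(5)
        rec.loc[2, list(lm.TRAIT_COLUMNS)[:8]] = np.nan
        with pytest.warns(UserWarning, match="excluding"):
            tm = lm.assemble_trait_matrix(rec)
        assert tm.values.shape[0] == 4 and tm.excluded == [2]

    def test_empty_input_gives_empty_matrix(self):
        tm = lm.assemble_trait_matrix([])
        assert tm.values.empty


class TestPca:
    def test_variance_fractions_sum_to_one(self):
        tm = TestTraitMatrix._records(50)
        res = lm.pca_traits(tm[list(lm.TRAIT_COLUMNS)])
        assert res.variance_fraction.sum() == pytest.approx(1.0)
        assert res.variance_fraction.size == 12
        assert np.all(np.diff(res.variance_fraction) <= 1e-12)

    def test_perfectly_correlated_pair_loads_on_single_component(self):
        x = np.linspace(0, 1, 20)
        res = lm.pca_traits(pd.DataFrame({"a": x, "b": 3 * x + 1}))
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_bivariate_closed_form_first_component(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(4000)
        y = 0.6 * x + math.sqrt(1 - 0.6 ** 2) * rng.standard_normal(4000)
        res = lm.pca_traits(pd.DataFrame({"x": x, "y": y}))
        r = np.corrcoef(x, y)[0, 1]
        assert res.variance_fraction[0] == pytest.approx((1 + abs(r)) / 2, abs=1e-9)

    def test_scores_centered_and_matrix_reconstructed(self):
        tm = TestTraitMatrix._records(30)[list(lm.TRAIT_COLUMNS)]
        res = lm.pca_traits(tm)
        assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-10)
        z = (tm - tm.mean()) / tm.std(ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, z.to_numpy(), atol=1e-8)
        # loadings columns orthonormal
        gram = res.loadings.to_numpy().T @ res.loadings.to_numpy()
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-10)

    def test_zero_variance_column_dropped_with_warning(self):
        tm = TestTraitMatrix._records(20)[list(lm.TRAIT_COLUMNS)].copy()
        tm["phy0"] = 3.14
        with pytest.warns(UserWarning, match="zero-variance"):
            res = lm.pca_traits(tm)
        assert res.dropped == ["phy0"]
        assert "phy0" not in res.loadings.index

    def test_non_finite_values_rejected(self):
        with pytest.raises(DataValidationError):
            lm.pca_traits(pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [1.0, 2.0, 3.0]}))
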