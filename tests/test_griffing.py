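import numpy as np
import pandas as pd
import pytest

from conftest import constrained_ls_effects, random_cross_matrix
from diallelkit import datasets
from diallelkit.core import CrossMeansMatrix, DiallelDesign
from diallelkit.griffing import (
    anova_combined,
    anova_single_env,
    griffing2_effects,
    griffing4_effects,
    parents_vs_hybrids_contrast,
    rank_effects,
)
from diallelkit.simulate import SimulationSpec, default_design, simulate_diallel


class TestMethod4Effects:
    def test_published_melon_gca(self):
        """The Latina-2015 yield LsM table reproduces the published GCA column."""
        x = datasets.melon_yield_lsm("latina_2015")
        eff = griffing4_effects(x)
        published = [-0.971, -0.084, -0.537, -0.798, -0.105, -0.551, 1.437, 1.609]
        np.testing.assert_allclose(eff.g.to_numpy(), published, atol=0.01)
        assert eff.g["PI414723"] == pytest.approx(1.437, abs=0.005)

    def test_published_melon_sca(self):
        x = datasets.melon_yield_lsm("latina_2015")
        eff = griffing4_effects(x)
        # printed 0.555 from inputs rounded to 2 dp
        assert eff.s.loc["PI414723", "PI161375"] == pytest.approx(0.555, abs=0.01)

    def test_constraints_and_saturation(self):
        for seed in range(5):
            x = random_cross_matrix(6, seed)
            eff = griffing4_effects(x)
            assert abs(eff.g.sum()) < 1e-10
            s = eff.s.to_numpy()
            np.testing.assert_allclose(np.nansum(s, axis=1), 0.0, atol=1e-10)
            off = ~np.eye(6, dtype=bool)
            np.testing.assert_allclose(
                eff.fitted().to_numpy()[off], x.values.to_numpy()[off], atol=1e-10
            )

    def test_matches_least_squares_oracle(self):
        for seed in range(10):
            x = random_cross_matrix(6, seed)
            eff = griffing4_effects(x)
            m, g, s = constrained_ls_effects(x)
            assert eff.m == pytest.approx(m, abs=1e-10)
            np.testing.assert_allclose(eff.g.to_numpy(), g, atol=1e-10)
            off = ~np.eye(6, dtype=bool)
            np.testing.assert_allclose(eff.s.to_numpy()[off], s[off], atol=1e-10)

    def test_standard_errors(self):
        x = datasets.melon_yield_lsm("latina_2015")
        eff = griffing4_effects(x, error_ms=4.04, n_reps=3)
        assert eff.se_s == pytest.approx(0.981, abs=0.001)
        assert eff.se_g == pytest.approx(np.sqrt(7 * 4.04 / (8 * 6 * 3)), abs=1e-12)

    def test_small_p_rejected(self):
        with pytest.raises(ValueError):
            griffing4_effects(random_cross_matrix(3, 0))


class TestMethod2Effects:
    def test_additive_table_has_zero_sca(self):
        a = np.array([1.0, -2.0, 0.5, 3.0, -2.5])
        table = 10.0 + a[:, None] + a[None, :]
        labels = list("ABCDE")
        x = CrossMeansMatrix(pd.DataFrame(table, index=labels, columns=labels),
                             method="method2")
        eff = griffing2_effects(x)
        np.testing.assert_allclose(eff.s.to_numpy(), 0.0, atol=1e-10)
        np.testing.assert_allclose(eff.g.to_numpy(), a - a.mean(), atol=1e-10)

    def test_constant_table(self):
        labels = list("ABCD")
        x = CrossMeansMatrix(pd.DataFrame(5.0, index=labels, columns=labels),
                             method="method2")
        eff = griffing2_effects(x)
        assert not eff.g.to_numpy().any()
        np.testing.assert_allclose(eff.s.to_numpy(), 0.0, atol=1e-12)
        assert eff.m == pytest.approx(5.0)

    def test_matches_least_squares_oracle(self):
        for seed in range(10):
            x = random_cross_matrix(5, seed, method="method2")
            eff = griffing2_effects(x)
            m, g, s = constrained_ls_effects(x)
            assert eff.m == pytest.approx(m, abs=1e-10)
            np.testing.assert_allclose(eff.g.to_numpy(), g, atol=1e-10)
            np.testing.assert_allclose(eff.s.to_numpy(), s, atol=1e-10)
            assert abs(eff.g.sum()) < 1e-10

    def test_missing_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            griffing2_effects(random_cross_matrix(5, 0, method="method4"))


class TestSingleEnvAnova:
    def test_df_structure(self, noisy_trial4, design4):
        records, _ = noisy_trial4
        anova = anova_single_env(records, "yield", "E1", "method4", design4)
        t = anova.table.set_index("source")
        assert [int(t.loc[s, "df"]) for s in ("Entries", "GCA", "SCA", "Error")] == \
            [27, 7, 20, 54]

    def test_constant_records_zero_ss(self, design4):
        spec = SimulationSpec(design=default_design("method4", n_envs=1),
                              sigma2_g=0, sigma2_s=0, sigma2_gE=0, sigma2_sE=0,
                              sigma2_block=0, sigma2_e=0)
        records, _ = simulate_diallel(spec)
        anova = anova_single_env(records, "yield", "E1", "method4", spec.design)
        # zero up to float cancellation in the Griffing totals (~1e4 scale)
        assert (anova.table["SS"].abs() < 1e-8).all()

    def test_partition_matches_cell_means_oracle(self, noisy_trial4, design4):
        """SS(Entries) equals a direct one-way decomposition and GCA+SCA add up."""
        records, _ = noisy_trial4
        anova = anova_single_env(records, "yield", "E1", "method4", design4)
        t = anova.table.set_index("source")
        sub = records[records["env"] == "E1"]
        means = sub.groupby(["parent_a", "parent_b"])["value"].mean()
        r = 3
        ss_entries_oracle = r * ((means - means.mean()) ** 2).sum()
        assert t.loc["Entries", "SS"] == pytest.approx(ss_entries_oracle, rel=1e-10)
        assert t.loc["GCA", "SS"] + t.loc["SCA", "SS"] == \
            pytest.approx(t.loc["Entries", "SS"], rel=1e-8)

    def test_method2_partition(self, design2_single):
        records, _ = simulate_diallel(SimulationSpec(design=design2_single, seed=8))
        anova = anova_single_env(records, "yield", "E1", "method2", design2_single)
        t = anova.table.set_index("source")
        assert [int(t.loc[s, "df"]) for s in ("Entries", "GCA", "SCA", "Error")] == \
            [35, 7, 28, 70]
        assert t.loc["GCA", "SS"] + t.loc["SCA", "SS"] == \
            pytest.approx(t.loc["Entries", "SS"], rel=1e-8)


class TestCombinedAnova:
    def test_df_structure(self, noisy_trial4, design4):
        records, _ = noisy_trial4
        anova = anova_combined(records, "yield", "method4", design4)
        t = anova.table.set_index("source")
        expected = {"Environments": 5, "Entries": 27, "GCA": 7, "SCA": 20,
                    "Env x Entries": 135, "Env x GCA": 35, "Env x SCA": 100,
                    "Error": 324}
        for source, df in expected.items():
            assert int(t.loc[source, "df"]) == df

    def test_duplicated_environment_kills_interactions(self, design4):
        d1 = default_design("method4", n_envs=1)
        records, _ = simulate_diallel(SimulationSpec(design=d1, seed=3))
        dup = records.assign(env="E2")
        both = pd.concat([records, dup], ignore_index=True)
        d2 = default_design("method4", n_envs=2)
        anova = anova_combined(both, "yield", "method4", d2)
        t = anova.table.set_index("source")
        for source in ("Env x Entries", "Env x GCA", "Env x SCA"):
            assert abs(t.loc[source, "SS"]) < 1e-8

    def test_interaction_decomposition_oracle(self, noisy_trial4, design4):
        """Env x Entries SS = sum of per-env entry SS minus pooled entry SS."""
        records, _ = noisy_trial4
        comb = anova_combined(records, "yield", "method4", design4)
        t = comb.table.set_index("source")
        per_env = sum(
            anova_single_env(records, "yield", env, "method4", design4)
            .table.set_index("source").loc["Entries", "SS"]
            for env in design4.environments
        )
        assert t.loc["Env x Entries", "SS"] == \
            pytest.approx(per_env - t.loc["Entries", "SS"], abs=1e-8)
        assert t.loc["Env x GCA", "SS"] + t.loc["Env x SCA", "SS"] == \
            pytest.approx(t.loc["Env x Entries", "SS"], rel=1e-8)

    def test_single_environment_rejected(self, design4):
        d1 = default_design("method4", n_envs=1)
        records, _ = simulate_diallel(SimulationSpec(design=d1, seed=3))
        with pytest.raises(ValueError, match="2 environments"):
            anova_combined(records, "yield", "method4", d1)


class TestParentsVsHybrids:
    def test_shift_between_pools_detected(self, design2_single):
        # parents sit delta = -2 below mu, hybrids at mu -> estimate +2
        spec = SimulationSpec(design=design2_single, delta_self=-2.0,
                              sigma2_g=0, sigma2_s=0, sigma2_gE=0,
                              sigma2_sE=0, sigma2_block=0, sigma2_e=0.25, seed=21)
        records, _ = simulate_diallel(spec)
        con = parents_vs_hybrids_contrast(records, "yield", "E1", design2_single)
        assert con.estimate == pytest.approx(2.0, abs=0.5)
        assert con.p < 0.001
        assert con.t == pytest.approx(con.estimate / con.se)

    def test_late_ripening_parents_give_negative_contrast(self):
        """Hybrids ripening earlier than parents show a negative DTR contrast."""
        d = default_design(method="method2", n_envs=1)
        spec = SimulationSpec(design=d, trait="dtr", mu=65.0, delta_self=1.5,
                              sigma2_g=0.5, sigma2_s=0.1, sigma2_gE=0,
                              sigma2_sE=0, sigma2_block=0, sigma2_e=0.5, seed=6)
        records, _ = simulate_diallel(spec)
        con = parents_vs_hybrids_contrast(records, "dtr", "E1", d)
        assert con.estimate < 0

    def test_requires_selfs(self, noisy_trial4, design4):
        records, _ = noisy_trial4
        with pytest.raises(ValueError, match="self"):
            parents_vs_hybrids_contrast(records, "yield", "E1", design4)


class TestRankEffects:
    def test_published_yield_ranks(self):
        x = datasets.melon_yield_lsm("latina_2015")
        eff = griffing4_effects(x)
        ranks = rank_effects(eff, "higher_better")
        assert ranks.g_rank["PI161375"] == 1
        assert ranks.g_rank["PI414723"] == 2
        assert ranks.g_rank["Vedrantais"] == 8

    def test_lower_better_ranks_most_negative_first(self):
        x = random_cross_matrix(6, 1)
        eff = griffing4_effects(x)
        lo = rank_effects(eff, "lower_better")
        assert lo.g_rank[eff.g.idxmin()] == 1
        hi = rank_effects(eff, "higher_better")
        assert hi.g_rank[eff.g.idxmax()] == 1

    def test_constant_effects_flag_ties(self):
        labels = list("ABCD")
        x = CrossMeansMatrix(pd.DataFrame(5.0, index=labels, columns=labels),
                             method="method2")
        eff = griffing2_effects(x)
        ranks = rank_effects(eff, "higher_better")
        assert ranks.ties
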