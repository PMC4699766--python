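"""Synthetic per-nucleus generator: counts, features, study structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import rifvar as rv
from rifvar.energy import EnergyDistributionSpec
from rifvar.population import DEFAULT_DOSE_GROUPS, PopulationConfig


class TestBackground:
    def test_zero_mean_gives_all_zeros(self):
        assert np.all(rv.simulate_background(100, mean=0.0, var=2.0, seed=0) == 0)

    def test_negative_binomial_moment_matching(self):
        # dispersion r = mean^2/(var-mean) = 0.24 reproduces (0.6, 2.1) exactly
        r = 0.6**2 / (2.1 - 0.6)
        assert r == pytest.approx(0.24)
        p = r / (r + 0.6)
        m, v = sps.nbinom.stats(r, p, moments="mv")
        assert float(m) == pytest.approx(0.6, rel=1e-12)
        assert float(v) == pytest.approx(2.1, rel=1e-12)

    def test_sham_population_statistics(self):
        n = 25114
        x = rv.simulate_background(n, mean=0.6, var=2.1, seed=1)
        r, p = 0.24, 0.24 / (0.24 + 0.6)
        kurt = float(sps.nbinom.stats(r, p, moments="k"))
        se_mean = np.sqrt(2.1 / n)
        se_var = 2.1 * np.sqrt((kurt + 2.0) / n)
        assert x.mean() == pytest.approx(0.6, abs=3 * se_mean)
        assert x.var(ddof=1) == pytest.approx(2.1, abs=3 * se_var)

    def test_poisson_fallback_when_var_not_overdispersed(self):
        x = rv.simulate_background(20000, mean=2.0, var=1.0, seed=2)
        assert x.var(ddof=1) == pytest.approx(2.0, rel=0.05)  # Poisson: var = mean


class TestRifCounts:
    def test_dose_zero_equals_background_draw(self, default_model):
        cfg = PopulationConfig(n_nuclei=500, dose_Gy=0.0)
        a = rv.simulate_rif_counts(cfg, default_model, seed=3)
        b = rv.simulate_background(500, cfg.background_mean, cfg.background_var, seed=3)
        assert np.array_equal(a, b)

    def test_missing_model_rejected_for_positive_dose(self):
        cfg = PopulationConfig(n_nuclei=10, dose_Gy=1.0)
        with pytest.raises(ValueError, match="Model"):
            rv.simulate_rif_counts(cfg, None, seed=0)

    def test_degenerate_generator_is_deterministic(self, default_model):
        # sd_z = 0 and no background: every count is round(foci_per_gray * D)
        cfg = PopulationConfig(
            n_nuclei=200, dose_Gy=1.0, background_mean=0.0, background_var=0.0
        )
        spec = EnergyDistributionSpec(mean_z=1.0, sd_z=0.0)
        x = rv.simulate_rif_counts(cfg, default_model, seed=4, spec=spec)
        assert np.all(x == round(15.5 * 1.0))

    @pytest.mark.parametrize("dose, n", [(0.5, 8242), (1.0, 8993), (2.0, 9010)])
    def test_energy_only_counts_match_propagated_moments(self, default_model, dose, n):
        """Mean ~ alpha*D + bg_mean and var ~ (alpha*sd_z)^2 + 1/12 + bg_var."""
        cfg = PopulationConfig(n_nuclei=n, dose_Gy=dose)
        x = rv.simulate_rif_counts(cfg, default_model, seed=5)
        sd_z = dose * rv.sd_rel(default_model, cfg.target_volume_um3, dose)
        exp_mean = 15.5 * dose + 0.6
        exp_var = (15.5 * sd_z) ** 2 + 1.0 / 12.0 + 2.1
        assert x.mean() == pytest.approx(exp_mean, abs=3 * np.sqrt(exp_var / n))
        assert x.var(ddof=1) == pytest.approx(exp_var, rel=0.07)
        # quasi-Poisson observation: variance/mean close to 1
        assert 0.95 <= x.var(ddof=1) / x.mean() <= 1.25

    def test_count_spread_converges_to_energy_spread_without_background(self, default_model):
        cfg = PopulationConfig(
            n_nuclei=60000, dose_Gy=2.0, background_mean=0.0, background_var=0.0
        )
        x = rv.simulate_rif_counts(cfg, default_model, seed=6)
        target = rv.sd_rel(default_model, 1.6, 2.0)
        assert x.std(ddof=1) / x.mean() == pytest.approx(target, rel=0.03)

    def test_poisson_given_z_adds_counting_noise(self, default_model):
        base = PopulationConfig(n_nuclei=30000, dose_Gy=1.0)
        noisy = PopulationConfig(n_nuclei=30000, dose_Gy=1.0, rif_mode="poisson_given_z")
        v_energy = rv.simulate_rif_counts(base, default_model, seed=7).var(ddof=1)
        v_poisson = rv.simulate_rif_counts(noisy, default_model, seed=7).var(ddof=1)
        # conditional Poisson adds ~ alpha*D to the variance
        assert v_poisson - v_energy == pytest.approx(15.5, rel=0.25)


class TestFeatures:
    def _frame(self, n, cycling_fraction, seed):
        rng = np.random.default_rng(seed)
        phases = rv.assign_phases(n, cycling_fraction, rng)
        counts = rv.simulate_background(n, seed=rng)
        return pd.DataFrame({"phase_true": phases, "rif_count": counts})

    def test_noncycling_population_is_unimodal_and_dim(self):
        df = rv.simulate_features(self._frame(4000, 0.0, 8), seed=8, cluster_fraction=0.0)
        # all 2N: no DAPI value reaches the 4N peak
        assert df["dapi_int"].max() < 2 * df["dapi_int"].median()
        assert df["a488_int"].median() < 200

    def test_cycling_nuclei_have_elevated_h2ax_background(self):
        df = rv.simulate_features(self._frame(6000, 0.2, 9), seed=9)
        g01 = df[df["phase_true"] == "G0G1"]["a488_int"].mean()
        cyc = df[df["phase_true"] != "G0G1"]["a488_int"].mean()
        assert cyc > 2 * g01

    def test_ki67_tracks_h2ax_background(self):
        df = rv.simulate_features(self._frame(6000, 0.2, 10), seed=10)
        rho = sps.spearmanr(df["ki67_int"], df["a488_int"]).statistic
        assert rho > 0.5

    def test_clusters_are_large_and_irregular(self):
        df = rv.simulate_features(self._frame(6000, 0.2, 11), seed=11, cluster_fraction=0.05)
        singlet = df[~df["is_cluster"]]
        cluster = df[df["is_cluster"]]
        assert cluster["area_um2"].min() > singlet["area_um2"].median()
        assert cluster["circularity"].max() < singlet["circularity"].quantile(0.01)


class TestStudy:
    def test_default_design_sizes(self, default_model):
        # pooled sizes of the four dose groups as in the experiments
        assert DEFAULT_DOSE_GROUPS == {
            0.0: (25114, 9),
            0.5: (8242, 3),
            1.0: (8993, 3),
            2.0: (9010, 3),
        }
        groups = {0.0: (900, 3), 1.0: (601, 3)}
        df = rv.simulate_study(dose_groups=groups, seed=12, model=default_model)
        sizes = df.groupby("dose_nominal_Gy").size()
        assert sizes[0.0] == 900 and sizes[1.0] == 601
        assert list(df.columns) == rv.NUCLEUS_COLUMNS

    def test_zero_jitter_gives_nominal_doses(self, default_model):
        cfg = PopulationConfig(n_nuclei=1, dose_Gy=0.0, dose_jitter_rel_sd=0.0)
        df = rv.simulate_study(dose_groups={1.0: (300, 3)}, seed=13, config=cfg)
        assert np.all(df["dose_actual_Gy"] == df["dose_nominal_Gy"])

    def test_replicate_mean_spread_under_dose_jitter(self, default_model):
        # 6% dose jitter at 1 Gy: replicate means spread by roughly
        # 15.5 * 1 * 0.06 ~ 0.9 foci (chi-distributed; wide band)
        df = rv.simulate_study(dose_groups={1.0: (6000, 12)}, seed=14)
        sd = df.groupby("replicate_id")["rif_count"].mean().std(ddof=1)
        assert 0.4 < sd < 1.8
        df0 = rv.simulate_study(
            dose_groups={1.0: (6000, 12)},
            seed=14,
            config=PopulationConfig(n_nuclei=1, dose_Gy=0.0, dose_jitter_rel_sd=0.0),
        )
        sd0 = df0.groupby("replicate_id")["rif_count"].mean().std(ddof=1)
        assert sd0 < 0.3

    def test_fixed_seed_is_bit_identical(self):
        groups = {0.0: (400, 2), 2.0: (400, 2)}
        a = rv.simulate_study(dose_groups=groups, seed=15)
        b = rv.simulate_study(dose_groups=groups, seed=15)
        pd.testing.assert_frame_equal(a, b)
        c = rv.simulate_study(dose_groups=groups, seed=16)
        assert not a["rif_count"].equals(c["rif_count"])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PopulationConfig(n_nuclei=0, dose_Gy=1.0)
        with pytest.raises(ValueError):
            PopulationConfig(n_nuclei=10, dose_Gy=-1.0)
        with pytest.raises(ValueError):
            PopulationConfig(n_nuclei=10, dose_Gy=1.0, rif_mode="bogus")
        with pytest.raises(ValueError):
            PopulationConfig(n_nuclei=10, dose_Gy=1.0, cycling_fraction=1.0)
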