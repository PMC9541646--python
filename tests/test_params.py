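import numpy as np
import pytest

from dynsad import (
    PopulationParams,
    VarianceComponents,
    from_population_params,
    linear_predictor_covariance,
    log_abundance_covariance,
    similarity_mean,
    similarity_relative,
    stationary_relative_variance,
    to_population_params,
    variance_proportions,
)


def vc(**kw):
    base = dict(beta0=1.0, sigma2_h=0.5, sigma2_e=0.3, sigma2_c=0.1, gamma=0.5)
    base.update(kw)
    return VarianceComponents(**base)


class TestLinearPredictorCovariance:
    def test_lag_zero_same_replicate_sums_all_components(self):
        v = vc(sigma2_o=0.1)
        assert linear_predictor_covariance(v, 0, True, True) == pytest.approx(1.0)

    def test_different_species_share_only_common_environment(self):
        assert linear_predictor_covariance(vc(), 0, same_species=False) == pytest.approx(0.1)

    def test_long_lag_leaves_only_heterogeneity(self):
        assert linear_predictor_covariance(vc(), 1e6, True) == pytest.approx(0.5)

    def test_common_term_uses_its_own_rate(self):
        v = vc(gamma_c=0.1)
        got = linear_predictor_covariance(v, 2.0, True)
        assert got == pytest.approx(0.5 + 0.3 * np.exp(-1.0) + 0.1 * np.exp(-0.2))


class TestPopulationScale:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (dict(gamma=0.1, sigma2_s=0.16, sigma2_r=0.002), 1.0),
            (dict(gamma=0.5, sigma2_s=0.2, sigma2_r=0.05), 0.4),
            (dict(gamma=0.3, sigma2_s=0.0, sigma2_r=0.0), 0.0),
        ],
    )
    def test_stationary_relative_variance(self, p, expected):
        pp = PopulationParams(
            mean_growth=p["gamma"], sigma2_E=0.0, logK=1.0, nu=1.0, **p
        )
        assert stationary_relative_variance(pp) == pytest.approx(expected)

    def test_transform_values(self):
        v = vc(gamma=0.1, sigma2_h=0.2, sigma2_e=0.8)
        pp = to_population_params(v, nu=1.0)
        assert pp.sigma2_r == pytest.approx(0.002)
        assert pp.sigma2_s == pytest.approx(0.16)

    def test_round_trip_is_identity(self):
        v = vc(sigma2_o=0.05, sigma2_u=0.02, gamma_c=0.2, beta0=3.0)
        pp = to_population_params(v, nu=0.25)
        back = from_population_params(pp, sigma2_o=0.05, sigma2_u=0.02)
        for f in ("beta0", "sigma2_h", "sigma2_e", "sigma2_c", "gamma"):
            assert getattr(back, f) == pytest.approx(getattr(v, f), abs=1e-12)

    def test_logk_consistency_enforced(self):
        with pytest.raises(ValueError):
            PopulationParams(
                mean_growth=1.0, sigma2_r=0, sigma2_s=0, sigma2_E=0,
                gamma=0.1, logK=5.0,
            )

    def test_covariance_matches_linear_predictor_under_mapping(self):
        # same-species GLMM covariance reproduces the process covariance
        pp = PopulationParams(
            mean_growth=1.0, sigma2_r=0.002, sigma2_s=0.16, sigma2_E=0.02,
            gamma=0.1, logK=10.0,
        )
        v = from_population_params(pp)
        for u in (0.0, 1.0, 5.0):
            assert log_abundance_covariance(pp, u) == pytest.approx(
                linear_predictor_covariance(v, u, same_species=True), abs=1e-14
            )

    def test_relative_variance_conserved_across_scales(self):
        pp = PopulationParams(
            mean_growth=0.5, sigma2_r=0.01, sigma2_s=0.2, sigma2_E=0.06,
            gamma=0.25, logK=2.0,
        )
        v = from_population_params(pp)
        same_species_var = linear_predictor_covariance(v, 0, True, True)
        assert stationary_relative_variance(pp) == pytest.approx(
            same_species_var - v.sigma2_c - v.sigma2_o
        )


class TestVarianceProportions:
    def test_normalization(self):
        for scale in (1.0, 10.0):
            props = variance_proportions(
                vc(sigma2_h=0.64 * scale, sigma2_e=0.36 * scale, sigma2_c=3 * scale,
                   sigma2_u=1 * scale)
            )
            ss = props["species_specific"]
            assert ss["sigma2_h"] == pytest.approx(0.64)
            assert ss["sigma2_e"] == pytest.approx(0.36)
            assert sum(ss.values()) == pytest.approx(1.0, abs=1e-12)
            assert props["general"]["sigma2_c"] == pytest.approx(0.75)
            assert props["general"]["sigma2_u"] == pytest.approx(0.25)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            variance_proportions(vc(sigma2_h=0, sigma2_e=0, sigma2_o=0))


class TestSimilarity:
    def test_lag_zero_without_observation_noise_is_one(self):
        assert similarity_relative(vc(), 0.0) == pytest.approx(1.0)

    def test_limit_is_heterogeneity_share(self):
        assert similarity_relative(vc(), 1e9) == pytest.approx(0.5 / 0.8)

    def test_fish_like_value_at_return_time(self):
        # at u = 1/gamma the environmental part has decayed by e^{-1}
        v = vc(sigma2_h=0.64, sigma2_e=0.36, sigma2_c=0.1, gamma=0.17)
        got = similarity_relative(v, 1 / 0.17)
        assert got == pytest.approx((0.36 * np.exp(-1) + 0.64) / 1.0, abs=1e-10)
        assert got == pytest.approx(0.7724, abs=5e-4)

    def test_mean_similarity_values(self):
        assert similarity_mean(vc(sigma2_u=0.0), 0.0) == pytest.approx(1.0)
        assert similarity_mean(vc(sigma2_u=0.1), 0.0) == pytest.approx(0.5)
        v = vc(gamma_c=0.25)
        assert similarity_mean(v, 4.0) == pytest.approx(np.exp(-1.0))

    def test_monotone_nonincreasing_and_bounded(self):
        v = vc(sigma2_o=0.2, gamma_c=0.3)
        u = np.linspace(0, 50, 200)
        for fn in (similarity_relative, similarity_mean):
            vals = fn(v, u)
            assert np.all(np.diff(vals) <= 1e-15)
            assert np.all(vals > 0) and np.all(vals <= 1.0)

    def test_observation_noise_dilutes_lag_zero_correlation(self):
        assert similarity_relative(vc(sigma2_o=0.2), 0.0) < 1.0


class TestSerialization:
    def test_yaml_json_round_trip(self, tmp_path):
        v = vc(gamma_c=0.2, sigma2_o=0.01, beta0=-1.5)
        for name in ("p.yaml", "p.json"):
            path = tmp_path / name
            v.save(path)
            assert VarianceComponents.load(path) == v

    def test_spatial_uses_alpha_keys(self, tmp_path):
        v = VarianceComponents(
            beta0=0.0, sigma2_h=1.0, sigma2_e=0.5, sigma2_c=0.1,
            gamma=0.12, dimension="spatial",
        )
        d = v.to_dict()
        assert d["alpha"] == pytest.approx(0.12)
        assert "gamma" not in d
        assert VarianceComponents.from_dict(d) == v
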