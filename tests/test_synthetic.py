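import numpy as np
import pytest

from conftest import small_config, uniform_turnover, zero_drift
from warmsoil.community import bray_curtis_similarity
from warmsoil.datamodel import ConfigurationError
from warmsoil.synthetic import (
    GeneratorConfig,
    generate_communities,
    generate_design,
    generate_experiment,
    generate_measurements,
    injected_cue_d,
    latent_trajectories,
    sample_id_for,
)

YEARS = (2010, 2012, 2014, 2016, 2018, 2020)


class TestConfig:
    def test_rho_bounds_enforced(self):
        with pytest.raises(ConfigurationError, match="turnover"):
            GeneratorConfig(turnover=uniform_turnover(1.0))

    def test_sequencing_blocks_bound(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(sequencing_blocks=5, n_blocks=4)

    def test_depth_validated(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(depth=0)

    def test_from_dict_nested_override(self):
        cfg = GeneratorConfig.from_dict(
            {"seed": 3, "soc_params": {"onset_year": 2014}, "noise": {"soc": 0.2}}
        )
        assert cfg.soc_params.onset_year == 2014
        assert cfg.noise.soc == 0.2
        assert cfg.soc_params.block_sd == GeneratorConfig().soc_params.block_sd

    def test_from_dict_unknown_field(self):
        with pytest.raises(ConfigurationError, match="unknown"):
            GeneratorConfig.from_dict({"bogus": 1})


class TestFactorialArithmetic:
    def test_design_and_sequenced_counts(self):
        exp = generate_experiment(small_config(seed=1))
        assert len(exp.design.samples) == 96  # 2 x 2 x 4 x 6
        for domain in ("bacteria", "fungi"):
            assert len(exp.tables[domain].sample_ids) == 72  # 3 blocks sequenced
        assert len(exp.incubations) == 96
        assert len(exp.amino_profiles) == 96

    def test_determinism(self):
        a = generate_experiment(small_config(seed=7))
        b = generate_experiment(small_config(seed=7))
        assert np.array_equal(a.tables["fungi"].counts, b.tables["fungi"].counts)
        assert a.truth.growth == b.truth.growth
        assert a.measurements == b.measurements
        assert a.incubations[0].dna_atpct_labeled == b.incubations[0].dna_atpct_labeled

    def test_different_seeds_differ(self):
        a = generate_experiment(small_config(seed=7))
        b = generate_experiment(small_config(seed=8))
        assert not np.array_equal(a.tables["fungi"].counts, b.tables["fungi"].counts)


class TestCommunityModel:
    def test_closed_form_geometric_replacement(self):
        # with disjoint replacement, shared mass after k steps is (1-rho)^k
        config = GeneratorConfig(
            seed=5,
            n_taxa=120,
            turnover=uniform_turnover(0.5),
            divergence_drift=zero_drift(),
            sequencing_blocks=1,
        )
        design = generate_design(config)
        table = generate_communities(
            config, design, "fungi", infinite_depth=True, disjoint_replacement=True
        )
        sim = bray_curtis_similarity(table)
        t0 = sample_id_for("conservation", "ambient", 1, 2010)
        t2 = sample_id_for("conservation", "ambient", 1, 2012)
        t4 = sample_id_for("conservation", "ambient", 1, 2014)
        assert sim.between(t0, t2) == pytest.approx(0.5, abs=1e-12)
        assert sim.between(t0, t4) == pytest.approx(0.25, abs=1e-12)

    def test_rho_zero_identity(self):
        config = GeneratorConfig(
            seed=5,
            n_taxa=120,
            turnover=uniform_turnover(0.0),
            divergence_drift=zero_drift(),
            sequencing_blocks=1,
        )
        design = generate_design(config)
        table = generate_communities(config, design, "fungi", infinite_depth=True)
        sim = bray_curtis_similarity(table)
        t0 = sample_id_for("conservation", "ambient", 1, 2010)
        for year in YEARS[1:]:
            t = sample_id_for("conservation", "ambient", 1, year)
            assert sim.between(t0, t) == pytest.approx(1.0, abs=1e-12)

    def test_higher_rho_lower_similarity_at_every_lag(self):
        def mean_sim_by_lag(rho, seed):
            config = GeneratorConfig(
                seed=seed,
                n_taxa=80,
                depth=2000,
                pool_concentration=1.0,
                turnover=uniform_turnover(rho),
                divergence_drift=zero_drift(),
            )
            design = generate_design(config)
            table = generate_communities(config, design, "fungi")
            sim = bray_curtis_similarity(table)
            from warmsoil.community import make_tdr_pairs

            pairs = make_tdr_pairs(sim, design)
            by_lag = {}
            for p in pairs:
                by_lag.setdefault(p.lag_years, []).append(p.similarity)
            return {lag: np.mean(v) for lag, v in by_lag.items()}

        wins = 0
        reps = 20
        for seed in range(reps):
            low = mean_sim_by_lag(0.1, seed)
            high = mean_sim_by_lag(0.5, seed)
            if all(high[lag] < low[lag] for lag in low):
                wins += 1
        assert wins >= 18

    def test_mean_similarity_nonincreasing_in_lag(self):
        config = small_config(seed=2, pool_concentration=1.0)
        design = generate_design(config)
        table = generate_communities(config, design, "fungi")
        sim = bray_curtis_similarity(table)
        from warmsoil.community import make_tdr_pairs

        pairs = make_tdr_pairs(
            sim, design, management="conservation", warming="ambient"
        )
        by_lag = {}
        for p in pairs:
            by_lag.setdefault(p.lag_years, []).append(p.similarity)
        means = [np.mean(by_lag[lag]) for lag in sorted(by_lag)]
        # allow tiny noise wiggle at long lags
        assert all(b <= a + 0.02 for a, b in zip(means, means[1:]))

    def test_infinite_depth_columns_sum_to_one(self):
        config = small_config(seed=2)
        design = generate_design(config)
        table = generate_communities(config, design, "fungi", infinite_depth=True)
        assert np.allclose(table.column_sums(), 1.0)

    def test_counts_sum_to_depth(self):
        config = small_config(seed=2)
        design = generate_design(config)
        table = generate_communities(config, design, "fungi")
        assert np.all(table.column_sums() == config.depth)


class TestMeasurements:
    def test_soc_multiplier_exact_at_zero_noise(self):
        config = GeneratorConfig(seed=3, noise_scale=0.0)
        design = generate_design(config)
        meas, _ = generate_measurements(config, design)
        final = config.years[-1]

        def group_mean(w):
            ids = [s.sample_id for s in design.subset(
                management="conservation", warming=w, year=final)]
            return meas.data.loc[ids, "soc"].mean()

        warmed, ambient = group_mean("warmed"), group_mean("ambient")
        assert (warmed - ambient) / ambient == pytest.approx(0.031, rel=1e-12)

    def test_conventional_null_arm(self):
        config = GeneratorConfig(seed=3, noise_scale=0.0)
        design = generate_design(config)
        meas, _ = generate_measurements(config, design)
        final = config.years[-1]
        for year in config.years:
            warmed = [s.sample_id for s in design.subset(
                management="conventional", warming="warmed", year=year)]
            ambient = [s.sample_id for s in design.subset(
                management="conventional", warming="ambient", year=year)]
            diff = meas.data.loc[warmed, "soc"].mean() - meas.data.loc[
                ambient, "soc"].mean()
            assert diff == pytest.approx(0.0, abs=1e-12)

    def test_no_warming_effect_before_onset(self):
        config = GeneratorConfig(seed=3, noise_scale=0.0)
        design = generate_design(config)
        meas, _ = generate_measurements(config, design)
        warmed = [s.sample_id for s in design.subset(
            management="conservation", warming="warmed", year=2014)]
        ambient = [s.sample_id for s in design.subset(
            management="conservation", warming="ambient", year=2014)]
        assert meas.data.loc[warmed, "soc"].mean() == pytest.approx(
            meas.data.loc[ambient, "soc"].mean(), abs=1e-12
        )


class TestInjectedCueTrajectory:
    def test_crosses_zero_near_year_five(self):
        config = GeneratorConfig(seed=0)
        d = {y: injected_cue_d(config, "conservation", y) for y in config.years}
        assert d[2010] < 0 < d[2020]
        assert d[2014] < 0 < d[2016]  # crossing at year 5 (2015)

    def test_ordering_recovered_at_zero_noise(self):
        from warmsoil.physiology import cue_from_incubation

        config = GeneratorConfig(seed=6, n_taxa=10, depth=100, noise_scale=0.0)
        exp = generate_experiment(config)

        def mean_cue(w, year):
            ids = [s.sample_id for s in exp.design.subset(
                management="conservation", warming=w, year=year)]
            cues = [cue_from_incubation(i).cue for i in exp.incubations
                    if i.sample_id in ids]
            return np.mean(cues)

        assert mean_cue("warmed", 2010) < mean_cue("ambient", 2010)
        assert mean_cue("warmed", 2020) > mean_cue("ambient", 2020)
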