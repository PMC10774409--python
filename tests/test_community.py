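import itertools
import math

import numpy as np
import pytest

from conftest import single_treatment_design, small_config, uniform_turnover, zero_drift
from warmsoil.community import (
    SimilarityMatrix,
    TdrPair,
    bray_curtis_similarity,
    divergence_series,
    lineage_tdr,
    lineage_tdr_relative_change,
    make_tdr_pairs,
    rarefy,
    tdr_fit,
    tdr_fit_from_pairs,
    tdr_slope_compare,
)
from warmsoil.datamodel import (
    FeatureTable,
    SampleMetadata,
    StudyDesign,
    ValidationError,
    plot_id_for,
)
from warmsoil.synthetic import (
    GeneratorConfig,
    generate_communities,
    generate_design,
    generate_taxonomy,
)

YEARS = (2010, 2012, 2014, 2016, 2018, 2020)


def sim_from_function(design: StudyDesign, func) -> SimilarityMatrix:
    ids = design.sample_ids
    n = len(ids)
    values = np.ones((n, n))
    meta = {s.sample_id: s for s in design.samples}
    for i, j in itertools.combinations(range(n), 2):
        v = func(meta[ids[i]], meta[ids[j]])
        values[i, j] = values[j, i] = v
    return SimilarityMatrix(ids, values)


class TestRarefy:
    def make_table(self, rng, totals, n_taxa=50):
        cols = [rng.multinomial(t, np.full(n_taxa, 1 / n_taxa)) for t in totals]
        return FeatureTable(
            [f"t{i}" for i in range(n_taxa)],
            [f"s{i}" for i in range(len(totals))],
            np.column_stack(cols),
        )

    def test_column_sums_equal_depth(self, rng):
        table = self.make_table(rng, [30000, 28000])
        out = rarefy(table, 24579, seed=1)
        assert list(out.column_sums()) == [24579, 24579]

    def test_depth_equal_to_total_identity(self, rng):
        table = self.make_table(rng, [5000])
        out = rarefy(table, 5000, seed=1)
        assert np.array_equal(out.counts, table.counts)

    def test_shallow_sample_dropped_with_log(self, rng, caplog):
        import logging

        table = self.make_table(rng, [30000, 10000])
        with caplog.at_level(logging.WARNING):
            out = rarefy(table, 21550, seed=1)
        assert out.sample_ids == ["s0"]
        assert "s1" in caplog.text

    def test_all_below_depth_errors(self, rng):
        table = self.make_table(rng, [100, 200])
        with pytest.raises(ValidationError, match="below rarefaction depth"):
            rarefy(table, 1000, seed=1)

    def test_subsample_without_replacement(self, rng):
        table = self.make_table(rng, [1000])
        out = rarefy(table, 900, seed=3)
        assert np.all(out.counts <= table.counts)


class TestBrayCurtis:
    def test_identical_samples(self):
        t = FeatureTable(["a", "b"], ["x", "y"], np.array([[2, 2], [1, 1]]))
        sim = bray_curtis_similarity(t)
        assert sim.between("x", "y") == pytest.approx(1.0)

    def test_disjoint_supports(self):
        t = FeatureTable(["a", "b"], ["x", "y"], np.array([[5, 0], [0, 7]]))
        assert bray_curtis_similarity(t).between("x", "y") == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        t = FeatureTable(["a", "b"], ["x", "y"], np.array([[2, 1], [1, 3]]))
        assert bray_curtis_similarity(t).between("x", "y") == pytest.approx(
            4.0 / 7.0, rel=1e-12
        )

    def test_zero_sum_sample_named(self):
        t = FeatureTable(["a"], ["x", "bad"], np.array([[2, 0]]))
        with pytest.raises(ValidationError, match="bad"):
            bray_curtis_similarity(t)


class TestTdrPairing:
    def test_single_plot_census(self):
        design = single_treatment_design(blocks=(1,))
        sim = sim_from_function(design, lambda a, b: 0.5)
        pairs = make_tdr_pairs(sim, design)
        assert len(pairs) == 15
        from collections import Counter

        census = Counter(p.lag_years for p in pairs)
        assert census == {2: 5, 4: 4, 6: 3, 8: 2, 10: 1}

    def test_three_plot_treatment_census(self):
        design = single_treatment_design(blocks=(1, 2, 3))
        sim = sim_from_function(design, lambda a, b: 0.5)
        res = tdr_fit(sim, design, management="conservation", warming="ambient")
        assert res.n_pairs == 45
        assert res.pairs_per_interval == {2: 15, 4: 12, 6: 9, 8: 6, 10: 3}
        assert res.n_pairs == sum(res.pairs_per_interval.values())

    def test_pairs_only_within_plot(self):
        design = single_treatment_design(blocks=(1, 2))
        sim = sim_from_function(design, lambda a, b: 0.5)
        pairs = make_tdr_pairs(sim, design)
        assert all(p.plot_id in {plot_id_for("conservation", "ambient", 1),
                                 plot_id_for("conservation", "ambient", 2)}
                   for p in pairs)
        assert len(pairs) == 30  # no cross-plot pairs


class TestTdrFit:
    def test_exact_power_law(self):
        design = single_treatment_design(blocks=(1,))
        sim = sim_from_function(
            design, lambda a, b: 0.5 * abs(a.year - b.year) ** -0.5
        )
        res = tdr_fit(sim, design)
        assert res.slope_w == pytest.approx(-0.5, abs=1e-12)
        assert res.turnover_v == pytest.approx(0.5, abs=1e-12)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.r2_adjusted == pytest.approx(1.0, abs=1e-12)
        assert res.turnover_v == -res.slope_w  # exact identity

    def test_slope_invariant_to_log_base(self):
        # fitting ln-ln instead of log10-log10 gives the same slope
        design = single_treatment_design(blocks=(1, 2))
        rng = np.random.default_rng(0)
        sim = sim_from_function(
            design,
            lambda a, b: 0.5 if a.year == b.year
            else 0.8 * abs(a.year - b.year) ** -0.3
            * math.exp(0.05 * rng.standard_normal()),
        )
        res = tdr_fit(sim, design)
        x = np.log([p.lag_years for p in res.pairs])
        y = np.log([p.similarity for p in res.pairs])
        ln_slope = np.polyfit(x, y, 1)[0]
        assert res.slope_w == pytest.approx(ln_slope, rel=1e-10)

    def test_brute_force_oracle(self):
        config = small_config(seed=8)
        design = generate_design(config)
        table = generate_communities(config, design, "fungi")
        sim = bray_curtis_similarity(table)
        res = tdr_fit(sim, design, management="conservation", warming="warmed")

        # independent recomputation: explicit double loop + closed-form OLS
        meta = {s.sample_id: s for s in design.samples}
        xs, ys = [], []
        ids = [
            s.sample_id
            for s in design.samples
            if s.management == "conservation"
            and s.warming == "warmed"
            and s.sample_id in set(sim.sample_ids)
        ]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = meta[ids[i]], meta[ids[j]]
                if a.plot_id != b.plot_id or a.year == b.year:
                    continue
                s = sim.between(a.sample_id, b.sample_id)
                if s <= 0:
                    continue
                xs.append(math.log10(abs(a.year - b.year)))
                ys.append(math.log10(s))
        xs, ys = np.array(xs), np.array(ys)
        slope = ((xs - xs.mean()) * (ys - ys.mean())).sum() / (
            (xs - xs.mean()) ** 2
        ).sum()
        assert len(xs) == res.n_pairs - res.n_zero_dropped
        assert res.slope_w == pytest.approx(slope, abs=1e-10)

    def test_fewer_than_two_lags_errors(self):
        design = single_treatment_design(years=(2010, 2012), blocks=(1,))
        sim = sim_from_function(design, lambda a, b: 0.5)
        with pytest.raises(ValidationError, match="2 distinct time lags"):
            tdr_fit(sim, design)

    def test_zero_similarity_pairs_dropped_and_counted(self):
        design = single_treatment_design(blocks=(1,))
        sim = sim_from_function(
            design, lambda a, b: 0.0 if abs(a.year - b.year) == 10 else 0.5
        )
        res = tdr_fit(sim, design)
        assert res.n_zero_dropped == 1
        assert res.n_pairs == 15

    def test_all_zero_similarity_errors(self):
        design = single_treatment_design(blocks=(1,))
        sim = sim_from_function(design, lambda a, b: 0.0)
        with pytest.raises(ValidationError, match="zero similarity"):
            tdr_fit(sim, design)


def synthetic_pairs(rng, plot, slope, noise=0.05, intercept=-0.1):
    lags = [2] * 5 + [4] * 4 + [6] * 3 + [8] * 2 + [10]
    return [
        TdrPair(
            plot_id=plot,
            lag_years=lag,
            similarity=10
            ** (intercept + slope * math.log10(lag) + noise * rng.standard_normal()),
        )
        for lag in lags
    ]


class TestSlopeCompare:
    def test_saturated_on_separable_data(self, rng):
        # enough plots that a resampled permutation practically never
        # reproduces the observed assignment
        a = [p for i in range(10) for p in synthetic_pairs(rng, f"a{i}", -0.2, 0.01)]
        b = [p for i in range(10) for p in synthetic_pairs(rng, f"b{i}", -0.9, 0.01)]
        ra, rb = tdr_fit_from_pairs(a), tdr_fit_from_pairs(b)
        p = tdr_slope_compare(ra, rb, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_null_calibration_median_large(self, rng):
        ps = []
        for seed in range(50):
            plots = [synthetic_pairs(rng, f"p{i}", -0.4) for i in range(8)]
            order = rng.permutation(8)
            a = [p for i in order[:4] for p in plots[i]]
            b = [p for i in order[4:] for p in plots[i]]
            ps.append(
                tdr_slope_compare(
                    tdr_fit_from_pairs(a), tdr_fit_from_pairs(b), 99, seed=seed
                )
            )
        assert np.median(ps) > 0.3

    def test_nperm_zero_errors(self, rng):
        a = tdr_fit_from_pairs(synthetic_pairs(rng, "a", -0.2))
        b = tdr_fit_from_pairs(synthetic_pairs(rng, "b", -0.9))
        with pytest.raises(ValidationError):
            tdr_slope_compare(a, b, n_perm=0, seed=0)


class TestLineageTdr:
    def test_whole_domain_equals_overall_fit(self):
        config = small_config(seed=5)
        design = generate_design(config)
        table = generate_communities(config, design, "bacteria")
        taxonomy = generate_taxonomy(config, "bacteria")
        overall = tdr_fit(
            bray_curtis_similarity(table.relative_abundance()),
            design,
            management="conservation",
            warming="ambient",
        )
        lin = lineage_tdr(
            table, taxonomy, "domain", "Bacteria", design,
            management="conservation", warming="ambient",
        )
        assert lin.slope_w == pytest.approx(overall.slope_w, rel=1e-10)
        assert lin.n_pairs == overall.n_pairs

    def test_single_taxon_lineage_degenerate(self):
        design = single_treatment_design(blocks=(1,))
        n = len(design.samples)
        counts = np.vstack([np.full(n, 10), np.arange(1, n + 1)])
        table = FeatureTable(["t0", "t1"], design.sample_ids, counts)
        from warmsoil.datamodel import Lineage, TaxonomyMap

        taxonomy = TaxonomyMap(
            {"t0": Lineage("Bacteria", "Solo"), "t1": Lineage("Bacteria", "Other")}
        )
        # a one-taxon lineage renormalizes to similarity 1 everywhere:
        # log(1)=0 for all pairs, zero-variance fit error surfaces
        with pytest.raises(ValidationError):
            lineage_tdr(table, taxonomy, "phylum", "Solo", design)

    def test_empty_lineage_named(self):
        config = small_config(seed=5)
        design = generate_design(config)
        table = generate_communities(config, design, "bacteria")
        taxonomy = generate_taxonomy(config, "bacteria")
        with pytest.raises(ValidationError, match="Missing"):
            lineage_tdr(table, taxonomy, "phylum", "Missing", design)

    def test_lineage_turnover_ordering(self):
        # two phyla evolving with rho 0.2 and 0.6: fitted v must order the same
        wins = 0
        reps = 10
        for seed in range(reps):
            config = GeneratorConfig(
                seed=seed,
                n_taxa=80,
                depth=4000,
                n_phyla=2,
                pool_concentration=1.0,
                lineage_turnover={"Phylum1": 0.2, "Phylum2": 0.6},
                divergence_drift=zero_drift(),
            )
            design = generate_design(config)
            table = generate_communities(config, design, "bacteria")
            taxonomy = generate_taxonomy(config, "bacteria")
            vs = {}
            for phylum in ("Phylum1", "Phylum2"):
                res = lineage_tdr(
                    table, taxonomy, "phylum", phylum, design,
                    management="conservation", warming="ambient",
                )
                vs[phylum] = res.turnover_v
            if vs["Phylum2"] > vs["Phylum1"]:
                wins += 1
        assert wins >= 9


class TestRelativeChange:
    def test_identity(self):
        assert lineage_tdr_relative_change(0.6, 0.6) == 0.0

    def test_arithmetic(self):
        assert lineage_tdr_relative_change(0.9, 0.6) == pytest.approx(0.5, rel=1e-12)
        assert lineage_tdr_relative_change(0.3, 0.6) == pytest.approx(-0.5, rel=1e-12)

    def test_zero_control_errors(self):
        with pytest.raises(ValidationError):
            lineage_tdr_relative_change(0.5, 0.0)


def paired_design(blocks=(1, 2, 3), years=YEARS, management="conservation"):
    samples = []
    for w in ("ambient", "warmed"):
        for b in blocks:
            for y in years:
                samples.append(
                    SampleMetadata(
                        sample_id=f"{management}-{w}-b{b}-y{y}",
                        plot_id=plot_id_for(management, w, b),
                        block=b,
                        management=management,
                        warming=w,
                        year=y,
                    )
                )
    return StudyDesign(samples=samples)


class TestDivergence:
    def test_constant_dissimilarity_flat_trend(self):
        design = paired_design()
        sim = sim_from_function(design, lambda a, b: 0.7)
        series = divergence_series(sim, design, management="conservation")
        assert series.trend_slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_line(self):
        design = paired_design()

        def func(a, b):
            if a.block == b.block and a.year == b.year and a.warming != b.warming:
                return 1.0 - 0.01 * (a.year - 2010)
            return 0.5

        sim = sim_from_function(design, func)
        series = divergence_series(sim, design, management="conservation")
        assert series.trend_slope == pytest.approx(0.01, abs=1e-12)
        assert series.trend_fit.r2 == pytest.approx(1.0, abs=1e-12)
        # one value per (block, year)
        assert all(len(v) == 3 for v in series.values.values())

    def test_missing_pair_member_skipped(self):
        design = paired_design()
        keep = [s for s in design.samples if not (s.block == 2 and s.year == 2014
                                                  and s.warming == "warmed")]
        sub_design = StudyDesign(samples=keep)
        sim = sim_from_function(sub_design, lambda a, b: 0.7)
        series = divergence_series(sim, sub_design, management="conservation")
        assert 2 not in series.values[2014]
        assert len(series.values[2014]) == 2

    def test_too_few_years_no_trend(self):
        design = paired_design(years=(2010, 2012))
        sim = sim_from_function(design, lambda a, b: 0.7)
        series = divergence_series(sim, design, management="conservation")
        assert math.isnan(series.trend_slope)
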