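import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from agstocks.synthetic import (
    LulcStandSpec,
    StandGenSpec,
    SpeciesTraitGen,
    TraitGenSpec,
    calibrate_registry,
    default_stand_spec,
    default_trait_spec,
    generate_area_table,
    generate_class_map,
    generate_inventory,
    generate_trait_samples,
)


class TestTraitSamples:
    def test_default_draw_is_277_samples_18_species(self):
        df = generate_trait_samples(seed=3)
        assert len(df) == 277
        assert df["species"].nunique() == 18

    def test_determinism(self):
        a = generate_trait_samples(seed=11)
        b = generate_trait_samples(seed=11)
        pd.testing.assert_frame_equal(a, b)
        c = generate_trait_samples(seed=12)
        assert not a["carbon_fraction"].equals(c["carbon_fraction"])

    def test_truncation_respected(self):
        spec = default_trait_spec()
        df = generate_trait_samples(spec, seed=5)
        for e in spec.entries:
            sub = df[df["species"] == e.species]
            assert sub["carbon_fraction"].between(e.c_min, e.c_max).all()
            assert sub["nitrogen_fraction"].between(e.n_min, e.n_max).all()

    def test_replicate_means_recover_generating_truth(self):
        """Grand mean over 200 replicates ≈ the truncated-normal mean.

        The generating truth per species is the truncated-normal expectation
        (not the nominal location, which truncation can shift); the check is
        at 4 standard errors of the 200-replicate grand mean.
        """
        spec = default_trait_spec()
        sums = {e.species: 0.0 for e in spec.entries}
        reps = 200
        for r in range(reps):
            df = generate_trait_samples(spec, seed=10_000 + r)
            g = df.groupby("species")["carbon_fraction"].mean()
            for sp, v in g.items():
                sums[sp] += v
        for e in spec.entries:
            a, b = (e.c_min - e.c_mean) / e.c_sd, (e.c_max - e.c_mean) / e.c_sd
            truth = stats.truncnorm.mean(a, b, loc=e.c_mean, scale=e.c_sd)
            sd = stats.truncnorm.std(a, b, loc=e.c_mean, scale=e.c_sd)
            tol = 4 * sd / math.sqrt(e.n * reps)
            assert abs(sums[e.species] / reps - truth) <= tol, e.species

    def test_infeasible_truncation_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            SpeciesTraitGen("X y", 5, 0.47, 0.01, 0.5, 0.5, 0.002, 0.001, 0.001, 0.003)


class TestInventory:
    def test_default_design_is_250_plots(self, study):
        assert len(study.plots) == 250
        areas = study.plots["width_m"] * study.plots["length_m"] / 1e4
        assert areas.sum() == pytest.approx(27.26)
        counts = study.plots.groupby("lulc").size()
        assert counts["Cropland and Fallow"] == 80
        assert counts["Settlements"] == 8

    def test_determinism(self):
        p1, c1 = generate_inventory(seed=9)
        p2, c2 = generate_inventory(seed=9)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(c1, c2)

    def test_zero_stem_rate_yields_treeless_plots(self):
        spec = StandGenSpec(classes=(LulcStandSpec(
            lulc="Savannah grassland", category="Grassland", n_plots=10,
            plot_width_m=30, plot_length_m=30, stems_per_ha=0.0,
            species_mix={"Vitelaria paradoxa": 1.0},
            dbh_median_cm=20, dbh_log_sd=0.4, dbh_max_cm=60,
        ),))
        plots, census = generate_inventory(spec, seed=1)
        assert len(plots) == 10
        assert census.empty

    def test_census_respects_dbh_threshold_and_bounds(self, study):
        assert study.census["dbh_cm"].min() >= 5.0
        assert (study.census["height_m"] > 0).all()
        assert study.census["wood_density_g_cm3"].between(0.1, 1.5).all()

    def test_unknown_species_in_mix_rejected(self, ref_traits):
        spec = StandGenSpec(classes=(LulcStandSpec(
            lulc="W", category="W", n_plots=2, plot_width_m=30, plot_length_m=30,
            stems_per_ha=100, species_mix={"Martian tree": 1.0},
            dbh_median_cm=10, dbh_log_sd=0.4, dbh_max_cm=40,
        ),))
        with pytest.raises(ValueError, match="not in the traits table"):
            generate_inventory(spec, seed=0, traits=ref_traits)

    def test_mix_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to"):
            LulcStandSpec(
                lulc="W", category="W", n_plots=1, plot_width_m=30, plot_length_m=30,
                stems_per_ha=10, species_mix={"Ficus sp": 0.6},
                dbh_median_cm=10, dbh_log_sd=0.4, dbh_max_cm=40,
            )


class TestCalibration:
    def test_expected_density_matches_target(self, ref_traits):
        """Large-sample pipeline density per class ≈ the calibration target.

        One big draw (plot count × 20) pins the Monte-Carlo expectation; the
        estimate must sit within 3 of its own standard errors of the target.
        """
        from agstocks.accounting import compute_tree_stocks, lulc_density, plot_stocks
        spec = default_stand_spec()
        sub = StandGenSpec(classes=tuple(
            c.__class__(**{**c.__dict__, "n_plots": c.n_plots * 20})
            for c in spec.classes if c.lulc in ("Cropland and Fallow", "Shrub Savannah")
        ))
        reg = calibrate_registry(sub, ref_traits)
        plots, census = generate_inventory(sub, seed=77, traits=ref_traits)
        stocks = compute_tree_stocks(census, plots, reg, ref_traits)
        pp = plot_stocks(stocks, plots)
        for c in sub.classes:
            est = lulc_density(pp[pp["lulc"] == c.lulc], "C")
            assert abs(est.mean_density - c.target_carbon_density) <= 3 * est.se_density


class TestAreaTable:
    def test_published_class_areas(self):
        areas = generate_area_table().set_index("lulc")
        assert areas.loc["Cropland and Fallow", "area_ha"] == pytest.approx(8031.15)
        assert areas.loc["Savannah Woodland", "area_ha"] == pytest.approx(5447.79)
        assert areas["n_plots"].sum() == 250

    def test_percentages_sum_below_100(self):
        # the basin also holds water bodies, roads and bare land
        assert generate_area_table()["percent_of_basin"].sum() < 100


class TestClassMap:
    def test_area_discretisation_bound(self):
        areas = generate_area_table()
        cmap = generate_class_map(areas, resolution_m=30.0, seed=0)
        got = cmap.class_areas_ha()
        for row in areas.itertuples(index=False):
            assert abs(got[row.lulc] - row.area_ha) <= 0.09 / 2 + 1e-9

    def test_determinism_and_seed_sensitivity(self):
        a = generate_class_map(resolution_m=100, seed=4)
        b = generate_class_map(resolution_m=100, seed=4)
        c = generate_class_map(resolution_m=100, seed=5)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_each_class_is_connected(self):
        cmap = generate_class_map(resolution_m=200, seed=1)
        grid = cmap.values
        for code in range(len(cmap.classes)):
            mask = grid == code
            assert mask.any()
            # flood fill from one seed cell must reach every cell of the class
            start = tuple(np.argwhere(mask)[0])
            seen = {start}
            stack = [start]
            while stack:
                r, c = stack.pop()
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    nr, nc = r + dr, c + dc
                    if (0 <= nr < mask.shape[0] and 0 <= nc < mask.shape[1]
                            and mask[nr, nc] and (nr, nc) not in seen):
                        seen.add((nr, nc))
                        stack.append((nr, nc))
            assert len(seen) == int(mask.sum())

    def test_too_coarse_grid_rejected(self):
        with pytest.raises(ValueError, match="too coarse"):
            generate_class_map(resolution_m=2000.0, seed=0)  # smallest class 16.74 ha
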