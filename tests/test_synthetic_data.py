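"""The synthetic generators reproduce the statistical structure they claim."""

import numpy as np
import pandas as pd
import pytest

from letfoci import (
    BeamParams,
    GeneratorConfig,
    clustering_probability,
    extract_max_volumes,
    gen_clonogenic_table,
    gen_foci_table,
    gen_mono_depth_profiles,
    gen_occupancy_table,
    gen_sobp_spec,
    sample_max_volumes,
)
from letfoci.let_mixing import composed_dose
from letfoci.unhit_model import classify_unhit


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_nuclei_per_let": 0},
            {"dose": 0.0},
            {"let_values": (13.0, -5.0)},
            {"plating_efficiency": 0.0},
            {"plating_efficiency": 1.5},
            {"true_unhit_coefficient": -0.1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeneratorConfig(**kwargs)

    def test_let_beyond_unhit_domain_rejected_at_generation(self):
        config = GeneratorConfig(let_values=(13.0, 170.0))  # law domain ends ~161.8
        with pytest.raises(ValueError):
            gen_foci_table(config)


class TestDeterminism:
    @pytest.mark.parametrize(
        "generator", [gen_foci_table, gen_occupancy_table, gen_clonogenic_table]
    )
    def test_fixed_seed_gives_identical_tables(self, generator):
        a = generator(GeneratorConfig(seed=42))
        b = generator(GeneratorConfig(seed=42))
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_different_seeds_differ(self):
        a = gen_foci_table(GeneratorConfig(seed=1))
        b = gen_foci_table(GeneratorConfig(seed=2))
        assert not a.equals(b)


class TestFociGenerator:
    def test_max_volume_mean_matches_law_at_let60(self, laws, rng):
        # mu(60) = 1.074 um^3, but draws below the 0.01 um^3 exclusion floor
        # are resampled, so the oracle is the floor-truncated normal mean
        from scipy import stats

        mu, sigma = laws.mu(60.0), laws.sigma(60.0)
        a = (0.01 - mu) / sigma
        truncated_mean = stats.truncnorm.mean(a, np.inf, loc=mu, scale=sigma)
        assert truncated_mean == pytest.approx(1.074, abs=0.02)  # floor bias is small
        values = sample_max_volumes(rng, 60.0, 10_000, laws)
        se = values.std(ddof=1) / np.sqrt(values.size)
        assert abs(values.mean() - truncated_mean) < 3 * se

    def test_zero_unhit_coefficient_keeps_all_nuclei(self):
        config = GeneratorConfig(seed=5, true_unhit_coefficient=0.0)
        table = gen_foci_table(config)
        for let in config.let_values:
            nuclei = table[table["let"] == let]["nucleus_id"].nunique()
            assert nuclei == config.n_nuclei_per_let

    def test_every_focus_at_or_above_floor(self, config):
        table = gen_foci_table(config)
        assert (table["volume"] >= config.volume_floor).all()

    def test_unhit_fraction_thins_high_let_nuclei(self):
        config = GeneratorConfig(seed=11, n_nuclei_per_let=400)
        table = gen_foci_table(config)
        hit_100 = table[table["let"] == 100.0]["nucleus_id"].nunique()
        # R_unhit(100) = 0.382: expect ~247 of 400 hit
        assert abs(hit_100 / 400 - (1 - 0.381924)) < 0.08

    def test_samples_feed_extraction(self, config):
        samples = extract_max_volumes(gen_foci_table(config))
        assert set(samples) == set(config.let_values)


class TestOccupancyGenerator:
    def test_zero_coefficient_means_no_unhit_cells(self):
        config = GeneratorConfig(seed=3, true_unhit_coefficient=0.0)
        table = gen_occupancy_table(config)
        flags = [
            classify_unhit(s, a)
            for s, a in zip(table["signal_area"], table["nucleus_area"])
        ]
        assert not any(flags)

    def test_unhit_fraction_converges_to_law_at_let100(self):
        # (0.0618*100)^2/100 = 0.381924, 3 SE band at n = 10^5
        config = GeneratorConfig(seed=9, let_values=(100.0,), n_cells_occupancy=100_000)
        table = gen_occupancy_table(config)
        flags = np.array(
            [
                classify_unhit(s, a)
                for s, a in zip(table["signal_area"], table["nucleus_area"])
            ]
        )
        frac = flags.mean()
        se = np.sqrt(0.381924 * (1 - 0.381924) / flags.size)
        assert abs(frac - 0.381924) < 3 * se

    def test_areas_are_positive_and_signal_bounded(self, config):
        table = gen_occupancy_table(config)
        assert (table["nucleus_area"] > 0).all()
        assert (table["signal_area"] >= 0).all()
        assert (table["signal_area"] <= table["nucleus_area"]).all()


class TestClonogenicGenerator:
    def test_generating_sf_value_at_let100(self, laws, unhit_law):
        # SF = 1 - R_hit(100) * p_100(0.7) = 1 - 0.6181*0.9086 ~ 0.4384
        p = clustering_probability(0.7, 100.0, laws)
        sf = 1.0 - unhit_law.r_hit(100.0) * p
        assert sf == pytest.approx(0.4384, abs=5e-4)

    def test_huge_threshold_gives_full_survival(self):
        config = GeneratorConfig(seed=4, true_lethal_threshold=100.0, n_seeded=20_000)
        table = gen_clonogenic_table(config)
        treated = table[~table["control"]]
        expected = config.n_seeded * config.plating_efficiency
        assert np.allclose(treated["colonies"], expected, rtol=0.05)

    def test_controls_reflect_plating_efficiency(self, config):
        table = gen_clonogenic_table(config)
        controls = table[table["control"]]
        assert len(controls) == config.replicates
        rate = controls["colonies"].sum() / controls["n_seeded"].sum()
        assert rate == pytest.approx(config.plating_efficiency, abs=0.03)


class TestDepthProfiles:
    def test_grid_spacing_is_tenth_of_mm(self):
        profile = gen_mono_depth_profiles()[0]
        assert np.allclose(np.diff(profile.depth), 0.1, atol=1e-9)

    def test_entrance_let_exact(self):
        profile = gen_mono_depth_profiles(BeamParams(entrance_let=13.0))[0]
        assert profile.let_mono[0] == pytest.approx(13.0)

    def test_let_monotone_up_to_peak(self):
        p = BeamParams()
        profile = gen_mono_depth_profiles(p)[0]
        upto = profile.depth <= p.range_mm
        assert np.all(np.diff(profile.let_mono[upto]) >= 0)
        peak_idx = int(round(p.range_mm / 0.1))
        assert profile.let_mono[peak_idx] >= profile.let_mono[0]

    def test_dose_has_single_peak_at_range(self):
        p = BeamParams()
        profile = gen_mono_depth_profiles(p)[0]
        peak = profile.depth[np.argmax(profile.dose_mono)]
        assert peak == pytest.approx(p.range_mm, abs=0.2)
        assert (profile.dose_mono >= 0).all()

    def test_nonpositive_range_rejected(self):
        with pytest.raises(ValueError):
            BeamParams(range_mm=-10.0)


@pytest.fixture(scope="module")
def beam():
    p = BeamParams(grid_max_mm=150.0 + 30.0 + 20.0)
    mono = gen_mono_depth_profiles(p)[0]
    return mono, gen_sobp_spec(30.0, mono)


class TestSOBPSpec:
    def test_shift_span_equals_width(self, beam):
        _, spec = beam
        shifts = [c.s for c in spec.components]
        assert max(shifts) - min(shifts) == pytest.approx(30.0)

    def test_weights_normalised_and_nonnegative(self, beam):
        _, spec = beam
        weights = [c.w for c in spec.components]
        assert all(w >= 0 for w in weights)
        assert sum(weights) == pytest.approx(1.0)

    def test_plateau_flat_within_tolerance(self, beam):
        mono, spec = beam
        peak = float(mono.depth[np.argmax(mono.dose_mono)])
        grid = np.arange(peak - 30.0 + 2.0, peak - 2.0 + 1e-9, 0.5)
        doses = np.array([composed_dose(mono, spec, z) for z in grid])
        assert doses.max() / doses.mean() < 1.05
        assert doses.min() / doses.mean() > 0.95

    def test_deterministic_for_given_width(self, beam):
        mono, spec = beam
        again = gen_sobp_spec(30.0, mono)
        assert [(c.w, c.s) for c in again.components] == [
            (c.w, c.s) for c in spec.components
        ]

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            gen_sobp_spec(0.0)
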