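"""Tests for the synthetic cohort, hypnogram, feature and image generators."""

import numpy as np
import pandas as pd
import pytest

import _oracles as oracle
from fspheno.synthetic import (
    ArchetypeSpec,
    CohortConfig,
    Dist,
    default_archetypes,
    generate_cfos_image,
    generate_cohort,
    generate_epoch_features,
    generate_hypnogram,
    sample_region_densities,
    stationary_distribution,
    transition_matrix,
)


class TestConfigValidation:
    def test_percentage_location_out_of_range(self):
        with pytest.raises(ValueError):
            Dist("truncnorm", 120.0, 5.0)

    def test_negative_scale(self):
        with pytest.raises(ValueError):
            Dist("lognorm", 1.0, -0.1)

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            Dist("uniform", 0.0, 1.0)

    def test_wake_to_rem_transition_forbidden(self):
        bad = np.array([[0.9, 0.05, 0.05], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
        spec = default_archetypes(1)[0]
        with pytest.raises(ValueError, match="WAKE->REM"):
            ArchetypeSpec("X", 1, spec.behavior, {"baseline": bad})

    def test_rows_must_sum_to_one(self):
        bad = np.array([[0.5, 0.4, 0.0], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
        spec = default_archetypes(1)[0]
        with pytest.raises(ValueError, match="sum to 1"):
            ArchetypeSpec("X", 1, spec.behavior, {"baseline": bad})


class TestGenerateCohort:
    def test_empty_cohort(self):
        cfg = CohortConfig(default_archetypes(0), seed=0)
        table = generate_cohort(cfg)
        assert len(table) == 0
        assert list(table.columns) == ["animal_id", "group", "test", "day",
                                       "variable", "value"]

    def test_determinism_under_seed(self):
        cfg = CohortConfig(default_archetypes(5), seed=42)
        a = generate_cohort(cfg)
        b = generate_cohort(CohortConfig(default_archetypes(5), seed=42))
        pd.testing.assert_frame_equal(a, b)
        c = generate_cohort(CohortConfig(default_archetypes(5), seed=43))
        assert not a["value"].equals(c["value"])

    def test_expected_rows_per_animal(self, study_cohort):
        per_animal = study_cohort.groupby("animal_id").size()
        assert (per_animal == per_animal.iloc[0]).all()
        assert study_cohort["animal_id"].nunique() == 16 + 11 + 13 + 7

    def test_percentages_bounded_counts_integer(self, large_cohort):
        pct = large_cohort[large_cohort["variable"].str.endswith("_pct")]["value"]
        assert ((pct >= 0) & (pct <= 100)).all()
        counts = large_cohort[large_cohort["variable"] == "escape_attempts"]["value"]
        assert (counts >= 0).all()
        assert np.allclose(counts, np.round(counts))

    def test_sample_means_match_distribution_oracle(self):
        """At n=200/group every variable's sample mean is within 3 SE of the
        exact mean of its configured family (scipy closed forms)."""
        n = 200
        cfg = CohortConfig(default_archetypes(n), seed=9)
        table = generate_cohort(cfg)
        for spec in cfg.archetypes:
            sub = table[table["group"] == spec.name]
            for (test, day, var), dist in spec.behavior.items():
                vals = sub[(sub["test"] == test) & (sub["day"] == day)
                           & (sub["variable"] == var)]["value"].to_numpy()
                se = dist.std() / np.sqrt(n)
                if se == 0:
                    assert np.allclose(vals, dist.mean())
                else:
                    assert abs(vals.mean() - dist.mean()) < 3 * se, (spec.name, test, var)

    def test_group_medians_within_central_interval(self):
        """Parameter recovery: per-group medians inside the central 95%
        interval implied by the configured distribution (order-statistic
        bound on the sample median at n=100)."""
        n = 100
        cfg = CohortConfig(default_archetypes(n), seed=13)
        table = generate_cohort(cfg)
        # central 95%+ interval for the sample median of n=100 iid draws:
        # its quantile level is ~N(0.5, 0.5/sqrt(n)); +-3.3 sd keeps the
        # per-variable miss probability ~1e-3
        from scipy import stats as sps
        for spec in cfg.archetypes:
            sub = table[table["group"] == spec.name]
            for (test, day, var), dist in spec.behavior.items():
                if dist.family != "truncnorm" or dist.scale == 0:
                    continue
                vals = sub[(sub["test"] == test) & (sub["day"] == day)
                           & (sub["variable"] == var)]["value"].to_numpy()
                a = (0 - dist.loc) / dist.scale
                b = (100 - dist.loc) / dist.scale
                lo = sps.truncnorm.ppf(0.335, a, b, loc=dist.loc, scale=dist.scale)
                hi = sps.truncnorm.ppf(0.665, a, b, loc=dist.loc, scale=dist.scale)
                assert lo <= np.median(vals) <= hi, (spec.name, test, var)


class TestHypnogramGenerator:
    def test_absorbing_wake(self):
        spec = default_archetypes(1)[0]
        absorbing = ArchetypeSpec(
            "NoFS", 1, spec.behavior,
            {"baseline": np.array([[1.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.5, 0.5, 0.0]])},
        )
        h = generate_hypnogram(absorbing, "baseline", seed=0, recording_hours=1)
        assert (h.states == "WAKE").all()

    def test_determinism(self):
        spec = default_archetypes(1)[1]
        a = generate_hypnogram(spec, "D14", seed=21)
        b = generate_hypnogram(spec, "D14", seed=21)
        assert (a.states == b.states).all()

    def test_rem_never_follows_wake(self):
        spec = default_archetypes(1)[2]
        h = generate_hypnogram(spec, "baseline", seed=2)
        prev, cur = h.states[:-1], h.states[1:]
        assert not np.any((prev == "WAKE") & (cur == "REM"))

    def test_long_run_fractions_match_stationary_oracle(self):
        """10 simulated days: state fractions within 2% absolute of the
        chain's stationary law, itself checked against brute-force matrix
        powering."""
        spec = default_archetypes(1)[1]
        mat = spec.sleep["D14"]
        pi = stationary_distribution(mat)
        assert np.allclose(pi, oracle.stationary_oracle(mat), atol=1e-10)
        h = generate_hypnogram(spec, "D14", seed=17, recording_hours=240)
        for i, st in enumerate(("WAKE", "SWS", "REM")):
            frac = np.mean(h.states == st)
            assert abs(frac - pi[i]) < 0.02

    def test_transition_matrix_constructor_hits_targets(self):
        targets = (0.45, 0.46, 0.09)
        mat = transition_matrix(targets)
        assert np.allclose(stationary_distribution(mat), targets, atol=1e-12)
        assert mat[0, 2] == 0.0


class TestEpochFeatures:
    def test_all_wake_hypnogram_draws_from_wake_distribution(self):
        from fspheno.sleep import Hypnogram
        spec = default_archetypes(1)[0]
        h = Hypnogram(np.array(["WAKE"] * 17280))
        feats = generate_epoch_features(h, spec, seed=1)
        assert feats["emg"].mean() == pytest.approx(
            spec.features.means["WAKE"]["emg"], abs=0.05)

    def test_zero_noise_gives_exact_state_means(self):
        from fspheno.sleep import Hypnogram
        from fspheno.synthetic import FeatureParams
        spec = default_archetypes(1)[0]
        spec = ArchetypeSpec(spec.name, 1, spec.behavior, spec.sleep,
                             features=FeatureParams(noise_sd=0.0))
        h = Hypnogram(np.array(["SWS", "REM", "WAKE"]))
        feats = generate_epoch_features(h, spec, seed=0)
        assert feats.loc[0, "delta"] == spec.features.means["SWS"]["delta"]
        assert feats.loc[1, "theta"] == spec.features.means["REM"]["theta"]
        assert feats.loc[2, "emg"] == spec.features.means["WAKE"]["emg"]


class TestImageGenerator:
    def test_zero_spots_is_background_only(self):
        img, truth = generate_cfos_image(64, 64, [], background=7.0)
        assert img.shape == (2, 64, 64)
        assert np.all(img == 7.0)
        assert len(truth) == 0

    def test_out_of_bounds_spot_rejected(self):
        with pytest.raises(ValueError):
            generate_cfos_image(32, 32, [(40, 10, 3.0)])

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            generate_cfos_image(32, 32, [], noise_sd=-1.0)

    def test_cfos_channel_contains_configured_subset(self):
        img, truth = generate_cfos_image(
            128, 64, [(20, 20, 4.0), (40, 100, 4.0)], cfos_positive=[True, False],
            background=0.0)
        assert img[0, 40, 100] > 50  # nuclear channel has both
        assert img[1, 20, 20] > 50
        assert img[1, 40, 100] < 1  # second spot absent from c-Fos channel

    def test_determinism(self):
        spots = [(10, 10, 3.0), (30, 30, 3.0)]
        a, _ = generate_cfos_image(64, 64, spots, noise_sd=5.0, seed=3)
        b, _ = generate_cfos_image(64, 64, spots, noise_sd=5.0, seed=3)
        assert np.array_equal(a, b)

    def test_region_density_sampler_deterministic(self):
        spec = default_archetypes(4)[3]
        a = sample_region_densities(spec, seed=5, animal_index=2)
        b = sample_region_densities(spec, seed=5, animal_index=2)
        pd.testing.assert_frame_equal(a, b)
        assert set(a["region"]) == set(spec.imaging)
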