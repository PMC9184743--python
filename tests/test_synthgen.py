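import numpy as np
import pytest

from restdyn import synthgen
from restdyn.mse import MseParams, mse_curve, mse_grid
from restdyn.preprocess import reject_epochs
from restdyn.spd import band_power, power_spectrum, relative_power


def _fit_loglog_slope(realizations, fs, fmin=1.0, fmax=40.0):
    """Least-squares slope of the mean periodogram on log-log axes."""
    acc = None
    for x in realizations:
        f = np.fft.rfftfreq(len(x), 1.0 / fs)
        p = np.abs(np.fft.rfft(x)) ** 2
        acc = p if acc is None else acc + p
    band = (f >= fmin) & (f <= fmax)
    return np.polyfit(np.log(f[band]), np.log(acc[band]), 1)[0]


class TestColoredNoise:
    def test_white_noise_has_flat_spectrum(self):
        xs = [synthgen.generate_colored_noise(2500, 0.0, 1000.0, s) for s in range(100)]
        assert abs(_fit_loglog_slope(xs, 1000.0)) < 0.1

    def test_determinism(self):
        a = synthgen.generate_colored_noise(2500, 2.0, 1000.0, 42)
        b = synthgen.generate_colored_noise(2500, 2.0, 1000.0, 42)
        np.testing.assert_array_equal(a, b)

    def test_pink_noise_slope_recovered(self):
        xs = [synthgen.generate_colored_noise(2500, 1.0, 1000.0, s) for s in range(200)]
        slope = _fit_loglog_slope(xs, 1000.0)
        assert slope == pytest.approx(-1.0, abs=0.15)

    def test_zero_mean_unit_sd(self):
        x = synthgen.generate_colored_noise(5000, 1.5, 1000.0, 0)
        assert abs(x.mean()) < 1e-12
        assert x.std() == pytest.approx(1.0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            synthgen.generate_colored_noise(1, 1.0, 1000.0, 0)
        with pytest.raises(ValueError):
            synthgen.generate_colored_noise(100, -0.5, 1000.0, 0)


class TestEpochedSubject:
    def test_artifact_injection_count_is_exact(self):
        profile = synthgen.SynthProfile(
            spectral_slope=1.0, background_sd_uV=5.0, noise_sd=0.5,
            artifact_rate=0.2, artifact_amplitude=150.0,
        )
        rec = synthgen.generate_epoched_subject(profile, 50, 1000.0, 1000.0, ["a", "b"], 3)
        ptp = (rec.data.max(axis=2) - rec.data.min(axis=2)).max(axis=1)
        assert int((ptp > 100.0).sum()) == 10
        assert len(rec.info["artifact_epochs"]) == 10

    def test_rejection_recovers_injected_epochs_exactly(self):
        """Cross-check against the generator's bookkeeping: the 100 µV rule
        flags exactly the contaminated epochs when background stays low."""
        profile = synthgen.SynthProfile(
            spectral_slope=1.0, background_sd_uV=5.0, noise_sd=0.5,
            artifact_rate=0.2, artifact_amplitude=150.0,
        )
        rec = synthgen.generate_epoched_subject(profile, 50, 1000.0, 1000.0, ["a"], 11)
        kept, report = reject_epochs(rec, 100.0)
        assert report.rejected_indices == rec.info["artifact_epochs"]
        assert kept.n_epochs == 40

    def test_single_oscillator_dominates_alpha_band(self):
        profile = synthgen.SynthProfile(
            spectral_slope=0.0,
            band_components=((10.0, 1.0, 50.0),),  # oscillation >> background
            noise_sd=0.0,
        )
        rec = synthgen.generate_epoched_subject(profile, 5, 2500.0, 1000.0, ["a"], 0)
        shares = []
        for e in range(5):
            f, p = power_spectrum(rec.data[e, 0], 1000.0)
            fsub, rel = relative_power(p, f)
            shares.append(band_power(rel, fsub, (8.0, 14.0)))
        assert np.mean(shares) > 0.9

    def test_empty_channel_list_raises(self):
        with pytest.raises(ValueError):
            synthgen.generate_epoched_subject(
                synthgen.young_profile(), 2, 2500.0, 1000.0, [], 0
            )

    def test_determinism(self):
        p = synthgen.old_profile()
        a = synthgen.generate_epoched_subject(p, 3, 1000.0, 1000.0, ["x", "y"], 9)
        b = synthgen.generate_epoched_subject(p, 3, 1000.0, 1000.0, ["x", "y"], 9)
        np.testing.assert_array_equal(a.data, b.data)


class TestStudyGeneration:
    def test_bookkeeping_cartesian_product(self):
        spec = synthgen.null_spec(n_subjects_per_group=10, n_epochs=2, n_channels=1)
        study = synthgen.generate_study(spec)
        assert len(study) == 40
        keys = {(g, c) for g, c, _ in study}
        assert keys == {(g, c) for g in spec.groups for c in spec.conditions}
        for g in spec.groups:
            subs = {s for gg, _, s in study if gg == g}
            assert len(subs) == 10

    def test_study_is_bit_deterministic(self):
        spec = synthgen.null_spec(n_subjects_per_group=2, n_epochs=2, n_channels=2)
        s1 = synthgen.generate_study(spec)
        s2 = synthgen.generate_study(spec)
        for k in s1:
            np.testing.assert_array_equal(s1[k].data, s2[k].data)

    def test_subject_identity_preserved_across_conditions(self):
        """The subject-level band scaling is shared pre/post, so a subject's
        alpha power is correlated across conditions beyond the group mean."""
        spec = synthgen.null_spec(n_subjects_per_group=12, n_epochs=4, n_channels=1,
                                  epoch_ms=1000.0, fs=250.0, seed=5)
        study = synthgen.generate_study(spec)
        pre, post = [], []
        for s in sorted({k[2] for k in study if k[0] == "g1"}):
            for cond, acc in (("c1", pre), ("c2", post)):
                rec = study[("g1", cond, s)]
                shares = []
                for e in range(rec.n_epochs):
                    f, p = power_spectrum(rec.data[e, 0], rec.fs)
                    fsub, rel = relative_power(p, f, (0.4, 40.0))
                    shares.append(band_power(rel, fsub, (8.0, 14.0)))
                acc.append(np.mean(shares))
        r = np.corrcoef(pre, post)[0, 1]
        assert r > 0.5

    def test_missing_profile_raises(self):
        spec = synthgen.null_spec()
        profiles = dict(spec.profiles)
        del profiles[("g1", "c1")]
        import dataclasses

        bad = dataclasses.replace(spec, profiles=profiles)
        with pytest.raises(ValueError, match="g1"):
            synthgen.generate_study(bad)


class TestEntropyDirections:
    def test_steeper_slope_lowers_fine_scale_entropy(self):
        """Monotonicity: more low-frequency dominance -> fewer fine-scale
        surprises relative to the fixed scale-1 tolerance."""
        means = []
        for alpha in (0.5, 1.0, 1.5):
            vals = []
            for s in range(20):
                x = synthgen.generate_colored_noise(1000, alpha, 1000.0, s)
                curve = mse_curve(x[None, :], MseParams(max_scale=5, min_coarse_samples=50))
                vals.append(np.nanmean(curve[0, :5]))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_old_profile_shifts_entropy_from_coarse_to_fine(self):
        """Flatter background + beta emphasis raises scale-1 and lowers
        scale-45 sample entropy relative to the young profile."""
        res = {}
        for name, prof in (("young", synthgen.young_profile()),
                           ("old", synthgen.old_profile())):
            s1, s45 = [], []
            for i in range(6):
                rec = synthgen.generate_epoched_subject(
                    prof, 2, 2500.0, 1000.0, ["a"], np.random.SeedSequence([name == "old", i])
                )
                g = mse_grid(rec, MseParams())
                s1.append(g.values[0, 0])
                s45.append(g.values[0, 44])
            res[name] = (np.mean(s1), np.mean(s45))
        assert res["old"][0] > res["young"][0]
        assert res["old"][1] < res["young"][1]


class TestConfigRoundTrip:
    def test_yaml_round_trip(self, tmp_path):
        spec = synthgen.default_training_spec(n_subjects_per_group=3, n_epochs=2)
        path = tmp_path / "spec.yaml"
        synthgen.spec_to_yaml(spec, str(path))
        back = synthgen.spec_from_yaml(str(path))
        assert back.groups == spec.groups
        assert back.conditions == spec.conditions
        assert back.profiles == spec.profiles
        assert back.seed == spec.seed

    def test_continuous_mode_segments_cleanly(self):
        from restdyn.preprocess import segment_continuous

        sig = synthgen.generate_continuous_subject(
            synthgen.young_profile(), 10_000.0, 1000.0, ["a", "b"], 0
        )
        rec = segment_continuous(sig, 1000.0, 2500.0, ["a", "b"])
        assert rec.n_epochs == 4
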