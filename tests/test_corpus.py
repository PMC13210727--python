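import json

import numpy as np
import pytest

import dopplerfall as df
from dopplerfall.corpus import _grid_draw


class TestGridDraws:
    def test_height_draws_on_millimetre_grid(self, rng):
        draws = np.array([_grid_draw(rng, (1.50, 1.90, 0.001)) for _ in range(10000)])
        assert draws.min() >= 1.50
        assert draws.max() <= 1.90
        steps = (draws - 1.50) / 0.001
        assert np.allclose(steps, np.round(steps), atol=1e-6)

    def test_degenerate_grid_is_constant(self, rng):
        draws = {_grid_draw(rng, (2.0, 2.0, 0.5)) for _ in range(100)}
        assert draws == {2.0}

    def test_same_seed_same_sequence(self):
        spec = df.RandomizationSpec(seed=3)
        a = [df.sample_trial_params(spec, "fall", np.random.default_rng(9)) for _ in range(5)]
        b = [df.sample_trial_params(spec, "fall", np.random.default_rng(9)) for _ in range(5)]
        assert a == b

    def test_unknown_class_rejected(self, rng):
        with pytest.raises(ValueError):
            df.sample_trial_params(df.RandomizationSpec(), "jump", rng)

    def test_midpoint_spec_collapses_grids(self, rng):
        spec = df.RandomizationSpec().at_midpoints()
        ps = [df.sample_trial_params(spec, "fall", rng) for _ in range(10)]
        assert len({p.body_height_H for p in ps}) == 1
        assert ps[0].v0 == pytest.approx(2.75)


class TestGenerateCorpus:
    def test_counts_files_and_balance(self, tmp_path):
        spec = df.RandomizationSpec(seed=5)
        manifest, X = df.generate_corpus(spec, 2, out_dir=tmp_path)
        assert len(manifest) == 6
        assert X.shape == (6, 64 * 64)
        assert manifest["class"].value_counts().to_dict() == {
            "fall": 2, "walk": 2, "breathe": 2
        }
        assert len(list((tmp_path / "waveforms").glob("*.wav"))) == 6
        assert len(list((tmp_path / "spectrograms").glob("*.png"))) == 6
        assert (tmp_path / "manifest.jsonl").exists()
        assert (tmp_path / "manifest.csv").exists()
        assert manifest["trial_id"].is_unique

    def test_reproducible_from_seed(self):
        spec = df.RandomizationSpec(seed=8)
        m1, x1 = df.generate_corpus(spec, 3)
        m2, x2 = df.generate_corpus(spec, 3)
        assert m1.equals(m2)
        assert np.array_equal(x1, x2)

    def test_fall_spectra_reach_higher_doppler_than_breathing(self):
        """Every fall trial shows a high-Doppler event that no breathing
        trial shows: compare the highest frequency carrying strong
        normalized energy."""
        spec = df.RandomizationSpec(seed=13)
        manifest, X = df.generate_corpus(spec, 6)
        imgs = X.reshape(-1, 64, 64)
        freqs = np.linspace(0, 500, 64)

        def top_energetic_freq(img):
            strong = (img > 0.6).any(axis=1)
            return freqs[strong].max() if strong.any() else 0.0

        tops = np.array([top_energetic_freq(im) for im in imgs])
        is_fall = (manifest["class"] == "fall").to_numpy()
        is_breathe = (manifest["class"] == "breathe").to_numpy()
        assert tops[is_fall].min() > tops[is_breathe].max()

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            df.generate_corpus(df.RandomizationSpec(), 0)


class TestExperiment2Manifest:
    def test_default_protocol_counts(self):
        m = df.build_experiment2_manifest()
        assert len(m) == 1440
        per = m.groupby(["participant_id", "class"]).size()
        assert set(per) == {48}
        assert m["trial_id"].is_unique

    def test_minimal_factorial(self):
        m = df.build_experiment2_manifest(1, ("A",), 1, 1)
        assert len(m) == 3

    def test_factorial_formula(self):
        m = df.build_experiment2_manifest(4, ("A", "B"), 5, 3)
        assert len(m) == 4 * 2 * 5 * 3 * 3


@pytest.fixture(scope="module")
def small_manifest():
    return df.build_experiment2_manifest(3, ("A", "B"), 2, 1)


class TestPseudoMeasured:

    def test_per_participant_parameters_tied(self, small_manifest):
        pm, _ = df.generate_pseudo_measured(
            df.pseudo_measured_spec(2), small_manifest, feature_size=None
        )
        falls = pm[pm["class"] == "fall"]
        for _, grp in falls.groupby("participant_id"):
            hs = {json.loads(p)["body_height_H"] for p in grp["params"]}
            ws = {json.loads(p)["body_width_W"] for p in grp["params"]}
            assert len(hs) == 1 and len(ws) == 1

    def test_rebound_perturbs_only_fall_trials(self, small_manifest):
        spec = df.pseudo_measured_spec(2)
        pm_off, x_off = df.generate_pseudo_measured(
            spec, small_manifest, rebound=False, clutter=False
        )
        pm_on, x_on = df.generate_pseudo_measured(
            spec, small_manifest, rebound=True, clutter=False
        )
        is_fall = (pm_off["class"] == "fall").to_numpy()
        assert not np.allclose(x_off[is_fall], x_on[is_fall])
        assert np.array_equal(x_off[~is_fall], x_on[~is_fall])

    def test_rebound_adds_post_fall_band_energy(self, small_manifest):
        """The mattress-rebound transient deposits extra mid-band energy in
        the late (post-contact) part of fall spectrograms."""
        spec = df.pseudo_measured_spec(2)
        _, x_off = df.generate_pseudo_measured(
            spec, small_manifest, rebound=False, clutter=False
        )
        pm, x_on = df.generate_pseudo_measured(
            spec, small_manifest, rebound=True, clutter=False
        )
        is_fall = (pm["class"] == "fall").to_numpy()
        off = x_off[is_fall].reshape(-1, 64, 64)
        on = x_on[is_fall].reshape(-1, 64, 64)
        # mid-band (20-250 Hz), last third of the trial
        band = slice(3, 32)
        late = slice(43, 64)
        gain = on[:, band, late].mean(axis=(1, 2)) - off[:, band, late].mean(axis=(1, 2))
        assert np.mean(gain > 0) > 0.8

    def test_disabled_perturbations_reproducible(self, small_manifest):
        spec = df.pseudo_measured_spec(4)
        _, x1 = df.generate_pseudo_measured(spec, small_manifest, rebound=False, clutter=False)
        _, x2 = df.generate_pseudo_measured(spec, small_manifest, rebound=False, clutter=False)
        assert np.array_equal(x1, x2)

    def test_manifest_rows_preserved(self, small_manifest):
        pm, X = df.generate_pseudo_measured(df.pseudo_measured_spec(2), small_manifest)
        assert len(pm) == len(small_manifest)
        assert X.shape[0] == len(small_manifest)
        assert list(pm["trial_id"]) == list(small_manifest["trial_id"])


def test_noise_bank_contains_tone_and_noise():
    bank = df.generate_noise_bank(n_samples=5000, seed=0)
    assert bank.dtype.kind == "c"
    spec = np.abs(np.fft.fft(bank))
    freqs = np.fft.fftfreq(len(bank), d=0.001)
    tone_bin = np.argmin(np.abs(freqs - 50.0))
    assert spec[tone_bin] > 5 * np.median(spec)
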