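import numpy as np
import pytest

import dopplerfall as df

# Desk-scale study conditions: a 600-trial domain-randomized training corpus
# and pseudo-measured fixtures over the full measurement-protocol factorial
# with one repetition (720 trials).  Seeds are fixed for reproducibility.
TRAIN_SEED = 7
PM_SEED = 11


@pytest.fixture(scope="session")
def sim_corpus():
    spec = df.RandomizationSpec(seed=TRAIN_SEED)
    manifest, X = df.generate_corpus(spec, 200)
    return spec, manifest, X


@pytest.fixture(scope="session")
def pm_fixtures():
    manifest = df.build_experiment2_manifest()
    manifest = manifest[manifest["repetition"] == 1].reset_index(drop=True)
    pm, Xpm = df.generate_pseudo_measured(df.pseudo_measured_spec(PM_SEED), manifest)
    return pm, Xpm


@pytest.fixture(scope="session")
def trained_model(sim_corpus):
    _, manifest, X = sim_corpus
    cfg = df.desk_config(seed=0)
    return df.train_classifier(X, manifest["class"], cfg), cfg


@pytest.fixture(scope="session")
def fall_spectrogram():
    """Normalized spectrogram of the representative fall trial
    (H = 1.5 m, W = 0.5 m, d = 2.5 m, h = 1.3 m, v0 = 2.0, K = 1/(WH))."""
    p = df.FallTrialParams(
        body_height_H=1.5, body_width_W=0.5, v0=2.0, K=1.0 / (0.5 * 1.5)
    )
    rs = df.fall_range_trajectory(p)
    sig = df.synthesize_iq(df.doppler_phase(rs, df.RadarConfig()), 1.0, 0.0)
    return df.preprocess(sig)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
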