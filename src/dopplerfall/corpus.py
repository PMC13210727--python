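"""Domain-randomized corpus generation and trial manifests.

Training corpora are synthesized by drawing motion-class parameters
uniformly on discrete grids (body height H in [1.50, 1.90] m at 1 mm steps,
width W in [0.30, 0.60] m at 1 mm steps, initial tip velocity v0 in
[0.5, 5.0] at 0.01 steps, effective-range factor K in [0.01, 5.0] m^-2 at
0.01 steps, walking-speed factor RV in [0.5, 3.0] at 0.01 steps, breathing
frequency in [0.1, 0.5] Hz at 0.01 Hz steps), with randomized aspect angle,
sensor range and per-trial SNR.

A pseudo-measured fixture generator emulates held-out measured data: the
same simulator driven from a *shifted* parameter regime, with per-subject
body parameters tied across that subject's trials, per-location sensor
geometry, a mains-clutter tone, lowered SNR, and a post-contact mattress
rebound transient on fall trials.  It stands in for recordings that are not
distributed with the package, so the full sim-to-real pipeline can be
exercised offline; it is synthetic by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as sk_resize

from .motion import (
    BreathTrialParams,
    FallTrialParams,
    GaitTrialParams,
    fall_range_trajectory,
    gait_range_trajectory,
    respiration_range_trajectory,
)
from .radar import (
    BasebandSignal,
    RadarConfig,
    RangeSeries,
    amplitude_model,
    doppler_phase,
    noise_sigma_for_snr,
    synthesize_iq,
    write_iq_wav,
)
from .spectrogram import Spectrogram, preprocess, write_spectrogram_png

__all__ = [
    "RandomizationSpec",
    "CLASSES",
    "sample_trial_params",
    "synthesize_trial",
    "generate_corpus",
    "build_experiment2_manifest",
    "generate_pseudo_measured",
    "generate_noise_bank",
    "pseudo_measured_spec",
]

CLASSES = ("fall", "walk", "breathe")

GridRange = tuple[float, float, float]  # (low, high, step)


@dataclass(frozen=True)
class RandomizationSpec:
    """Parameter grids for domain-randomized synthesis."""

    H_range: GridRange = (1.50, 1.90, 0.001)
    W_range: GridRange = (0.30, 0.60, 0.001)
    v0_range: GridRange = (0.5, 5.0, 0.01)
    K_range: GridRange = (0.01, 5.0, 0.01)
    RV_range: GridRange = (0.5, 3.0, 0.01)
    fb_range: GridRange = (0.1, 0.5, 0.01)
    phi_set_deg: tuple | None = None  # None -> continuous in [-180, 180)
    d_range: GridRange = (1.5, 4.0, 0.01)
    snr_range_db: tuple[float, float] = (5.0, 25.0)
    sensor_height_h: float = 1.3
    chest_amp_range: tuple[float, float] = (0.004, 0.012)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("H_range", "W_range", "v0_range", "K_range", "RV_range", "fb_range", "d_range"):
            lo, hi, step = getattr(self, name)
            if hi < lo or step <= 0:
                raise ValueError(f"invalid grid for {name}")

    def at_midpoints(self) -> "RandomizationSpec":
        """Degenerate spec with every grid collapsed to its midpoint
        (the 'fixed fall parameters, no domain randomization' ablation)."""

        def mid(g: GridRange) -> GridRange:
            m = (g[0] + g[1]) / 2.0
            return (m, m, g[2])

        return replace(
            self,
            H_range=mid(self.H_range),
            W_range=mid(self.W_range),
            v0_range=mid(self.v0_range),
            K_range=mid(self.K_range),
            RV_range=mid(self.RV_range),
            fb_range=mid(self.fb_range),
            d_range=mid(self.d_range),
            snr_range_db=(
                (self.snr_range_db[0] + self.snr_range_db[1]) / 2.0,
            ) * 2,
            chest_amp_range=(
                (self.chest_amp_range[0] + self.chest_amp_range[1]) / 2.0,
            ) * 2,
        )


def _grid_draw(rng: np.random.Generator, grid: GridRange) -> float:
    lo, hi, step = grid
    n = int(round((hi - lo) / step)) + 1
    return round(lo + step * int(rng.integers(0, n)), 10)


def _draw_phi(rng: np.random.Generator, spec: RandomizationSpec) -> float:
    if spec.phi_set_deg is None:
        return float(rng.uniform(-math.pi, math.pi))
    deg = float(rng.choice(np.asarray(spec.phi_set_deg, dtype=float)))
    return math.radians(((deg + 180.0) % 360.0) - 180.0)


def sample_trial_params(
    spec: RandomizationSpec,
    cls: str,
    rng: np.random.Generator,
    phi: float | None = None,
    d: float | None = None,
):
    """Draw class-specific trial parameters from the randomization grids."""
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}")
    phi = _draw_phi(rng, spec) if phi is None else phi
    d = _grid_draw(rng, spec.d_range) if d is None else d
    if cls == "fall":
        return FallTrialParams(
            body_height_H=_grid_draw(rng, spec.H_range),
            body_width_W=_grid_draw(rng, spec.W_range),
            v0=_grid_draw(rng, spec.v0_range),
            K=_grid_draw(rng, spec.K_range),
            fall_azimuth_phi=phi,
            sensor_range_d=d,
            sensor_height_h=spec.sensor_height_h,
        )
    if cls == "walk":
        return GaitTrialParams(
            body_height_H=_grid_draw(rng, spec.H_range),
            body_width_W=_grid_draw(rng, spec.W_range),
            speed_factor_RV=_grid_draw(rng, spec.RV_range),
            heading_phi=phi,
            start_range_d=d,
            sensor_height_h=spec.sensor_height_h,
        )
    return BreathTrialParams(
        breathing_freq=_grid_draw(rng, spec.fb_range),
        chest_amplitude=float(rng.uniform(*spec.chest_amp_range)),
        facing_phi=phi,
        sensor_range_d=d,
    )


def _range_series(params, cls: str, linearized: bool = False) -> RangeSeries:
    if cls == "fall":
        return fall_range_trajectory(params, linearized=linearized)
    if cls == "walk":
        return gait_range_trajectory(params)
    return respiration_range_trajectory(params)


def _add_rebound(rs: RangeSeries, hold_start: float, rng: np.random.Generator) -> RangeSeries:
    """Brief damped post-contact oscillation (mattress rebound) at the start
    of the hold segment: a transient artifact, not a sustained signature."""
    t_rel = rs.times - hold_start
    mask = t_rel > 0
    amp = rng.uniform(0.01, 0.03)
    f_r = rng.uniform(3.0, 6.0)
    wig = amp * np.exp(-t_rel[mask] / 0.12) * np.sin(2 * np.pi * f_r * t_rel[mask])
    d = rs.range_D.copy()
    d[mask] = np.maximum(d[mask] + wig, 1e-3)
    return RangeSeries(times=rs.times, range_D=d, label=rs.label)


def _add_clutter_tone(
    sig: BasebandSignal, rng: np.random.Generator, tone_hz: float = 50.0
) -> BasebandSignal:
    level = rng.uniform(0.05, 0.15) * float(
        np.sqrt(np.mean(sig.channel_I**2 + sig.channel_Q**2))
    )
    psi = rng.uniform(0, 2 * np.pi)
    w = 2 * np.pi * tone_hz * sig.times + psi
    return BasebandSignal(
        times=sig.times,
        channel_I=sig.channel_I + level * np.sin(w),
        channel_Q=sig.channel_Q + level * np.cos(w),
        meta=dict(sig.meta, clutter_tone_hz=tone_hz),
    )


def synthesize_trial(
    params,
    cls: str,
    rng: np.random.Generator,
    snr_db: float,
    radar_cfg: RadarConfig | None = None,
    linearized: bool = False,
    rebound: bool = False,
    clutter: bool = False,
    trial_id: str | None = None,
) -> tuple[BasebandSignal, Spectrogram]:
    """Full synthesis chain: motion -> range -> I/Q -> normalized spectrogram."""
    cfg = radar_cfg or RadarConfig()
    rs = _range_series(params, cls, linearized=linearized)
    if rebound and cls == "fall":
        hold_start = rs.times[-1] - params.post_fall_hold
        rs = _add_rebound(rs, hold_start, rng)
    alpha0 = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
    alpha = amplitude_model(rs, alpha0=alpha0, attenuation_exponent=2.0)
    phase = doppler_phase(rs, cfg)
    sigma = noise_sigma_for_snr(alpha, snr_db)
    sig = synthesize_iq(
        phase,
        alpha,
        sigma,
        seed=rng,
        sampling_rate=cfg.sampling_rate,
        meta={"class": cls, "snr_db": snr_db, "alpha0": alpha0, "trial_id": trial_id},
    )
    if clutter:
        sig = _add_clutter_tone(sig, rng)
    return sig, preprocess(sig)


def _features(spec_img: Spectrogram, feature_size) -> np.ndarray:
    img = sk_resize(
        spec_img.magnitude, feature_size, order=1, preserve_range=True, anti_aliasing=True
    )
    return img.astype(np.float32).ravel()


def generate_corpus(
    spec: RandomizationSpec,
    n_per_class: int,
    out_dir=None,
    radar_cfg: RadarConfig | None = None,
    linearized: bool = False,
    feature_size: tuple[int, int] | None = (64, 64),
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Generate a balanced domain-randomized corpus.

    Returns the trial manifest and (optionally) a [n_trials x n_pixels]
    float32 feature matrix of downsampled normalized spectrograms.  When
    ``out_dir`` is given, waveforms (WAV + JSON sidecar) and spectrograms
    (16-bit PNG + sidecar) are written under ``out_dir/waveforms`` and
    ``out_dir/spectrograms`` and the manifest is serialized as JSON-Lines
    with a CSV mirror.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = ss.spawn(3 * n_per_class)
    cfg = radar_cfg or RadarConfig()

    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "waveforms").mkdir(parents=True, exist_ok=True)
        (out_dir / "spectrograms").mkdir(parents=True, exist_ok=True)

    rows, feats = [], []
    k = 0
    for cls in CLASSES:
        for rep in range(n_per_class):
            rng = np.random.default_rng(child_seeds[k])
            k += 1
            trial_id = f"sim_{cls}_{rep:05d}"
            params = sample_trial_params(spec, cls, rng)
            snr_db = float(rng.uniform(*spec.snr_range_db))
            sig, spg = synthesize_trial(
                params, cls, rng, snr_db, cfg, linearized=linearized, trial_id=trial_id
            )
            row = {
                "trial_id": trial_id,
                "class": cls,
                "participant_id": "sim",
                "location": "-",
                "direction_deg": round(math.degrees(_heading_of(params)), 3),
                "repetition": rep,
                "snr_db": round(snr_db, 3),
                "params": json.dumps(_params_dict(params)),
                "waveform_path": "",
                "spectrogram_path": "",
            }
            if out_dir is not None:
                wav = out_dir / "waveforms" / f"{trial_id}.wav"
                png = out_dir / "spectrograms" / f"{trial_id}.png"
                write_iq_wav(wav, sig, cfg)
                write_spectrogram_png(png, spg)
                row["waveform_path"] = str(wav)
                row["spectrogram_path"] = str(png)
            if feature_size is not None:
                feats.append(_features(spg, feature_size))
            rows.append(row)

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_json(out_dir / "manifest.jsonl", orient="records", lines=True)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    X = np.stack(feats) if feats else None
    return manifest, X


def _heading_of(params) -> float:
    for attr in ("fall_azimuth_phi", "heading_phi", "facing_phi"):
        if hasattr(params, attr):
            return getattr(params, attr)
    return 0.0


def _params_dict(params) -> dict:
    from dataclasses import asdict

    return {kk: (vv if not isinstance(vv, float) else round(vv, 6)) for kk, vv in asdict(params).items()}


def build_experiment2_manifest(
    n_participants: int = 10,
    locations: tuple = ("A", "B", "C"),
    n_directions: int = 8,
    repetitions: int = 2,
) -> pd.DataFrame:
    """Full-factorial trial manifest of the measurement protocol:
    participants x locations x directions x repetitions x 3 classes."""
    if min(n_participants, len(locations), n_directions, repetitions) < 1:
        raise ValueError("all factors must be >= 1")
    directions = [i * 360.0 / n_directions for i in range(n_directions)]
    rows = []
    for p in range(1, n_participants + 1):
        pid = f"P{p:02d}"
        for loc in locations:
            for direction in directions:
                for rep in range(1, repetitions + 1):
                    for cls in CLASSES:
                        rows.append(
                            {
                                "trial_id": f"{pid}_{loc}_{int(direction):03d}_r{rep}_{cls}",
                                "class": cls,
                                "participant_id": pid,
                                "location": loc,
                                "direction_deg": direction,
                                "repetition": rep,
                            }
                        )
    return pd.DataFrame(rows)


def pseudo_measured_spec(seed: int = 1) -> RandomizationSpec:
    """Default shifted regime for pseudo-measured fixtures: body sizes in the
    measured-participant envelope, slower/faster tail of v0 trimmed, K near
    the physical area average, and lower SNR than the training corpus."""
    return RandomizationSpec(
        H_range=(1.55, 1.88, 0.001),
        W_range=(0.34, 0.55, 0.001),
        v0_range=(0.8, 4.0, 0.01),
        K_range=(0.2, 2.0, 0.01),
        RV_range=(0.7, 2.2, 0.01),
        fb_range=(0.15, 0.4, 0.01),
        d_range=(1.8, 3.5, 0.01),
        snr_range_db=(0.0, 15.0),
        seed=seed,
    )


def generate_pseudo_measured(
    spec_shifted: RandomizationSpec,
    manifest: pd.DataFrame,
    out_dir=None,
    radar_cfg: RadarConfig | None = None,
    rebound: bool = True,
    clutter: bool = True,
    feature_size: tuple[int, int] | None = (64, 64),
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Synthesize domain-gap fixtures for every row of a protocol manifest.

    Per-participant body parameters (H, W) are drawn once and shared across
    that participant's trials; each location gets its own sensor range and
    azimuth offset; fall trials carry a mattress-rebound transient and all
    trials a mains-clutter tone (both switchable).
    """
    cfg = radar_cfg or RadarConfig()
    ss = np.random.SeedSequence(spec_shifted.seed)
    setup_rng = np.random.default_rng(ss.spawn(1)[0])

    participants = sorted(manifest["participant_id"].unique())
    locations = sorted(manifest["location"].unique())
    body = {
        pid: (
            _grid_draw(setup_rng, spec_shifted.H_range),
            _grid_draw(setup_rng, spec_shifted.W_range),
        )
        for pid in participants
    }
    geom = {
        loc: (
            _grid_draw(setup_rng, spec_shifted.d_range),
            float(setup_rng.uniform(-30.0, 30.0)),  # azimuth offset, deg
        )
        for loc in locations
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "waveforms").mkdir(parents=True, exist_ok=True)
        (out_dir / "spectrograms").mkdir(parents=True, exist_ok=True)

    child_seeds = ss.spawn(len(manifest))
    rows, feats = [], []
    for k, (_, mrow) in enumerate(manifest.iterrows()):
        rng = np.random.default_rng(child_seeds[k])
        cls = mrow["class"]
        h_body, w_body = body[mrow["participant_id"]]
        d_loc, az_off = geom[mrow["location"]]
        phi = math.radians(((mrow["direction_deg"] + az_off + 180.0) % 360.0) - 180.0)
        if cls == "fall":
            params = FallTrialParams(
                body_height_H=h_body,
                body_width_W=w_body,
                v0=_grid_draw(rng, spec_shifted.v0_range),
                K=_grid_draw(rng, spec_shifted.K_range),
                fall_azimuth_phi=phi,
                sensor_range_d=d_loc,
                sensor_height_h=spec_shifted.sensor_height_h,
            )
        elif cls == "walk":
            params = GaitTrialParams(
                body_height_H=h_body,
                body_width_W=w_body,
                speed_factor_RV=_grid_draw(rng, spec_shifted.RV_range),
                heading_phi=phi,
                start_range_d=d_loc,
                sensor_height_h=spec_shifted.sensor_height_h,
            )
        else:
            params = BreathTrialParams(
                breathing_freq=_grid_draw(rng, spec_shifted.fb_range),
                chest_amplitude=float(rng.uniform(*spec_shifted.chest_amp_range)),
                facing_phi=phi,
                sensor_range_d=d_loc,
            )
        snr_db = float(rng.uniform(*spec_shifted.snr_range_db))
        sig, spg = synthesize_trial(
            params,
            cls,
            rng,
            snr_db,
            cfg,
            rebound=rebound,
            clutter=clutter,
            trial_id=str(mrow["trial_id"]),
        )
        row = dict(mrow)
        row.update(
            snr_db=round(snr_db, 3),
            params=json.dumps(_params_dict(params)),
            waveform_path="",
            spectrogram_path="",
        )
        if out_dir is not None:
            wav = out_dir / "waveforms" / f"{mrow['trial_id']}.wav"
            png = out_dir / "spectrograms" / f"{mrow['trial_id']}.png"
            write_iq_wav(wav, sig, cfg)
            write_spectrogram_png(png, spg)
            row["waveform_path"] = str(wav)
            row["spectrogram_path"] = str(png)
        if feature_size is not None:
            feats.append(_features(spg, feature_size))
        rows.append(row)

    out_manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_manifest.to_json(out_dir / "manifest.jsonl", orient="records", lines=True)
        out_manifest.to_csv(out_dir / "manifest.csv", index=False)
    X = np.stack(feats) if feats else None
    return out_manifest, X


def generate_noise_bank(
    n_samples: int = 20000, seed: int = 0, tone_hz: float = 50.0
) -> np.ndarray:
    """Complex noise + clutter excerpt for the noise-mixing augmentation.

    Recorded from the pseudo-measured generator's noise/clutter channel
    (white Gaussian noise plus the mains tone) — the artifact ships no
    measured noise.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / 1000.0
    tone = 0.3 * np.exp(1j * (2 * np.pi * tone_hz * t + rng.uniform(0, 2 * np.pi)))
    noise = rng.normal(0, 1.0, n_samples) + 1j * rng.normal(0, 1.0, n_samples)
    return tone + noise
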