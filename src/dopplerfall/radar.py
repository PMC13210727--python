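"""CW Doppler radar baseband synthesis.

A continuous-wave radar at carrier f0 observing a target at effective range
D(t) produces, after I/Q demodulation and low-pass removal of the
sum-frequency term, the baseband pair

    I*(t) = alpha(t) sin(phi_d(t)) + n_I(t)
    Q*(t) = alpha(t) cos(phi_d(t)) + n_Q(t)

with Doppler phase phi_d(t) = 4 pi f0 D(t) / c, so the instantaneous
baseband frequency is f_d = 2 f0 v(t) / c for radial velocity v.  The
amplitude alpha(t) lumps reflectivity, antenna/receiver gain and
range-dependent attenuation; only D(t) enters the phase.  The sum-frequency
term near 2 f0 is not synthesized (it is removed by the receiver's low-pass
filter), and the start-stop approximation is used (range change within one
round trip is neglected).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "RadarConfig",
    "RangeSeries",
    "BasebandSignal",
    "doppler_phase",
    "amplitude_model",
    "noise_sigma_for_snr",
    "synthesize_iq",
    "write_iq_wav",
    "read_iq_wav",
]


@dataclass(frozen=True)
class RadarConfig:
    """Radar carrier and sampling parameters (24 GHz CW sensor defaults)."""

    carrier_f0: float = 24e9
    sampling_rate: float = 1000.0
    speed_of_light_c: float = 299792458.0
    initial_phase_os: float = 0.0

    def __post_init__(self) -> None:
        if self.carrier_f0 <= 0 or self.sampling_rate <= 0:
            raise ValueError("carrier_f0 and sampling_rate must be positive")


@dataclass
class RangeSeries:
    """Uniformly sampled effective range of one trial."""

    times: np.ndarray
    range_D: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.range_D = np.asarray(self.range_D, dtype=float)
        if self.times.shape != self.range_D.shape:
            raise ValueError("times and range_D must have equal length")
        if np.any(self.range_D <= 0):
            raise ValueError("range_D must be strictly positive")


@dataclass
class BasebandSignal:
    """Two-channel I/Q baseband waveform with its generating parameters."""

    times: np.ndarray
    channel_I: np.ndarray
    channel_Q: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.channel_I) == len(self.channel_Q)):
            raise ValueError("times, I and Q must have equal length")

    @property
    def complex_baseband(self) -> np.ndarray:
        """s(t) = I(t) + j Q(t), the classifier-input signal."""
        return self.channel_I + 1j * self.channel_Q


def doppler_phase(rs: RangeSeries, cfg: RadarConfig) -> np.ndarray:
    """Continuous (unwrapped-by-construction) Doppler phase, rad per sample.

    phi_d(t) = 4 pi f0 D(t) / c + os.  No wrapping is applied at synthesis;
    wrapping happens implicitly in sin/cos.
    """
    return (
        4.0 * np.pi * cfg.carrier_f0 * rs.range_D / cfg.speed_of_light_c
        + cfg.initial_phase_os
    )


def amplitude_model(rs: RangeSeries, alpha0: float, attenuation_exponent: float = 2.0) -> np.ndarray:
    """Power-law range attenuation alpha(t) = alpha0 / D(t)^p.

    The functional form is a modelling choice (reflectivity and gain are not
    separately identifiable in CW baseband); p = 0 disables attenuation.
    """
    if alpha0 <= 0:
        raise ValueError("alpha0 must be positive")
    return alpha0 / rs.range_D**attenuation_exponent


def noise_sigma_for_snr(alpha: np.ndarray, snr_db: float) -> float:
    """Per-channel Gaussian noise std achieving the target SNR.

    Signal power of the noise-free complex baseband is mean(alpha^2); total
    noise power over both channels is 2 sigma^2.
    """
    p_sig = float(np.mean(np.asarray(alpha) ** 2))
    return float(np.sqrt(p_sig / (2.0 * 10.0 ** (snr_db / 10.0))))


def synthesize_iq(
    phase: np.ndarray,
    amplitude_alpha,
    noise_sigma: float,
    seed=None,
    sampling_rate: float = 1000.0,
    meta: dict | None = None,
) -> BasebandSignal:
    """Synthesize I = alpha sin(phi) + n_I, Q = alpha cos(phi) + n_Q.

    ``amplitude_alpha`` may be scalar or per-sample; noise is i.i.d.
    zero-mean Gaussian per channel with std ``noise_sigma``, reproducible
    under ``seed`` (an int or a numpy Generator).
    """
    phase = np.asarray(phase, dtype=float)
    alpha = np.broadcast_to(np.asarray(amplitude_alpha, dtype=float), phase.shape)
    if np.asarray(amplitude_alpha).ndim > 0 and len(np.asarray(amplitude_alpha)) != len(phase):
        raise ValueError("phase and amplitude_alpha must have equal length")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")

    i_sig = alpha * np.sin(phase)
    q_sig = alpha * np.cos(phase)
    if noise_sigma > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        i_sig = i_sig + rng.normal(0.0, noise_sigma, phase.shape)
        q_sig = q_sig + rng.normal(0.0, noise_sigma, phase.shape)

    times = np.arange(len(phase)) / sampling_rate
    return BasebandSignal(
        times=times,
        channel_I=i_sig,
        channel_Q=q_sig,
        meta=dict(meta or {}, noise_sigma=float(noise_sigma)),
    )


def write_iq_wav(path, sig: BasebandSignal, cfg: RadarConfig | None = None) -> None:
    """Write a 2-channel float32 WAV (ch0 = I, ch1 = Q) plus a JSON sidecar."""
    path = Path(path)
    rate = int(round(1.0 / np.diff(sig.times[:2])[0])) if len(sig.times) > 1 else 1000
    data = np.stack([sig.channel_I, sig.channel_Q], axis=1).astype(np.float32)
    wavfile.write(path, rate, data)
    sidecar = {"meta": _jsonable(sig.meta)}
    if cfg is not None:
        sidecar["radar_config"] = asdict(cfg)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_iq_wav(path) -> BasebandSignal:
    path = Path(path)
    rate, data = wavfile.read(path)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text()).get("meta", {})
    times = np.arange(data.shape[0]) / float(rate)
    return BasebandSignal(
        times=times,
        channel_I=data[:, 0].astype(float),
        channel_Q=data[:, 1].astype(float),
        meta=meta,
    )


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        elif isinstance(v, np.ndarray):
            v = v.tolist()
        out[k] = v
    return out
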