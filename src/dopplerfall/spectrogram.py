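"""STFT spectrograms of complex baseband, normalization, and augmentation.

Every trial — simulated, pseudo-measured, or augmented — is routed through
the same pipeline: Hann-windowed STFT of s(t) = I + jQ with a 0.5 s window
and 0.1 s hop, magnitudes folded into the 0-500 Hz band, log-magnitude +
min-max normalization and a bilinear resize to 224 x 224.

The complex baseband has a two-sided spectrum (approach and recession map
to opposite frequency signs); to keep both inside the 0-500 Hz band the
default folds by taking, for each |f|, the elementwise maximum of the +f
and -f magnitudes.  ``band_mode`` exposes positive-only and sum folding as
alternatives.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import signal as sps
from skimage.transform import resize as sk_resize

from .radar import BasebandSignal

__all__ = [
    "Spectrogram",
    "stft_spectrogram",
    "normalize_resize",
    "preprocess",
    "augment",
    "write_spectrogram_png",
    "read_spectrogram_png",
]

LOG_EPS_REL = 1e-10  # floor relative to per-spectrogram max before log


@dataclass
class Spectrogram:
    """Time-frequency magnitude matrix [freq_bins x time_frames]."""

    magnitude: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray
    normalized: bool = False
    source_trial: str | None = None
    meta: dict = field(default_factory=dict)


def stft_spectrogram(
    sig: BasebandSignal,
    window_s: float = 0.5,
    hop_s: float = 0.1,
    band_mode: str = "fold-max",
    max_freq: float = 500.0,
) -> Spectrogram:
    """Hann STFT of the complex baseband, folded into [0, max_freq] Hz.

    Only fully supported frames are produced: n_frames =
    floor((L - window) / hop) + 1.  Magnitude (not power) is retained.
    """
    if band_mode not in ("fold-max", "fold-sum", "positive-only"):
        raise ValueError(f"unknown band_mode {band_mode!r}")
    fs = 1.0 / float(np.diff(sig.times[:2])[0]) if len(sig.times) > 1 else 1000.0
    nperseg = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    s = sig.complex_baseband
    if len(s) < nperseg:
        raise ValueError(
            f"signal too short for STFT: {len(s)} samples < window of {nperseg}"
        )
    freqs, times, z = sps.stft(
        s,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg - hop,
        boundary=None,
        padded=False,
        return_onesided=False,
    )
    mag = np.abs(z)

    # fold the two-sided axis into [0, max_freq]
    order = np.argsort(freqs)
    freqs, mag = freqs[order], mag[order]
    df = fs / nperseg
    pos_mask = (freqs >= -df / 4) & (freqs <= max_freq + df / 4)
    out_f = freqs[pos_mask]
    out = mag[pos_mask].copy()
    if band_mode != "positive-only":
        # index of -f in the sorted axis, where present (freqs are on a
        # uniform df grid starting at freqs[0])
        neg_idx = np.round((-out_f - freqs[0]) / df).astype(int)
        valid = (neg_idx >= 0) & (neg_idx < len(freqs)) & (out_f > df / 4)
        folded = np.where(
            valid[:, None], mag[np.clip(neg_idx, 0, len(freqs) - 1)], 0.0
        )
        out = np.maximum(out, folded) if band_mode == "fold-max" else out + folded
        # Nyquist (-fs/2) belongs at the top of the band when absent from +freqs
        if out_f[-1] < max_freq - df / 4 and np.isclose(freqs[0], -fs / 2.0):
            out = np.vstack([out, mag[0][None, :]])
            out_f = np.append(out_f, fs / 2.0)

    return Spectrogram(
        magnitude=out,
        freq_axis=out_f,
        time_axis=times,
        normalized=False,
        source_trial=sig.meta.get("trial_id"),
        meta={"band_mode": band_mode, "window_s": window_s, "hop_s": hop_s},
    )


def normalize_resize(spec: Spectrogram, size: tuple[int, int] = (224, 224)) -> Spectrogram:
    """log-magnitude + min-max to [0, 1], then bilinear resize.

    A constant input (no dynamic range) yields an all-zero image with a
    warning rather than an error.
    """
    mag = np.asarray(spec.magnitude, dtype=float)
    if mag.size == 0:
        raise ValueError("empty spectrogram")
    if spec.normalized:
        # idempotent: already log-scaled and min-max pinned, only resize
        norm = mag
    else:
        peak = mag.max()
        logm = np.log(mag + LOG_EPS_REL * (peak if peak > 0 else 1.0))
        lo, hi = logm.min(), logm.max()
        if hi - lo <= 0:
            warnings.warn("constant spectrogram: normalized output is all zeros")
            norm = np.zeros_like(logm)
        else:
            norm = (logm - lo) / (hi - lo)
    if size is not None and norm.shape != tuple(size):
        norm = sk_resize(norm, size, order=1, preserve_range=True, anti_aliasing=False)
        span = norm.max() - norm.min()
        if span > 0:  # re-pin the min-max contract after interpolation
            norm = (norm - norm.min()) / span
    return Spectrogram(
        magnitude=norm,
        freq_axis=np.linspace(spec.freq_axis[0], spec.freq_axis[-1], norm.shape[0]),
        time_axis=np.linspace(spec.time_axis[0], spec.time_axis[-1], norm.shape[1]),
        normalized=True,
        source_trial=spec.source_trial,
        meta=dict(spec.meta),
    )


def preprocess(sig: BasebandSignal, size=(224, 224), band_mode: str = "fold-max") -> Spectrogram:
    """The single preprocessing path used for every trial source."""
    return normalize_resize(stft_spectrogram(sig, band_mode=band_mode), size=size)


# ---------------------------------------------------------------- augmentation

KNOWN_OPS = ("amplitude_scale", "time_shift", "noise_mix", "tf_mask")


def augment(
    obj,
    ops,
    rng: np.random.Generator | int | None = None,
    scale_range=(0.7, 1.3),
    max_shift_frac: float = 0.10,
    noise_bank: np.ndarray | None = None,
    mix_snr_db_range=(5.0, 20.0),
    max_masks: int = 2,
    max_mask_frac: float = 0.15,
):
    """Apply a subset of the four augmentation operators.

    Waveform ops (amplitude_scale, time_shift, noise_mix) act on a
    BasebandSignal; tf_mask acts on a Spectrogram.  An empty op set is the
    identity.  ``noise_bank`` is a complex (or 2-column real) array of
    recorded noise samples for the noise-mixing op.
    """
    ops = list(ops)
    for op in ops:
        if op not in KNOWN_OPS:
            raise ValueError(f"unknown augmentation op {op!r}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    if isinstance(obj, BasebandSignal):
        i, q = obj.channel_I.copy(), obj.channel_Q.copy()
        for op in ops:
            if op == "amplitude_scale":
                g = rng.uniform(*scale_range)
                i, q = g * i, g * q
            elif op == "time_shift":
                n = len(i)
                shift = rng.integers(-int(max_shift_frac * n), int(max_shift_frac * n) + 1)
                i, q = np.roll(i, shift), np.roll(q, shift)
            elif op == "noise_mix":
                if noise_bank is None:
                    raise ValueError("noise_mix requires a noise_bank")
                bank = np.asarray(noise_bank)
                if bank.ndim == 2:
                    bank = bank[:, 0] + 1j * bank[:, 1]
                start = rng.integers(0, max(1, len(bank) - len(i)))
                chunk = np.resize(bank[start:], len(i))
                p_sig = np.mean(i**2 + q**2)
                p_noise = np.mean(np.abs(chunk) ** 2)
                if p_noise > 0:
                    snr = rng.uniform(*mix_snr_db_range)
                    g = np.sqrt(p_sig / (p_noise * 10.0 ** (snr / 10.0)))
                    i = i + g * chunk.real
                    q = q + g * chunk.imag
        return BasebandSignal(times=obj.times, channel_I=i, channel_Q=q, meta=dict(obj.meta))

    if isinstance(obj, Spectrogram):
        mag = obj.magnitude.copy()
        for op in ops:
            if op != "tf_mask":
                raise ValueError(f"op {op!r} applies to waveforms, not spectrograms")
            nf, nt = mag.shape
            for _ in range(int(rng.integers(0, max_masks + 1))):
                df = int(rng.integers(0, int(max_mask_frac * nf) + 1))
                dt = int(rng.integers(0, int(max_mask_frac * nt) + 1))
                if df == 0 or dt == 0:
                    continue
                f0 = int(rng.integers(0, nf - df + 1))
                t0 = int(rng.integers(0, nt - dt + 1))
                mag[f0 : f0 + df, t0 : t0 + dt] = 0.0
        return Spectrogram(
            magnitude=mag,
            freq_axis=obj.freq_axis,
            time_axis=obj.time_axis,
            normalized=obj.normalized,
            source_trial=obj.source_trial,
            meta=dict(obj.meta),
        )

    raise TypeError(f"cannot augment object of type {type(obj).__name__}")


# ----------------------------------------------------------------------- I/O


def write_spectrogram_png(path, spec: Spectrogram) -> None:
    """16-bit grayscale PNG of a normalized spectrogram plus JSON sidecar."""
    if not spec.normalized:
        raise ValueError("write normalized spectrograms only")
    path = Path(path)
    img = (np.clip(spec.magnitude, 0.0, 1.0) * 65535.0).round().astype(np.uint16)
    Image.fromarray(img).save(path)
    path.with_suffix(".json").write_text(
        json.dumps(
            {
                "freq_axis_hz": [float(spec.freq_axis[0]), float(spec.freq_axis[-1])],
                "time_axis_s": [float(spec.time_axis[0]), float(spec.time_axis[-1])],
                "source_trial": spec.source_trial,
            }
        )
    )


def read_spectrogram_png(path) -> Spectrogram:
    path = Path(path)
    img = np.asarray(Image.open(path), dtype=float) / 65535.0
    f0f1, t0t1, src = (0.0, 500.0), (0.0, 1.0), None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        d = json.loads(sidecar.read_text())
        f0f1, t0t1, src = d["freq_axis_hz"], d["time_axis_s"], d.get("source_trial")
    return Spectrogram(
        magnitude=img,
        freq_axis=np.linspace(f0f1[0], f0f1[1], img.shape[0]),
        time_axis=np.linspace(t0t1[0], t0t1[1], img.shape[1]),
        normalized=True,
        source_trial=src,
    )
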