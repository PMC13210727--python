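"""Quantitative similarity between two Doppler spectrograms.

Spectrogram pairs (e.g. simulated vs. measured trials of the same action)
are compared after time normalization — linear resampling of each
spectrogram's time axis to a common number of frames, since trial durations
differ across subjects.  Four metrics are reported:

* SSIM of the normalized log-magnitude images (standard Gaussian-weighted
  variant, sigma = 1.5, K1 = 0.01, K2 = 0.03, dynamic range 1);
* Doppler-ridge MAE — mean |ridge_a(t) - ridge_b(t)| in Hz, where the ridge
  is the per-frame frequency bin of maximum magnitude above a DC cut;
* peak-Doppler error — |max_t ridge_a - max_t ridge_b|, computed on ridge
  maxima so an isolated noise pixel cannot dominate;
* spectral-centroid error — mean per-frame |centroid_a - centroid_b| with
  centroid = sum(f * m) / sum(m) over f > dc_cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import interp1d
from skimage.metrics import structural_similarity

from .spectrogram import Spectrogram, normalize_resize

__all__ = ["MetricsReport", "RidgeSeries", "time_normalize", "extract_ridge", "compare"]

DEFAULT_DC_CUT = 10.0  # Hz; ~6 cm/s radial velocity, below any fall/walk Doppler
DEFAULT_N_FRAMES = 64


@dataclass
class MetricsReport:
    ssim: float
    ridge_mae: float
    peak_doppler_error: float
    centroid_error: float
    n_frames_compared: int


@dataclass
class RidgeSeries:
    frame_times: np.ndarray
    ridge_freq: np.ndarray


def time_normalize(
    a: Spectrogram, b: Spectrogram, n_frames: int = DEFAULT_N_FRAMES
) -> tuple[Spectrogram, Spectrogram]:
    """Resample both spectrograms' time axes to ``n_frames`` frames."""
    return _resample(a, n_frames), _resample(b, n_frames)


def _resample(spec: Spectrogram, n_frames: int) -> Spectrogram:
    t = np.asarray(spec.time_axis, dtype=float)
    if len(t) < 2:
        raise ValueError("spectrogram must have at least 2 frames")
    new_t = np.linspace(t[0], t[-1], n_frames)
    mag = interp1d(t, spec.magnitude, axis=1, assume_sorted=True)(new_t)
    return Spectrogram(
        magnitude=mag,
        freq_axis=spec.freq_axis,
        time_axis=new_t,
        normalized=spec.normalized,
        source_trial=spec.source_trial,
        meta=dict(spec.meta),
    )


def extract_ridge(spec: Spectrogram, dc_cut: float = DEFAULT_DC_CUT) -> RidgeSeries:
    """Per-frame frequency of maximum magnitude above the DC cut.

    Ties resolve to the lowest frequency (argmax takes the first maximum on
    an ascending frequency axis).
    """
    mask = np.asarray(spec.freq_axis) > dc_cut
    if not np.any(mask):
        raise ValueError("dc_cut removes every frequency bin")
    sub = np.asarray(spec.magnitude)[mask]
    freqs = np.asarray(spec.freq_axis)[mask]
    return RidgeSeries(
        frame_times=np.asarray(spec.time_axis), ridge_freq=freqs[np.argmax(sub, axis=0)]
    )


def _spectral_centroid(spec: Spectrogram, dc_cut: float) -> np.ndarray:
    mask = np.asarray(spec.freq_axis) > dc_cut
    m = np.asarray(spec.magnitude)[mask]
    f = np.asarray(spec.freq_axis)[mask]
    denom = m.sum(axis=0)
    denom = np.where(denom > 0, denom, 1.0)
    return (f[:, None] * m).sum(axis=0) / denom


def compare(
    a: Spectrogram,
    b: Spectrogram,
    dc_cut: float = DEFAULT_DC_CUT,
    n_frames: int = DEFAULT_N_FRAMES,
) -> MetricsReport:
    """Time-normalize then compute all four similarity metrics.

    Raises on an all-zero input, naming the offending spectrogram.
    """
    for name, s in (("a", a), ("b", b)):
        if not np.any(np.asarray(s.magnitude) > 0):
            raise ValueError(f"spectrogram {name!r} is all-zero")

    an, bn = time_normalize(a, b, n_frames)
    # SSIM on normalized log-magnitude images
    a_img = an if an.normalized else normalize_resize(an, size=None)
    b_img = bn if bn.normalized else normalize_resize(bn, size=None)
    if a_img.magnitude.shape != b_img.magnitude.shape:
        raise ValueError("spectrograms must share a frequency axis for SSIM")
    ssim = structural_similarity(
        a_img.magnitude,
        b_img.magnitude,
        data_range=1.0,
        gaussian_weights=True,
        sigma=1.5,
        use_sample_covariance=False,
        K1=0.01,
        K2=0.03,
    )

    ridge_a = extract_ridge(an, dc_cut).ridge_freq
    ridge_b = extract_ridge(bn, dc_cut).ridge_freq
    cent_a = _spectral_centroid(an, dc_cut)
    cent_b = _spectral_centroid(bn, dc_cut)
    return MetricsReport(
        ssim=float(ssim),
        ridge_mae=float(np.mean(np.abs(ridge_a - ridge_b))),
        peak_doppler_error=float(abs(ridge_a.max() - ridge_b.max())),
        centroid_error=float(np.mean(np.abs(cent_a - cent_b))),
        n_frames_compared=n_frames,
    )
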