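"""Power spectra and aperiodic/periodic spectral parameterization.

Spectra come from 6-s Hanning-tapered epochs with 50% overlap, zero-padded
so the FFT grid contains exact 0.2-Hz multiples, averaged and restricted
to 1-45 Hz. Each channel spectrum is then decomposed, in log10-log10
space, into an aperiodic component 10^b / f^x (knee fixed at 0, so the
log-log slope is -x) plus at most three Gaussian oscillatory peaks:

1. robust aperiodic fit — an initial linear fit is refined on the points
   whose positive residual is below a low percentile, which discounts
   oscillatory peaks;
2. iterative Gaussian peak extraction on the flattened spectrum, honouring
   the maximum peak count, minimum height and width limits;
3. a final aperiodic refit on the peak-subtracted spectrum.

The reported "spectral slope" is -x throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .core import Hypnogram, Recording, STAGE_ORDER

FREQ_RANGE = (1.0, 45.0)
FREQ_RESOLUTION = 0.2
FLATTEN_RANGE = (1.0, 20.0)

#: Frequency bands used on the flattened (aperiodic-corrected) spectrum.
BANDS = {
    "delta": (1.0, 4.0),
    "alpha_cluster": (5.8, 11.3),
    "spindle_cluster": (11.5, 15.2),
}


@dataclass
class SpectrumSet:
    power: np.ndarray       # (n_channels, n_freqs), µV²/Hz
    frequencies: np.ndarray
    channel_names: list[str]
    n_epochs_averaged: int
    provenance: str = "whole-nap"  # or "deepest-stage"

    def row(self, channel: str) -> np.ndarray:
        return self.power[self.channel_names.index(channel)]


@dataclass
class SpectralFit:
    offset: float                   # b, log10(µV²/Hz)
    exponent: float                 # x >= 0; slope = -x
    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    fit_error: float = float("nan")  # RMSE in log10 space
    converged: bool = True
    knee: float = 0.0

    @property
    def slope(self) -> float:
        return -self.exponent

    def aperiodic_log10(self, freqs: np.ndarray) -> np.ndarray:
        return self.offset - self.exponent * np.log10(freqs)


# ---------------------------------------------------------------------------
# epoching and PSD
# ---------------------------------------------------------------------------

def epoch_signal(
    recording: Recording,
    epoch_s: float = 6.0,
    overlap: float = 0.5,
    hypnogram: Hypnogram | None = None,
    stage: str | None = None,
) -> np.ndarray:
    """Slice a recording into overlapping epochs -> (n_epochs, n_ch, n_samp).

    With a hypnogram and target stage, only windows fully contained in a
    contiguous run of 30-s scoring epochs of that stage are kept, so no
    window mixes stages.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    fs = recording.sampling_rate
    n_samp = int(round(epoch_s * fs))
    if recording.samples.shape[1] < n_samp:
        raise ValueError("recording shorter than one epoch")
    stride = int(round(n_samp * (1.0 - overlap)))

    if stage is None:
        segments = [(0, recording.samples.shape[1])]
    else:
        if hypnogram is None:
            raise ValueError("stage restriction requires a hypnogram")
        ep_len = int(round(hypnogram.epoch_length * fs))
        segments = []
        run_start = None
        for i, lab in enumerate(hypnogram.epoch_labels):
            if lab == stage and run_start is None:
                run_start = i
            elif lab != stage and run_start is not None:
                segments.append((run_start * ep_len, i * ep_len))
                run_start = None
        if run_start is not None:
            segments.append(
                (run_start * ep_len, len(hypnogram.epoch_labels) * ep_len)
            )
    out = []
    for s0, s1 in segments:
        s1 = min(s1, recording.samples.shape[1])
        start = s0
        while start + n_samp <= s1:
            out.append(recording.samples[:, start : start + n_samp])
            start += stride
    if not out:
        return np.empty((0, recording.samples.shape[0], n_samp))
    return np.stack(out)


def compute_psd(
    epochs: np.ndarray,
    sampling_rate: float,
    channel_names: list[str] | None = None,
    fmin: float = FREQ_RANGE[0],
    fmax: float = FREQ_RANGE[1],
    resolution: float = FREQ_RESOLUTION,
    provenance: str = "whole-nap",
) -> SpectrumSet:
    """Average Hanning-tapered periodograms on an exact ``resolution`` grid.

    Epochs are zero-padded to the smallest length whose FFT grid contains
    every multiple of ``resolution``; the 6-s / 200-Hz default pads 1200
    samples to 2000 (a 0.1-Hz grid) and keeps every 0.2-Hz bin.
    """
    if epochs.ndim != 3 or epochs.shape[0] == 0:
        raise ValueError("epochs must be a non-empty (n_epochs, n_ch, n_samp) array")
    if sampling_rate < 2 * fmax:
        raise ValueError(
            f"sampling rate {sampling_rate} Hz cannot resolve {fmax} Hz"
        )
    n_ep, n_ch, n_samp = epochs.shape
    base = int(round(sampling_rate / resolution))
    nfft = base * math.ceil(n_samp / base)
    window = np.hanning(n_samp)
    u = np.sum(window**2)
    spec = np.fft.rfft(epochs * window, n=nfft, axis=-1)
    psd = (2.0 / (sampling_rate * u)) * np.abs(spec) ** 2
    psd = psd.mean(axis=0)  # average over epochs
    freqs = np.fft.rfftfreq(nfft, 1.0 / sampling_rate)
    step = nfft // base  # every step-th bin is an exact resolution multiple
    idx = np.arange(0, freqs.size, step)
    freqs = freqs[idx]
    psd = psd[:, idx]
    keep = (freqs >= fmin - 1e-9) & (freqs <= fmax + 1e-9)
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_ch)]
    return SpectrumSet(
        power=psd[:, keep],
        frequencies=freqs[keep],
        channel_names=list(channel_names),
        n_epochs_averaged=n_ep,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# spectral model fit
# ---------------------------------------------------------------------------

def _aperiodic(log_f: np.ndarray, b: float, x: float) -> np.ndarray:
    return b - x * log_f


def _fit_aperiodic(log_f: np.ndarray, log_p: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(log_f, log_p, 1)
    x0 = max(-slope, 0.0)
    try:
        popt, _ = curve_fit(
            _aperiodic, log_f, log_p, p0=[intercept, x0],
            bounds=([-np.inf, 0.0], [np.inf, np.inf]), maxfev=5000,
        )
        return float(popt[0]), float(popt[1])
    except RuntimeError:
        return float(intercept), float(x0)


def _robust_aperiodic(
    log_f: np.ndarray, log_p: np.ndarray, percentile: float
) -> tuple[float, float]:
    """Initial fit, then refit on points with low positive residual.

    Negative residuals are clipped to zero before thresholding, so the
    refit keeps the (majority) points at or below the initial fit and
    discards the oscillatory bumps above it.
    """
    b0, x0 = _fit_aperiodic(log_f, log_p)
    flat = log_p - _aperiodic(log_f, b0, x0)
    flat = np.where(flat < 0.0, 0.0, flat)
    thresh = np.percentile(flat, percentile)
    mask = flat <= thresh
    if mask.sum() < 2:
        return b0, x0
    return _fit_aperiodic(log_f[mask], log_p[mask])


def _gaussian_sum(freqs: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(freqs)
    for i in range(0, len(params), 3):
        cf, h, sd = params[i : i + 3]
        out += h * np.exp(-((freqs - cf) ** 2) / (2.0 * sd**2))
    return out


def fit_spectral_model(
    frequencies: np.ndarray,
    power: np.ndarray,
    max_n_peaks: int = 3,
    min_peak_height: float = 0.3,
    peak_threshold_sd: float = 2.0,
    peak_width_limits: tuple[float, float] = (0.5, 12.0),
    ap_percentile: float = 2.5,
) -> SpectralFit:
    """Two-stage aperiodic + Gaussian-peak decomposition of one spectrum.

    ``min_peak_height`` is in log10-power units (the 3-dB default equals
    0.3 bel); ``peak_width_limits`` bound the full width (2 sd) of each
    Gaussian in Hz. Raises on non-positive power values.
    """
    freqs = np.asarray(frequencies, dtype=float)
    power = np.asarray(power, dtype=float)
    if np.any(power <= 0.0):
        raise ValueError("power values must be strictly positive")
    log_f = np.log10(freqs)
    log_p = np.log10(power)

    b, x = _robust_aperiodic(log_f, log_p, ap_percentile)
    flat = log_p - _aperiodic(log_f, b, x)

    sd_lo, sd_hi = peak_width_limits[0] / 2.0, peak_width_limits[1] / 2.0
    guesses: list[tuple[float, float, float]] = []
    residual = flat.copy()
    for _ in range(max_n_peaks):
        i = int(np.argmax(residual))
        height = residual[i]
        if height < min_peak_height or height < peak_threshold_sd * np.std(residual):
            break
        cf = freqs[i]
        # estimate sd from the half-height crossing nearest the apex
        half = height / 2.0
        right = i
        while right + 1 < residual.size and residual[right + 1] > half:
            right += 1
        left = i
        while left - 1 >= 0 and residual[left - 1] > half:
            left -= 1
        fwhm = max(freqs[min(right, residual.size - 1)] - freqs[max(left, 0)],
                   FREQ_RESOLUTION)
        sd = float(np.clip(fwhm / 2.355, sd_lo, sd_hi))
        guesses.append((float(cf), float(height), sd))
        residual = residual - guesses[-1][1] * np.exp(
            -((freqs - cf) ** 2) / (2.0 * sd**2)
        )

    peaks: list[tuple[float, float, float]] = []
    converged = True
    if guesses:
        p0, lb, ub = [], [], []
        for cf, h, sd in guesses:
            p0 += [cf, h, sd]
            lb += [max(freqs[0], cf - 2.0 * sd), 0.0, sd_lo]
            ub += [min(freqs[-1], cf + 2.0 * sd), np.inf, sd_hi]
        try:
            popt, _ = curve_fit(
                _gaussian_sum, freqs, flat, p0=p0, bounds=(lb, ub), maxfev=10000
            )
            peaks = [
                (float(popt[i]), float(popt[i + 1]), float(popt[i + 2]))
                for i in range(0, len(popt), 3)
            ]
        except RuntimeError:
            peaks = guesses
            converged = False

    peak_model = _gaussian_sum(freqs, *[v for pk in peaks for v in pk])
    b, x = _fit_aperiodic(log_f, log_p - peak_model)
    model = _aperiodic(log_f, b, x) + peak_model
    rmse = float(np.sqrt(np.mean((log_p - model) ** 2)))
    peaks.sort(key=lambda pk: pk[0])
    return SpectralFit(
        offset=b, exponent=x, peaks=peaks, fit_error=rmse, converged=converged
    )


def flatten_spectrum(
    frequencies: np.ndarray,
    power: np.ndarray,
    fit: SpectralFit,
    fmax: float = FLATTEN_RANGE[1],
) -> tuple[np.ndarray, np.ndarray]:
    """log10 power minus the fitted aperiodic component, up to ``fmax`` Hz."""
    freqs = np.asarray(frequencies, dtype=float)
    keep = freqs <= fmax + 1e-9
    resid = np.log10(np.asarray(power, dtype=float)[keep]) - fit.aperiodic_log10(
        freqs[keep]
    )
    return freqs[keep], resid


def band_power(
    frequencies: np.ndarray, flattened: np.ndarray, band: tuple[float, float]
) -> float:
    """Mean flattened (periodic) power over an inclusive frequency band."""
    freqs = np.asarray(frequencies, dtype=float)
    lo, hi = band
    mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins")
    return float(np.mean(np.asarray(flattened)[mask]))


# ---------------------------------------------------------------------------
# cohort-level slope table
# ---------------------------------------------------------------------------

def subject_spectra(
    recording: Recording,
    hypnogram: Hypnogram | None = None,
    provenance: str = "whole-nap",
) -> SpectrumSet:
    """Channel spectra for one subject under the chosen epoch provenance."""
    if provenance == "whole-nap":
        epochs = epoch_signal(recording)
    elif provenance == "deepest-stage":
        if hypnogram is None:
            raise ValueError("deepest-stage provenance requires a hypnogram")
        epochs = epoch_signal(
            recording, hypnogram=hypnogram, stage=hypnogram.deepest_stage()
        )
    else:
        raise ValueError(f"unknown provenance {provenance!r}")
    if epochs.shape[0] == 0:
        raise ValueError("no epochs available under the requested provenance")
    return compute_psd(
        epochs,
        recording.sampling_rate,
        channel_names=recording.channel_names,
        provenance=provenance,
    )


def slope_per_subject(
    subjects: list,
    provenance: str = "whole-nap",
    **fit_kwargs,
):
    """Spectral slope (-x) per subject and channel as a DataFrame.

    ``subjects`` is an iterable of objects with ``subject_id``,
    ``recording`` and ``hypnogram`` attributes (e.g. simulated Subjects).
    Subjects without epochs under the requested provenance get NaN slopes.
    """
    import pandas as pd

    rows = {}
    for subj in subjects:
        if subj.recording is None:
            continue
        try:
            spec = subject_spectra(subj.recording, subj.hypnogram, provenance)
        except ValueError:
            rows[subj.subject_id] = {
                ch: float("nan") for ch in subj.recording.channel_names
            }
            continue
        rows[subj.subject_id] = {
            ch: fit_spectral_model(
                spec.frequencies, spec.row(ch), **fit_kwargs
            ).slope
            for ch in spec.channel_names
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def deepest_stage_of(hypnogram: Hypnogram) -> str:
    return max(hypnogram.epoch_labels, key=STAGE_ORDER.__getitem__)
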