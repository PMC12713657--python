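"""Deterministic signal conditioning.

Force calibration from known weights, fluorescence ΔF/F0 with neuropil
correction and a running-median baseline, EMG conditioning (high-pass,
rectify, Gaussian smoothing), and zero-phase Butterworth force filtering.

All filters are applied forward-backward (zero phase) so that event times
measured on the filtered traces are not shifted relative to the raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "CalibrationModel",
    "FluorescenceSet",
    "calibrate_force",
    "compute_dff",
    "gaussian_kernel",
    "highpass_filter_emg",
    "preprocess_emg",
    "lowpass_filter_force",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Linear load-cell calibration: force (g) = (voltage - baseline) * factor."""

    baseline_v: float
    conversion_g_per_v: float
    fit_residual_g: float


def calibrate_force(voltage, baseline_v, weights_table):
    """Calibrate a load-cell voltage trace against known weights.

    The conversion factor is the least-squares slope of grams against
    (volts - baseline) constrained through the origin: a sensor with no
    load reads the baseline voltage by definition.

    Parameters
    ----------
    voltage : array
        Raw voltage trace (volts).
    baseline_v : float
        No-load baseline voltage measured before the session.
    weights_table : sequence of (grams, volts)
        Known calibration weights and the voltages they produced.

    Returns
    -------
    (CalibrationModel, force)
        The fitted model and the calibrated force trace in grams.
    """
    table = np.asarray(weights_table, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2 or table.shape[0] < 2:
        raise ValueError("weights_table must hold at least two (grams, volts) pairs")
    grams = table[:, 0]
    dv = table[:, 1] - baseline_v
    denom = float(np.dot(dv, dv))
    if denom == 0.0:
        raise ValueError("all calibration weights produced the baseline voltage; singular fit")
    factor = float(np.dot(grams, dv) / denom)
    residual = float(np.sqrt(np.mean((grams - factor * dv) ** 2)))
    force = (np.asarray(voltage, dtype=float) - baseline_v) * factor
    return CalibrationModel(float(baseline_v), factor, residual), force


@dataclass
class FluorescenceSet:
    """Raw, neuropil, corrected fluorescence and derived ΔF/F0 matrices.

    All matrices are neurons x frames. ``dff_z`` is the per-neuron session
    z-score of ΔF/F0; a zero-variance neuron maps to zeros rather than NaN.
    """

    f_raw: np.ndarray
    f_neuropil: np.ndarray
    f_corrected: np.ndarray
    f0: np.ndarray
    dff: np.ndarray
    dff_z: np.ndarray


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running median along the last axis, truncated at the edges."""
    frame = pd.DataFrame(np.asarray(x, dtype=float).T)
    med = frame.rolling(window, center=True, min_periods=1).median()
    return med.to_numpy().T


def compute_dff(f_raw, f_neuropil, neuropil_coeff=0.7, baseline_window_s=60.0, frame_rate=30.0):
    """Neuropil-corrected ΔF/F0 with a running-median baseline.

    F_corrected = F_raw - 0.7 * F_neuropil; F0 is the centered one-minute
    running median of F_corrected (shorter windows at the session edges);
    ΔF/F0 = (F_corrected - F0) / F0, z-scored per neuron over the session.
    """
    f_raw = np.asarray(f_raw, dtype=float)
    f_neuropil = np.asarray(f_neuropil, dtype=float)
    if f_raw.shape != f_neuropil.shape:
        raise ValueError("f_raw and f_neuropil must share shape")
    if f_raw.ndim == 1:
        f_raw = f_raw[None, :]
        f_neuropil = f_neuropil[None, :]
    window = int(round(baseline_window_s * frame_rate))
    if window < 3:
        raise ValueError("baseline window must span at least 3 frames")
    window |= 1  # odd length: symmetric centered window
    f_corrected = f_raw - neuropil_coeff * f_neuropil
    f0 = _running_median(f_corrected, window)
    bad = np.argwhere(f0 <= 0)
    if bad.size:
        n, t = bad[0]
        raise ValueError(f"non-positive F0 baseline at neuron {n}, frame {t}; ΔF/F0 undefined")
    dff = (f_corrected - f0) / f0
    mu = dff.mean(axis=1, keepdims=True)
    sd = dff.std(axis=1, keepdims=True)
    dff_z = np.where(sd > 0, (dff - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return FluorescenceSet(f_raw, f_neuropil, f_corrected, f0, dff, dff_z)


def gaussian_kernel(sd_s: float, rate_hz: float) -> np.ndarray:
    """Discrete Gaussian smoothing kernel, truncated at ±4 SD, summing to 1."""
    if sd_s <= 0 or rate_hz <= 0:
        raise ValueError("kernel SD and rate must be positive")
    half = int(np.ceil(4.0 * sd_s * rate_hz))
    t = np.arange(-half, half + 1) / rate_hz
    k = np.exp(-0.5 * (t / sd_s) ** 2)
    return k / k.sum()


def highpass_filter_emg(x, fs_hz=1000.0, cutoff_hz=40.0, order=4):
    """Zero-phase Butterworth high-pass used by the EMG conditioning chain."""
    if cutoff_hz >= fs_hz / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=fs_hz, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def preprocess_emg(raw_emg, in_rate_hz=24000.0, out_rate_hz=1000.0,
                   highpass_hz=40.0, smooth_sd_s=0.025, order=4):
    """Condition raw multi-channel EMG into 1 kHz activity envelopes.

    Downsample to ``out_rate_hz``, zero-phase Butterworth high-pass at
    ``highpass_hz`` (order 4 single pass), full-wave rectify, then smooth
    with a unit-area Gaussian kernel (SD 25 ms).
    """
    x = np.atleast_2d(np.asarray(raw_emg, dtype=float))
    if in_rate_hz < 2 * highpass_hz:
        raise ValueError("input rate must be at least twice the high-pass cutoff")
    kernel = gaussian_kernel(smooth_sd_s, out_rate_hz)
    from fractions import Fraction

    ratio = Fraction(int(round(out_rate_hz)), int(round(in_rate_hz)))
    if ratio != 1:
        x = sps.resample_poly(x, ratio.numerator, ratio.denominator, axis=-1)
    if x.shape[-1] < 3 * kernel.size:
        raise ValueError("trace shorter than 3x the smoothing-kernel support")
    x = np.abs(highpass_filter_emg(x, out_rate_hz, highpass_hz, order))
    smoothed = np.empty_like(x)
    for i in range(x.shape[0]):
        smoothed[i] = np.convolve(x[i], kernel, mode="same")
    return smoothed


def lowpass_filter_force(force, fs_hz=1000.0, cutoff_hz=30.0, order=10, zero_phase=True):
    """Butterworth low-pass for force traces (DC gain 1).

    ``zero_phase=True`` applies the filter forward-backward, which preserves
    peak times but doubles the attenuation in dB; a single pass has the
    textbook -3 dB gain at the cutoff.
    """
    force = np.asarray(force, dtype=float)
    if cutoff_hz >= fs_hz / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = sps.butter(order, cutoff_hz, btype="lowpass", fs=fs_hz, output="sos")
    if zero_phase:
        padlen = 3 * (2 * sos.shape[0] + 1)
        if force.shape[-1] <= 3 * padlen:
            raise ValueError("trace too short for stable zero-phase filtering")
        return sps.sosfiltfilt(sos, force, axis=-1)
    return sps.sosfilt(sos, force, axis=-1)
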