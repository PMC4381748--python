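"""FT-ICR spectral front end: transient to calibrated, stitched peak list.

An FT-ICR cell records an induced-current transient whose component
frequencies are the cyclotron frequencies of the trapped ions.  One
replicate injection is acquired as seven overlapping selected-ion-monitoring
(SIM) windows spanning 70-590 Da (100 Da wide, 30 Da overlap).  Each
window's averaged transient is Hanning-apodised, zero-filled once and
Fourier transformed; peaks are picked above a signal-to-noise threshold of
3.5 (strictly greater), frequencies converted to m/z with the two-term
calibration

    m/z = A/f + B/f**2

(A set by the magnetic field, B absorbing space-charge effects), and the
seven windows are stitched into a single peak list, splicing each overlap
at its midpoint and keeping the higher-SNR peak when the same ion appears
on both sides of a splice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import CalibrantList, CalibrationUnavailable, PeakList

LN2 = math.log(2.0)


@dataclass(frozen=True)
class SimWindow:
    """One selected-ion-monitoring acquisition window."""

    index: int
    mz_low: float
    mz_high: float

    def __post_init__(self):
        if not 0 < self.mz_low < self.mz_high:
            raise ValueError("require 0 < mz_low < mz_high")

    def contains(self, mz) -> np.ndarray:
        mz = np.asarray(mz, dtype=float)
        return (mz >= self.mz_low) & (mz <= self.mz_high)


def default_windows(
    n: int = 7, start: float = 70.0, width: float = 100.0, overlap: float = 30.0
) -> list[SimWindow]:
    """The study's seven 100-Da windows with 30-Da overlaps, 70-590 Da."""
    step = width - overlap
    return [
        SimWindow(i + 1, start + i * step, start + i * step + width) for i in range(n)
    ]


@dataclass(frozen=True)
class Calibration:
    """Two-parameter frequency-to-m/z calibration, m/z = A/f + B/f^2."""

    A: float
    B: float
    source: str = "external"
    residual_rms_ppm: float | None = None
    n_calibrants: int = 0

    def __post_init__(self):
        if not self.A > 0:
            raise ValueError("calibration parameter A must be positive")
        if self.source not in ("internal", "external"):
            raise ValueError("calibration source must be internal or external")

    def mz(self, freq) -> np.ndarray:
        freq = np.asarray(freq, dtype=float)
        if np.any(freq <= 0):
            raise ValueError("frequencies must be positive")
        return self.A / freq + self.B / freq**2

    def freq(self, mz) -> np.ndarray:
        """Invert the calibration: the positive root of m*f^2 - A*f - B = 0."""
        mz = np.asarray(mz, dtype=float)
        if np.any(mz <= 0):
            raise ValueError("m/z must be positive")
        return (self.A + np.sqrt(self.A**2 + 4.0 * mz * self.B)) / (2.0 * mz)


@dataclass
class Transient:
    """Time-domain signal for one SIM window of one injection."""

    samples: np.ndarray
    sampling_rate: float
    window: SimWindow
    n_scans: int = 1
    default_calibration: Calibration | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("transient must be non-empty")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")


@dataclass
class FrequencySpectrum:
    """Magnitude spectrum on the positive-frequency half grid."""

    frequency: np.ndarray
    magnitude: np.ndarray
    window: SimWindow

    def __post_init__(self):
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if len(self.frequency) != len(self.magnitude):
            raise ValueError("frequency and magnitude lengths differ")
        df = np.diff(self.frequency)
        if len(df) and not (np.all(df > 0) and np.allclose(df, df[0])):
            raise ValueError("frequency grid must be uniform and ascending")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitudes must be non-negative")


# ---------------------------------------------------------------------------
# Transient conditioning
# ---------------------------------------------------------------------------

def average_transients(transients: Sequence[Transient]) -> Transient:
    """Pointwise arithmetic mean of same-window transients; scans are summed."""
    if not transients:
        raise ValueError("no transients to average")
    first = transients[0]
    for t in transients[1:]:
        if t.window != first.window:
            raise ValueError("cannot average transients from different windows")
        if len(t.samples) != len(first.samples) or t.sampling_rate != first.sampling_rate:
            raise ValueError("transients must share length and sampling rate")
    mean = np.mean([t.samples for t in transients], axis=0)
    return Transient(
        mean,
        first.sampling_rate,
        first.window,
        n_scans=sum(t.n_scans for t in transients),
        default_calibration=first.default_calibration,
    )


def apodize_hanning(transient: Transient) -> Transient:
    """Apply a Hanning window of the sample length (endpoints map to zero)."""
    w = np.hanning(len(transient.samples))
    return Transient(
        transient.samples * w,
        transient.sampling_rate,
        transient.window,
        transient.n_scans,
        transient.default_calibration,
    )


def zero_fill_once(transient: Transient) -> Transient:
    """Append zeros to exactly double the transient length."""
    n = len(transient.samples)
    return Transient(
        np.concatenate([transient.samples, np.zeros(n)]),
        transient.sampling_rate,
        transient.window,
        transient.n_scans,
        transient.default_calibration,
    )


def fft_magnitude(transient: Transient) -> FrequencySpectrum:
    """Magnitude FFT on the positive-frequency half grid (DC excluded)."""
    mag = np.abs(np.fft.rfft(transient.samples))
    freq = np.fft.rfftfreq(len(transient.samples), d=1.0 / transient.sampling_rate)
    return FrequencySpectrum(freq[1:], mag[1:], transient.window)


# ---------------------------------------------------------------------------
# Noise and peak picking
# ---------------------------------------------------------------------------

def estimate_noise(spectrum: FrequencySpectrum) -> float:
    """Robust noise scale: median(magnitude) / ln 2.

    For Rayleigh-distributed noise magnitudes (the FFT of white Gaussian
    noise) the median is sigma*sqrt(2 ln 2), so this convention is a fixed
    monotone rescaling of sigma that a handful of large signal bins cannot
    perturb.  Raises on an all-zero spectrum.
    """
    med = float(np.median(spectrum.magnitude))
    if med <= 0:
        raise ValueError("cannot estimate noise from an all-zero spectrum")
    return med / LN2


def pick_peaks(
    spectrum: FrequencySpectrum,
    snr_threshold: float = 3.5,
    noise_level: float | None = None,
    min_snr_keep: float = 1.0,
) -> PeakList:
    """Pick local maxima and flag those strictly above the SNR threshold.

    Every local maximum with SNR >= ``min_snr_keep`` is returned, with
    noise_flag 1 only when magnitude/noise is strictly greater than
    ``snr_threshold`` (a peak at exactly the threshold is flagged 0).  Peak
    frequencies are refined by three-point parabolic interpolation of the
    log-magnitude, which is near-exact for the Gaussian-like main lobe of a
    Hanning-windowed sinusoid.
    """
    if noise_level is None:
        noise_level = estimate_noise(spectrum)
    mag = spectrum.magnitude
    freq = spectrum.frequency
    if len(mag) < 3:
        return PeakList(np.array([]), np.array([]), np.array([]), np.array([], int))
    interior = np.arange(1, len(mag) - 1)
    is_max = (mag[interior] > mag[interior - 1]) & (mag[interior] >= mag[interior + 1])
    idx = interior[is_max]
    snr = mag[idx] / noise_level
    keep = snr >= min_snr_keep
    idx, snr = idx[keep], snr[keep]
    if idx.size == 0:
        return PeakList(np.array([]), np.array([]), np.array([]), np.array([], int))

    df = freq[1] - freq[0]
    with np.errstate(divide="ignore"):
        la = np.log(np.maximum(mag[idx - 1], 1e-300))
        lb = np.log(np.maximum(mag[idx], 1e-300))
        lc = np.log(np.maximum(mag[idx + 1], 1e-300))
    denom = la - 2.0 * lb + lc
    delta = np.where(np.abs(denom) > 0, 0.5 * (la - lc) / np.where(denom == 0, 1, denom), 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    f_ref = freq[idx] + delta * df
    intensity = np.exp(lb - 0.25 * (la - lc) * delta)

    flags = (snr > snr_threshold).astype(int)
    order = np.argsort(f_ref, kind="stable")
    f_ref, intensity, snr, flags = f_ref[order], intensity[order], snr[order], flags[order]
    uniq = np.concatenate([[True], np.diff(f_ref) > 0])
    return PeakList(f_ref[uniq], intensity[uniq], snr[uniq], flags[uniq])


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def fit_calibration(
    picked: PeakList,
    calibrants: CalibrantList,
    initial: Calibration,
    match_tolerance_ppm: float = 6.5,
) -> Calibration:
    """Fit (A, B) of m/z = A/f + B/f^2 from matched internal calibrants.

    Picked peak frequencies are converted to approximate m/z with the
    ``initial`` (external) calibration, each calibrant is matched to the
    nearest flagged peak within ``match_tolerance_ppm``, and (A, B) are
    estimated by least squares in the regressors (1/f, 1/f^2) with column
    scaling for conditioning.  Raises :class:`CalibrationUnavailable` with
    fewer than two matches; callers then fall back to external calibration.
    """
    flagged = picked.flagged()
    if len(flagged) == 0:
        raise CalibrationUnavailable("no flagged peaks to match against calibrants")
    approx_mz = initial.mz(flagged.mz)
    order = np.argsort(approx_mz)
    approx_sorted = approx_mz[order]
    matched_f, matched_m = [], []
    for mz_theo in calibrants.mz:
        j = np.searchsorted(approx_sorted, mz_theo)
        best, best_err = None, np.inf
        for k in (j - 1, j):
            if 0 <= k < len(approx_sorted):
                err = abs(approx_sorted[k] - mz_theo) / mz_theo * 1e6
                if err < best_err:
                    best, best_err = k, err
        if best is not None and best_err <= match_tolerance_ppm:
            matched_f.append(flagged.mz[order[best]])  # still frequency here
            matched_m.append(mz_theo)
    if len(matched_f) < 2:
        raise CalibrationUnavailable(
            f"only {len(matched_f)} calibrant(s) matched; need >= 2"
        )
    f = np.asarray(matched_f)
    m = np.asarray(matched_m)
    X = np.column_stack([1.0 / f, 1.0 / f**2])
    scale = np.abs(X).max(axis=0)
    coef, *_ = np.linalg.lstsq(X / scale, m, rcond=None)
    A, B = coef / scale
    fitted = A / f + B / f**2
    rms_ppm = float(np.sqrt(np.mean(((fitted - m) / m * 1e6) ** 2)))
    return Calibration(A=A, B=B, source="internal",
                       residual_rms_ppm=rms_ppm, n_calibrants=len(f))


def apply_calibration(picked: PeakList, calibration: Calibration) -> PeakList:
    """Convert a frequency-domain peak list to m/z, sorted ascending."""
    if len(picked) == 0:
        return PeakList(
            np.array([]), np.array([]), np.array([]), np.array([], int),
            sample_id=picked.sample_id, replicate_index=picked.replicate_index,
        )
    mz = calibration.mz(picked.mz)
    order = np.argsort(mz, kind="stable")
    mz = mz[order]
    uniq = np.concatenate([[True], np.diff(mz) > 0])
    return PeakList(
        mz[uniq],
        picked.intensity[order][uniq],
        picked.snr[order][uniq],
        picked.noise_flag[order][uniq],
        sample_id=picked.sample_id,
        replicate_index=picked.replicate_index,
    )


# ---------------------------------------------------------------------------
# Stitching
# ---------------------------------------------------------------------------

def stitch(
    window_peaklists: Sequence[tuple[SimWindow, PeakList]],
    mz_tolerance_ppm: float = 1.5,
) -> PeakList:
    """Combine calibrated per-window peak lists into one list.

    Each window contributes its exclusive m/z region plus half of each
    shared overlap (splice at the overlap midpoint, where edge
    mis-calibration is smallest).  Residual duplicates within the ppm
    tolerance across a splice are merged keeping the higher-SNR peak.
    """
    if not window_peaklists:
        raise ValueError("no windows to stitch")
    items = sorted(window_peaklists, key=lambda wp: wp[0].mz_low)
    windows = [w for w, _ in items]
    indices = sorted(w.index for w in windows)
    expected = list(range(min(indices), max(indices) + 1))
    if indices != expected:
        missing = sorted(set(expected) - set(indices))
        raise ValueError(f"missing or duplicated SIM windows: {missing or indices}")
    for a, b in zip(windows, windows[1:]):
        if b.mz_low >= a.mz_high:
            raise ValueError(
                f"windows {a.index} and {b.index} do not overlap: coverage gap"
            )

    mz_all, int_all, snr_all, flag_all = [], [], [], []
    for i, (w, pl) in enumerate(items):
        lo = -np.inf if i == 0 else (items[i - 1][0].mz_high + w.mz_low) / 2.0
        hi = np.inf if i == len(items) - 1 else (w.mz_high + items[i + 1][0].mz_low) / 2.0
        keep = (pl.mz >= lo) & (pl.mz < hi)
        mz_all.append(pl.mz[keep])
        int_all.append(pl.intensity[keep])
        snr_all.append(pl.snr[keep])
        flag_all.append(pl.noise_flag[keep])
    mz = np.concatenate(mz_all)
    inten = np.concatenate(int_all)
    snr = np.concatenate(snr_all)
    flag = np.concatenate(flag_all)
    order = np.argsort(mz, kind="stable")
    mz, inten, snr, flag = mz[order], inten[order], snr[order], flag[order]

    keep_idx: list[int] = []
    for i in range(len(mz)):
        if keep_idx and (mz[i] - mz[keep_idx[-1]]) <= mz_tolerance_ppm * 1e-6 * mz[i]:
            if snr[i] > snr[keep_idx[-1]]:
                keep_idx[-1] = i
        else:
            keep_idx.append(i)
    k = np.array(keep_idx, dtype=int)
    sid = items[0][1].sample_id
    rep = items[0][1].replicate_index
    return PeakList(mz[k], inten[k], snr[k], flag[k], sample_id=sid, replicate_index=rep)


# ---------------------------------------------------------------------------
# Per-replicate convenience chain
# ---------------------------------------------------------------------------

def process_replicate(
    window_transients: dict[int, Sequence[Transient]],
    calibrants: CalibrantList | None = None,
    snr_threshold: float = 3.5,
    calibrant_tolerance_ppm: float = 6.5,
    mz_tolerance_ppm: float = 1.5,
) -> PeakList:
    """Average, apodise, transform, pick, calibrate and stitch one replicate.

    ``window_transients`` maps window index to the transients acquired for
    that window.  Internal calibration is attempted per window when a
    calibrant list is given; windows without two matched calibrants fall
    back to their transient's default (external) calibration.
    """
    per_window = []
    for _, transients in sorted(window_transients.items()):
        avg = average_transients(list(transients))
        spec = fft_magnitude(zero_fill_once(apodize_hanning(avg)))
        picked = pick_peaks(spec, snr_threshold=snr_threshold)
        cal = avg.default_calibration
        if cal is None:
            raise ValueError(f"window {avg.window.index} lacks a default calibration")
        if calibrants is not None:
            try:
                cal = fit_calibration(
                    picked, calibrants, cal, match_tolerance_ppm=calibrant_tolerance_ppm
                )
            except CalibrationUnavailable:
                pass
        calibrated = apply_calibration(picked, cal)
        in_window = avg.window.contains(calibrated.mz)
        per_window.append(
            (
                avg.window,
                PeakList(
                    calibrated.mz[in_window],
                    calibrated.intensity[in_window],
                    calibrated.snr[in_window],
                    calibrated.noise_flag[in_window],
                ),
            )
        )
    return stitch(per_window, mz_tolerance_ppm=mz_tolerance_ppm)
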