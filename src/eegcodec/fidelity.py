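"""Fidelity metrics for reconstructed EEG: PRD, SNR, PSNR, RMSE, CC, PSD.

All logarithms are base-10 decibels.  The headline distortion metric is the
percent root-mean-square difference

    PRD = 100 * sqrt( sum (X - X~)^2 / sum X^2 ),

with SNR = -20 log10(0.01 PRD) (equivalently 10 log10 of the energy ratio),
PSNR = 20 log10(max|X| / RMSE), and CC the Pearson correlation between
original and reconstruction.  Spectral resemblance — the property a
clinician reads diagnostic rhythms from — is summarised as the RMS
difference of the Welch log-spectra over bins carrying appreciable power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .records import EEGRecord

__all__ = [
    "FidelityReport",
    "prd",
    "snr_from_prd",
    "rmse",
    "psnr",
    "cross_correlation",
    "psd",
    "psd_distance",
    "evaluate",
]

#: sentinel for the PSNR of a perfect reconstruction (RMSE = 0)
PSNR_PERFECT = math.inf


def _pair(X, Xr) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64).ravel()
    Xr = np.asarray(Xr, dtype=np.float64).ravel()
    if X.shape != Xr.shape:
        raise ValueError(f"length mismatch: {X.shape} vs {Xr.shape}")
    if X.size < 1:
        raise ValueError("empty signals")
    return X, Xr


def prd(X, Xr) -> float:
    """Percent root-mean-square difference (lower is better)."""
    X, Xr = _pair(X, Xr)
    denom = float(X @ X)
    if denom == 0.0:
        raise ValueError("PRD undefined for an all-zero original signal")
    d = X - Xr
    return 100.0 * math.sqrt(float(d @ d) / denom)


def snr_from_prd(prd_percent: float) -> float:
    """SNR in dB from a PRD percentage: -20 log10(0.01 PRD)."""
    if prd_percent <= 0:
        raise ValueError("SNR undefined for PRD <= 0")
    return -20.0 * math.log10(0.01 * prd_percent)


def rmse(X, Xr) -> float:
    """Root-mean-square error in sample units."""
    X, Xr = _pair(X, Xr)
    d = X - Xr
    return math.sqrt(float(d @ d) / X.size)


def psnr(X, Xr) -> float:
    """Peak SNR in dB: 20 log10(max|X| / RMSE); +inf for exact recovery."""
    X, Xr = _pair(X, Xr)
    e = rmse(X, Xr)
    peak = float(np.max(np.abs(X)))
    if peak == 0.0:
        raise ValueError("PSNR undefined for an all-zero original signal")
    if e == 0.0:
        return PSNR_PERFECT
    return 20.0 * math.log10(peak / e)


def cross_correlation(X, Xr) -> float:
    """Pearson correlation between original and reconstruction.

    1 for a perfect reconstruction, -1 for a sign-flipped one.
    """
    X, Xr = _pair(X, Xr)
    if X.size < 2:
        raise ValueError("correlation needs at least 2 samples")
    xc = X - X.mean()
    yc = Xr - Xr.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx == 0.0 or vy == 0.0:
        raise ValueError("correlation undefined for a zero-variance signal")
    return float(np.clip((xc @ yc) / math.sqrt(vx * vy), -1.0, 1.0))


_SEGMENT = 256


def psd(X, sampling_rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density (Hamming window, 50% overlap).

    Segment length 256 (shorter records use the full length).
    Returns (frequencies_hz, power).
    """
    X = np.asarray(X, dtype=np.float64).ravel()
    nseg = min(_SEGMENT, X.size)
    if X.size < 2:
        raise ValueError("record too short for a PSD estimate")
    return welch(X, fs=sampling_rate_hz, window="hamming",
                 nperseg=nseg, noverlap=nseg // 2)


def psd_distance(X, Xr, sampling_rate_hz: float) -> float:
    """RMS log-spectral distance (dB) over bins with appreciable power.

    Bins whose original power is more than 60 dB below the spectral peak are
    excluded: differences buried that far under the dominant rhythms carry
    no diagnostic weight and would otherwise dominate the log distance.
    """
    X, Xr = _pair(X, Xr)
    f, p_orig = psd(X, sampling_rate_hz)
    _, p_rec = psd(Xr, sampling_rate_hz)
    peak = p_orig.max()
    if peak <= 0:
        raise ValueError("PSD distance undefined for a zero-power signal")
    mask = p_orig > peak * 1e-6           # within 60 dB of the peak
    tiny = np.finfo(float).tiny
    d = 10.0 * np.log10(np.maximum(p_orig[mask], tiny)) \
        - 10.0 * np.log10(np.maximum(p_rec[mask], tiny))
    return float(np.sqrt(np.mean(d * d)))


@dataclass(frozen=True)
class FidelityReport:
    """All quality metrics for one original/reconstruction pair."""

    prd: float
    snr_db: float
    rmse: float
    psnr_db: float
    cc: float
    psd_distance_db: float
    window_length: int

    def as_dict(self) -> dict:
        return {
            "prd": self.prd, "snr_db": self.snr_db, "rmse": self.rmse,
            "psnr_db": self.psnr_db, "cc": self.cc,
            "psd_distance_db": self.psd_distance_db,
            "window_length": self.window_length,
        }


def evaluate(original: EEGRecord | np.ndarray,
             reconstructed: EEGRecord | np.ndarray,
             sampling_rate_hz: float | None = None) -> FidelityReport:
    """Full fidelity report; multichannel records report channel means.

    PRD is computed over the whole record (the evaluation window N equals
    the record length); pass sliced arrays for windowed PRD.
    """
    if isinstance(original, EEGRecord):
        if sampling_rate_hz is None:
            sampling_rate_hz = original.sampling_rate_hz
        pairs = [(original.channel(i), _coerce(reconstructed, i))
                 for i in range(original.n_channels)]
    else:
        if sampling_rate_hz is None:
            raise ValueError("sampling_rate_hz required for array inputs")
        pairs = [(np.asarray(original), np.asarray(reconstructed))]

    reports = []
    for X, Xr in pairs:
        p = prd(X, Xr)
        reports.append((
            p,
            snr_from_prd(p) if p > 0 else math.inf,
            rmse(X, Xr),
            psnr(X, Xr),
            cross_correlation(X, Xr),
            psd_distance(X, Xr, sampling_rate_hz),
            len(np.ravel(X)),
        ))
    cols = list(zip(*reports))
    return FidelityReport(
        prd=float(np.mean(cols[0])),
        snr_db=float(np.mean(cols[1])),
        rmse=float(np.mean(cols[2])),
        psnr_db=float(np.mean(cols[3])),
        cc=float(np.mean(cols[4])),
        psd_distance_db=float(np.mean(cols[5])),
        window_length=int(cols[6][0]),
    )


def _coerce(rec, i):
    if isinstance(rec, EEGRecord):
        return rec.channel(i)
    return np.asarray(rec)[i] if np.asarray(rec).ndim > 1 else np.asarray(rec)
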