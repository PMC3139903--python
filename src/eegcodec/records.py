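"""EEG record container, file I/O and synthetic-EEG generation.

An :class:`EEGRecord` holds one or more channels of signed-integer samples
(ADC units) with a sampling rate and a bit depth.  Synthetic records are
produced by :func:`synth_eeg` from a :class:`SynthProfile`; three built-in
profiles emulate the broad classes of clinical EEG this codec targets:

``epileptic_seizure``
    1/f background activity interrupted by ~3 Hz high-amplitude spike-wave
    bursts, the classic surface signature of generalised epileptic seizures.
``normal_eyes``
    1/f background plus a narrow ~10 Hz alpha rhythm (awake, eyes closed).
``ictal``
    A dominant high-amplitude 2-5 Hz delta/theta rhythm as seen inside a
    seizure, sampled at 173.61 Hz.

All synthesis is a pure function of the profile, including its seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import edf as _edf

__all__ = [
    "EEGRecord",
    "SynthProfile",
    "PROFILES",
    "read_record",
    "write_record",
    "synth_eeg",
]


@dataclass(frozen=True)
class EEGRecord:
    """Multi-channel integer EEG signal.

    Parameters
    ----------
    channels : list of str
        Channel labels, e.g. ``["Fp1", "Fp2"]``.
    samples : ndarray, shape (n_channels, n_samples)
        Signed integer samples in ADC units.
    sampling_rate_hz : float
        Sampling rate, > 0.
    bit_depth : int
        Bits per sample ``n``; every sample must satisfy
        ``-2**(n-1) <= x < 2**(n-1)``.
    """

    channels: list[str]
    samples: np.ndarray
    sampling_rate_hz: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples)
        if arr.ndim == 1:
            arr = arr[None, :]
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise ValueError("samples must be integers")
            arr = arr.astype(np.int64)
        arr = np.ascontiguousarray(arr, dtype=np.int64)
        object.__setattr__(self, "samples", arr)
        if arr.shape[0] != len(self.channels):
            raise ValueError(
                f"{len(self.channels)} channel labels but {arr.shape[0]} sample rows"
            )
        if arr.shape[1] < 1:
            raise ValueError("record must contain at least one sample")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        n = self.bit_depth
        if n < 2:
            raise ValueError("bit_depth must be >= 2")
        lo, hi = -(1 << (n - 1)), (1 << (n - 1)) - 1
        if arr.min() < lo or arr.max() > hi:
            raise ValueError(
                f"samples outside signed {n}-bit range [{lo}, {hi}]"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channel(self, idx: int) -> np.ndarray:
        """Return one channel as a 1-D int64 array."""
        return self.samples[idx]


@dataclass(frozen=True)
class SynthProfile:
    """Recipe for a synthetic EEG record.

    ``band_components`` are ``(center_hz, bandwidth_hz, relative_power)``
    triples realised as narrow-band Gaussian processes; ``background_exponent``
    is the spectral slope beta of the 1/f**beta background; ``burst_spec`` is
    an optional ``(burst_rate_hz, spike_wave_freq_hz, amplitude_gain)`` triple
    adding intermittent spike-wave bursts.
    """

    profile_name: str
    duration_s: float
    sampling_rate_hz: float
    band_components: tuple = ()
    background_exponent: float = 1.0
    background_power: float = 1.0
    burst_spec: tuple | None = None
    seed: int = 0
    bit_depth: int = 16
    # fraction of full-scale that the signal's peak is scaled to
    peak_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if any(c[2] < 0 for c in self.band_components):
            raise ValueError("relative powers must be >= 0")
        if self.background_power < 0:
            raise ValueError("background_power must be >= 0")
        if self.background_power == 0 and not self.band_components:
            raise ValueError("need background or at least one band component")

    def with_(self, **kw) -> "SynthProfile":
        return replace(self, **kw)


#: Built-in profiles emulating the three clinical recording conditions.
PROFILES: dict[str, SynthProfile] = {
    "epileptic_seizure": SynthProfile(
        profile_name="epileptic_seizure",
        duration_s=10.0,
        sampling_rate_hz=256.0,
        band_components=((10.0, 2.0, 0.3),),
        background_exponent=1.0,
        background_power=1.0,
        burst_spec=(0.2, 3.0, 4.0),
        seed=0,
    ),
    "normal_eyes": SynthProfile(
        profile_name="normal_eyes",
        duration_s=10.0,
        sampling_rate_hz=256.0,
        band_components=((10.0, 2.0, 1.0),),
        background_exponent=1.0,
        background_power=1.0,
        burst_spec=None,
        seed=0,
    ),
    "ictal": SynthProfile(
        profile_name="ictal",
        duration_s=10.0,
        sampling_rate_hz=173.61,
        band_components=((3.5, 3.0, 10.0),),
        background_exponent=1.0,
        background_power=0.5,
        burst_spec=None,
        seed=0,
    ),
}


def _colored_noise(rng: np.random.Generator, n: int, rate: float, beta: float) -> np.ndarray:
    """Gaussian noise with a 1/f**beta power spectrum, unit variance."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _narrowband(rng: np.random.Generator, n: int, rate: float,
                center: float, bw: float) -> np.ndarray:
    """Unit-variance Gaussian process with a Gaussian spectral bump."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    sigma = max(bw / 2.0, rate / n)  # at least one bin wide
    amp = np.exp(-0.5 * ((freqs - center) / sigma) ** 2)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _spike_wave_burst(rng: np.random.Generator, t: np.ndarray, rate: float,
                      burst_rate: float, sw_freq: float, gain: float) -> np.ndarray:
    """Intermittent spike-and-wave activity gated by random burst windows.

    Each burst lasts ~2 s; within a burst every spike-wave cycle is a sharp
    positive transient followed by a slow half-sine wave.
    """
    n = len(t)
    out = np.zeros(n)
    expected = max(1, int(round(burst_rate * t[-1]))) if burst_rate > 0 else 0
    n_bursts = rng.poisson(expected) if expected else 0
    n_bursts = max(n_bursts, 1) if burst_rate > 0 else 0
    phase = 2 * np.pi * sw_freq * t
    # spike: narrow gaussian at cycle start; wave: rectified slow component
    cyc = np.mod(phase / (2 * np.pi), 1.0)
    spike = np.exp(-0.5 * ((cyc - 0.1) / 0.03) ** 2) * 2.0
    wave = np.sin(np.pi * np.clip((cyc - 0.25) / 0.7, 0, 1))
    pattern = spike + wave
    burst_len = int(round(2.0 * rate))
    for _ in range(n_bursts):
        start = rng.integers(0, max(1, n - burst_len))
        win = np.hanning(burst_len)
        seg = slice(start, start + burst_len)
        out[seg] += pattern[seg] * win[: n - start][:burst_len]
    return out * gain


def synth_eeg(profile: SynthProfile) -> EEGRecord:
    """Generate a synthetic single-channel EEG record from a profile.

    Deterministic: the same profile (seed included) always yields a
    bit-identical record.  The output is scaled so its peak occupies
    ``peak_fraction`` of the signed ``bit_depth`` range, then rounded.
    """
    rate = profile.sampling_rate_hz
    n = int(round(profile.duration_s * rate))
    if n < 1:
        raise ValueError("duration too short for one sample")
    rng = np.random.default_rng(profile.seed)
    t = np.arange(n) / rate

    x = np.zeros(n)
    if profile.background_power > 0:
        x += np.sqrt(profile.background_power) * _colored_noise(
            rng, n, rate, profile.background_exponent
        )
    for center, bw, power in profile.band_components:
        if power > 0:
            x += np.sqrt(power) * _narrowband(rng, n, rate, center, bw)
    if profile.burst_spec is not None:
        br, swf, gain = profile.burst_spec
        base_rms = x.std() if x.std() > 0 else 1.0
        x += _spike_wave_burst(rng, t, rate, br, swf, gain * base_rms)

    peak = np.abs(x).max()
    full = (1 << (profile.bit_depth - 1)) - 1
    if peak > 0:
        x = x * (profile.peak_fraction * full / peak)
    samples = np.clip(np.round(x), -full - 1, full).astype(np.int64)
    return EEGRecord(
        channels=[profile.profile_name],
        samples=samples[None, :],
        sampling_rate_hz=rate,
        bit_depth=profile.bit_depth,
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_FORMATS = ("edf", "csv", "txt")


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is None:
        ext = os.path.splitext(path)[1].lstrip(".").lower()
        fmt = ext if ext in _FORMATS else "csv"
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def read_record(path: str, format: str | None = None, *,
                sampling_rate_hz: float | None = None,
                bit_depth: int = 16) -> EEGRecord:
    """Read an EEG record from EDF, CSV or plain text.

    CSV/txt files carry one sample per line (comma-separated columns for
    multiple channels) with an optional header line
    ``# rate=<hz> bits=<n> channels=<a,b,...>``; when the header is absent,
    ``sampling_rate_hz`` must be supplied.
    """
    fmt = _infer_format(path, format)
    if fmt == "edf":
        channels, samples, rate = _edf.read_edf(path)
        return EEGRecord(channels=channels, samples=samples,
                         sampling_rate_hz=rate, bit_depth=bit_depth)
    return _read_text(path, sampling_rate_hz, bit_depth)


def _read_text(path: str, rate: float | None, bit_depth: int) -> EEGRecord:
    channels: list[str] | None = None
    rows: list[list[int]] = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line.lstrip("#").split():
                    if token.startswith("rate="):
                        rate = float(token[5:])
                    elif token.startswith("bits="):
                        bit_depth = int(token[5:])
                    elif token.startswith("channels="):
                        channels = token[9:].split(",")
                continue
            fields = line.replace(",", " ").split()
            try:
                rows.append([int(f) for f in fields])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer sample {line!r}") from exc
    if not rows:
        raise ValueError(f"{path}: no samples")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: inconsistent column counts {sorted(widths)}")
    if rate is None:
        raise ValueError(
            f"{path}: sampling rate not in file header; pass sampling_rate_hz"
        )
    arr = np.asarray(rows, dtype=np.int64).T
    if channels is None:
        channels = [f"ch{i}" for i in range(arr.shape[0])]
    return EEGRecord(channels=channels, samples=arr,
                     sampling_rate_hz=rate, bit_depth=bit_depth)


def write_record(record: EEGRecord, path: str, format: str | None = None) -> None:
    """Write a record to EDF, CSV or plain text (lossless round-trip)."""
    fmt = _infer_format(path, format)
    if fmt == "edf":
        _edf.write_edf(path, record.channels, record.samples,
                       record.sampling_rate_hz, bit_depth=record.bit_depth)
        return
    tmp = path + ".tmp"
    with open(tmp, "w") as fh:
        rate = record.sampling_rate_hz
        rate_s = repr(float(rate))
        fh.write(f"# rate={rate_s} bits={record.bit_depth} "
                 f"channels={','.join(record.channels)}\n")
        for row in record.samples.T:
            fh.write(",".join(str(int(v)) for v in row) + "\n")
    os.replace(tmp, path)
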