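"""Minimal EDF (European Data Format) reader and writer.

Supports the subset this codec needs: integer signals stored with a unit
digital-to-physical mapping (physical min/max equal to digital min/max) so
that 16-bit ADC samples survive a write/read round trip bit-exactly.

The whole record is written as a single EDF data record.  EDF stores the
sampling rate only implicitly as samples-per-record / record-duration, and
the duration field has 8 ASCII characters — rates such as 173.61 Hz are not
exactly representable that way, so the exact rate is additionally embedded
in the per-signal prefiltering field as ``SR=<rate>`` and preferred when
reading files written by this module.  Other EDF readers simply ignore it.
"""

from __future__ import annotations

import os
import struct

import numpy as np

_HDR = 256  # bytes of the fixed header and of each per-signal block


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field {text!r} exceeds {width} ASCII chars")
    return b.ljust(width)


def _num(value: float, width: int) -> bytes:
    """Format a number into a fixed-width EDF ASCII field."""
    if float(value).is_integer():
        s = str(int(value))
    else:
        s = repr(float(value))
        if len(s) > width:
            s = f"{value:.{width - 2}g}"[:width]
    return _pad(s, width)


def write_edf(path: str, channels: list[str], samples: np.ndarray,
              sampling_rate_hz: float, bit_depth: int = 16) -> None:
    samples = np.asarray(samples)
    if samples.ndim != 2:
        raise ValueError("samples must be (n_channels, n_samples)")
    if bit_depth > 16:
        raise ValueError("EDF stores 16-bit samples; bit_depth > 16 unsupported")
    ns, v = samples.shape
    if ns != len(channels):
        raise ValueError("channel count mismatch")
    if samples.min() < -32768 or samples.max() > 32767:
        raise ValueError("samples outside EDF 16-bit range")

    duration = v / sampling_rate_hz
    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate X X X X", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _num(_HDR * (1 + ns), 8),
        _pad("", 44),
        _num(1, 8),                    # one data record
        _num(duration, 8),
        _num(ns, 4),
    ])
    dig_min, dig_max = -32768, 32767
    sig = b"".join([
        b"".join(_pad(c, 16) for c in channels),
        b"".join(_pad("", 80) for _ in channels),          # transducer
        b"".join(_pad("uV", 8) for _ in channels),
        b"".join(_num(dig_min, 8) for _ in channels),      # physical min
        b"".join(_num(dig_max, 8) for _ in channels),      # physical max
        b"".join(_num(dig_min, 8) for _ in channels),
        b"".join(_num(dig_max, 8) for _ in channels),
        b"".join(_pad(f"SR={sampling_rate_hz!r}", 80) for _ in channels),
        b"".join(_num(v, 8) for _ in channels),
        b"".join(_pad("", 32) for _ in channels),
    ])
    payload = samples.astype("<i2").tobytes()
    tmp = path + ".tmp"
    with open(tmp, "wb") as fh:
        fh.write(header + sig + payload)
    os.replace(tmp, path)


def read_edf(path: str) -> tuple[list[str], np.ndarray, float]:
    with open(path, "rb") as fh:
        head = fh.read(_HDR)
        if len(head) < _HDR:
            raise ValueError(f"{path}: truncated EDF header")
        n_records = int(head[236:244].decode("ascii").strip())
        duration = float(head[244:252].decode("ascii").strip())
        ns = int(head[252:256].decode("ascii").strip())
        sig = fh.read(_HDR * ns)
        if len(sig) < _HDR * ns:
            raise ValueError(f"{path}: truncated EDF signal header")

        def fields(offset: int, width: int) -> list[str]:
            base = offset * ns
            return [
                sig[base + i * width: base + (i + 1) * width].decode("ascii").strip()
                for i in range(ns)
            ]

        labels = fields(0, 16)
        # field offsets (in bytes from start of signal header block)
        off = {}
        pos = 0
        for name, w in [("label", 16), ("transducer", 80), ("dim", 8),
                        ("pmin", 8), ("pmax", 8), ("dmin", 8), ("dmax", 8),
                        ("prefilter", 80), ("spr", 8), ("reserved", 32)]:
            off[name] = (pos, w)
            pos += w * ns

        def col(name: str) -> list[str]:
            p, w = off[name]
            return [sig[p + i * w: p + (i + 1) * w].decode("ascii").strip()
                    for i in range(ns)]

        labels = col("label")
        pmin = [float(x) for x in col("pmin")]
        pmax = [float(x) for x in col("pmax")]
        dmin = [float(x) for x in col("dmin")]
        dmax = [float(x) for x in col("dmax")]
        prefilter = col("prefilter")
        spr = [int(x) for x in col("spr")]

        if n_records < 0:
            raise ValueError(f"{path}: unknown record count")
        raw = fh.read(2 * sum(spr) * n_records)

    data = [np.empty(s * n_records, dtype=np.int64) for s in spr]
    offset = 0
    arr = np.frombuffer(raw, dtype="<i2")
    for rec in range(n_records):
        for i, s in enumerate(spr):
            data[i][rec * s:(rec + 1) * s] = arr[offset:offset + s]
            offset += s

    out = []
    for i in range(ns):
        d = data[i].astype(np.float64)
        if (dmax[i] - dmin[i]) != 0 and (pmin[i], pmax[i]) != (dmin[i], dmax[i]):
            scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
            d = pmin[i] + (d - dmin[i]) * scale
        di = np.round(d).astype(np.int64)
        if not np.allclose(d, di, atol=1e-6):
            raise ValueError(f"{path}: signal {labels[i]} has non-integer samples")
        out.append(di)

    lengths = {len(d) for d in out}
    if len(lengths) != 1:
        raise ValueError(f"{path}: channels differ in length; unsupported layout")

    rate = None
    for pf in prefilter:
        if pf.startswith("SR="):
            rate = float(pf[3:])
            break
    if rate is None:
        if duration <= 0:
            raise ValueError(f"{path}: non-positive record duration")
        rate = spr[0] / duration
    return labels, np.vstack(out), rate
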