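"""Near-lossless residual codec: threshold, quantize, entropy-code, decode.

The encoder trains a predictor per channel, fixes an absolute threshold
``T_abs`` as a percentage of the peak open-loop residue, then runs a
closed-loop (DPCM) pass: each sample is predicted from the *reconstructed*
history, the residue ``e_n = X_n - X^_n`` is thresholded,

    [e_n]_T = 0        if |e_n| <  T,
    [e_n]_T = e_n      if |e_n| >= T,

uniformly quantized to a signed level ``k`` and arithmetic-coded; both
sides then append ``X~_n = X^_n + k*Delta`` to their history.  Because
encoder and decoder run the identical prediction and reconstruction
arithmetic from the transmitted header (float32 weights + first ``p``
samples), their states never diverge; the reconstruction error per
non-saturated sample is bounded by ``max(T_abs, Delta/2)`` plus the final
0.5 integer-rounding step.

Closed-loop prediction is deliberate: feeding the predictor the original
samples while the decoder only has lossy reconstructions would let the
error accumulate without bound.  The threshold scale, by contrast, is set
from one open-loop pass so that "T percent of the peak residue" is well
defined before any quantization feedback exists.
"""

from __future__ import annotations

import math
import struct
import zlib
from dataclasses import dataclass, field

import numpy as np

from .entropy import arith_decode, arith_encode, DecodeError
from .predictors import (
    KINDS,
    PredictorConfig,
    PredictorModel,
    default_config,
    open_loop_residues,
    train_predictor,
)
from .records import EEGRecord

__all__ = [
    "ResidualBlock",
    "ChannelInfo",
    "CompressedStream",
    "DecodeError",
    "threshold_residues",
    "make_quantizer",
    "quantize",
    "dequantize",
    "make_residual_block",
    "lossless_quant_bits",
    "encode_record",
    "compress",
    "decompress",
]

_MAGIC = b"EQOD"
_VERSION = 1
#: bits used to serialise one predictor weight (IEEE-754 single)
WEIGHT_BITS = 32


# ---------------------------------------------------------------------------
# thresholding and quantization
# ---------------------------------------------------------------------------

def threshold_residues(e, T_abs: float) -> np.ndarray:
    """Zero every residue with magnitude strictly below ``T_abs``.

    The boundary ``|e| == T_abs`` is kept (transmitted), matching the
    near-lossless convention that only strictly sub-threshold residues are
    assumed negligible.  Idempotent.
    """
    if T_abs < 0:
        raise ValueError("threshold must be >= 0")
    e = np.asarray(e, dtype=np.float64)
    return np.where(np.abs(e) < T_abs, 0.0, e)


def make_quantizer(e_T, r: int) -> float:
    """Uniform step ``Delta`` so that ``2**(r-1) - 1`` levels cover ``e_T``.

    ``Delta = max|e_T| / (2**(r-1) - 1)``; guarantees no saturation on the
    block the step was fitted to.  An all-zero block degenerates to
    ``Delta = 1``.
    """
    if r < 2:
        raise ValueError("quantizer needs r >= 2 bits")
    peak = float(np.max(np.abs(e_T))) if np.size(e_T) else 0.0
    if peak == 0.0:
        return 1.0
    return peak / ((1 << (r - 1)) - 1)


def quantize(e_T, r: int, delta: float) -> np.ndarray:
    """Midtread quantizer indices ``k = clamp(round(e/Delta))``.

    Rounds half away from zero is not required — any fixed rule works since
    only the encoder quantizes; half-up (floor(x+0.5)) is used.  Indices are
    clamped to ``[-(2**(r-1)-1), 2**(r-1)-1]``; 0 maps to index 0, so
    thresholded residues reconstruct to exactly 0.
    """
    if r < 2:
        raise ValueError("quantizer needs r >= 2 bits")
    if delta <= 0:
        raise ValueError("delta must be positive")
    lim = (1 << (r - 1)) - 1
    k = np.floor(np.asarray(e_T, dtype=np.float64) / delta + 0.5).astype(np.int64)
    return np.clip(k, -lim, lim)


def dequantize(k, r: int, delta: float) -> np.ndarray:
    """Reconstruction values ``k * Delta`` ([e]_TQ)."""
    if r < 2:
        raise ValueError("quantizer needs r >= 2 bits")
    return np.asarray(k, dtype=np.float64) * delta


@dataclass(frozen=True)
class ResidualBlock:
    """Raw, thresholded and quantized residues for one channel."""

    residues: np.ndarray
    threshold_percent: float
    T_abs: float
    thresholded: np.ndarray
    quant_bits: int
    delta: float
    levels: np.ndarray          # signed quantizer indices k
    symbols: np.ndarray         # offset-binary indices in [0, 2**r - 2]

    @property
    def q(self) -> int:
        """Number of residues suppressed by the threshold."""
        return int(np.sum(np.abs(self.residues) < self.T_abs))


def make_residual_block(e, threshold_percent: float, r: int) -> ResidualBlock:
    """Threshold + quantize a residue block (open-loop convenience)."""
    if not 0 <= threshold_percent <= 100:
        raise ValueError("threshold_percent must be in [0, 100]")
    e = np.asarray(e, dtype=np.float64)
    T_abs = threshold_percent / 100.0 * float(np.max(np.abs(e))) if e.size else 0.0
    e_T = threshold_residues(e, T_abs)
    delta = make_quantizer(e_T, r)
    k = quantize(e_T, r, delta)
    offset = (1 << (r - 1)) - 1
    return ResidualBlock(residues=e, threshold_percent=threshold_percent,
                         T_abs=T_abs, thresholded=e_T, quant_bits=r,
                         delta=delta, levels=k, symbols=k + offset)


def lossless_quant_bits(max_abs_residue: float) -> int:
    """Residue bits guaranteeing ``Delta <= 0.5`` with 2x level headroom.

    With ``Delta <= 0.5`` every quantization error is below the 0.5-LSB
    integer rounding step, so (at threshold 0) the decoder reproduces the
    integer samples exactly; the headroom absorbs the slightly different
    residues seen in the closed loop.
    """
    m = max(1.0, float(max_abs_residue))
    return max(2, math.ceil(math.log2(2.0 * m + 1.0)) + 1)


# ---------------------------------------------------------------------------
# stream structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelInfo:
    """Bookkeeping for one encoded channel."""

    kind: str
    order: int
    hidden_units: int
    seed: int
    n_weights: int
    weight_bits: int
    threshold_percent: float
    T_abs: float
    quant_bits: int
    delta: float
    q: int                      # residues suppressed by the threshold
    n_zero_symbols: int         # coded symbols equal to level 0
    n_saturated: int
    payload_bits: int


@dataclass(frozen=True)
class CompressedStream:
    """Self-contained compressed EEG stream (header + payload + CRC)."""

    data: bytes
    bit_depth: int
    sampling_rate_hz: float
    channels: list[str]
    n_samples: int
    infos: list[ChannelInfo]

    @property
    def total_bits(self) -> int:
        return 8 * len(self.data)

    @property
    def payload_bits(self) -> int:
        return sum(ci.payload_bits for ci in self.infos)

    @property
    def header_bits(self) -> int:
        """Everything that is not arithmetic-coded payload (exact)."""
        padded = sum(8 * ((ci.payload_bits + 7) // 8) for ci in self.infos)
        return self.total_bits - padded

    def tofile(self, path: str) -> None:
        import os
        tmp = path + ".tmp"
        with open(tmp, "wb") as fh:
            fh.write(self.data)
        os.replace(tmp, path)

    @classmethod
    def fromfile(cls, path: str) -> "CompressedStream":
        with open(path, "rb") as fh:
            return parse_stream(fh.read())


# ---------------------------------------------------------------------------
# serialisation helpers
# ---------------------------------------------------------------------------

def _pack_signed(values: np.ndarray, bits: int) -> bytes:
    """Pack signed integers MSB-first at ``bits`` bits each."""
    acc = 0
    nacc = 0
    out = bytearray()
    mask = (1 << bits) - 1
    for v in values:
        acc = (acc << bits) | (int(v) & mask)
        nacc += bits
        while nacc >= 8:
            nacc -= 8
            out.append((acc >> nacc) & 0xFF)
    if nacc:
        out.append((acc << (8 - nacc)) & 0xFF)
    return bytes(out)


def _unpack_signed(data: bytes, count: int, bits: int) -> np.ndarray:
    acc = 0
    nacc = 0
    out = np.empty(count, dtype=np.int64)
    pos = 0
    sign = 1 << (bits - 1)
    mask = (1 << bits) - 1
    for i in range(count):
        while nacc < bits:
            if pos >= len(data):
                raise DecodeError("truncated seed-sample block")
            acc = (acc << 8) | data[pos]
            pos += 1
            nacc += 8
        nacc -= bits
        v = (acc >> nacc) & mask
        out[i] = v - (1 << bits) if v & sign else v
    return out


# ---------------------------------------------------------------------------
# closed-loop encode / decode core
# ---------------------------------------------------------------------------

def _closed_loop_encode(x: np.ndarray, model: PredictorModel, T_abs: float,
                        r: int, delta: float):
    """DPCM pass over one channel; returns (levels k, recon_real, q, sat)."""
    p = model.config.order
    v = len(x)
    lim = (1 << (r - 1)) - 1
    recon = np.empty(v, dtype=np.float64)
    recon[:p] = x[:p]
    levels = np.empty(v - p, dtype=np.int64)
    q = 0
    sat = 0
    model.reset_context()
    predict = model.predict
    for i in range(p, v):
        window = recon[i - p: i][::-1]
        xhat = predict(window)
        e = x[i] - xhat
        if abs(e) < T_abs:
            k = 0
            q += 1
        else:
            k = math.floor(e / delta + 0.5)
            if k > lim:
                k = lim
                sat += 1
            elif k < -lim:
                k = -lim
                sat += 1
        levels[i - p] = k
        recon[i] = xhat + k * delta
    model.reset_context()
    return levels, recon, q, sat


def _closed_loop_decode(seed: np.ndarray, levels: np.ndarray,
                        model: PredictorModel, delta: float) -> np.ndarray:
    """Replay the identical prediction process from the header state."""
    p = model.config.order
    v = p + len(levels)
    recon = np.empty(v, dtype=np.float64)
    recon[:p] = seed
    model.reset_context()
    predict = model.predict
    for i in range(p, v):
        window = recon[i - p: i][::-1]
        xhat = predict(window)
        recon[i] = xhat + levels[i - p] * delta
    model.reset_context()
    return recon


def _round_to_record(recon: np.ndarray, bit_depth: int) -> np.ndarray:
    full = (1 << (bit_depth - 1)) - 1
    return np.clip(np.round(recon), -full - 1, full).astype(np.int64)


# ---------------------------------------------------------------------------
# compress / decompress
# ---------------------------------------------------------------------------

def encode_record(record: EEGRecord,
                  predictor_config: PredictorConfig | str = "slp",
                  threshold_percent: float = 0.0,
                  quant_bits: int | None = None,
                  models: list[PredictorModel] | None = None,
                  ) -> tuple[CompressedStream, EEGRecord]:
    """Compress a record and return (stream, encoder-side reconstruction).

    The reconstruction equals ``decompress(stream)`` exactly — the decoder
    replays the identical closed loop — and is returned so rate-distortion
    sweeps need not decode every stream.  Channels are coded independently,
    each with its own trained model (reused from ``models`` if given),
    threshold and quantizer.  ``quant_bits=None`` picks the per-channel
    lossless setting (Delta <= 0.5).
    """
    if isinstance(predictor_config, str):
        predictor_config = default_config(predictor_config)
    if not 0 <= threshold_percent <= 100:
        raise ValueError("threshold_percent must be in [0, 100]")
    if quant_bits is not None and quant_bits < 2:
        raise ValueError("quant_bits must be >= 2")
    p = predictor_config.order
    if record.n_samples <= max(p, 10 * p if models is None else p):
        raise ValueError("record too short for this predictor order")

    out = bytearray()
    out += struct.pack(">4sBBdIH", _MAGIC, _VERSION, record.bit_depth,
                       record.sampling_rate_hz, record.n_samples,
                       record.n_channels)
    for label in record.channels:
        lb = label.encode("utf-8")
        out += struct.pack(">H", len(lb)) + lb

    infos: list[ChannelInfo] = []
    recon_int = np.empty_like(record.samples)
    for ch in range(record.n_channels):
        x = record.channel(ch).astype(np.float64)
        if models is not None:
            model = models[ch].round_to_float32()
        else:
            ch_rec = EEGRecord(channels=[record.channels[ch]],
                               samples=record.samples[ch:ch + 1],
                               sampling_rate_hz=record.sampling_rate_hz,
                               bit_depth=record.bit_depth)
            model = train_predictor(ch_rec, predictor_config).round_to_float32()
        e_open = open_loop_residues(model, x)
        T_abs = threshold_percent / 100.0 * float(np.max(np.abs(e_open)))
        e_T = threshold_residues(e_open, T_abs)
        r = quant_bits if quant_bits is not None else lossless_quant_bits(
            float(np.max(np.abs(e_T))) if e_T.size else 0.0)
        delta = make_quantizer(e_T, r)
        levels, recon, q, sat = _closed_loop_encode(x, model, T_abs, r, delta)
        recon_int[ch] = _round_to_record(recon, record.bit_depth)

        offset = (1 << (r - 1)) - 1
        alphabet = (1 << r) - 1
        payload, nbits = arith_encode(levels + offset, alphabet)
        n_zero = int(np.sum(levels == 0))

        cfg = model.config
        params32 = model.parameters.astype(">f4").tobytes()
        seed_block = _pack_signed(record.channel(ch)[:cfg.order],
                                  record.bit_depth)
        out += struct.pack(">BBBIH", KINDS.index(cfg.kind), cfg.order,
                           cfg.hidden_units, cfg.seed & 0xFFFFFFFF,
                           model.n_parameters)
        out += params32
        out += seed_block
        out += struct.pack(">fdBdIIIII", threshold_percent, T_abs, r, delta,
                           q, n_zero, sat, len(levels), nbits)
        out += struct.pack(">I", len(payload))
        out += payload
        infos.append(ChannelInfo(
            kind=cfg.kind, order=cfg.order, hidden_units=cfg.hidden_units,
            seed=cfg.seed, n_weights=model.n_parameters,
            weight_bits=WEIGHT_BITS, threshold_percent=threshold_percent,
            T_abs=T_abs, quant_bits=r, delta=delta, q=q,
            n_zero_symbols=n_zero, n_saturated=sat, payload_bits=nbits,
        ))

    out += struct.pack(">I", zlib.crc32(bytes(out)) & 0xFFFFFFFF)
    stream = CompressedStream(
        data=bytes(out), bit_depth=record.bit_depth,
        sampling_rate_hz=record.sampling_rate_hz,
        channels=list(record.channels), n_samples=record.n_samples,
        infos=infos,
    )
    recon_record = EEGRecord(channels=list(record.channels),
                             samples=recon_int,
                             sampling_rate_hz=record.sampling_rate_hz,
                             bit_depth=record.bit_depth)
    return stream, recon_record


def compress(record: EEGRecord,
             predictor_config: PredictorConfig | str = "slp",
             threshold_percent: float = 0.0,
             quant_bits: int | None = None,
             models: list[PredictorModel] | None = None) -> CompressedStream:
    """Compress a record into a self-contained stream."""
    stream, _ = encode_record(record, predictor_config, threshold_percent,
                              quant_bits, models)
    return stream


def parse_stream(data: bytes) -> CompressedStream:
    """Validate CRC and parse a serialized stream's header bookkeeping."""
    if len(data) < 24:
        raise DecodeError("stream too short")
    body, crc = data[:-4], struct.unpack(">I", data[-4:])[0]
    if zlib.crc32(body) & 0xFFFFFFFF != crc:
        raise DecodeError("CRC mismatch: stream corrupt or truncated")
    magic, version, n, rate, v, nch = struct.unpack_from(">4sBBdIH", body, 0)
    if magic != _MAGIC:
        raise DecodeError("not an EQOD stream")
    if version != _VERSION:
        raise DecodeError(f"unsupported stream version {version}")
    pos = struct.calcsize(">4sBBdIH")
    channels = []
    for _ in range(nch):
        (ln,) = struct.unpack_from(">H", body, pos)
        pos += 2
        channels.append(body[pos:pos + ln].decode("utf-8"))
        pos += ln
    infos = []
    for _ in range(nch):
        kind_i, p, h, seed, w = struct.unpack_from(">BBBIH", body, pos)
        pos += struct.calcsize(">BBBIH")
        pos += 4 * w                              # float32 params
        pos += (p * n + 7) // 8                   # packed seed samples
        (t_pct, T_abs, r, delta, q, n_zero, sat, n_lv, nbits) = \
            struct.unpack_from(">fdBdIIIII", body, pos)
        pos += struct.calcsize(">fdBdIIIII")
        (plen,) = struct.unpack_from(">I", body, pos)
        pos += 4 + plen
        infos.append(ChannelInfo(
            kind=KINDS[kind_i], order=p, hidden_units=h, seed=seed,
            n_weights=w, weight_bits=WEIGHT_BITS, threshold_percent=t_pct,
            T_abs=T_abs, quant_bits=r, delta=delta, q=q,
            n_zero_symbols=n_zero, n_saturated=sat, payload_bits=nbits,
        ))
    if pos != len(body):
        raise DecodeError("trailing bytes after last channel block")
    return CompressedStream(data=data, bit_depth=n, sampling_rate_hz=rate,
                            channels=channels, n_samples=v, infos=infos)


def decompress(stream: CompressedStream | bytes) -> EEGRecord:
    """Reconstruct the EEG record from a compressed stream.

    The first ``p`` samples of every channel are the transmitted originals;
    the rest are ``round(X^_n + k*Delta)`` from the replayed closed loop.
    """
    if isinstance(stream, bytes):
        stream = parse_stream(stream)
    data = stream.data
    body = data[:-4]
    n = stream.bit_depth
    v = stream.n_samples
    pos = struct.calcsize(">4sBBdIH")
    for _ in range(len(stream.channels)):
        (ln,) = struct.unpack_from(">H", body, pos)
        pos += 2 + ln
    samples = np.empty((len(stream.channels), v), dtype=np.int64)
    for ch in range(len(stream.channels)):
        kind_i, p, h, seed, w = struct.unpack_from(">BBBIH", body, pos)
        pos += struct.calcsize(">BBBIH")
        params = np.frombuffer(body, dtype=">f4", count=w, offset=pos
                               ).astype(np.float64)
        pos += 4 * w
        nseed = (p * n + 7) // 8
        seed_samples = _unpack_signed(body[pos:pos + nseed], p, n)
        pos += nseed
        (t_pct, T_abs, r, delta, q, n_zero, sat, n_lv, nbits) = \
            struct.unpack_from(">fdBdIIIII", body, pos)
        pos += struct.calcsize(">fdBdIIIII")
        (plen,) = struct.unpack_from(">I", body, pos)
        pos += 4
        payload = body[pos:pos + plen]
        pos += plen
        if n_lv != v - p:
            raise DecodeError("level count inconsistent with sample count")
        kind = KINDS[kind_i]
        cfg = default_config(kind).with_(order=p, seed=seed, **(
            {"hidden_units": h} if kind in ("mlp", "en") else {}))
        model = PredictorModel(config=cfg, parameters=params,
                               scale=float(1 << (n - 1)))
        offset = (1 << (r - 1)) - 1
        alphabet = (1 << r) - 1
        symbols = arith_decode(payload, n_lv, alphabet, nbits)
        levels = symbols - offset
        recon = _closed_loop_decode(seed_samples.astype(np.float64),
                                    levels, model, delta)
        samples[ch] = _round_to_record(recon, n)
    return EEGRecord(channels=list(stream.channels), samples=samples,
                     sampling_rate_hz=stream.sampling_rate_hz, bit_depth=n)
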