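"""Adaptive order-0 integer arithmetic coder.

Classic 32-bit-register implementation: symbol frequencies start at 1, are
incremented after every coded symbol, and are halved (rounding up, so no
count reaches 0) when the total hits a cap.  Encoder and decoder maintain
the identical model, so the code is exactly decodable for any input.
Cumulative frequencies are kept in a Fenwick tree for O(log K) updates.
"""

from __future__ import annotations

import numpy as np

__all__ = ["arith_encode", "arith_decode", "AdaptiveModel", "DecodeError"]

_PRECISION = 32
_FULL = (1 << _PRECISION) - 1
_HALF = 1 << (_PRECISION - 1)
_QUARTER = 1 << (_PRECISION - 2)
_THREE_Q = 3 * _QUARTER
_COUNT_CAP = 1 << 16   # model rescale threshold; << _QUARTER so ranges never vanish


class DecodeError(ValueError):
    """Bitstream exhausted or inconsistent during arithmetic decoding."""


class _Fenwick:
    """Binary indexed tree over symbol counts."""

    __slots__ = ("size", "tree")

    def __init__(self, counts):
        n = len(counts)
        self.size = n
        tree = [0] * (n + 1)
        for i, c in enumerate(counts):
            j = i + 1
            tree[j] += c
            k = j + (j & -j)
            if k <= n:
                tree[k] += tree[j]
        self.tree = tree

    def add(self, i: int, delta: int) -> None:
        j = i + 1
        tree = self.tree
        while j <= self.size:
            tree[j] += delta
            j += j & -j

    def prefix(self, i: int) -> int:
        """Sum of counts[0:i]."""
        s = 0
        tree = self.tree
        while i > 0:
            s += tree[i]
            i -= i & -i
        return s

    def find(self, target: int) -> int:
        """Largest index i with prefix(i) <= target (i.e. the symbol whose
        cumulative interval contains target)."""
        idx = 0
        bit = 1 << (self.size.bit_length())
        tree = self.tree
        while bit:
            nxt = idx + bit
            if nxt <= self.size and tree[nxt] <= target:
                idx = nxt
                target -= tree[nxt]
            bit >>= 1
        return idx


class AdaptiveModel:
    """Order-0 adaptive frequency model over ``alphabet_size`` symbols."""

    def __init__(self, alphabet_size: int):
        if alphabet_size < 1:
            raise ValueError("alphabet_size must be >= 1")
        self.alphabet_size = alphabet_size
        self.counts = [1] * alphabet_size
        self.total = alphabet_size
        self.fen = _Fenwick(self.counts)

    def interval(self, symbol: int) -> tuple[int, int, int]:
        lo = self.fen.prefix(symbol)
        return lo, lo + self.counts[symbol], self.total

    def update(self, symbol: int) -> None:
        self.fen.add(symbol, 1)
        self.counts[symbol] += 1
        self.total += 1
        if self.total >= _COUNT_CAP:
            self.counts = [(c + 1) >> 1 for c in self.counts]
            self.total = sum(self.counts)
            self.fen = _Fenwick(self.counts)

    def locate(self, target: int) -> int:
        return self.fen.find(target)


class _BitSink:
    __slots__ = ("buf", "cur", "ncur", "nbits")

    def __init__(self):
        self.buf = bytearray()
        self.cur = 0
        self.ncur = 0
        self.nbits = 0

    def put(self, bit: int) -> None:
        self.cur = (self.cur << 1) | bit
        self.ncur += 1
        self.nbits += 1
        if self.ncur == 8:
            self.buf.append(self.cur)
            self.cur = 0
            self.ncur = 0

    def bytes(self) -> bytes:
        if self.ncur:
            return bytes(self.buf) + bytes([self.cur << (8 - self.ncur)])
        return bytes(self.buf)


class _BitSource:
    """Reads bits MSB-first; allows exactly one register width of zero
    padding past the declared end, then raises :class:`DecodeError`."""

    __slots__ = ("data", "nbits", "pos")

    def __init__(self, data: bytes, nbits: int):
        if nbits > 8 * len(data):
            raise DecodeError("declared bit count exceeds buffer size")
        self.data = data
        self.nbits = nbits
        self.pos = 0

    def get(self) -> int:
        if self.pos >= self.nbits:
            if self.pos >= self.nbits + _PRECISION:
                raise DecodeError("truncated arithmetic bitstream")
            self.pos += 1
            return 0
        b = (self.data[self.pos >> 3] >> (7 - (self.pos & 7))) & 1
        self.pos += 1
        return b


def arith_encode(symbols, alphabet_size: int) -> tuple[bytes, int]:
    """Encode a symbol sequence; returns (payload bytes, exact bit count).

    Symbols must lie in ``[0, alphabet_size)``.  The empty sequence encodes
    to zero bits.
    """
    model = AdaptiveModel(alphabet_size)
    sink = _BitSink()
    low, high, pending = 0, _FULL, 0

    def emit(bit: int) -> None:
        nonlocal pending
        sink.put(bit)
        while pending:
            sink.put(1 - bit)
            pending -= 1

    n = 0
    for s in symbols:
        s = int(s)
        if not 0 <= s < alphabet_size:
            raise ValueError(f"symbol {s} outside alphabet [0, {alphabet_size})")
        c_lo, c_hi, total = model.interval(s)
        span = high - low + 1
        high = low + (span * c_hi) // total - 1
        low = low + (span * c_lo) // total
        while True:
            if high < _HALF:
                emit(0)
            elif low >= _HALF:
                emit(1)
                low -= _HALF
                high -= _HALF
            elif low >= _QUARTER and high < _THREE_Q:
                pending += 1
                low -= _QUARTER
                high -= _QUARTER
            else:
                break
            low <<= 1
            high = (high << 1) | 1
        model.update(s)
        n += 1
    if n:
        pending += 1
        emit(0 if low < _QUARTER else 1)
    return sink.bytes(), sink.nbits


def arith_decode(data: bytes, count: int, alphabet_size: int,
                 nbits: int | None = None) -> np.ndarray:
    """Decode ``count`` symbols from an :func:`arith_encode` payload."""
    if count == 0:
        return np.empty(0, dtype=np.int64)
    if nbits is None:
        nbits = 8 * len(data)
    src = _BitSource(data, nbits)
    model = AdaptiveModel(alphabet_size)
    low, high = 0, _FULL
    value = 0
    for _ in range(_PRECISION):
        value = (value << 1) | src.get()
    out = np.empty(count, dtype=np.int64)
    for i in range(count):
        total = model.total
        span = high - low + 1
        target = ((value - low + 1) * total - 1) // span
        s = model.locate(target)
        c_lo, c_hi, _ = model.interval(s)
        high = low + (span * c_hi) // total - 1
        low = low + (span * c_lo) // total
        while True:
            if high < _HALF:
                pass
            elif low >= _HALF:
                low -= _HALF
                high -= _HALF
                value -= _HALF
            elif low >= _QUARTER and high < _THREE_Q:
                low -= _QUARTER
                high -= _QUARTER
                value -= _QUARTER
            else:
                break
            low <<= 1
            high = (high << 1) | 1
            value = (value << 1) | src.get()
        model.update(s)
        out[i] = s
    return out
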