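"""Exact big-rational arithmetic coder used as a test oracle.

Implements ideal (infinite-precision) arithmetic coding with the same
adaptive order-0 model as the production coder: the interval is narrowed
with exact ``fractions.Fraction`` arithmetic and the shortest binary
fraction inside the final interval is emitted.  Decoding reverses the
process exactly.  This is hopelessly slow but indisputably correct, which
is the point.
"""

from fractions import Fraction


class _Counts:
    def __init__(self, alphabet_size: int, cap: int = 1 << 16):
        self.counts = [1] * alphabet_size
        self.total = alphabet_size
        self.cap = cap

    def interval(self, s: int):
        lo = sum(self.counts[:s])
        return lo, lo + self.counts[s], self.total

    def update(self, s: int) -> None:
        self.counts[s] += 1
        self.total += 1
        if self.total >= self.cap:
            self.counts = [(c + 1) >> 1 for c in self.counts]
            self.total = sum(self.counts)


def encode(symbols, alphabet_size: int) -> list[int]:
    """Encode to a bit list: a dyadic fraction of minimal guaranteed length.

    With ``m = ceil(-log2 width) + 1`` bits, ``v = ceil(low * 2^m) / 2^m``
    always lies in ``[low, low + width)``, so the decoder (which pads with
    zeros) recovers the sequence exactly.
    """
    model = _Counts(alphabet_size)
    low, width = Fraction(0), Fraction(1)
    for s in symbols:
        c_lo, c_hi, total = model.interval(int(s))
        low = low + width * Fraction(c_lo, total)
        width = width * Fraction(c_hi - c_lo, total)
        model.update(int(s))
    if not symbols:
        return []
    m = 1
    while Fraction(1, 1 << m) > width / 2:
        m += 1
    num = -((-low.numerator * (1 << m)) // low.denominator)   # ceil(low * 2^m)
    v = Fraction(num, 1 << m)
    assert low <= v < low + width
    return [(num >> (m - 1 - i)) & 1 for i in range(m)]


def decode(bits, count: int, alphabet_size: int) -> list[int]:
    """Decode ``count`` symbols from a bit list (zero-padded as needed)."""
    model = _Counts(alphabet_size)
    value = Fraction(0)
    step = Fraction(1, 2)
    for b in bits:
        if b:
            value += step
        step /= 2
    low, width = Fraction(0), Fraction(1)
    out = []
    for _ in range(count):
        target = (value - low) / width
        cum = 0
        total = model.total
        for s, c in enumerate(model.counts):
            if Fraction(cum, total) <= target < Fraction(cum + c, total):
                break
            cum += c
        out.append(s)
        low = low + width * Fraction(cum, total)
        width = width * Fraction(c, total)
        model.update(s)
    return out


def ideal_code_length_bits(symbols, alphabet_size: int) -> float:
    """-log2 of the sequence probability under the adaptive model."""
    import math
    model = _Counts(alphabet_size)
    log_p = 0.0
    for s in symbols:
        c_lo, c_hi, total = model.interval(int(s))
        log_p += math.log2((c_hi - c_lo) / total)
        model.update(int(s))
    return -log_p
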