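import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eegcodec as ec
from eegcodec.codec import (
    _closed_loop_decode,
    _closed_loop_encode,
    lossless_quant_bits,
    make_residual_block,
    parse_stream,
)
from eegcodec.entropy import DecodeError


class TestThreshold:
    def test_boundary_kept(self):
        # |e| == T survives; only strictly smaller magnitudes are zeroed
        out = ec.threshold_residues([2, -5, 7], 5.0)
        assert list(out) == [0, -5, 7]

    def test_zero_threshold_identity(self):
        e = np.array([1.5, -0.1, 0.0, 3.0])
        assert np.array_equal(ec.threshold_residues(e, 0.0), e)

    def test_all_suppressed(self):
        assert list(ec.threshold_residues([1, -1], 10.0)) == [0, 0]

    def test_negative_threshold(self):
        with pytest.raises(ValueError):
            ec.threshold_residues([1.0], -1.0)

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=50),
           st.floats(0, 50))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_idempotent(self, e, t):
        once = ec.threshold_residues(e, t)
        assert np.array_equal(ec.threshold_residues(once, t), once)


class TestQuantizer:
    def test_step_examples(self):
        assert ec.make_quantizer(np.array([127.0, -5.0]), 8) == pytest.approx(1.0)
        assert ec.make_quantizer(np.zeros(4), 8) == 1.0
        assert ec.make_quantizer(np.array([100.0]), 3) == pytest.approx(100 / 3)

    def test_zero_preserved(self):
        k = ec.quantize(np.array([0.0]), 8, 2.5)
        assert k[0] == 0
        assert ec.dequantize(k, 8, 2.5)[0] == 0.0

    def test_midtread_example(self):
        # e=60, step 25: k = round(2.4) = 2 -> 50, error 10 <= step/2... no:
        # error 10 <= 12.5 = step/2
        k = ec.quantize(np.array([60.0]), 4, 25.0)
        assert k[0] == 2
        assert ec.dequantize(k, 4, 25.0)[0] == 50.0

    def test_saturation_clamped(self):
        k = ec.quantize(np.array([1e6, -1e6]), 4, 1.0)
        assert list(k) == [7, -7]

    def test_r_too_small(self):
        with pytest.raises(ValueError):
            ec.make_quantizer(np.array([1.0]), 1)

    @given(st.lists(st.floats(-1000, 1000), min_size=1, max_size=100),
           st.integers(2, 10))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_halfstep_error_bound(self, e, r):
        e = np.asarray(e)
        delta = ec.make_quantizer(e, r)
        back = ec.dequantize(ec.quantize(e, r, delta), r, delta)
        # delta was fitted to this block, so nothing saturates
        assert np.all(np.abs(e - back) <= delta / 2 + 1e-9)


def test_residual_block_bookkeeping():
    e = np.array([10.0, -2.0, 0.5, -40.0, 3.0])
    blk = make_residual_block(e, threshold_percent=10.0, r=4)
    assert blk.T_abs == pytest.approx(4.0)
    assert blk.q == 3                       # |e| < 4 suppressed
    assert np.all((blk.symbols >= 0) & (blk.symbols <= 2 ** 4 - 2))
    zero_sym = (1 << 3) - 1
    assert np.all(blk.symbols[np.abs(e) < blk.T_abs] == zero_sym)
    assert np.all(blk.levels[np.abs(e) < blk.T_abs] == 0)


class TestLosslessLimit:
    def test_bit_exact_roundtrip(self, normal_record):
        stream, recon = ec.encode_record(normal_record, "slp",
                                         threshold_percent=0.0)
        out = ec.decompress(stream)
        assert np.array_equal(out.samples, normal_record.samples)
        assert np.array_equal(recon.samples, normal_record.samples)

    def test_quant_bits_rule(self):
        # Delta <= 0.5 with 2x headroom for closed-loop excursions
        r = lossless_quant_bits(100.0)
        assert ((1 << (r - 1)) - 1) >= 2 * 100
        assert 100.0 / ((1 << (r - 1)) - 1) <= 0.5


class TestStreamContract:
    def test_deterministic_bytes(self, short_record):
        a = ec.compress(short_record, "slp", threshold_percent=3, quant_bits=7)
        b = ec.compress(short_record, "slp", threshold_percent=3, quant_bits=7)
        assert a.data == b.data

    def test_payload_nonincreasing_in_threshold(self, short_record):
        model = [ec.train_predictor(short_record, ec.default_config("slp"))]
        sizes = []
        for t in (0, 2, 4, 6, 8, 10):
            s, _ = ec.encode_record(short_record, "slp", threshold_percent=t,
                                    quant_bits=7, models=model)
            sizes.append(s.payload_bits)
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_decoder_matches_encoder_reconstruction(self, short_record):
        stream, recon = ec.encode_record(short_record, "ar",
                                         threshold_percent=5, quant_bits=6)
        out = ec.decompress(stream)
        assert np.array_equal(out.samples, recon.samples)

    def test_first_p_samples_verbatim(self, short_record):
        stream, _ = ec.encode_record(short_record, "slp",
                                     threshold_percent=8, quant_bits=5)
        out = ec.decompress(stream)
        p = stream.infos[0].order
        assert np.array_equal(out.samples[:, :p],
                              short_record.samples[:, :p])

    def test_corrupt_byte_detected(self, short_record):
        stream = ec.compress(short_record, "slp", threshold_percent=3,
                             quant_bits=7)
        bad = bytearray(stream.data)
        bad[len(bad) // 2] ^= 0xFF
        with pytest.raises(DecodeError):
            ec.decompress(bytes(bad))

    def test_truncated_stream_detected(self, short_record):
        stream = ec.compress(short_record, "slp", quant_bits=8,
                             threshold_percent=2)
        with pytest.raises(DecodeError):
            parse_stream(stream.data[:-10])

    def test_total_bits_accounting(self, short_record):
        stream = ec.compress(short_record, "slp", threshold_percent=3,
                             quant_bits=7)
        assert stream.total_bits == 8 * len(stream.data)
        assert stream.header_bits + sum(
            8 * ((ci.payload_bits + 7) // 8) for ci in stream.infos
        ) == stream.total_bits

    def test_file_roundtrip(self, short_record, tmp_path):
        stream = ec.compress(short_record, "fir", threshold_percent=4,
                             quant_bits=6)
        path = str(tmp_path / "x.eqod")
        stream.tofile(path)
        back = ec.CompressedStream.fromfile(path)
        assert back.data == stream.data
        assert back.infos == stream.infos


def test_multichannel_independent_coding(tmp_path):
    rng = np.random.default_rng(8)
    base = ec.synth_eeg(ec.PROFILES["normal_eyes"].with_(duration_s=3.0))
    other = ec.synth_eeg(ec.PROFILES["normal_eyes"].with_(duration_s=3.0,
                                                          seed=9))
    rec = ec.EEGRecord(["a", "b"],
                       np.vstack([base.samples, other.samples]), 256.0)
    stream, recon = ec.encode_record(rec, "slp", threshold_percent=0.0)
    out = ec.decompress(stream)
    assert np.array_equal(out.samples, rec.samples)
    assert len(stream.infos) == 2


def test_encoder_decoder_state_equivalence(short_record):
    """After every sample both sides hold identical reconstructed
    histories — checked on the real-valued internal state, not just the
    rounded output."""
    x = short_record.channel(0).astype(float)
    model = ec.train_predictor(short_record,
                               ec.default_config("slp")).round_to_float32()
    e_open = ec.open_loop_residues(model, x)
    T_abs = 0.05 * np.max(np.abs(e_open))
    delta = ec.make_quantizer(ec.threshold_residues(e_open, T_abs), 7)
    levels, recon_enc, q, sat = _closed_loop_encode(x, model, T_abs, 7, delta)
    recon_dec = _closed_loop_decode(x[:5], levels, model, delta)
    assert np.array_equal(recon_enc, recon_dec)      # bitwise, all samples


def test_near_lossless_bound_single_point(short_record):
    stream, recon = ec.encode_record(short_record, "slp",
                                     threshold_percent=6, quant_bits=6)
    ci = stream.infos[0]
    err = np.abs(short_record.samples - recon.samples)
    bound = max(ci.T_abs, ci.delta / 2) + 0.5
    assert int(np.sum(err > bound)) <= ci.n_saturated
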