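import numpy as np
import pytest

import eegcodec as ec


@pytest.fixture(scope="session")
def normal_record():
    """10 s of the normal (alpha-rhythm) profile, seed 0."""
    return ec.synth_eeg(ec.PROFILES["normal_eyes"])


@pytest.fixture(scope="session")
def ictal_record():
    return ec.synth_eeg(ec.PROFILES["ictal"])


@pytest.fixture(scope="session")
def short_record():
    """5 s record for tests that train the slower networks."""
    return ec.synth_eeg(ec.PROFILES["normal_eyes"].with_(duration_s=5.0))


def ar1_series(phi: float, n: int, seed: int, scale: float = 2000.0,
               noise: float = 100.0) -> np.ndarray:
    """Integer-quantized AR(1) process for predictor-recovery tests."""
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = 0.0
    eps = rng.standard_normal(n) * noise
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    return np.clip(np.round(x), -32768, 32767).astype(np.int64)


@pytest.fixture(scope="session")
def grid_sweep(normal_record):
    """Full (T, QL, predictor) grid with per-point codec bookkeeping.

    Models are trained once per predictor; every grid point records the
    stream bookkeeping (T_abs, delta, saturation count) plus the maximum
    per-sample reconstruction error, so both the near-lossless bound and
    the rate-distortion trends can be checked from one pass.
    """
    import pandas as pd

    rec = normal_record
    x = rec.channel(0)
    ql_map = ec.ql_preset("normal_eyes")
    rows = []
    for kind in ("slp", "ar", "fir"):
        cfg = ec.default_config(kind, seed=0)
        model = ec.train_predictor(rec, cfg)
        for t in range(1, 11):
            for ql, r in sorted(ql_map.items()):
                stream, recon = ec.encode_record(
                    rec, cfg, threshold_percent=float(t), quant_bits=r,
                    models=[model])
                ci = stream.infos[0]
                err = np.abs(x - recon.channel(0))
                fid = ec.evaluate(rec, recon)
                rows.append({
                    "predictor": kind, "threshold_pct": float(t), "ql": ql,
                    "quant_bits": r, "T_abs": ci.T_abs, "delta": ci.delta,
                    "q": ci.q, "n_saturated": ci.n_saturated,
                    "max_err": float(err.max()),
                    "n_above_bound": int(np.sum(
                        err > max(ci.T_abs, ci.delta / 2) + 0.5)),
                    "cr_actual": rec.n_samples * rec.bit_depth / stream.total_bits,
                    "bps_actual": stream.total_bits / rec.n_samples,
                    "prd": fid.prd, "cc": fid.cc,
                })
    return pd.DataFrame(rows)
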