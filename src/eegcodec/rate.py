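"""Compression-ratio accounting, (T, QL) sweeps and operating-point choice.

Two compression-ratio figures are reported for every operating point:

``cr_formula``
    The classical predictive-coding formula
    ``CR = v*n / (p*n + w*x + (v - p - q)*r)`` — seed samples at ``n`` bits,
    ``w`` weights at ``x`` bits, and the ``v - p - q`` surviving residues at
    ``r`` bits each.  It charges nothing for locating the ``q``
    threshold-suppressed residues, a cost no real decoder can avoid.
``cr_actual``
    ``v*n`` divided by the actual serialized stream size in bits — header,
    arithmetic-coded payload (where suppressed residues are paid for as
    cheap zero symbols), padding and CRC included.

Their ratio is data dependent: the formula ignores both the zero-location
cost (making it optimistic) and the entropy coder's gains on the surviving
residues (making it pessimistic), so neither dominates the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codec import CompressedStream, encode_record
from .fidelity import FidelityReport, evaluate
from .predictors import PredictorConfig, default_config, train_predictor
from .records import EEGRecord

__all__ = [
    "compression_ratio",
    "bits_per_sample",
    "QL_PRESETS",
    "ql_preset",
    "OperatingPoint",
    "sweep",
    "BandUnreachableError",
    "select_operating_point",
]

logger = logging.getLogger(__name__)

#: Quantization-level presets (bits per residue at Q1/Q2/Q3) per profile
#: class — finer for wideband seizure data, coarser for the low-rate ictal
#: recordings.
QL_PRESETS: dict[str, dict[str, int]] = {
    "epileptic_seizure": {"Q1": 9, "Q2": 8, "Q3": 7},
    "normal_eyes": {"Q1": 8, "Q2": 7, "Q3": 6},
    "ictal": {"Q1": 6, "Q2": 5, "Q3": 4},
}

#: Default threshold grid: 1..10 percent of the peak open-loop residue.
THRESHOLD_GRID = tuple(range(1, 11))


def ql_preset(profile_name: str) -> dict[str, int]:
    """QL -> residue bits mapping for a synthetic profile name."""
    try:
        return dict(QL_PRESETS[profile_name])
    except KeyError:
        raise KeyError(
            f"no QL preset for {profile_name!r}; known: {sorted(QL_PRESETS)}"
        ) from None


def compression_ratio(v: int, n: int, p: int, q: int, w: int, x: int,
                      r: int) -> float:
    """Formula CR = v*n / (p*n + w*x + (v-p-q)*r)."""
    for name, val in [("v", v), ("n", n), ("p", p), ("q", q), ("w", w),
                      ("x", x), ("r", r)]:
        if val < 0:
            raise ValueError(f"{name} must be >= 0")
    if v <= p:
        raise ValueError("v must exceed p")
    denom = p * n + w * x + (v - p - q) * r
    if denom <= 0:
        raise ValueError("non-positive denominator")
    return v * n / denom


def bits_per_sample(cr_or_stream, n: int | None = None) -> float:
    """BPS from a compression ratio (``n / CR``) or a stream (exact).

    For a :class:`CompressedStream` this is ``total_bits / v`` per channel
    sample, the honest figure including all header costs.
    """
    if isinstance(cr_or_stream, CompressedStream):
        s = cr_or_stream
        return s.total_bits / (s.n_samples * len(s.channels))
    cr = float(cr_or_stream)
    if cr <= 0:
        raise ValueError("compression ratio must be positive")
    if n is None:
        raise ValueError("bit depth n required with a numeric CR")
    return n / cr


def _stream_cr_formula(stream: CompressedStream) -> float:
    """Eq-style CR aggregated over channels (sum of bit budgets)."""
    n = stream.bit_depth
    v = stream.n_samples
    num = 0
    den = 0
    for ci in stream.infos:
        num += v * n
        den += ci.order * n + ci.n_weights * ci.weight_bits \
            + (v - ci.order - ci.q) * ci.quant_bits
    return num / den


@dataclass(frozen=True)
class OperatingPoint:
    """One (predictor, T%, QL) codec configuration with its measurements."""

    predictor: str
    threshold_percent: float
    ql: str
    quant_bits: int
    cr_formula: float
    cr_actual: float
    bps_formula: float
    bps_actual: float
    fidelity: FidelityReport

    def as_row(self) -> dict:
        row = {
            "predictor": self.predictor,
            "threshold_pct": self.threshold_percent,
            "ql": self.ql,
            "quant_bits": self.quant_bits,
            "cr_formula": self.cr_formula,
            "cr_actual": self.cr_actual,
            "bps_formula": self.bps_formula,
            "bps_actual": self.bps_actual,
        }
        row.update(self.fidelity.as_dict())
        return row


def sweep(record: EEGRecord,
          predictors=("slp",),
          threshold_grid=THRESHOLD_GRID,
          ql_map: dict[str, int] | None = None,
          seed: int = 0) -> pd.DataFrame:
    """Measure every (predictor, T, QL) operating point on one record.

    Each predictor is trained once per channel and reused across the grid
    (the threshold and quantizer do not enter training).  Returns a tidy
    DataFrame, one row per operating point, with rate columns
    (cr_formula/cr_actual/bps_*) and the full fidelity report; rows are
    ordered by predictor, threshold, then QL.
    """
    if ql_map is None:
        name = record.channels[0]
        ql_map = QL_PRESETS.get(name, QL_PRESETS["normal_eyes"])
    if any(not 0 <= t <= 10 for t in threshold_grid):
        raise ValueError("threshold grid must lie within [0, 10] percent")

    rows = []
    for pred in predictors:
        cfg = pred if isinstance(pred, PredictorConfig) else \
            default_config(pred, seed=seed)
        models = []
        for ch in range(record.n_channels):
            ch_rec = EEGRecord(channels=[record.channels[ch]],
                               samples=record.samples[ch:ch + 1],
                               sampling_rate_hz=record.sampling_rate_hz,
                               bit_depth=record.bit_depth)
            models.append(train_predictor(ch_rec, cfg))
        for t in threshold_grid:
            for ql, r in sorted(ql_map.items()):
                stream, recon = encode_record(
                    record, cfg, threshold_percent=float(t), quant_bits=r,
                    models=models)
                fid = evaluate(record, recon)
                cr_f = _stream_cr_formula(stream)
                cr_a = record.n_samples * record.n_channels * \
                    record.bit_depth / stream.total_bits
                op = OperatingPoint(
                    predictor=cfg.kind, threshold_percent=float(t), ql=ql,
                    quant_bits=r, cr_formula=cr_f, cr_actual=cr_a,
                    bps_formula=record.bit_depth / cr_f,
                    bps_actual=bits_per_sample(stream),
                    fidelity=fid,
                )
                logger.debug("sweep %s T=%s %s: CR %.3f/%.3f PRD %.3f",
                             cfg.kind, t, ql, cr_f, cr_a, fid.prd)
                rows.append(op.as_row())
    return pd.DataFrame(rows)


class BandUnreachableError(ValueError):
    """No swept operating point falls inside the requested PRD band."""

    def __init__(self, band, nearest_prd):
        self.band = band
        self.nearest_prd = nearest_prd
        super().__init__(
            f"no operating point with PRD in [{band[0]}, {band[1]}); "
            f"nearest achievable PRD is {nearest_prd}"
        )


def select_operating_point(table: pd.DataFrame,
                           prd_band: tuple[float, float]) -> pd.Series:
    """Cheapest operating point whose PRD lies in ``[lo, hi)``.

    This is the quality-on-demand step: the receiving physician states a
    tolerable PRD band and gets the configuration with the lowest actual
    bits per sample; ties break toward the lower threshold, then the lower
    residue bit count.
    """
    lo, hi = prd_band
    if table.empty:
        raise ValueError("empty sweep table")
    feasible = table[(table["prd"] >= lo) & (table["prd"] < hi)]
    if feasible.empty:
        mid = 0.5 * (lo + hi)
        nearest = float(table.loc[(table["prd"] - mid).abs().idxmin(), "prd"])
        raise BandUnreachableError(prd_band, nearest)
    ordered = feasible.sort_values(
        ["bps_actual", "threshold_pct", "quant_bits"],
        ascending=[True, True, True],
    )
    return ordered.iloc[0]
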