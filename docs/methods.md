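# Methods

This note records the model, the numerical choices, and the limits of what
the synthetic experiments demonstrate.

## Codec model

The codec is closed-loop DPCM with a near-lossless residual stage.  Per
channel (channels are coded independently; no cross-channel prediction):

1. **Training.**  A predictor is trained on the channel's own samples,
   normalised to [−1, 1] by `2^(n−1)` (`n` = bit depth; sigmoid activations
   need bounded inputs).  The trained weights are rounded to IEEE-754
   single precision *before* encoding, because the decoder only ever sees
   the float32 weights from the header — both sides must predict with the
   identical numbers.
2. **Threshold scale.**  One open-loop pass over the original samples
   yields residues `e_n = X_n − X̂_n`; the absolute threshold is
   `T_abs = T% × max|e|`.  Freezing `T_abs` from the open-loop pass makes
   "percent of the peak residue" well defined before quantization feedback
   exists; `T_abs` is transmitted, not recomputed.
3. **Quantizer.**  Uniform midtread with step
   `Δ = max|e_T| / (2^(r−1) − 1)`, so the `2^(r−1) − 1` levels per sign
   cover the thresholded open-loop residues without saturation.  Level
   `k = clamp(⌊e/Δ + 0.5⌋)`; index 0 reconstructs exactly 0, so suppressed
   residues decode to zero by construction.  Closed-loop residues can
   slightly exceed the open-loop peak; those samples saturate, are counted
   in the stream bookkeeping, and are the only ones exempt from the error
   bound.
4. **Closed loop.**  For each sample past the first `p`, prediction uses
   the *reconstructed* history `X̃ = X̂ + kΔ` (kept in float64; rounding to
   integer happens only at the output).  Open-loop encoding would let the
   decoder drift without bound once residues are lossy; the closed loop is
   what makes the per-sample bound
   `|X_n − X̃_n| ≤ max(T_abs, Δ/2) + 0.5` hold for non-saturated samples.
   At `T = 0` and `Δ ≤ 0.5` every quantization error is below the final
   0.5-LSB rounding step, so reconstruction is bit-exact (the lossless
   limit; `lossless_quant_bits` picks `r` with a 2× level headroom to keep
   the closed-loop pass out of saturation).
5. **Entropy coding.**  Quantizer levels, offset to `[0, 2^r − 2]`, go
   through an adaptive order-0 arithmetic coder (32-bit registers, counts
   initialised to 1, halved at a 2^16 total cap, Fenwick-tree cumulative
   counts).  Suppressed residues are coded as ordinary zero symbols — their
   high probability makes them cheap, and unlike dropping them from the
   bit budget, a real decoder can actually locate them.
6. **Bitstream.**  Magic `EQOD`, version byte, big-endian header (bit
   depth, rate, length, per-channel predictor architecture + float32
   weights + first `p` samples packed at `n` bits + `T`, `Δ`, `r` and the
   bookkeeping counts), byte-padded arithmetic payload, trailing CRC-32.
   The decoder needs nothing outside the stream; any corruption fails the
   CRC rather than yielding a silently wrong record.

## Predictors

* **SLP** — linear, order 5 + bias; Levenberg–Marquardt (standard damping:
  λ starts at 1e-3, ×10 on a rejected step, ÷10 on acceptance; full-batch
  Jacobian; stop at the epoch budget, at normalised-MSE 1e-5, or when no
  damping step improves).  On a linear model LM converges to the
  normal-equations least-squares solution, which the tests assert to 1e-6.
* **MLP** — order 3, five log-sigmoid hidden units, linear output, LM with
  the analytic Jacobian.
* **Elman network** — order 5, five tan-sigmoid hidden units whose
  previous activation re-enters as context, linear output; trained with
  GDX (learning rate 0.01, momentum 0.9, lr ×1.05 on improvement, ×0.7
  with a rejected step when the error grows > 4%) on teacher-forced,
  one-step-truncated gradients — the classic Elman scheme; full BPTT is
  deliberately out of scope.  The context is zeroed at every block start
  so encoder and decoder agree without transmitting state.
* **AR** — least-squares (covariance method), no intercept; rank-deficient
  systems fall back to the last-value predictor.
* **FIR** — Wiener one-step design by the autocorrelation method (Toeplitz
  normal equations on the biased autocorrelation).  AR and FIR are both
  order-5 least-squares linear predictors and serve as the linear baseline
  for the networks.

Epoch budgets (65 / 230 / 750 for SLP / MLP / EN) are stopping defaults,
not exact rules.  Weight initialisation is uniform [−0.5, 0.5] from the
model seed; every training path is a pure function of (data, config).
Every trained model is checked against the zero predictor and falls back
to zero output (logged) if an unlucky run ends worse — in-sample this
essentially never triggers.

## Fidelity metrics

All logarithms are base-10 dB.  `PRD = 100·√(Σ(X−X̃)²/ΣX²)` over the whole
record (windowed evaluation is available by slicing);
`SNR = −20·log10(0.01·PRD)`; `RMSE = √(Σ(X−X̃)²/N)`;
`PSNR = 20·log10(max|X|/RMSE)` (reported +∞ for exact recovery); CC is the
Pearson correlation — the only reading under which a perfect
reconstruction scores 1.  PSD comparison uses Welch (segment 256, 50%
overlap, Hamming) and summarises the RMS difference of the log-spectra
over bins within 60 dB of the original's spectral peak; quieter bins carry
no diagnostic weight and would dominate the log distance as noise.

## Rate accounting

`cr_formula` applies `CR = vn/(pn + wx + (v−p−q)r)` with `x = 32` bits per
weight and `q` the count of threshold-suppressed residues.  `cr_actual`
divides `v·n` by the full serialized stream size.  Neither bounds the
other: the formula omits the cost of locating suppressed residues
(optimistic) and the entropy-coding gain on the survivors (pessimistic),
so both are reported.  QL presets per profile are Q1/Q2/Q3 =
{9,8,7}, {8,7,6}, {6,5,4} bits; the threshold grid is 1–10% in steps of 1.

## Synthetic EEG

Real clinical recordings are not redistributable, so the generator
produces the three target classes from components with known spectra:

* `epileptic_seizure` — 1/f background (β = 1) plus a weak 10 Hz component
  and intermittent ~3 Hz spike-wave bursts (2 s Hann-windowed bursts, a
  sharp per-cycle transient plus a slow half-sine wave) at 256 Hz;
* `normal_eyes` — 1/f background plus a 10 Hz ± 1 Hz alpha band, 256 Hz;
* `ictal` — dominant 2–5 Hz high-amplitude rhythm over a weak background,
  173.61 Hz.

Narrow-band components are Gaussian processes shaped in the frequency
domain; amplitudes are scaled so the peak occupies ~50% of the signed
16-bit range before rounding.  Ten-second records are the default study
size — long enough for stable Welch spectra and adaptive-coder
convergence on the lossy grid, short enough that the full acceptance grid
runs in seconds.

What the profiles emulate: the dominant rhythms, the 1/f spectral
envelope, amplitude scale, sampling rates, and strong lag-1
autocorrelation (> 0.9 for ictal), hence realistic prediction gains.
What they do not: artifacts (eye blinks, EMG, electrode pops),
non-stationary background drift, inter-channel correlation, or true
seizure morphology.  Passing tests therefore demonstrate the *codec's*
contracts (exact losslessness, error bounds, rate orderings) on
EEG-like statistics — not clinical rate figures, which depend on the
recording and are explicitly not reproduced here.

## Numerical notes and edge cases

* Quantizer rounding is half-up; only the encoder quantizes, so the choice
  needs no cross-side agreement.  Reconstruction arithmetic *is*
  cross-side: both run `X̂ + kΔ` in float64 in identical order.
* An all-zero thresholded block degenerates to `Δ = 1` (transmitted as
  such); a constant channel trains to an exact predictor and codes to a
  stream of zero symbols.
* The arithmetic coder starts from a uniform model; with the large
  alphabets of the lossless limit (`r ≈ 15`) a 10 s record is too short
  for the model to adapt, so lossless bits-per-sample can approach — for
  unlucky seeds slightly exceed — the raw 16 bits.  The lossless limit is
  the codec's correctness anchor, not its operating regime; the lossy grid
  compresses 2.5–4× throughout.
* PRD is non-decreasing in `T` wherever the threshold is active
  (`T_abs ≥ Δ/2`).  Below the quantizer's dead zone the threshold zeroes
  residues the midtread quantizer would map to level 0 anyway, and two
  such operating points differ only through closed-loop feedback noise;
  strict per-step monotonicity is not a theorem there, and the acceptance
  test scopes the assertion accordingly.
* Thresholding keeps the boundary case `|e| = T` (transmitted), and is
  idempotent.
* EDF stores the sampling rate as samples-per-record over an 8-character
  record duration; 173.61 Hz is not exactly representable, so the writer
  also embeds `SR=<rate>` in the per-signal prefiltering field and the
  reader prefers it, keeping round-trips exact while remaining readable by
  standard EDF tools (verified against mne).

## Design choices that were genuinely open

* **Closed-loop prediction** despite the residue definition being written
  on originals: open-loop encoding under lossy residues has unbounded
  decoder drift and contradicts the requirement that both ends simulate an
  identical process.
* **Zero symbols are paid for** in the bitstream rather than dropped from
  the accounting; the formula CR is still reported for comparability.
* **Weight precision 32 bits**: single precision keeps headers small
  (~200 bits for the SLP) and the prediction mismatch at float32 rounding
  is absorbed by the closed loop on both sides equally.
* **Whole-record = one block**: no mid-stream retraining; simplest
  reproducible contract, appropriate at the 10 s scale studied.
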