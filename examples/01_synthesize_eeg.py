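"""Generate the three synthetic EEG profiles and inspect their spectra.

Each profile emulates one clinical recording condition: epileptic
background with 3 Hz spike-wave bursts, normal awake EEG with a 10 Hz
alpha rhythm, and ictal (in-seizure) activity dominated by 2-5 Hz waves.
"""

import numpy as np

import eegcodec as ec

for name in sorted(ec.PROFILES):
    rec = ec.synth_eeg(ec.PROFILES[name])
    x = rec.channel(0).astype(float)
    f, p = ec.psd(x, rec.sampling_rate_hz)
    dominant = f[np.argmax(p * (f > 0.5))]   # ignore the DC-adjacent bins
    xc = x - x.mean()
    lag1 = (xc[:-1] @ xc[1:]) / (xc @ xc)
    print(f"{name:18s} {rec.n_samples:5d} samples @ {rec.sampling_rate_hz:7.2f} Hz  "
          f"peak |x| {np.abs(x).max():7.0f}  dominant {dominant:5.2f} Hz  "
          f"lag-1 autocorr {lag1:.3f}")

print()
print("The dominant spectral peak sits in the band each profile prescribes")
print("(3 Hz spike-wave, 10 Hz alpha, 2-5 Hz ictal delta/theta), and the")
print("high lag-1 autocorrelation is what a one-step predictor exploits.")
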