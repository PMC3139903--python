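"""Sweep the quality-on-demand grid and pick operating points per PRD band.

The two knobs are the residual threshold T (percent of the peak residue)
and the quantization level QL (bits per residue).  The sweep measures
rate (CR, bits per sample) and fidelity at every grid point; the selector
then answers "cheapest configuration with PRD in a requested band".
"""

import eegcodec as ec
from eegcodec.rate import BandUnreachableError

rec = ec.synth_eeg(ec.PROFILES["normal_eyes"])
table = ec.sweep(rec, predictors=("slp", "ar"),
                 threshold_grid=(1, 3, 5, 7, 9),
                 ql_map=ec.ql_preset("normal_eyes"))

cols = ["predictor", "threshold_pct", "ql", "cr_actual", "bps_actual",
        "prd", "cc"]
print(table[cols].round(3).to_string(index=False))
print()

for band in ((0.0, 1.0), (1.0, 3.0), (3.0, 5.0)):
    try:
        row = ec.select_operating_point(table, band)
        print(f"PRD in [{band[0]}, {band[1]}): T={row['threshold_pct']:.0f}% "
              f"{row['ql']} -> {row['bps_actual']:.2f} bits/sample "
              f"(PRD {row['prd']:.2f}, CC {row['cc']:.4f})")
    except BandUnreachableError as exc:
        print(f"PRD in [{band[0]}, {band[1]}): unreachable "
              f"(nearest PRD {exc.nearest_prd:.2f})")
print()
print("Looser quality bands buy lower bit rates — the quality-on-demand")
print("trade a telemedicine receiver dials in.")
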