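"""Compute ENMO and MAD for a tiny hand-built raw recording.

Builds a 100 Hz signal: 5 s perfectly still (gravity on +z), then 5 s with
a 50 mg oscillation superimposed, and prints the two intensity metrics per
5-second epoch.  The still epoch shows both metrics at zero; the moving
epoch shows how each metric captures the dynamic component (ENMO via the
clamped magnitude excess over 1 g, MAD via dispersion about the epoch
mean).
"""

import numpy as np

from accelcut import RawRecording, compute_epoch_metrics

fs = 100.0
t = np.arange(500) / fs

still = np.tile([0.0, 0.0, 1000.0], (500, 1))
moving = still.copy()
moving[:, 2] += 50.0 * np.sin(2 * np.pi * 2.0 * t)  # 50 mg sway at 2 Hz

rec = RawRecording(xyz=np.vstack([still, moving]), fs=fs, participant_id="demo")
table = compute_epoch_metrics(rec, epoch_s=5.0)

print(table[["epoch_start", "enmo_mg", "mad_mg"]].round(2).to_string(index=False))
print()
print(
    "Epoch 0 is at rest: magnitude is exactly 1 g, so ENMO and MAD are 0.\n"
    "Epoch 1 carries a 50 mg sinusoid: MAD ~ 2/pi * 50 ~ 31.8 mg measures the\n"
    "dispersion; ENMO ~ 15.9 mg because only above-1 g half-waves survive the\n"
    "negative clamp."
)
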