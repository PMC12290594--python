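"""Plant a heartbeat-locked artifact and remove it by joint decorrelation.

Simulates 5 minutes of microstate-structured EEG contaminated by a
ballistocardiogram-like artifact (fixed spatial patterns x stereotyped
waveforms locked to ~1 Hz R-peaks), fits the joint-decorrelation model
and projects out the components whose rescaled eigenvalue exceeds the
threshold.
"""

import numpy as np

from msretest import (
    SynthConfig, apply_jd, erp, fit_jd, select_events, simulate_recording,
    spatial_corr,
)

cfg = SynthConfig(n_channels=32, duration_s=300.0, bcg_snr=2.0,
                  n_bcg_components=3, seed=11)
rec, truth = simulate_recording(cfg)
r_peaks = select_events(rec, "R")
print(f"recording: {rec.n_channels} ch, {rec.duration_s:.0f} s, "
      f"{len(r_peaks)} heartbeats")

model = fit_jd(rec, r_peaks, n_avg=25, seed=1)
print(f"noise-reduction ratio gamma_bar = {model.gamma_bar:.1f} "
      f"(about the block size 25: averaging 25 epochs cuts variance 25-fold)")
print(f"top rescaled eigenvalues: {np.round(model.rescaled[:5], 2)} "
      f"(values near 1 = heartbeat locking explains nothing extra)")

result = apply_jd(rec, model, threshold=1.15)
print(f"threshold 1.15 rejects {len(result.rejected_indices)} of "
      f"{rec.n_channels} components")

for i in result.rejected_indices:
    best = max(spatial_corr(model.patterns[:, i], p) for p in truth.bcg_patterns)
    print(f"  component {i}: |corr| with closest planted artifact "
          f"topography = {best:.3f}")

# heartbeat-locked evoked power before/after, the direct artifact read-out
before = erp(rec, r_peaks, window=(0.0, 0.7), baseline=(0.0, 0.02))
after = erp(result.cleaned, r_peaks, window=(0.0, 0.7), baseline=(0.0, 0.02))
ratio = np.mean(after.data ** 2) / np.mean(before.data ** 2)
print(f"heartbeat-locked evoked power reduced to {100 * ratio:.1f}% of its "
      f"uncleaned value")
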