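"""Choose a low-pass cutoff by residual analysis.

Builds a 1 Hz movement signal contaminated with wideband noise and lets
the Winter-style residual analysis pick the cutoff where the residual
meets the extrapolated noise floor.
"""
import numpy as np

from mechwork.signal_processing import (
    TimeSeries,
    butterworth_lowpass,
    residual_analysis_cutoff,
)

rng = np.random.default_rng(3)
rate = 200.0
t = np.arange(int(30 * rate)) / rate
signal = 0.4 * np.sin(2 * np.pi * 1.0 * t) + 0.1 * np.sin(2 * np.pi * 2.5 * t)
noise = rng.normal(0.0, 0.01, t.size)
series = TimeSeries(signal + noise, rate)

candidates = list(np.arange(2.0, 21.0, 1.0))
cutoff = residual_analysis_cutoff(series, candidates)
filtered = butterworth_lowpass(series, cutoff)
residual = np.sqrt(np.mean((series.values - filtered.values) ** 2))

print(f"candidate cutoffs: {candidates[0]:.0f}..{candidates[-1]:.0f} Hz")
print(f"selected cutoff:   {cutoff:.0f} Hz")
print(f"residual at selection: {residual:.4f} (injected noise RMS "
      f"{np.sqrt(np.mean(noise**2)):.4f})")
print("the residual at the chosen cutoff matches the injected noise floor:")
print("the filter removes noise while leaving the movement content intact.")
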