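"""Choi-Williams analysis of a two-tone signal: marginals and cross-terms.

A bilinear time-frequency distribution of an 8 Hz + 16 Hz mixture shows
oscillatory cross-terms midway between the tones (around 12 Hz). The kernel
parameter sigma controls how hard they are suppressed; the marginal
identities tie the distribution back to instantaneous power and energy.
"""

import numpy as np
from scipy.signal import hilbert

from cwdetect import cwd, marginal_freq, marginal_time, total_power, truncate_positive

fs = 250.0
t = np.arange(512) / fs
x = np.sin(2 * np.pi * 8 * t) + np.sin(2 * np.pi * 16 * t)

print("midband (11.5-12.5 Hz) cross-term level vs kernel parameter sigma:")
for sigma in (10.0, 1.0, 0.1, 0.01):
    m = cwd(x, fs, sigma=sigma)
    sel = (m.freq_axis >= 11.5) & (m.freq_axis <= 12.5)
    print(f"  sigma={sigma:>5}: {np.abs(m.values[:, sel]).mean():.4f}")
print("-> smaller sigma suppresses the interference between the tones harder.\n")

m = cwd(x, fs, sigma=1.0)
analytic_energy = float(np.sum(np.abs(hilbert(x)) ** 2) / fs)
print(f"total power of the distribution : {total_power(m):.4f}")
print(f"analytic signal energy          : {analytic_energy:.4f}")

mt = marginal_time(m)
inst = np.abs(hilbert(x)) ** 2
c = slice(128, 384)
print(f"time-marginal RMS error (central half): "
      f"{np.sqrt(np.mean((mt[c] - inst[c]) ** 2)) / inst[c].mean():.2e}")

mf = marginal_freq(m)
lo = (m.freq_axis >= 4) & (m.freq_axis <= 12)
hi = (m.freq_axis >= 12) & (m.freq_axis <= 20)
print("frequency-marginal peaks: "
      f"{m.freq_axis[lo][np.argmax(mf[lo])]:.1f} Hz and "
      f"{m.freq_axis[hi][np.argmax(mf[hi])]:.1f} Hz (true tones at 8 and 16 Hz)")

tr = truncate_positive(m)
print(f"\nnegative fraction before truncation: {(m.values < 0).mean():.2%}; "
      f"after: {(tr.values < 0).mean():.0%} "
      "(the positive part carries the component information)")
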