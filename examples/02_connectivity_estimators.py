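"""wPLI and AEC-c on signals with known coupling.

Constructs three textbook cases and prints both estimators' values:
a constant-lag pair (pure phase coupling), a zero-lag mixture of one
source (pure volume conduction), and a shared-envelope pair with
orthogonal carriers (pure amplitude coupling).
"""

import numpy as np
from scipy.signal import butter, sosfiltfilt

from eegmst import aec_pair, analytic_signal, wpli_pair

fs, n = 512.0, 7 * 4096
rng = np.random.default_rng(0)
sos = butter(4, [7.0, 13.0], btype="bandpass", fs=fs, output="sos")
narrowband = lambda: sosfiltfilt(sos, rng.standard_normal(n))

# 1. constant phase lag: the phase-coupling signature wPLI is built for
x = narrowband()
z = analytic_signal(x)
y = (z * np.exp(-1j * np.pi / 3)).real
print("constant pi/3 lag:       wPLI = %.3f   AEC-c = %.3f"
      % (wpli_pair(z, analytic_signal(y)), aec_pair(x, y)))

# 2. zero-lag mixture of a single source: the volume-conduction confound
s = narrowband()
a, b = s, 0.6 * s + 0.05 * narrowband()
print("zero-lag mixture:        wPLI = %.3f   AEC-c = %.3f"
      % (wpli_pair(analytic_signal(a), analytic_signal(b)), aec_pair(a, b)))

# 3. shared slow envelope on independent carriers: AEC-c sees it, wPLI cannot
t = np.arange(n) / fs
m = 1.0 + 0.5 * np.sin(2 * np.pi * 0.3 * t)
z1, z2 = analytic_signal(narrowband()), analytic_signal(narrowband())
p, q = m * (z1 / np.abs(z1)).real, m * (z2 / np.abs(z2)).real
print("shared envelope:         wPLI = %.3f   AEC-c = %.3f"
      % (wpli_pair(analytic_signal(p), analytic_signal(q)), aec_pair(p, q)))

print("\nwPLI responds only to consistent nonzero phase lags; AEC-c responds "
      "to co-modulated amplitudes after zero-lag leakage is regressed out. "
      "Neither is fooled by the instantaneous mixture in case 2.")
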