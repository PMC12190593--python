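"""Delta-gamma coupling strength via the 18-bin modulation index.

Sweeps the generator's true coupling depth chi and shows that the
measured MI rank-orders it, then destroys the coupling with a circular
amplitude shift (surrogate control).
"""

import numpy as np

from pacnet import DELTA, GAMMA, GeneratorSpec, gen_coupled_channel, mi_from_series, surrogate_mi
from pacnet.spectral import analytic_signal, bandpass_signal, edge_samples


def measure_mi(chi, seed):
    spec = GeneratorSpec(chi=chi, duration_s=60.0, seed=seed)
    x, _ = gen_coupled_channel(spec, np.random.default_rng(seed))
    slow = bandpass_signal(x, spec.fs, DELTA)
    fast = bandpass_signal(x, spec.fs, GAMMA)
    trim = edge_samples(DELTA, spec.fs, len(x))
    phase = analytic_signal(slow, spec.fs, DELTA).phase[trim:-trim]
    amp = analytic_signal(fast, spec.fs, GAMMA).amplitude[trim:-trim]
    return phase, amp, mi_from_series(phase, amp).mi


print("true chi ->  measured MI (18 phase bins, 60 s at 1 kHz)")
for chi in (0.0, 0.2, 0.4, 0.6, 0.8):
    _, _, mi = measure_mi(chi, seed=3)
    print(f"   {chi:.1f}   ->  {mi:.5f}")

phase, amp, intact = measure_mi(0.8, seed=3)
rng = np.random.default_rng(0)
sur = np.median([surrogate_mi(phase, amp, rng, fs=1000.0).mi for _ in range(10)])
print(f"\nsurrogate control at chi=0.8: intact MI {intact:.5f}, "
      f"median shifted MI {sur:.5f} ({100 * (1 - sur / intact):.0f}% reduction)")
print("MI grows monotonically with the true modulation depth and collapses")
print("when the phase-amplitude alignment is destroyed - it measures")
print("coupling, not band power.")
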