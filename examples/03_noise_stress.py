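"""Noise stress: how sync delay degrades as SNR falls.

Aligns the same 20 sample pairs under electrode-motion noise injected at
each SNR level of the stress grid.  Above the 6 dB pivot the alignment is
essentially exact; below it, gross misalignments (picking the wrong beat
or worse) appear and inflate the mean.
"""

import numpy as np

from ecgsync.experiments import BenchmarkConfig, build_pairs, evaluate_pair

cfg = BenchmarkConfig(pairs=20)
pairs = build_pairs(20, 30.0, cfg, seed=4)

print("SNR (dB)   mean sync delay (s)   gross failures (>0.5 s)")
for snr in (24, 12, 6, 0, -6):
    delays = np.array([
        evaluate_pair(p, cfg, "EM", snr, seed=100 * (snr + 6) + i)["sync_delay_seconds"]
        for i, p in enumerate(pairs)
    ])
    print(f"{snr:+7d}   {delays.mean():19.3f}   {np.sum(delays > 0.5):d}/20")
# Baseline wander and muscle artifact barely move these numbers: the 2-10 Hz
# alignment band-pass excludes almost all of their power.
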