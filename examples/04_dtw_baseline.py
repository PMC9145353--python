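"""Compare amplitude cross-correlation against DTW on RR intervals.

The DTW baseline reduces each signal to its beat-to-beat intervals and can
therefore only localize the reference to about one heartbeat; the
cross-correlation estimator works at the sample level.
"""

import numpy as np

from ecgsync.experiments import BenchmarkConfig, build_pairs, evaluate_pair

cfg = BenchmarkConfig(pairs=10)
pairs = build_pairs(10, 30.0, cfg, seed=5)

for method in ("xcorr", "dtw"):
    delays = [
        evaluate_pair(p, cfg, "EM", 6.0, seed=i, method=method)["sync_delay_seconds"]
        for i, p in enumerate(pairs)
    ]
    print(f"{method:6s}: mean sync delay {np.mean(delays):.3f} s "
          f"(median {np.median(delays):.3f} s) over {len(pairs)} pairs")
# Cross-correlation errs by a few milliseconds on every pair.  DTW is
# limited by beat-timing granularity: when the RR pattern is distinctive it
# can land within a fraction of a beat, but ambiguous rhythm stretches
# produce gross misalignments that dominate its mean.
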