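"""Align a short watch-style ECG sample inside a longer patch recording.

Builds a synthetic pair of simultaneously recorded leads (lead I for the
watch, lead V2 for the patch), cuts a 30 s reference from lead I and a 90 s
search window from lead V2 that starts 30 s earlier, preprocesses both, and
sweeps the Pearson correlation over every sample lag.  The argmax is the
estimated position of the reference inside the search window; ground truth
is 30 s by construction.
"""

from ecgsync import RhythmSpec, estimate_sync_delay, generate_record_pair, preprocess

lead_i, lead_v2, r_times = generate_record_pair(
    duration=180, rhythm=RhythmSpec(mean_hr=70, rr_jitter_sd=0.04), seed=1
)

start = 60.0
reference = preprocess(lead_i.slice_seconds(start, start + 30))
search = preprocess(lead_v2.slice_seconds(start - 30, start + 60))

result = estimate_sync_delay(reference, search)
error = abs(result.lag_seconds - 30.0)

print(f"estimated lag : {result.lag_seconds:.3f} s (truth: 30.000 s)")
print(f"sync delay    : {error * 1000:.1f} ms")
print(f"peak Pearson r: {result.peak_r:.3f} over {len(result.curve)} lags")
# The sync delay is the study's metric: the absolute deviation of the
# estimated lag from the known ground truth, here a few milliseconds.
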