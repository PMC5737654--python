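"""Summary statistics of a transcript set: GC%, N50, length summary, bins.

Builds a small synthetic isoform set and prints the one-row summary a
sequencing report would show, plus log-binned length counts.
"""

from isotriage.simulate import SimConfig, simulate_dataset
from isotriage.stats import length_histogram, log_bin_edges, summarize

dataset = simulate_dataset(SimConfig(seed=1, n_transcripts=40))
stats = summarize(dataset.transcripts)
print(stats.to_frame().to_string(index=False))
# gc_percent ~ the simulated GC target; n50 is the length at which the
# descending cumulative sum first reaches half the total bases.

edges = log_bin_edges(300, 25_000, 8)
hist = length_histogram([t.length for t in dataset.transcripts], edges)
for lo, hi, count in zip(hist.edges, hist.edges[1:], hist.counts):
    print(f"[{lo:8.0f}, {hi:8.0f}) {count:3d} {'#' * count}")
# Counts over half-open log-scale bins; they sum to the number of
# transcripts (overflow would be reported separately).
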