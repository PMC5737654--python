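"""Sub-genome assignment and intron-retention calls.

An allotetraploid expresses gene copies from two progenitor sub-genomes.
Global alignment identity to each progenitor reference assigns each
transcript to sub-genome A or B (ambiguous within a 0.5-point margin);
intron retention is called per intron of a reference gene model from the
genomic intervals the transcript covers.
"""

from isotriage.simulate import SimConfig, simulate_dataset
from isotriage.variants import assign_subgenome, detect_retention

dataset = simulate_dataset(SimConfig(seed=5, n_transcripts=20))

print("sub-genome calls (margin 0.5 percentage points):")
for case in dataset.subgenome_cases:
    call = assign_subgenome(case.qid, case.transcript.seq,
                            case.ref_a.seq, case.ref_b.seq)
    print(
        f"  {case.qid}: identity A={call.identity_to_A:6.2f}% "
        f"B={call.identity_to_B:6.2f}% -> {call.call} (planted {case.origin})"
    )
# The transcript's identity to its true progenitor sits near 99% (the
# 1% sequencing-error rate); identity to the other progenitor drops by
# roughly the progenitor divergence, giving a clear call.

print("\nintron-retention calls (threshold 0.95 of intron covered):")
for case in dataset.retention_cases:
    for call in detect_retention(case.qid, case.covered_blocks, case.model):
        print(
            f"  {case.qid} intron {call.intron}: "
            f"{call.fraction_covered:.0%} covered -> retained={call.retained}"
        )
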