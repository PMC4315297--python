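"""Assemble P4RNA transcript models from dsRNA-seq reads.

Reads from the three dcl234 replicates inside P4RNA regions are joined
whenever neighbours are <= 60 nt apart; transcripts must then be > 60 nt,
> 1 RPM, >= 4-fold above dcl234 nrpd1 and overlap a P4siRNA locus.
"""

import numpy as np

from p4rna import SimulationConfig, run_pipeline
from p4rna.assembly import transcript_length_distribution

res = run_pipeline(SimulationConfig(seed=1))

edges, counts = transcript_length_distribution(res.transcripts)
lengths = [t.length for t in res.transcripts]
print(f"transcripts passing all four filters: {len(res.transcripts)}")
print(f"median length: {np.median(lengths):.0f} nt")
in_range = 100 * np.mean([100 <= ln <= 500 for ln in lengths])
print(f"in 100-500 nt: {in_range:.1f}%  (the planted length range)")
print("length histogram (100-nt bins):")
for lo, c in zip(edges[:-1], counts):
    if c:
        print(f"  {int(lo):4d}-{int(lo) + 99:4d} nt: {c}")
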