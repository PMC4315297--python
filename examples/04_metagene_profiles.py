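"""Metagene profiles around P4 locus starts: A/T composition and
nucleosome occupancy.

Pol IV-transcribed regions sit in GC-richer bodies flanked by A/T-rich,
nucleosome-depleted ~50-nt margins — the same architecture seen at Pol II
transcription start sites.
"""

from p4rna import SimulationConfig, simulate
from p4rna.profiles import at_composition_profile, nucleosome_occupancy_profile

sim = simulate(SimulationConfig(seed=1))
loci = sim.truth.p4_intervals()

at = at_composition_profile(sim.genome, loci, "start", flank=200)
off = at.offsets
flank = at.values[(off >= -50) & (off <= -1)].mean()
body = at.values[(off >= 60) & (off <= 150)].mean()
far = at.values[(off >= -200) & (off <= -120)].mean()

nuc = nucleosome_occupancy_profile(
    sim.nucleosomes, loci, sim.chrom_sizes, "start", flank=300, min_length=200
)
o = nuc.offsets
up = nuc.values[(o >= -200) & (o <= -50)].mean()
inside = nuc.values[(o >= 50) & (o <= 200)].mean()

print(f"A/T proportion, upstream flank [-50,-1]: {flank:.3f}")
print(f"A/T proportion, locus body  [+60,+150]: {body:.3f}")
print(f"A/T proportion, distal      [-200,-120]: {far:.3f}")
print(f"nucleosome occupancy upstream [-200,-50]: {up:.3f}")
print(f"nucleosome occupancy inside   [+50,+200]: {inside:.3f}")
# Expected: flank A/T near the planted enrichment (0.8), body near
# 1 - body GC (0.5), and upstream occupancy well below the body.
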