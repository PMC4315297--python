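"""CHH DMRs, D2/C2 locus classes, histone marks and normalized siRNA
abundance.

D2 loci lose CHH methylation in drm1 drm2 (chromosome arms), C2 loci in
cmt2 (pericentromeric heterochromatin, where H3K9me2/H3K27me1 domains
live). siRNA abundance in a mutant is normalized against small RNAs from
non-P4siRNA loci, so wild type is 1 by construction.
"""

from p4rna import SimulationConfig, simulate
from p4rna.epigenetics import (
    call_chh_dmrs,
    classify_d2_c2,
    mark_overlap_windows,
    relative_sirna_abundance,
)

sim = simulate(SimulationConfig(seed=1, p4_fold_change=4.0))
loci = sim.truth.p4_intervals()

drm2 = call_chh_dmrs(sim.methylomes["WT"], sim.methylomes["drm12"])
cmt2 = call_chh_dmrs(sim.methylomes["WT"], sim.methylomes["cmt2"])
classes = [k for _, k in classify_d2_c2(loci, drm2, cmt2)]
print(f"CHH DMRs: drm1 drm2 {len(drm2)}, cmt2 {len(cmt2)}")
print(f"locus classes: D2 {classes.count('D2')}, C2 {classes.count('C2')}, "
      f"other {classes.count('other')}")

_, locus_table = mark_overlap_windows(
    {"k9": sim.marks["h3k9me2"], "k27": sim.marks["h3k27me1"]}, loci, classes
)
print(locus_table.to_string(index=False, float_format="%.1f"))

val = relative_sirna_abundance(
    sim.library_reads("sRNA_nrpd1_r1"), sim.library_reads("sRNA_WT_r1"), loci
)
print(f"relative siRNA abundance in nrpd1 (planted 4x loss): {val:.3f}")
# Expect ~0.25; C2 loci should carry both heterochromatic marks far more
# often than D2 loci.
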