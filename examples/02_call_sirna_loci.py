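"""Call P4siRNA loci (WT vs nrpd1 sRNA-seq) and P4RNA regions (dcl234 vs
dcl234 nrpd1 / dcl234 rdr2 dsRNA-seq), then intersect them.

A locus is a run of 300-bp windows with >= 4-fold loss in the mutant at
Fisher P < 0.01 and >= 1 RPM in the control.
"""

import numpy as np

from p4rna import SimulationConfig, simulate
from p4rna.intervals import build_interval_index, overlaps_any
from p4rna.regions import (
    call_differential_regions,
    define_p4sirna_loci,
    intersect_locus_sets,
    merge_significant,
    require_both_dependencies,
    tile_genome,
)

sim = simulate(SimulationConfig(seed=1))

loci = define_p4sirna_loci(
    sim.libraries_for("sRNA", "WT"),
    sim.libraries_for("sRNA", "nrpd1"),
    sim.chrom_sizes,
)
windows = tile_genome(sim.chrom_sizes, 300)
dcl = sim.libraries_for("dsRNA", "dcl234")
pol_iv = merge_significant(
    call_differential_regions(dcl, sim.libraries_for("dsRNA", "dcl234_nrpd1"), windows)
)
rdr2 = merge_significant(
    call_differential_regions(dcl, sim.libraries_for("dsRNA", "dcl234_rdr2"), windows)
)
common = require_both_dependencies(pol_iv, rdr2)

planted = sim.truth.p4_intervals()
idx = build_interval_index(loci)
sens = 100 * np.mean([overlaps_any(iv, idx) for iv in planted])

part = intersect_locus_sets(common, loci)
print(f"P4siRNA loci called: {len(loci)}  "
      f"(planted loci recovered: {sens:.1f}%)")
print(f"Pol IV-dependent regions: {len(pol_iv)}; "
      f"RDR2-dependent: {len(rdr2)}; common to both: {len(common)}")
print(f"common regions also producing P4siRNAs: {len(part.both)}")
# Nearly every transcript region should overlap a siRNA locus: the
# precursors and the siRNAs come from the same places.
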