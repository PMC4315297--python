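"""Generate a synthetic RdDM dataset with planted ground truth.

Builds a small two-chromosome genome carrying Pol IV-dependent (P4) loci,
Pol II loci and intron-containing genes, simulates all sequencing
libraries plus methylomes/nucleosomes/histone marks, and writes the
dataset as plain-text files.
"""

from p4rna import SimulationConfig, simulate

config = SimulationConfig(
    seed=1,
    genome_size=120_000,
    n_p4_loci=60,
    n_pol2_loci=12,
    n_genes=20,
    default_depth=50_000,
)
sim = simulate(config)
sim.write("scratch_example_dataset")

print(f"chromosomes: {list(sim.chrom_sizes)} of {config.genome_size:,} bp")
print(f"planted P4 loci: {len(sim.truth.p4_loci)} "
      f"(D2 {len(sim.truth.loci_of_class('D2'))}, "
      f"C2 {len(sim.truth.loci_of_class('C2'))})")
print(f"libraries: {len(sim.libraries)}, "
      f"total reads {sum(len(r) for r in sim.reads.values()):,}")
print(f"spliced reads with truth: {len(sim.truth.spliced_read_ids)}")
print("written to scratch_example_dataset/ (FASTA, GFF3, BED, TSV, JSON)")
# The fold change planted between control and Pol IV/RDR2 mutants is
# config.p4_fold_change (default 20x, near-complete loss).
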