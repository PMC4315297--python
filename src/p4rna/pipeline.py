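"""End-to-end orchestration: simulate (or load) a dataset, call loci and
regions, assemble transcripts, profile features and classify loci, writing
every product as deterministic plain-text tables."""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

from . import io as pio
from .assembly import assemble
from .epigenetics import call_chh_dmrs, classify_d2_c2
from .profiles import at_composition_profile, nucleosome_occupancy_profile
from .regions import define_p4sirna_loci, require_both_dependencies, tile_genome
from .regions import call_differential_regions, merge_significant
from .simulate import Simulation, SimulationConfig, simulate


@dataclass
class PipelineResult:
    sim: Simulation
    p4sirna_loci: list
    pol_iv_regions: list
    rdr2_regions: list
    p4rna_regions: list  # dependent on both Pol IV and RDR2
    transcripts: list
    drm2_dmrs: list
    cmt2_dmrs: list
    locus_classes: list  # [(locus, klass), ...]
    profiles: dict = field(default_factory=dict)


def run_pipeline(
    config: SimulationConfig | None = None,
    sim: Simulation | None = None,
    window_size: int = 300,
) -> PipelineResult:
    """Run discovery, assembly, profiling and classification on a
    simulated dataset (generated from ``config`` unless ``sim`` given)."""
    sim = sim if sim is not None else simulate(config)
    sizes = sim.chrom_sizes

    wt_srna = sim.libraries_for("sRNA", "WT")
    nrpd1_srna = sim.libraries_for("sRNA", "nrpd1")
    dcl = sim.libraries_for("dsRNA", "dcl234")
    dcl_nrpd1 = sim.libraries_for("dsRNA", "dcl234_nrpd1")
    dcl_rdr2 = sim.libraries_for("dsRNA", "dcl234_rdr2")

    loci = define_p4sirna_loci(wt_srna, nrpd1_srna, sizes, window_size)

    windows = tile_genome(sizes, window_size)
    pol_iv = merge_significant(
        call_differential_regions(dcl, dcl_nrpd1, windows)
    )
    rdr2 = merge_significant(call_differential_regions(dcl, dcl_rdr2, windows))
    common = require_both_dependencies(pol_iv, rdr2)

    transcripts = assemble(dcl, dcl_nrpd1, common, loci)

    drm2_dmrs = call_chh_dmrs(sim.methylomes["WT"], sim.methylomes["drm12"])
    cmt2_dmrs = call_chh_dmrs(sim.methylomes["WT"], sim.methylomes["cmt2"])
    locus_classes = classify_d2_c2(loci, drm2_dmrs, cmt2_dmrs)

    t_ivs = [t.interval for t in transcripts]
    profiles = {}
    if t_ivs:
        for end in ("start", "end"):
            profiles[f"at_{end}"] = at_composition_profile(
                sim.genome, t_ivs, which_end=end
            )
            profiles[f"nucleosome_{end}"] = nucleosome_occupancy_profile(
                sim.nucleosomes, t_ivs, sizes, which_end=end, min_length=200
            )

    return PipelineResult(
        sim=sim,
        p4sirna_loci=loci,
        pol_iv_regions=pol_iv,
        rdr2_regions=rdr2,
        p4rna_regions=common,
        transcripts=transcripts,
        drm2_dmrs=drm2_dmrs,
        cmt2_dmrs=cmt2_dmrs,
        locus_classes=locus_classes,
        profiles=profiles,
    )


def write_pipeline_outputs(result: PipelineResult, outdir: str) -> None:
    """Write all pipeline products (text formats, deterministic order)."""
    pio.ensure_dir(outdir)
    result.sim.write(os.path.join(outdir, "simulation"))
    pio.write_bed(result.p4sirna_loci, os.path.join(outdir, "p4sirna_loci.bed"))
    pio.write_bed(result.pol_iv_regions, os.path.join(outdir, "pol_iv_regions.bed"))
    pio.write_bed(result.rdr2_regions, os.path.join(outdir, "rdr2_regions.bed"))
    pio.write_bed(result.p4rna_regions, os.path.join(outdir, "p4rna_regions.bed"))
    pio.write_bed(result.drm2_dmrs, os.path.join(outdir, "drm2_dmrs.bed"))
    pio.write_bed(result.cmt2_dmrs, os.path.join(outdir, "cmt2_dmrs.bed"))
    with open(os.path.join(outdir, "transcripts.tsv"), "w") as fh:
        fh.write(
            "chrom\tstart\tend\tlength\trpm_dcl234\tfold_vs_nrpd1\toverlaps_p4sirna\n"
        )
        for t in result.transcripts:
            iv = t.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{t.length}\t"
                f"{t.rpm_dcl234_combined:.6f}\t{t.fold_vs_nrpd1:.6f}\t"
                f"{int(t.overlaps_p4sirna)}\n"
            )
    with open(os.path.join(outdir, "locus_classes.tsv"), "w") as fh:
        fh.write("chrom\tstart\tend\tclass\n")
        for iv, klass in result.locus_classes:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{klass}\n")
    for name in sorted(result.profiles):
        prof = result.profiles[name]
        df = pd.DataFrame(
            {"offset": prof.offsets, "value": prof.values, "n": prof.n}
        )
        df.to_csv(
            os.path.join(outdir, f"profile_{name}.tsv"),
            sep="\t", index=False, float_format="%.6f",
        )
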