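#!/usr/bin/env python
"""Materialize one synthetic dataset of every input class on disk.

Writes the text formats (cohort/PSM/XIC CSVs, FASTA, SAM, TSV, truth tables)
under results/data/ and the image stack (binary TIFF) under scratch/data/.
Later analysis scripts regenerate their inputs deterministically from the
same seeds, so this script exists to exercise and document the on-disk
interchange formats.
"""

import argparse
from pathlib import Path

from paleovia import io, simulate

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    text_dir = ROOT / "results" / "data"
    bin_dir = ROOT / "scratch" / "data"
    text_dir.mkdir(parents=True, exist_ok=True)
    bin_dir.mkdir(parents=True, exist_ok=True)

    params = simulate.ImageSimParams(
        nuclei=[
            simulate.NucleusSpec((22.0, 14.0, 14.0), 5.0, 100.0, 0.5),
            simulate.NucleusSpec((22.0, 34.0, 34.0), 5.0, 100.0, 3.0),
        ],
        seed=seed,
    )
    stack, truth = simulate.gen_nucleus_stack(params)
    io.write_stack(stack, bin_dir / "stack.tiff")
    truth.to_csv(text_dir / "stack_truth.csv", index=False)
    print(f"image stack: {stack.voxels.shape} voxels -> {bin_dir / 'stack.tiff'}")

    spec = simulate.CohortSpec(
        groups=[("fresh", 30, ("lognormal", -0.2, 0.4)),
                ("FT_1", 30, ("lognormal", 0.6, 0.4)),
                ("FT_20", 30, ("lognormal", 1.1, 0.4))],
        reference_group="fresh",
    )
    cohort = simulate.gen_ddi_cohort(spec, seed=seed + 1)
    cohort.to_csv(text_dir / "cohort.csv", index=False)
    print(f"DDI cohort: {len(cohort)} embryos in {cohort.group.nunique()} groups")

    psms, psm_truth = simulate.gen_psm_table(50, 5, 0.3, seed=seed + 2)
    psms.to_csv(text_dir / "psms.csv", index=False)
    psm_truth.to_csv(text_dir / "psm_truth.csv", index=False)
    print(f"PSM table: {len(psms)} spectra over {psm_truth.shape[0]} peptides")

    trace = simulate.gen_xic_trace(
        [("nondeamidated", 40.0, 100.0, 0.3),
         ("deamidated_shifted", 40.0, 30.0, 0.3),
         ("deamidated_shifted", 43.0, 50.0, 0.3)],
        peptide="GPAGPQGPR",
    )
    io.write_xic_csv(trace, text_dir / "xic.csv")
    print(f"XIC trace: {trace.time.size} samples, collagen peptide GPAGPQGPR")

    ref = simulate.random_reference(5000, seed=seed + 3)
    reads, read_truth = simulate.gen_ancient_reads(
        ref, simulate.DamageSimParams(n_reads=2000, delta0=0.3, decay=0.5, seed=seed + 4)
    )
    io.write_fasta({"ref": ref}, text_dir / "reference.fasta")
    io.write_reads_sam(reads, text_dir / "reads.sam", {"ref": len(ref)})
    io.write_reads_tsv(reads, text_dir / "reads.tsv")
    read_truth.to_csv(text_dir / "reads_truth.csv", index=False)
    print(f"ancient reads: {len(reads)} fragments on a {len(ref)} bp reference "
          "(SAM + TSV dialects)")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20)
    main(ap.parse_args().seed)
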