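#!/usr/bin/env python
"""Ancient-DNA track: simulate deaminated nucleosomal fragments, run QC,
build the terminal damage profile, fit the geometric decay, summarize
fragment lengths, and call SNVs against the reference.

Finding (seed 24): the 5' C->T and 3' G->A profiles recover the programmed
(delta0, decay) within a few percent at 10,000 reads; the fragment-length
mode falls in the 140-180 bp mononucleosome window; damage-induced SNVs
appear at sites where >= 2 deaminated reads stack at depth >= 3.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from paleovia import adna, io, simulate

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    out = ROOT / "results"
    out.mkdir(exist_ok=True)

    ref = simulate.random_reference(5000, seed=seed)
    params = simulate.DamageSimParams(
        n_reads=10_000, delta0=0.3, decay=0.5,
        frag_length_mix=[(158.0, 8.0, 0.8), (320.0, 30.0, 0.2)],
        seed=seed + 1,
    )
    reads, _ = simulate.gen_ancient_reads(ref, params)
    kept, qc = adna.filter_reads(reads)
    print(f"QC: {qc}")

    profile = adna.terminal_damage_profile(kept, ref, k=25)
    pd.DataFrame({
        "position": profile.positions,
        "ct5_freq": profile.ct5_freq, "ct5_den": profile.ct5_den,
        "ga3_freq": profile.ga3_freq, "ga3_den": profile.ga3_den,
    }).to_csv(out / "damage_profile.csv", index=False)
    fits = {end: adna.fit_damage_model(profile, end=end) for end in ("5p", "3p")}
    for end, fit in fits.items():
        print(f"{end} fit: delta0 = {fit.delta0:.3f} (truth {params.delta0}), "
              f"decay = {fit.decay:.3f} (truth {params.decay}), "
              f"{fit.n_positions} positions used")

    fld = adna.fragment_length_distribution(kept)
    fld.histogram.to_csv(out / "fragment_lengths.csv", index=False)
    print(f"modal fragment length {fld.modal_length} bp; "
          f"nucleosome footprint peak: {fld.nucleosome_peak}")

    pileup = adna.build_pileup(kept, len(ref), reference=ref)
    calls = adna.call_snvs(pileup, ref, min_depth=3, min_alt=2)
    io.write_vcf(calls, out / "snvs.vcf", "ref", len(ref))
    ct_like = int(((calls.ref == "C") & (calls.alt == "T")).sum()
                  + ((calls.ref == "G") & (calls.alt == "A")).sum())
    print(f"{len(calls)} SNVs at depth >= 3 with >= 2 alternate reads; "
          f"{ct_like} are C->T/G->A (deamination-driven)")

    (out / "adna_summary.json").write_text(json.dumps({
        "seed": seed, "qc": qc,
        "fit_5p": {"delta0": fits['5p'].delta0, "decay": fits['5p'].decay},
        "fit_3p": {"delta0": fits['3p'].delta0, "decay": fits['3p'].decay},
        "modal_fragment_length_bp": fld.modal_length,
        "nucleosome_peak": fld.nucleosome_peak,
        "n_snv_calls": int(len(calls)),
        "n_deamination_type_snvs": ct_like,
    }, indent=2) + "\n")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=24)
    main(ap.parse_args().seed)
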