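#!/usr/bin/env python
"""Proteomics track, counting score: confidence-filter PSM tables from two
synthetic tissues with different deterioration levels, apply the even-once
deamidation rule, and compare the per-sample rates.

Finding (seed 22): the 95%-confidence filter removes about a quarter of the
spectra; the better-preserved "muscle" sample shows a significantly lower
N/Q deamidation rate than the "bone marrow" sample (Fisher exact p < 0.05),
and both mass constants print as expected (+0.984 Da vs +1.0 Da).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from paleovia import proteomics, simulate

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    out = ROOT / "results"
    out.mkdir(exist_ok=True)

    # bone marrow deteriorated more than muscle: higher per-residue probability
    bm, _ = simulate.gen_psm_table(120, 4, 0.35, seed=seed, sample="bone_marrow")
    mu, _ = simulate.gen_psm_table(120, 4, 0.10, seed=seed + 1, sample="muscle")
    psms = pd.concat([bm, mu], ignore_index=True)

    kept = proteomics.filter_psms(psms, min_confidence=95.0)
    print(f"confidence filter: {len(psms)} -> {len(kept)} PSMs at >= 95%")

    rates = proteomics.deamidation_rates(kept)
    rates.to_csv(out / "deamidation_rates.csv", index=False)
    for row in rates.itertuples(index=False):
        print(f"  {row.sample}: {row.n_deamidated}/{row.n_sequences_with_nq} "
              f"N/Q sequences deamidated (rate {row.rate:.2f})")

    a = rates[rates["sample"] == "bone_marrow"].iloc[0]
    b = rates[rates["sample"] == "muscle"].iloc[0]
    orat, p = proteomics.compare_deamidation(a, b)
    print(f"bone marrow vs muscle: OR = {orat:.2f}, Fisher exact p = {p:.2e}")

    shift = proteomics.deamidation_mass_shift()
    spacing = proteomics.isotopologue_spacing()
    print(f"deamidation mass shift {shift:+.3f} Da; 13C isotopologue spacing "
          f"{spacing:+.1f} Da; difference {spacing - shift:.4f} Da "
          "(chromatography, not mass, separates them)")

    (out / "deamidation_summary.json").write_text(json.dumps({
        "seed": seed,
        "n_psms": len(psms), "n_retained": len(kept),
        "rates": rates.to_dict(orient="records"),
        "odds_ratio": orat, "fisher_p": p,
        "deamidation_mass_shift_da": shift,
        "isotopologue_spacing_da": spacing,
    }, indent=2) + "\n")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=22)
    main(ap.parse_args().seed)
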