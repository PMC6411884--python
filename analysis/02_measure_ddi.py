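#!/usr/bin/env python
"""Imaging track: segment nuclei in a synthetic two-channel stack, measure
background-subtracted signals, and check recovery of the rendered ground
truth.

Finding (seed 20): both nuclei are detected, their gamma/H2B signal ratios
match the generator's noise-free truth to well under 5%, and over a 4-frame
movie with linear repair the raw-ratio decline matches the programmed
repair rate.
"""

import argparse
import json
from pathlib import Path

from paleovia import imaging, simulate

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    out = ROOT / "results"
    out.mkdir(exist_ok=True)

    params = simulate.ImageSimParams(
        nuclei=[
            simulate.NucleusSpec((22.0, 14.0, 14.0), 5.0, 100.0, 0.5),
            simulate.NucleusSpec((22.0, 34.0, 34.0), 5.0, 100.0, 3.0),
        ],
        n_frames=4,
        repair_rate=0.4,
        seed=seed,
    )
    stack, truth = simulate.gen_nucleus_stack(params)
    meas = imaging.track_nuclei(stack, min_volume=50)
    meas["raw_ratio"] = meas["gamma_signal"] / meas["h2b_signal"]
    meas["time"] = meas["frame"]
    meas.to_csv(out / "ddi_measurements.csv", index=False)

    frame0 = meas[meas.frame == 0].sort_values("centroid_y").reset_index(drop=True)
    t0 = truth[truth.frame == 0].sort_values("centroid_y_um").reset_index(drop=True)
    errors = []
    for i in range(len(frame0)):
        expect = t0.gamma_signal[i] / t0.h2b_signal[i]
        got = frame0.raw_ratio[i]
        errors.append(abs(got / expect - 1) if expect else abs(got))
    print(f"detected {meas.nucleus.nunique()} nuclei over {params.n_frames} frames")
    print(f"frame-0 ratio recovery errors: {[f'{e:.2%}' for e in errors]}")

    tc = imaging.ddi_timecourse(meas, value_col="raw_ratio")
    tc.to_csv(out / "ddi_timecourse.csv", index=False)
    expected_delta = -params.repair_rate * (params.n_frames - 1) * \
        params.gamma_per_damage / 100.0
    print(f"time-course deltas: {tc.delta.round(3).tolist()} "
          f"(repair model predicts {expected_delta:.3f} for the damaged nucleus)")
    print(f"repair-consistent flags: {tc.repair_consistent.tolist()}")

    summary = {
        "seed": seed,
        "n_nuclei": int(meas.nucleus.nunique()),
        "ratio_recovery_max_rel_error": max(errors),
        "timecourse_deltas": tc.delta.round(4).tolist(),
    }
    (out / "ddi_imaging_summary.json").write_text(json.dumps(summary, indent=2) + "\n")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20)
    main(ap.parse_args().seed)
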