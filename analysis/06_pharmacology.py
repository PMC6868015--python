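#!/usr/bin/env python
"""Percent-change-in-spike-rate summaries for simulated drug responses.

Emulates a pharmacology session on four wells per condition: a baseline
recording from the hPSC-like preset, then a treatment recording with the
generator's rates scaled to mimic typical responses — an AMPA/kainate
antagonist (strong reduction), a GABA-A antagonist (disinhibition,
increased rates), and a sodium-channel blocker (complete silencing).
Reports the per-well percent change in array-wide spike rate relative to
the same well's baseline.
"""

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from meanet.features import percent_change
from meanet.simulate import preset, simulate_trains

DURATION = 300.0
SEED = 77
OUT = Path(__file__).resolve().parents[1] / "results"

# multiplicative effects on (burst rate, intra-burst rate, tonic rate)
TREATMENTS = {
    "antagonist_glutamatergic": (0.1, 0.6, 0.3),
    "antagonist_gabaergic": (1.4, 1.2, 1.5),
    "ttx_like": (0.0, 0.0, 0.0),
}


def well_rate(truth) -> float:
    return truth.true_spikes.n_spikes() / DURATION


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    base_params = replace(preset("hPSC_peak"), duration_s=DURATION)
    rows = []
    for name, (f_burst, f_intra, f_tonic) in TREATMENTS.items():
        treated = replace(
            base_params,
            burst_rate_per_min=base_params.burst_rate_per_min * f_burst,
            intra_burst_rate_hz=base_params.intra_burst_rate_hz * f_intra,
            tonic_rate_hz=base_params.tonic_rate_hz * f_tonic,
        )
        for w in range(4):
            b = simulate_trains(base_params, seed=SEED + w, well_id=f"W{w + 1:02d}")
            t = simulate_trains(treated, seed=SEED + 100 + w, well_id=f"W{w + 1:02d}")
            pct = percent_change(well_rate(b), well_rate(t))
            rows.append({"treatment": name, "well_id": f"W{w + 1:02d}", "pct_change": pct})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "pharmacology_pct_change.csv", index=False, lineterminator="\n")
    for name, grp in df.groupby("treatment"):
        print(f"{name}: median change {np.median(grp['pct_change']):+.1f}%")


if __name__ == "__main__":
    main()
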