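#!/usr/bin/env python
"""Burst analysis of the simulated plates and recovery of preset values.

Runs logISI burst detection (5-spike minimum, 100 ms merge rule) on every
well of the day-0 plates from 01_simulate_plates.py and compares the
plate-median burst rate and duration with the generator presets
(hPSC-like: 11 bursts/min, 0.7 s; rat-like: 15 bursts/min, 0.3 s).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from meanet.bursts import analyze_bursts, bursts_to_dataframe, well_burst_features
from meanet.io import LogisiConfig, read_spikes

DURATION = 300.0
SIM = Path(__file__).resolve().parents[1] / "results" / "sim"
OUT = Path(__file__).resolve().parents[1] / "results"

PRESET_VALUES = {"hpsc": (11.0, 0.7), "rat": (15.0, 0.3)}


def main() -> None:
    cfg = LogisiConfig()
    rows = []
    for tag, (rate0, dur0) in PRESET_VALUES.items():
        path = SIM / f"{tag}_day0_spikes.csv"
        if not path.exists():
            raise SystemExit(f"{path} missing — run analysis/01_simulate_plates.py first")
        table = read_spikes(path, DURATION)
        bsets = analyze_bursts(table, cfg)
        bursts_to_dataframe(bsets).pipe(
            lambda d: d.to_csv(OUT / f"{tag}_bursts.csv", index=False, lineterminator="\n")
        )
        feats = well_burst_features(table, bsets)
        for well, f in sorted(feats.items()):
            rows.append({"preset": tag, "well_id": well, **f})
        med_rate = np.median([f["burst_rate_per_min"] for f in feats.values()])
        med_dur = np.median([f["burst_duration_s"] for f in feats.values()])
        print(
            f"{tag}: plate-median burst rate {med_rate:.2f}/min (preset {rate0}), "
            f"duration {med_dur:.3f} s (preset {dur0}) — "
            f"errors {100 * (med_rate / rate0 - 1):+.1f}% / {100 * (med_dur / dur0 - 1):+.1f}%"
        )
    pd.DataFrame(rows).to_csv(OUT / "burst_features_by_well.csv", index=False, lineterminator="\n")


if __name__ == "__main__":
    main()
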