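#!/usr/bin/env python
"""Simulate the two phenotype plates used by the downstream analyses.

Generates 12-well plates for the human-PSC-like and rat-like presets at
three "measurement days" each (independent draws at peak-activity
parameters), and writes the spike tables plus the generator's own burst
windows under results/sim/.
"""

from pathlib import Path

import pandas as pd

from meanet.io import SpikeTable, write_bursts, write_spikes
from meanet.simulate import simulate_plate

DURATION = 300.0
N_WELLS = 12
SEED = 20260920
OUT = Path(__file__).resolve().parents[1] / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary = []
    for kind, tag, off in (("hPSC_peak", "hpsc", 0), ("rat_peak", "rat", 500)):
        for day in range(3):
            plate = simulate_plate(
                kind, N_WELLS, seed=SEED + day + off, duration_s=DURATION
            )
            spikes, burst_rows = {}, []
            for g in plate:
                spikes.update(g.true_spikes.spikes)
                for (w, e), blist in g.true_bursts.items():
                    burst_rows += [(w, e, b[0], b[1], b[2]) for b in blist]
            table = SpikeTable(duration=DURATION, spikes=spikes)
            write_spikes(table, OUT / f"{tag}_day{day}_spikes.csv")
            write_bursts(
                pd.DataFrame(
                    burst_rows,
                    columns=["well_id", "electrode_id", "t_start_s", "t_end_s", "n_spikes"],
                ),
                OUT / f"{tag}_day{day}_true_bursts.csv",
            )
            summary.append(
                {
                    "preset": kind,
                    "day": day,
                    "wells": N_WELLS,
                    "spikes": table.n_spikes(),
                    "true_bursts": len(burst_rows),
                }
            )
            print(
                f"{kind} day {day}: {table.n_spikes()} spikes, "
                f"{len(burst_rows)} ground-truth bursts"
            )
    pd.DataFrame(summary).to_csv(OUT / "summary.csv", index=False, lineterminator="\n")
    print(f"wrote plates to {OUT}")


if __name__ == "__main__":
    main()
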