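#!/usr/bin/env python
"""Acceptor-channel FRET rise analysis.

The slow (~1 ns) energy-transfer pathway appears in TCSPC as a small
negative-amplitude rise on the sensitized Nile red decay. This driver
simulates 20 acceptor-channel histograms per barrel (rise:decay amplitude
ratio 0.15, acceptor decay fixed at its with-donor control value) and
extracts the rise constant by reconvolution, for the heptamer (0.98 ns) and
octamer (1.3 ns) ground truths. A hexamer-style control with no rise in the
truth must come back 'no resolvable rise'.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from barrelfret import report
from barrelfret.synth import NoiseSpec, simulate_tcspc
from barrelfret.tcspc import MultiExpModel, extract_fret_time

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    rows = []
    for tid in ("t4", "t5"):
        res = report.run_target(tid, seed=seed)
        rows.append(
            {
                "target": tid,
                "condition": res["label"],
                "true_ns": res["reference"],
                "recovered_ns": round(res["value"], 3),
                "sd_ns": round(float(np.std(res["per_seed"])), 4),
                "within_tolerance": res["passed"],
            }
        )
        print(f"{tid} {res['label']}: {res['value']:.3f} ns "
              f"(truth {res['reference']}) {'ok' if res['passed'] else 'FAIL'}")

    # hexamer-style negative control: no transfer pathway in the truth
    trace = simulate_tcspc(
        MultiExpModel([1.0], [4.9]), t_max=50.0, noise=NoiseSpec("poisson", 0.0, seed)
    )
    ctrl = extract_fret_time(trace, 4.9)
    print(f"hexamer control: resolvable rise = {ctrl.resolvable} (expected False)")
    rows.append(
        {
            "target": "hexamer_control",
            "condition": "no-transfer control",
            "true_ns": np.nan,
            "recovered_ns": np.nan,
            "sd_ns": np.nan,
            "within_tolerance": not ctrl.resolvable,
        }
    )
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "fret_rise.csv", index=False)


if __name__ == "__main__":
    main()
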