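#!/usr/bin/env python
"""DA-Ach covariance: lag recovery, null controls and gated coupling.

Recovers the generator's DA->Ach delay from noise-mode cross-covariance for
three ground-truth lags, checks the g=0 control against the circular-shift
null, and shows the off-diagonal of K(t1, t2) collapsing inside a gated
epoch.  Writes results/covariance/.
"""

import argparse
import json
from pathlib import Path

from achda import studies

OUT = Path(__file__).resolve().parents[1] / "results" / "covariance"


def main(seed: int) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary = {}
    for lag in (0.054, 0.108, 0.216):
        res = studies.coupling_lag_recovery(seed, lag=lag)
        ms = int(round(lag * 1000))
        print(f"true lag {ms:>3} ms -> recovered "
              f"{res['recovered_lag_s']*1000:.0f} ms, min cov "
              f"{res['min_cov']:.4f}, outside 95% null: {res['min_outside_null']}")
        summary[f"recovered_ms_d{ms}"] = res["recovered_lag_s"] * 1000
    res0 = studies.coupling_lag_recovery(seed, lag=0.108, gain=0.0)
    print(f"uncoupled control (g=0): all lags inside the null band: "
          f"{res0['all_inside_null']}")
    gc = studies.gated_coupling(seed)
    print(f"gated coupling: |off-diagonal| inside the gated epoch is "
          f"{100*gc['ratio']:.1f}% of its magnitude outside "
          f"(outside mean {gc['outside_mean']:.4f})")
    summary.update(g0_all_inside=res0["all_inside_null"], gated_ratio=gc["ratio"])
    with open(OUT / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
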