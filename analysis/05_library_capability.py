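#!/usr/bin/env python
"""Plated-library capability bookkeeping for a selection experiment.

Computes the transformant-count estimate for the canonical worked example
(50 CFU from 2 uL of a 20 mL culture) and pools a three-plate dilution
series, printing exact and order-of-magnitude renderings.
"""

import argparse
import json
from pathlib import Path

from metastab.library_stats import PlatingObservation, dilution_series_estimate, library_capability


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/library"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    obs = PlatingObservation(50, 2.0, 20.0)
    exact = library_capability(obs)
    print(f"single plate (50 CFU / 2 uL, 20 mL culture): {exact:.3g} transformants")

    series = dilution_series_estimate(
        [
            PlatingObservation(50, 2.0, 20.0),
            PlatingObservation(480, 20.0, 20.0),
            PlatingObservation(5200, 200.0, 20.0),
        ]
    )
    print(f"dilution series per-plate estimates: {[f'{v:.3g}' for v in series['per_plate']]}")
    print(f"mean {series['mean']:.4g}, range {series['range']:.3g}, "
          f"order of magnitude {series['order_of_magnitude']:.1g}")
    (args.out / "library_capability.json").write_text(json.dumps(series, indent=1) + "\n")


if __name__ == "__main__":
    main()
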