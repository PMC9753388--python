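#!/usr/bin/env python
"""Generate the synthetic market study: reference panel, 22 market samples
(7 truly authentic) and the hidden truth table.

Writes panel.fasta, market.fasta, groups.csv and truth.csv under results/study/.
"""

import argparse
from pathlib import Path

from barcodeauth.simulate import SimulationConfig, make_market_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    study = make_market_study(SimulationConfig(seed=args.seed))
    study.write(args.outdir)
    comp = study.truth.true_species.value_counts()
    print(f"panel: {len(study.panel)} sequences, market: {len(study.market)} samples")
    print("true market composition:")
    print(comp.to_string())
    print(f"wrote study files to {args.outdir}/")


if __name__ == "__main__":
    main()
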