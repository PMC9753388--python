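#!/usr/bin/env python
"""NJ and UPGMA trees of panel + market samples with column-bootstrap support.

Writes Newick files under results/. Market samples are expected to attach
inside the clade of the species they were drawn from; the reference clade
should carry high support.
"""

import argparse
from pathlib import Path

from barcodeauth import seqio
from barcodeauth.trees import bootstrap_support


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--replicates", type=int, default=200)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    aln = seqio.read_alignment(args.outdir / "aligned.fasta")
    for method in ("nj", "upgma"):
        tree = bootstrap_support(aln, method=method, replicates=args.replicates,
                                 seed=args.seed)
        out = args.outdir / f"tree_{method}.nwk"
        seqio.write_newick(tree, out)
        supports = [int(nd.label) for nd in tree.preorder_node_iter()
                    if not nd.is_leaf() and nd.parent_node is not None
                    and nd.label is not None]
        strong = sum(s >= 95 for s in supports)
        print(f"{method}: {args.replicates} replicates "
              f"({tree.bootstrap_skipped} skipped), {strong}/{len(supports)} "
              f"bipartitions with support >= 95 -> {out}")


if __name__ == "__main__":
    main()
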