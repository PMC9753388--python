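#!/usr/bin/env python
"""Barcoding-gap analyses: the distance-based discrimination criterion for the
reference species and diagnostic-nucleotide discovery against each adulterant.

Reads results/ artifacts from the previous steps; writes gap_report.csv and
diagnostic_sites_<group>.csv tables.
"""

import argparse
from pathlib import Path

import pandas as pd

from barcodeauth import seqio
from barcodeauth.distances import distance_matrix
from barcodeauth.gap import diagnostic_sites, gap_test, site_report

REFERENCE = "Melissa officinalis"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--studydir", type=Path, default=Path("results/study"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    gm = seqio.read_group_map(args.studydir / "groups.csv")
    panel = seqio.read_fasta(args.studydir / "panel.fasta")
    aln = seqio.read_alignment(args.outdir / "aligned.fasta")
    panel_ids = [r.id for r in panel]
    panel_aln = seqio.Alignment([aln.row(i) for i in panel_ids])
    dm = distance_matrix(panel_aln)

    rows = []
    for level in ("species", "genus"):
        target = REFERENCE if level == "species" else REFERENCE.split()[0]
        rep = gap_test(dm, gm, target, level=level)
        rows.append({
            "level": level, "group": rep.group, "max_intra": rep.max_intra,
            "min_inter": rep.min_inter, "nearest_group": rep.nearest_group,
            "discriminated": rep.discriminated,
        })
        print(f"[{level}] max_intra={rep.max_intra:.2f} min_inter={rep.min_inter:.2f} "
              f"nearest={rep.nearest_group} discriminated={rep.discriminated}")
    pd.DataFrame(rows).to_csv(args.outdir / "gap_report.csv", index=False)

    contrasts = sorted({e.species for e in gm.entries.values()
                        if e.role == "adulterant"})
    for group in contrasts:
        ds = diagnostic_sites(panel_aln, gm, REFERENCE, {group})
        tag = group.split()[0].lower()
        site_report(ds).to_csv(args.outdir / f"diagnostic_sites_{tag}.csv", index=False)
        print(f"{len(ds):4d} diagnostic positions vs {group}")
    pooled = diagnostic_sites(panel_aln, gm, REFERENCE, set(contrasts))
    site_report(pooled).to_csv(args.outdir / "diagnostic_sites_all.csv", index=False)
    print(f"{len(pooled):4d} diagnostic positions vs all adulterants pooled")


if __name__ == "__main__":
    main()
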