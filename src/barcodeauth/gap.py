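"""Barcoding-gap analyses.

Two complementary criteria decide whether a barcode region can discriminate
the target species from its adulterants:

* the distance criterion — the species is discriminated when its minimum
  interspecific distance strictly exceeds its maximum intraspecific distance
  (ties fail);
* diagnostic nucleotides — alignment columns where every target sequence
  shares one state and every contrast sequence differs from it.

Positions in every report are 1-based alignment columns.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .seqio import Alignment, GroupMap, GAP_CODE, decode

__all__ = [
    "GapReport",
    "DiagnosticSites",
    "GapAnalysisError",
    "gap_test",
    "diagnostic_sites",
    "site_report",
]

_CHARS = "ACGTN-"


class GapAnalysisError(ValueError):
    """Invalid barcoding-gap request."""


@dataclass(frozen=True)
class GapReport:
    """Distance-criterion verdict for one group."""

    group: str
    max_intra: float | None
    mean_intra: float | None
    min_inter: float | None
    nearest_group: str | None
    discriminated: bool
    n_undefined: int = 0


@dataclass(frozen=True)
class DiagnosticSites:
    """Columns separating a target group from a set of contrast groups."""

    target_group: str
    contrast_groups: tuple[str, ...]
    positions: tuple[int, ...]  # sorted, 1-based
    target_states: dict[int, str] = field(default_factory=dict)
    contrast_states: dict[int, Counter] = field(default_factory=dict)
    indel_positions: tuple[int, ...] = ()

    def __len__(self) -> int:
        return len(self.positions)


def gap_test(dm: DistanceMatrix, gm: GroupMap, target: str,
             level: str = "species") -> GapReport:
    """Apply the strict min-inter > max-intra discrimination criterion."""
    gm.require_covers(dm.labels)
    members = [lab for lab in dm.labels if gm.group_of(lab, level) == target]
    if len(members) < 2:
        raise GapAnalysisError(
            f"group {target!r} has {len(members)} member(s) in the matrix; "
            "the distance criterion needs >= 2 — use diagnostic-site mode instead"
        )
    idx = {lab: i for i, lab in enumerate(dm.labels)}
    mem = np.zeros(len(dm.labels), dtype=bool)
    mem[[idx[m] for m in members]] = True

    intra_vals, inter_vals, inter_partner = [], [], []
    for i in range(len(dm.labels)):
        for j in range(i + 1, len(dm.labels)):
            d = dm.values[i, j]
            if mem[i] and mem[j]:
                intra_vals.append(d)
            elif mem[i] != mem[j]:
                inter_vals.append(d)
                inter_partner.append(j if mem[i] else i)
    intra = np.array(intra_vals)
    inter = np.array(inter_vals)
    n_undef = int(np.isnan(intra).sum() + np.isnan(inter).sum())
    intra = intra[~np.isnan(intra)]
    defined = ~np.isnan(inter)
    max_intra = float(intra.max()) if intra.size else None
    mean_intra = float(intra.mean()) if intra.size else None
    if defined.any():
        k = int(np.argmin(inter[defined]))
        min_inter = float(inter[defined][k])
        nearest = gm.group_of(dm.labels[np.array(inter_partner)[defined][k]], level)
    else:
        min_inter, nearest = None, None
    discriminated = (
        max_intra is not None and min_inter is not None and min_inter > max_intra
    )
    return GapReport(
        group=target,
        max_intra=max_intra,
        mean_intra=mean_intra,
        min_inter=min_inter,
        nearest_group=nearest,
        discriminated=discriminated,
        n_undefined=n_undef,
    )


def diagnostic_sites(
    aln: Alignment,
    gm: GroupMap,
    target: str,
    contrast: set[str] | list[str],
    min_coverage: float = 1.0,
    level: str = "species",
    include_indels: bool = False,
) -> DiagnosticSites:
    """Scan every column for target-fixed states absent from all contrast rows.

    A column qualifies iff all non-missing target states are identical, target
    missingness is at most ``1 - min_coverage`` (default: none allowed), at
    least one contrast state is observed, and every observed contrast state
    differs from the target state. Contrast rows need not agree among
    themselves, and missing data in a contrast row never disqualifies a column.
    """
    contrast = tuple(sorted(set(contrast)))
    if not contrast:
        raise GapAnalysisError("contrast group set must be nonempty")
    gm.require_covers(aln.ids)
    t_rows = [i for i, lab in enumerate(aln.ids) if gm.group_of(lab, level) == target]
    c_rows = [i for i, lab in enumerate(aln.ids) if gm.group_of(lab, level) in contrast]
    if not t_rows:
        raise GapAnalysisError(f"target group {target!r} has no rows in the alignment")
    if not c_rows:
        raise GapAnalysisError(f"no rows found for contrast groups {contrast!r}")

    mat = aln.matrix()
    tmat = mat[t_rows]
    cmat = mat[c_rows]
    t_missing = tmat >= 4  # gap or ambiguity counts against target coverage
    miss_frac = t_missing.mean(axis=0)
    tmin = np.where(t_missing, 99, tmat).min(axis=0)
    tmax = np.where(t_missing, -1, tmat).max(axis=0)
    uniform = (tmin == tmax) & (tmax >= 0)  # one shared observed state
    covered = miss_frac <= (1.0 - min_coverage) + 1e-12
    c_valid = cmat < 4
    has_contrast = c_valid.any(axis=0)
    matches_target = ((cmat == tmax[None, :]) & c_valid).any(axis=0)
    qualifies = uniform & covered & has_contrast & ~matches_target

    positions = tuple(int(c) + 1 for c in np.nonzero(qualifies)[0])
    target_states = {p: _CHARS[tmax[p - 1]] for p in positions}
    contrast_states = {
        p: Counter(_CHARS[code] for code in cmat[:, p - 1] if code < 4)
        for p in positions
    }

    indel_positions: tuple[int, ...] = ()
    if include_indels:
        t_all_gap = (tmat == GAP_CODE).all(axis=0)
        c_no_gap = (cmat != GAP_CODE).all(axis=0)
        indel_positions = tuple(
            int(c) + 1 for c in np.nonzero(t_all_gap & c_no_gap & has_contrast)[0]
        )

    return DiagnosticSites(
        target_group=target,
        contrast_groups=contrast,
        positions=positions,
        target_states=target_states,
        contrast_states=contrast_states,
        indel_positions=indel_positions,
    )


def site_report(ds: DiagnosticSites) -> pd.DataFrame:
    """One row per diagnostic position: column, target state, contrast states."""
    rows = [
        {
            "position": p,
            "target_state": ds.target_states.get(p, ""),
            "contrast_states": ";".join(
                f"{state}:{count}"
                for state, count in sorted(ds.contrast_states.get(p, Counter()).items())
            ),
        }
        for p in ds.positions
    ]
    return pd.DataFrame(rows, columns=["position", "target_state", "contrast_states"])
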