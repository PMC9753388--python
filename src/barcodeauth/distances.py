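"""Pairwise evolutionary distances and group-wise summaries.

The quantitative core of the pipeline: per-pair transition/transversion
counts under pairwise deletion, the Kimura 2-parameter (K2P) distance

    d = -(1/2) * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

with P and Q the transition and transversion proportions over compared sites,
the uncorrected p-distance, full distance matrices, and per-group
max-intra / min-inter summaries used by the barcoding-gap criterion.

Undefined entries (empty site overlap, or a non-positive logarithm argument at
large divergence) are carried as NaN and excluded — never silently zeroed —
from every summary; summaries report how many pairs were excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import Alignment, GroupMap, encode

__all__ = [
    "SitePairCounts",
    "DistanceMatrix",
    "DistanceError",
    "count_site_pairs",
    "k2p_distance",
    "p_distance",
    "distance_matrix",
    "pairwise_distances",
    "group_distance_summary",
    "UNDEFINED",
]

UNDEFINED = float("nan")


class DistanceError(ValueError):
    """Invalid distance computation request."""


@dataclass(frozen=True)
class SitePairCounts:
    """Site-pattern counts for one sequence pair under pairwise deletion."""

    n: int
    transitions: int
    transversions: int

    def __post_init__(self) -> None:
        if min(self.n, self.transitions, self.transversions) < 0:
            raise DistanceError("negative site counts")
        if self.transitions + self.transversions > self.n:
            raise DistanceError("more substitutions than compared sites")

    @property
    def matches(self) -> int:
        return self.n - self.transitions - self.transversions

    @property
    def P(self) -> float:
        return self.transitions / self.n if self.n else UNDEFINED

    @property
    def Q(self) -> float:
        return self.transversions / self.n if self.n else UNDEFINED


def _counts_from_codes(x: np.ndarray, y: np.ndarray) -> SitePairCounts:
    valid = (x < 4) & (y < 4)  # pairwise deletion of gaps/ambiguity
    diff = valid & (x != y)
    ts = int((diff & (np.abs(x - y) == 2)).sum())  # A<->G (0,2) and C<->T (1,3)
    return SitePairCounts(n=int(valid.sum()), transitions=ts,
                          transversions=int(diff.sum()) - ts)


def count_site_pairs(row_a: str, row_b: str) -> SitePairCounts:
    """Compare two equal-length gapped rows; gap/ambiguity columns are skipped.

    Transitions are A<->G and C<->T; every other mismatch is a transversion.
    """
    if len(row_a) != len(row_b):
        raise DistanceError(
            f"rows differ in length ({len(row_a)} vs {len(row_b)})"
        )
    return _counts_from_codes(encode(row_a.upper()), encode(row_b.upper()))


def k2p_distance(counts: SitePairCounts) -> float:
    """K2P distance in substitutions/site; NaN when outside the formula's domain."""
    if counts.n == 0:
        return UNDEFINED
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return UNDEFINED
    return -0.5 * math.log(w1 * math.sqrt(w2)) + 0.0  # + 0.0 avoids -0.0


def p_distance(counts: SitePairCounts) -> float:
    """Uncorrected proportion of differing compared sites."""
    if counts.n == 0:
        return UNDEFINED
    return (counts.transitions + counts.transversions) / counts.n


_MODELS = {"k2p": k2p_distance, "p": p_distance}


class DistanceMatrix:
    """Symmetric nonnegative pairwise distances with NaN-flagged undefined entries."""

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        labels = list(labels)
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (len(labels), len(labels)):
            raise DistanceError("matrix shape does not match label count")
        if len(set(labels)) != len(labels):
            raise DistanceError("duplicate labels")
        if not np.all(np.diag(values) == 0.0):
            raise DistanceError("diagonal must be exactly 0")
        both = ~np.isnan(values) & ~np.isnan(values.T)
        if not np.allclose(values[both & (both.T)].reshape(-1), values.T[both & both.T].reshape(-1)):
            raise DistanceError("matrix must be symmetric")
        if np.nanmin(values) < 0:
            raise DistanceError("distances must be nonnegative")
        self.labels = labels
        self.values = values
        self._index = {lab: i for i, lab in enumerate(labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(len(self.labels)):
            for j in range(i + 1, len(self.labels)):
                if math.isnan(self.values[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[lab] for lab in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def pairwise_distances(matrix: np.ndarray, model: str = "k2p") -> np.ndarray:
    """All-pairs distances on an encoded (n, L) code matrix (internal fast path)."""
    try:
        fn = _MODELS[model]
    except KeyError:
        raise DistanceError(f"unknown model {model!r}; choose from {sorted(_MODELS)}")
    n = matrix.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = fn(_counts_from_codes(matrix[i], matrix[j]))
            out[i, j] = out[j, i] = d
    return out


def distance_matrix(aln: Alignment, model: str = "k2p") -> DistanceMatrix:
    """Pairwise distance matrix over all alignment rows."""
    if len(aln) < 2:
        raise DistanceError("alignment must contain at least 2 rows")
    return DistanceMatrix(aln.ids, pairwise_distances(aln.matrix(), model=model))


def group_distance_summary(dm: DistanceMatrix, gm: GroupMap,
                           level: str = "species") -> pd.DataFrame:
    """Per-group max/mean intra-group and min inter-group distances.

    Groups with a single member (or no defined intra pair) report intra
    statistics as NA — never zero. Undefined pairwise entries are excluded and
    counted in ``n_undefined``.
    """
    gm.require_covers(dm.labels)
    groups = sorted({gm.group_of(lab, level) for lab in dm.labels})
    membership = np.array([gm.group_of(lab, level) for lab in dm.labels])
    rows = []
    n = len(dm.labels)
    iu = np.triu_indices(n, k=1)
    for group in groups:
        in_group = membership == group
        intra_mask = in_group[iu[0]] & in_group[iu[1]]
        inter_mask = in_group[iu[0]] ^ in_group[iu[1]]
        intra = dm.values[iu][intra_mask]
        inter = dm.values[iu][inter_mask]
        n_undef = int(np.isnan(intra).sum() + np.isnan(inter).sum())
        intra = intra[~np.isnan(intra)]
        inter_pairs_i = iu[0][inter_mask]
        inter_pairs_j = iu[1][inter_mask]
        defined_inter = ~np.isnan(dm.values[iu][inter_mask])
        inter_def = inter[defined_inter]
        if inter_def.size:
            k = int(np.argmin(inter_def))
            ii = inter_pairs_i[defined_inter][k]
            jj = inter_pairs_j[defined_inter][k]
            partner = jj if membership[ii] == group else ii
            nearest = membership[partner]
            min_inter = float(inter_def[k])
        else:
            nearest, min_inter = None, UNDEFINED
        rows.append({
            "group": group,
            "n_members": int(in_group.sum()),
            "max_intra": float(intra.max()) if intra.size else UNDEFINED,
            "mean_intra": float(intra.mean()) if intra.size else UNDEFINED,
            "min_inter": min_inter,
            "nearest_group": nearest,
            "n_undefined": n_undef,
        })
    return pd.DataFrame(rows).set_index("group")
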