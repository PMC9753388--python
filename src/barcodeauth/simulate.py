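"""Synthetic reference panels and market samples.

Generates data with the statistical structure the analysis assumes, so every
pipeline stage is testable offline: sequences evolve along a tree under the
continuous-time two-parameter substitution process (transition rate kappa
times each transversion rate, uniform base frequencies — the generative form
of the K2P distance), with branch lengths in expected substitutions/site.

The default study emulates a herbal-market survey: ~750 nt amplicons, a tight
reference clade for the authentic species, congeneric / confamilial
adulterants at 0.08-0.20 divergence, deeper off-family contaminants, and a
market set of 22 unknowns of which 7 are authentic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm

from .seqio import (
    Alignment,
    GroupEntry,
    GroupMap,
    SequenceRecord,
    decode,
    write_fasta,
    write_group_map,
)

__all__ = [
    "GroupSpec",
    "SimulationConfig",
    "MarketStudy",
    "SimulationError",
    "DEFAULT_GROUPS",
    "DEFAULT_ADULTERANT_COMPOSITION",
    "rate_matrix",
    "evolve_along_tree",
    "simulate_alignment",
    "plant_diagnostics",
    "make_market_study",
]


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class GroupSpec:
    """One taxon in the study design.

    ``stem`` is the branch length (substitutions/site) from the study root to
    the group ancestor, so the divergence between two groups is the sum of
    their stems; ``tip_spread`` bounds the uniform draw for each member's
    terminal branch, so intra-group divergence is at most ``2 * tip_spread``.
    """

    species: str
    genus: str
    role: str
    n_panel: int
    stem: float
    tip_spread: float
    tag: str


DEFAULT_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec("Melissa officinalis", "Melissa", "reference", 4, 0.050, 0.001, "Moff"),
    GroupSpec("Melissa axillaris", "Melissa", "adulterant", 3, 0.050, 0.005, "Maxi"),
    GroupSpec("Dracocephalum moldavica", "Dracocephalum", "adulterant", 2, 0.075, 0.005, "Dmol"),
    GroupSpec("Hymenocrater bituminosus", "Hymenocrater", "adulterant", 2, 0.075, 0.005, "Hbit"),
    # off-family contaminants seen in market surveys (Boraginaceae, Fabaceae)
    GroupSpec("Asperugo procumbens", "Asperugo", "adulterant", 2, 0.180, 0.005, "Apro"),
    GroupSpec("Trigonella foenum-graecum", "Trigonella", "adulterant", 2, 0.180, 0.005, "Tfoe"),
)

DEFAULT_ADULTERANT_COMPOSITION: dict[str, int] = {
    "Hymenocrater bituminosus": 7,
    "Asperugo procumbens": 4,
    "Dracocephalum moldavica": 2,
    "Trigonella foenum-graecum": 2,
}


@dataclass(frozen=True)
class SimulationConfig:
    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    length: int = 750
    kappa: float = 2.0
    n_samples: int = 22
    authentic_count: int = 7
    adulterant_composition: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ADULTERANT_COMPOSITION)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise SimulationError("length must be >= 1")
        if self.kappa <= 0:
            raise SimulationError("kappa must be positive")
        if self.authentic_count > self.n_samples:
            raise SimulationError("authentic_count exceeds n_samples")
        if any(g.stem < 0 or g.tip_spread < 0 for g in self.groups):
            raise SimulationError("branch lengths must be >= 0")
        total = self.authentic_count + sum(self.adulterant_composition.values())
        if total != self.n_samples:
            raise SimulationError(
                f"market composition sums to {total}, expected n_samples={self.n_samples}"
            )
        known = {g.species for g in self.groups}
        unknown = set(self.adulterant_composition) - known
        if unknown:
            raise SimulationError(f"composition names unknown groups: {sorted(unknown)}")

    def reference_group(self) -> GroupSpec:
        refs = [g for g in self.groups if g.role == "reference"]
        if len(refs) != 1:
            raise SimulationError("exactly one reference group required")
        return refs[0]


def rate_matrix(kappa: float) -> np.ndarray:
    """K2P rate matrix normalized to one expected substitution per unit time."""
    alpha = kappa / (kappa + 2.0)
    beta = 1.0 / (kappa + 2.0)
    Q = np.full((4, 4), beta)
    for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):  # A<->G, C<->T
        Q[i, j] = alpha
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _evolve_states(parent: np.ndarray, P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    child = np.empty_like(parent)
    u = rng.random(parent.size)
    cum = P.cumsum(axis=1)
    for s in range(4):
        mask = parent == s
        child[mask] = np.searchsorted(cum[s], u[mask], side="right")
    return np.minimum(child, 3).astype(np.int8)


def evolve_along_tree(
    tree: dendropy.Tree,
    length: int,
    kappa: float,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Simulate sequences down a tree; returns leaf-label -> residue string.

    The root sequence is drawn uniformly; each edge applies the matrix
    exponential of the rate matrix scaled by its branch length.
    """
    Q = rate_matrix(kappa)
    pcache: dict[float, np.ndarray] = {}

    def transition(t: float) -> np.ndarray:
        key = round(t, 12)
        if key not in pcache:
            pcache[key] = expm(Q * t)
        return pcache[key]

    states: dict[int, np.ndarray] = {}
    out: dict[str, str] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            seq = rng.integers(0, 4, size=length).astype(np.int8)
        else:
            t = nd.edge.length or 0.0
            parent = states[id(nd.parent_node)]
            seq = parent.copy() if t == 0.0 else _evolve_states(parent, transition(t), rng)
        states[id(nd)] = seq
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon is not None else nd.label
            out[label] = decode(seq)
    return out


# ---------------------------------------------------------------------------
# Study-tree construction


def _star_tree(tip_specs: list[tuple[str, GroupSpec]],
               rng: np.random.Generator) -> dendropy.Tree:
    """Root -> group-ancestor -> member tips, with drawn terminal branches."""
    tns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    ancestors: dict[str, dendropy.Node] = {}
    for tip_id, spec in tip_specs:
        if spec.species not in ancestors:
            anc = dendropy.Node()
            root.add_child(anc)
            anc.edge.length = spec.stem
            ancestors[spec.species] = anc
        leaf = dendropy.Node()
        leaf.taxon = tns.require_taxon(label=tip_id)
        ancestors[spec.species].add_child(leaf)
        leaf.edge.length = float(rng.uniform(0.0, spec.tip_spread))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def _panel_tips(cfg: SimulationConfig) -> list[tuple[str, GroupSpec]]:
    return [
        (f"{g.tag}_ref{i}", g)
        for g in cfg.groups
        for i in range(1, g.n_panel + 1)
    ]


def simulate_alignment(cfg: SimulationConfig) -> tuple[Alignment, GroupMap]:
    """Simulate the reference-panel alignment for a configuration.

    Same seed -> byte-identical output. Leaves are labelled by group via the
    returned :class:`GroupMap`.
    """
    rng = np.random.default_rng(cfg.seed)
    tips = _panel_tips(cfg)
    tree = _star_tree(tips, rng)
    seqs = evolve_along_tree(tree, cfg.length, cfg.kappa, rng)
    records = [SequenceRecord(id=tid, residues=seqs[tid], description=spec.species)
               for tid, spec in tips]
    gm = GroupMap({
        tid: GroupEntry(spec.species, spec.genus, spec.role) for tid, spec in tips
    })
    return Alignment(records), gm


def plant_diagnostics(
    aln: Alignment,
    gm: GroupMap,
    target: str,
    contrast: str,
    k: int,
    seed: int | None = None,
    level: str = "species",
) -> tuple[Alignment, tuple[int, ...]]:
    """Overwrite ``k`` random columns so the target group is fixed for one
    state and every contrast row differs there; returns the planted 1-based
    positions (sorted)."""
    if k > aln.length:
        raise SimulationError(f"k={k} exceeds alignment length {aln.length}")
    rng = np.random.default_rng(seed)
    t_rows = [i for i, lab in enumerate(aln.ids) if gm.group_of(lab, level) == target]
    c_rows = [i for i, lab in enumerate(aln.ids) if gm.group_of(lab, level) == contrast]
    if not t_rows or not c_rows:
        raise SimulationError("target and contrast groups must both have rows")
    mat = aln.matrix().copy()
    cols = rng.choice(aln.length, size=k, replace=False) if k else np.array([], dtype=int)
    for col in cols:
        x = int(rng.integers(0, 4))
        mat[t_rows, col] = x
        others = np.array([s for s in range(4) if s != x], dtype=np.int8)
        mat[c_rows, col] = rng.choice(others, size=len(c_rows))
    records = [
        SequenceRecord(id=rec.id, residues=decode(mat[i]), description=rec.description)
        for i, rec in enumerate(aln.records)
    ]
    return Alignment(records), tuple(sorted(int(c) + 1 for c in cols))


# ---------------------------------------------------------------------------
# Market study


@dataclass(frozen=True)
class MarketStudy:
    """A complete synthetic study: panel, unlabeled market set and truth table."""

    panel: list[SequenceRecord]
    market: list[SequenceRecord]
    group_map: GroupMap
    truth: pd.DataFrame  # columns: id, true_species, true_genus
    tree: dendropy.Tree
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.panel, outdir / "panel.fasta")
        write_fasta(self.market, outdir / "market.fasta")
        write_group_map(self.group_map, outdir / "groups.csv")
        self.truth.to_csv(outdir / "truth.csv", index=False)


def make_market_study(cfg: SimulationConfig | None = None) -> MarketStudy:
    """Simulate a reference panel plus a market set with known truth.

    Market samples evolve inside the clade of their true species, with the
    same terminal-branch spread as panel members, so authentic samples sit at
    near-zero distance from the reference panel and adulterants at their
    group's divergence.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    by_species = {g.species: g for g in cfg.groups}
    ref = cfg.reference_group()

    market_truth = [ref.species] * cfg.authentic_count
    for species, count in sorted(cfg.adulterant_composition.items()):
        market_truth.extend([species] * count)
    market_truth = list(np.array(market_truth)[rng.permutation(cfg.n_samples)])

    tips = _panel_tips(cfg)
    market_ids = [f"mkt_{i:02d}" for i in range(1, cfg.n_samples + 1)]
    tips += [(mid, by_species[sp]) for mid, sp in zip(market_ids, market_truth)]

    tree = _star_tree(tips, rng)
    seqs = evolve_along_tree(tree, cfg.length, cfg.kappa, rng)

    panel = [
        SequenceRecord(id=tid, residues=seqs[tid], description=spec.species)
        for tid, spec in tips[: len(tips) - cfg.n_samples]
    ]
    market = [
        SequenceRecord(id=mid, residues=seqs[mid], description="market sample")
        for mid in market_ids
    ]
    entries = {
        tid: GroupEntry(spec.species, spec.genus, spec.role)
        for tid, spec in tips[: len(tips) - cfg.n_samples]
    }
    entries.update({
        mid: GroupEntry("unknown", "unknown", "unknown") for mid in market_ids
    })
    truth = pd.DataFrame({
        "id": market_ids,
        "true_species": market_truth,
        "true_genus": [by_species[sp].genus for sp in market_truth],
    })
    return MarketStudy(
        panel=panel,
        market=market,
        group_map=GroupMap(entries),
        truth=truth,
        tree=tree,
        config=cfg,
    )
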