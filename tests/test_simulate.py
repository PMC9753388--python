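"""Synthetic-data generator: substitution process, planting, market studies."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from barcodeauth.distances import count_site_pairs, k2p_distance
from barcodeauth.gap import diagnostic_sites
from barcodeauth.simulate import (
    DEFAULT_ADULTERANT_COMPOSITION,
    SimulationConfig,
    SimulationError,
    evolve_along_tree,
    make_market_study,
    plant_diagnostics,
    rate_matrix,
    simulate_alignment,
)


def chain_tree(d):
    tns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    for lab, length in (("x", 0.0), ("y", d)):
        nd = dendropy.Node()
        nd.taxon = tns.require_taxon(label=lab)
        root.add_child(nd)
        nd.edge.length = length
    t = dendropy.Tree(taxon_namespace=tns)
    t.seed_node = root
    return t


def test_rate_matrix_normalized_to_one_substitution_per_unit():
    for kappa in (0.5, 1.0, 2.0, 5.0):
        Q = rate_matrix(kappa)
        assert np.allclose(Q.sum(axis=1), 0.0)
        assert np.allclose(-np.diag(Q), 1.0)


def test_zero_branch_lengths_give_identical_leaves(flat_study):
    aln, _ = flat_study
    first = aln.records[0].residues
    assert all(r.residues == first for r in aln)


def test_same_seed_byte_identical():
    a1, _ = simulate_alignment(SimulationConfig(seed=123))
    a2, _ = simulate_alignment(SimulationConfig(seed=123))
    assert [(r.id, r.residues) for r in a1] == [(r.id, r.residues) for r in a2]
    a3, _ = simulate_alignment(SimulationConfig(seed=124))
    assert any(x.residues != y.residues for x, y in zip(a1, a3))


def test_k2p_estimator_consistent_on_long_branch():
    rng = np.random.default_rng(0)
    seqs = evolve_along_tree(chain_tree(0.1), 100_000, 1.0, rng)
    c = count_site_pairs(seqs["x"], seqs["y"])
    d = k2p_distance(c)
    # 3-SE band via the binomial noise on p at this length
    assert abs(d - 0.1) < 3 * np.sqrt(0.1 / 100_000) * 2


def test_transition_transversion_ratio_converges_to_kappa_over_two():
    rng = np.random.default_rng(1)
    for kappa in (1.0, 2.0, 4.0):
        seqs = evolve_along_tree(chain_tree(0.05), 200_000, kappa, rng)
        c = count_site_pairs(seqs["x"], seqs["y"])
        ratio = c.transitions / c.transversions
        assert ratio == pytest.approx(kappa / 2.0, rel=0.15)


def test_sister_pair_k2p_unbiased_for_branch_sum():
    tns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    for lab in ("x", "y"):
        nd = dendropy.Node()
        nd.taxon = tns.require_taxon(label=lab)
        root.add_child(nd)
        nd.edge.length = 0.04
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    rng = np.random.default_rng(5)
    seqs = evolve_along_tree(tree, 100_000, 2.0, rng)
    d = k2p_distance(count_site_pairs(seqs["x"], seqs["y"]))
    assert d == pytest.approx(0.08, abs=0.005)


def test_config_validation():
    with pytest.raises(SimulationError):
        SimulationConfig(authentic_count=30)
    with pytest.raises(SimulationError):
        SimulationConfig(adulterant_composition={"Hymenocrater bituminosus": 20})
    with pytest.raises(SimulationError):
        SimulationConfig(adulterant_composition={"No such": 15})
    with pytest.raises(SimulationError):
        SimulationConfig(length=0)


def test_plant_diagnostics_contract(flat_study):
    aln, gm = flat_study
    planted, pos = plant_diagnostics(
        aln, gm, "Melissa officinalis", "Melissa axillaris", 6, seed=7
    )
    assert len(pos) == 6 and pos == tuple(sorted(pos))
    ds = diagnostic_sites(planted, gm, "Melissa officinalis", {"Melissa axillaris"})
    assert ds.positions == pos
    # untouched rows unchanged
    other = [r for r in planted if r.id.startswith("Dmol")]
    orig = {r.id: r.residues for r in aln}
    assert all(orig[r.id] == r.residues for r in other)


def test_plant_diagnostics_k_zero_and_overflow(flat_study):
    aln, gm = flat_study
    same, pos = plant_diagnostics(aln, gm, "Melissa officinalis", "Melissa axillaris", 0)
    assert pos == ()
    assert [r.residues for r in same] == [r.residues for r in aln]
    with pytest.raises(SimulationError):
        plant_diagnostics(aln, gm, "Melissa officinalis", "Melissa axillaris",
                          aln.length + 1)


def test_market_study_structure(market_study):
    study = market_study
    assert len(study.market) == 22
    assert (study.truth.true_species == "Melissa officinalis").sum() == 7
    counts = study.truth.true_species.value_counts().to_dict()
    for species, n in DEFAULT_ADULTERANT_COMPOSITION.items():
        assert counts[species] == n
    # group map covers panel (labelled) and market (unknown)
    for r in study.panel:
        assert study.group_map.role_of(r.id) in ("reference", "adulterant")
    for r in study.market:
        assert study.group_map.role_of(r.id) == "unknown"
    assert all(len(r.residues) == 750 for r in study.market)


def test_market_study_files_round_trip(tmp_path, market_study):
    from barcodeauth import seqio

    market_study.write(tmp_path)
    panel = seqio.read_fasta(tmp_path / "panel.fasta")
    market = seqio.read_fasta(tmp_path / "market.fasta")
    gm = seqio.read_group_map(tmp_path / "groups.csv")
    truth = pd.read_csv(tmp_path / "truth.csv")
    assert [r.id for r in panel] == [r.id for r in market_study.panel]
    assert [r.residues for r in market] == [r.residues for r in market_study.market]
    assert set(gm.ids) == set(market_study.group_map.ids)
    assert truth.shape == market_study.truth.shape


def test_all_authentic_market_gives_zero_rate():
    from barcodeauth.classify import classify_market, market_report

    cfg = SimulationConfig(
        n_samples=5, authentic_count=5, adulterant_composition={}, seed=2
    )
    study = make_market_study(cfg)
    results = classify_market(study.market, study.panel, study.group_map,
                              tree_verify=False)
    rep = market_report(results)
    assert rep.adulteration_rate == 0.0
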