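"""Ground-truth simulators: determinism, stationarity, closed-form agreement."""

import json

import numpy as np
import pytest

from paleoclock.seq_identity import AlignedPair, percent_identity
from paleoclock.substitution import SubstitutionModel, discrete_gamma_rates
from paleoclock.synthetic import (
    SimulationSpec,
    make_duplication_fixture,
    simulate_alignment,
    simulate_chronogram,
    simulate_rates,
)
from paleoclock.timetree import TimeTree


def test_chronogram_shape_and_root_age():
    t3 = simulate_chronogram(SimulationSpec(n_taxa=3, seed=1))
    assert t3.n_leaves == 3
    assert sum(1 for c in t3.children if c) == 2  # exactly n-1 internal nodes
    for n in (3, 5, 8, 12):
        t = simulate_chronogram(SimulationSpec(n_taxa=n, seed=n))
        t.validate()
        assert t.ages[t.root] == pytest.approx(3500.0)
        assert np.all(t.ages[t.leaves] == 0.0)


def test_chronogram_deterministic_under_seed():
    spec = SimulationSpec(n_taxa=7, seed=99)
    assert simulate_chronogram(spec).to_newick() == simulate_chronogram(spec).to_newick()
    other = SimulationSpec(n_taxa=7, seed=100)
    assert simulate_chronogram(spec).to_newick() != simulate_chronogram(other).to_newick()


def test_rates_strict_clock_and_determinism():
    t = simulate_chronogram(SimulationSpec(n_taxa=6, seed=2))
    strict = simulate_rates(t, sigma2=0.0, root_rate=3e-4, seed=5)
    assert np.allclose(strict.rates, 3e-4)
    a = simulate_rates(t, sigma2=1e-4, root_rate=3e-4, seed=5)
    b = simulate_rates(t, sigma2=1e-4, root_rate=3e-4, seed=5)
    assert np.array_equal(a.rates, b.rates)
    assert np.all(a.rates > 0)


def test_alignment_deterministic_and_degenerate_limits():
    spec = SimulationSpec(n_taxa=5, seed=8)
    t = simulate_rates(simulate_chronogram(spec), 1e-4, 1.25e-4, 9)
    model = SubstitutionModel(0.5, 4)
    assert simulate_alignment(t, model, 50, 11) == simulate_alignment(t, model, 50, 11)
    # vanishing rates: all sequences identical
    frozen = simulate_rates(simulate_chronogram(spec), 0.0, 1e-12, 9)
    aln = simulate_alignment(frozen, model, 80, 11)
    assert len(set(aln.values())) == 1
    # enormous divergence: identity collapses to the stationary 5%
    saturated = simulate_rates(simulate_chronogram(spec), 0.0, 1.0, 9)
    aln_sat = simulate_alignment(saturated, SubstitutionModel(100.0, 4), 20000, 13)
    seqs = list(aln_sat.values())
    ident = percent_identity(AlignedPair("a", "b", seqs[0], seqs[1]))
    assert ident == pytest.approx(5.0, abs=0.7)


def test_two_leaf_identity_matches_closed_form():
    # strict clock, single rate category: P(identical residue) is exactly
    # p_same(total path length); binomial check at 1e5 sites
    t = TimeTree.from_newick("(A:1,B:1)r;")  # ages 1 Ma each side
    t.rates = np.full(3, 0.05)  # path length 2 * 1 * 0.05 = 0.1
    aln = simulate_alignment(t, SubstitutionModel(1.0, 1), 100000, 21)
    obs = percent_identity(AlignedPair("a", "b", aln["A"], aln["B"])) / 100.0
    expected = 1 / 20 + (19 / 20) * np.exp(-(20 / 19) * 0.1)
    se = np.sqrt(expected * (1 - expected) / 100000)
    assert abs(obs - expected) < 4 * se


def test_identity_decreases_with_path_length():
    # expectation check across exchangeable replicate pairs
    model = SubstitutionModel(1.0, 1)
    means = []
    for age in (200.0, 1000.0, 4000.0):
        vals = []
        for seed in range(5):
            t = TimeTree.from_newick(f"(A:{age},B:{age})r;")
            t.rates = np.full(3, 2e-4)
            aln = simulate_alignment(t, model, 2000, 31 + seed)
            vals.append(percent_identity(AlignedPair("a", "b", aln["A"], aln["B"])))
        means.append(np.mean(vals))
    assert means[0] > means[1] > means[2]


class TestDuplicationFixture:
    spec = SimulationSpec(seed=17)

    def test_structure_and_truth(self):
        fx = make_duplication_fixture(self.spec)
        t = fx.true_tree
        t.validate()
        assert t.n_leaves == 8
        dup = t.node_by_label("dup")
        root = t.root
        # the duplication analogue is the oldest node after the root
        internal_ages = [t.ages[i] for i in range(t.n_nodes) if t.children[i] and i != root]
        assert t.ages[dup] == max(internal_ages)
        assert fx.truth["ages_ma"]["dup"] == pytest.approx(t.ages[dup])
        # mirrored paralogue clades: identical shapes and ages
        a, b = t.node_by_label("cladeA"), t.node_by_label("cladeB")
        assert t.ages[a] == t.ages[b]
        assert len(fx.calibrations) == 3
        # bare topology for the sampler
        assert fx.topology.ages is None and fx.topology.rates is None

    def test_truth_file_roundtrips(self, tmp_path):
        fx = make_duplication_fixture(self.spec)
        fx.write(str(tmp_path))
        reread = TimeTree.from_newick(str(tmp_path / "true_chronogram.nwk"))
        for lbl, age in fx.truth["ages_ma"].items():
            assert reread.ages[reread.node_by_label(lbl)] == pytest.approx(age, abs=1e-3)
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["duplication_node"] == "dup"
        aln_lines = (tmp_path / "alignment.fasta").read_text().splitlines()
        assert sum(1 for l in aln_lines if l.startswith(">")) == 8

    def test_cross_clade_identity_in_observed_band(self):
        # With branch lengths tuned to the deep-paralogue regime (strict
        # clock so the expectation is exact), A-vs-B leaf identity falls in
        # the empirically observed ~40-45% band.
        spec = SimulationSpec(seed=23, sigma2=0.0, root_rate=4e-4, n_sites=4000)
        fx = make_duplication_fixture(spec)
        t = fx.true_tree
        dup_age = fx.truth["ages_ma"]["dup"]
        d = 2 * dup_age * spec.root_rate
        cats = discrete_gamma_rates(spec.alpha, 4)
        expected = np.mean(1 / 20 + (19 / 20) * np.exp(-(20 / 19) * d * cats)) * 100
        assert 40.0 < expected < 45.0
        obs = []
        for la in ("AT1", "AT2", "AT3"):
            for lb in ("BT1", "BT2", "BT3"):
                obs.append(
                    percent_identity(
                        AlignedPair("a", "b", fx.alignment[la], fx.alignment[lb])
                    )
                )
        assert np.mean(obs) == pytest.approx(expected, abs=2.0)

    def test_fixture_requires_even_clade_split(self):
        with pytest.raises(ValueError):
            make_duplication_fixture(SimulationSpec(n_taxa=7, seed=1))
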