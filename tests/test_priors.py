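"""Rate and age priors: closed forms, normalisation, soft-bound calibrations."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest, norm

from paleoclock.priors import (
    Calibration,
    CalibrationSet,
    ClockModel,
    RootPrior,
    SoftBoundDensity,
    log_prior_ages,
    log_prior_rates,
    read_calibration_tsv,
    write_calibration_tsv,
)
from paleoclock.synthetic import simulate_rates
from paleoclock.timetree import TimeTree


class TestSoftBound:
    sb = SoftBoundDensity(82.0, 127.0, 0.025)

    def test_total_mass_and_tail_masses(self):
        total, _ = quad(self.sb.pdf, -200, 800, limit=200)
        assert abs(total - 1.0) < 1e-6
        below, _ = quad(self.sb.pdf, -400, 82.0)
        above, _ = quad(self.sb.pdf, 127.0, 1200)
        assert abs(below - 0.025) < 1e-8
        assert abs(above - 0.025) < 1e-8

    def test_core_density_is_flat_at_core_level(self):
        level = (1 - 2 * 0.025) / (127 - 82)
        for t in (82.0, 90.0, 104.5, 127.0):
            assert self.sb.pdf(t) == pytest.approx(level)

    def test_mean_is_core_midpoint(self):
        # symmetric tails cancel: mean = (min+max)/2
        assert self.sb.mean() == pytest.approx(104.5)
        num, _ = quad(lambda t: t * self.sb.pdf(t), -400, 1200, limit=400)
        assert num == pytest.approx(self.sb.mean(), rel=1e-6)

    def test_cdf_ppf_consistency(self):
        u = np.linspace(1e-9, 1 - 1e-9, 501)
        assert np.abs(self.sb.cdf(self.sb.ppf(u)) - u).max() < 1e-12
        ts = np.linspace(-50, 400, 301)
        pdf_num = np.gradient(self.sb.cdf(ts), ts)
        # numerical derivative of the CDF tracks the density away from kinks
        interior = (ts > 85) & (ts < 124)
        assert np.allclose(pdf_num[interior], self.sb.pdf(ts[interior]), rtol=5e-3)


def test_calibration_validation():
    with pytest.raises(ValueError, match="at least one bound"):
        Calibration("n")
    with pytest.raises(ValueError, match="min_ma"):
        Calibration("n", 100.0, 50.0)
    assert Calibration("n", 82.0, 127.0).tail_prob == 0.025
    assert Calibration("n", 475.0, None).tail_prob == 0.05  # single-minimum default


def test_calibration_resolve_errors():
    t = TimeTree.from_newick("((A,B)ab,C)r;", ages_from_lengths=False)
    with pytest.raises(KeyError):
        CalibrationSet([Calibration("nope", 1.0, 2.0)]).resolve(t)
    with pytest.raises(ValueError, match="root"):
        CalibrationSet([Calibration("r", 1.0, 2.0)]).resolve(t)


def test_calibration_tsv_roundtrip(tmp_path):
    cals = CalibrationSet(
        [Calibration("node1", 82.0, 127.0), Calibration("node4", 475.0, None)]
    )
    path = tmp_path / "cal.tsv"
    write_calibration_tsv(cals, str(path))
    back = read_calibration_tsv(str(path))
    assert [(c.node_label, c.min_ma, c.max_ma) for c in back] == [
        ("node1", 82.0, 127.0),
        ("node4", 475.0, None),
    ]


def chain_tree(dt=1.0, parent_rate=1.0, child_rate=1.0):
    """Minimal parent->child tree for closed-form rate-prior checks."""
    t = TimeTree(
        parent=np.array([-1, 0]),
        children=[[1], []],
        labels=["p", "c"],
        ages=np.array([dt, 0.0]),
        rates=np.array([parent_rate, child_rate]),
    )
    return t


def test_log_prior_rates_closed_form():
    # child_rate = parent * e^{-1/2} with sigma2*dt = 1 sits at the mode of
    # the increment: density = N(0,1) pdf at 0 minus log(child_rate)
    child = np.exp(-0.5)
    t = chain_tree(dt=1.0, parent_rate=1.0, child_rate=child)
    expected = norm.logpdf(0.0) - np.log(child)
    assert log_prior_rates(t, ClockModel(sigma2=1.0, root_rate=1.0)) == pytest.approx(
        expected
    )


def test_log_prior_rates_strict_clock_limit():
    # as sigma2 -> 0 with all rates equal, the density concentrates
    t = chain_tree(child_rate=1.0)
    vals = [
        log_prior_rates(t, ClockModel(sigma2=s, root_rate=1.0))
        for s in (1e-2, 1e-4, 1e-6)
    ]
    assert vals[0] < vals[1] < vals[2]
    with pytest.raises(ValueError):
        log_prior_rates(chain_tree(child_rate=-1.0), ClockModel(1.0, 1.0))


def test_forward_rate_simulation_is_mean_preserving_and_matches_density():
    # Monte-Carlo: E[child_rate] = parent_rate, and log child-rate draws
    # follow N(log r0 - v/2, v) -- the same law log_prior_rates scores.
    base = TimeTree.from_newick("(A:10,B:10)r;")
    sigma2, r0 = 0.05, 2.0
    draws = []
    for seed in range(4000):
        sim = simulate_rates(base, sigma2=sigma2, root_rate=r0, seed=seed)
        draws.extend(sim.rates[i] for i in sim.leaves)
    draws = np.array(draws)
    var = sigma2 * 10.0
    se = draws.std() / np.sqrt(len(draws))
    assert abs(draws.mean() - r0) < 3 * se
    ks = kstest(np.log(draws), norm(np.log(r0) - var / 2, np.sqrt(var)).cdf)
    assert ks.pvalue > 0.01


class TestLogPriorAges:
    def make_tree(self, cal_age=100.0, root_age=3500.0):
        t = TimeTree.from_newick("((A,B)cal,C)r;", ages_from_lengths=False)
        ages = np.zeros(t.n_nodes)
        ages[t.node_by_label("cal")] = cal_age
        ages[t.root] = root_age
        t.ages = ages
        return t

    def test_uncalibrated_prior_is_root_density_plus_simplex_term(self):
        t = self.make_tree()
        rp = RootPrior(3500.0, 50.0)
        lp = log_prior_ages(t, CalibrationSet([]), rp)
        # 2 internal nodes -> one free internal age, uniform on (0, root)
        expected = norm.logpdf(3500.0, 3500.0, 50.0) - np.log(3500.0)
        assert lp == pytest.approx(expected)

    def test_calibrated_interior_point_adds_core_level(self):
        t = self.make_tree(cal_age=100.0)
        rp = RootPrior(3500.0, 50.0)
        calset = CalibrationSet([Calibration("cal", 82.0, 127.0)])
        base = log_prior_ages(t, CalibrationSet([]), rp)
        lp = log_prior_ages(t, calset, rp)
        assert lp - base == pytest.approx(np.log((1 - 0.05) / 45.0))

    def test_order_violation_gives_minus_inf(self):
        t = self.make_tree(cal_age=4000.0)  # older than the root
        lp = log_prior_ages(t, CalibrationSet([]), RootPrior(3500.0, 50.0))
        assert lp == -np.inf

    def test_min_only_calibration_renormalises_with_root(self):
        rp = RootPrior(3500.0, 50.0)
        calset = CalibrationSet([Calibration("cal", min_ma=475.0)])
        t1 = self.make_tree(cal_age=600.0, root_age=3500.0)
        t2 = self.make_tree(cal_age=600.0, root_age=3000.0)
        lp1 = log_prior_ages(t1, calset, rp)
        lp2 = log_prior_ages(t2, calset, rp)
        # above the minimum the density is uniform on [min, root]
        delta_root = norm.logpdf(3500.0, 3500.0, 50.0) - norm.logpdf(3000.0, 3500.0, 50.0)
        delta_simplex = -np.log(3500.0) + np.log(3000.0)
        delta_cal = -np.log(3500.0 - 475.0) + np.log(3000.0 - 475.0)
        assert lp1 - lp2 == pytest.approx(delta_root + delta_simplex + delta_cal)
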