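"""Priors for relaxed-clock node dating.

Three pieces:

* **Autocorrelated log-normal rates** (Thorne–Kishino geometric Brownian
  motion): along a branch of duration Δt (Ma), the child's log-rate is
  normal with mean ``log(parent_rate) - sigma2*Δt/2`` and variance
  ``sigma2*Δt``.  The -sigma2*Δt/2 shift makes the process mean-preserving,
  E[child_rate | parent_rate] = parent_rate.

* **Node ages**: the root age carries a normal prior (e.g. 3500 ± 50 Ma);
  conditional on the root, the remaining internal ages are uniform on the
  order polytope (every parent older than its children).  The polytope's
  volume scales as root^(n_internal - 1), which contributes the
  ``-(n_internal-1) * log(root_age)`` term.

* **Soft-bound fossil calibrations**: a calibrated node multiplies in a
  density with a uniform core on [min, max] and exponential tails carrying a
  fixed small probability mass outside each bound — 2.5% per side for a
  two-sided bound, 5% below the bound when only a minimum exists.  Tail
  scale is 10% of the core width (or of the minimum age for one-sided
  bounds), a smoothing choice.  A minimum-only calibration has no natural
  upper limit, so its core is uniform on [min, root_age] — proper, and
  renormalised as the root moves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .timetree import TimeTree

__all__ = [
    "ClockModel",
    "RootPrior",
    "Calibration",
    "CalibrationSet",
    "SoftBoundDensity",
    "log_prior_rates",
    "log_prior_ages",
    "read_calibration_tsv",
]


@dataclass(frozen=True)
class ClockModel:
    """Hyperparameters of the autocorrelated log-normal rate process."""

    sigma2: float  # variance of log-rate increments per Ma
    root_rate: float  # substitutions/site/Ma at the root

    def __post_init__(self):
        if self.sigma2 < 0 or self.root_rate <= 0:
            raise ValueError("sigma2 must be >= 0 and root_rate > 0")


@dataclass(frozen=True)
class RootPrior:
    mean_ma: float
    sd_ma: float

    def __post_init__(self):
        if self.mean_ma <= 0 or self.sd_ma <= 0:
            raise ValueError("root prior mean and sd must be positive")


@dataclass(frozen=True)
class Calibration:
    node_label: str
    min_ma: float | None = None
    max_ma: float | None = None
    tail_prob: float | None = None  # default: 0.025 two-sided, 0.05 min-only

    def __post_init__(self):
        if self.min_ma is None and self.max_ma is None:
            raise ValueError("calibration needs at least one bound")
        if self.min_ma is not None and self.max_ma is not None and self.min_ma > self.max_ma:
            raise ValueError("min_ma must not exceed max_ma")
        tp = self.tail_prob
        if tp is None:
            tp = 0.025 if (self.min_ma is not None and self.max_ma is not None) else 0.05
            object.__setattr__(self, "tail_prob", tp)
        if not 0.0 < self.tail_prob < 0.5:
            raise ValueError("tail_prob must lie in (0, 0.5)")

    @property
    def two_sided(self) -> bool:
        return self.min_ma is not None and self.max_ma is not None


class SoftBoundDensity:
    """Analytic form of a two-sided soft-bound calibration density.

    Core: uniform on [min, max] with mass 1 - 2*tail; tails: exponential with
    mass ``tail`` each and scale 10% of the core width.  Used both to score
    MCMC states and as the reference distribution in prior-fidelity checks.
    """

    def __init__(self, min_ma: float, max_ma: float, tail_prob: float = 0.025):
        if not min_ma < max_ma:
            raise ValueError("need min < max for a two-sided bound")
        self.lo = min_ma
        self.hi = max_ma
        self.tail = tail_prob
        self.width = max_ma - min_ma
        self.scale = 0.1 * self.width
        self.core_height = (1.0 - 2.0 * tail_prob) / self.width

    def logpdf(self, t):
        scalar = np.ndim(t) == 0
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty_like(t)
        below = t < self.lo
        above = t > self.hi
        core = ~(below | above)
        out[core] = np.log(self.core_height)
        out[below] = np.log(self.tail / self.scale) - (self.lo - t[below]) / self.scale
        out[above] = np.log(self.tail / self.scale) - (t[above] - self.hi) / self.scale
        return float(out[0]) if scalar else out

    def pdf(self, t):
        return np.exp(self.logpdf(t))

    def cdf(self, t):
        scalar = np.ndim(t) == 0
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty_like(t)
        below = t < self.lo
        above = t > self.hi
        core = ~(below | above)
        out[below] = self.tail * np.exp(-(self.lo - t[below]) / self.scale)
        out[core] = self.tail + self.core_height * (t[core] - self.lo)
        out[above] = 1.0 - self.tail * np.exp(-(t[above] - self.hi) / self.scale)
        return float(out[0]) if scalar else out

    def ppf(self, u):
        """Inverse CDF (used for direct sampling and independence proposals)."""
        scalar = np.ndim(u) == 0
        u = np.atleast_1d(np.asarray(u, dtype=float))
        out = np.empty_like(u)
        below = u < self.tail
        above = u > 1.0 - self.tail
        core = ~(below | above)
        out[below] = self.lo + self.scale * np.log(u[below] / self.tail)
        out[core] = self.lo + (u[core] - self.tail) / self.core_height
        out[above] = self.hi - self.scale * np.log((1.0 - u[above]) / self.tail)
        return float(out[0]) if scalar else out

    def mean(self) -> float:
        """Analytic mean: core midpoint; the symmetric tails shift it outward equally."""
        core = (1.0 - 2.0 * self.tail) * (self.lo + self.hi) / 2.0
        lower_tail = self.tail * (self.lo - self.scale)
        upper_tail = self.tail * (self.hi + self.scale)
        return core + lower_tail + upper_tail


def _min_only_logpdf(t: float, min_ma: float, root_age: float, tail: float) -> float:
    """Min-only soft bound: uniform on [min, root] plus a 5% exponential tail below."""
    scale = 0.1 * min_ma
    if t >= min_ma:
        if root_age <= min_ma:
            return -np.inf
        return float(np.log((1.0 - tail) / (root_age - min_ma)))
    return float(np.log(tail / scale) - (min_ma - t) / scale)


@dataclass
class CalibrationSet:
    calibrations: list[Calibration] = field(default_factory=list)

    def __iter__(self):
        return iter(self.calibrations)

    def __len__(self):
        return len(self.calibrations)

    def resolve(self, tree: TimeTree) -> list[tuple[int, Calibration]]:
        """Map node labels to node indices; error on unknown labels or the root."""
        out = []
        for cal in self.calibrations:
            idx = tree.node_by_label(cal.node_label)  # KeyError if absent
            if idx == tree.root:
                raise ValueError(
                    "the root age is constrained by the root prior, not a calibration"
                )
            out.append((idx, cal))
        return out


def log_prior_rates(tree: TimeTree, clock: ClockModel) -> float:
    """Log-density of all non-root branch rates under the autocorrelated model."""
    if tree.ages is None or tree.rates is None:
        raise ValueError("tree needs ages and rates")
    if np.any(tree.rates <= 0):
        raise ValueError("rates must be positive")
    has_parent = tree.parent >= 0
    idx = np.flatnonzero(has_parent)
    dt = tree.ages[tree.parent[idx]] - tree.ages[idx]
    if np.any(dt <= 0):
        raise ValueError("parent must be strictly older than child")
    var = clock.sigma2 * dt
    log_r = np.log(tree.rates[idx])
    log_rp = np.log(tree.rates[tree.parent[idx]])
    mu = log_rp - var / 2.0
    # log-normal density of the child rate
    return float(np.sum(norm.logpdf(log_r, loc=mu, scale=np.sqrt(var)) - log_r))


def log_prior_ages(
    tree: TimeTree,
    calibrations: CalibrationSet,
    root_prior: RootPrior,
    resolved: list[tuple[int, Calibration]] | None = None,
) -> float:
    """Log prior of the node ages: root normal x order-polytope uniform x soft bounds."""
    if tree.ages is None:
        raise ValueError("tree needs ages")
    root = tree.root
    root_age = float(tree.ages[root])
    # ordering support
    has_parent = tree.parent >= 0
    if np.any(tree.ages[tree.parent[has_parent]] <= tree.ages[has_parent]):
        return -np.inf
    lp = float(norm.logpdf(root_age, loc=root_prior.mean_ma, scale=root_prior.sd_ma))
    n_internal = int(sum(1 for c in tree.children if c))
    lp += -(n_internal - 1) * np.log(root_age)
    if resolved is None:
        resolved = calibrations.resolve(tree)
    for idx, cal in resolved:
        t = float(tree.ages[idx])
        if cal.two_sided:
            lp += float(SoftBoundDensity(cal.min_ma, cal.max_ma, cal.tail_prob).logpdf(t))
        elif cal.min_ma is not None:
            lp += _min_only_logpdf(t, cal.min_ma, root_age, cal.tail_prob)
        else:  # max-only: uniform core on [0, max] with a 5% tail above
            scale = 0.1 * cal.max_ma
            if t <= cal.max_ma:
                lp += float(np.log((1.0 - cal.tail_prob) / cal.max_ma))
            else:
                lp += float(
                    np.log(cal.tail_prob / scale) - (t - cal.max_ma) / scale
                )
    return lp


def read_calibration_tsv(path: str) -> CalibrationSet:
    """Read calibrations from TSV columns node_label, min_ma, max_ma (blank = absent)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cals = []
    for row in df.itertuples(index=False):
        lo = getattr(row, "min_ma", None)
        hi = getattr(row, "max_ma", None)
        lo = None if lo is None or pd.isna(lo) else float(lo)
        hi = None if hi is None or pd.isna(hi) else float(hi)
        cals.append(Calibration(node_label=str(row.node_label), min_ma=lo, max_ma=hi))
    return CalibrationSet(cals)


def write_calibration_tsv(calset: CalibrationSet, path: str) -> None:
    rows = [
        {"node_label": c.node_label, "min_ma": c.min_ma, "max_ma": c.max_ma}
        for c in calset
    ]
    pd.DataFrame(rows, columns=["node_label", "min_ma", "max_ma"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
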