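"""Posterior traces from relaxed-clock MCMC: storage, summaries, diagnostics.

A :class:`ClockPosterior` holds post-burn-in, thinned samples of every node
age (Ma), every branch rate (subs/site/Ma), the clock variance ``sigma2``
and the gamma shape ``alpha``, per chain, plus split-R-hat convergence
diagnostics.  Summaries report posterior mean, standard deviation and the
central 95% credible interval (both as percentile bounds and as a
half-width, since "mean ± x" tables in the literature use either).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ClockPosterior", "split_rhat", "summarize_posterior", "rates_vs_time"]


def split_rhat(chains: list[np.ndarray]) -> float:
    """Split-R-hat of one scalar parameter across chains.

    Each chain is split in half; R-hat compares between-half and within-half
    variance.  Constant traces return 1.0.
    """
    halves = []
    for c in chains:
        c = np.asarray(c, dtype=float)
        n = len(c) // 2
        if n < 2:
            raise ValueError("chains too short for split-R-hat")
        halves.append(c[:n])
        halves.append(c[n : 2 * n])
    arr = np.stack(halves)  # (m, n)
    m, n = arr.shape
    W = arr.var(axis=1, ddof=1).mean()
    B = n * arr.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


@dataclass
class ClockPosterior:
    """MCMC trace of node ages, branch rates and hyperparameters."""

    node_names: list[str]
    leaf_mask: np.ndarray  # True where the node is a leaf (age fixed at 0)
    chains: list[dict]  # per chain: ages (S, n), rates (S, n), sigma2, alpha, loglik, logprior
    burn_in: int
    thin: int
    seed: int
    rhat: dict = field(default_factory=dict)
    converged: bool = True
    messages: list[str] = field(default_factory=list)

    # ------------------------------------------------------------- accessors
    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def pooled(self, key: str) -> np.ndarray:
        return np.concatenate([c[key] for c in self.chains], axis=0)

    def node_index(self, name: str) -> int:
        return self.node_names.index(name)

    def node_ages(self, name: str) -> np.ndarray:
        return self.pooled("ages")[:, self.node_index(name)]

    # ------------------------------------------------------------- summaries
    def summarize(self) -> pd.DataFrame:
        return summarize_posterior(self)

    def to_trace_frames(self) -> list[pd.DataFrame]:
        """One tidy DataFrame per chain (one row per retained sample)."""
        frames = []
        for c in self.chains:
            cols = {}
            for j, name in enumerate(self.node_names):
                if not self.leaf_mask[j]:
                    cols[f"age_{name}"] = c["ages"][:, j]
            for j, name in enumerate(self.node_names):
                cols[f"rate_{name}"] = c["rates"][:, j]
            cols["sigma2"] = c["sigma2"]
            cols["alpha"] = c["alpha"]
            cols["loglik"] = c["loglik"]
            cols["logprior"] = c["logprior"]
            frames.append(pd.DataFrame(cols))
        return frames


def _summary_row(samples: np.ndarray) -> dict:
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return {
        "mean": float(samples.mean()),
        "sd": float(samples.std(ddof=1)) if len(samples) > 1 else 0.0,
        "ci2.5": float(lo),
        "ci97.5": float(hi),
        "ci95_halfwidth": float((hi - lo) / 2.0),
    }


def summarize_posterior(posterior: ClockPosterior) -> pd.DataFrame:
    """Per-node posterior summaries of ages and rates.

    Returns a DataFrame indexed by (parameter kind, node name) with mean, sd
    and the central 95% credible interval.
    """
    ages = posterior.pooled("ages")
    rates = posterior.pooled("rates")
    if ages.shape[0] == 0:
        raise ValueError("empty trace: nothing to summarise")
    rows = []
    for j, name in enumerate(posterior.node_names):
        if not posterior.leaf_mask[j]:
            rows.append({"kind": "age_ma", "node": name, **_summary_row(ages[:, j])})
    for j, name in enumerate(posterior.node_names):
        rows.append({"kind": "rate", "node": name, **_summary_row(rates[:, j])})
    for key in ("sigma2", "alpha"):
        rows.append({"kind": key, "node": "", **_summary_row(posterior.pooled(key))})
    return pd.DataFrame(rows).set_index(["kind", "node"])


def rates_vs_time(posterior: ClockPosterior) -> pd.DataFrame:
    """Posterior mean node age vs mean branch rate, rate converted to per Ga.

    One row per node (leaves included: their rates are the tip branch rates,
    their ages 0).  Suitable for a rate-through-time scatter.
    """
    ages = posterior.pooled("ages")
    rates = posterior.pooled("rates")
    rows = [
        {
            "node": name,
            "mean_age_ma": float(ages[:, j].mean()),
            "mean_rate_per_ga": float(rates[:, j].mean()) * 1000.0,
        }
        for j, name in enumerate(posterior.node_names)
    ]
    return pd.DataFrame(rows)
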