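"""Felsenstein pruning likelihood for the Poisson+discrete-gamma model.

The engine computes the log-likelihood of an aligned amino-acid matrix on a
dated, rated tree, summing per site over equal-weight discrete-gamma rate
categories.  Site patterns are compressed (identical columns share one
computation), gaps and 'X' enter as missing data (all-ones conditional
vectors), and conditional likelihoods are rescaled per pattern and category
to avoid underflow.

Because the Poisson model's transition matrix has only two distinct entries,
the matrix-vector product in the pruning recursion reduces to

    P @ v = p_diff * sum(v) + (p_same - p_diff) * v

which the compiled kernel exploits throughout; the explicit 20x20 matrices
from :mod:`paleoclock.substitution` serve as an independent reference.

For MCMC use, a proposal that changes one node's age or rate only dirties
the conditional likelihoods on the path from that node to the root; the
engine recomputes exactly that path in one kernel call and can restore the
previous state on rejection.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .substitution import MISSING_CODE, N_STATES, encode_sequence
from .timetree import TimeTree

__all__ = ["PruningEngine", "log_likelihood", "branch_length"]


def branch_length(
    parent_age: float, child_age: float, parent_rate: float, child_rate: float
) -> float:
    """Expected substitutions/site on a branch under endpoint-mean rates."""
    if parent_age < child_age:
        raise ValueError("parent must be older than child")
    if parent_rate <= 0 or child_rate <= 0:
        raise ValueError("rates must be positive")
    return (parent_age - child_age) * (parent_rate + child_rate) / 2.0


@njit(cache=True)
def _update_and_loglik(
    partial, scalelog, child1, child2, blen, cat_rates, nodes, root, weights
):
    """Recompute conditional likelihoods for ``nodes`` (postorder) and return
    the root log-likelihood.

    ``partial`` is (n_nodes, npat, ncat, 20); leaf slots hold fixed one-hot
    (or all-ones) vectors with zero scalelog.
    """
    n_nodes, npat, ncat, K = partial.shape
    kk = K / (K - 1.0)
    for idx in range(nodes.size):
        node = nodes[idx]
        c1 = child1[node]
        c2 = child2[node]
        for c in range(ncat):
            ps1 = 1.0 / K + (K - 1.0) / K * np.exp(-kk * blen[c1] * cat_rates[c])
            pd1 = (1.0 - ps1) / (K - 1.0)
            ps2 = 1.0 / K + (K - 1.0) / K * np.exp(-kk * blen[c2] * cat_rates[c])
            pd2 = (1.0 - ps2) / (K - 1.0)
            for p in range(npat):
                s1 = 0.0
                s2 = 0.0
                for k in range(K):
                    s1 += partial[c1, p, c, k]
                    s2 += partial[c2, p, c, k]
                mx = 0.0
                for k in range(K):
                    m1 = pd1 * s1 + (ps1 - pd1) * partial[c1, p, c, k]
                    m2 = pd2 * s2 + (ps2 - pd2) * partial[c2, p, c, k]
                    val = m1 * m2
                    partial[node, p, c, k] = val
                    if val > mx:
                        mx = val
                base = scalelog[c1, p, c] + scalelog[c2, p, c]
                if mx > 0.0:
                    inv = 1.0 / mx
                    for k in range(K):
                        partial[node, p, c, k] *= inv
                    scalelog[node, p, c] = base + np.log(mx)
                else:
                    scalelog[node, p, c] = -np.inf

    total = 0.0
    logs = np.empty(ncat)
    for p in range(npat):
        mx = -np.inf
        for c in range(ncat):
            s = 0.0
            for k in range(K):
                s += partial[root, p, c, k]
            if s > 0.0 and np.isfinite(scalelog[root, p, c]):
                logs[c] = np.log(s / K) + scalelog[root, p, c]
            else:
                logs[c] = -np.inf
            if logs[c] > mx:
                mx = logs[c]
        if not np.isfinite(mx):
            return -np.inf
        acc = 0.0
        for c in range(ncat):
            acc += np.exp(logs[c] - mx)
        total += weights[p] * (mx + np.log(acc) - np.log(ncat))
    return total


class PruningEngine:
    def __init__(self, alignment: dict[str, str], tree: TimeTree, n_categories: int = 4):
        if not alignment:
            raise ValueError("empty alignment")
        self.parent = tree.parent
        self.children = [list(c) for c in tree.children]
        self.postorder = tree.postorder()
        self.root = tree.root
        self.n_nodes = tree.n_nodes
        self.ncat = n_categories
        self.is_leaf = np.array([not c for c in self.children])
        if any(len(c) not in (0, 2) for c in self.children):
            raise ValueError("pruning engine requires a strictly binary tree")
        self.child1 = np.array(
            [c[0] if c else -1 for c in self.children], dtype=np.int64
        )
        self.child2 = np.array(
            [c[1] if c else -1 for c in self.children], dtype=np.int64
        )
        self._internal_postorder = np.array(
            [n for n in self.postorder if not self.is_leaf[n]], dtype=np.int64
        )

        leaf_nodes = [i for i in range(self.n_nodes) if self.is_leaf[i]]
        labels = tree.labels
        missing = [labels[i] for i in leaf_nodes if labels[i] not in alignment]
        if missing:
            raise ValueError(f"alignment lacks sequences for leaves: {missing}")
        codes = np.stack([encode_sequence(alignment[labels[i]]) for i in leaf_nodes])
        patterns, inverse, counts = np.unique(
            codes, axis=1, return_inverse=True, return_counts=True
        )
        self.pattern_weights = counts.astype(float)
        self.n_sites = codes.shape[1]
        self.site_to_pattern = inverse
        npat = patterns.shape[1]
        self.npat = npat

        # Conditional-likelihood storage; leaf slots hold the one-hot (or
        # all-ones, for missing data) vectors replicated across categories.
        self.partial = np.zeros((self.n_nodes, npat, n_categories, N_STATES))
        self.scalelog = np.zeros((self.n_nodes, npat, n_categories))
        for row, node in enumerate(leaf_nodes):
            L = np.zeros((npat, N_STATES))
            obs = patterns[row] != MISSING_CODE
            L[np.arange(npat)[obs], patterns[row][obs]] = 1.0
            L[~obs, :] = 1.0
            self.partial[node] = L[:, None, :]

        self.blen = np.zeros(self.n_nodes)
        self.cat_rates = np.ones(n_categories)
        self.loglik = -np.inf
        self._backup: dict | None = None

        # postorder position, for sorting dirty sets
        self._pos = np.empty(self.n_nodes, dtype=int)
        self._pos[self.postorder] = np.arange(self.n_nodes)

    # ------------------------------------------------------------- public API
    def set_state(self, blen: np.ndarray, cat_rates: np.ndarray) -> float:
        """Full recomputation; establishes the accepted state."""
        self.blen = np.asarray(blen, dtype=float).copy()
        self.cat_rates = np.asarray(cat_rates, dtype=float).copy()
        self.loglik = float(
            _update_and_loglik(
                self.partial, self.scalelog, self.child1, self.child2,
                self.blen, self.cat_rates, self._internal_postorder,
                self.root, self.pattern_weights,
            )
        )
        self._backup = None
        return self.loglik

    def _affected(self, dirty_nodes) -> np.ndarray:
        touched = set()
        for d in dirty_nodes:
            start = d if not self.is_leaf[d] else self.parent[d]
            node = int(start)
            while node >= 0 and node not in touched:
                touched.add(node)
                node = int(self.parent[node])
        return np.array(sorted(touched, key=lambda i: self._pos[i]), dtype=np.int64)

    def propose(self, blen: np.ndarray, cat_rates: np.ndarray, dirty_nodes=None) -> float:
        """Evaluate the likelihood of a proposed state, keeping a restore point.

        ``dirty_nodes`` lists nodes whose age or rate changed; ``None`` means
        recompute everything (e.g. after a gamma-shape move).
        """
        if self._backup is not None:
            raise RuntimeError("pending proposal: call accept() or reject() first")
        if dirty_nodes is None:
            recompute = self._internal_postorder
        else:
            recompute = self._affected(dirty_nodes)
        self._backup = {
            "nodes": recompute,
            "partial": self.partial[recompute].copy(),
            "scalelog": self.scalelog[recompute].copy(),
            "blen": self.blen,
            "cat_rates": self.cat_rates,
            "loglik": self.loglik,
        }
        self.blen = np.asarray(blen, dtype=float).copy()
        self.cat_rates = np.asarray(cat_rates, dtype=float).copy()
        self.loglik = float(
            _update_and_loglik(
                self.partial, self.scalelog, self.child1, self.child2,
                self.blen, self.cat_rates, recompute, self.root,
                self.pattern_weights,
            )
        )
        return self.loglik

    def accept(self) -> None:
        self._backup = None

    def reject(self) -> None:
        if self._backup is None:
            raise RuntimeError("no pending proposal to reject")
        b = self._backup
        self.partial[b["nodes"]] = b["partial"]
        self.scalelog[b["nodes"]] = b["scalelog"]
        self.blen = b["blen"]
        self.cat_rates = b["cat_rates"]
        self.loglik = b["loglik"]
        self._backup = None


def branch_lengths_from_tree(tree: TimeTree) -> np.ndarray:
    """Expected substitutions/site on the branch above each node.

    Uses the trapezoidal (endpoint-mean) rate convention:
    duration * (parent_rate + child_rate) / 2.
    """
    if tree.ages is None or tree.rates is None:
        raise ValueError("tree needs both ages and rates")
    dur = tree.branch_durations()
    if np.any(dur < 0):
        raise ValueError("parent younger than child: invalid chronogram")
    blen = np.zeros(tree.n_nodes)
    has_parent = tree.parent >= 0
    mean_rate = np.zeros(tree.n_nodes)
    mean_rate[has_parent] = (tree.rates[tree.parent[has_parent]] + tree.rates[has_parent]) / 2.0
    blen[has_parent] = dur[has_parent] * mean_rate[has_parent]
    return blen


def log_likelihood(
    alignment: dict[str, str],
    tree: TimeTree,
    gamma_shape: float = 1.0,
    n_categories: int = 4,
) -> float:
    """One-shot pruning log-likelihood of an alignment on a dated, rated tree."""
    from .substitution import discrete_gamma_rates

    engine = PruningEngine(alignment, tree, n_categories=n_categories)
    blen = branch_lengths_from_tree(tree)
    return engine.set_state(blen, discrete_gamma_rates(gamma_shape, n_categories))
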