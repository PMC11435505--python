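"""Polytomous latent class analysis for the network's latent nodes.

Each latent node (CYTOX, CYSTEINE, HCLAT, BIOAV, INSILICO) summarises a group
of correlated categorical indicators.  The indicators are modelled as a finite
mixture: a compound belongs to one of ``n_classes`` latent classes with
probability ``class_weights[k]``, and given the class its indicators are
independent with per-level item-response probabilities.  Missing indicator
entries contribute nothing to the likelihood (missing at random).

The log-likelihood surface is multimodal, so the EM fit is restarted
``n_rep`` times from independent seeded initialisations and the restart with
the highest converged log-likelihood is kept.  Restart ``r`` is seeded with
``seed + r``, making best-of-n likelihoods non-decreasing in ``n_rep`` for a
fixed base seed.

EM details: class weights start uniform and item-response rows are drawn from
a flat Dirichlet; convergence is declared when the log-likelihood gain drops
below 1e-8 or after 1000 iterations; a ridge of 1e-6 is added to each
item-response estimate in the M-step to avoid zero-probability lock-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

RIDGE = 1e-6
TOL = 1e-8
MAX_ITER = 1000


@dataclass
class LatentSpec:
    node_name: str
    member_variables: list[str]
    n_classes: int
    n_rep: int = 20

    def __post_init__(self):
        if not self.member_variables:
            raise ValueError(f"{self.node_name}: member_variables must be non-empty")
        if self.n_classes < 1:
            raise ValueError(f"{self.node_name}: n_classes must be >= 1")


@dataclass
class LCAModel:
    """Fitted latent-class mixture for one latent node."""

    node_name: str
    member_variables: list[str]
    n_levels: list[int]                       # levels per member variable
    class_weights: np.ndarray                 # (K,)
    item_response: list[np.ndarray]           # per variable: (K, n_levels[v])
    log_likelihood: float
    n_restarts_used: int
    seed: int
    ll_history: list[float] = field(default_factory=list, repr=False)

    @property
    def n_classes(self) -> int:
        return len(self.class_weights)

    def to_json(self) -> dict:
        return {
            "node_name": self.node_name,
            "member_variables": list(self.member_variables),
            "n_levels": [int(x) for x in self.n_levels],
            "class_weights": self.class_weights.tolist(),
            "item_response": [t.tolist() for t in self.item_response],
            "log_likelihood": float(self.log_likelihood),
            "n_restarts_used": int(self.n_restarts_used),
            "seed": int(self.seed),
        }

    @classmethod
    def from_json(cls, d: dict) -> "LCAModel":
        return cls(
            node_name=d["node_name"],
            member_variables=list(d["member_variables"]),
            n_levels=[int(x) for x in d["n_levels"]],
            class_weights=np.asarray(d["class_weights"], dtype=float),
            item_response=[np.asarray(t, dtype=float) for t in d["item_response"]],
            log_likelihood=float(d["log_likelihood"]),
            n_restarts_used=int(d["n_restarts_used"]),
            seed=int(d["seed"]),
        )


def _coerce_matrix(rows, n_vars: int) -> np.ndarray:
    X = np.asarray(rows)
    if X.ndim != 2 or X.shape[1] != n_vars:
        raise ValueError(f"expected an (n, {n_vars}) categorical matrix")
    X = np.where(np.equal(X, None), -1, X)
    Xf = X.astype(float)
    Xf[~np.isfinite(Xf)] = -1
    return Xf.astype(np.int64)


def _em_once(X: np.ndarray, n_levels: list[int], K: int,
             rng: np.random.Generator) -> tuple[np.ndarray, list[np.ndarray], float, list[float]]:
    n, V = X.shape
    w = np.full(K, 1.0 / K)
    theta = [rng.dirichlet(np.ones(L), size=K) for L in n_levels]
    observed = [X[:, v] >= 0 for v in range(V)]
    history: list[float] = []
    ll_prev = -np.inf
    for _ in range(MAX_ITER):
        # E-step: log responsibilities
        logp = np.tile(np.log(w), (n, 1))                      # (n, K)
        for v in range(V):
            obs = observed[v]
            logp[obs] += np.log(theta[v][:, X[obs, v]]).T
        ll = float(logsumexp(logp, axis=1).sum())
        history.append(ll)
        resp = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))  # (n, K)
        # M-step
        w = resp.mean(axis=0)
        w /= w.sum()
        for v in range(V):
            obs = observed[v]
            counts = np.zeros((K, n_levels[v]))
            np.add.at(counts.T, X[obs, v], resp[obs])
            counts += RIDGE
            theta[v] = counts / counts.sum(axis=1, keepdims=True)
        if ll - ll_prev < TOL and np.isfinite(ll_prev):
            break
        ll_prev = ll
    return w, theta, history[-1], history


def lca_fit(rows, spec: LatentSpec, seed: int,
            n_levels: Optional[Sequence[int]] = None) -> LCAModel:
    """Fit an LCA model with multi-restart EM; returns the best restart.

    ``rows`` is an (n, V) integer matrix of category indices with missing
    entries as -1 (or None/NaN).  ``n_levels`` fixes the number of levels per
    variable; by default it is inferred as max observed index + 1.
    """
    V = len(spec.member_variables)
    X = _coerce_matrix(rows, V)
    if X.shape[0] == 0:
        raise ValueError(f"{spec.node_name}: no rows to fit")
    if not (X >= 0).any(axis=1).sum() >= spec.n_classes:
        raise ValueError(
            f"{spec.node_name}: need at least n_classes={spec.n_classes} rows "
            f"with an observed member variable")
    if n_levels is None:
        n_levels = [max(int(X[:, v].max()), 0) + 1 for v in range(V)]
    n_levels = [int(L) for L in n_levels]
    for v in range(V):
        if X[:, v].max() >= n_levels[v]:
            raise ValueError(f"{spec.node_name}: level out of range in "
                             f"variable {spec.member_variables[v]!r}")

    best = None
    for r in range(spec.n_rep):
        rng = np.random.default_rng(seed + r)
        w, theta, ll, history = _em_once(X, n_levels, spec.n_classes, rng)
        if best is None or ll > best[2]:
            best = (w, theta, ll, history, r)
    w, theta, ll, history, _ = best
    return LCAModel(
        node_name=spec.node_name,
        member_variables=list(spec.member_variables),
        n_levels=n_levels,
        class_weights=w,
        item_response=theta,
        log_likelihood=ll,
        n_restarts_used=spec.n_rep,
        seed=seed,
        ll_history=history,
    )


def lca_posterior(model: LCAModel, row) -> np.ndarray:
    """Posterior over latent classes for one row (missing entries = -1/None)."""
    x = _coerce_matrix([row], len(model.member_variables))[0]
    logp = np.log(model.class_weights).copy()
    for v, xv in enumerate(x):
        if xv < 0:
            continue
        if xv >= model.n_levels[v]:
            raise ValueError(
                f"{model.node_name}: unseen level {xv} for variable "
                f"{model.member_variables[v]!r} (has {model.n_levels[v]} levels)")
        logp += np.log(model.item_response[v][:, xv])
    p = np.exp(logp - logsumexp(logp))
    return p / p.sum()


def lca_assign(model: LCAModel, row) -> tuple[int, np.ndarray]:
    """Modal latent class (ties -> lowest index) and its posterior vector."""
    post = lca_posterior(model, row)
    return int(np.argmax(post)), post


def lca_assign_matrix(model: LCAModel, rows) -> np.ndarray:
    """Modal class per row of a categorical matrix."""
    X = _coerce_matrix(rows, len(model.member_variables))
    return np.array([lca_assign(model, x)[0] for x in X], dtype=np.int64)
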