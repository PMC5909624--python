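"""Kendall-τ rank concordance and its spatial decomposition on networks.

Two per-segment value vectors from different periods are compared pair by
pair: a pair (i, j) is concordant when its rank order is preserved between
the periods, discordant when reversed.  With
concordance(i, j) = sgn(v_i(t1) − v_j(t1)) · sgn(v_i(t2) − v_j(t2)):

* τ = (C − D) / (n(n−1)/2) — the classical Kendall coefficient;
* τ′ = (C − D) / √((C+D+E_t1)(C+D+E_t2)) — tie-adjusted, where E_t1 counts
  pairs tied only in period 2 and E_t2 pairs tied only in period 1 (pairs
  tied in both periods enter no count);
* under a binary weight matrix W the pairs split into neighbors and
  non-neighbors, giving the exact decomposition
  τ = ψ·τ_w + (1−ψ)·τ_w̄ with ψ the share of neighbor pairs.  τ_w — the
  concordance of neighboring segments only — acts as a global indicator of
  (spatially local) rank stability between the periods (GIMA);
* three local indicators (LIMA): τ_i (focal vs all), τ̃_i (focal vs its
  neighbors), τ̃̃_i (all pairs within the focal neighborhood set
  NS_i = neighbors of i plus i).

Local inference holds the focal segment's value pair fixed and jointly
permutes the remaining pairs across the other segments; global τ_w
inference permutes segment locations wholesale while holding W fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, InvalidInputError
from .network import NetworkWeightMatrix

__all__ = [
    "ConcordanceStats",
    "GimaResult",
    "concordance_matrix",
    "kendall_tau",
    "kendall_tau_ties",
    "decompose",
    "lima_local",
    "lima_neighbor",
    "lima_neighborhood",
    "lima_permutation",
    "gima",
    "gima_matrix",
]


def _check_pair(v1, v2) -> tuple[np.ndarray, np.ndarray]:
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise InvalidInputError("value vectors must be 1-d and equally long")
    if len(v1) < 2:
        raise InvalidInputError("need at least two observations")
    return v1, v2


def _as_w(W) -> np.ndarray:
    if isinstance(W, NetworkWeightMatrix):
        return W.w.astype(float)
    w = np.asarray(W, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise InvalidInputError("weight matrix must be square")
    return w


def concordance_matrix(v1, v2) -> np.ndarray:
    """Symmetric matrix of sgn(v1_i−v1_j)·sgn(v2_i−v2_j), zero diagonal."""
    v1, v2 = _check_pair(v1, v2)
    s1 = np.sign(v1[:, None] - v1[None, :])
    s2 = np.sign(v2[:, None] - v2[None, :])
    return s1 * s2


@dataclass
class ConcordanceStats:
    tau: float
    tau_prime: float | None
    C: int
    D: int
    E_t1: int
    E_t2: int
    n: int


def _pair_counts(v1: np.ndarray, v2: np.ndarray) -> tuple[int, int, int, int]:
    iu = np.triu_indices(len(v1), k=1)
    s1 = np.sign(v1[:, None] - v1[None, :])[iu]
    s2 = np.sign(v2[:, None] - v2[None, :])[iu]
    c = int(np.sum(s1 * s2 == 1))
    d = int(np.sum(s1 * s2 == -1))
    e_t1 = int(np.sum((s1 != 0) & (s2 == 0)))   # tied only in period 2
    e_t2 = int(np.sum((s1 == 0) & (s2 != 0)))   # tied only in period 1
    return c, d, e_t1, e_t2


def kendall_tau(v1, v2) -> ConcordanceStats:
    """Kendall's τ by exhaustive pair enumeration, with pair counts."""
    v1, v2 = _check_pair(v1, v2)
    n = len(v1)
    c, d, e1, e2 = _pair_counts(v1, v2)
    tau = (c - d) / (n * (n - 1) / 2)
    denom = (c + d + e1) * (c + d + e2)
    tp = (c - d) / np.sqrt(denom) if denom > 0 else None
    return ConcordanceStats(tau=float(tau), tau_prime=tp, C=c, D=d,
                            E_t1=e1, E_t2=e2, n=n)


def kendall_tau_ties(v1, v2) -> float:
    """Tie-adjusted τ′; raises when every pair is tied in some period."""
    stats = kendall_tau(v1, v2)
    if stats.tau_prime is None:
        raise DegenerateInputError(
            "all pairs tied: tie-adjusted tau denominator is zero")
    return float(stats.tau_prime)


def decompose(v1, v2, W) -> tuple[float, float, float]:
    """(ψ, τ_w, τ_w̄): split of τ into neighbor and non-neighbor pair
    concordance.  τ_w̄ is NaN when W is complete (no non-neighbor pairs)."""
    v1, v2 = _check_pair(v1, v2)
    w = _as_w(W)
    n = len(v1)
    if w.shape != (n, n):
        raise InvalidInputError("weight matrix does not match vectors")
    conc = concordance_matrix(v1, v2)
    sw = w.sum()
    if sw == 0:
        raise DegenerateInputError("weight matrix has no neighbor pairs; "
                                   "tau_w is undefined")
    tau_w = float((w * conc).sum() / sw)
    wbar = np.ones_like(w) - w - np.eye(n)
    swb = wbar.sum()
    tau_wbar = float((wbar * conc).sum() / swb) if swb > 0 else float("nan")
    psi = float(sw / (n * (n - 1)))
    return psi, tau_w, tau_wbar


def lima_local(v1, v2) -> np.ndarray:
    """Local concordance τ_i = Σ_{j≠i} concordance(i, j) / (n−1)."""
    v1, v2 = _check_pair(v1, v2)
    conc = concordance_matrix(v1, v2)
    return conc.sum(axis=1) / (len(v1) - 1)


def lima_neighbor(v1, v2, W) -> np.ndarray:
    """Neighbor-set LIMA τ̃_i = Σ_j w_ij concordance(i,j) / Σ_j w_ij;
    isolated segments get NaN."""
    v1, v2 = _check_pair(v1, v2)
    w = _as_w(W)
    conc = concordance_matrix(v1, v2)
    card = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (w * conc).sum(axis=1) / card
    out[card == 0] = np.nan
    return out


def lima_neighborhood(v1, v2, W) -> np.ndarray:
    """Neighborhood-set LIMA τ̃̃_i over all ordered pairs m ≠ n inside
    NS_i = {i} ∪ neighbors(i), divided by |NS_i|(|NS_i|−1); undefined
    (NaN) when |NS_i| < 2."""
    v1, v2 = _check_pair(v1, v2)
    w = _as_w(W)
    conc = concordance_matrix(v1, v2)
    n = len(v1)
    out = np.full(n, np.nan)
    for i in range(n):
        ns = np.flatnonzero(w[i])
        ns = np.append(ns, i)
        m = len(ns)
        if m < 2:
            continue
        sub = conc[np.ix_(ns, ns)]
        out[i] = sub.sum() / (m * (m - 1))   # ordered pairs; diagonal is 0
    return out


def lima_permutation(v1, v2, W, statistic: str = "neighbor",
                     n_perm: int = 999, seed: int | None = None,
                     alternative: str = "directional") -> np.ndarray:
    """Conditional-permutation pseudo p-values for a LIMA statistic.

    The focal segment keeps its (v_t1, v_t2) pair; the remaining pairs are
    jointly permuted over the other segments.  The default p-value takes
    the tail on the side of the observed deviation from the permutation
    mean (the usual LISA-style convention; liberal under the null because
    the tail is picked after seeing the statistic);
    ``alternative="two-sided"`` doubles the smaller tail and is calibrated.
    Segments where the statistic is undefined get NaN.
    """
    if statistic not in ("neighbor", "neighborhood"):
        raise InvalidInputError(f"unknown LIMA statistic: {statistic}")
    if alternative not in ("directional", "two-sided"):
        raise InvalidInputError(f"unknown alternative: {alternative}")
    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    v1, v2 = _check_pair(v1, v2)
    w = _as_w(W)
    n = len(v1)
    conc = concordance_matrix(v1, v2)
    rng = np.random.default_rng(seed)
    obs = (lima_neighbor(v1, v2, w) if statistic == "neighbor"
           else lima_neighborhood(v1, v2, w))
    p = np.full(n, np.nan)
    idx_all = np.arange(n)
    for i in range(n):
        if not np.isfinite(obs[i]):
            continue
        nbrs = np.flatnonzero(w[i])
        k = len(nbrs)
        others = idx_all[idx_all != i]
        conc_i = conc[i, others]             # focal-vs-other concordances
        sims = np.empty(n_perm)
        for s in range(n_perm):
            pick = rng.choice(n - 1, size=k, replace=False)
            if statistic == "neighbor":
                sims[s] = conc_i[pick].mean()
            else:
                members = others[pick]
                sub = conc[np.ix_(members, members)].sum()
                m = k + 1
                sims[s] = (2.0 * conc_i[pick].sum() + sub) / (m * (m - 1))
        greater = int(np.sum(sims >= obs[i]))
        less = int(np.sum(sims <= obs[i]))
        p_up = (1 + greater) / (1 + n_perm)
        p_lo = (1 + less) / (1 + n_perm)
        if alternative == "two-sided":
            p[i] = min(1.0, 2.0 * min(p_up, p_lo))
        else:
            p[i] = p_up if obs[i] >= sims.mean() else p_lo
    return p


@dataclass
class GimaResult:
    """Global concordance report for one period pair."""

    tau: float
    tau_prime: float | None
    psi: float
    tau_w: float
    tau_wbar: float
    p: float | None
    n_perm: int | None
    seed: int | None


def gima(v1, v2, W, n_perm: int | None = 999,
         seed: int | None = None) -> GimaResult:
    """τ, τ′, ψ, τ_w, τ_w̄ plus a whole-map permutation p-value for τ_w.

    Significance permutes the segment locations jointly in both periods
    (W held fixed), two-sided around the permutation mean.
    """
    v1, v2 = _check_pair(v1, v2)
    w = _as_w(W)
    stats = kendall_tau(v1, v2)
    psi, tau_w, tau_wbar = decompose(v1, v2, w)
    p = None
    if n_perm:
        rng = np.random.default_rng(seed)
        conc = concordance_matrix(v1, v2)
        sw = w.sum()
        sims = np.empty(n_perm)
        n = len(v1)
        for s in range(n_perm):
            perm = rng.permutation(n)
            sims[s] = (w * conc[np.ix_(perm, perm)]).sum() / sw
        greater = int(np.sum(sims >= tau_w))
        less = int(np.sum(sims <= tau_w))
        p_up = (1 + greater) / (1 + n_perm)
        p_lo = (1 + less) / (1 + n_perm)
        p = min(1.0, 2.0 * min(p_up, p_lo))
    return GimaResult(tau=stats.tau, tau_prime=stats.tau_prime, psi=psi,
                      tau_w=tau_w, tau_wbar=tau_wbar, p=p,
                      n_perm=n_perm, seed=seed)


def gima_matrix(values: list[np.ndarray], W, labels: list[str] | None = None,
                n_perm: int | None = None,
                seed: int | None = None) -> pd.DataFrame:
    """Symmetric k×k matrix of τ_w between every pair of k period vectors
    (the period-pair concordance table); diagonal is NaN.

    With ``n_perm`` set, a companion column layout is not produced — use
    :func:`gima` per pair for p-values.
    """
    k = len(values)
    if labels is None:
        labels = [f"period_{i}" for i in range(k)]
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            _, tau_w, _ = decompose(values[i], values[j], W)
            out[i, j] = out[j, i] = tau_w
    return pd.DataFrame(out, index=labels, columns=labels)
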