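"""Three-state discretization, discrete mutual information, and mRMR ranking.

The ranking criterion is the difference ("MID") form of minimal-Redundancy
Maximal-Relevance: at each greedy step the candidate g maximizing

    I(g, l) - (1/m) * sum_{g_i in selected} I(g, g_i)

is moved from the candidate pool to the selected list, where I is discrete
mutual information (bits by default) computed on beta values discretized per
site into {-1, 0, +1} at mean +/- t * sd (sample sd, ddof=1).  The objective
value at the moment of selection is recorded as the site's mRMR score; the
first score is therefore exactly the site's relevance.

Relevance values are computed once; redundancy accumulates incrementally
(each newly selected site contributes one MI term against every remaining
candidate), so ranking N sites from a pool of n costs O(N * n) MI
evaluations rather than all pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import BetaMatrix, ClassLabels

#: discretization width in sample standard deviations
DEFAULT_T = 1.0
#: mutual-information log base (2 -> bits)
DEFAULT_BASE = 2.0


@dataclass(frozen=True)
class DiscretizedMatrix:
    """Per-site three-state representation of a beta matrix."""

    probe_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    states: np.ndarray

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.int8)
        object.__setattr__(self, "states", states)
        if states.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError("states shape does not match identifiers")
        if states.size and not np.isin(states, (-1, 0, 1)).all():
            raise ValueError("states must be drawn from {-1, 0, +1}")


@dataclass(frozen=True)
class MRMRRanking:
    """Ordered (probe_id, score) pairs; score = objective value at selection."""

    entries: tuple[tuple[str, float], ...]
    pool_size: int = 0

    def __post_init__(self) -> None:
        probes = [p for p, _ in self.entries]
        if len(set(probes)) != len(probes):
            raise ValueError("ranking contains a repeated probe")
        if not self.pool_size:
            object.__setattr__(self, "pool_size", len(self.entries))

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def probe_ids(self) -> tuple[str, ...]:
        return tuple(p for p, _ in self.entries)

    def top(self, r: int) -> tuple[tuple[str, float], ...]:
        if r > len(self.entries):
            raise ValueError(f"requested top {r} of a {len(self.entries)}-site ranking")
        return self.entries[:r]


def discretize(matrix: BetaMatrix, t: float = DEFAULT_T) -> DiscretizedMatrix:
    """Map each site to {-1, 0, +1} at mean +/- t * sd (ddof=1).

    A zero-variance site maps to all zeros (its thresholds collapse onto the
    mean and no value can exceed them strictly).
    """
    if t <= 0:
        raise ValueError("t must be positive")
    v = matrix.values
    m = v.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        s = v.std(axis=1, ddof=1, keepdims=True) if v.shape[1] > 1 else np.zeros_like(m)
    states = np.zeros(v.shape, dtype=np.int8)
    states[v > m + t * s] = 1
    states[v < m - t * s] = -1
    return DiscretizedMatrix(matrix.probe_ids, matrix.sample_ids, states)


def _codes(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Factorize a vector to consecutive integer codes."""
    _, inv = np.unique(np.asarray(x), return_inverse=True)
    return inv.astype(np.int64), int(inv.max()) + 1 if inv.size else 0


def mutual_information(a, b, base: float = DEFAULT_BASE) -> float:
    """Empirical mutual information between two categorical vectors.

    Probabilities are plain frequencies of the observed joint table; cells
    with zero count contribute nothing.  Symmetric and non-negative up to
    rounding.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length vectors")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    ia, ka = _codes(a)
    ib, kb = _codes(b)
    joint = np.bincount(ia * kb + ib, minlength=ka * kb).reshape(ka, kb)
    return _mi_from_joint(joint.astype(float), base)


def _mi_from_joint(joint: np.ndarray, base: float) -> float:
    n = joint.sum()
    pj = joint / n
    pa = pj.sum(axis=1, keepdims=True)
    pb = pj.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pj * np.log(pj / (pa * pb))
    mi = float(np.nansum(terms)) / math.log(base)
    return mi


def relevance(site_states, labels, base: float = DEFAULT_BASE) -> float:
    """MI between one site's states and the class labels.

    ``labels`` may be a ClassLabels (matched by position is not possible
    then, so a plain per-sample label sequence is also accepted).
    """
    site_states = np.asarray(site_states)
    if isinstance(labels, ClassLabels):
        raise TypeError(
            "pass the per-sample label sequence (labels.for_samples(sample_ids))"
        )
    labels = np.asarray(labels)
    if labels.shape != site_states.shape:
        raise ValueError("site states and labels must cover the same samples")
    return mutual_information(site_states, labels, base=base)


def redundancy(site_states, selected, base: float = DEFAULT_BASE) -> float:
    """Mean MI between a site and each already-selected site; 0 when empty.

    The empty-selection convention makes the mRMR objective reduce to pure
    relevance at the first step.
    """
    selected = list(selected)
    if not selected:
        return 0.0
    site_states = np.asarray(site_states)
    total = 0.0
    for g in selected:
        g = np.asarray(g)
        if g.shape != site_states.shape:
            raise ValueError("selected site has mismatched sample length")
        total += mutual_information(site_states, g, base=base)
    return total / len(selected)


def _mi_one_vs_many(sel: np.ndarray, others: np.ndarray, base: float) -> np.ndarray:
    """MI of one three-state vector against each row of a three-state matrix."""
    n_rows, n = others.shape
    a = (sel + 1).astype(np.int64)          # 0..2
    b = (others + 1).astype(np.int64)       # rows of 0..2
    codes = b * 3 + a[None, :]              # 0..8 per cell
    flat = (np.arange(n_rows)[:, None] * 9 + codes).ravel()
    joint = np.bincount(flat, minlength=n_rows * 9).reshape(n_rows, 3, 3).astype(float)
    pj = joint / n
    pa = pj.sum(axis=2, keepdims=True)
    pb = pj.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pj * np.log(pj / (pa * pb))
    return np.nansum(terms, axis=(1, 2)) / math.log(base)


def mrmr_rank(
    dmatrix: DiscretizedMatrix,
    labels: ClassLabels,
    n_select: int,
    base: float = DEFAULT_BASE,
) -> MRMRRanking:
    """Greedy mRMR (difference form) ranking of the top ``n_select`` sites.

    Ties in the objective are broken toward the lexicographically smallest
    probe ID, which makes the ranking deterministic and independent of input
    row order.
    """
    n_sites = len(dmatrix.probe_ids)
    if n_select > n_sites:
        raise ValueError(f"cannot select {n_select} of {n_sites} sites")
    if n_select == 0:
        return MRMRRanking(entries=(), pool_size=n_sites)

    y = labels.encode(dmatrix.sample_ids)
    states = dmatrix.states.astype(np.int8)
    rel = np.array(
        [mutual_information(states[i], y, base=base) for i in range(n_sites)]
    )

    probe_arr = np.array(dmatrix.probe_ids)
    remaining = np.ones(n_sites, dtype=bool)
    red_sum = np.zeros(n_sites, dtype=float)
    entries: list[tuple[str, float]] = []

    for step in range(n_select):
        m = step
        objective = rel - (red_sum / m if m else 0.0)
        cand = np.where(remaining)[0]
        vals = objective[cand]
        best_val = vals.max()
        tied = cand[vals == best_val]
        pick = tied[np.argmin(probe_arr[tied])] if tied.size > 1 else tied[0]
        entries.append((str(probe_arr[pick]), float(objective[pick])))
        remaining[pick] = False
        if step + 1 < n_select:
            idx = np.where(remaining)[0]
            red_sum[idx] += _mi_one_vs_many(states[pick], states[idx], base)

    return MRMRRanking(entries=tuple(entries), pool_size=n_sites)
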