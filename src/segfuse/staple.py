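"""Binary STAPLE: Simultaneous Truth and Performance Level Estimation.

Expectation-maximization over N binary raters voting on M pixels. The hidden
truth is a per-pixel foreground probability W; each rater j is characterized
by a sensitivity p_j (probability of marking a true foreground pixel) and a
specificity q_j (probability of leaving a true background pixel unmarked).

* init: reference = per-pixel majority vote; W is its 0/1 indicator.
* M-step:  p_j = sum_i W_i D_ij / sum_i W_i,
           q_j = sum_i (1 - W_i)(1 - D_ij) / sum_i (1 - W_i).
* E-step:  W_i = a_i / (a_i + b_i) with
           a_i = pi * prod_j p_j^D_ij (1 - p_j)^(1 - D_ij),
           b_i = (1 - pi) * prod_j q_j^(1 - D_ij) (1 - q_j)^D_ij,
  computed in log space. The prevalence prior pi is held fixed.

Iteration stops when the largest change in W drops below ``tol``, when the
thresholded reference stops changing between iterations, or at ``max_iter``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateVoteError

_EPS = 1e-7


@dataclass(frozen=True)
class RaterPerformance:
    """Estimated per-rater accuracy and the fixed prevalence prior."""

    sensitivity: np.ndarray  # p_j in [0, 1], one per rater
    specificity: np.ndarray  # q_j in [0, 1], one per rater
    prevalence: float


@dataclass(frozen=True)
class StapleResult:
    weights: np.ndarray  # posterior foreground probability per pixel
    performance: RaterPerformance
    iterations: int
    converged: bool


def staple_em(
    votes: np.ndarray,
    prior: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    threshold: float = 0.5,
) -> StapleResult:
    """Run binary STAPLE on a stack of votes.

    Parameters
    ----------
    votes : (N, ...) boolean array
        One binary mask per rater; trailing dimensions are flattened.
    prior : float, optional
        Prevalence pi; defaults to the mean foreground fraction of the votes.
    """
    d = np.asarray(votes, dtype=float)
    n_raters = d.shape[0]
    d = d.reshape(n_raters, -1)
    if n_raters < 2:
        raise DegenerateVoteError("STAPLE needs at least 2 raters")
    pi = float(d.mean()) if prior is None else float(prior)
    if not 0.0 < pi < 1.0:
        raise DegenerateVoteError(f"prevalence prior must be in (0, 1), got {pi}")

    w = (d.mean(axis=0) >= 0.5).astype(float)  # majority-vote init
    if w.all() or not w.any():
        raise DegenerateVoteError(
            "majority vote is all-foreground or all-background; cannot seed EM"
        )
    ref = w >= threshold
    log_pi, log_1mpi = np.log(pi), np.log1p(-pi)

    p = q = np.full(n_raters, np.nan)
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        # M-step
        w_sum = w.sum()
        bg_sum = len(w) - w_sum
        p = np.clip((d @ w) / w_sum, _EPS, 1 - _EPS)
        q = np.clip(((1 - d) @ (1 - w)) / bg_sum, _EPS, 1 - _EPS)
        # E-step (log space)
        log_a = log_pi + np.log(p) @ d + np.log1p(-p) @ (1 - d)
        log_b = log_1mpi + np.log(q) @ (1 - d) + np.log1p(-q) @ d
        w_new = 1.0 / (1.0 + np.exp(np.clip(log_b - log_a, -700, 700)))
        ref_new = w_new >= threshold
        delta = float(np.abs(w_new - w).max())
        w = w_new
        if delta < tol or (ref_new == ref).all():
            ref = ref_new
            converged = True
            break
        ref = ref_new
    if not converged:
        warnings.warn(
            f"STAPLE did not converge within {max_iter} iterations "
            f"(last max |dW| = {delta:.2e})",
            stacklevel=2,
        )
    perf = RaterPerformance(sensitivity=p, specificity=q, prevalence=pi)
    return StapleResult(weights=w, performance=perf, iterations=iteration, converged=converged)
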