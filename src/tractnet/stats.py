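"""Max-t permutation test for two-group differences across tracking variants.

For one network measure, each subject contributes one value per tracking
algorithm. Per algorithm a pooled-variance two-sample t statistic is
computed, and the test statistic is the maximum of |t| over algorithms; its
permutation distribution (relabeling subjects across groups) sets a
significance level that controls the family-wise error over the simultaneous
per-algorithm comparisons. With C(nA+nB, nA) <= 20,000 all distinct label
assignments are enumerated (exact test); otherwise a seeded Monte-Carlo
sample of assignments is drawn. The identity assignment is always counted in
both numerator and denominator, so p > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["PermutationResult", "maxt_permutation_test"]

EXACT_LIMIT = 20_000


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a max-t permutation test."""

    t_obs: np.ndarray  # per-algorithm pooled-variance t
    max_t: float  # observed max |t|
    p_value: float
    n_perm: int  # denominator (distinct assignments or MC draws + identity)
    mode: str  # "exact" or "monte_carlo"
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "t_obs", np.asarray(self.t_obs, dtype=float))
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value must lie in (0, 1]")


def _pooled_t(
    sum_a: np.ndarray, ssq_a: np.ndarray, n_a: int,
    sum_tot: np.ndarray, ssq_tot: np.ndarray, n: int,
) -> np.ndarray:
    """Vectorized pooled-variance two-sample t from group-A sums and totals.

    Zero pooled variance yields t = 0 when the mean difference is also zero
    (all permutations tie), +/- inf otherwise.
    """
    n_b = n - n_a
    mean_a = sum_a / n_a
    mean_b = (sum_tot - sum_a) / n_b
    var_a = ssq_a - n_a * mean_a**2
    var_b = (ssq_tot - ssq_a) - n_b * mean_b**2
    sp2 = (var_a + var_b) / (n - 2)
    denom = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    zero_var = denom <= 0
    if np.any(zero_var):
        logger.info("zero pooled variance in %d cells; t set to 0 where the "
                    "mean difference also vanishes", int(np.sum(zero_var)))
        t = np.where(zero_var & (np.abs(diff) < 1e-300), 0.0, t)
        t = np.where(zero_var & (diff > 0), np.inf, t)
        t = np.where(zero_var & (diff < 0), -np.inf, t)
    return t


def maxt_permutation_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    mode: str = "auto",
    n_perm: int = 2000,
    seed=None,
) -> PermutationResult:
    """Two-sided max-t permutation test of equal group means.

    Parameters
    ----------
    group_a, group_b
        Value arrays of shape (n_subjects, n_algorithms) — one row per
        subject, one column per tracking-algorithm variant. Column counts
        must match; each group needs >= 2 subjects.
    mode
        "exact" enumerates all C(nA+nB, nA) label assignments, "monte_carlo"
        draws ``n_perm`` random assignments, "auto" (default) picks exact
        when the enumeration is <= 20,000 assignments.
    n_perm, seed
        Monte-Carlo sample size and RNG seed (unused in exact mode).

    Returns
    -------
    PermutationResult
        p = #{assignments with permuted max |t| >= observed} / denominator,
        identity assignment included in both counts.
    """
    A = np.atleast_2d(np.asarray(group_a, dtype=float))
    B = np.atleast_2d(np.asarray(group_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("both groups must have the same algorithm count")
    n_a, n_b = A.shape[0], B.shape[0]
    if min(n_a, n_b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    X = np.vstack([A, B])
    n = n_a + n_b
    n_exact = comb(n, n_a)
    if mode == "auto":
        mode = "exact" if n_exact <= EXACT_LIMIT else "monte_carlo"
    if mode not in ("exact", "monte_carlo"):
        raise ValueError("mode must be 'auto', 'exact' or 'monte_carlo'")

    sum_tot = X.sum(axis=0)
    ssq_tot = (X**2).sum(axis=0)
    t_obs = _pooled_t(A.sum(axis=0), (A**2).sum(axis=0), n_a, sum_tot, ssq_tot, n)
    max_t_obs = float(np.max(np.abs(t_obs)))

    if mode == "exact":
        masks = _assignment_masks(n, n_a)
        denom = n_exact
        seed_out = None
    else:
        rng = np.random.default_rng(seed)
        masks = np.zeros((n_perm, n), dtype=bool)
        for r in range(n_perm):
            masks[r, rng.choice(n, size=n_a, replace=False)] = True
        # include the identity assignment explicitly
        identity = np.zeros((1, n), dtype=bool)
        identity[0, :n_a] = True
        masks = np.vstack([identity, masks])
        denom = n_perm + 1
        seed_out = seed

    M = masks.astype(float)
    sum_a = M @ X
    ssq_a = M @ (X**2)
    t_perm = _pooled_t(sum_a, ssq_a, n_a, sum_tot, ssq_tot, n)
    max_t_perm = np.max(np.abs(t_perm), axis=1)
    tol = 1e-12 * max(1.0, max_t_obs if np.isfinite(max_t_obs) else 1.0)
    count = int(np.sum(max_t_perm >= max_t_obs - tol))
    return PermutationResult(
        t_obs=t_obs,
        max_t=max_t_obs,
        p_value=count / denom,
        n_perm=denom,
        mode=mode,
        seed=seed_out,
    )


def _assignment_masks(n: int, n_a: int) -> np.ndarray:
    """Boolean masks for all C(n, n_a) group-A assignments; identity first."""
    masks = np.zeros((comb(n, n_a), n), dtype=bool)
    for r, idx in enumerate(combinations(range(n), n_a)):
        masks[r, list(idx)] = True
    return masks
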