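"""Accuracy metrics: best-match mean absolute error and a random-guess
baseline.

Inferred ancestor proportions are unlabeled up to sibling swaps at every
internal node of the pedigree, so errors are scored after minimising over
all pedigree-consistent rotations (2 for parents, 8 for grandparents, 128
for great-grandparents).  Only population-A proportions are scored: with
two source populations the error for B is identical.
"""

from __future__ import annotations

import dataclasses
import functools

import numpy as np

__all__ = ["ErrorReport", "pedigree_rotations", "best_match_error",
           "mean_error", "random_guess_baseline"]


@functools.lru_cache(maxsize=None)
def pedigree_rotations(K: int) -> tuple[tuple[int, ...], ...]:
    """All index permutations of the 2**K ancestors reachable by swapping
    the two children of any internal pedigree node (2**(2**K - 1) of them)."""
    if K < 0:
        raise ValueError("K must be >= 0")

    def arrangements(depth: int, leaves: tuple[int, ...]):
        if depth == 0:
            return [leaves]
        half = len(leaves) // 2
        left = arrangements(depth - 1, leaves[:half])
        right = arrangements(depth - 1, leaves[half:])
        out = []
        for l in left:
            for r in right:
                out.append(l + r)
                out.append(r + l)
        return out

    perms = arrangements(K, tuple(range(1 << K)))
    # deterministic, duplicate-free enumeration order
    seen, ordered = set(), []
    for p in perms:
        if p not in seen:
            seen.add(p)
            ordered.append(p)
    return tuple(ordered)


def best_match_error(truth, est, K: int | None = None):
    """Minimal mean |est - truth| over pedigree rotations of the estimates.

    Returns ``(error, matching)``; ``matching[i]`` is the index of the
    estimate assigned to true ancestor ``i``.  Ties keep the first matching
    in enumeration order.
    """
    truth = np.asarray(truth, dtype=np.float64)
    est = np.asarray(est, dtype=np.float64)
    if truth.shape != est.shape or truth.ndim != 1:
        raise ValueError("truth and est must be equal-length vectors")
    n = truth.shape[0]
    if K is None:
        K = int(np.log2(n))
    if (1 << K) != n:
        raise ValueError(f"vector length {n} is not 2**K for K={K}")
    best_err, best_perm = np.inf, None
    for perm in pedigree_rotations(K):
        err = float(np.mean(np.abs(est[list(perm)] - truth)))
        if err < best_err - 1e-15:
            best_err, best_perm = err, perm
    return best_err, best_perm


def mean_error(per_individual_errors) -> float:
    """Average of per-individual best-match errors (the overall metric)."""
    errs = np.asarray(list(per_individual_errors), dtype=np.float64)
    if errs.size == 0:
        raise ValueError("no errors to average")
    return float(errs.mean())


@dataclasses.dataclass
class ErrorReport:
    K: int
    per_individual: list
    matchings: list
    mean: float

    def to_dict(self) -> dict:
        return {"K": self.K,
                "per_individual": [float(e) for e in self.per_individual],
                "matchings": [list(m) for m in self.matchings],
                "mean": float(self.mean)}


def score(truth_vectors, est_vectors, K: int) -> ErrorReport:
    """Best-match score of estimated vs true ancestor proportions for a cohort."""
    errs, matches = [], []
    for truth, est in zip(truth_vectors, est_vectors, strict=True):
        e, m = best_match_error(truth, est, K)
        errs.append(e)
        matches.append(m)
    return ErrorReport(K=K, per_individual=errs, matchings=matches,
                       mean=mean_error(errs))


def random_guess_baseline(truth_vectors, proportion_pool, K: int,
                          n_draws: int = 200,
                          seed: int | None = None) -> float:
    """Expected best-match error of guessing ancestor proportions from the
    empirical distribution of individual proportions in the population.

    ``proportion_pool`` is a 1-D sample of individual admixture proportions;
    each Monte-Carlo draw guesses 2**K values iid from it and is scored with
    :func:`best_match_error` against each truth vector.
    """
    rng = np.random.default_rng(seed)
    pool = np.asarray(proportion_pool, dtype=np.float64)
    if pool.size == 0:
        raise ValueError("empty proportion pool")
    nf = 1 << K
    errs = []
    for truth in truth_vectors:
        for _ in range(n_draws):
            guess = rng.choice(pool, size=nf, replace=True)
            errs.append(best_match_error(truth, guess, K)[0])
    return float(np.mean(errs))
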