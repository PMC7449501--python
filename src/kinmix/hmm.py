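"""Transition/emission model and forward likelihood of the pedigree HMM.

Every bit of the state transitions independently between adjacent sites, so
the full ``N x N`` transition matrix is a Kronecker product of 2x2 per-bit
matrices.  :func:`forward_step_dc` exploits this with a divide-and-conquer
bipartition (peel the top unpeeled bit, recurse on the two halves), bringing
one forward step from ``O(N^2)`` down to ``O(N log N)`` multiply-adds.

Per-site rescaling of the forward vector with accumulated log normalisers
guards against underflow; the log-likelihood of a multi-chromosome genome is
the sum of independent per-chromosome log-likelihoods.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .ac import (
    AncestralConfiguration,
    emission_routing,
    n_bits,
    n_founders,
    n_states,
)
from .data import PhasedGenome, SiteTable

#: switch probabilities d*rate are clamped to this value (a binary chain
#: cannot be more informative than a fair coin flip per interval)
SWITCH_CAP = 0.5


# ----------------------------------------------------------------------
# model
# ----------------------------------------------------------------------
@dataclasses.dataclass
class FounderModel:
    """Per-founder ancestry switch rates plus the phase-switch rate.

    ``rateAB[j]`` / ``rateBA[j]`` are the per-bp probabilities that founder
    ``j``'s ancestry switches A->B / B->A between adjacent bases; ``pp`` is
    the per-bp phase-switch rate (known, fixed during inference).
    """

    K: int
    rateAB: np.ndarray
    rateBA: np.ndarray
    pp: float = 0.0
    rate_cap: float = 1e-2

    def __post_init__(self) -> None:
        nf = n_founders(self.K)
        self.rateAB = np.ascontiguousarray(np.asarray(self.rateAB, dtype=np.float64))
        self.rateBA = np.ascontiguousarray(np.asarray(self.rateBA, dtype=np.float64))
        if self.rateAB.shape != (nf,) or self.rateBA.shape != (nf,):
            raise ValueError(f"rate vectors must have length {nf} for K={self.K}")
        for name, arr in (("rateAB", self.rateAB), ("rateBA", self.rateBA)):
            if np.any(arr <= 0) or np.any(arr > self.rate_cap):
                raise ValueError(f"{name} must lie in (0, {self.rate_cap}]")
        if self.pp < 0:
            raise ValueError("pp must be >= 0")

    @property
    def m0(self) -> np.ndarray:
        """Stationary population-A proportion per founder."""
        return self.rateBA / (self.rateAB + self.rateBA)

    def swap_halves(self) -> "FounderModel":
        """Mirror the pedigree: exchange the left and right founder blocks."""
        half = n_founders(self.K) // 2
        order = np.concatenate([np.arange(half, 2 * half), np.arange(half)])
        return FounderModel(self.K, self.rateAB[order], self.rateBA[order],
                            self.pp, self.rate_cap)


@dataclasses.dataclass
class ForwardState:
    """Scaled forward vector at one site plus the accumulated log normaliser."""

    probs: np.ndarray
    log_scale: float
    site_index: int


# ----------------------------------------------------------------------
# per-bit step probabilities
# ----------------------------------------------------------------------
def _switch(d: float, rate: float, cap: float = SWITCH_CAP) -> float:
    if d < 0:
        raise ValueError(f"inter-site distance d must be >= 0, got {d}")
    return min(d * rate, cap)


def ancestry_step_prob(prev_bit: int, cur_bit: int, d: float,
                       rateAB: float, rateBA: float) -> float:
    """d-step ancestry transition of one founder (linear, clamped)."""
    sw = _switch(d, rateAB) if prev_bit == 0 else _switch(d, rateBA)
    return sw if prev_bit != cur_bit else 1.0 - sw


def phase_step_prob(prev_P: int, cur_P: int, d: float, pp: float) -> float:
    """d-step phase-switch transition (same linear/clamped form)."""
    sw = _switch(d, pp)
    return sw if prev_P != cur_P else 1.0 - sw


def recomb_step_prob(prev_bit: int, cur_bit: int, rec_prob: float) -> float:
    """Transition of one recombination-arrow bit between adjacent sites."""
    if not 0.0 <= rec_prob <= 0.5:
        raise ValueError(f"rec_prob must lie in [0, 0.5], got {rec_prob}")
    return rec_prob if prev_bit != cur_bit else 1.0 - rec_prob


def _bit_matrices(d: float, rec_prob: float, model: FounderModel) -> list[np.ndarray]:
    """2x2 matrices ``m[x, y] = P(bit x -> y)`` in packed bit order [P|C|R]."""
    sp = _switch(d, model.pp)
    mats = [np.array([[1 - sp, sp], [sp, 1 - sp]])]
    for ab, ba in zip(model.rateAB, model.rateBA):
        sab, sba = _switch(d, ab), _switch(d, ba)
        mats.append(np.array([[1 - sab, sab], [sba, 1 - sba]]))
    if not 0.0 <= rec_prob <= 0.5:
        raise ValueError(f"rec_prob must lie in [0, 0.5], got {rec_prob}")
    r = np.array([[1 - rec_prob, rec_prob], [rec_prob, 1 - rec_prob]])
    mats.extend([r] * (n_founders(model.K) - 2))
    return mats


# ----------------------------------------------------------------------
# dense definitions (used directly for small problems and as semantics)
# ----------------------------------------------------------------------
def transition_prob(ac_from: AncestralConfiguration, ac_to: AncestralConfiguration,
                    d: float, rec_prob: float, model: FounderModel) -> float:
    """Exact transition probability: product over the independent bits."""
    if ac_from.K != ac_to.K or ac_from.K != model.K:
        raise ValueError("ac_from, ac_to and model must share K")
    p = phase_step_prob(ac_from.P, ac_to.P, d, model.pp)
    for j, (c0, c1) in enumerate(zip(ac_from.C, ac_to.C)):
        p *= ancestry_step_prob(c0, c1, d, model.rateAB[j], model.rateBA[j])
    for r0, r1 in zip(ac_from.R, ac_to.R):
        p *= recomb_step_prob(r0, r1, rec_prob)
    return p


def emission_prob(ac: AncestralConfiguration, alleles: tuple[int, int],
                  freqA: float, freqB: float) -> float:
    """Probability of the observed allele pair given the configuration."""
    for f in (freqA, freqB):
        if not 0.0 <= f <= 1.0:
            raise ValueError("allele frequencies must lie in [0, 1]")
    p = 1.0
    for hap, allele in zip((1, 2), alleles):
        pop = ac.C[ac.founder_of(hap) - 1]
        f = freqB if pop == 1 else freqA
        p *= f if allele == 1 else 1.0 - f
    return p


def emission_vector(allele1: int, allele2: int, freqA: float, freqB: float,
                    K: int) -> np.ndarray:
    """Emission probabilities for all states at one site."""
    pop1, pop2 = emission_routing(K)
    f1 = np.where(pop1 == 1, freqB, freqA)
    f2 = np.where(pop2 == 1, freqB, freqA)
    e1 = f1 if allele1 == 1 else 1.0 - f1
    e2 = f2 if allele2 == 1 else 1.0 - f2
    return e1 * e2


def init_distribution(model: FounderModel, K: int | None = None) -> np.ndarray:
    """Site-1 state distribution: P and R uniform, C at its stationary law."""
    if K is not None and K != model.K:
        raise ValueError("K does not match model.K")
    K = model.K
    v = np.array([0.5, 0.5])
    for m0 in model.m0:
        v = np.kron(v, np.array([m0, 1.0 - m0]))
    for _ in range(n_founders(K) - 2):
        v = np.kron(v, np.array([0.5, 0.5]))
    return v


# ----------------------------------------------------------------------
# divide-and-conquer forward step
# ----------------------------------------------------------------------
class OpCounter:
    """Counts scalar multiply-adds (for the complexity guarantee)."""

    def __init__(self) -> None:
        self.multiply_adds = 0


def _dc_apply(v: np.ndarray, mats: list[np.ndarray], bit: int,
              counter: OpCounter | None) -> np.ndarray:
    if v.shape[0] == 1:
        return v.copy()
    half = v.shape[0] // 2
    u0 = _dc_apply(v[:half], mats, bit + 1, counter)
    u1 = _dc_apply(v[half:], mats, bit + 1, counter)
    m = mats[bit]
    out = np.empty_like(v)
    out[:half] = m[0, 0] * u0 + m[1, 0] * u1
    out[half:] = m[0, 1] * u0 + m[1, 1] * u1
    if counter is not None:
        counter.multiply_adds += 4 * half
    return out


def forward_step_dc(prev_probs: np.ndarray, d: float, rec_prob: float,
                    model: FounderModel,
                    counter: OpCounter | None = None) -> np.ndarray:
    """Apply the full transition matrix to ``prev_probs`` in O(N log N).

    Equivalent (up to roundoff) to the dense matrix-vector product with the
    matrix whose entries are :func:`transition_prob`.
    """
    prev_probs = np.asarray(prev_probs, dtype=np.float64)
    N = n_states(model.K)
    if prev_probs.shape != (N,):
        raise ValueError(f"prev_probs must have length {N} for K={model.K}")
    mats = _bit_matrices(d, rec_prob, model)
    return _dc_apply(prev_probs, mats, 0, counter)


# ----------------------------------------------------------------------
# full forward pass
# ----------------------------------------------------------------------
def _forward_chrom_numpy(h1, h2, freqA, freqB, gap, rec, model: FounderModel) -> float:
    K = model.K
    v = init_distribution(model) * emission_vector(h1[0], h2[0], freqA[0], freqB[0], K)
    s = v.sum()
    if s <= 0:
        return float("-inf")
    v /= s
    ll = np.log(s)
    for i in range(1, h1.shape[0]):
        v = forward_step_dc(v, float(gap[i]), float(rec[i]), model)
        v *= emission_vector(h1[i], h2[i], freqA[i], freqB[i], K)
        s = v.sum()
        if s <= 0:
            return float("-inf")
        v /= s
        ll += np.log(s)
    return float(ll)


def forward_scan(genome: PhasedGenome, sites: SiteTable,
                 model: FounderModel) -> list[ForwardState]:
    """Final scaled forward state of each chromosome (numpy engine)."""
    out = []
    gap, rec = sites.gap_bp, sites.rec_prob
    for sl in sites.chrom_slices():
        h1, h2 = genome.h1[sl], genome.h2[sl]
        fA, fB = sites.freqA[sl], sites.freqB[sl]
        v = init_distribution(model) * emission_vector(h1[0], h2[0], fA[0], fB[0], model.K)
        s = v.sum()
        v = v / s
        ll = np.log(s)
        for i in range(1, h1.shape[0]):
            v = forward_step_dc(v, float(gap[sl][i]), float(rec[sl][i]), model)
            v *= emission_vector(h1[i], h2[i], fA[i], fB[i], model.K)
            s = v.sum()
            v /= s
            ll += np.log(s)
        out.append(ForwardState(probs=v, log_scale=float(ll), site_index=sl.stop - 1))
    return out


def chain_arrays(sites: SiteTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (gap_bp, rec_prob) arrays for the linked single-chain pass.

    Chromosomes are laid end to end, as in a concatenated genome divided
    into chromosomes: at each chromosome boundary the recombination arrows
    re-randomize (rec_prob = 0.5) while phase and founder-ancestry bits
    evolve across the concatenated bp gap (estimated from the last/first
    site positions, with the observed span as the chromosome-length proxy).
    """
    gap = sites.gap_bp.astype(np.float64)
    rec = sites.rec_prob.copy()
    slices = sites.chrom_slices()
    for cur in slices[1:]:
        # last SNP of the previous chromosome sits near its end (span proxy),
        # so the concatenated gap is about the next chromosome's first position
        gap[cur.start] = max(1.0, float(sites.pos_bp[cur.start]))
        rec[cur.start] = REC_PROB_CAP_BOUNDARY
    return gap, rec


#: recombination-arrow bits are fully re-randomized between chromosomes
REC_PROB_CAP_BOUNDARY = 0.5


def loglikelihood(genome: PhasedGenome, sites: SiteTable, model: FounderModel,
                  engine: str = "auto", linked: bool = True) -> float:
    """Log-likelihood of a phased genome under the pedigree HMM.

    With ``linked=True`` (default) the genome is one forward chain, as for a
    concatenated genome divided into chromosomes: recombination arrows
    re-randomize at chromosome boundaries while phase identity and founder
    ancestry persist across them.  ``linked=False`` restarts the chain at
    every boundary and sums per-chromosome log-likelihoods.

    Parameters
    ----------
    engine : {"auto", "numba", "numpy"}
        "numba" uses the compiled kernel (same divide-and-conquer arithmetic,
        iterative bit peeling); "numpy" uses :func:`forward_step_dc` directly.
    """
    if sites.n == 0:
        raise ValueError("empty SiteTable")
    if genome.n != sites.n:
        raise ValueError(f"genome has {genome.n} sites, table has {sites.n}")
    for name, arr in (("freqA", sites.freqA), ("freqB", sites.freqB)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite values in {name}")

    if engine == "auto":
        from . import _kernels
        engine = "numba" if _kernels.HAVE_NUMBA else "numpy"

    if linked:
        gap, rec = chain_arrays(sites)
        blocks = [slice(0, sites.n)]
    else:
        gap = sites.gap_bp.astype(np.float64)
        rec = sites.rec_prob
        blocks = sites.chrom_slices()

    total = 0.0
    if engine == "numba":
        from ._kernels import forward_loglik_chrom
        pop1, pop2 = emission_routing(model.K)
        init = init_distribution(model)
        for sl in blocks:
            total += forward_loglik_chrom(
                genome.h1[sl], genome.h2[sl],
                sites.freqA[sl], sites.freqB[sl],
                gap[sl], rec[sl],
                model.rateAB, model.rateBA, float(model.pp), SWITCH_CAP,
                pop1, pop2, init,
            )
    elif engine == "numpy":
        for sl in blocks:
            total += _forward_chrom_numpy(
                genome.h1[sl], genome.h2[sl],
                sites.freqA[sl], sites.freqB[sl],
                gap[sl], rec[sl], model,
            )
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return total
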