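"""Ancestral-configuration state space of the pedigree HMM.

A hidden state at one site is the bit triple ``(P, C, R)``:

* ``P`` (1 bit) — phase arrow: 0 routes haplotype 1 to the left half of the
  pedigree, 1 to the right half;
* ``C`` (``2**K`` bits) — population of each generation-K founder at this
  site, left-to-right (0 = population A, 1 = population B);
* ``R`` (``2**K - 2`` bits) — recombination arrows for the internal meioses,
  level by level from the top, left-to-right within a level
  (0 = left child, 1 = right child).

States are packed into an integer as ``[P | C | R]`` most-significant-first,
so the whole space for generation ``K`` is ``[0, 2**(2**(K+1) - 1))``.
"""

from __future__ import annotations

import dataclasses
import functools

import numpy as np

__all__ = [
    "n_bits",
    "n_states",
    "n_founders",
    "encode_ac",
    "decode_ac",
    "founder_of",
    "emission_routing",
    "AncestralConfiguration",
]


def n_founders(K: int) -> int:
    """Number of generation-K founders (2 parents, 4 grandparents, ...)."""
    _check_K(K)
    return 1 << K


def n_bits(K: int) -> int:
    """Bits per state: 1 phase + 2**K founder + 2**K - 2 recombination."""
    _check_K(K)
    return (1 << (K + 1)) - 1


def n_states(K: int) -> int:
    """Size of the state space: 8 / 128 / 32768 for K = 1 / 2 / 3."""
    return 1 << n_bits(K)


def _check_K(K: int) -> None:
    if not isinstance(K, (int, np.integer)) or K < 1:
        raise ValueError(f"K must be a positive integer, got {K!r}")


def encode_ac(P: int, C, R, K: int) -> int:
    """Pack ``(P, C, R)`` bit vectors into the state index (layout [P|C|R])."""
    C = np.asarray(C, dtype=np.int64)
    R = np.asarray(R, dtype=np.int64)
    nf = n_founders(K)
    if C.shape != (nf,):
        raise ValueError(f"C must have {nf} bits for K={K}, got shape {C.shape}")
    if R.shape != (nf - 2,):
        raise ValueError(f"R must have {nf - 2} bits for K={K}, got shape {R.shape}")
    bits = np.concatenate(([int(P)], C, R))
    if np.any((bits != 0) & (bits != 1)):
        raise ValueError("all components must be 0/1 bits")
    idx = 0
    for b in bits:
        idx = (idx << 1) | int(b)
    return idx


def decode_ac(index: int, K: int) -> tuple[int, np.ndarray, np.ndarray]:
    """Inverse of :func:`encode_ac`; returns ``(P, C, R)``."""
    b = n_bits(K)
    index = int(index)
    if not 0 <= index < (1 << b):
        raise ValueError(f"index {index} out of range for K={K}")
    bits = np.array([(index >> (b - 1 - i)) & 1 for i in range(b)], dtype=np.int64)
    nf = n_founders(K)
    return int(bits[0]), bits[1:1 + nf], bits[1 + nf:]


def founder_of(hap: int, P: int, R, K: int) -> int:
    """Trace haplotype ``hap`` (1 or 2) through the arrows to its founder.

    Returns the 1-based founder index (left-to-right).  ``P`` picks the
    pedigree half, then at each internal meiosis the corresponding ``R`` bit
    picks the left (0) or right (1) child founder.
    """
    if hap not in (1, 2):
        raise ValueError(f"hap must be 1 or 2, got {hap!r}")
    R = np.asarray(R, dtype=np.int64)
    nf = n_founders(K)
    if R.shape != (nf - 2,):
        raise ValueError(f"R must have {nf - 2} bits for K={K}, got shape {R.shape}")
    q = int(P) if hap == 1 else 1 - int(P)
    for level in range(1, K):
        offset = (1 << level) - 2
        q = 2 * q + int(R[offset + q])
    return q + 1


@functools.lru_cache(maxsize=None)
def emission_routing(K: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-state population bit of the founder emitting each haplotype.

    Returns ``(pop1, pop2)``, two int8 arrays of length ``n_states(K)``;
    ``pop1[s]`` is the C bit (0 = A, 1 = B) of the founder that haplotype 1
    traces to in state ``s``, and likewise ``pop2`` for haplotype 2.
    """
    b = n_bits(K)
    N = n_states(K)
    nf = n_founders(K)
    idx = np.arange(N, dtype=np.int64)
    P = (idx >> (b - 1)) & 1
    C = np.stack([(idx >> (b - 1 - j)) & 1 for j in range(1, nf + 1)], axis=1)
    R = np.stack(
        [(idx >> (b - 1 - j)) & 1 for j in range(nf + 1, b)], axis=1
    ) if nf > 2 else np.zeros((N, 0), dtype=np.int64)

    out = []
    rows = np.arange(N)
    for hap in (1, 2):
        q = P.copy() if hap == 1 else 1 - P
        for level in range(1, K):
            offset = (1 << level) - 2
            q = 2 * q + R[rows, offset + q]
        out.append(C[rows, q].astype(np.int8))
    pop1, pop2 = out
    pop1.setflags(write=False)
    pop2.setflags(write=False)
    return pop1, pop2


@dataclasses.dataclass(frozen=True)
class AncestralConfiguration:
    """One hidden state ``(P, C, R)`` of the generation-K pedigree HMM."""

    K: int
    P: int
    C: tuple
    R: tuple

    @classmethod
    def from_index(cls, index: int, K: int) -> "AncestralConfiguration":
        P, C, R = decode_ac(index, K)
        return cls(K=K, P=P, C=tuple(int(c) for c in C), R=tuple(int(r) for r in R))

    @property
    def index(self) -> int:
        return encode_ac(self.P, np.array(self.C), np.array(self.R), self.K)

    def founder_of(self, hap: int) -> int:
        return founder_of(hap, self.P, np.array(self.R), self.K)
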