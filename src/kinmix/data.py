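"""Core data containers: site metadata and phased genomes.

A :class:`SiteTable` holds ordered SNP metadata for one or more chromosomes.
Genetic distance is stored as a cumulative expected-crossover coordinate
(``gen_pos``, in Morgans, restarting at 0 on each chromosome); the per-interval
crossover probability ``rec_prob`` is derived from it so that dropping sites
(pruning) automatically re-aggregates recombination across removed intervals.
"""

from __future__ import annotations

import dataclasses

import numpy as np

#: maximal informative switch probability for a binary chain
REC_PROB_CAP = 0.5


def _as_f8(x) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(x, dtype=np.float64))


@dataclasses.dataclass
class SiteTable:
    """Ordered SNP metadata aligned with haplotype vectors.

    Parameters
    ----------
    chrom : array of str
        Chromosome label per site.  Sites of one chromosome must be contiguous.
    pos_bp : array of int
        1-based base-pair coordinate, strictly increasing within a chromosome.
    freqA, freqB : array of float
        Frequency of the designated "1" (ALT) allele in source populations
        A and B, each in [0, 1].
    gen_pos : array of float
        Cumulative genetic position in Morgans from the chromosome start
        (sum of per-bp map rates); non-decreasing within a chromosome.
    """

    chrom: np.ndarray
    pos_bp: np.ndarray
    freqA: np.ndarray
    freqB: np.ndarray
    gen_pos: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.ascontiguousarray(np.asarray(self.pos_bp, dtype=np.int64))
        self.freqA = _as_f8(self.freqA)
        self.freqB = _as_f8(self.freqB)
        self.gen_pos = _as_f8(self.gen_pos)
        n = self.pos_bp.shape[0]
        for name in ("chrom", "freqA", "freqB", "gen_pos"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"field {name!r} has length "
                                 f"{getattr(self, name).shape[0]}, expected {n}")
        for name in ("freqA", "freqB"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)) or arr.min(initial=0.0) < 0 or arr.max(initial=0.0) > 1:
                raise ValueError(f"{name} must be finite and within [0, 1]")
        # chromosome runs must be contiguous
        seen: set = set()
        for lab, sl in self._runs():
            if lab in seen:
                raise ValueError(f"chromosome {lab!r} appears in non-contiguous blocks")
            seen.add(lab)
            if np.any(np.diff(self.pos_bp[sl]) < 1):
                raise ValueError(f"positions not strictly increasing on chromosome {lab!r}")
            if np.any(np.diff(self.gen_pos[sl]) < 0):
                raise ValueError(f"genetic positions decrease on chromosome {lab!r}")

    # ------------------------------------------------------------------
    def _runs(self) -> list[tuple[object, slice]]:
        if self.n == 0:
            return []
        lab = self.chrom
        breaks = np.flatnonzero(lab[1:] != lab[:-1]) + 1
        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [self.n]))
        return [(lab[s], slice(int(s), int(e))) for s, e in zip(starts, ends)]

    @property
    def n(self) -> int:
        return int(self.pos_bp.shape[0])

    def chrom_slices(self) -> list[slice]:
        """Slices of the contiguous per-chromosome blocks, in order."""
        return [sl for _, sl in self._runs()]

    @property
    def gap_bp(self) -> np.ndarray:
        """bp distance to the previous retained site; 0 at each chromosome start."""
        gap = np.zeros(self.n, dtype=np.int64)
        for sl in self.chrom_slices():
            gap[sl.start + 1:sl.stop] = np.diff(self.pos_bp[sl])
        return gap

    @property
    def rec_prob(self) -> np.ndarray:
        """Probability of a crossover between site i-1 and i (capped at 0.5).

        The entry at the first site of each chromosome is 0 and is never used.
        """
        rp = np.zeros(self.n, dtype=np.float64)
        for sl in self.chrom_slices():
            rp[sl.start + 1:sl.stop] = np.minimum(np.diff(self.gen_pos[sl]), REC_PROB_CAP)
        return rp

    def subset(self, mask_or_index) -> "SiteTable":
        """Return a new table with the selected sites (order preserved)."""
        idx = np.asarray(mask_or_index)
        return SiteTable(
            chrom=self.chrom[idx],
            pos_bp=self.pos_bp[idx],
            freqA=self.freqA[idx],
            freqB=self.freqB[idx],
            gen_pos=self.gen_pos[idx],
        )


@dataclasses.dataclass
class PhasedGenome:
    """Two binary haplotype vectors aligned to a :class:`SiteTable`."""

    h1: np.ndarray
    h2: np.ndarray
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.h1 = np.ascontiguousarray(np.asarray(self.h1, dtype=np.uint8))
        self.h2 = np.ascontiguousarray(np.asarray(self.h2, dtype=np.uint8))
        if self.h1.shape != self.h2.shape or self.h1.ndim != 1:
            raise ValueError("h1 and h2 must be 1-D vectors of equal length")
        if self.h1.max(initial=0) > 1 or self.h2.max(initial=0) > 1:
            raise ValueError("haplotype entries must be 0/1")

    @property
    def n(self) -> int:
        return int(self.h1.shape[0])

    def subset(self, mask_or_index) -> "PhasedGenome":
        idx = np.asarray(mask_or_index)
        return PhasedGenome(self.h1[idx], self.h2[idx], self.sample_id)

    def genotype(self) -> np.ndarray:
        """Unphased allele counts h1+h2 (invariant under re-phasing)."""
        return self.h1.astype(np.int8) + self.h2.astype(np.int8)
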