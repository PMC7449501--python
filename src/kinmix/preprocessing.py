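"""SNP pruning and phase-switch-error cleanup applied before inference.

Frequency pruning drops sites whose A/B allele-frequency difference is below
a threshold (keeping the most ancestry-informative sites); LD pruning is the
usual windowed greedy r^2 thinning.  Because genetic distance lives on the
cumulative ``gen_pos`` coordinate, recombination probabilities re-aggregate
across removed sites automatically.

``phase_cleanup`` decodes per-haplotype ancestry with a two-state HMM and
flips the phase wherever the two haplotypes switch ancestry in opposite
directions within a short window — the signature of a phase-switch error
splitting two long tracts.  It also returns a reduced effective phase-error
rate to use during inference.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data import PhasedGenome, SiteTable

__all__ = ["PruneReport", "frequency_prune", "ld_prune", "phase_cleanup"]


@dataclasses.dataclass
class PruneReport:
    method: str
    threshold: float
    n_before: int
    n_after: int
    per_chromosome: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _apply_mask(sites: SiteTable, genomes, mask: np.ndarray):
    kept = sites.subset(mask)
    if isinstance(genomes, PhasedGenome):
        return kept, genomes.subset(mask)
    return kept, [g.subset(mask) for g in genomes]


def _per_chrom_counts(sites: SiteTable, mask: np.ndarray) -> dict:
    out = {}
    for (lab, sl) in sites._runs():
        out[str(lab)] = {"before": sl.stop - sl.start,
                         "after": int(mask[sl].sum())}
    return out


def frequency_prune(sites: SiteTable, genomes, d_f: float):
    """Remove every site with ``|freqA - freqB| < d_f``.

    Returns ``(sites, genomes, report)`` with genomes subset in step.
    """
    if not 0.0 <= d_f <= 1.0:
        raise ValueError(f"d_f must lie in [0, 1], got {d_f}")
    mask = np.abs(sites.freqA - sites.freqB) >= d_f
    if not mask.any():
        raise ValueError(f"frequency pruning at d_f={d_f} removed all "
                         f"{sites.n} sites")
    report = PruneReport("frequency", d_f, sites.n, int(mask.sum()),
                         _per_chrom_counts(sites, mask))
    kept, genomes = _apply_mask(sites, genomes, mask)
    return kept, genomes, report


def _r2_matrix(panel: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between haplotype columns; monomorphic
    columns get r^2 = 0 with everything."""
    x = panel.astype(np.float64)
    x = x - x.mean(axis=0)
    sd = np.sqrt((x ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (x.T @ x) / np.outer(sd, sd)
    c[~np.isfinite(c)] = 0.0
    return c ** 2


def ld_prune(sites: SiteTable, genomes, panel: np.ndarray | None = None,
             window: int = 50, step: int = 5, r2_max: float = 0.1):
    """Sliding-window greedy r^2 thinning (PLINK-style).

    Within each window of ``window`` SNPs, pairs with ``r^2 > r2_max`` lose
    their later member; the window then advances by ``step``.  ``panel`` is a
    (haplotypes x sites) 0/1 matrix used to estimate r^2; if omitted, the
    haplotypes of ``genomes`` are stacked.
    """
    if window < 2 or step < 1:
        raise ValueError("window must be >= 2 and step >= 1")
    gen_list = [genomes] if isinstance(genomes, PhasedGenome) else list(genomes)
    if panel is None:
        panel = np.vstack([np.vstack([g.h1, g.h2]) for g in gen_list])
    panel = np.asarray(panel)
    if panel.shape[1] != sites.n:
        raise ValueError("panel column count does not match the site table")

    keep = np.ones(sites.n, dtype=bool)
    for sl in sites.chrom_slices():
        start = sl.start
        while start < sl.stop:
            idx = np.flatnonzero(keep[start:min(start + window, sl.stop)]) + start
            if idx.shape[0] >= 2:
                r2 = _r2_matrix(panel[:, idx])
                m = idx.shape[0]
                alive = np.ones(m, dtype=bool)
                for a in range(m):
                    if not alive[a]:
                        continue
                    for bidx in range(a + 1, m):
                        if alive[bidx] and r2[a, bidx] > r2_max:
                            alive[bidx] = False
                keep[idx[~alive]] = False
            start += step
    if not keep.any():
        raise ValueError(f"LD pruning at r2_max={r2_max} removed all sites")
    report = PruneReport("ld", r2_max, sites.n, int(keep.sum()),
                         _per_chrom_counts(sites, keep))
    kept, genomes = _apply_mask(sites, genomes, keep)
    return kept, genomes, report


# ----------------------------------------------------------------------
# phase cleanup
# ----------------------------------------------------------------------
def _viterbi_ancestry(h: np.ndarray, freqA: np.ndarray, freqB: np.ndarray,
                      gap: np.ndarray, switch_rate: float) -> np.ndarray:
    """Most probable A/B path of a single haplotype (two-state HMM)."""
    n = h.shape[0]
    eps = 1e-9
    fA = np.clip(np.where(h == 1, freqA, 1.0 - freqA), eps, 1.0)
    fB = np.clip(np.where(h == 1, freqB, 1.0 - freqB), eps, 1.0)
    le = np.log(np.column_stack([fA, fB]))
    score = np.array([np.log(0.5), np.log(0.5)]) + le[0]
    back = np.zeros((n, 2), dtype=np.int8)
    for i in range(1, n):
        sw = min(float(gap[i]) * switch_rate, 0.5)
        sw = max(sw, 1e-12)
        lstay, lsw = np.log1p(-sw), np.log(sw)
        for s in (0, 1):
            stay = score[s] + lstay
            move = score[1 - s] + lsw
            if stay >= move:
                back[i, s] = s
            else:
                back[i, s] = 1 - s
        score = np.array([
            max(score[0] + lstay, score[1] + lsw) + le[i, 0],
            max(score[1] + lstay, score[0] + lsw) + le[i, 1],
        ])
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(score))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def _switch_events(path: np.ndarray, pos: np.ndarray) -> list[tuple[int, int, int]]:
    """(site index i, bp position, direction) for each ancestry change at i."""
    idx = np.flatnonzero(np.diff(path.astype(np.int8))) + 1
    return [(int(i), int(pos[i]), int(path[i] - path[i - 1])) for i in idx]


def _detect_double_switches(g: PhasedGenome, sites: SiteTable,
                            switch_rate: float, min_tract: int) -> list[int]:
    """Site indices where both haplotypes switch ancestry in opposite
    directions within ``min_tract`` bp (phase-switch signature)."""
    flips: list[int] = []
    gap = sites.gap_bp
    for sl in sites.chrom_slices():
        fA, fB = sites.freqA[sl], sites.freqB[sl]
        pos = sites.pos_bp[sl]
        p1 = _viterbi_ancestry(g.h1[sl], fA, fB, gap[sl], switch_rate)
        p2 = _viterbi_ancestry(g.h2[sl], fA, fB, gap[sl], switch_rate)
        ev = sorted(
            [(i, bp, d, 1) for i, bp, d in _switch_events(p1, pos)]
            + [(i, bp, d, 2) for i, bp, d in _switch_events(p2, pos)],
            key=lambda e: (e[1], e[3]),
        )
        used = [False] * len(ev)
        for a in range(len(ev)):
            if used[a]:
                continue
            for b in range(a + 1, len(ev)):
                if used[b]:
                    continue
                if ev[b][1] - ev[a][1] > min_tract:
                    break
                if ev[b][3] != ev[a][3] and ev[b][2] == -ev[a][2]:
                    used[a] = used[b] = True
                    flips.append(sl.start + min(ev[a][0], ev[b][0]))
                    break
    return sorted(flips)


def _hap_forward_loglik(h, freqA, freqB, gap, rate):
    """Forward log-likelihood of one haplotype under the 2-state HMM."""
    eps = 1e-9
    pA = np.clip(np.where(h == 1, freqA, 1.0 - freqA), eps, 1.0)
    pB = np.clip(np.where(h == 1, freqB, 1.0 - freqB), eps, 1.0)
    v0, v1 = 0.5, 0.5
    ll = 0.0
    for i in range(h.shape[0]):
        if i:
            sw = min(float(gap[i]) * rate, 0.5)
            v0, v1 = (1 - sw) * v0 + sw * v1, sw * v0 + (1 - sw) * v1
        v0 *= pA[i]
        v1 *= pB[i]
        s = v0 + v1
        v0 /= s
        v1 /= s
        ll += np.log(s)
    return ll


def phase_cleanup(genome: PhasedGenome, sites: SiteTable,
                  model_guess: float = 1e-6, min_tract: int = 100_000,
                  pp: float = 2e-5, validate_window: int = 150,
                  max_rounds: int = 3):
    """Remove detectable phase-switch errors; returns ``(genome, reduced_pp)``.

    ``model_guess`` is the per-bp ancestry switch rate of the rough two-state
    HMM used to decode tracts (order g*rho).  Wherever the two haplotypes
    switch ancestry in opposite directions within ``min_tract`` bp, the phase
    of the downstream segment is flipped.  The returned effective rate scales
    ``pp`` by the fraction of expected switch points still uncorrected —
    ``pp * (expected - corrected) / expected`` with ``expected = pp * span``
    — floored at ``pp / 10`` (with very sparse errors the cleanup removes
    essentially all of them).

    Only re-phases: the per-site genotype multiset is never altered.
    """
    if min_tract <= 0:
        raise ValueError(f"min_tract must be positive, got {min_tract}")
    if genome.n != sites.n:
        raise ValueError("genome is not aligned to the site table")
    h1, h2 = genome.h1.copy(), genome.h2.copy()
    gap = sites.gap_bp
    chrom_of = {}
    for sl in sites.chrom_slices():
        for i in range(sl.start, sl.stop):
            chrom_of[i] = sl

    flips: list[int] = []
    for _round in range(max_rounds):
        cur = PhasedGenome(h1, h2, genome.sample_id)
        candidates = _detect_double_switches(cur, sites, model_guess, min_tract)
        accepted = 0
        # accept a flip only where it raises the local two-haplotype likelihood
        for i in candidates:
            sl = chrom_of[i]
            lo = max(sl.start, i - validate_window)
            hi = min(sl.stop, i + validate_window)

            def _pair_ll(a, b):
                return (_hap_forward_loglik(a[lo:hi], sites.freqA[lo:hi],
                                            sites.freqB[lo:hi], gap[lo:hi],
                                            model_guess)
                        + _hap_forward_loglik(b[lo:hi], sites.freqA[lo:hi],
                                              sites.freqB[lo:hi], gap[lo:hi],
                                              model_guess))

            base = _pair_ll(h1, h2)
            a1, a2 = h1.copy(), h2.copy()
            a1[i:], a2[i:] = h2[i:].copy(), h1[i:].copy()
            if _pair_ll(a1, a2) > base:
                h1, h2 = a1, a2
                flips.append(i)
                accepted += 1
        if accepted == 0:
            break
    cleaned = PhasedGenome(h1, h2, genome.sample_id)

    span = float(sum(sites.pos_bp[sl.stop - 1] - sites.pos_bp[sl.start]
                     for sl in sites.chrom_slices()))
    expected = max(pp * span, float(len(flips)), 1.0)
    reduced_pp = max(pp * (expected - len(flips)) / expected, pp / 10.0)
    return cleaned, min(reduced_pp, pp)
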