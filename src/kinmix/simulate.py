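"""Synthetic-data generator: diverged source populations, generations of
diploid Wright-Fisher admixture with recombination on a hotspot-like map,
truth tracking for recent ancestors, and phase-switch-error injection.

Founder haplotypes come either from a fast site-independent Balding-Nichols
approximation (default; divergence F = 1 - exp(-t)) or from a two-population
split coalescent simulated with msprime.  The admixed population is then
evolved forward for ``g`` generations: each child draws two distinct parents
uniformly and each gamete is a crossover mosaic of the parent's haplotypes,
with crossovers placed as a Poisson process on the genetic map.  Every
haplotype is a list of tracts pointing back to founder-panel rows, so true
admixture proportions and tract lists of any recent ancestor are exact.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data import PhasedGenome, SiteTable

__all__ = [
    "SimConfig", "Tract", "TruthRecord", "GeneticMap", "FounderPanel",
    "PopulationHistory", "SimResult", "simulate_founders", "evolve_admixed",
    "inject_phase_errors", "simulate",
]


# ----------------------------------------------------------------------
# configuration and result containers
# ----------------------------------------------------------------------
@dataclasses.dataclass
class SimConfig:
    n_h: int = 1000            # founder haplotypes
    n_c: int = 22              # chromosomes (equal length)
    Ne: float = 10_000         # effective population size
    L: float = 3e9             # total region length in bp
    mu: float = 1e-8           # mutation rate per bp per generation
    rho: float = 1e-8          # mean recombination rate per bp per generation
    t: float = 0.2             # split time of the source populations, /Ne units
    g: int = 10                # generations since admixture
    n_i: int = 10              # individuals to sample
    d_f: float = 0.5           # default frequency-pruning threshold
    pp: float = 0.0            # phase-switch error rate per bp (0 = none)
    admix_frac: float = 0.5    # fraction of generation 0 drawn from population A
    seed: int | None = None
    founder_engine: str = "bn"     # "bn" or "msprime"
    map_segment_bp: float = 1e6    # hotspot-map segment length
    map_sigma: float = 1.0         # log-normal spread of segment rates
    K_max: int = 3                 # deepest ancestor generation recorded

    def __post_init__(self) -> None:
        if not 0.0 <= self.admix_frac <= 1.0:
            raise ValueError("admix_frac must lie in [0, 1]")
        for name in ("n_h", "n_c", "Ne", "L", "mu", "rho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.g < 0 or self.n_i < 1:
            raise ValueError("g must be >= 0 and n_i >= 1")


@dataclasses.dataclass
class Tract:
    chrom: str
    start_bp: int   # 1-based, inclusive
    end_bp: int     # inclusive
    pop: str        # "A" or "B"


@dataclasses.dataclass
class TruthRecord:
    """True admixture proportions/tracts for one sampled individual."""

    sample_id: str
    focal_prop: float                  # fraction of the genome from population A
    generations: dict                  # k -> {"ancestor_ids", "proportions", "tracts"}

    def proportions(self, K: int) -> np.ndarray:
        return np.asarray(self.generations[K]["proportions"], dtype=np.float64)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "focal_prop": self.focal_prop,
            "generations": {
                str(k): {
                    "ancestor_ids": v["ancestor_ids"],
                    "proportions": v["proportions"],
                    "tracts": [[dataclasses.asdict(t) for t in tl]
                               for tl in v["tracts"]],
                }
                for k, v in self.generations.items()
            },
        }


# ----------------------------------------------------------------------
# genetic map
# ----------------------------------------------------------------------
class GeneticMap:
    """Piecewise-constant recombination map over [0, L), with chromosome
    boundaries at multiples of L / n_c and segment rates drawn log-normally
    around the mean rate (hotspot stand-in)."""

    def __init__(self, edges: np.ndarray, rates: np.ndarray, n_c: int):
        self.edges = np.asarray(edges, dtype=np.float64)       # n_seg + 1
        self.rates = np.asarray(rates, dtype=np.float64)       # Morgans per bp
        self.n_c = n_c
        self.L = float(self.edges[-1])
        self.chrom_len = self.L / n_c
        self.cumM = np.concatenate(([0.0], np.cumsum(np.diff(self.edges) * self.rates)))

    @classmethod
    def build(cls, L: float, n_c: int, rho: float, segment_bp: float,
              sigma: float, rng: np.random.Generator) -> "GeneticMap":
        chrom_len = L / n_c
        per_chrom = max(1, int(round(chrom_len / segment_bp)))
        edges = [0.0]
        for c in range(n_c):
            start, stop = c * chrom_len, (c + 1) * chrom_len
            edges.extend(np.linspace(start, stop, per_chrom + 1)[1:])
        edges = np.asarray(edges)
        mult = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma,
                             size=edges.shape[0] - 1)
        return cls(edges, rho * mult, n_c)

    def gen_pos(self, bp) -> np.ndarray:
        """Cumulative genetic position (Morgans, whole region) at bp."""
        return np.interp(np.asarray(bp, dtype=np.float64), self.edges, self.cumM)

    def chrom_morgans(self, c: int) -> float:
        return float(self.gen_pos((c + 1) * self.chrom_len)
                     - self.gen_pos(c * self.chrom_len))

    def sample_crossovers(self, c: int, rng: np.random.Generator) -> np.ndarray:
        """Crossover bp positions of one meiosis on chromosome ``c``."""
        m0 = self.gen_pos(c * self.chrom_len)
        mc = self.chrom_morgans(c)
        k = rng.poisson(mc)
        if k == 0:
            return np.empty(0)
        u = np.sort(rng.uniform(0.0, mc, size=k)) + m0
        return np.interp(u, self.cumM, self.edges)

    def to_dataframe(self):
        """HapMap-style map rows: chrom, pos (1-based), cM/Mb, cumulative cM."""
        import pandas as pd

        rows = []
        for c in range(self.n_c):
            start, stop = c * self.chrom_len, (c + 1) * self.chrom_len
            lo = np.searchsorted(self.edges, start, side="left")
            hi = np.searchsorted(self.edges, stop, side="left")
            base = self.gen_pos(start)
            for e in range(lo, hi + 1):
                bp = min(self.edges[e], stop)
                rate = self.rates[min(e, self.rates.shape[0] - 1)]
                rows.append({
                    "chrom": str(c + 1),
                    "pos": int(bp - start) + 1,
                    "rate_cM_Mb": rate * 1e8,
                    "cM": (self.gen_pos(bp) - base) * 100.0,
                })
        return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# founders
# ----------------------------------------------------------------------
@dataclasses.dataclass
class FounderPanel:
    haps: np.ndarray        # (n_rows, n_sites) 0/1; population A rows first
    n_A_rows: int
    global_pos: np.ndarray  # bp positions over [1, L], strictly increasing
    freqA: np.ndarray       # population frequency of the "1" allele
    freqB: np.ndarray
    p_anc: np.ndarray       # ancestral frequency used by the BN draw

    @property
    def panel_freqA(self) -> np.ndarray:
        """Realized "1"-allele frequency in the population-A panel rows."""
        return self.haps[:self.n_A_rows].mean(axis=0)

    @property
    def panel_freqB(self) -> np.ndarray:
        return self.haps[self.n_A_rows:].mean(axis=0)


def simulate_founders(cfg: SimConfig,
                      rng: np.random.Generator | None = None) -> FounderPanel:
    """Two diverged source panels plus per-site population frequencies."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if cfg.founder_engine == "msprime":
        return _founders_msprime(cfg, rng)
    if cfg.founder_engine != "bn":
        raise ValueError(f"unknown founder engine {cfg.founder_engine!r}")

    n_per = max(2, cfg.n_h // 2)
    theta = 4.0 * cfg.Ne * cfg.mu * cfg.L
    harmonic = np.sum(1.0 / np.arange(1, max(cfg.n_h, 2)))
    n_sites = int(rng.poisson(theta * harmonic))
    if n_sites < 1:
        raise ValueError("no segregating sites; increase L or mu")
    pos = np.unique(rng.integers(1, int(cfg.L) + 1, size=n_sites))
    S = pos.shape[0]

    p = rng.uniform(0.0, 1.0, size=S)
    F = 1.0 - np.exp(-cfg.t)
    if F <= 0.0:
        fA = p.copy()
        fB = p.copy()
    else:
        a = p * (1.0 - F) / F
        b = (1.0 - p) * (1.0 - F) / F
        fA = rng.beta(a, b)
        fB = rng.beta(a, b)
    hapsA = (rng.random((n_per, S)) < fA).astype(np.uint8)
    hapsB = (rng.random((n_per, S)) < fB).astype(np.uint8)
    return FounderPanel(np.vstack([hapsA, hapsB]), n_per, pos, fA, fB, p)


def _founders_msprime(cfg: SimConfig, rng: np.random.Generator) -> FounderPanel:
    import msprime

    n_per = max(2, cfg.n_h // 2)
    demography = msprime.Demography()
    demography.add_population(name="A", initial_size=cfg.Ne)
    demography.add_population(name="B", initial_size=cfg.Ne)
    demography.add_population(name="anc", initial_size=cfg.Ne)
    demography.add_population_split(time=4.0 * cfg.Ne * cfg.t,
                                    derived=["A", "B"], ancestral="anc")
    seed = int(rng.integers(1, 2 ** 31 - 1))
    ts = msprime.sim_ancestry(
        samples={"A": n_per, "B": n_per}, demography=demography, ploidy=1,
        sequence_length=cfg.L, recombination_rate=cfg.rho, random_seed=seed)
    ts = msprime.sim_mutations(ts, rate=cfg.mu, random_seed=seed + 1,
                               model=msprime.BinaryMutationModel())
    gm = ts.genotype_matrix()          # (sites, haplotypes)
    pos = np.array([int(s.position) + 1 for s in ts.sites()], dtype=np.int64)
    keep = np.concatenate(([True], np.diff(pos) > 0)) & (gm.max(axis=1) == 1)
    gm, pos = gm[keep], pos[keep]
    haps = np.ascontiguousarray(gm.T.astype(np.uint8))
    fA = haps[:n_per].mean(axis=0)
    fB = haps[n_per:].mean(axis=0)
    p = haps.mean(axis=0)
    return FounderPanel(haps, n_per, pos, fA, fB, p)


# ----------------------------------------------------------------------
# Wright-Fisher forward simulation on tracts
# ----------------------------------------------------------------------
# A haplotype is (ends, fids): tract m covers [ends[m-1], ends[m]) in global
# bp coordinates and copies founder-panel row fids[m]; ends[-1] == L.
Hap = tuple[np.ndarray, np.ndarray]


@dataclasses.dataclass
class PopulationHistory:
    generations: list      # per generation: list of (hap1, hap2)
    parents: list          # parents[gen-1][child] = (p1, p2), for gen >= 1
    n_A_rows: int
    L: float

    def individual(self, gen: int, idx: int):
        return self.generations[gen][idx]

    def ancestors_of(self, idx: int, k: int) -> list[int]:
        """Indices of the 2**k generation-k ancestors, left-to-right
        (haplotype 1's lineage first)."""
        g = len(self.generations) - 1
        if k > min(g, len(self.parents)):
            raise ValueError(f"pedigree records only {len(self.parents)} generations")
        layer = [idx]
        for level in range(k):
            gen_above = g - level
            layer = [p for i in layer for p in self.parents[gen_above - 1][i]]
        return layer

    def prop_A(self, gen: int, idx: int) -> float:
        h1, h2 = self.generations[gen][idx]
        return (self._hap_prop(h1) + self._hap_prop(h2)) / 2.0

    def hap_prop_A(self, hap: Hap) -> float:
        return self._hap_prop(hap)

    def _hap_prop(self, hap: Hap) -> float:
        ends, fids = hap
        starts = np.concatenate(([0.0], ends[:-1]))
        lengths = ends - starts
        return float(lengths[fids < self.n_A_rows].sum() / self.L)


def _slice_hap(hap: Hap, lo: float, hi: float, out_ends: list, out_fids: list) -> None:
    ends, fids = hap
    i = int(np.searchsorted(ends, lo, side="right"))
    while i < ends.shape[0] and lo < hi:
        e = min(float(ends[i]), hi)
        out_ends.append(e)
        out_fids.append(int(fids[i]))
        lo = e
        i += 1


def _gamete(ind, gmap: GeneticMap, rng: np.random.Generator) -> Hap:
    out_ends: list = []
    out_fids: list = []
    for c in range(gmap.n_c):
        start, stop = c * gmap.chrom_len, (c + 1) * gmap.chrom_len
        cx = gmap.sample_crossovers(c, rng)
        cur = int(rng.integers(0, 2))
        bounds = np.concatenate(([start], cx, [stop]))
        for k in range(bounds.shape[0] - 1):
            _slice_hap(ind[cur], bounds[k], bounds[k + 1], out_ends, out_fids)
            cur = 1 - cur
    # merge adjacent tracts copying the same founder row
    ends = np.asarray(out_ends)
    fids = np.asarray(out_fids, dtype=np.int64)
    keep = np.concatenate((fids[1:] != fids[:-1], [True]))
    return ends[keep], fids[keep]


def evolve_admixed(panel: FounderPanel, cfg: SimConfig, gmap: GeneticMap,
                   rng: np.random.Generator) -> PopulationHistory:
    """Merge the panels (fraction ``admix_frac`` from A) and run ``g``
    generations of diploid Wright-Fisher mating with recombination."""
    n_ind = max(2, cfg.n_h // 2)
    n_rows = panel.haps.shape[0]
    nA_hap = int(round(cfg.admix_frac * 2 * n_ind))

    def founder_hap(j: int) -> Hap:
        if j < nA_hap:
            fid = int(rng.integers(0, panel.n_A_rows))
        else:
            fid = int(rng.integers(panel.n_A_rows, n_rows))
        return (np.array([cfg.L]), np.array([fid], dtype=np.int64))

    order = rng.permutation(2 * n_ind)
    gen0 = [(founder_hap(order[2 * i]), founder_hap(order[2 * i + 1]))
            for i in range(n_ind)]
    generations = [gen0]
    parents: list = []
    for _ in range(cfg.g):
        cur = generations[-1]
        kids = []
        recs = []
        for _child in range(n_ind):
            p1 = int(rng.integers(0, n_ind))
            p2 = int(rng.integers(0, n_ind - 1))
            if p2 >= p1:
                p2 += 1
            kids.append((_gamete(cur[p1], gmap, rng), _gamete(cur[p2], gmap, rng)))
            recs.append((p1, p2))
        generations.append(kids)
        parents.append(recs)
    return PopulationHistory(generations, parents, panel.n_A_rows, cfg.L)


# ----------------------------------------------------------------------
# sampled genomes, truth, phase errors
# ----------------------------------------------------------------------
def _hap_alleles(hap: Hap, panel: FounderPanel) -> np.ndarray:
    ends, fids = hap
    out = np.empty(panel.global_pos.shape[0], dtype=np.uint8)
    lo = 0
    for e, fid in zip(ends, fids):
        hi = int(np.searchsorted(panel.global_pos, e, side="right"))
        out[lo:hi] = panel.haps[fid, lo:hi]
        lo = hi
    return out


def _pop_tracts(hap: Hap, n_A_rows: int, gmap: GeneticMap) -> list[Tract]:
    ends, fids = hap
    tracts: list[Tract] = []
    prev = 0.0
    for e, fid in zip(ends, fids):
        pop = "A" if fid < n_A_rows else "B"
        c0 = min(int(prev // gmap.chrom_len), gmap.n_c - 1)
        c1 = min(int((e - 1) // gmap.chrom_len), gmap.n_c - 1)
        for c in range(c0, c1 + 1):
            lo = max(prev, c * gmap.chrom_len)
            hi = min(e, (c + 1) * gmap.chrom_len)
            seg = Tract(str(c + 1), int(lo - c * gmap.chrom_len) + 1,
                        int(hi - c * gmap.chrom_len), pop)
            if tracts and tracts[-1].pop == pop and tracts[-1].chrom == seg.chrom \
                    and tracts[-1].end_bp + 1 >= seg.start_bp:
                tracts[-1].end_bp = seg.end_bp
            else:
                tracts.append(seg)
        prev = e
    return tracts


def _truth_record(pop: PopulationHistory, sample_idx: int, sample_id: str,
                  gmap: GeneticMap, K_max: int) -> TruthRecord:
    g = len(pop.generations) - 1
    generations = {}
    for k in range(1, min(K_max, g, len(pop.parents)) + 1):
        ancestors = pop.ancestors_of(sample_idx, k)
        props = [pop.prop_A(g - k, a) for a in ancestors]
        tracts = []
        for a in ancestors:
            h1, h2 = pop.generations[g - k][a]
            tracts.append(_pop_tracts(h1, pop.n_A_rows, gmap)
                          + _pop_tracts(h2, pop.n_A_rows, gmap))
        generations[k] = {"ancestor_ids": [f"g{g - k}i{a}" for a in ancestors],
                          "proportions": props, "tracts": tracts}
    return TruthRecord(sample_id=sample_id,
                       focal_prop=pop.prop_A(g, sample_idx),
                       generations=generations)


def inject_phase_errors(genome: PhasedGenome, global_pos: np.ndarray, L: float,
                        pp: float, rng: np.random.Generator | int | None = None):
    """Swap the haplotypes downstream of Poisson(rate pp per bp) switch
    points; genotypes are unchanged.  Returns (genome, switch positions)."""
    if pp < 0:
        raise ValueError("pp must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if pp == 0.0:
        return PhasedGenome(genome.h1.copy(), genome.h2.copy(), genome.sample_id), \
            np.empty(0)
    n_sw = rng.poisson(pp * L)
    switch_pos = np.sort(rng.uniform(0.0, L, size=n_sw))
    parity = np.searchsorted(switch_pos, global_pos.astype(np.float64)) % 2
    swap = parity.astype(bool)
    h1 = np.where(swap, genome.h2, genome.h1)
    h2 = np.where(swap, genome.h1, genome.h2)
    return PhasedGenome(h1, h2, genome.sample_id), switch_pos


# ----------------------------------------------------------------------
# full pipeline
# ----------------------------------------------------------------------
@dataclasses.dataclass
class SimResult:
    cfg: SimConfig
    sites: SiteTable
    genomes: list            # with phase errors when cfg.pp > 0
    clean_genomes: list      # before error injection
    truths: list
    panel: FounderPanel
    gmap: GeneticMap
    population: PopulationHistory


def _site_table(panel: FounderPanel, gmap: GeneticMap) -> SiteTable:
    pos = panel.global_pos
    chrom_idx = np.minimum((pos - 1) // int(gmap.chrom_len), gmap.n_c - 1)
    chrom = np.array([str(c + 1) for c in chrom_idx], dtype=object)
    pos_in = pos - chrom_idx * int(gmap.chrom_len)
    gp = gmap.gen_pos(pos) - gmap.gen_pos(chrom_idx * gmap.chrom_len)
    # realized panel frequencies: the exact emission law of sampled alleles
    return SiteTable(chrom=chrom, pos_bp=pos_in, freqA=panel.panel_freqA,
                     freqB=panel.panel_freqB, gen_pos=gp)


def simulate(cfg: SimConfig) -> SimResult:
    """Run the full generator: founders, admixed WF population, sampled
    phased genomes with truth records, optional phase errors."""
    rng = np.random.default_rng(cfg.seed)
    gmap = GeneticMap.build(cfg.L, cfg.n_c, cfg.rho, cfg.map_segment_bp,
                            cfg.map_sigma, rng)
    panel = simulate_founders(cfg, rng)
    pop = evolve_admixed(panel, cfg, gmap, rng)
    sites = _site_table(panel, gmap)

    g = cfg.g
    n_ind = len(pop.generations[g])
    chosen = rng.choice(n_ind, size=min(cfg.n_i, n_ind), replace=False)
    clean, noisy, truths = [], [], []
    for rank, idx in enumerate(chosen):
        sid = f"ind{rank}"
        h1, h2 = pop.generations[g][int(idx)]
        genome = PhasedGenome(_hap_alleles(h1, panel), _hap_alleles(h2, panel), sid)
        clean.append(genome)
        noisy.append(inject_phase_errors(genome, panel.global_pos, cfg.L,
                                         cfg.pp, rng)[0])
        truths.append(_truth_record(pop, int(idx), sid, gmap, cfg.K_max))
    return SimResult(cfg=cfg, sites=sites, genomes=noisy, clean_genomes=clean,
                     truths=truths, panel=panel, gmap=gmap, population=pop)
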