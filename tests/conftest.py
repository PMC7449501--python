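import numpy as np
import pytest

from kinmix import FounderModel, PhasedGenome, SiteTable


def random_sites(rng, n, n_chrom=1, span=1_000_000, morgans_per_bp=1e-8):
    """Small random SiteTable spread over ``n_chrom`` equal chromosomes."""
    per = [n // n_chrom + (1 if i < n % n_chrom else 0) for i in range(n_chrom)]
    chrom, pos, gp = [], [], []
    for c, k in enumerate(per):
        p = np.sort(rng.choice(np.arange(1, span), size=k, replace=False))
        chrom.extend([str(c + 1)] * k)
        pos.extend(p.tolist())
        gp.extend((p * morgans_per_bp).tolist())
    return SiteTable(chrom=np.array(chrom, dtype=object), pos_bp=pos,
                     freqA=rng.uniform(0.05, 0.95, n),
                     freqB=rng.uniform(0.05, 0.95, n), gen_pos=gp)


def random_genome(rng, n):
    return PhasedGenome(rng.integers(0, 2, n), rng.integers(0, 2, n))


def random_model(rng, K, pp=0.0):
    nf = 1 << K
    return FounderModel(K, rateAB=np.exp(rng.uniform(np.log(1e-9), np.log(1e-6), nf)),
                        rateBA=np.exp(rng.uniform(np.log(1e-9), np.log(1e-6), nf)),
                        pp=pp)


@pytest.fixture
def rng():
    return np.random.default_rng(20240811)
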