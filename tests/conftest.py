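import numpy as np
import pytest

from mrdml import HarmonizedInstrumentSet, SimulationConfig, harmonize, simulate_pair


def make_hset(beta_x, beta_y, se_y, se_x=None, chrom=None, pos=None,
              snp_ids=None, eaf=None):
    """Build a harmonized set directly from effect vectors."""
    beta_x = np.asarray(beta_x, dtype=float)
    n = beta_x.size
    beta_y = np.asarray(beta_y, dtype=float)
    se_y = np.broadcast_to(np.asarray(se_y, dtype=float), (n,)).copy()
    se_x = np.broadcast_to(np.asarray(
        0.01 if se_x is None else se_x, dtype=float), (n,)).copy()
    chrom = (np.ones(n, dtype=int) if chrom is None
             else np.broadcast_to(np.asarray(chrom), (n,)).copy())
    pos = (np.arange(1, n + 1) * 1_000_000 if pos is None
           else np.broadcast_to(np.asarray(pos), (n,)).copy())
    ids = (np.array([f"rs{j:06d}" for j in range(1, n + 1)], dtype=object)
           if snp_ids is None else np.asarray(snp_ids, dtype=object))
    eaf = np.full(n, 0.3) if eaf is None else np.asarray(eaf, dtype=float)
    from scipy import stats
    return HarmonizedInstrumentSet(
        snp_ids=ids, beta_x=beta_x, se_x=se_x, beta_y=beta_y, se_y=se_y,
        eaf=eaf, chrom=chrom, pos=pos,
        pval_x=2 * stats.norm.sf(np.abs(beta_x / se_x)),
        pval_y=2 * stats.norm.sf(np.abs(beta_y / se_y)),
        n_x=np.full(n, 8428), n_y=np.full(n, 100_000),
    )


def simulate_instrument_set(config: SimulationConfig):
    """Simulate a pair and return the harmonized true-instrument set."""
    exposure, outcome, truth = simulate_pair(config)
    hset = harmonize(exposure, outcome)
    inst_ids = exposure["SNP"].to_numpy()[truth.instrument_indices]
    return hset.subset(np.isin(hset.snp_ids, inst_ids)), truth


@pytest.fixture
def two_snp_set():
    """The hand-computable heterogeneity fixture: IVW beta 0.6, Q = 20."""
    return make_hset(beta_x=[0.2, 0.1], beta_y=[0.1, 0.1], se_y=0.01)


@pytest.fixture
def make_harmonized():
    return make_hset


@pytest.fixture
def sim_instruments():
    return simulate_instrument_set
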