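import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mrmediate.io import HarmonizedInstrumentSet, SnpAssociation

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def mk_hset(beta_exp, beta_out, se_out, se_exp=None, snp_ids=None) -> HarmonizedInstrumentSet:
    """Build a harmonized set directly from arrays (all rows kept)."""
    beta_exp = np.asarray(beta_exp, float)
    k = len(beta_exp)
    records = pd.DataFrame(
        {
            "snp_id": list(snp_ids) if snp_ids is not None else [f"rs{i}" for i in range(k)],
            "beta_exp": beta_exp,
            "se_exp": np.full(k, 0.01) if se_exp is None else np.asarray(se_exp, float),
            "beta_out": np.asarray(beta_out, float),
            "se_out": np.asarray(se_out, float),
            "action": "kept",
        }
    )
    return HarmonizedInstrumentSet("exposure", "outcome", records)


def random_panel(rng, k=12, theta=0.3, z=12.0, se_exp_scale=0.01, se_out_scale=0.015):
    """Simple homogeneous panel: strong instruments, no pleiotropy.

    Instrument strengths are spread over [0.5z, 2z] so the exposure betas
    carry real variance relative to their sampling error — without that
    spread MR-Egger suffers textbook errors-in-variables attenuation.
    """
    se_exp = np.full(k, se_exp_scale)
    se_out = np.full(k, se_out_scale)
    gamma = rng.choice([-1, 1], size=k) * rng.uniform(0.5 * z, 2.0 * z, size=k) * se_exp
    beta_exp = gamma + rng.normal(0, se_exp)
    beta_out = theta * gamma + rng.normal(0, se_out)
    return beta_exp, se_exp, beta_out, se_out, gamma


def random_records(rng, n=10, chrom="1", start_pos=1000) -> list[SnpAssociation]:
    pairs = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
    recs = []
    for i in range(n):
        ea, oa = pairs[rng.integers(len(pairs))]
        beta = float(rng.normal(0, 0.1))
        se = float(rng.uniform(0.01, 0.05))
        recs.append(
            SnpAssociation(
                snp_id=f"rs{i+1}",
                chrom=chrom,
                pos=start_pos + i * 100_000,
                effect_allele=ea,
                other_allele=oa,
                eaf=float(rng.uniform(0.05, 0.95)),
                beta=beta,
                se=se,
                pval=float(rng.uniform(1e-12, 1.0)),
                n=int(rng.integers(1_000, 100_000)),
            )
        )
    return recs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def world():
    from mrmediate.simulate import simulate_screen_world

    return simulate_screen_world(seed=0)
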