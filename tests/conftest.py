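import numpy as np
import pytest

from twosmr.harmonization import HarmonizedPair, HarmonizedSet
from twosmr.summary_data import VariantAssociation


def make_variant(snp="rs1", ea="A", oa="G", eaf=0.3, beta=0.02, se=0.004,
                 pvalue=1e-9, n=100000, chrom="1", pos=1000, trait="x"):
    return VariantAssociation(
        snp_id=snp, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=beta, se=se, pvalue=pvalue, n=n, trait=trait,
    )


def make_set(beta_exp, beta_out, se_out, se_exp=None, eaf=None):
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.asarray(se_out, dtype=float)
    se_exp = np.full_like(beta_exp, 0.003) if se_exp is None else np.asarray(se_exp, float)
    eaf = np.full_like(beta_exp, 0.4) if eaf is None else np.asarray(eaf, float)
    pairs = [
        HarmonizedPair(
            snp_id=f"rs{i}", beta_exp=float(x), se_exp=float(sx),
            beta_out=float(y), se_out=float(sy), eaf_exp=float(f), eaf_out=float(f),
        )
        for i, (x, sx, y, sy, f) in enumerate(zip(beta_exp, se_exp, beta_out, se_out, eaf))
    ]
    return HarmonizedSet(pairs)


@pytest.fixture
def toy_set():
    """5 instruments with heterogeneous ratios and weights."""
    rng = np.random.default_rng(7)
    x = rng.uniform(0.02, 0.05, 5) * rng.choice([-1, 1], 5)
    theta = 0.1
    sy = rng.uniform(0.004, 0.01, 5)
    y = theta * x + rng.normal(0, sy)
    return make_set(x, y, sy)


@pytest.fixture
def random_set_factory():
    def factory(seed, n=20):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.01, 0.06, n) * rng.choice([-1, 1], n)
        sy = rng.uniform(0.002, 0.02, n)
        y = 0.08 * x + rng.normal(0, sy)
        return make_set(x, y, sy)

    return factory
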