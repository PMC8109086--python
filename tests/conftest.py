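import numpy as np
import pandas as pd
import pytest

from mrsuite.summary_io import SummaryDataset, VariantAssociation


def make_variant(rsid="rs1", chrom="1", pos=1000, effect_allele="A",
                 other_allele="G", eaf=0.3, beta=0.1, se=0.01, pval=1e-10):
    return VariantAssociation(rsid=rsid, chrom=chrom, pos=pos,
                              effect_allele=effect_allele,
                              other_allele=other_allele, eaf=eaf,
                              beta=beta, se=se, pval=pval)


def make_dataset(records, **meta):
    return SummaryDataset(records=list(records), **meta)


def random_instrument_frame(rng, n=30, true_beta=0.1, alpha_sd=0.0):
    """Simple homogeneous instrument table for estimator tests."""
    x = np.abs(rng.normal(0.0, 0.08, n)) + 0.03
    sx = rng.uniform(0.004, 0.008, n)
    sy = rng.uniform(0.001, 0.003, n)
    alpha = rng.normal(0.0, alpha_sd, n) if alpha_sd else np.zeros(n)
    xh = x + sx * rng.standard_normal(n)
    yh = true_beta * x + alpha + sy * rng.standard_normal(n)
    return pd.DataFrame({
        "rsid": [f"rs{i}" for i in range(n)],
        "beta_exp": xh, "se_exp": sx, "beta_out": yh, "se_out": sy,
    })


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
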