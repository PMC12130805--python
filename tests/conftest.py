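import numpy as np
import pytest

from mrpanel.harmonize import HarmonizedSet
from mrpanel.io_config import VariantAssoc


@pytest.fixture
def simple_hset() -> HarmonizedSet:
    """Three uncorrelated instruments with an exact proportional signal."""
    return HarmonizedSet(
        variant_ids=("rs1", "rs2", "rs3"),
        bx=np.array([0.1, 0.2, 0.3]),
        sx=np.array([0.01, 0.01, 0.01]),
        by=np.array([0.05, 0.12, 0.14]),
        sy=np.array([0.01, 0.01, 0.01]),
    )


@pytest.fixture
def equal_weight_hset() -> HarmonizedSet:
    """Four equal-weight instruments with ratio estimates (1, 2, 3, 10)."""
    return HarmonizedSet(
        variant_ids=("rs1", "rs2", "rs3", "rs4"),
        bx=np.ones(4),
        sx=np.full(4, 0.1),
        by=np.array([1.0, 2.0, 3.0, 10.0]),
        sy=np.ones(4),
    )


def make_assoc(variant_id="rs1", effect_allele="A", other_allele="G", beta=0.1,
               se=0.01, pval=1e-9, eaf=0.3, n=10000, trait_id="x") -> VariantAssoc:
    return VariantAssoc(variant_id=variant_id, effect_allele=effect_allele,
                        other_allele=other_allele, beta=beta, se=se, pval=pval,
                        eaf=eaf, n=n, trait_id=trait_id)
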