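import numpy as np
import pytest

from ldstack import SnpAssociation
from ldstack.ld import R2_MISSING


def make_assoc(bp, p, odds_ratio=2.0, chrom="1", snp_id=None, a1="A"):
    return SnpAssociation(chrom=chrom, bp=bp,
                          snp_id=snp_id or f"rs{bp}", a1=a1,
                          odds_ratio=odds_ratio, p_value=p)


class DictLd:
    """LD source backed by an explicit symmetric r² dictionary.

    Unlisted pairs default to 0.0; unlisted self-pairs to 1.0. Useful for
    hand-constructed grouping fixtures where genotypes would be noise.
    """

    def __init__(self, pairs=None, missing_ids=()):
        self._pairs = {}
        self._missing = set(missing_ids)
        for (a, b), r2 in (pairs or {}).items():
            self._pairs[(a, b)] = r2
            self._pairs[(b, a)] = r2

    def r2(self, a, b):
        if a in self._missing or b in self._missing:
            return R2_MISSING
        if a == b:
            return self._pairs.get((a, b), 1.0)
        return self._pairs.get((a, b), 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
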