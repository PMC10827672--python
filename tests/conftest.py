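import numpy as np
import pytest

import mosaicenrich as me


@pytest.fixture(scope="session")
def toy_universe():
    """Six random 30-codon intronless genes on one chromosome."""
    return me.make_toy_reference(6, 30, 0.0, seed=11)


@pytest.fixture(scope="session")
def toy_index(toy_universe):
    reference, models = toy_universe
    return me.build_site_index(reference, models)


@pytest.fixture(scope="session")
def mito_toy():
    return me.make_mito_fixture("toy", seed=0)


@pytest.fixture(scope="session")
def mito_rcrs():
    return me.make_mito_fixture("rcrs_like", seed=0)


def fet_enumeration_oracle(a, b, c, d, comb=None):
    """Independent brute-force two-sided Fisher p-value: enumerate every table
    with the observed margins in exact integer arithmetic and sum the point
    probabilities not exceeding the observed one (1e-7 relative tie band)."""
    import math

    comb = comb or math.comb
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    obs = nums[a - lo]
    scale = 10**9
    thresh = obs * (scale + 100)  # obs * (1 + 1e-7)
    total = sum(v for v in nums if v * scale <= thresh)
    return total / comb(n, c1)
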