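import numpy as np
import pandas as pd
import pytest

import cagecorr as cc


@pytest.fixture
def small_positive_cohort():
    """200 cages of 4 per arm, ICC 0.05, fixed seed."""
    st = cc.make_cage_structure(100, 4, n_arms=2, seed=101)
    return cc.sample_exchangeable_outcomes(
        st, cc.GeneratorConfig(icc=0.05, seed=101))


@pytest.fixture
def negative_cohort():
    """400 cages of 4, ICC -0.10 (dispersion within cages)."""
    st = cc.make_cage_structure(200, 4, n_arms=2, seed=102)
    return cc.sample_exchangeable_outcomes(
        st, cc.GeneratorConfig(icc=-0.10, seed=102))


@pytest.fixture
def independent_cohort():
    """400 cages of 4 with ICC exactly 0.

    This seed draws a sample whose moment ICC is (slightly) negative, so
    the REML fit is provably on the zero boundary — convenient for the
    truncation tests.
    """
    st = cc.make_cage_structure(200, 4, n_arms=2, seed=104)
    return cc.sample_exchangeable_outcomes(
        st, cc.GeneratorConfig(icc=0.0, seed=104))


def toy_cohort(values_per_cage, arm=None):
    """Tiny hand-made cohort from a list of per-cage value tuples."""
    rows = []
    i = 0
    for j, vals in enumerate(values_per_cage):
        for v in vals:
            rows.append({"animal_id": f"A{i}", "cage_id": f"C{j}",
                         "arm": (arm[j] if arm else "control"),
                         "lifespan_months": float(v), "censored": False})
            i += 1
    return pd.DataFrame(rows)
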