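import math
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import settings

from seedaging.io import paper_design

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design():
    return paper_design()


def exact_proportion_dishes(ki, slope, durations, n_seeds=30, lot_id="L", species_id="sp"):
    """Dish-like records whose 'counts' put the observed proportion exactly
    on the probit line ki + slope*t (fractional counts; test-only stub)."""
    from scipy.stats import norm

    out = []
    for t in durations:
        p = float(norm.cdf(ki + slope * t))
        out.append(
            SimpleNamespace(
                lot_id=lot_id,
                species_id=species_id,
                aging_days=float(t),
                replicate_id=f"t{t}",
                n_seeds=n_seeds,
                n_germinated=p * n_seeds,
                contaminated=False,
                proportion=p,
            )
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
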