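import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from vlcdprot.design import build_itraq_layout, build_study_design

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def study_design():
    """The full cohort: 13 + 14 patients, 27 obese and 27 lean controls."""
    return build_study_design()


@pytest.fixture(scope="session")
def study_layouts(study_design):
    return build_itraq_layout(study_design, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_group_abundance(design, t2dm0, t2dm16, obese, lean, jitter=0.01, seed=0,
                         protein="PROT"):
    """One protein's abundance row with group means and deterministic jitter."""
    rng = np.random.default_rng(seed)
    vals = {}
    for s in design.samples:
        if s.group in ("T2DM_EX", "T2DM_ONLY"):
            mean = t2dm0 if s.timepoint == "BASELINE" else t2dm16
        elif s.group == "OBESE_CTRL":
            mean = obese
        else:
            mean = lean
        vals[s.sample_id] = mean * float(np.exp(rng.normal(0.0, jitter)))
    return pd.DataFrame(vals, index=[protein])
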