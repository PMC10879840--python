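import numpy as np
import pandas as pd
import pytest

from owlmhc import simdata
from owlmhc.divergence import divergence_table
from owlmhc.genotyper import translate


@pytest.fixture(scope="session")
def dab2_pool():
    spec = simdata.DEFAULT_LOCI["DAB2"]
    return spec, simdata.generate_allele_pool(spec, seed=3)


@pytest.fixture(scope="session")
def dab2_alignment(dab2_pool):
    _, pool = dab2_pool
    return {lab: translate(seq) for lab, seq in pool.items()}


@pytest.fixture(scope="session")
def small_breeding():
    """A small fully cross-fostered dataset with a known injected paternal
    divergence effect, shared by association tests."""
    div = pd.Series(
        np.random.default_rng(11).gamma(4, 1.2, 240),
        index=[f"ind{i:04d}" for i in range(240)],
    )
    effects = simdata.EffectConfig(beta_div_genetic_father=-0.8)
    nests = simdata.simulate_breeding(div, effects, 100, seed=5, crossfoster_plan="full")
    div_df = pd.DataFrame(
        {"sample_id": div.index, "locus": "MHC-Ia", "functional_divergence": div.to_numpy()}
    )
    return nests, div_df
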