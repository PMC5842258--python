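import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from atscan import synth

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20180221)


@pytest.fixture(scope="session")
def small_panel():
    """A small structured panel with one planted causal SNP and one
    planted expression mediator (on well-separated markers)."""
    cfg = synth.PanelConfig(
        n_accessions=40,
        n_markers=400,
        n_genes=60,
        causal_snps=((10, 0.6),),
        mediator_genes=((5, 200, 1.5, 0.4),),
        polygenic_var=0.2,
        seed=3,
    )
    return synth.simulate_panel(cfg)


@pytest.fixture(scope="session")
def small_means(small_panel):
    return small_panel.traits.groupby("accession").mean(numeric_only=True).drop(
        columns=["replicate"]
    )
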