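import numpy as np
import pytest

from regulonkit.coexpression import (
    estimate_bicluster,
    extract_upstreams,
    feeding_order,
    filter_operon_heads,
)
from regulonkit.pipeline import PipelineParams, run_pipeline_objects
from regulonkit.simulate import (
    make_default_bundle,
    make_planted_sequences,
    make_pwm,
)

UNIFORM_BG = np.full(4, 0.25)


@pytest.fixture(scope="session")
def bundle():
    """The default end-to-end synthetic study system (seed 7)."""
    return make_default_bundle(seed=7)


@pytest.fixture(scope="session")
def planted16():
    """Planted-motif discovery fixture: 20 x 300 bp, 16-bp palindrome,
    per-position identity 0.85, presence 0.9, seed 5."""
    pwm = make_pwm(16, "palindromic", conservation=0.85, seed=3)
    seqs, truth = make_planted_sequences(
        20, 300, pwm, identity=0.85, presence=0.9, seed=5
    )
    return pwm, seqs, truth


@pytest.fixture(scope="session")
def pipeline_run(bundle):
    """One full pipeline execution on the default bundle (shared: it is
    the most expensive fixture in the suite)."""
    params = PipelineParams(tf=bundle.tf, seed=7)
    return run_pipeline_objects(
        bundle.genome,
        bundle.annotations,
        bundle.expression,
        params,
        fitness=bundle.fitness,
        operons=bundle.operons,
    )
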