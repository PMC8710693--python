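import numpy as np
import pytest

from pmgae.evaluation import Dataset, run_cv
from pmgae.io_formats import RunConfig
from pmgae.synthetic_data import SyntheticSpec, generate

# Reduced-epoch configuration used for cross-validated runs in the suite:
# sae_dim must stay below the smaller node set (60 miRNAs at fixture scale).
CV_CONFIG = RunConfig(sae_dim=32, sae_epochs=200, gae_epochs=500, random_seed=1)

# Small geometry for fast structural tests of the orchestration layer.
SMALL_SPEC = SyntheticSpec(
    n_pseudogenes=30, n_mirnas=16, n_tissues=10, latent_dim=4, n_edges=80, seed=3
)
FAST_CONFIG = RunConfig(
    sae_dim=8, sae_hidden=32, sae_epochs=30, gae_epochs=50,
    snf_iterations=5, snf_neighbors=5, cv_folds=3, random_seed=3,
)


@pytest.fixture(scope="session")
def default_fixture():
    """The default 120x60 / 500-edge synthetic dataset, seed 1."""
    expr, seqs, assoc, truth = generate(SyntheticSpec(seed=1))
    return Dataset(expr, seqs, assoc), truth


@pytest.fixture(scope="session")
def small_fixture():
    expr, seqs, assoc, truth = generate(SMALL_SPEC)
    return Dataset(expr, seqs, assoc), truth


@pytest.fixture(scope="session")
def cv_results(default_fixture):
    """Cross-validation reports reused across acceptance checks.

    Computed once per session: the default fixture at negative ratios
    1/2/5/10 plus the null-signal control at ratio 1.
    """
    ds, _ = default_fixture
    reports = {
        ratio: run_cv(ds, CV_CONFIG.with_overrides(neg_ratio=ratio))
        for ratio in (1, 2, 5, 10)
    }
    e2, s2, a2, _ = generate(
        SyntheticSpec(seed=1, motif_strength=0.0, decouple_edges=True)
    )
    reports["null"] = run_cv(Dataset(e2, s2, a2), CV_CONFIG)
    return reports
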