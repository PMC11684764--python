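import numpy as np
import pytest

from admixpca.experiment import planted_feature_study
from admixpca.simulate import AdmixtureModel, random_panel, simulate_cohort


@pytest.fixture(scope="session")
def feature_study():
    """Planted-feature cohort with four-regime PCA (shared; ~15 s to build)."""
    return planted_feature_study(seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """Small admixed cohort without features, for fast unit tests."""
    panel = random_panel(n_chrom=3, variants_per_chrom=40, fst=0.2, seed=np.random.default_rng(123))
    return simulate_cohort(
        panel, 400, admixture=AdmixtureModel(family="beta", a=3.0, b=1.3), seed=5
    )
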