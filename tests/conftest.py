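import pytest

from moodkit.latent import fit_mz_pca
from moodkit.synthetic import default_presets, generate_study


@pytest.fixture(scope="session")
def small_study():
    """Compact synthetic study: 3 cohorts x 5 participants x 60 days."""
    return generate_study(default_presets(seed=7, n_participants=5, n_days=60))


@pytest.fixture(scope="session")
def small_loadings(small_study):
    return fit_mz_pca(small_study.timelines)
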