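import pytest

from cognorm.sampler import SamplerConfig
from cognorm.synthetic_cohort import GeneratorConfig, generate_cohort_frame


@pytest.fixture(scope="session")
def reduced_sampler():
    """Short-chain sampler settings for test-speed fits."""
    return SamplerConfig(warmup_iters=500, sampling_iters=500, rhat_max=1.05)


@pytest.fixture(scope="session")
def cohort_frame():
    """One mid-sized synthetic cohort shared across tests (seeded)."""
    return generate_cohort_frame(GeneratorConfig(n=400, seed=7))


@pytest.fixture(scope="session")
def rvpa_fit(cohort_frame, reduced_sampler):
    """A converged beta-family fit reused by table/PPC tests."""
    from cognorm.bayes_glm import NormativeGLM

    model = NormativeGLM(cohort_frame, "RVPA")
    return model.fit(reduced_sampler, check_convergence=False)
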