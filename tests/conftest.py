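import numpy as np
import pytest

from camr.data_model import ModalityBlock, MultimodalCohort, SurvivalLabels
from camr.networks import CamrParameters, NetworkConfig
from camr.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def tiny_network_config() -> NetworkConfig:
    return NetworkConfig(
        input_dim=6, latent_dim=4,
        shared_encoder_widths=(8,), specific_encoder_widths=(8,),
        discriminator_widths=(5,), decoder_widths=(8,),
        survival_head_widths=(10, 6, 4, 3), fusion_rank=2,
    )


@pytest.fixture()
def tiny_params(tiny_network_config) -> CamrParameters:
    return CamrParameters(tiny_network_config, seed=42)


@pytest.fixture(scope="session")
def small_cohort() -> MultimodalCohort:
    """A 30-patient cohort with random features and ~30% censoring."""
    rng = np.random.default_rng(7)
    n, p = 30, 6
    blocks = {
        tag: ModalityBlock(tag, rng.standard_normal((n, p)),
                           [f"{tag}{j}" for j in range(p)])
        for tag in "PGC"
    }
    labels = SurvivalLabels(
        time=rng.exponential(100, n) + 1.0,
        event=(rng.random(n) > 0.3).astype(int),
        patient_ids=[f"S{i:03d}" for i in range(n)],
    )
    return MultimodalCohort(blocks, labels)


@pytest.fixture(scope="session")
def shift_cohort_with_truth():
    """The modality-gap cohort: n=300, offsets (0, +5, -5)."""
    cfg = SimulationConfig(n_patients=300, seed=3, modality_shift=(0.0, 5.0, -5.0))
    return simulate_cohort(cfg)


def random_labels(rng: np.random.Generator, n: int,
                  censor_frac: float = 0.3) -> SurvivalLabels:
    """Random survival labels with roughly the requested censoring level."""
    return SurvivalLabels(
        time=rng.exponential(50, n) + 0.5,
        event=(rng.random(n) > censor_frac).astype(int),
        patient_ids=[f"R{i:03d}" for i in range(n)],
    )
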