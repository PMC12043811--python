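import numpy as np
import pytest

from pca_triage import (
    DetectionConfig,
    OperatingCharacteristics,
    PhantomConfig,
    RadiologistModel,
)


@pytest.fixture
def small_config() -> PhantomConfig:
    """Compact phantom grid used by most generator tests."""
    return PhantomConfig(seed=11)


@pytest.fixture
def perfect_detector() -> OperatingCharacteristics:
    """Detects every aggressive lesion at confidence 0.9, no false positives."""
    return OperatingCharacteristics(
        sensitivity=1.0,
        fp_rate_inside=0.0,
        fp_rate_outside=0.0,
        confidence_min=0.9,
        confidence_max=0.9,
        seed=11,
    )


@pytest.fixture
def aggressive_only_config() -> PhantomConfig:
    """Every case carries exactly one aggressive lesion."""
    return PhantomConfig(
        lesion_count_probs=(0.0, 1.0, 0.0, 0.0, 0.0),
        isup_probs=(0.0, 0.0, 0.4, 0.3, 0.2, 0.1),
        seed=11,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def default_detection() -> DetectionConfig:
    return DetectionConfig()


@pytest.fixture
def radiologist() -> RadiologistModel:
    return RadiologistModel(sensitivity=0.9, specificity=0.4, seed=11)
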