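import numpy as np
import pytest

from warmsoil.datamodel import (
    MANAGEMENTS,
    WARMING_LEVELS,
    SampleMetadata,
    StudyDesign,
    plot_id_for,
)
from warmsoil.synthetic import DOMAINS, GeneratorConfig


def uniform_turnover(rho: float) -> dict[str, float]:
    return {
        f"{d}/{m}/{w}": rho for d in DOMAINS for m in MANAGEMENTS for w in WARMING_LEVELS
    }


def zero_drift() -> dict[str, float]:
    return {f"{d}/{m}": 0.0 for d in DOMAINS for m in MANAGEMENTS}


def small_config(seed: int = 0, **overrides) -> GeneratorConfig:
    defaults = dict(seed=seed, n_taxa=80, depth=2000)
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def single_treatment_design(
    years=(2010, 2012, 2014, 2016, 2018, 2020),
    blocks=(1, 2, 3),
    management="conservation",
    warming="ambient",
) -> StudyDesign:
    samples = [
        SampleMetadata(
            sample_id=f"s-b{b}-y{y}",
            plot_id=plot_id_for(management, warming, b),
            block=b,
            management=management,
            warming=warming,
            year=y,
        )
        for b in blocks
        for y in years
    ]
    return StudyDesign(samples=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
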