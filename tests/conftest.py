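import numpy as np
import pandas as pd
import pytest

from crowdscore.aggregation import aggregate_cores
from crowdscore.synthetic import (
    RaterModel,
    core_map_frame,
    generate_classifications,
    generate_cores,
    generate_expert_scores,
)


@pytest.fixture(scope="session")
def small_crowd():
    """A shared moderate-noise synthetic dataset: 100 patients x 2 cores,
    5 raters per central segment, 12% expert coverage."""
    cores = generate_cores(100, 2, marker_id="M1", seed=11)
    classifications = generate_classifications(
        cores,
        raters_per_segment=5,
        rater_model=RaterModel(),
        scheme=1,
        central_only=True,
        seed=12,
    )
    experts = generate_expert_scores(cores, 0.12, expert_noise_sd=2.0, seed=13)
    return {
        "cores": cores,
        "classifications": classifications,
        "experts": experts,
        "core_map": core_map_frame(cores),
        "scheme": 1,
    }


@pytest.fixture(scope="session")
def small_scores(small_crowd):
    return aggregate_cores(
        small_crowd["classifications"], small_crowd["scheme"], marker_id="M1"
    )
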