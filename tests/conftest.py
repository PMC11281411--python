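import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from momnet.synthio import SimConfig, generate_multiomics, generate_symptoms


@pytest.fixture(scope="session")
def small_run():
    """Default study-scale simulation (12 patients vs 8 controls)."""
    config = SimConfig(seed=3)
    tables, samples, truth = generate_multiomics(config)
    symptoms = generate_symptoms(config, truth)
    return config, tables, symptoms, truth


@pytest.fixture(scope="session")
def bench_run():
    """Structure-recovery benchmark: 60 samples per group, within-block
    Spearman 0.95, 3-log2 group effects, within-layer blocks."""
    config = SimConfig(
        n_case=60,
        n_control=60,
        rho_within=0.95,
        effect_log2fc=3.0,
        cross_layer=False,
        seed=11,
    )
    tables, samples, truth = generate_multiomics(config)
    return config, tables, samples, truth
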