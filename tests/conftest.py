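import numpy as np
import pytest

from neurosep import GeneratorConfig
from neurosep.pipeline import RunConfig, process_rendered_subject


def small_config(**overrides) -> GeneratorConfig:
    """Reduced-size session used where the full 1000-trial render is overkill."""
    defaults = dict(n_trials=120, n_channels=16, n_subjects=3, seed=7)
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def rendered_subject():
    """One subject pushed through the full render -> preprocess -> CCA ->
    features chain, with the ground-truth latents attached (session-scoped:
    rendering at 5 kHz is the expensive part of the suite)."""
    cfg = small_config()
    run = RunConfig(generator=cfg, seed=7)
    table = process_rendered_subject(run, subject_id=0, seed=42)
    return cfg, run, table
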